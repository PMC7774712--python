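"""Equilibrium base-pair probabilities via inside/outside recursions.

``partition_function`` folds a single RNA sequence under an
:class:`~mirtarsnp.rna_struct.energy.EnergyModel` and returns the full
base-pair probability matrix together with the partition function value.
``partition_Z`` runs the inside pass only, optionally with positions
constrained to stay unpaired — the primitive behind target-site
accessibility (opening probability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energy import EnergyModel, encode


@dataclass(frozen=True)
class BasePairProbMatrix:
    """Pair probabilities of one sequence under one energy model.

    Attributes
    ----------
    sequence : str
    P : (n, n) symmetric matrix, ``P[i, j]`` = probability that bases i
        and j form a pair in the thermodynamic ensemble.
    Z : partition function (Boltzmann sum over all structures; the open
        chain contributes 1).
    """

    sequence: str
    P: np.ndarray
    Z: float


def _tables(model: EnergyModel, n: int):
    eh, eb, ei, wcu = model.loop_weight_arrays(n)
    beta = 1.0 / model.kT
    sw = np.exp(-beta * model.stack)
    wa = float(np.exp(-beta * (0.0 if model.mode == "unit" else model.ml_a)))
    wb = float(np.exp(-beta * (0.0 if model.mode == "unit" else model.ml_b)))
    return eh, eb, ei, wcu, sw, wa, wb


def partition_function(
    seq: str,
    model: EnergyModel | None = None,
    unpaired_mask: np.ndarray | None = None,
) -> BasePairProbMatrix:
    """Fold ``seq`` and return its base-pair probability matrix."""
    model = model or EnergyModel.turner()
    idx = encode(seq)
    n = len(idx)
    if n == 0:
        raise ValueError("empty sequence")
    w, pt = model.pair_weight_matrix(idx, unpaired_mask)
    if n <= model.min_hairpin or not w.any():
        return BasePairProbMatrix(seq, np.zeros((n, n)), 1.0)
    eh, eb, ei, wcu, sw, wa, wb = _tables(model, n)
    q, qb, qm1, qm = _kernels.inside(
        w, pt, sw, eh, eb, ei, wcu, wa, wb, model.min_hairpin, model.max_loop
    )
    pb = _kernels.outside(
        q, qb, qm, w, pt, sw, eb, ei, wcu, wa, wb, model.min_hairpin, model.max_loop
    )
    p = pb + pb.T
    return BasePairProbMatrix(seq, p, float(q[0, n - 1]))


def partition_Z(
    seq: str,
    model: EnergyModel | None = None,
    unpaired_mask: np.ndarray | None = None,
) -> float:
    """Partition function only (inside pass), with optional unpaired
    constraints: positions where ``unpaired_mask`` is True cannot pair."""
    model = model or EnergyModel.turner()
    idx = encode(seq)
    n = len(idx)
    if n == 0:
        raise ValueError("empty sequence")
    w, pt = model.pair_weight_matrix(idx, unpaired_mask)
    if n <= model.min_hairpin or not w.any():
        return 1.0
    eh, eb, ei, wcu, sw, wa, wb = _tables(model, n)
    q, _, _, _ = _kernels.inside(
        w, pt, sw, eh, eb, ei, wcu, wa, wb, model.min_hairpin, model.max_loop
    )
    return float(q[0, n - 1])
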