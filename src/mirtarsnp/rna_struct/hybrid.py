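"""miRNA:mRNA duplex stability (RNAhybrid-style intermolecular MFE).

The duplex dynamic program considers antiparallel intermolecular base
pairs only (no intramolecular structure on either strand): consecutive
pairs either stack or are separated by bulge/internal loops capped at
``duplex_max_bulge`` nt per side.  The reported free energy includes a
duplex-initiation term; when no legal configuration is stable
(best energy > 0) or no pair is possible at all, the sentinel value 0 is
returned with the ``no_hybrid`` flag set.

ddG_hybrid = dG(ALT) - dG(WT); positive values mean the variant allele
destabilises the hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energy import PAIR_TYPE, EnergyModel, encode


@dataclass(frozen=True)
class HybridScore:
    dg: float            # reported energy (kcal/mol; 0 when no_hybrid)
    no_hybrid: bool
    dg_raw: float | None  # unclamped DP optimum, None when no pair exists


@dataclass(frozen=True)
class HybridResult:
    dg_wt: float
    dg_alt: float
    ddg: float
    no_hybrid_wt: bool
    no_hybrid_alt: bool


def hybrid_mfe(mirna_seq: str, target_seq: str,
               model: EnergyModel | None = None) -> HybridScore:
    """Minimum free energy of the miRNA:target duplex (both 5'->3')."""
    model = model or EnergyModel.turner()
    if not mirna_seq or not target_seq:
        raise ValueError("sequences must be non-empty")
    if len(target_seq) > 2000:
        raise ValueError("target longer than 2000 nt")
    m = encode(mirna_seq)
    t = encode(target_seq)
    cap = model.duplex_max_bulge
    be, ie = model.loop_energy_arrays(2 * cap)
    found, e = _kernels.duplex_mfe(
        m, t, PAIR_TYPE, model.stack.astype(np.float64), be, ie,
        model.duplex_init, cap,
    )
    if not found:
        return HybridScore(0.0, True, None)
    if e > 0.0:
        return HybridScore(0.0, True, float(e))
    return HybridScore(float(e), False, float(e))


def ddg_hybrid(mirna_seq: str, wt_context: str, alt_context: str,
               model: EnergyModel | None = None) -> HybridResult:
    """Change in duplex stability imposed by the variant allele."""
    wt = hybrid_mfe(mirna_seq, wt_context, model)
    alt = hybrid_mfe(mirna_seq, alt_context, model)
    return HybridResult(
        dg_wt=wt.dg,
        dg_alt=alt.dg,
        ddg=alt.dg - wt.dg,
        no_hybrid_wt=wt.no_hybrid,
        no_hybrid_alt=alt.no_hybrid,
    )
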