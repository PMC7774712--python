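"""Nearest-neighbor energy model for RNA secondary structure and duplexes.

The model assigns a free energy (kcal/mol) to a pseudoknot-free secondary
structure through the standard loop decomposition:

* stacked pair steps get a stacking energy from a Turner-style table,
* hairpin, bulge and internal loops get length-dependent penalties
  (tabulated for small loops, Jacobson-Stockmayer logarithmic extrapolation
  beyond the table),
* multibranch loops get a linear ``a + b * branches + c * unpaired`` cost,
* every base pair may additionally carry a per-pair energy (zero in the
  nearest-neighbor mode; this term carries the whole energy in unit mode).

Two modes are provided.  ``nearest_neighbor`` (the default) embeds
approximate Turner 2004 constants; exact agreement with any third-party
folding tool is explicitly not promised — the model is instead validated
against exhaustive Boltzmann enumeration in the test suite.  ``unit`` mode
assigns a constant energy per pair and no loop terms, which makes hand
enumeration trivial; it exists for oracle tests.

Bases are encoded A=0, C=1, G=2, U=3.  Pair types are indexed
AU=0, UA=1, GC=2, CG=3, GU=4, UG=5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: pair-type index for (5' base, 3' base); -1 = not pairable
PAIR_TYPE = -np.ones((4, 4), dtype=np.int8)
_PAIRS = ["AU", "UA", "GC", "CG", "GU", "UG"]
for _t, _p in enumerate(_PAIRS):
    PAIR_TYPE[BASE_INDEX[_p[0]], BASE_INDEX[_p[1]]] = _t

#: reversed pair type (the same pair read from the other strand)
_REV_TYPE = np.array([1, 0, 3, 2, 5, 4], dtype=np.int8)

# Watson-Crick / Watson-Crick stack energies, kcal/mol at 37 C,
# keyed by (5'-side pair, 3'-side pair).  Turner 2004 values.
_WC_STACKS = {
    ("AU", "AU"): -0.93, ("AU", "UA"): -1.10, ("AU", "GC"): -2.08,
    ("AU", "CG"): -2.24, ("UA", "AU"): -1.33, ("UA", "UA"): -0.93,
    ("UA", "GC"): -2.11, ("UA", "CG"): -2.35, ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24, ("GC", "GC"): -3.26, ("GC", "CG"): -3.42,
    ("CG", "AU"): -2.11, ("CG", "UA"): -2.08, ("CG", "GC"): -2.36,
    ("CG", "CG"): -3.26,
}
# Wobble-containing stacks: class averages rather than the full published
# table (adequate for ranking; enumeration oracle uses the same values).
_GU_STACK_ONE = -1.3
_GU_STACK_TWO = -0.5

_HAIRPIN_TAB = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_TAB = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_TAB = {2: 1.5, 3: 1.6, 4: 1.7, 5: 2.0, 6: 2.0}
_JS_COEF = 1.75  # Jacobson-Stockmayer prefactor (times kT)

KT37 = 0.6156  # kcal/mol at 37 C


def _build_stack_table() -> np.ndarray:
    table = np.zeros((6, 6))
    for t1, p1 in enumerate(_PAIRS):
        for t2, p2 in enumerate(_PAIRS):
            n_gu = (p1 in ("GU", "UG")) + (p2 in ("GU", "UG"))
            if n_gu == 0:
                table[t1, t2] = _WC_STACKS[(p1, p2)]
            elif n_gu == 1:
                table[t1, t2] = _GU_STACK_ONE
            else:
                table[t1, t2] = _GU_STACK_TWO
    # a helix step must read the same from either strand
    for t1 in range(6):
        for t2 in range(6):
            assert table[t1, t2] == table[_REV_TYPE[t2], _REV_TYPE[t1]]
    return table


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains a character outside A/C/G/U."""


def encode(seq: str) -> np.ndarray:
    """Encode an RNA string as an int8 array, rejecting bad characters."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        idx = BASE_INDEX.get(ch)
        if idx is None:
            raise InvalidSequenceError(
                f"invalid character {ch!r} at position {i}; expected A/C/G/U"
            )
        out[i] = idx
    return out


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class EnergyModel:
    """Energy parameters for folding and duplex dynamic programs.

    Parameters are plain data so that a model instance fully determines
    every computed quantity; all kernels receive numeric tables derived
    from it and nothing else.
    """

    mode: str = "nearest_neighbor"
    kT: float = KT37
    min_hairpin: int = 3
    max_loop: int = 30          # intramolecular interior/bulge cap (total nt)
    duplex_max_bulge: int = 15  # duplex cap, nt per side
    duplex_init: float = 4.09
    pair_energy: tuple = (0.0,) * 6     # per-pair term, by pair type
    ml_a: float = 3.4
    ml_b: float = 0.4
    ml_c: float = 0.0
    _stack: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        if self._stack is None:
            stack = (
                _build_stack_table()
                if self.mode == "nearest_neighbor"
                else np.zeros((6, 6))
            )
            object.__setattr__(self, "_stack", stack)

    # -- factory -----------------------------------------------------------
    @classmethod
    def turner(cls) -> "EnergyModel":
        """Default nearest-neighbor model (Turner-style constants)."""
        return cls()

    @classmethod
    def unit(cls, pair_energy: float = -1.0, kT: float = 0.6) -> "EnergyModel":
        """Constant-energy-per-pair model used by enumeration oracles."""
        return cls(mode="unit", kT=kT, pair_energy=(pair_energy,) * 6)

    # -- energies ----------------------------------------------------------
    @property
    def stack(self) -> np.ndarray:
        return self._stack

    def stack_energy(self, outer_type: int, inner_type: int) -> float:
        return float(self._stack[outer_type, inner_type])

    def hairpin_energy(self, u: int) -> float:
        if self.mode == "unit":
            return 0.0
        if u in _HAIRPIN_TAB:
            return _HAIRPIN_TAB[u]
        return _HAIRPIN_TAB[9] + _JS_COEF * self.kT * math.log(u / 9.0)

    def bulge_energy(self, u: int) -> float:
        if self.mode == "unit":
            return 0.0
        if u in _BULGE_TAB:
            return _BULGE_TAB[u]
        return _BULGE_TAB[6] + _JS_COEF * self.kT * math.log(u / 6.0)

    def internal_energy(self, u: int) -> float:
        if self.mode == "unit":
            return 0.0
        if u in _INTERNAL_TAB:
            return _INTERNAL_TAB[u]
        return _INTERNAL_TAB[6] + _JS_COEF * self.kT * math.log(u / 6.0)

    def multiloop_energy(self, branches: int, unpaired: int) -> float:
        if self.mode == "unit":
            return 0.0
        return self.ml_a + self.ml_b * branches + self.ml_c * unpaired

    # -- derived tables for the kernels -----------------------------------
    def loop_weight_arrays(self, n: int):
        """Boltzmann factors e^(-E/kT) for loop penalties up to size n."""
        beta = 1.0 / self.kT
        u = np.arange(n + 2)
        eh = np.ones(n + 2)
        eb = np.ones(n + 2)
        ei = np.ones(n + 2)
        for k in range(3, n + 2):
            eh[k] = math.exp(-beta * self.hairpin_energy(k))
        for k in range(1, n + 2):
            eb[k] = math.exp(-beta * self.bulge_energy(k))
        for k in range(2, n + 2):
            ei[k] = math.exp(-beta * self.internal_energy(k))
        wcu = np.exp(-beta * self.ml_c * u) if self.mode != "unit" else np.ones(n + 2)
        return eh, eb, ei, wcu

    def loop_energy_arrays(self, cap: int):
        """Plain-energy penalty arrays (for MFE duplex DP)."""
        be = np.zeros(cap + 1)
        ie = np.zeros(cap + 1)
        for k in range(1, cap + 1):
            be[k] = self.bulge_energy(k)
        for k in range(2, cap + 1):
            ie[k] = self.internal_energy(k)
        return be, ie

    def pair_weight_matrix(self, idx: np.ndarray,
                           unpaired_mask: np.ndarray | None = None):
        """(W, PT) for a sequence: Boltzmann pair weights and pair types.

        ``unpaired_mask`` marks positions that are forced single-stranded
        (used for accessibility constraints).
        """
        n = len(idx)
        pt = PAIR_TYPE[idx[:, None], idx[None, :]].copy()
        w = np.zeros((n, n))
        beta = 1.0 / self.kT
        epair = np.array(self.pair_energy)
        ii, jj = np.nonzero(pt >= 0)
        keep = jj - ii > self.min_hairpin
        ii, jj = ii[keep], jj[keep]
        w[ii, jj] = np.exp(-beta * epair[pt[ii, jj]])
        if unpaired_mask is not None:
            w[unpaired_mask, :] = 0.0
            w[:, unpaired_mask] = 0.0
        return w, pt
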