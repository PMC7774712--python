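"""Target-site accessibility: probability that the whole site is unpaired.

Pu = Z_constrained / Z, where Z_constrained forces every site position to
stay single-stranded; this is the equilibrium probability that a miRNA
finds its entire binding site open.  The fold is local: a window of the
context centred on the site (site +/- ``acc_flank`` nt, clamped).

delta_pu_pct = 100 * (Pu_alt - Pu_wt): negative values mean the variant
allele reduces accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energy import EnergyModel
from .partition import partition_Z


@dataclass(frozen=True)
class AccessibilityResult:
    pu_wt: float
    pu_alt: float
    delta_pu_pct: float


def _site_pu(context: str, site: tuple, model: EnergyModel,
             acc_flank: int) -> float:
    n = len(context)
    s, e = site
    a = max(0, s - acc_flank)
    b = min(n, e + acc_flank)
    window = context[a:b]
    mask = np.zeros(len(window), dtype=bool)
    mask[s - a:e - a] = True
    z = partition_Z(window, model)
    zc = partition_Z(window, model, unpaired_mask=mask)
    return zc / z


def accessibility(
    wt_context: str,
    alt_context: str,
    site: tuple,
    model: EnergyModel | None = None,
    acc_flank: int = 50,
) -> AccessibilityResult:
    """Opening probability of ``site`` (half-open context coords) for the
    wild-type and variant contexts, and the change in percentage points."""
    model = model or EnergyModel.turner()
    s, e = site
    if not (0 <= s < e <= len(wt_context)):
        raise ValueError(f"site {site} outside context of length {len(wt_context)}")
    if len(wt_context) != len(alt_context):
        raise ValueError("wt and alt contexts must have equal length")
    pu_wt = _site_pu(wt_context, site, model, acc_flank)
    pu_alt = _site_pu(alt_context, site, model, acc_flank)
    return AccessibilityResult(pu_wt, pu_alt, 100.0 * (pu_alt - pu_wt))
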