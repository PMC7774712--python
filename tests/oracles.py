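"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic programs: secondary
structures are enumerated exhaustively and weighted by the same loop-based
energy function (evaluated through the EnergyModel's scalar energy
accessors), and duplex configurations are enumerated by explicit chain
recursion.  Feasible for sequences up to ~16 nt.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from mirtarsnp.rna_struct.energy import PAIR_TYPE, EnergyModel, encode


def enumerate_structures(seq: str, model: EnergyModel):
    """All pseudoknot-free pair sets over ``seq`` (no loop-size screening)."""
    idx = encode(seq)
    n = len(idx)
    mh = model.min_hairpin

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if i >= j:
            return [()]
        out = list(rec(i + 1, j))
        for k in range(i + mh + 1, j + 1):
            if PAIR_TYPE[idx[i], idx[k]] >= 0:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        out.append(((i, k),) + left + right)
        return out

    return rec(0, n - 1)


def structure_energy(seq: str, pairs, model: EnergyModel):
    """Loop-decomposition energy of one structure; None if the structure
    contains an interior/bulge loop larger than the model cap."""
    idx = encode(seq)
    ptype = {p: int(PAIR_TYPE[idx[p[0]], idx[p[1]]]) for p in pairs}
    # parent of each pair = smallest enclosing pair
    parent = {}
    for p in pairs:
        best = None
        for q in pairs:
            if q is not p and q[0] < p[0] and p[1] < q[1]:
                if best is None or (q[1] - q[0]) < (best[1] - best[0]):
                    best = q
        parent[p] = best
    children = {p: [] for p in pairs}
    for p, par in parent.items():
        if par is not None:
            children[par].append(p)
    e = 0.0
    for (i, j) in pairs:
        e += model.pair_energy[ptype[(i, j)]]
        ch = sorted(children[(i, j)])
        if not ch:
            e += model.hairpin_energy(j - i - 1)
        elif len(ch) == 1:
            (k, l) = ch[0]
            u1, u2 = k - i - 1, j - l - 1
            if u1 == 0 and u2 == 0:
                e += model.stack_energy(ptype[(i, j)], ptype[(k, l)])
            else:
                if u1 + u2 > model.max_loop:
                    return None
                if u1 == 0 or u2 == 0:
                    e += model.bulge_energy(u1 + u2)
                else:
                    e += model.internal_energy(u1 + u2)
        else:
            span = sum(l - k + 1 for (k, l) in ch)
            e += model.multiloop_energy(len(ch), (j - i - 1) - span)
    return e


def bpp_by_enumeration(seq: str, model: EnergyModel):
    """(P, Z) by exhaustive Boltzmann summation."""
    n = len(seq)
    beta = 1.0 / model.kT
    z = 0.0
    num = np.zeros((n, n))
    for pairs in enumerate_structures(seq, model):
        e = structure_energy(seq, pairs, model)
        if e is None:
            continue
        w = np.exp(-beta * e)
        z += w
        for (i, j) in pairs:
            num[i, j] += w
            num[j, i] += w
    return num / z, z


def duplex_mfe_by_enumeration(mirna: str, target: str, model: EnergyModel):
    """Best duplex energy by explicit chain enumeration (None: no pair)."""
    m = encode(mirna)
    t = encode(target)
    cap = model.duplex_max_bulge
    best = [None]

    def note(e):
        if best[0] is None or e < best[0]:
            best[0] = e

    def extend(i, j, e):
        note(e)
        for i2 in range(i + 1, min(len(m), i + cap + 2)):
            u1 = i2 - i - 1
            for j2 in range(max(0, j - cap - 1), j):
                if PAIR_TYPE[m[i2], t[j2]] < 0:
                    continue
                u2 = j - j2 - 1
                if u1 == 0 and u2 == 0:
                    cost = model.stack_energy(
                        int(PAIR_TYPE[m[i], t[j]]), int(PAIR_TYPE[m[i2], t[j2]])
                    )
                elif u1 == 0 or u2 == 0:
                    cost = model.bulge_energy(u1 + u2)
                else:
                    cost = model.internal_energy(u1 + u2)
                extend(i2, j2, e + cost)

    for i in range(len(m)):
        for j in range(len(t)):
            if PAIR_TYPE[m[i], t[j]] >= 0:
                extend(i, j, model.duplex_init)
    return best[0]


def random_rna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.random.default_rng(rng.integers(2**31)).choice(
        list("ACGU"), size=length, p=p))
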