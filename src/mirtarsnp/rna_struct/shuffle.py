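"""Dinucleotide-preserving sequence shuffling (Altschul-Erickson).

The standard null for RNA-structure statistics: a shuffle that preserves
the exact dinucleotide counts (and hence the first and last base) of the
input.  Implemented as a random Eulerian walk on the dinucleotide
multigraph; the per-vertex "last edges" are resampled until they form an
arborescence into the final base, which guarantees the walk is Eulerian.
"""

from __future__ import annotations

import numpy as np


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Return a random dinucleotide-preserving shuffle of ``seq``."""
    n = len(seq)
    if n <= 3:
        return seq
    chars = list(seq)
    adj: dict[str, list[str]] = {}
    for a, b in zip(chars, chars[1:]):
        adj.setdefault(a, []).append(b)
    adj.setdefault(chars[-1], [])
    root = chars[-1]
    verts = [v for v in adj if v != root and adj[v]]
    if not verts:
        return seq

    # sample last-edge choices until they form an arborescence into root;
    # one always exists (the original walk's last exits), so this terminates
    while True:
        last_edge = {v: adj[v][rng.integers(len(adj[v]))] for v in verts}
        ok = True
        for v in verts:
            cur = v
            for _ in range(len(verts) + 1):
                if cur == root:
                    break
                cur = last_edge[cur]
            else:
                ok = False
            if not ok:
                break
        if ok:
            break

    lists: dict[str, list[str]] = {}
    for v, edges in adj.items():
        pool = list(edges)
        if v in last_edge:
            pool.remove(last_edge[v])
        order = rng.permutation(len(pool))
        shuffled = [pool[k] for k in order]
        if v in last_edge:
            shuffled.append(last_edge[v])
        lists[v] = shuffled

    out = [chars[0]]
    ptr = {v: 0 for v in adj}
    cur = chars[0]
    while len(out) < n:
        nxt = lists[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)
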