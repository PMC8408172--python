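"""Independent brute-force oracles, kept deliberately naive.

These re-derive the quantities the library computes by exhaustive
enumeration so the two routes share no code.
"""

from __future__ import annotations

from itertools import product

import networkx as nx
import numpy as np

MISSING = -1


def _alleles(g):
    return {int(a) for a in g if a != MISSING}


def marker_state_oracle(ga, gb) -> int:
    """+1 match / -1 mismatch / 0 uninformative for one marker pair."""
    sa, sb = _alleles(ga), _alleles(gb)
    if sa & sb:
        return 1
    if len(ga) == 2 and len(gb) == 2 and MISSING not in set(map(int, ga)) | set(map(int, gb)):
        return -1
    return 0


def shared_segments_oracle(a, b, chrom, pos, min_length=0.0):
    """All maximal MATCH-bounded, MISMATCH-free index intervals, by checking
    every candidate (i, j) pair exhaustively.  Returns (i, j) index tuples of
    segments with cM length >= min_length."""
    n = len(pos)
    states = [marker_state_oracle(a[i], b[i]) for i in range(n)]

    def valid(i, j):
        if chrom[i] != chrom[j]:
            return False
        if states[i] != 1 or states[j] != 1:
            return False
        return all(states[k] != -1 for k in range(i, j + 1))

    candidates = [(i, j) for i in range(n) for j in range(i, n) if valid(i, j)]
    maximal = [
        (i, j)
        for (i, j) in candidates
        if not any((p <= i and j <= q and (p, q) != (i, j)) for (p, q) in candidates)
    ]
    return [(i, j) for (i, j) in maximal if pos[j] - pos[i] >= min_length]


def kinship_path_oracle(parents: dict, a: str, b: str) -> float:
    """Kinship by exhaustive path-pair enumeration (founders unrelated,
    non-inbred).  Only valid for pedigrees whose common ancestors are
    non-inbred founders-or-derived with f computed recursively here too."""
    g = nx.DiGraph()
    for child, (p1, p2) in parents.items():
        for p in (p1, p2):
            if p is not None:
                g.add_edge(p, child)
    g.add_nodes_from(parents)

    def inbreeding(x):
        p1, p2 = parents.get(x, (None, None))
        if p1 is None or p2 is None:
            return 0.0
        return kinship_path_oracle(parents, p1, p2)

    if a == b:
        return 0.5 * (1.0 + inbreeding(a))
    total = 0.0
    for anc in g.nodes:
        paths_a = (
            [[anc]]
            if anc == a
            else list(nx.all_simple_paths(g, anc, a))
        )
        paths_b = (
            [[anc]]
            if anc == b
            else list(nx.all_simple_paths(g, anc, b))
        )
        for pa, pb in product(paths_a, paths_b):
            # path pair must share only the common ancestor
            if set(pa) & set(pb) != {anc}:
                continue
            n_links = (len(pa) - 1) + (len(pb) - 1)
            total += 0.5 ** (n_links + 1) * (1.0 + inbreeding(anc))
    return total


def cre_counting_oracle(pools: dict[str, np.ndarray], query: float, window: float):
    counts = {l: int(sum(abs(v - query) <= window for v in pool)) for l, pool in pools.items()}
    tot = sum(counts.values())
    if tot == 0:
        return None
    return {l: c / tot for l, c in counts.items()}
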