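"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route independent of the library
implementation (exhaustive enumeration, recursive search, combinatorial
counting) so agreement is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np


# ---------------------------------------------------------------------------
# Modularity: exhaustive maximum over all set partitions
# ---------------------------------------------------------------------------

def all_set_partitions(n: int):
    """Every partition of n items as a restricted-growth label tuple."""
    def rec(prefix, mx):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))
    yield from rec([], -1)


def modularity_of_labels(edges: dict[tuple[int, int], float],
                         labels: Sequence[int]) -> float:
    """Newman weighted modularity computed directly from the definition."""
    W = sum(edges.values())
    if W == 0:
        return 0.0
    intra: dict[int, float] = {}
    deg: dict[int, float] = {}
    for (i, j), w in edges.items():
        deg[labels[i]] = deg.get(labels[i], 0.0) + w
        deg[labels[j]] = deg.get(labels[j], 0.0) + w
        if labels[i] == labels[j]:
            intra[labels[i]] = intra.get(labels[i], 0.0) + w
    return sum(intra.get(c, 0.0) / W - (deg[c] / (2 * W)) ** 2 for c in deg)


def exhaustive_max_modularity(n: int,
                              edges: dict[tuple[int, int], float]) -> float:
    best = -1.0
    for labels in all_set_partitions(n):
        best = max(best, modularity_of_labels(edges, labels))
    return best


# ---------------------------------------------------------------------------
# Microsynteny: exhaustive enumeration of maximal colinear chains
# ---------------------------------------------------------------------------

def _valid_step(m1, m2, direction: int, gap: int) -> bool:
    # match layout: (og, chrom_a, ord_a, chrom_b, ord_b, ...)
    if m1[1] != m2[1] or m1[3] != m2[3]:
        return False
    oa1, ob1, oa2, ob2 = m1[2], m1[4], m2[2], m2[4]
    if oa2 <= oa1 or oa2 - oa1 - 1 > gap:
        return False
    if direction > 0:
        return ob2 > ob1 and ob2 - ob1 - 1 <= gap
    return ob2 < ob1 and ob1 - ob2 - 1 <= gap


def enumerate_maximal_chains(matches, gap: int):
    """All maximal colinear chains over ``matches``.

    Each match is (og, chrom_a, ord_a, chrom_b, ord_b, gene_a, gene_b) —
    chromosome names included so cross-chromosome steps are invalid.  A chain
    is maximal when no match in the pool can extend it at either end.
    """
    sm = [(m[0], m[1], m[2], m[3], m[4]) for m in matches]
    out = []
    n = len(sm)
    for direction in (+1, -1):
        def succs(i):
            return [j for j in range(n) if _valid_step(sm[i], sm[j], direction, gap)]

        def preds(i):
            return [j for j in range(n) if _valid_step(sm[j], sm[i], direction, gap)]

        def dfs(chain):
            nxt = succs(chain[-1])
            if not nxt:
                if not preds(chain[0]):
                    out.append((direction, tuple(chain)))
                return
            for j in nxt:
                dfs(chain + [j])

        for i in range(n):
            if not preds(i):
                dfs([i])
    # dedupe: a strictly-increasing-B 2-chain never appears under direction -1,
    # but identical chains can arise if ord_b pattern is degenerate; use set
    seen = set()
    chains = []
    for direction, chain in out:
        if len(chain) < 2:
            continue
        if chain in seen:
            continue
        seen.add(chain)
        chains.append([matches[i] for i in chain])
    return chains


def chain_key(chain) -> tuple:
    return (-len(chain), chain[0][1], chain[0][3],
            tuple((m[2], m[4]) for m in chain))


def greedy_blocks_bruteforce(matches, gap: int, min_len: int):
    """Reference block extraction: repeatedly enumerate ALL maximal chains
    over the unused matches and take the minimum-key (longest-first) one."""
    pool = list(matches)
    blocks = []
    while True:
        chains = [c for c in enumerate_maximal_chains(pool, gap)
                  if len(c) >= min_len]
        if not chains:
            break
        best = min(chains, key=chain_key)
        blocks.append(best)
        used_a = {m[5] for m in best}
        used_b = {m[6] for m in best}
        pool = [m for m in pool if m[5] not in used_a and m[6] not in used_b]
    return blocks


# ---------------------------------------------------------------------------
# Mann-Whitney U: full enumeration with midranks
# ---------------------------------------------------------------------------

def mwu_exact_bruteforce(a: Sequence[float], b: Sequence[float]
                         ) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating every assignment of the
    pooled values to the two groups, using the rank-sum formulation with
    midranks (independent of the pairwise-comparison implementation)."""
    from scipy.stats import rankdata

    a = list(map(float, a))
    b = list(map(float, b))
    n, m = len(a), len(b)
    pooled = np.array(a + b)
    ranks = rankdata(pooled)

    def u_of(sel: tuple[int, ...]) -> float:
        r = sum(ranks[list(sel)])
        return r - n * (n + 1) / 2.0

    u_obs = u_of(tuple(range(n)))
    centre = n * m / 2.0
    dev = abs(u_obs - centre)
    hits = total = 0
    for sel in itertools.combinations(range(n + m), n):
        total += 1
        if abs(u_of(sel) - centre) >= dev - 1e-12:
            hits += 1
    return u_obs, hits / total
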