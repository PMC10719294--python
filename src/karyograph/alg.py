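"""Ancestral linkage group inference.

Orthogroups are the nodes of a weighted graph; two orthogroups are linked when
they occur on the same chromosome (or scaffold) in a species, the edge weight
counting the supporting species.  Consensus community detection with the
Leiden algorithm over this graph yields ancestral linkage groups (ALGs):
groups of orthogroups with high chromosomal linkage within and low linkage
between, i.e. a partition maximizing weighted modularity.  A resolution sweep
evaluates alternative ALG-count scenarios and the max-modularity scenario is
selected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import igraph as ig
import leidenalg
import numpy as np

from .io import GenomeAnnotation, OrthogroupTable

MAX_CONSENSUS_ITERATIONS = 50
TINY_COMMUNITY_FRACTION = 0.01


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def place_orthogroups(table: OrthogroupTable,
                      annotations: Mapping[str, GenomeAnnotation]
                      ) -> dict[str, dict[str, str | None]]:
    """Per species, assign each orthogroup to the chromosome holding a strict
    plurality of its member genes; plurality ties give ``None`` (unplaced).
    Orthogroups with no gene in a species are simply absent from that
    species' map."""
    placements: dict[str, dict[str, str | None]] = {}
    for sp, ann in annotations.items():
        if sp not in table.species:
            continue
        sp_map: dict[str, str | None] = {}
        for og, row in table.entries.items():
            gids = row.get(sp, [])
            if not gids:
                continue
            counts: dict[str, int] = {}
            for gid in gids:
                if gid not in ann:
                    raise KeyError(
                        f"gene {gid!r} of {og} absent from annotation {sp}"
                    )
                chrom = ann.gene(gid).chrom
                counts[chrom] = counts.get(chrom, 0) + 1
            top = max(counts.values())
            winners = [c for c, n in counts.items() if n == top]
            sp_map[og] = winners[0] if len(winners) == 1 else None
        placements[sp] = sp_map
    return placements


@dataclass
class LinkageGraph:
    """Weighted undirected orthogroup co-linkage graph (no self loops)."""

    nodes: list[str]
    edges: dict[tuple[int, int], int]  # (i, j) with i < j -> species support

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=len(self.nodes), edges=list(self.edges.keys()))
        g.es["weight"] = [float(w) for w in self.edges.values()]
        g.vs["name"] = self.nodes
        return g

    def write_edges(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("orthogroup_u\torthogroup_v\tweight\n")
            for (i, j) in sorted(self.edges, key=lambda e: (self.nodes[e[0]],
                                                            self.nodes[e[1]])):
                fh.write(f"{self.nodes[i]}\t{self.nodes[j]}\t{self.edges[(i, j)]}\n")


def build_linkage_graph(placements: Mapping[str, Mapping[str, str | None]],
                        min_support: int = 2) -> LinkageGraph:
    """Edge weight = number of species in which both orthogroups are placed on
    the same chromosome; edges below ``min_support`` are dropped, isolated
    nodes retained."""
    if len(placements) < 2:
        raise ValueError("need placements from >= 2 species")
    node_set: set[str] = set()
    for sp_map in placements.values():
        node_set.update(sp_map.keys())
    nodes = sorted(node_set)
    index = {og: i for i, og in enumerate(nodes)}

    weights: dict[tuple[int, int], int] = {}
    for sp in sorted(placements):
        groups: dict[str, list[int]] = {}
        for og, chrom in placements[sp].items():
            if chrom is not None:
                groups.setdefault(chrom, []).append(index[og])
        for members in groups.values():
            members.sort()
            for a, b in itertools.combinations(members, 2):
                weights[(a, b)] = weights.get((a, b), 0) + 1

    edges = {e: w for e, w in weights.items() if w >= min_support}
    return LinkageGraph(nodes, edges)


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def modularity(graph: LinkageGraph, partition: Mapping[str, object],
               resolution: float = 1.0) -> float:
    """Newman weighted modularity with a resolution multiplier gamma:

        Q = sum_c [ W_c / W  -  gamma * (S_c / 2W)^2 ]

    with W the total edge weight, W_c the intra-community weight and S_c the
    community degree-weight sum.  Empty graphs score 0."""
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise KeyError(f"partition misses {len(missing)} nodes, e.g. {missing[0]!r}")
    if not graph.edges:
        return 0.0
    W = float(sum(graph.edges.values()))
    intra: dict[object, float] = {}
    degree: dict[object, float] = {}
    for (i, j), w in graph.edges.items():
        ci, cj = partition[graph.nodes[i]], partition[graph.nodes[j]]
        degree[ci] = degree.get(ci, 0.0) + w
        degree[cj] = degree.get(cj, 0.0) + w
        if ci == cj:
            intra[ci] = intra.get(ci, 0.0) + w
    q = 0.0
    for c in degree:
        q += intra.get(c, 0.0) / W - resolution * (degree[c] / (2.0 * W)) ** 2
    return q


# ---------------------------------------------------------------------------
# Consensus Leiden
# ---------------------------------------------------------------------------

@dataclass
class ALGPartition:
    assignment: dict[str, int]
    n_algs: int
    modularity: float
    resolution: float
    stability: float
    n_communities: int = 0

    def labels_for(self, nodes: Sequence[str]) -> list[int]:
        return [self.assignment[n] for n in nodes]

    def members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for og, lab in self.assignment.items():
            out.setdefault(lab, set()).add(og)
        return out

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("orthogroup\talg\n")
            for og in sorted(self.assignment):
                fh.write(f"{og}\t{self.assignment[og]}\n")


def _derived_seed(seed: int, *key) -> int:
    entropy = [int(seed)] + [
        int.from_bytes(str(k).encode(), "little") % (2**32) for k in key
    ]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31 - 1))


def _leiden_runs(g: ig.Graph, resolution: float, n_runs: int, seed: int,
                 stage: object) -> np.ndarray:
    """n_runs Leiden optimizations with distinct derived seeds; returns the
    (n_runs, n_nodes) membership matrix.

    The ensemble alternates the optimiser's node-move strategy between the
    greedy default and stochastic neighbour-community selection: the greedy
    moves converge fast, while the stochastic runs escape local optima the
    greedy trajectory cannot leave, which matters on small dense graphs."""
    memberships = np.empty((n_runs, g.vcount()), dtype=np.int32)
    weights = g.es["weight"] if g.ecount() else None
    for r in range(n_runs):
        run_seed = _derived_seed(seed, stage, r)
        if r % 2 == 0:
            part = leidenalg.find_partition(
                g, leidenalg.RBConfigurationVertexPartition,
                weights=weights, resolution_parameter=resolution,
                seed=run_seed, n_iterations=-1,
            )
        else:
            part = leidenalg.RBConfigurationVertexPartition(
                g, weights=weights, resolution_parameter=resolution)
            opt = leidenalg.Optimiser()
            opt.set_rng_seed(run_seed)
            opt.consider_comms = leidenalg.RAND_NEIGH_COMM
            opt.optimise_partition(part, n_iterations=-1)
        memberships[r] = part.membership
    return memberships


def _coassignment(memberships: np.ndarray) -> np.ndarray:
    n_runs, n = memberships.shape
    freq = np.zeros((n, n), dtype=np.float64)
    for r in range(n_runs):
        m = memberships[r]
        freq += (m[:, None] == m[None, :])
    return freq / n_runs


def _canonical(memb: np.ndarray) -> tuple:
    """Label-invariant canonical form of a membership vector."""
    remap: dict[int, int] = {}
    out = []
    for x in memb.tolist():
        if x not in remap:
            remap[x] = len(remap)
        out.append(remap[x])
    return tuple(out)


def consensus_communities(graph: LinkageGraph, resolution: float = 1.0,
                          n_runs: int = 100, co_threshold: float = 0.5,
                          seed: int = 0) -> ALGPartition:
    """Consensus community detection (Lancichinetti-Fortunato style).

    ``n_runs`` Leiden optimizations at the given resolution are summarized in
    a co-assignment frequency matrix; frequencies >= ``co_threshold`` define a
    consensus graph on which Leiden is re-applied, iterating until two
    consecutive iterations produce the identical partition.  Reported
    modularity is plain (resolution 1) weighted modularity on the original
    graph; stability is the expected agreement of two independent runs on a
    random node pair, from the first-round co-assignment frequencies.
    """
    if graph.n_nodes == 0:
        raise ValueError("graph is empty")
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")

    g0 = graph.to_igraph()
    n = graph.n_nodes

    if graph.n_edges == 0:
        assignment = {node: i for i, node in enumerate(graph.nodes)}
        return ALGPartition(assignment, n_algs=_count_major(assignment, n),
                            modularity=0.0, resolution=resolution,
                            stability=1.0, n_communities=n)

    memberships = _leiden_runs(g0, resolution, n_runs, seed, "initial")
    freq0 = _coassignment(memberships)
    iu = np.triu_indices(n, k=1)
    f = freq0[iu]
    stability = float(np.mean(f**2 + (1.0 - f)**2)) if f.size else 1.0

    best_run = None  # quality safeguard: never return worse than best sampled run
    best_q = -np.inf
    weights = g0.es["weight"]
    for r in range(memberships.shape[0]):
        q = g0.modularity(memberships[r].tolist(), weights=weights,
                          resolution=resolution)
        if q > best_q:
            best_q, best_run = q, memberships[r].copy()

    freq = freq0
    prev = None
    final = None
    for it in range(MAX_CONSENSUS_ITERATIONS):
        ii, jj = np.nonzero(np.triu(freq >= co_threshold, k=1))
        cg = ig.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())))
        cg.es["weight"] = freq[ii, jj].tolist()
        memberships = _leiden_runs(cg, resolution, n_runs, seed, ("consensus", it))
        canon = {_canonical(memberships[r]) for r in range(memberships.shape[0])}
        current = memberships[0]
        if len(canon) == 1 and prev is not None and _canonical(prev) == _canonical(current):
            final = current
            break
        prev = current
        freq = _coassignment(memberships)
    else:
        raise RuntimeError(
            f"consensus did not converge in {MAX_CONSENSUS_ITERATIONS} iterations"
        )

    q_final = g0.modularity(final.tolist(), weights=weights, resolution=resolution)
    if best_q > q_final + 1e-12:
        final = best_run  # consensus degraded quality; keep the best run

    # relabel communities by decreasing size, then by smallest member name
    members: dict[int, list[int]] = {}
    for idx, lab in enumerate(final.tolist()):
        members.setdefault(lab, []).append(idx)
    order = sorted(members,
                   key=lambda c: (-len(members[c]), graph.nodes[min(members[c])]))
    relabel = {c: i for i, c in enumerate(order)}
    assignment = {graph.nodes[idx]: relabel[lab]
                  for idx, lab in enumerate(final.tolist())}

    q = modularity(graph, assignment)
    return ALGPartition(
        assignment, n_algs=_count_major(assignment, n), modularity=q,
        resolution=resolution, stability=stability,
        n_communities=len(members),
    )


def _count_major(assignment: Mapping[str, int], n_nodes: int) -> int:
    """Communities holding >= 1% of nodes (tiny remnants are reported in the
    assignment but not counted as ALGs)."""
    sizes: dict[int, int] = {}
    for lab in assignment.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    cutoff = max(1, int(np.ceil(TINY_COMMUNITY_FRACTION * n_nodes)))
    return sum(1 for s in sizes.values() if s >= cutoff)


def scenario_sweep(graph: LinkageGraph, resolutions: Sequence[float],
                   n_runs: int = 100, co_threshold: float = 0.5,
                   seed: int = 0) -> list[ALGPartition]:
    """One consensus partition per resolution, sorted by modularity on the
    original graph (descending); ties break toward fewer ALGs.  The first
    element is the selected scenario."""
    if not resolutions:
        raise ValueError("resolution grid is empty")
    parts = [
        consensus_communities(graph, resolution=r, n_runs=n_runs,
                              co_threshold=co_threshold, seed=seed)
        for r in resolutions
    ]
    parts.sort(key=lambda p: (-p.modularity, p.n_algs, p.resolution))
    return parts
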