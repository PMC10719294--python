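"""Microsynteny block detection and the clade census.

A microsyntenic block is a run of orthologous genes whose order is conserved
between two species up to a budget of intervening (non-member) genes between
consecutive members in each species.  Member order must be colinear: strictly
increasing gene rank in species A and strictly monotone (increasing or
decreasing) in species B; orientation/strand is ignored.  A gene whose
orthogroup is absent in the partner species still counts as intervening.

Blocks are extracted greedily: the longest colinear chain is selected first
(ties resolved by the leftmost match pair, compared pairwise along the
chain), its genes are consumed, and the search repeats on the remaining
matches, so every orthologous gene instance is used in at most one block per
species pair and every reported block is maximal among the matches that
remain when it is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .io import GenomeAnnotation, OrthogroupTable
from .orthology import filter_clade_complete


@dataclass
class Match:
    """One orthologous gene pair, addressed by rank on its chromosomes."""
    orthogroup: str
    gene_a: str
    gene_b: str
    chrom_a: str
    ord_a: int
    chrom_b: str
    ord_b: int


@dataclass
class SyntenyBlock:
    species_a: str
    species_b: str
    orthogroups: list[str]
    genes_a: list[str]
    genes_b: list[str]
    chrom_a: str
    chrom_b: str
    span_a: tuple[int, int]     # inclusive ordinal span in A
    span_b: tuple[int, int]
    direction: int              # +1 colinear, -1 antiparallel (B descending)
    max_intervening_used: int

    @property
    def n_genes(self) -> int:
        return len(self.orthogroups)


def _matches(ann_a: GenomeAnnotation, ann_b: GenomeAnnotation,
             table: OrthogroupTable) -> list[Match]:
    sa, sb = ann_a.species_id, ann_b.species_id
    out = []
    for og in sorted(table.entries):
        row = table.entries[og]
        for ga in row.get(sa, []):
            ca, oa = ann_a.rank_index[ga]
            for gb in row.get(sb, []):
                cb, ob = ann_b.rank_index[gb]
                out.append(Match(og, ga, gb, ca, oa, cb, ob))
    return out


def _successors(ms: Sequence[Match], i: int, direction: int,
                max_intervening: int) -> list[int]:
    m = ms[i]
    out = []
    for j, m2 in enumerate(ms):
        if m2.ord_a <= m.ord_a:
            continue
        if m2.ord_a - m.ord_a - 1 > max_intervening:
            continue
        if direction > 0:
            ok = m2.ord_b > m.ord_b and m2.ord_b - m.ord_b - 1 <= max_intervening
        else:
            ok = m2.ord_b < m.ord_b and m.ord_b - m2.ord_b - 1 <= max_intervening
        if ok:
            out.append(j)
    return out


def _longest_chain(ms: list[Match], max_intervening: int) -> list[Match] | None:
    """Longest colinear chain over the given matches of one (chrom_a, chrom_b)
    pair and direction set; deterministic tie-break: lexicographically
    smallest sequence of (ord_a, ord_b) pairs among maximum-length chains."""
    best: list[Match] | None = None

    for direction in (+1, -1):
        order = sorted(range(len(ms)),
                       key=lambda k: (ms[k].ord_a, direction * ms[k].ord_b))
        # f[i]: longest chain starting at i (computed right-to-left in ord_a)
        f = [1] * len(ms)
        succs = {i: _successors(ms, i, direction, max_intervening)
                 for i in range(len(ms))}
        for i in sorted(range(len(ms)), key=lambda k: -ms[k].ord_a):
            for j in succs[i]:
                f[i] = max(f[i], 1 + f[j])
        if not ms:
            continue
        lmax = max(f)
        starts = [i for i in range(len(ms)) if f[i] == lmax]
        start = min(starts, key=lambda i: (ms[i].ord_a, ms[i].ord_b))
        chain = [start]
        while f[chain[-1]] > 1:
            want = f[chain[-1]] - 1
            cands = [j for j in succs[chain[-1]] if f[j] == want]
            chain.append(min(cands, key=lambda j: (ms[j].ord_a, ms[j].ord_b)))
        cm = [ms[i] for i in chain]
        if best is None or _chain_key(cm) < _chain_key(best):
            best = cm
    return best


def _chain_key(chain: list[Match]) -> tuple:
    return (-len(chain), chain[0].chrom_a, chain[0].chrom_b,
            tuple((m.ord_a, m.ord_b) for m in chain))


def find_blocks(ann_a: GenomeAnnotation, ann_b: GenomeAnnotation,
                table: OrthogroupTable, max_intervening: int = 0,
                min_len: int = 2) -> list[SyntenyBlock]:
    """Greedy longest-first extraction of colinear blocks (see module doc)."""
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    if min_len < 2:
        raise ValueError("min_len must be >= 2")

    pool = _matches(ann_a, ann_b, table)
    by_pair: dict[tuple[str, str], list[Match]] = {}
    for m in pool:
        by_pair.setdefault((m.chrom_a, m.chrom_b), []).append(m)

    blocks: list[SyntenyBlock] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    while True:
        candidates: list[list[Match]] = []
        for key in sorted(by_pair):
            ms = [m for m in by_pair[key]
                  if m.gene_a not in used_a and m.gene_b not in used_b]
            if len(ms) < 2:
                continue
            chain = _longest_chain(ms, max_intervening)
            if chain is not None and len(chain) >= min_len:
                candidates.append(chain)
        if not candidates:
            break
        chain = min(candidates, key=_chain_key)
        for m in chain:
            used_a.add(m.gene_a)
            used_b.add(m.gene_b)
        ords_b = [m.ord_b for m in chain]
        direction = +1 if len(chain) < 2 or ords_b[1] > ords_b[0] else -1
        gaps = [chain[k + 1].ord_a - chain[k].ord_a - 1 for k in range(len(chain) - 1)]
        gaps += [abs(chain[k + 1].ord_b - chain[k].ord_b) - 1
                 for k in range(len(chain) - 1)]
        blocks.append(SyntenyBlock(
            species_a=ann_a.species_id, species_b=ann_b.species_id,
            orthogroups=[m.orthogroup for m in chain],
            genes_a=[m.gene_a for m in chain],
            genes_b=[m.gene_b for m in chain],
            chrom_a=chain[0].chrom_a, chrom_b=chain[0].chrom_b,
            span_a=(chain[0].ord_a, chain[-1].ord_a),
            span_b=(min(ords_b), max(ords_b)),
            direction=direction,
            max_intervening_used=max(gaps) if gaps else 0,
        ))
    return blocks


def filter_paralog_blocks(blocks: Sequence[SyntenyBlock],
                          table: OrthogroupTable | None = None
                          ) -> list[SyntenyBlock]:
    """Drop blocks composed of paralogous genes: a block is removed when a
    majority (> 50%) of its members share one orthogroup id, which captures
    tandem-array self-synteny while keeping ordinary blocks of distinct
    orthogroups (including 2-gene blocks)."""
    kept = []
    for b in blocks:
        counts: dict[str, int] = {}
        for og in b.orthogroups:
            counts[og] = counts.get(og, 0) + 1
        if max(counts.values()) / b.n_genes > 0.5:
            continue
        kept.append(b)
    return kept


def block_census(clades: Mapping[str, Sequence[str]],
                 annotations: Mapping[str, GenomeAnnotation],
                 tables: Mapping[str, OrthogroupTable],
                 max_intervening_values: Sequence[int] = (0, 5),
                 min_lens: Sequence[int] = (2, 3, 4)) -> pd.DataFrame:
    """Block counts for every within-clade species pair at every
    (max_intervening, min_len) combination, plus per-clade medians.

    ``tables`` maps clade name to that clade's orthogroup table; the
    clade-complete filter (>= 1 gene in every clade member) is applied before
    block detection, matching how within-clade censuses correct for missing
    genes.  Returns a tidy frame with columns clade, species_a, species_b,
    max_intervening, min_len, n_blocks, clade_median.
    """
    rows = []
    for clade, species in clades.items():
        if len(species) < 2:
            raise ValueError(f"clade {clade!r} has < 2 species")
        table = filter_clade_complete(tables[clade], list(species))
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                sa, sb = species[i], species[j]
                for g in max_intervening_values:
                    # selection is longest-first, so one min_len=2 run yields
                    # the block set of every higher min_len as its long blocks
                    all_blocks = filter_paralog_blocks(find_blocks(
                        annotations[sa], annotations[sb], table,
                        max_intervening=g, min_len=2))
                    for ml in min_lens:
                        n = sum(1 for b in all_blocks if b.n_genes >= ml)
                        rows.append((clade, sa, sb, g, ml, n))
    df = pd.DataFrame(rows, columns=["clade", "species_a", "species_b",
                                     "max_intervening", "min_len", "n_blocks"])
    med = (df.groupby(["clade", "max_intervening", "min_len"])["n_blocks"]
             .median().rename("clade_median"))
    return df.join(med, on=["clade", "max_intervening", "min_len"])


def write_blocks(blocks: Sequence[SyntenyBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_a\tspecies_b\tchrom_a\tchrom_b\tspan_a\tspan_b\t"
                 "direction\tn_genes\tmax_intervening_used\torthogroups\n")
        for b in blocks:
            fh.write("\t".join(map(str, [
                b.species_a, b.species_b, b.chrom_a, b.chrom_b,
                f"{b.span_a[0]}-{b.span_a[1]}", f"{b.span_b[0]}-{b.span_b[1]}",
                b.direction, b.n_genes, b.max_intervening_used,
                ",".join(b.orthogroups),
            ])) + "\n")
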