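"""Macrosynteny: Oxford-plot tables, chromosome correspondences, ALG
projection onto extant chromosomes, and ancestor-to-ancestor mapping graphs.

Macrosynteny is conservation of the gene-to-chromosome assignment between
species irrespective of local gene order; an Oxford plot scatters orthologous
gene pairs by their rank position on the chromosomes of the two genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .alg import ALGPartition
from .io import GenomeAnnotation, OrthogroupTable
from .orthology import MutualBestHitSet

OXFORD_COLUMNS = ["gene_a", "gene_b", "chrom_a", "ordinal_a",
                  "chrom_b", "ordinal_b", "alg"]


def oxford_table(pairs: MutualBestHitSet | OrthogroupTable,
                 ann_a: GenomeAnnotation, ann_b: GenomeAnnotation,
                 partition: ALGPartition | None = None,
                 expand_multi: bool = False) -> pd.DataFrame:
    """One row per orthologous gene pair with both genes' chromosome and rank.

    From an orthogroup table only single-copy orthogroups (exactly one gene in
    each of the two species) contribute unless ``expand_multi`` requests the
    full cross product.  ALG labels are joined from ``partition`` when given
    (orthogroup input only; mutual-best-hit pairs carry no orthogroup id).
    """
    rows = []
    if isinstance(pairs, MutualBestHitSet):
        for a, b, _score in pairs.pairs:
            rows.append((a, b, None))
    else:
        sa, sb = ann_a.species_id, ann_b.species_id
        for og in sorted(pairs.entries):
            row = pairs.entries[og]
            ga, gb = row.get(sa, []), row.get(sb, [])
            if not ga or not gb:
                continue
            if len(ga) == 1 and len(gb) == 1:
                rows.append((ga[0], gb[0], og))
            elif expand_multi:
                for a in ga:
                    for b in gb:
                        rows.append((a, b, og))

    records = []
    for a, b, og in rows:
        if a not in ann_a:
            raise KeyError(f"gene {a!r} missing from annotation {ann_a.species_id}")
        if b not in ann_b:
            raise KeyError(f"gene {b!r} missing from annotation {ann_b.species_id}")
        ca, oa = ann_a.rank_index[a]
        cb, ob = ann_b.rank_index[b]
        alg = None
        if partition is not None and og is not None:
            alg = partition.assignment.get(og)
        records.append((a, b, ca, oa, cb, ob, alg))
    df = pd.DataFrame(records, columns=OXFORD_COLUMNS)
    return df.sort_values(["chrom_a", "ordinal_a", "chrom_b", "ordinal_b"],
                          kind="mergesort").reset_index(drop=True)


@dataclass
class CorrespondenceMap:
    contingency: pd.DataFrame              # chromosomes_A x chromosomes_B counts
    partners_a: dict[str, list[str]]       # significant partners per A chromosome
    partners_b: dict[str, list[str]]
    classification_a: dict[str, str]       # e.g. "1-to-1", "1-to-2", "1-to-0"
    classification_b: dict[str, str]


def chromosome_correspondence(table: pd.DataFrame,
                              min_fraction: float = 0.05,
                              min_count: int = 5) -> CorrespondenceMap:
    """Classify chromosome-to-chromosome correspondence from an Oxford table.

    A cell (a, b) is a significant partnership when its shared-pair count is
    at least ``min_count`` and at least ``min_fraction`` of the chromosome's
    row total.  Chromosome a is then "1-to-m" with m significant partners
    (and symmetrically for the B genome).  The joint count+fraction rule,
    rather than a statistical test, mirrors how such correspondences are
    reported descriptively; defaults are set so uniform background scatter
    yields no spurious partner.
    """
    if table.empty:
        raise ValueError("oxford table is empty")
    cont = pd.crosstab(table["chrom_a"], table["chrom_b"])

    def classify(counts: pd.DataFrame, axis_chroms, other_axis: int):
        partners: dict[str, list[str]] = {}
        labels: dict[str, str] = {}
        for chrom in axis_chroms:
            row = counts.loc[chrom] if other_axis == 1 else counts[chrom]
            total = int(row.sum())
            sig = [
                str(p) for p, c in row.items()
                if c >= min_count and total > 0 and c >= min_fraction * total
            ]
            sig.sort(key=lambda p: -row[p])
            partners[str(chrom)] = sig
            labels[str(chrom)] = f"1-to-{len(sig)}"
        return partners, labels

    pa, la = classify(cont, cont.index, 1)
    pb, lb = classify(cont, cont.columns, 0)
    return CorrespondenceMap(cont, pa, pb, la, lb)


@dataclass
class ALGProjection:
    species: str
    composition: pd.DataFrame       # chromosomes x ALG labels, orthogroup counts
    fractions: pd.DataFrame         # same shape, fraction of chromosome total
    fusions: list[tuple[str, tuple]]    # (chromosome, algs present above threshold)
    fissions: list[tuple[object, tuple]]  # (alg, chromosomes it split across)


def project_algs(partition: ALGPartition,
                 placements: Mapping[str, Mapping[str, str | None]],
                 species: str,
                 fraction_threshold: float = 0.1,
                 count_threshold: int = 10) -> ALGProjection:
    """Project ALGs onto one extant species' chromosomes.

    A chromosome carrying >= 2 ALGs above both thresholds is called a fusion;
    an ALG above thresholds on >= 2 chromosomes is called a fission.
    """
    if species not in placements:
        raise KeyError(f"species {species!r} absent from placements")
    rows = []
    for og, chrom in placements[species].items():
        if chrom is None or og not in partition.assignment:
            continue
        rows.append((chrom, partition.assignment[og]))
    df = pd.DataFrame(rows, columns=["chrom", "alg"])
    if df.empty:
        empty = pd.DataFrame()
        return ALGProjection(species, empty, empty, [], [])
    comp = pd.crosstab(df["chrom"], df["alg"])
    frac = comp.div(comp.sum(axis=1), axis=0)

    above = (comp >= count_threshold) & (frac >= fraction_threshold)
    fusions = []
    for chrom in comp.index:
        algs = tuple(a for a in comp.columns if above.loc[chrom, a])
        if len(algs) >= 2:
            fusions.append((str(chrom), algs))
    fissions = []
    for alg in comp.columns:
        chroms = tuple(str(c) for c in comp.index if above.loc[c, alg])
        if len(chroms) >= 2:
            fissions.append((alg, chroms))
    return ALGProjection(species, comp, frac, fusions, fissions)


@dataclass
class AncestorMappingEdge:
    parent: object
    child: object
    weight: float           # |parent ∩ child| / |parent| over orthogroups
    near_one_to_one: bool   # weight strictly > faded threshold


def ancestor_mapping(partition_parent: ALGPartition,
                     partition_child: ALGPartition,
                     faded_threshold: float = 0.8) -> list[AncestorMappingEdge]:
    """Weighted bipartite graph between two ALG reconstructions: edge weight is
    the fraction of the parent ALG's orthogroup content found in the child
    ALG; edges with weight strictly above ``faded_threshold`` are flagged as
    near one-to-one relationships."""
    parents = partition_parent.members()
    children = partition_child.members()
    edges: list[AncestorMappingEdge] = []
    for p_lab in sorted(parents):
        p = parents[p_lab]
        if not p:
            raise ValueError(f"parent ALG {p_lab!r} is empty")
        for c_lab in sorted(children):
            inter = len(p & children[c_lab])
            if inter == 0:
                continue
            w = inter / len(p)
            edges.append(AncestorMappingEdge(p_lab, c_lab, w, w > faded_threshold))
    return edges


def write_correspondence(cmap: CorrespondenceMap, path: str | Path) -> None:
    cmap.contingency.to_csv(path, sep="\t")
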