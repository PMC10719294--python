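"""Ultraconserved element detection from pairwise alignment HSPs.

Candidate elements are alignment-column intervals of at least ``window``
columns whose identity (gap columns count as mismatches) is at least
``min_identity``, found by seeding fixed-length windows that pass the
threshold and extending them rightward while the cumulative identity holds,
merging overlapping survivors, and trimming flanking mismatch columns so every
element starts and ends on a matching column.  Multi-mapping elements are
reduced to the longest locus pair, elements mostly covered by coding sequence
are removed, the rest are classified intronic or non-coding, and recurrent
(repeat-like) elements are flagged by single-linkage clustering of
element-vs-element hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GenomeAnnotation, HSPRecord


@dataclass
class ConservedElement:
    element_id: str
    hsp_index: int
    col_start: int
    col_end: int
    identity: float
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    klass: str = "unclassified"

    @property
    def n_columns(self) -> int:
        return self.col_end - self.col_start

    @property
    def len_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def len_b(self) -> int:
        return self.end_b - self.start_b


def _match_array(hsp: HSPRecord) -> np.ndarray:
    q = np.frombuffer(hsp.aligned_query.upper().encode(), dtype="S1")
    s = np.frombuffer(hsp.aligned_subject.upper().encode(), dtype="S1")
    if len(q) != len(s):
        raise ValueError("aligned strings differ in length")
    return (q == s) & (q != b"-")


def _map_to_genomes(hsp: HSPRecord, col_start: int, col_end: int
                    ) -> tuple[int, int, int, int]:
    """Map an alignment-column interval to 0-based half-open coordinates in
    both genomes, skipping gap columns."""
    qgap = np.frombuffer(hsp.aligned_query.encode(), dtype="S1") == b"-"
    sgap = np.frombuffer(hsp.aligned_subject.encode(), dtype="S1") == b"-"
    q_off = np.concatenate([[0], np.cumsum(~qgap)])
    s_off = np.concatenate([[0], np.cumsum(~sgap)])
    qa = hsp.q_start + int(q_off[col_start])
    qb = hsp.q_start + int(q_off[col_end])
    if hsp.s_strand == "+":
        sa = hsp.s_start + int(s_off[col_start])
        sb = hsp.s_start + int(s_off[col_end])
    else:
        sb = hsp.s_end - int(s_off[col_start])
        sa = hsp.s_end - int(s_off[col_end])
    return qa, qb, sa, sb


def window_scan(hsp: HSPRecord, min_identity: float = 0.95,
                window: int = 20, hsp_index: int = 0) -> list[ConservedElement]:
    """Seed-and-extend identity scan over one HSP (see module docstring)."""
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    match = _match_array(hsp)
    n = match.size
    if n < window:
        return []
    csum = np.concatenate([[0], np.cumsum(match)])

    def identity(a: int, b: int) -> float:
        return (csum[b] - csum[a]) / (b - a)

    # seed windows passing the threshold
    win_matches = csum[window:] - csum[:-window]
    seeds = np.nonzero(win_matches >= min_identity * window)[0]
    if seeds.size == 0:
        return []

    # extend each passing window rightward while the cumulative identity holds
    intervals: list[tuple[int, int]] = []
    for a in seeds:
        a = int(a)
        b = a + window
        while b < n and identity(a, b + 1) >= min_identity:
            b += 1
        intervals.append((a, b))

    # union of overlapping survivors
    merged: list[tuple[int, int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))

    def trimmed(a: int, b: int, floor: int) -> tuple[int, int] | None:
        """Trim flanking mismatch columns; require length and identity."""
        a = max(a, floor)
        while a < b and not match[a]:
            a += 1
        while b > a and not match[b - 1]:
            b -= 1
        if b - a < window or identity(a, b) < min_identity:
            return None
        return a, b

    out: list[ConservedElement] = []
    floor = 0
    for a, b in merged:
        span = trimmed(a, b, floor)
        if span is None:
            # a union of passing pieces can dip below the threshold; fall back
            # to the individual extended intervals inside it, kept disjoint
            pieces = []
            for ia, ib in sorted(intervals):
                if ia >= a and ib <= b:
                    sub = trimmed(ia, ib, floor if not pieces else pieces[-1][1])
                    if sub is not None:
                        pieces.append(sub)
            spans = pieces
        else:
            spans = [span]
        for a2, b2 in spans:
            qa, qb, sa, sb = _map_to_genomes(hsp, a2, b2)
            out.append(ConservedElement(
                element_id=f"{hsp.query_id}:{qa}-{qb}",
                hsp_index=hsp_index, col_start=a2, col_end=b2,
                identity=identity(a2, b2),
                chrom_a=hsp.query_id, start_a=qa, end_a=qb,
                chrom_b=hsp.subject_id, start_b=sa, end_b=sb,
            ))
            floor = b2
    return out


def scan_hsps(hsps: Sequence[HSPRecord], min_identity: float = 0.95,
              window: int = 20) -> list[ConservedElement]:
    """Scan a collection of HSPs; output order is by genome-A coordinate, so
    it is invariant to the input order of the HSPs."""
    elements: list[ConservedElement] = []
    for idx, hsp in enumerate(hsps):
        elements.extend(window_scan(hsp, min_identity, window, hsp_index=idx))
    elements.sort(key=lambda e: (e.chrom_a, e.start_a, e.end_a, e.chrom_b,
                                 e.start_b))
    return elements


def _overlap(a: ConservedElement, b: ConservedElement) -> int:
    if a.chrom_a != b.chrom_a:
        return 0
    return max(0, min(a.end_a, b.end_a) - max(a.start_a, b.start_a))


def resolve_multimapping(elements: Sequence[ConservedElement],
                         min_overlap: float = 0.5) -> list[ConservedElement]:
    """Reduce elements sharing a genome-A locus to the single longest pair.

    Elements are grouped by single linkage over the relation "A-spans overlap
    by at least ``min_overlap`` of the shorter span"; within a group the
    element maximizing summed length in both genomes survives, ties going to
    the lowest coordinate."""
    els = sorted(elements, key=lambda e: (e.chrom_a, e.start_a, e.end_a,
                                          e.chrom_b, e.start_b))
    parent = list(range(len(els)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(els)):
        for j in range(i + 1, len(els)):
            if els[j].chrom_a != els[i].chrom_a or els[j].start_a >= els[i].end_a:
                break
            ov = _overlap(els[i], els[j])
            if ov >= min_overlap * min(els[i].len_a, els[j].len_a):
                parent[find(j)] = find(i)

    groups: dict[int, list[ConservedElement]] = {}
    for i, e in enumerate(els):
        groups.setdefault(find(i), []).append(e)
    out = []
    for grp in groups.values():
        out.append(min(grp, key=lambda e: (-(e.len_a + e.len_b), e.chrom_a,
                                           e.start_a, e.chrom_b, e.start_b)))
    out.sort(key=lambda e: (e.chrom_a, e.start_a, e.end_a))
    return out


def classify_elements(elements: Sequence[ConservedElement],
                      cds: Iterable[tuple[str, int, int]],
                      introns: Iterable[tuple[str, int, int]],
                      threshold: float = 0.5) -> list[ConservedElement]:
    """Remove elements mostly (> threshold of their genome-A span) covered by
    coding sequence; classify the survivors intronic when mostly inside an
    intron, non-coding otherwise."""
    cds_trees: dict[str, IntervalTree] = {}
    for chrom, s, e in cds:
        cds_trees.setdefault(chrom, IntervalTree()).addi(s, e)
    intron_trees: dict[str, IntervalTree] = {}
    for chrom, s, e in introns:
        intron_trees.setdefault(chrom, IntervalTree()).addi(s, e)

    def coverage(trees, chrom, s, e):
        tree = trees.get(chrom)
        if tree is None:
            return 0.0
        covered = 0
        merged = sorted(
            (max(iv.begin, s), min(iv.end, e)) for iv in tree.overlap(s, e)
        )
        last = s
        for a, b in merged:
            a = max(a, last)
            if b > a:
                covered += b - a
                last = b
        return covered / (e - s)

    out = []
    for e in elements:
        cds_frac = coverage(cds_trees, e.chrom_a, e.start_a, e.end_a)
        if cds_frac > threshold:
            continue
        intron_frac = coverage(intron_trees, e.chrom_a, e.start_a, e.end_a)
        klass = "intronic" if intron_frac > threshold else "non_coding"
        out.append(ConservedElement(**{**e.__dict__, "klass": klass}))
    return out


def cluster_recurrent(elements: Sequence[ConservedElement],
                      self_hits: Sequence[HSPRecord],
                      coverage: float = 0.9) -> list[list[str]]:
    """Single-linkage clusters of elements over the relation "an
    element-vs-element hit covers at least ``coverage`` of either element".
    Clusters of size >= 2 mark recurrent (unmasked repeat candidate)
    sequences; returned first, each sorted, then singletons."""
    ids = [e.element_id for e in elements]
    length = {e.element_id: e.len_a for e in elements}
    index = {eid: i for i, eid in enumerate(ids)}
    parent = list(range(len(ids)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for h in self_hits:
        if h.query_id not in index or h.subject_id not in index:
            continue
        if h.query_id == h.subject_id:
            continue
        span = h.n_columns
        if (span >= coverage * length[h.query_id]
                or span >= coverage * length[h.subject_id]):
            a, b = find(index[h.query_id]), find(index[h.subject_id])
            if a != b:
                parent[b] = a

    groups: dict[int, list[str]] = {}
    for eid, i in index.items():
        groups.setdefault(find(i), []).append(eid)
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda g: (-len(g), g[0]))
    return clusters


def write_elements(elements: Sequence[ConservedElement],
                   path_a: str | Path, path_b: str | Path,
                   summary: str | Path | None = None) -> None:
    """Paired BED output (one file per genome, matched by element id)."""
    with open(path_a, "w") as fa, open(path_b, "w") as fb:
        for e in elements:
            fa.write(f"{e.chrom_a}\t{e.start_a}\t{e.end_a}\t{e.element_id}\n")
            fb.write(f"{e.chrom_b}\t{e.start_b}\t{e.end_b}\t{e.element_id}\n")
    if summary is not None:
        with open(summary, "w") as fh:
            fh.write("element_id\tcolumns\tidentity\tclass\n")
            for e in elements:
                fh.write(f"{e.element_id}\t{e.n_columns}\t{e.identity:.4f}\t"
                         f"{e.klass}\n")
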