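"""Reciprocal best hits and clade-complete orthogroup filtering.

Orthogroup inference itself (OrthoFinder/OMA) is consumed, not re-implemented;
these helpers derive mutual-best-hit pairs from similarity tables and prepare
the orthogroup subsets the synteny stages operate on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import OrthogroupTable


@dataclass
class MutualBestHitSet:
    species_a: str
    species_b: str
    pairs: list[tuple[str, str, float]]

    def __len__(self):
        return len(self.pairs)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"gene_{self.species_a}\tgene_{self.species_b}\tscore\n")
            for a, b, s in sorted(self.pairs):
                fh.write(f"{a}\t{b}\t{s:.10g}\n")


def _unique_best(rows: Iterable[tuple[str, str, float]]) -> dict[str, str]:
    """Per query, the unique top-scoring subject; queries whose best score is
    tied between subjects are dropped (conservative tie rule)."""
    best: dict[str, tuple[float, str, bool]] = {}  # query -> (score, subject, tied)
    for q, s, score in rows:
        cur = best.get(q)
        if cur is None or score > cur[0]:
            best[q] = (score, s, False)
        elif score == cur[0] and s != cur[1]:
            best[q] = (cur[0], cur[1], True)
    return {q: s for q, (sc, s, tied) in best.items() if not tied}


def reciprocal_best_hits(hits_ab: Iterable[tuple[str, str, float]],
                         hits_ba: Iterable[tuple[str, str, float]],
                         species_a: str = "A",
                         species_b: str = "B") -> MutualBestHitSet:
    """Pairs (a, b) where b is a's unique best hit and a is b's unique best.

    Scores follow bit-score semantics (larger is better).  Duplicate
    query/subject rows keep their maximal score implicitly via the max rule.
    """
    hits_ab = list(hits_ab)
    best_ab = _unique_best(hits_ab)
    best_ba = _unique_best(hits_ba)
    score_ab = {}
    for q, s, score in hits_ab:
        key = (q, s)
        if key not in score_ab or score > score_ab[key]:
            score_ab[key] = score
    pairs = [
        (a, b, score_ab[(a, b)])
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    pairs.sort()
    return MutualBestHitSet(species_a, species_b, pairs)


def filter_clade_complete(table: OrthogroupTable,
                          species: Sequence[str]) -> OrthogroupTable:
    """Keep orthogroups with at least one gene in every listed species."""
    if not species:
        raise ValueError("species list must be non-empty")
    unknown = [sp for sp in species if sp not in table.species]
    if unknown:
        raise ValueError(f"unknown species: {', '.join(unknown)}")
    keep = [
        og for og, row in table.entries.items()
        if all(row[sp] for sp in species)
    ]
    return table.subset(keep)
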