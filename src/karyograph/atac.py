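"""ATAC peak to nearest-gene distances and the genome-size regression.

Open-chromatin peaks that do not overlap genes (or repeats) are assigned the
gap to the closest gene boundary — transcription unit start or end — on their
chromosome.  Species summaries (n, median, mean, SEM) feed an ordinary least
squares regression of mean peak-to-gene distance on genome size, the scaling
relation expected if compact genomes keep cis-regulatory elements close to
their targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .io import GenomeAnnotation
from .simulate import ATACPeakSet


@dataclass
class DistanceSummary:
    species_id: str
    distances: np.ndarray
    genome_size: int

    @property
    def n(self) -> int:
        return self.distances.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    @property
    def sem(self) -> float:
        return float(stats.sem(self.distances)) if self.n > 1 else float("nan")


def peak_gene_distances(peaks: ATACPeakSet, annotation: GenomeAnnotation,
                        repeats: Sequence[tuple[str, int, int]] = ()
                        ) -> DistanceSummary:
    """Distance from each retained peak to its closest gene.

    Peaks overlapping any repeat interval or any gene are excluded; the
    distance is the minimum gap between a peak edge and the nearest gene edge
    (start or end) on the same chromosome.  Peaks on gene-free chromosomes
    are dropped.  Abutting peaks (gap 0) count as gene-overlapping and are
    excluded, so all reported distances are >= 1.
    """
    bad = sorted({c for c, _, _ in peaks.peaks} - set(annotation.chrom_sizes))
    if bad:
        raise ValueError(
            f"peak chromosomes absent from annotation: {', '.join(bad)}"
        )

    rep_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in repeats:
        rep_by_chrom.setdefault(c, []).append((s, e))
    for v in rep_by_chrom.values():
        v.sort()

    # per chromosome: sorted gene starts/ends for nearest-boundary queries
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for g in annotation.genes:
        intervals.setdefault(g.chrom, []).append((g.start, g.end))
    for c, iv in intervals.items():
        iv.sort()
        starts[c] = np.array([s for s, _ in iv])
        ends[c] = np.array(sorted(e for _, e in iv))

    def overlaps_any(sorted_iv: list[tuple[int, int]], s: int, e: int) -> bool:
        import bisect
        i = bisect.bisect_left(sorted_iv, (e, e))
        for gs, ge in sorted_iv[max(0, i - 50):i + 1]:
            if gs < e and s < ge:
                return True
        return False

    dists = []
    for chrom, ps, pe in peaks.peaks:
        if chrom in rep_by_chrom and overlaps_any(rep_by_chrom[chrom], ps, pe):
            continue
        if chrom not in intervals:
            continue  # gene-free chromosome
        if overlaps_any(intervals[chrom], ps, pe):
            continue
        # nearest gene end at or left of peak start
        e_arr, s_arr = ends[chrom], starts[chrom]
        left = None
        i = int(np.searchsorted(e_arr, ps, side="right")) - 1
        if i >= 0:
            left = ps - int(e_arr[i])
        right = None
        j = int(np.searchsorted(s_arr, pe, side="left"))
        if j < s_arr.size:
            right = int(s_arr[j]) - pe
        cands = [d for d in (left, right) if d is not None]
        if not cands:
            continue
        d = min(cands)
        if d >= 1:
            dists.append(d)
    return DistanceSummary(peaks.species_id, np.array(dists, dtype=int),
                           annotation.genome_size)


def iqr_filter(values: Sequence[float]) -> np.ndarray:
    """Tukey fence outlier removal: keep x with Q1 - 1.5*IQR <= x <= Q3 +
    1.5*IQR, quartiles by linear interpolation (type-7).  Fewer than 4 values
    pass through unchanged with a warning."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn("iqr_filter: fewer than 4 values, passing through")
        return x
    q1, q3 = np.quantile(x, [0.25, 0.75])  # numpy default is type-7
    iqr = q3 - q1
    return x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]


@dataclass
class SizeRegression:
    slope: float
    intercept: float
    r: float
    slope_stderr: float
    slope_ci: tuple[float, float]   # 95% CI on the slope
    x: np.ndarray
    y: np.ndarray

    def predict(self, x: Sequence[float]) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def confidence_band(self, x: Sequence[float], level: float = 0.95
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band of the fitted mean line."""
        xq = np.asarray(x, dtype=float)
        n = self.x.size
        dof = n - 2
        resid = self.y - self.predict(self.x)
        s2 = float(resid @ resid) / dof
        xbar = self.x.mean()
        sxx = float(((self.x - xbar) ** 2).sum())
        se = np.sqrt(s2 * (1.0 / n + (xq - xbar) ** 2 / sxx))
        t = stats.t.ppf(0.5 + level / 2, dof)
        fit = self.predict(xq)
        return fit - t * se, fit + t * se


def size_regression(summaries: Sequence[DistanceSummary]) -> SizeRegression:
    """OLS of mean peak-to-gene distance on genome size across species."""
    if len(summaries) < 3:
        raise ValueError("need >= 3 species for the regression")
    x = np.array([s.genome_size for s in summaries], dtype=float)
    y = np.array([s.mean for s in summaries], dtype=float)
    if np.allclose(y, y[0]):
        # degenerate flat response: slope 0, r defined as 0
        return SizeRegression(0.0, float(y[0]), 0.0, 0.0, (0.0, 0.0), x, y)
    res = stats.linregress(x, y)
    dof = x.size - 2
    t = stats.t.ppf(0.975, dof) if dof > 0 else float("inf")
    ci = (res.slope - t * res.stderr, res.slope + t * res.stderr)
    return SizeRegression(float(res.slope), float(res.intercept),
                          float(res.rvalue), float(res.stderr), ci, x, y)


def write_summaries(summaries: Sequence[DistanceSummary],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn\tmedian\tmean\tsem\tgenome_size\n")
        for s in summaries:
            fh.write(f"{s.species_id}\t{s.n}\t{s.median:.6g}\t{s.mean:.6g}\t"
                     f"{s.sem:.6g}\t{s.genome_size}\n")
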