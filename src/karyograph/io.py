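"""Readers, writers and core containers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  GFF3 (1-based, closed) is
converted on read and back on write; BED is consumed natively.  Gene order on a
chromosome ("rank") is by start coordinate, ties broken by (end, gene_id).
Strand is recorded but never used by the synteny computations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class ParseError(ValueError):
    """Raised on malformed input files; carries the offending line number."""


# ---------------------------------------------------------------------------
# GenomeAnnotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class GenomeAnnotation:
    """One species' chromosomes and gene intervals.

    Every sequence named in the input is treated as a "chromosome", so
    scaffold-level assemblies are handled uniformly.  ``rank_index`` maps each
    gene id to its (chrom, ordinal) position, ordinals being the 0-based rank
    of the gene on its chromosome sorted by (start, end, gene_id).
    """

    def __init__(
        self,
        species_id: str,
        genes: Iterable[Gene],
        chromosomes: Sequence[tuple[str, int]] | None = None,
    ):
        self.species_id = species_id
        self.genes: list[Gene] = sorted(
            genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)
        )
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r} in {species_id}")
            seen.add(g.gene_id)

        if chromosomes is None:
            # infer lengths from the furthest gene end
            ends: dict[str, int] = {}
            for g in self.genes:
                ends[g.chrom] = max(ends.get(g.chrom, 0), g.end)
            chromosomes = sorted(ends.items())
        self.chromosomes: list[tuple[str, int]] = list(chromosomes)
        self.chrom_sizes: dict[str, int] = dict(self.chromosomes)
        if len(self.chrom_sizes) != len(self.chromosomes):
            raise ValueError("duplicate chromosome name")

        for g in self.genes:
            length = self.chrom_sizes.get(g.chrom)
            if length is None:
                raise ValueError(
                    f"gene {g.gene_id} on unknown chromosome {g.chrom!r}"
                )
            if g.end > length:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom} "
                    f"({g.end} > {length})"
                )

        # per-chromosome gene order and the global rank index
        self.chrom_genes: dict[str, list[str]] = {name: [] for name, _ in self.chromosomes}
        for g in self.genes:
            self.chrom_genes[g.chrom].append(g.gene_id)
        self.rank_index: dict[str, tuple[str, int]] = {}
        for chrom, ids in self.chrom_genes.items():
            for i, gid in enumerate(ids):
                self.rank_index[gid] = (chrom, i)
        self._by_id: dict[str, Gene] = {g.gene_id: g for g in self.genes}

    # -- accessors ----------------------------------------------------------

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation {self.species_id}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def genome_size(self) -> int:
        return sum(length for _, length in self.chromosomes)

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_bed(cls, path: str | Path, species_id: str | None = None,
                 chrom_sizes: Sequence[tuple[str, int]] | None = None) -> "GenomeAnnotation":
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: expected >=4 BED columns")
                try:
                    start, end = int(parts[1]), int(parts[2])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
                strand = parts[5] if len(parts) >= 6 else "."
                try:
                    genes.append(Gene(parts[3], parts[0], start, end, strand))
                except ValueError as e:
                    raise ParseError(f"{path}:{lineno}: {e}") from None
        sid = species_id or Path(path).stem
        try:
            return cls(sid, genes, chrom_sizes)
        except ValueError as e:
            raise ParseError(f"{path}: {e}") from None

    @classmethod
    def from_gff3(cls, path: str | Path, species_id: str | None = None,
                  chrom_sizes: Sequence[tuple[str, int]] | None = None,
                  feature: str = "gene") -> "GenomeAnnotation":
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
                if parts[2] != feature:
                    continue
                try:
                    start1, end1 = int(parts[3]), int(parts[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: {feature} feature without ID")
                strand = parts[6] if parts[6] in ("+", "-") else "."
                # 1-based closed -> 0-based half-open
                try:
                    genes.append(Gene(gid, parts[0], start1 - 1, end1, strand))
                except ValueError as e:
                    raise ParseError(f"{path}:{lineno}: {e}") from None
        sid = species_id or Path(path).stem
        try:
            return cls(sid, genes, chrom_sizes)
        except ValueError as e:
            raise ParseError(f"{path}: {e}") from None

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")

    def to_gff3(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(
                    f"{g.chrom}\t.\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")


def read_annotation(path: str | Path, format: str = "bed", **kwargs) -> GenomeAnnotation:
    """Read a gene annotation from BED6 or GFF3 (gene features only)."""
    if format == "bed":
        return GenomeAnnotation.from_bed(path, **kwargs)
    if format == "gff3":
        return GenomeAnnotation.from_gff3(path, **kwargs)
    raise ValueError(f"unknown annotation format {format!r}")


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two columns")
            out.append((parts[0], int(parts[1])))
    return out


# ---------------------------------------------------------------------------
# OrthogroupTable
# ---------------------------------------------------------------------------

class OrthogroupTable:
    """Orthogroup -> species -> gene-id lists (OrthoFinder-style layout).

    Invariant: within one species a gene id belongs to at most one orthogroup.
    """

    def __init__(self, species: Sequence[str],
                 entries: Mapping[str, Mapping[str, Sequence[str]]]):
        self.species: list[str] = list(species)
        self.entries: dict[str, dict[str, list[str]]] = {
            og: {sp: list(row.get(sp, [])) for sp in self.species}
            for og, row in entries.items()
        }
        seen: dict[str, dict[str, str]] = {sp: {} for sp in self.species}
        for og, row in self.entries.items():
            for sp, gids in row.items():
                for gid in gids:
                    prev = seen[sp].get(gid)
                    if prev is not None and prev != og:
                        raise ValueError(
                            f"gene {gid!r} ({sp}) listed in orthogroups {prev} and {og}"
                        )
                    seen[sp][gid] = og

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, og: str) -> bool:
        return og in self.entries

    def genes(self, og: str, species: str) -> list[str]:
        return self.entries[og][species]

    def subset(self, orthogroups: Iterable[str]) -> "OrthogroupTable":
        keep = set(orthogroups)
        return OrthogroupTable(
            self.species, {og: row for og, row in self.entries.items() if og in keep}
        )

    @classmethod
    def read(cls, path: str | Path) -> "OrthogroupTable":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header:
                raise ParseError(f"{path}: empty file")
            cols = header.split("\t")
            species = cols[1:]
            ncol = len(cols)
            entries: dict[str, dict[str, list[str]]] = {}
            for lineno, line in enumerate(fh, 2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != ncol:
                    raise ParseError(
                        f"{path}:{lineno}: ragged row ({len(parts)} columns, "
                        f"expected {ncol})"
                    )
                og = parts[0]
                if og in entries:
                    raise ParseError(f"{path}:{lineno}: duplicate orthogroup {og}")
                entries[og] = {
                    sp: [g for g in cell.split(",") if g] if cell.strip() else []
                    for sp, cell in zip(species, (c.strip() for c in parts[1:]))
                }
        try:
            return cls(species, entries)
        except ValueError as e:
            raise ParseError(f"{path}: {e}") from None

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("Orthogroup\t" + "\t".join(self.species) + "\n")
            for og in sorted(self.entries):
                row = self.entries[og]
                fh.write(og + "\t" + "\t".join(
                    ",".join(row[sp]) for sp in self.species) + "\n")


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    return OrthogroupTable.read(path)


# ---------------------------------------------------------------------------
# ContactMatrix
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Binned intra-chromosomal Hi-C matrix: symmetric, non-negative."""

    chrom: str
    bin_size: int
    values: np.ndarray
    balanced: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if (v < 0).any():
            raise ValueError("contact matrix has negative entries")
        if not np.allclose(v, v.T):
            raise ValueError("contact matrix is not symmetric")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def write_coo(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            n = self.n_bins
            for i in range(n):
                for j in range(i, n):
                    v = self.values[i, j]
                    if v != 0:
                        fh.write(f"{i}\t{j}\t{v:.10g}\n")

    def write_dense(self, path: str | Path) -> None:
        np.savetxt(path, self.values, fmt="%.10g", delimiter="\t")


def read_contact_matrix(path: str | Path, format: str = "coo",
                        chrom: str = "chr", bin_size: int = 1,
                        n_bins: int | None = None,
                        balanced: bool = False) -> ContactMatrix:
    """Read a COO (``bin_i bin_j value``, upper triangle sufficient) or dense
    whitespace matrix.  COO input is symmetrized by mirroring; an entry given
    on both sides of the diagonal must agree."""
    if format == "dense":
        v = np.loadtxt(path, ndmin=2)
        if v.shape[0] != v.shape[1]:
            raise ParseError(f"{path}: dense matrix is not square {v.shape}")
        return ContactMatrix(chrom, bin_size, v, balanced)
    if format != "coo":
        raise ValueError(f"unknown matrix format {format!r}")
    triples = []
    maxidx = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 'bin_i bin_j value'")
            i, j, val = int(parts[0]), int(parts[1]), float(parts[2])
            if val < 0:
                raise ParseError(f"{path}:{lineno}: negative contact value")
            triples.append((i, j, val))
            maxidx = max(maxidx, i, j)
    n = n_bins if n_bins is not None else maxidx + 1
    v = np.zeros((n, n))
    filled = np.zeros((n, n), dtype=bool)
    for i, j, val in triples:
        for a, b in ((i, j), (j, i)):
            if filled[a, b] and v[a, b] != val:
                raise ParseError(
                    f"{path}: conflicting values for bins ({i},{j})"
                )
            v[a, b] = val
            filled[a, b] = True
    return ContactMatrix(chrom, bin_size, v, balanced)


def expected_n_bins(chrom_length: int, bin_size: int) -> int:
    return math.ceil(chrom_length / bin_size)


# ---------------------------------------------------------------------------
# HSPRecord (BLAST tabular outfmt 6 + qseq/sseq)
# ---------------------------------------------------------------------------

@dataclass
class HSPRecord:
    """One local alignment unit.  Coordinates are 0-based half-open on the
    forward strand of each sequence; ``s_strand`` records subject orientation."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    s_strand: str
    evalue: float
    bitscore: float
    aligned_query: str
    aligned_subject: str

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValueError(
                f"HSP {self.query_id}/{self.subject_id}: aligned strings differ "
                f"in length ({len(self.aligned_query)} vs {len(self.aligned_subject)})"
            )
        qlen = sum(1 for c in self.aligned_query if c != "-")
        slen = sum(1 for c in self.aligned_subject if c != "-")
        if qlen != self.q_end - self.q_start:
            raise ValueError(
                f"HSP {self.query_id}: ungapped query length {qlen} != interval "
                f"{self.q_end - self.q_start}"
            )
        if slen != self.s_end - self.s_start:
            raise ValueError(
                f"HSP {self.subject_id}: ungapped subject length {slen} != interval "
                f"{self.s_end - self.s_start}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)


def read_hsps(path: str | Path) -> list[HSPRecord]:
    """Read BLAST tabular format 6 extended with trailing qseq/sseq columns:

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore qseq sseq

    BLAST coordinates are 1-based closed; subject orientation is encoded by
    sstart > send for minus-strand hits.  Both are normalized on read.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 14:
                raise ParseError(
                    f"{path}:{lineno}: expected 14 columns (outfmt 6 + qseq sseq)"
                )
            try:
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                evalue, bits = float(parts[10]), float(parts[11])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from None
            strand = "+" if sstart <= send else "-"
            if strand == "-":
                sstart, send = send, sstart
            try:
                out.append(HSPRecord(
                    parts[0], parts[1], qstart - 1, qend, sstart - 1, send,
                    strand, evalue, bits, parts[12], parts[13],
                ))
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from None
    return out


def write_hsps(hsps: Sequence[HSPRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hsps:
            matches = sum(
                1 for a, b in zip(h.aligned_query, h.aligned_subject)
                if a == b and a != "-"
            )
            pident = 100.0 * matches / h.n_columns if h.n_columns else 0.0
            mism = sum(
                1 for a, b in zip(h.aligned_query, h.aligned_subject)
                if a != b and a != "-" and b != "-"
            )
            gapopen = 0
            prev_gap = False
            for a, b in zip(h.aligned_query, h.aligned_subject):
                gap = a == "-" or b == "-"
                if gap and not prev_gap:
                    gapopen += 1
                prev_gap = gap
            if h.s_strand == "+":
                s1, s2 = h.s_start + 1, h.s_end
            else:
                s1, s2 = h.s_end, h.s_start + 1
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, f"{pident:.3f}", h.n_columns, mism,
                gapopen, h.q_start + 1, h.q_end, s1, s2,
                f"{h.evalue:.3g}", f"{h.bitscore:.10g}",
                h.aligned_query, h.aligned_subject,
            ])) + "\n")


def read_blast_scores(path: str | Path, evalue_cutoff: float | None = None):
    """Read plain outfmt-6 similarity rows into (query, subject, bitscore)
    tuples, for reciprocal-best-hit derivation."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: expected >=12 columns")
            ev, bits = float(parts[10]), float(parts[11])
            if evalue_cutoff is not None and ev > evalue_cutoff:
                continue
            rows.append((parts[0], parts[1], bits))
    return rows


# ---------------------------------------------------------------------------
# BED intervals (peaks, repeats)
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            start, end = int(parts[1]), int(parts[2])
            if not 0 <= start < end:
                raise ParseError(f"{path}:{lineno}: invalid interval")
            out.append((parts[0], start, end))
    return sorted(out)


def write_bed_intervals(intervals: Iterable[tuple[str, int, int]],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")
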