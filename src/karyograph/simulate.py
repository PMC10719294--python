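"""Synthetic data generators with ground truth.

The centrepiece is a karyotype-evolution simulator: an ancestral genome of
``n_ancestral_chromosomes`` chromosomes evolves along a rooted species tree
under chromosome fusion, fission and reciprocal translocation plus
intra-chromosomal gene transposition, gene loss and gene duplication.  Every
extant gene traces to an ancestral gene, so the true orthology table and the
true ancestral linkage group (= ancestral chromosome) of every orthogroup are
known exactly.

Also here: distance-decay Hi-C maps with optional TAD blocks, pairwise
alignments with planted perfectly conserved elements, and ATAC peak sets with
a controlled peak-to-gene distance law.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Phylo

from .io import ContactMatrix, Gene, GenomeAnnotation, HSPRecord, OrthogroupTable


def _child_rng(seed: int, *key) -> np.random.Generator:
    """Derive an independent stream from a root seed and a structured key, so
    adding one event type or branch does not perturb the others."""
    entropy = [int(seed)] + [
        int.from_bytes(str(k).encode(), "little") % (2**32) for k in key
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Karyotype evolution
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    seed: int = 0
    tree: str = "(A:1,B:1,C:1,D:1,E:1,F:1);"
    n_ancestral_chromosomes: int = 18
    genes_per_chromosome: int = 150
    fusion_rate: float = 2.0
    fission_rate: float = 2.0
    translocation_rate: float = 0.5
    transposition_rate: float = 200.0
    gene_loss_rate: float = 0.0
    gene_dup_rate: float = 0.0
    gene_length: int = 500
    gene_spacing: int = 1000

    def __post_init__(self):
        if self.n_ancestral_chromosomes < 1:
            raise ValueError("n_ancestral_chromosomes must be >= 1")
        for name in ("fusion_rate", "fission_rate", "translocation_rate",
                     "transposition_rate", "gene_loss_rate", "gene_dup_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticClade:
    ancestor: GenomeAnnotation
    ancestral_chromosome: dict[str, str]      # ancestral gene id -> chromosome
    extant: dict[str, GenomeAnnotation]
    truth: OrthogroupTable
    alg_truth: dict[str, str]                 # orthogroup id -> ancestral chromosome
    event_log: list[tuple[str, str, dict]]
    config: SimulationConfig = None

    def write(self, outdir: str | Path) -> None:
        """Emit per-species BED + orthogroup TSV + the tree, i.e. exactly the
        inputs of the downstream modules."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in sorted(self.extant):
            ann = self.extant[sp]
            ann.to_bed(outdir / f"{sp}.bed")
            ann.write_chrom_sizes(outdir / f"{sp}.chrom.sizes")
        self.truth.write(outdir / "orthogroups.tsv")
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(self.config.tree.strip() + "\n")
        with open(outdir / "alg_truth.tsv", "w") as fh:
            fh.write("orthogroup\tancestral_chromosome\n")
            for og in sorted(self.alg_truth):
                fh.write(f"{og}\t{self.alg_truth[og]}\n")


# internal mutable genome: list of chromosomes, each an ordered list of
# (lineage_id) strings; lineage ids are globally unique per gene copy.

_EVENT_ORDER = ("fusion", "fission", "translocation", "transposition",
                "loss", "duplication")


def _apply_events(genome: list[list[str]], branch: str, length: float,
                  cfg: SimulationConfig, seed: int,
                  log: list, next_copy: list[int],
                  ancestor_of: dict[str, str]) -> None:
    rates = {
        "fusion": cfg.fusion_rate, "fission": cfg.fission_rate,
        "translocation": cfg.translocation_rate,
        "transposition": cfg.transposition_rate,
        "loss": cfg.gene_loss_rate, "duplication": cfg.gene_dup_rate,
    }
    counts = {
        ev: int(_child_rng(seed, branch, ev, "count").poisson(rates[ev] * length))
        for ev in _EVENT_ORDER
    }
    for ev in _EVENT_ORDER:
        rng = _child_rng(seed, branch, ev, "ops")
        for k in range(counts[ev]):
            if ev == "fusion":
                if len(genome) < 2:
                    log.append((branch, "fusion_skipped", {"reason": "one chromosome"}))
                    continue
                i, j = sorted(rng.choice(len(genome), size=2, replace=False))
                first = int(rng.integers(2))  # which partner goes first
                a, b = (i, j) if first == 0 else (j, i)
                merged = genome[a] + genome[b]
                log.append((branch, "fusion", {"first": a, "second": b}))
                genome[min(i, j)] = merged
                del genome[max(i, j)]
            elif ev == "fission":
                sizes = [len(c) for c in genome]
                if not sizes or max(sizes) < 2:
                    log.append((branch, "fission_skipped", {"reason": "all 1-gene"}))
                    continue
                while True:  # resample 1-gene chromosomes
                    i = int(rng.integers(len(genome)))
                    if len(genome[i]) >= 2:
                        break
                cut = int(rng.integers(1, len(genome[i])))
                left, right = genome[i][:cut], genome[i][cut:]
                log.append((branch, "fission", {"chrom": i, "cut": cut}))
                genome[i] = left
                genome.append(right)
            elif ev == "translocation":
                if len(genome) < 2:
                    log.append((branch, "translocation_skipped",
                                {"reason": "one chromosome"}))
                    continue
                i, j = sorted(rng.choice(len(genome), size=2, replace=False))
                ci = int(rng.integers(0, len(genome[i]) + 1))
                cj = int(rng.integers(0, len(genome[j]) + 1))
                gi, gj = genome[i], genome[j]
                genome[i] = gi[:ci] + gj[cj:]
                genome[j] = gj[:cj] + gi[ci:]
                log.append((branch, "translocation",
                            {"chroms": (i, j), "cuts": (ci, cj)}))
            elif ev == "transposition":
                if not genome:
                    continue
                i = int(rng.integers(len(genome)))
                if len(genome[i]) < 2:
                    continue
                src = int(rng.integers(len(genome[i])))
                gid = genome[i].pop(src)
                dst = int(rng.integers(0, len(genome[i]) + 1))
                genome[i].insert(dst, gid)
                log.append((branch, "transposition",
                            {"chrom": i, "src": src, "dst": dst}))
            elif ev == "loss":
                total = sum(len(c) for c in genome)
                if total == 0:
                    continue
                flat = int(rng.integers(total))
                for i, c in enumerate(genome):
                    if flat < len(c):
                        gid = c.pop(flat)
                        log.append((branch, "loss", {"gene": gid}))
                        break
                    flat -= len(c)
                genome[:] = [c for c in genome if c] or genome
            elif ev == "duplication":
                total = sum(len(c) for c in genome)
                if total == 0:
                    continue
                flat = int(rng.integers(total))
                src_gid = None
                for c in genome:
                    if flat < len(c):
                        src_gid = c[flat]
                        break
                    flat -= len(c)
                next_copy[0] += 1
                new_gid = f"{src_gid.split('.')[0]}.d{next_copy[0]}"
                ancestor_of[new_gid] = ancestor_of[src_gid]
                i = int(rng.integers(len(genome)))
                dst = int(rng.integers(0, len(genome[i]) + 1))
                genome[i].insert(dst, new_gid)
                log.append((branch, "duplication",
                            {"source": src_gid, "copy": new_gid}))


def _genome_to_annotation(species: str, genome: list[list[str]],
                          cfg: SimulationConfig,
                          rename: bool = True) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Lay genes out with fixed spacing; returns the annotation and the map
    species gene id -> lineage id."""
    genes = []
    lineage_of = {}
    for ci, chrom_genes in enumerate(genome):
        chrom = f"{species}_chr{ci + 1:02d}"
        for gi, lid in enumerate(chrom_genes):
            gid = f"{species}|{lid}" if rename else lid
            start = gi * cfg.gene_spacing + cfg.gene_spacing // 4
            genes.append(Gene(gid, chrom, start, start + cfg.gene_length, "+"))
            lineage_of[gid] = lid
    chromosomes = [
        (f"{species}_chr{ci + 1:02d}",
         max(1, len(chrom_genes)) * cfg.gene_spacing + cfg.gene_spacing)
        for ci, chrom_genes in enumerate(genome)
    ]
    return GenomeAnnotation(species, genes, chromosomes), lineage_of


def simulate_clade(config: SimulationConfig) -> SyntheticClade:
    """Simulate karyotype evolution along the configured tree.

    Event counts per branch are Poisson(rate x branch length); a branch
    without a stated length gets length 1.  The same config (incl. seed)
    always reproduces the identical clade.
    """
    tree = Phylo.read(_io.StringIO(config.tree), "newick")
    n_chr, n_gen = config.n_ancestral_chromosomes, config.genes_per_chromosome

    anc_genome = [
        [f"g{c:02d}_{i:04d}" for i in range(n_gen)] for c in range(n_chr)
    ]
    ancestor_of = {lid: lid for chrom in anc_genome for lid in chrom}
    anc_ann, _ = _genome_to_annotation("ancestor", anc_genome, config, rename=False)
    ancestral_chromosome = {
        lid: f"ancestor_chr{c + 1:02d}"
        for c, chrom in enumerate(anc_genome) for lid in chrom
    }

    log: list[tuple[str, str, dict]] = []
    next_copy = [0]
    extant: dict[str, GenomeAnnotation] = {}
    lineage_maps: dict[str, dict[str, str]] = {}

    # name unnamed internal nodes deterministically (preorder index)
    for idx, clade in enumerate(tree.find_clades(order="preorder")):
        if not clade.name:
            clade.name = f"node{idx}"

    def walk(clade, genome):
        for child in clade.clades:
            child_genome = [list(c) for c in genome]
            length = child.branch_length if child.branch_length is not None else 1.0
            _apply_events(child_genome, child.name, length, config, config.seed,
                          log, next_copy, ancestor_of)
            if child.is_terminal():
                ann, lmap = _genome_to_annotation(child.name, child_genome, config)
                extant[child.name] = ann
                lineage_maps[child.name] = lmap
            else:
                walk(child, child_genome)

    walk(tree.root, anc_genome)

    species = sorted(extant)
    entries: dict[str, dict[str, list[str]]] = {}
    for sp in species:
        for gid, lid in lineage_maps[sp].items():
            og = "OG_" + ancestor_of[lid]
            entries.setdefault(og, {s: [] for s in species})[sp].append(gid)
    truth = OrthogroupTable(species, entries)
    alg_truth = {
        "OG_" + lid: ancestral_chromosome[lid] for lid in ancestral_chromosome
        if "OG_" + lid in entries
    }
    return SyntheticClade(anc_ann, ancestral_chromosome, extant, truth,
                          alg_truth, log, config)


# ---------------------------------------------------------------------------
# Hi-C contact maps
# ---------------------------------------------------------------------------

def generate_contact_map(n_bins: int, mode: str = "decay_only",
                         decay_exponent: float = 1.0,
                         tad_boundaries: Sequence[int] = (),
                         tad_enrichment: float = 3.0,
                         noise_sd: float = 0.0,
                         seed: int = 0,
                         bin_size: int = 100_000,
                         chrom: str = "chrS") -> ContactMatrix:
    """Distance-decay contact map, optionally with enriched TAD blocks.

    Expected contact at bin distance s is ``(1+s)**(-decay_exponent)``; in
    ``tads`` mode pairs whose bins fall in the same inter-boundary block are
    multiplied by ``tad_enrichment``.  Noise is multiplicative log-normal with
    the given sd in log space, applied symmetrically.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if mode not in ("decay_only", "tads"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "tads" and tad_enrichment <= 1:
        raise ValueError("tad_enrichment must be > 1 in tads mode")
    for b in tad_boundaries:
        if not 0 <= b < n_bins:
            raise ValueError(f"boundary {b} outside [0, {n_bins})")

    s = np.abs(np.subtract.outer(np.arange(n_bins), np.arange(n_bins)))
    expected = (1.0 + s) ** (-decay_exponent)

    if mode == "tads":
        edges = sorted(set([0, *tad_boundaries, n_bins]))
        block = np.empty(n_bins, dtype=int)
        for k in range(len(edges) - 1):
            block[edges[k]:edges[k + 1]] = k
        same = block[:, None] == block[None, :]
        expected = np.where(same, expected * tad_enrichment, expected)

    if noise_sd > 0:
        rng = _child_rng(seed, "contact_map", n_bins, mode)
        noise = rng.normal(0.0, noise_sd, size=(n_bins, n_bins))
        noise = np.triu(noise) + np.triu(noise, 1).T
        expected = expected * np.exp(noise)

    return ContactMatrix(chrom, bin_size, expected, balanced=False)


# ---------------------------------------------------------------------------
# Alignments with planted conserved elements
# ---------------------------------------------------------------------------

_ALPHABET = np.array(list("ACGT"))
# mismatch guard run planted at each element flank; makes the true span the
# unique interval the identity-extension scan can report
GUARD = 3


def plant_conserved_alignments(n_hsps: int, hsp_len: int, n_elements: int,
                               element_len: int, background_identity: float,
                               seed: int = 0
                               ) -> tuple[list[HSPRecord], list[tuple[int, int, int]]]:
    """Random gapless alignments with per-column match probability
    ``background_identity``, except planted 100%-identity segments.

    Each planted element is flanked on both sides by a short run of forced
    mismatches so its column span is unambiguous ground truth.  Returns the
    HSP list and truth as (hsp index, col_start, col_end) triples.
    """
    if element_len > hsp_len:
        raise ValueError("element_len must be <= hsp_len")
    if not 0 <= background_identity < 0.95:
        raise ValueError("background_identity must be in [0, 0.95)")
    if n_elements > n_hsps:
        raise ValueError("at most one planted element per HSP")

    root = _child_rng(seed, "planted_alignments")
    with_element = set(root.choice(n_hsps, size=n_elements, replace=False).tolist())

    hsps: list[HSPRecord] = []
    truth: list[tuple[int, int, int]] = []
    for h in range(n_hsps):
        rng = _child_rng(seed, "planted_alignments", h)
        q = rng.choice(_ALPHABET, size=hsp_len)
        match = rng.random(hsp_len) < background_identity
        # mismatching columns: shift by 1-3 letters so chars always differ
        shift = rng.integers(1, 4, size=hsp_len)
        q_idx = np.searchsorted(_ALPHABET, q)
        s = np.where(match, q, _ALPHABET[(q_idx + shift) % 4])
        if h in with_element:
            lo = GUARD
            hi = hsp_len - element_len - GUARD
            start = int(rng.integers(lo, hi + 1))
            s = s.copy()
            s[start:start + element_len] = q[start:start + element_len]
            for g in range(1, GUARD + 1):  # forced flanking mismatches
                for pos in (start - g, start + element_len + g - 1):
                    s[pos] = _ALPHABET[(q_idx[pos] + 1) % 4]
            truth.append((h, start, start + element_len))
        hsps.append(HSPRecord(
            query_id=f"qchr{h}", subject_id=f"schr{h}",
            q_start=0, q_end=hsp_len, s_start=0, s_end=hsp_len,
            s_strand="+", evalue=1e-20, bitscore=100.0,
            aligned_query="".join(q), aligned_subject="".join(s),
        ))
    return hsps, truth


# ---------------------------------------------------------------------------
# ATAC peak sets
# ---------------------------------------------------------------------------

@dataclass
class ATACPeakSet:
    species_id: str
    peaks: list[tuple[str, int, int]]
    repeat_filtered: bool = False

    def __post_init__(self):
        self.peaks = sorted(self.peaks)
        for chrom, start, end in self.peaks:
            if not 0 <= start < end:
                raise ValueError(f"invalid peak [{start},{end}) on {chrom}")

    def __len__(self):
        return len(self.peaks)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.peaks:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def generate_atac_dataset(annotation: GenomeAnnotation, n_peaks: int,
                          distance_law: str = "exponential",
                          mean_distance: float = 100.0,
                          peak_width: int = 150,
                          seed: int = 0,
                          max_tries: int = 200
                          ) -> tuple[ATACPeakSet, list[int]]:
    """Place peaks at signed exponential offsets from uniformly chosen gene
    boundaries, within intergenic space.  Returns the peak set and the true
    planted offset (gap between the peak and its anchor gene) per peak."""
    if distance_law != "exponential":
        raise ValueError(f"unknown distance law {distance_law!r}")
    if not annotation.genes:
        raise ValueError("annotation has no genes")
    rng = _child_rng(seed, "atac", annotation.species_id)
    genes = annotation.genes
    peaks: list[tuple[str, int, int]] = []
    offsets: list[int] = []

    # per-chromosome sorted gene intervals for overlap rejection
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    for v in by_chrom.values():
        v.sort()

    def overlaps_gene(chrom: str, s: int, e: int) -> bool:
        import bisect
        iv = by_chrom[chrom]
        i = bisect.bisect_left(iv, (e, e))
        for gs, ge in iv[max(0, i - 2):i + 1]:
            if gs < e and s < ge:
                return True
        return False

    placed = 0
    attempts = 0
    while placed < n_peaks:
        attempts += 1
        if attempts > max_tries * max(1, n_peaks):
            raise ValueError("no intergenic space to place peaks")
        g = genes[int(rng.integers(len(genes)))]
        side = int(rng.integers(2))        # 0: upstream of start, 1: downstream of end
        gap = int(round(rng.exponential(mean_distance))) + 1
        if side == 0:
            end = g.start - gap
            start = end - peak_width
        else:
            start = g.end + gap
            end = start + peak_width
        if start < 0 or end > annotation.chrom_sizes[g.chrom]:
            continue
        if overlaps_gene(g.chrom, start, end):
            continue
        peaks.append((g.chrom, start, end))
        offsets.append(gap)
        placed += 1
    return ATACPeakSet(annotation.species_id, peaks), offsets
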