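import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from karyograph.io import Gene, GenomeAnnotation, OrthogroupTable
from karyograph.simulate import SimulationConfig, simulate_clade


@pytest.fixture
def tiny_annotation():
    """Two chromosomes, five genes, deliberately unsorted input order."""
    genes = [
        Gene("gC", "chr1", 500, 600, "+"),
        Gene("gA", "chr1", 100, 200, "+"),
        Gene("gB", "chr1", 300, 400, "-"),
        Gene("gE", "chr2", 250, 350, "+"),
        Gene("gD", "chr2", 50, 150, "+"),
    ]
    return GenomeAnnotation("S1", genes, [("chr1", 1000), ("chr2", 500)])


@pytest.fixture
def clone_clade():
    """Three identical genomes (all event rates zero): every downstream
    comparison has a known, trivial answer."""
    cfg = SimulationConfig(
        seed=5, tree="(A:1,B:1,C:1);", n_ancestral_chromosomes=3,
        genes_per_chromosome=20, fusion_rate=0, fission_rate=0,
        translocation_rate=0, transposition_rate=0,
        gene_loss_rate=0, gene_dup_rate=0,
    )
    return simulate_clade(cfg)


def random_genome_pair(rng, n_genes, n_chroms=2, n_paralogs=0):
    """Two random single-chromosome-set genomes over a shared orthogroup
    universe, with optional duplicated orthogroups; used by the microsynteny
    oracle tests."""
    ogs = [f"OG{i}" for i in range(n_genes)]

    def genome(sp):
        order = list(rng.permutation(n_genes))
        items = [ogs[i] for i in order]
        items += [ogs[int(rng.integers(n_genes))] for _ in range(n_paralogs)]
        genes, entries = [], {}
        if n_chroms > 1 and len(items) > n_chroms:
            cuts = sorted(rng.choice(range(1, len(items)), size=n_chroms - 1,
                                     replace=False))
        else:
            cuts = []
        bounds = [0] + list(cuts) + [len(items)]
        k = 0
        for c in range(len(bounds) - 1):
            for pos, og in enumerate(items[bounds[c]:bounds[c + 1]]):
                gid = f"{sp}_g{k}"
                k += 1
                genes.append(Gene(gid, f"{sp}_chr{c}", pos * 10, pos * 10 + 5))
                entries.setdefault(og, []).append(gid)
        return genes, entries

    ga, ea = genome("A")
    gb, eb = genome("B")
    ann_a = GenomeAnnotation("A", ga)
    ann_b = GenomeAnnotation("B", gb)
    entries = {og: {"A": ea.get(og, []), "B": eb.get(og, [])}
               for og in set(ea) | set(eb)}
    return ann_a, ann_b, OrthogroupTable(["A", "B"], entries)


def matches_as_tuples(ann_a, ann_b, table):
    out = []
    for og in sorted(table.entries):
        row = table.entries[og]
        for a in row["A"]:
            ca, oa = ann_a.rank_index[a]
            for b in row["B"]:
                cb, ob = ann_b.rank_index[b]
                out.append((og, ca, oa, cb, ob, a, b))
    return out


def atac_species_summaries(beta, seed, n_peaks=300,
                           sizes_mb=(200, 400, 600, 800)):
    """Four synthetic species with genome sizes spanning 200-800 Mb whose
    mean peak-to-gene distance is beta * genome size; returns their distance
    summaries for the size regression."""
    from karyograph.atac import peak_gene_distances
    from karyograph.simulate import generate_atac_dataset

    spacing = 50_000
    summaries = []
    for k, mb in enumerate(sizes_mb):
        n_chrom = 10
        genes_per_chrom = int(mb * 1_000_000 / (n_chrom * spacing))
        cfg = SimulationConfig(
            seed=seed * 100 + k, tree="(A:1,B:1);",
            n_ancestral_chromosomes=n_chrom,
            genes_per_chromosome=genes_per_chrom,
            fusion_rate=0, fission_rate=0, translocation_rate=0,
            transposition_rate=0, gene_spacing=spacing)
        ann = simulate_clade(cfg).extant["A"]
        peaks, _ = generate_atac_dataset(
            ann, n_peaks, mean_distance=beta * ann.genome_size,
            seed=seed * 100 + k)
        summaries.append(peak_gene_distances(peaks, ann))
    return summaries
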