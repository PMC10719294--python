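import numpy as np
import pytest

from karyograph.simulate import (SimulationConfig, generate_atac_dataset,
                                 generate_contact_map,
                                 plant_conserved_alignments, simulate_clade)


class TestClade:
    def test_zero_rates_give_clone_set(self, clone_clade):
        c = clone_clade
        anc_per_chrom = {ch: ids for ch, ids in c.ancestor.chrom_genes.items()}
        for sp, ann in c.extant.items():
            assert len(ann.chromosomes) == len(c.ancestor.chromosomes)
            assert len(ann) == len(c.ancestor)
        # every orthogroup single copy in every species
        for og, row in c.truth.entries.items():
            assert all(len(g) == 1 for g in row.values())
        assert c.event_log == []
        assert anc_per_chrom  # ancestor retains its chromosome structure

    def test_single_fusion_reduces_chromosome_count(self):
        # pick a seed whose log shows exactly one fusion on some branch
        for seed in range(30):
            cfg = SimulationConfig(seed=seed, tree="(A:1,B:1);",
                                   n_ancestral_chromosomes=5,
                                   genes_per_chromosome=10,
                                   fusion_rate=0.5, fission_rate=0,
                                   translocation_rate=0, transposition_rate=0)
            c = simulate_clade(cfg)
            by_branch = {}
            for br, ev, _ in c.event_log:
                by_branch.setdefault(br, []).append(ev)
            for sp in c.extant:
                evs = by_branch.get(sp, [])
                if evs == ["fusion"]:
                    assert len(c.extant[sp].chromosomes) == 4
                    return
        pytest.fail("no seed produced a single-fusion branch")

    def test_fission_increases_chromosome_count(self):
        cfg = SimulationConfig(seed=3, tree="(A:1,B:1);",
                               n_ancestral_chromosomes=4,
                               genes_per_chromosome=10,
                               fusion_rate=0, fission_rate=1.0,
                               translocation_rate=0, transposition_rate=0)
        c = simulate_clade(cfg)
        for sp in c.extant:
            n_fis = sum(1 for br, ev, _ in c.event_log
                        if br == sp and ev == "fission")
            assert len(c.extant[sp].chromosomes) == 4 + n_fis

    def test_duplications_add_exactly_logged_genes(self):
        cfg = SimulationConfig(seed=7, tree="(A:1,B:1);",
                               n_ancestral_chromosomes=3,
                               genes_per_chromosome=15,
                               fusion_rate=0, fission_rate=0,
                               translocation_rate=0, transposition_rate=0,
                               gene_dup_rate=2.0)
        c = simulate_clade(cfg)
        for sp in c.extant:
            n_dup = sum(1 for br, ev, _ in c.event_log
                        if br == sp and ev == "duplication")
            assert len(c.extant[sp]) == 45 + n_dup

    def test_gene_content_conserved_without_loss_or_dup(self):
        cfg = SimulationConfig(seed=2, tree="(A:1,B:1,C:1);",
                               n_ancestral_chromosomes=4,
                               genes_per_chromosome=12,
                               transposition_rate=50.0)
        c = simulate_clade(cfg)
        for sp, ann in c.extant.items():
            assert len(ann) == 48
        assert len(c.truth) == 48

    def test_same_seed_reproduces_identical_clade(self):
        cfg = SimulationConfig(seed=11, n_ancestral_chromosomes=5,
                               genes_per_chromosome=10)
        a, b = simulate_clade(cfg), simulate_clade(cfg)
        assert a.event_log == b.event_log
        for sp in a.extant:
            assert a.extant[sp].genes == b.extant[sp].genes

    def test_alg_truth_labels_cover_orthogroups(self):
        cfg = SimulationConfig(seed=4, n_ancestral_chromosomes=3,
                               genes_per_chromosome=8)
        c = simulate_clade(cfg)
        assert set(c.alg_truth) == set(c.truth.entries)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_ancestral_chromosomes=0)
        with pytest.raises(ValueError):
            SimulationConfig(fusion_rate=-1)


class TestContactMap:
    def test_noiseless_decay_closed_form(self):
        m = generate_contact_map(20, "decay_only", decay_exponent=1.0,
                                 noise_sd=0.0)
        i, j = np.indices(m.values.shape)
        assert np.allclose(m.values, 1.0 / (1.0 + np.abs(i - j)))

    def test_tad_enrichment_ratio_at_equal_distance(self):
        m = generate_contact_map(100, "tads", decay_exponent=1.0,
                                 tad_boundaries=[50], tad_enrichment=3.0,
                                 noise_sd=0.0)
        # distance 5: within-block vs cross-block
        within = m.values[10, 15]
        cross = m.values[48, 53]
        assert within / cross == pytest.approx(3.0)

    def test_same_seed_identical(self):
        a = generate_contact_map(30, noise_sd=0.3, seed=9)
        b = generate_contact_map(30, noise_sd=0.3, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_output_symmetric_with_noise(self):
        m = generate_contact_map(40, noise_sd=0.5, seed=1)
        assert np.allclose(m.values, m.values.T)

    def test_boundary_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_contact_map(20, "tads", tad_boundaries=[25],
                                 tad_enrichment=2.0)


class TestPlantedAlignments:
    def test_planted_element_is_perfectly_conserved(self):
        hsps, truth = plant_conserved_alignments(
            n_hsps=1, hsp_len=100, n_elements=1, element_len=30,
            background_identity=0.0, seed=0)
        (h,) = hsps
        ((idx, s, e),) = truth
        matches = [a == b for a, b in zip(h.aligned_query, h.aligned_subject)]
        assert sum(matches) == 30
        assert all(matches[s:e])

    def test_no_elements_empty_truth(self):
        hsps, truth = plant_conserved_alignments(3, 50, 0, 20, 0.5, seed=1)
        assert truth == []
        assert len(hsps) == 3

    def test_deterministic(self):
        a = plant_conserved_alignments(5, 200, 2, 40, 0.7, seed=42)
        b = plant_conserved_alignments(5, 200, 2, 40, 0.7, seed=42)
        assert [h.aligned_query for h in a[0]] == [h.aligned_query for h in b[0]]
        assert a[1] == b[1]

    def test_too_many_elements_rejected(self):
        with pytest.raises(ValueError, match="one planted element"):
            plant_conserved_alignments(2, 100, 3, 20, 0.5)


class TestAtacDataset:
    def test_peaks_disjoint_from_genes(self, clone_clade):
        ann = clone_clade.extant["A"]
        peaks, _ = generate_atac_dataset(ann, 100, mean_distance=80, seed=0)
        gene_iv = {(g.chrom, g.start, g.end) for g in ann.genes}
        for chrom, s, e in peaks.peaks:
            for gc, gs, ge in gene_iv:
                if gc == chrom:
                    assert not (gs < e and s < ge)

    def test_mean_offset_near_request(self):
        # wide intergenic space so the exponential law is barely truncated
        cfg = SimulationConfig(seed=8, tree="(A:1,B:1);",
                               n_ancestral_chromosomes=4,
                               genes_per_chromosome=50,
                               fusion_rate=0, fission_rate=0,
                               translocation_rate=0, transposition_rate=0,
                               gene_spacing=5000)
        ann = simulate_clade(cfg).extant["A"]
        _, offsets = generate_atac_dataset(ann, 2000, mean_distance=100, seed=3)
        assert np.mean(offsets) == pytest.approx(100, rel=0.10)

    def test_zero_peaks(self, clone_clade):
        peaks, offsets = generate_atac_dataset(clone_clade.extant["A"], 0)
        assert len(peaks) == 0 and offsets == []
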