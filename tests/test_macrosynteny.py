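import pandas as pd
import pytest

from karyograph.alg import ALGPartition
from karyograph.io import Gene, GenomeAnnotation, OrthogroupTable
from karyograph.macrosynteny import (ancestor_mapping,
                                     chromosome_correspondence, oxford_table,
                                     project_algs)
from karyograph.orthology import MutualBestHitSet


def ann(species, spec):
    """spec: list of (gene, chrom, start)."""
    return GenomeAnnotation(
        species, [Gene(g, c, s, s + 10) for g, c, s in spec])


def make_partition(assignment, resolution=1.0):
    return ALGPartition(assignment, n_algs=len(set(assignment.values())),
                        modularity=0.0, resolution=resolution, stability=1.0)


class TestOxfordTable:
    def test_ordinals_from_rank_index(self):
        a = ann("A", [("a1", "c1", 0), ("a2", "c1", 100)])
        b = ann("B", [("b1", "x1", 0), ("b2", "x1", 100)])
        t = OrthogroupTable(["A", "B"], {
            "OG1": {"A": ["a1"], "B": ["b1"]},
            "OG2": {"A": ["a2"], "B": ["b2"]},
        })
        df = oxford_table(t, a, b)
        assert list(zip(df.ordinal_a, df.ordinal_b)) == [(0, 0), (1, 1)]

    def test_multi_copy_excluded_by_default(self):
        a = ann("A", [("a1", "c1", 0), ("a2", "c1", 100)])
        b = ann("B", [("b1", "x1", 0)])
        t = OrthogroupTable(["A", "B"], {"OG1": {"A": ["a1", "a2"],
                                                 "B": ["b1"]}})
        assert oxford_table(t, a, b).empty
        assert len(oxford_table(t, a, b, expand_multi=True)) == 2

    def test_partition_labels_joined(self):
        a = ann("A", [("a1", "c1", 0)])
        b = ann("B", [("b1", "x1", 0)])
        t = OrthogroupTable(["A", "B"], {"OG1": {"A": ["a1"], "B": ["b1"]}})
        df = oxford_table(t, a, b, partition=make_partition({"OG1": 7}))
        assert df.alg.tolist() == [7]

    def test_missing_gene_rejected(self):
        a = ann("A", [("a1", "c1", 0)])
        b = ann("B", [("b1", "x1", 0)])
        t = OrthogroupTable(["A", "B"], {"OG1": {"A": ["zz"], "B": ["b1"]}})
        with pytest.raises(KeyError, match="zz"):
            oxford_table(t, a, b)

    def test_transpose_symmetry(self):
        a = ann("A", [("a1", "c1", 0), ("a2", "c1", 50), ("a3", "c2", 0)])
        b = ann("B", [("b1", "x1", 0), ("b2", "x2", 50), ("b3", "x2", 90)])
        t = OrthogroupTable(["A", "B"], {
            f"OG{i}": {"A": [f"a{i}"], "B": [f"b{i}"]} for i in (1, 2, 3)
        })
        fwd = oxford_table(t, a, b)
        rev = oxford_table(t, b, a)
        fwd_pairs = set(zip(fwd.gene_a, fwd.gene_b, fwd.ordinal_a, fwd.ordinal_b))
        rev_pairs = set(zip(rev.gene_b, rev.gene_a, rev.ordinal_b, rev.ordinal_a))
        assert fwd_pairs == rev_pairs

    def test_accepts_mutual_best_hits(self):
        a = ann("A", [("a1", "c1", 0)])
        b = ann("B", [("x1", "k1", 0)])
        mb = MutualBestHitSet("A", "B", [("a1", "x1", 99.0)])
        df = oxford_table(mb, a, b)
        assert df.chrom_a.tolist() == ["c1"] and df.chrom_b.tolist() == ["k1"]


def table_from_counts(counts):
    """Build an Oxford-style frame with the given (chrom_a, chrom_b) pair
    counts."""
    rows = []
    k = 0
    for (ca, cb), n in counts.items():
        for _ in range(n):
            rows.append((f"a{k}", f"b{k}", ca, k, cb, k, None))
            k += 1
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "chrom_a",
                                       "ordinal_a", "chrom_b", "ordinal_b",
                                       "alg"])


class TestCorrespondence:
    def test_one_to_one(self):
        t = table_from_counts({("A1", "B1"): 50, ("A1", "B2"): 2})
        c = chromosome_correspondence(t)
        assert c.classification_a["A1"] == "1-to-1"
        assert c.partners_a["A1"] == ["B1"]

    def test_one_to_two(self):
        t = table_from_counts({("A2", "B2"): 30, ("A2", "B3"): 30})
        c = chromosome_correspondence(t)
        assert c.classification_a["A2"] == "1-to-2"

    def test_below_thresholds_is_one_to_zero(self):
        t = table_from_counts({("A1", "B1"): 3, ("A2", "B1"): 100})
        c = chromosome_correspondence(t, min_count=5)
        assert c.classification_a["A1"] == "1-to-0"

    def test_contingency_sums_to_rows(self):
        t = table_from_counts({("A1", "B1"): 10, ("A1", "B2"): 6,
                               ("A2", "B2"): 4})
        c = chromosome_correspondence(t)
        assert int(c.contingency.values.sum()) == len(t)

    def test_symmetric_classification_for_b(self):
        t = table_from_counts({("A1", "B1"): 20, ("A2", "B1"): 20})
        c = chromosome_correspondence(t)
        assert c.classification_b["B1"] == "1-to-2"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            chromosome_correspondence(table_from_counts({}))


class TestProjectAlgs:
    def placements_from(self, chrom_of):
        return {"S": dict(chrom_of)}

    def test_fusion_called_when_two_algs_exceed_thresholds(self):
        chrom_of = {f"og{i}": "chr1" for i in range(75)}
        part = {f"og{i}": (1 if i < 40 else 2) for i in range(75)}
        proj = project_algs(make_partition(part), self.placements_from(chrom_of),
                            "S")
        assert proj.fusions == [("chr1", (1, 2))]

    def test_fission_called_when_alg_spans_two_chromosomes(self):
        chrom_of = {f"og{i}": ("chr1" if i < 60 else "chr2")
                    for i in range(105)}
        part = {f"og{i}": 3 for i in range(105)}
        proj = project_algs(make_partition(part), self.placements_from(chrom_of),
                            "S")
        assert proj.fissions == [(3, ("chr1", "chr2"))]

    def test_minor_contamination_below_count_threshold_ignored(self):
        chrom_of = {f"og{i}": "chr1" for i in range(98)}
        part = {f"og{i}": (1 if i < 95 else 2) for i in range(98)}
        proj = project_algs(make_partition(part), self.placements_from(chrom_of),
                            "S")
        assert proj.fusions == [] and proj.fissions == []

    def test_unknown_species_rejected(self):
        with pytest.raises(KeyError):
            project_algs(make_partition({"og": 1}), {}, "S")


class TestAncestorMapping:
    def test_set_arithmetic_and_strict_fade_threshold(self):
        parent = make_partition({f"OG{i}": "P1" for i in range(1, 11)})
        child = make_partition({**{f"OG{i}": "C1" for i in range(1, 9)},
                                **{f"OG{i}": "C2" for i in (9, 10)}})
        edges = {(e.parent, e.child): e for e in ancestor_mapping(parent, child)}
        assert edges[("P1", "C1")].weight == pytest.approx(0.8)
        assert edges[("P1", "C2")].weight == pytest.approx(0.2)
        # 0.8 is not > 0.8: not flagged
        assert not edges[("P1", "C1")].near_one_to_one

    def test_identical_partitions_flagged(self):
        p = make_partition({"OG1": "X", "OG2": "X"})
        (e,) = ancestor_mapping(p, p)
        assert e.weight == 1.0 and e.near_one_to_one

    def test_disjoint_universes_no_edges(self):
        p = make_partition({"OG1": "P"})
        c = make_partition({"OG2": "C"})
        assert ancestor_mapping(p, c) == []


class TestCloneCladeInvariants:
    def test_every_chromosome_one_to_one_on_clone_clade(self, clone_clade):
        c = clone_clade
        df = oxford_table(c.truth, c.extant["A"], c.extant["B"])
        cmap = chromosome_correspondence(df)
        assert all(v == "1-to-1" for v in cmap.classification_a.values())
        assert all(v == "1-to-1" for v in cmap.classification_b.values())
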