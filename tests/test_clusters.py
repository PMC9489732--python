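import numpy as np
import pandas as pd
import pytest

from hyperchrom import clusters as cl
from hyperchrom import simulate as sim
from hyperchrom.io import GenomicInterval, IntervalSet, MotifTable

from conftest import make_read


def interval_set(*triples):
    return IntervalSet([GenomicInterval(*t) for t in triples])


def annotate_single(read, atac, polii, genes=None, expression=None, **kw):
    return cl.annotate_loci(
        [read],
        atac,
        polii,
        genes if genes is not None else IntervalSet(),
        expression or {},
        **kw,
    )[0]


class TestAnnotation:
    def test_locus_inside_peak_is_accessible(self):
        contact = annotate_single(
            make_read("r", [("chr1", 100_000, 101_000)]),
            atac=interval_set(("chr1", 90_000, 120_000)),
            polii=IntervalSet(),
        )
        assert contact.loci[0].accessible
        assert not contact.loci[0].polii_bound

    def test_gene_within_flank_is_attached(self):
        genes = IntervalSet([GenomicInterval("chr1", 105_000, 107_000, "g1")])
        contact = annotate_single(
            make_read("r", [("chr1", 100_000, 101_000)]),
            atac=IntervalSet(),
            polii=IntervalSet(),
            genes=genes,
            expression={"g1": 10.0},
        )
        # gene body starts 4 kb downstream of the locus end: inside the 5 kb flank
        assert contact.loci[0].genes == [("g1", True)]

    def test_gene_beyond_flank_is_excluded(self):
        genes = IntervalSet([GenomicInterval("chr1", 106_500, 108_000, "g1")])
        contact = annotate_single(
            make_read("r", [("chr1", 100_000, 101_000)]),
            atac=IntervalSet(),
            polii=IntervalSet(),
            genes=genes,
            expression={"g1": 10.0},
        )
        assert contact.loci[0].genes == []

    def test_flank_clipped_at_chromosome_start_and_end(self):
        contact = annotate_single(
            make_read("r", [("chr1", 2_000, 3_000)]),
            atac=IntervalSet(),
            polii=IntervalSet(),
            chrom_sizes={"chr1": 6_000},
        )
        assert contact.loci[0].flanked.start == 0
        assert contact.loci[0].flanked.end == 6_000

    def test_missing_expression_treated_unexpressed(self, caplog):
        genes = IntervalSet([GenomicInterval("chr1", 100_500, 102_000, "gX")])
        with caplog.at_level("WARNING"):
            contact = annotate_single(
                make_read("r", [("chr1", 100_000, 101_000)]),
                atac=IntervalSet(),
                polii=IntervalSet(),
                genes=genes,
                expression={},
            )
        assert contact.loci[0].genes == [("gX", False)]
        assert "gX" in caplog.text

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            annotate_single(
                make_read("r", [("chr1", 0, 10)]),
                atac=IntervalSet(),
                polii=IntervalSet(),
                flank=-1,
            )


def build_contact(read_id, flags):
    """flags: list of (accessible, polii, [(gene, expressed), ...])."""
    loci = []
    for i, (acc, pol, genes) in enumerate(flags):
        iv = GenomicInterval("chr1", 1000 * (i + 1), 1000 * (i + 1) + 100)
        loci.append(cl.AnnotatedLocus(iv, iv, acc, pol, list(genes), {}))
    return cl.AnnotatedContact(read_id, loci)


class TestPotential:
    def test_all_accessible_one_polii_is_potential(self):
        contact = build_contact("r", [(True, True, []), (True, False, []), (True, False, [])])
        assert len(cl.find_potential_clusters([contact])) == 1

    def test_one_inaccessible_locus_excludes(self):
        contact = build_contact("r", [(True, True, []), (False, False, [])])
        assert cl.find_potential_clusters([contact]) == []

    def test_no_polii_excludes(self):
        contact = build_contact("r", [(True, False, []), (True, False, [])])
        assert cl.find_potential_clusters([contact]) == []

    def test_order_one_contact_excluded(self):
        contact = build_contact("r", [(True, True, [])])
        assert cl.find_potential_clusters([contact]) == []


class TestCommonTFs:
    def test_two_genes_require_both_bound(self, toy_motifs):
        # TF_A counts (5, 3): both >= 3 -> common; TF_B (4, 0) -> not
        assert cl.common_tfs(["g1", "g2"], toy_motifs) == ["TF_A"]

    def test_count_below_min_sites_not_common(self):
        counts = pd.DataFrame({"TF_A": [5, 2]}, index=["g1", "g2"])
        assert cl.common_tfs(["g1", "g2"], MotifTable(counts)) == []

    def test_three_genes_use_strict_majority(self):
        counts = pd.DataFrame(
            {"TF_A": [4, 3, 0], "TF_B": [9, 0, 0]}, index=["g1", "g2", "g3"]
        )
        motifs = MotifTable(counts)
        # TF_A binds 2/3 (strict majority) -> common; TF_B binds 1/3 -> not
        assert cl.common_tfs(["g1", "g2", "g3"], motifs) == ["TF_A"]

    def test_four_genes_need_three(self):
        counts = pd.DataFrame({"TF_A": [4, 4, 0, 0]}, index=list("abcd"))
        assert cl.common_tfs(list("abcd"), MotifTable(counts)) == []


class TestTiers:
    def make_cluster(self, genes, motifs):
        flags = [(True, True, [(g, True)]) for g in genes]
        if len(flags) < 2:  # potential clusters need order >= 2
            flags.append((True, False, []))
        contact = build_contact("r", flags)
        (cluster,) = cl.find_potential_clusters([contact])
        cl.find_clusters([cluster], motifs)
        return cluster

    def test_cluster_requires_two_expressed_genes_and_common_tf(self, toy_motifs):
        cluster = self.make_cluster(["g1", "g2"], toy_motifs)
        assert cluster.status == "cluster"
        assert cluster.common_tfs == ["TF_A"]

    def test_one_expressed_gene_stays_potential(self, toy_motifs):
        cluster = self.make_cluster(["g1"], toy_motifs)
        assert cluster.status == "potential"

    def test_specialized_needs_master_regulator(self, toy_motifs):
        cluster = self.make_cluster(["g1", "g2"], toy_motifs)
        cl.find_specialized([cluster], toy_motifs)
        # TF_A's encoding gene is g1 with 5 self-sites -> master regulator
        assert cluster.status == "specialized"
        assert cluster.common_mrs == ["TF_A"]

    def test_common_tf_without_self_binding_not_specialized(self):
        counts = pd.DataFrame({"TF_B": [4, 3, 0]}, index=["g1", "g2", "gB"])
        motifs = MotifTable(counts, {"TF_B": "gB"})
        cluster = self.make_cluster(["g1", "g2"], motifs)
        cl.find_specialized([cluster], motifs)
        assert cluster.status == "cluster" and cluster.common_mrs == []

    def test_unmapped_tf_cannot_be_master_regulator(self):
        counts = pd.DataFrame({"TF_X": [4, 3]}, index=["g1", "g2"])
        motifs = MotifTable(counts, {})
        cluster = self.make_cluster(["g1", "g2"], motifs)
        assert cl.find_specialized([cluster], motifs) == []


class TestSelfSustaining:
    def test_tf_gene_in_cluster_with_binding_is_self_sustaining(self):
        # gA encodes TF_A; TF_A binds g2 (in cluster) but not gA
        counts = pd.DataFrame({"TF_A": [0, 5, 4]}, index=["gA", "g2", "g3"])
        motifs = MotifTable(counts, {"TF_A": "gA"})
        cluster = TestTiers().make_cluster(["gA", "g2", "g3"], motifs)
        assert cluster.status == "cluster"  # TF_A binds 2/3, strict majority
        cl.find_self_sustaining([cluster], motifs)
        assert cluster.self_sustaining and not cluster.core

    def test_self_binding_master_regulator_makes_core(self):
        counts = pd.DataFrame({"TF_A": [5, 4]}, index=["gA", "g2"])
        motifs = MotifTable(counts, {"TF_A": "gA"})
        cluster = TestTiers().make_cluster(["gA", "g2"], motifs)
        cl.find_self_sustaining([cluster], motifs)
        assert cluster.self_sustaining and cluster.core

    def test_analog_independent_pair_across_clusters(self):
        # cluster X expresses gC (encoding TF_C); TF_C binds only in cluster Y
        counts = pd.DataFrame(
            {"TF_C": [0, 0, 5, 3], "TF_D": [4, 3, 0, 0]},
            index=["gC", "gx", "gy1", "gy2"],
        )
        motifs = MotifTable(counts, {"TF_C": "gC"})
        tiers = TestTiers()
        x = tiers.make_cluster(["gC", "gx"], motifs)
        y = tiers.make_cluster(["gy1", "gy2"], motifs)
        report = cl.find_self_sustaining([x, y], motifs)
        assert not x.self_sustaining and not y.self_sustaining
        assert report.analog_independent_pairs == [("TF_C", 0, 1)]

    def test_unclustered_tf_gene_tallied(self):
        counts = pd.DataFrame({"TF_E": [5, 3]}, index=["g1", "g2"])
        motifs = MotifTable(counts, {"TF_E": "gE"})
        cluster = TestTiers().make_cluster(["g1", "g2"], motifs)
        report = cl.find_self_sustaining(
            [cluster], motifs, expression={"gE": 8.0}, expr_threshold=1.0
        )
        assert report.unclustered_tf_genes == ["TF_E"]


class TestEnrichment:
    def annotated_pool(self, n=20, factor_at=()):
        contacts = []
        for i in range(n):
            loci = []
            for k in range(3):
                iv = GenomicInterval("chr1", 10_000 * i + 1_000 * k, 10_000 * i + 1_000 * k + 100)
                loci.append(
                    cl.AnnotatedLocus(iv, iv, True, k == 0, [], {"ctcf": i in factor_at})
                )
            contacts.append(cl.AnnotatedContact(f"r{i}", loci))
        return contacts

    def test_factor_everywhere_gives_p_near_one(self):
        contacts = self.annotated_pool(factor_at=range(20))
        clusters = cl.find_potential_clusters(contacts[:5])
        res = cl.binding_enrichment(clusters, contacts, "ctcf", n_trials=50, seed=0)
        assert res.cluster_fraction == 1.0
        assert res.background_fraction == 1.0
        assert res.p_value == 1.0

    def test_no_peaks_gives_zero_fractions(self):
        contacts = self.annotated_pool(factor_at=())
        clusters = cl.find_potential_clusters(contacts[:5])
        res = cl.binding_enrichment(clusters, contacts, "ctcf", n_trials=50, seed=0)
        assert res.cluster_fraction == 0.0 and res.background_fraction == 0.0

    def test_planted_factor_only_at_clusters_is_significant(self):
        contacts = self.annotated_pool(n=100, factor_at=range(5))
        clusters = cl.find_potential_clusters(contacts[:5])
        res = cl.binding_enrichment(clusters, contacts, "ctcf", n_trials=200, seed=1)
        assert res.cluster_fraction == 1.0
        assert res.p_value <= 0.01

    def test_empty_clusters_rejected(self):
        with pytest.raises(ValueError):
            cl.binding_enrichment([], self.annotated_pool(), "ctcf")


class TestClusterPermutation:
    def test_all_contacts_satisfying_gives_p_one(self, toy_motifs):
        contacts = [
            build_contact(f"r{i}", [(True, True, [("g1", True)]), (True, False, [("g2", True)]), (True, False, [])])
            for i in range(10)
        ]
        candidates = cl.find_potential_clusters(contacts)
        cl.find_clusters(candidates, toy_motifs)
        frame = cl.permutation_test_clusters(contacts, candidates, toy_motifs, n_trials=50, seed=0)
        assert (frame["p_value"] == 1.0).all()

    def test_reproducible_under_seed(self, toy_motifs):
        contacts = [
            build_contact(f"r{i}", [(True, True, [("g1", i % 2 == 0)]), (True, False, [("g2", True)]), (True, False, [])])
            for i in range(20)
        ]
        candidates = cl.find_potential_clusters(contacts[:8])
        cl.find_clusters(candidates, toy_motifs)
        f1 = cl.permutation_test_clusters(contacts, candidates, toy_motifs, n_trials=40, seed=9)
        f2 = cl.permutation_test_clusters(contacts, candidates, toy_motifs, n_trials=40, seed=9)
        pd.testing.assert_frame_equal(f1, f2)
        assert f1["p_value"].between(0, 1).all()


class TestRanking:
    def test_frequency_is_fraction_of_clusters_bound(self, toy_motifs):
        tiers = TestTiers()
        bound = [tiers.make_cluster(["g1", "g2"], toy_motifs) for _ in range(2)]
        unbound = [tiers.make_cluster(["g3", "g3b"], toy_motifs) for _ in range(2)]
        rank = cl.rank_tfs(bound + unbound, toy_motifs)
        assert rank.iloc[0]["tf"] == "TF_A"
        assert rank.iloc[0]["frequency"] == 0.5

    def test_overlap_identical_and_disjoint(self, toy_motifs):
        a = pd.DataFrame({"tf": ["TF_A", "TF_B"], "frequency": [1.0, 0.5]})
        b = pd.DataFrame({"tf": ["TF_C", "TF_D"], "frequency": [1.0, 0.5]})
        assert cl.tf_overlap(a, a, k=2) == 1.0
        assert cl.tf_overlap(a, b, k=2) == 0.0


@pytest.fixture(scope="module")
def dataset():
    config = sim.SimConfig(seed=5, n_reads=600)
    ds = sim.simulate_dataset(config)
    annotated = cl.annotate_loci(
        ds.reads, ds.atac, ds.polii, ds.genes, ds.expression,
        config.flank, config.expr_threshold, config.chrom_sizes, ds.factors,
    )
    return config, ds, annotated


class TestPipelineInvariants:

    def test_containment_chain(self, dataset):
        config, ds, annotated = dataset
        potential, _ = cl.identify_clusters(
            annotated, ds.motifs, config.min_sites, ds.expression, config.expr_threshold
        )
        ids = {
            "potential": {c.read_id for c in potential},
            "cluster": {c.read_id for c in potential if c.status in ("cluster", "specialized")},
            "specialized": {c.read_id for c in potential if c.status == "specialized"},
            "self_sustaining": {c.read_id for c in potential if c.self_sustaining},
            "core": {c.read_id for c in potential if c.core},
        }
        assert ids["specialized"] <= ids["cluster"] <= ids["potential"]
        assert ids["core"] <= ids["self_sustaining"] <= ids["cluster"]

    def test_rerun_is_deterministic(self, dataset):
        config, ds, annotated = dataset
        tables = []
        for _ in range(2):
            potential, _ = cl.identify_clusters(
                annotated, ds.motifs, config.min_sites, ds.expression, config.expr_threshold
            )
            tables.append(cl.cluster_table(potential).to_csv())
        assert tables[0] == tables[1]

    @pytest.mark.parametrize("knob", ["expr_threshold", "min_sites"])
    def test_tightening_thresholds_never_adds_clusters(self, dataset, knob):
        config, ds, annotated_base = dataset
        counts = []
        for value in (1.0, 3.0) if knob == "expr_threshold" else (3, 5):
            if knob == "expr_threshold":
                annotated = cl.annotate_loci(
                    ds.reads, ds.atac, ds.polii, ds.genes, ds.expression,
                    config.flank, value, config.chrom_sizes, ds.factors,
                )
                potential, _ = cl.identify_clusters(annotated, ds.motifs, 3, ds.expression, value)
            else:
                potential, _ = cl.identify_clusters(
                    annotated_base, ds.motifs, value, ds.expression, config.expr_threshold
                )
            counts.append(
                {
                    "potential": len(potential),
                    "cluster": sum(c.status in ("cluster", "specialized") for c in potential),
                    "specialized": sum(c.status == "specialized" for c in potential),
                    "self_sustaining": sum(c.self_sustaining for c in potential),
                    "core": sum(c.core for c in potential),
                }
            )
        loose, tight = counts
        for tier in loose:
            assert tight[tier] <= loose[tier]
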