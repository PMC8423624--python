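import numpy as np
import pytest
from scipy import stats

import adjphylo as ap
from adjphylo.fusion import (
    FusionTest,
    call_fusions,
    enrichment_test,
    one_to_one_pairs,
    ortholog_sharing_counts,
    yates_chi2,
)
from adjphylo.io_formats import GeneOrder


def genomes_from_mapping(mapping):
    """mapping: list of (chromA, chromB) per one-to-one ortholog."""
    chrom_a, chrom_b = {}, {}
    for k, (ca, cb) in enumerate(mapping):
        chrom_a.setdefault(ca, []).append((f"a{k}", f"f{k}", "+"))
        chrom_b.setdefault(cb, []).append((f"b{k}", f"f{k}", "+"))
    return GeneOrder("A", chrom_a), GeneOrder("B", chrom_b)


class TestSharingCounts:
    def test_degenerate_single_pair(self):
        ga, gb = genomes_from_mapping([("chr1", "chrX")] * 10)
        counts = ortholog_sharing_counts(ga, gb)
        assert counts.tables == {("chr1", "chrX"): (10, 0, 0, 0)}

    def test_split_mapping_matches_hand_tally(self):
        mapping = [("c1", "x1")] * 6 + [("c1", "x2")] * 4 + [("c2", "x2")] * 10
        ga, gb = genomes_from_mapping(mapping)
        counts = ortholog_sharing_counts(ga, gb)
        assert counts.tables[("c1", "x1")] == (6, 4, 0, 10)
        assert counts.tables[("c1", "x2")] == (4, 6, 10, 0)
        assert counts.tables[("c2", "x2")] == (10, 0, 4, 6)

    def test_marginals_conserved(self):
        rng = np.random.default_rng(1)
        mapping = [
            (f"c{rng.integers(3)}", f"x{rng.integers(3)}") for _ in range(200)
        ]
        ga, gb = genomes_from_mapping(mapping)
        counts = ortholog_sharing_counts(ga, gb)
        for (ca, cb), (a, b, c, d) in counts.tables.items():
            assert a + b == sum(1 for m in mapping if m[0] == ca)
            assert a + c == sum(1 for m in mapping if m[1] == cb)
            assert a + b + c + d == len(mapping)

    def test_multicopy_families_excluded(self):
        ga = GeneOrder("A", {"c1": [("a1", "f1", "+"), ("a2", "f1", "+"), ("a3", "f2", "+")]})
        gb = GeneOrder("B", {"x1": [("b1", "f1", "+"), ("b2", "f2", "+")]})
        counts = ortholog_sharing_counts(ga, gb)
        assert counts.n_orthologs == 1
        assert counts.n_excluded_multicopy == 1

    def test_collapse_duplicates_counts_each_chromosome_pair_once(self):
        ga = GeneOrder("A", {"c1": [("a1", "f1", "+")], "c2": [("a2", "f1", "+"), ("a3", "f2", "+")]})
        gb = GeneOrder("B", {"x1": [("b1", "f1", "+"), ("b2", "f2", "+")]})
        counts = ortholog_sharing_counts(ga, gb, collapse_duplicates=True)
        assert sorted(counts.assignments) == [("c1", "x1"), ("c2", "x1"), ("c2", "x1")]


class TestEnrichment:
    def test_yates_worked_value(self):
        assert yates_chi2(30, 10, 10, 50) == pytest.approx(31.640625, abs=1e-9)

    def test_matches_scipy_contingency_with_correction(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            a, b, c, d = rng.integers(1, 80, size=4)
            got = yates_chi2(a, b, c, d)
            expected = stats.chi2_contingency(
                np.array([[a, b], [c, d]]), correction=True
            ).statistic
            assert got == pytest.approx(expected, abs=1e-9)

    def test_independence_table_not_significant(self):
        # a/b/c/d proportional to marginals: 20/20/30/30
        mapping = (
            [("c1", "x1")] * 20 + [("c1", "x2")] * 20
            + [("c2", "x1")] * 30 + [("c2", "x2")] * 30
        )
        ga, gb = genomes_from_mapping(mapping)
        tests = enrichment_test(ortholog_sharing_counts(ga, gb))
        assert all(not t.significant for t in tests)
        assert all(t.chi2 == pytest.approx(0, abs=1.0) for t in tests)

    def test_significance_requires_enrichment_direction(self):
        # strong DEPLETION of (c1, x1): chi2 is large but a < expected
        mapping = [("c1", "x2")] * 50 + [("c2", "x1")] * 50 + [("c1", "x1")] * 2 + [("c2", "x2")] * 2
        ga, gb = genomes_from_mapping(mapping)
        tests = {(t.chrom_a, t.chrom_b): t for t in enrichment_test(ortholog_sharing_counts(ga, gb))}
        deplete = tests[("c1", "x1")]
        assert deplete.a < deplete.expected
        assert not deplete.significant

    def test_bonferroni_monotone_and_counts_tested_pairs(self):
        rng = np.random.default_rng(9)
        mapping = [(f"c{rng.integers(4)}", f"x{rng.integers(4)}") for _ in range(300)]
        ga, gb = genomes_from_mapping(mapping)
        tests = enrichment_test(ortholog_sharing_counts(ga, gb))
        m = len(tests)
        for t in tests:
            assert t.p_adj == pytest.approx(min(1.0, t.p_raw * m))
        ordered = sorted(tests, key=lambda t: t.p_raw)
        adj = [t.p_adj for t in ordered]
        assert adj == sorted(adj)

    def test_permutation_and_chi2_agree_on_fixture(self):
        from adjphylo.simulate import make_fixture

        fx = make_fixture("fusion_karyotype", seed=0)
        counts = ortholog_sharing_counts(fx.gene_orders[1], fx.gene_orders[0])
        by_chi = enrichment_test(counts, mode="chi2_yates")
        by_perm = enrichment_test(counts, mode="permutation", n_perm=2000, seed=4)
        assert [t.significant for t in by_chi] == [t.significant for t in by_perm]


class TestCalls:
    def _tests(self, links, reference_chroms):
        """links: list of (derived, ancestral, significant)."""
        return [
            FusionTest("A", "B", ca, cb, 10, 1, 1, 100, 1.0, 50.0, 1e-9, 1e-7, sig)
            for ca, cb, sig in links
        ]

    def test_single_partner_is_no_fusion(self):
        tests = self._tests([("d1", "r1", True), ("d1", "r2", False)], ["r1", "r2"])
        (call,) = call_fusions(tests, micro_chromosomes=["r1", "r2"])
        assert call.classification == "no_fusion"

    def test_two_micros_is_micro_fusion(self):
        tests = self._tests([("d1", "r1", True), ("d1", "r2", True)], ["r1", "r2"])
        (call,) = call_fusions(tests, micro_chromosomes=["r1", "r2"])
        assert call.classification == "micro_fusion"
        assert call.linked_ancestral == ["r1", "r2"]

    def test_macro_plus_micro_is_macro_micro(self):
        tests = self._tests([("d1", "mac", True), ("d1", "mic", True)], ["mic"])
        (call,) = call_fusions(tests, micro_chromosomes=["mic"])
        assert call.classification == "macro_micro_fusion"

    def test_unknown_micro_chromosome_rejected(self):
        tests = self._tests([("d1", "r1", True)], ["r1"])
        with pytest.raises(ValueError, match="unknown"):
            call_fusions(tests, micro_chromosomes=["does_not_exist"])

    def test_scripted_fusion_fixture_recovered(self):
        from adjphylo.simulate import make_fixture

        fx = make_fixture("fusion_karyotype", seed=1)
        counts = ortholog_sharing_counts(fx.gene_orders[1], fx.gene_orders[0])
        tests = enrichment_test(counts)
        calls = call_fusions(tests, fx.species_config.micro_chromosomes["RefSp"])
        fused = {c.derived_chromosome: set(c.linked_ancestral)
                 for c in calls if c.classification != "no_fusion"}
        assert fused == {f["derived"]: set(f["ancestral"]) for f in fx.scripted_fusions}


class TestOneToOne:
    def test_identity_mapping_gives_k_pairs(self):
        mapping = [(f"c{i}", f"x{i}") for i in range(5) for _ in range(30)]
        ga, gb = genomes_from_mapping(mapping)
        tests = enrichment_test(ortholog_sharing_counts(ga, gb))
        assert len(one_to_one_pairs(tests)) == 5

    def test_multi_partner_chromosome_excluded(self):
        mapping = (
            [("c1", "x1")] * 40 + [("c1", "x2")] * 40
            + [("c2", "x3")] * 40 + [("c3", "x4")] * 40
        )
        ga, gb = genomes_from_mapping(mapping)
        tests = enrichment_test(ortholog_sharing_counts(ga, gb))
        pairs = one_to_one_pairs(tests)
        assert ("c2", "x3") in pairs and ("c3", "x4") in pairs
        assert all(ca != "c1" for ca, _ in pairs)

    def test_fusion_fixture_one_to_one_count_matches_event_log(self):
        from adjphylo.simulate import make_fixture

        fx = make_fixture("fusion_karyotype", seed=2)
        counts = ortholog_sharing_counts(fx.gene_orders[1], fx.gene_orders[0])
        tests = enrichment_test(counts)
        # 4 macro-chromosomes untouched by the 3 scripted fusions
        assert len(one_to_one_pairs(tests)) == 4
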