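"""Gene-set loading, regulation mapping, ES, Fisher test and selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

import mirpath as mp
from mirpath.enrichment import EnrichmentResult, results_frame
from mirpath.targets import ScoringMatrix

from conftest import brute_force_hypergeom_tail

UNIVERSE = [f"g{i}" for i in range(1, 6)]  # g1..g5


def gmt_lines(*sets):
    return [("\t".join([name, "desc"] + members)) for name, members in sets]


class TestLoadGeneSets:
    def test_min_size_boundary_inclusive(self):
        universe = [f"g{i}" for i in range(1, 61)]
        lines = gmt_lines(
            ("small", universe[:10]),
            ("edge", universe[10:25]),   # exactly 15
            ("big", universe[20:60]),
        )
        coll = mp.load_gene_sets(lines, universe, min_size=15)
        assert set(coll.sets) == {"edge", "big"}
        assert coll.n_dropped_small == 1

    def test_size_computed_after_universe_intersection(self):
        lines = gmt_lines(("s", ["g1", "g2", "gX", "gY"]))
        coll = mp.load_gene_sets(lines, UNIVERSE, min_size=3)
        assert "s" not in coll.sets  # 2 members in-universe < 3
        coll2 = mp.load_gene_sets(lines, UNIVERSE, min_size=2)
        assert coll2.sets["s"] == ["g1", "g2"]

    def test_duplicate_members_deduplicated(self):
        lines = gmt_lines(("s", ["g1", "g2", "g1", "g3"]))
        coll = mp.load_gene_sets(lines, UNIVERSE)
        assert coll.sets["s"] == ["g1", "g2", "g3"]

    def test_malformed_line_reports_line_number(self):
        lines = ["ok\tdesc\tg1\tg2", "broken_line_without_tabs"]
        with pytest.raises(ValueError, match="line 2"):
            mp.load_gene_sets(lines, UNIVERSE)

    def test_indicator_rows_sum_to_set_sizes(self):
        lines = gmt_lines(("a", ["g1", "g2"]), ("b", ["g2", "g3", "g4"]))
        coll = mp.load_gene_sets(lines, UNIVERSE)
        P = coll.indicator_matrix()
        assert list(P.sum(axis=1)) == [2, 3]


def toy_inputs():
    """1 miRNA (Δx = 2), 2 target genes (b = 0.8, 1.0), one set with both."""
    scoring = ScoringMatrix(UNIVERSE, ["m1"], np.array([[0.8], [1.0], [0], [0], [0]]))
    delta = mp.DifferentialTable(["m1"], ["CL1"], np.array([[2.0]]))
    coll = mp.load_gene_sets(gmt_lines(("s", ["g1", "g2"])), UNIVERSE)
    return scoring, delta, coll


class TestAggregateRegulation:
    def test_hand_matrix_product(self):
        scoring, delta, coll = toy_inputs()
        strength = mp.aggregate_regulation(scoring, delta, coll)
        assert strength.set_regulation[0, 0] == pytest.approx(
            2 * 0.8 + 2 * 1.0
        )  # 3.6
        np.testing.assert_allclose(
            strength.gene_regulation[:, 0], [1.6, 2.0, 0, 0, 0]
        )

    def test_zero_delta_gives_zero_strength(self):
        scoring, delta, coll = toy_inputs()
        delta.delta_x[:] = 0.0
        strength = mp.aggregate_regulation(scoring, delta, coll)
        assert not strength.set_regulation.any()

    def test_additive_in_delta(self):
        rng = np.random.default_rng(41)
        b = rng.random((5, 3))
        scoring = ScoringMatrix(UNIVERSE, ["m1", "m2", "m3"], b)
        coll = mp.load_gene_sets(
            gmt_lines(("a", ["g1", "g3"]), ("b", ["g2", "g4", "g5"])), UNIVERSE
        )
        d1 = rng.random((3, 2))
        d2 = rng.random((3, 2))
        mk = lambda dx: mp.DifferentialTable(["m1", "m2", "m3"], ["x", "y"], dx)
        s1 = mp.aggregate_regulation(scoring, mk(d1), coll).set_regulation
        s2 = mp.aggregate_regulation(scoring, mk(d2), coll).set_regulation
        s12 = mp.aggregate_regulation(scoring, mk(d1 + d2), coll).set_regulation
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-12)

    def test_missing_delta_counts_as_zero(self):
        scoring, delta, coll = toy_inputs()
        delta.delta_x[0, 0] = np.nan
        strength = mp.aggregate_regulation(scoring, delta, coll)
        assert strength.set_regulation[0, 0] == 0.0

    def test_signed_variant_keeps_direction(self):
        scoring, _, coll = toy_inputs()
        delta = mp.DifferentialTable(["m1"], ["CL1"], np.array([[-2.0]]))
        mag = mp.aggregate_regulation(scoring, delta, coll)
        sig = mp.aggregate_regulation(scoring, delta, coll, signed=True)
        assert mag.set_regulation[0, 0] == pytest.approx(3.6)
        assert sig.set_regulation[0, 0] == pytest.approx(-3.6)

    def test_disjoint_mirna_axes_error(self):
        scoring, _, coll = toy_inputs()
        delta = mp.DifferentialTable(["other"], ["CL1"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="miRNA axis"):
            mp.aggregate_regulation(scoring, delta, coll)


class TestEnrichmentScore:
    def test_uniform_regulation_gives_unit_es(self):
        scoring = ScoringMatrix(UNIVERSE, ["m1"],
                                np.array([[1.0], [1.0], [1.0], [0], [0]]))
        delta = mp.DifferentialTable(["m1"], ["CL1"], np.array([[2.0]]))
        coll = mp.load_gene_sets(
            gmt_lines(("a", ["g1", "g2"]), ("b", ["g3", "g4"])), UNIVERSE
        )
        strength = mp.aggregate_regulation(scoring, delta, coll)
        es, no_signal = mp.enrichment_scores(strength, scoring.targeted_genes, coll)
        np.testing.assert_allclose(es, [1.0, 1.0])
        assert not no_signal.any()

    def test_double_regulation_doubles_es(self):
        # set members carry exactly 2x the mean regulation of targeted genes
        universe = [f"g{i}" for i in range(1, 7)]
        b = np.array([[1.0], [1.0], [0.25], [0.25], [0.25], [0.25]])
        scoring = ScoringMatrix(universe, ["m1"], b)
        delta = mp.DifferentialTable(["m1"], ["CL1"], np.array([[1.0]]))
        coll = mp.load_gene_sets(gmt_lines(("hot", ["g1", "g2"])), universe)
        strength = mp.aggregate_regulation(scoring, delta, coll)
        es, _ = mp.enrichment_scores(strength, scoring.targeted_genes, coll)
        # mean in set = 1.0; mean over all targeted genes = 0.5 → ES = 2
        assert es[0] == pytest.approx(2.0)

    def test_set_without_targeted_members_flagged(self):
        scoring, delta, coll_unused = toy_inputs()
        coll = mp.load_gene_sets(gmt_lines(("cold", ["g4", "g5"])), UNIVERSE)
        strength = mp.aggregate_regulation(scoring, delta, coll)
        es, no_signal = mp.enrichment_scores(strength, scoring.targeted_genes, coll)
        assert es[0] == 0.0
        assert no_signal[0]

    def test_scale_invariance_of_es(self):
        rng = np.random.default_rng(51)
        universe = [f"g{i}" for i in range(30)]
        b = (rng.random((30, 4)) < 0.3) * rng.random((30, 4))
        scoring = ScoringMatrix(universe, list("mnop"), b)
        coll = mp.load_gene_sets(
            gmt_lines(("s1", universe[:10]), ("s2", universe[12:25])), universe
        )
        dx = rng.normal(0, 2, size=(4, 3))
        mk = lambda m: mp.DifferentialTable(list("mnop"), list("abc"), m)
        s_a = mp.aggregate_regulation(scoring, mk(dx), coll)
        s_b = mp.aggregate_regulation(scoring, mk(dx * 7.3), coll)
        t = scoring.targeted_genes
        es_a, _ = mp.enrichment_scores(s_a, t, coll)
        es_b, _ = mp.enrichment_scores(s_b, t, coll)
        np.testing.assert_allclose(es_a, es_b, atol=1e-12)
        np.testing.assert_allclose(
            s_b.set_regulation, 7.3 * s_a.set_regulation, atol=1e-9
        )

    def test_zero_signal_everywhere_errors(self):
        scoring, delta, coll = toy_inputs()
        delta.delta_x[:] = 0.0
        strength = mp.aggregate_regulation(scoring, delta, coll)
        with pytest.raises(ValueError, match="zero genome-wide"):
            mp.enrichment_scores(strength, scoring.targeted_genes, coll)


class TestFisherCoverage:
    def test_zero_overlap_gives_one(self):
        assert mp.fisher_coverage_test(0, 20, 50, 1000) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "m_l,n_l,m_total,M",
        [(8, 20, 50, 1000), (3, 15, 100, 500), (1, 10, 10, 200), (12, 40, 60, 2000)],
    )
    def test_matches_brute_force_tail(self, m_l, n_l, m_total, M):
        mine = mp.fisher_coverage_test(m_l, n_l, m_total, M)
        brute = brute_force_hypergeom_tail(m_l, n_l, m_total, M)
        assert mine == pytest.approx(brute, abs=1e-12)

    def test_extreme_table_point_mass(self):
        import math

        p = mp.fisher_coverage_test(5, 5, 5, 100)
        assert p == pytest.approx(1 / math.comb(100, 5), rel=1e-12)

    def test_agrees_with_scipy_fisher_exact(self):
        m_l, n_l, m_total, M = 8, 20, 50, 1000
        table = [[m_l, n_l - m_l], [m_total - m_l, M - n_l - m_total + m_l]]
        _, p_scipy = fisher_exact(table, alternative="greater")
        assert mp.fisher_coverage_test(m_l, n_l, m_total, M) == pytest.approx(
            p_scipy, rel=1e-9
        )

    def test_inconsistent_margins_error(self):
        with pytest.raises(ValueError, match="margins"):
            mp.fisher_coverage_test(10, 5, 50, 1000)


def result(name, size, targeted, es, p, min_coverage=0.10, min_genes=3,
           es_min=1.5, p_max=0.01):
    coverage = targeted / size
    return EnrichmentResult(
        name=name, size=size, targeted=targeted, coverage=coverage, es=es,
        no_signal=False, p=p,
        passes_coverage=(coverage > min_coverage) and (targeted >= min_genes),
        passes_es=es > es_min, passes_p=p < p_max,
    )


class TestSelection:
    def test_table_style_pass(self):
        # 10 of 66 genes (15%), ES 2.18, p < 0.001: passes all three
        r = result("p53-like", 66, 10, 2.18, 5e-4)
        assert r.passes

    def test_min_genes_floor(self):
        r = result("tiny", 5, 2, 3.0, 1e-5)  # 40% coverage but only 2 genes
        assert not r.passes_coverage and not r.passes

    def test_exactly_ten_percent_fails_strict_coverage(self):
        r = result("edge", 50, 5, 2.0, 1e-4)
        assert r.coverage == pytest.approx(0.10)
        assert not r.passes_coverage

    def test_ranking_and_near_miss_split(self):
        rs = [
            result("a", 60, 12, 2.0, 1e-4),
            result("b", 60, 12, 2.5, 1e-3),
            result("c", 60, 12, 2.5, 1e-4),     # ties with b on ES, smaller p
            result("near", 60, 2, 3.0, 1e-5),   # fails gene floor only
            result("dull", 60, 12, 1.2, 1e-4),  # fails ES
        ]
        selected, near = mp.select_enriched(rs)
        assert [r.name for r in selected] == ["c", "b", "a"]
        assert [r.name for r in near] == ["near"]

    def test_results_frame_has_pass_flags(self):
        df = results_frame([result("a", 60, 12, 2.0, 1e-4)])
        assert df.loc[0, "passes"]
        assert df.loc[0, "coverage_pct"] == pytest.approx(20.0)


class TestCoverageFormatting:
    @pytest.mark.parametrize(
        "m,n,style,expected",
        [
            (10, 66, "integer", "15%"),
            (8, 22, "integer", "36%"),
            (12, 83, "integer", "14%"),
            (5, 19, "one_decimal", "26.3%"),
            (9, 90, "one_decimal", "10.0%"),
            (13, 124, "one_decimal", "10.5%"),
        ],
    )
    def test_table_rendering(self, m, n, style, expected):
        assert mp.format_coverage(m, n, style) == expected

    def test_full_precision_retained_internally(self):
        r = result("x", 66, 10, 2.0, 1e-4)
        assert r.coverage == 10 / 66
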