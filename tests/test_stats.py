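import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from oometh.io import AnnotationTrack, Feature, GenomeIndex
from oometh.stats import (
    ContingencyTable2x2,
    DMRResult,
    VennPartition,
    ZeroMarginError,
    bh_adjust,
    call_dmrs_pooled,
    call_dmrs_replicates,
    chisq_2x2,
    export_gene_lists,
    panel_analysis,
    ttest_groups,
    venn_partition,
)
from oometh.tiling import MethylationQuant
from conftest import make_library


def closed_form_chi2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestChisq2x2:
    def test_equal_proportions_give_zero(self):
        stat, p = chisq_2x2(ContingencyTable2x2(10, 10, 20, 20))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_closed_form_example(self):
        # (90,10) vs (50,50): 200*(90*50-10*50)^2 / (100*100*140*60) = 38.095238...
        stat, p = chisq_2x2(ContingencyTable2x2(90, 10, 50, 50))
        assert stat == pytest.approx(closed_form_chi2(90, 10, 50, 50), abs=1e-10)
        assert stat == pytest.approx(38.095238095238095, abs=1e-10)
        assert p == pytest.approx(6.7374e-10, rel=1e-3)

    def test_zero_margin_is_undefined(self):
        with pytest.raises(ZeroMarginError):
            chisq_2x2(ContingencyTable2x2(0, 10, 0, 10))

    def test_yates_correction_shrinks_statistic(self):
        plain, _ = chisq_2x2(ContingencyTable2x2(9, 1, 5, 5))
        yates, _ = chisq_2x2(ContingencyTable2x2(9, 1, 5, 5), yates=True)
        assert yates < plain

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            a, b, c, d = rng.integers(1, 500, size=4)
            stat, _ = chisq_2x2(ContingencyTable2x2(a, b, c, d))
            assert stat == pytest.approx(closed_form_chi2(a, b, c, d), abs=1e-10)


class TestTtestGroups:
    def test_hand_pooled_variance_example(self):
        t, p = ttest_groups([10, 20, 30], [40, 50, 60])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_zero_variance_degenerate_returns_none(self):
        assert ttest_groups([5, 5, 5], [5, 5, 5]) is None

    def test_fewer_than_two_replicates_returns_none(self):
        assert ttest_groups([5], [1, 2, 3]) is None

    def test_label_swap_negates_statistic(self):
        t1, p1 = ttest_groups([10, 20, 30], [40, 55, 60])
        t2, p2 = ttest_groups([40, 55, 60], [10, 20, 30])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04], m=3)
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_all_zeros_stay_zero(self):
        assert bh_adjust([0.0, 0.0, 0.0]).tolist() == [0.0, 0.0, 0.0]

    def test_m_below_count_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_statsmodels_when_m_equals_count(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_step_up_invariants(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_larger_family_reproduces_reported_panel_fdr(self):
        # seven reported CGI-panel p-values within a family of eight tests
        p = [0.0, 0.0, 9.842796e-5, 5.962238e-4, 8.9613185e-4, 0.0020540599, 0.010897397]
        adj = bh_adjust(p, m=8)
        expect = [0.0, 0.0, 2.6247456e-4, 1.1924476e-3, 1.43381096e-3, 2.73874653e-3, 1.24541680e-2]
        assert adj == pytest.approx(expect, rel=1e-8)


def pooled_quant(rid, n_meth, n_unmeth, n_obs=20, n_genomic=20):
    return MethylationQuant(rid, n_meth, n_unmeth, n_obs, n_genomic)


class TestCallDmrsPooled:
    def test_small_diff_never_passes_despite_tiny_p(self):
        # 9.9-point difference at extreme depth: p is minute, diff filter bites
        qa = [pooled_quant("r", 9010, 990)]
        qb = [pooled_quant("r", 8020, 1980)]
        (res,) = call_dmrs_pooled(qa, qb)
        assert res.p_raw < 1e-10
        assert res.abs_diff < 10
        assert not res.passes

    def test_identical_groups_do_not_pass(self):
        qa = [pooled_quant("r", 50, 50)]
        (res,) = call_dmrs_pooled(qa, qa)
        assert res.p_raw == pytest.approx(1.0)
        assert not res.passes

    def test_injected_effect_at_depth_passes(self):
        qa = [pooled_quant("r", 250, 250)]  # 50%
        qb = [pooled_quant("r", 400, 100)]  # 80%
        (res,) = call_dmrs_pooled(qa, qb)
        assert res.passes

    def test_zero_margin_reported_not_passing(self):
        qa = [pooled_quant("r", 0, 50)]
        qb = [pooled_quant("r", 0, 70)]
        (res,) = call_dmrs_pooled(qa, qb)
        assert res.p_raw is None
        assert "undefined_test" in res.flags and not res.passes

    def test_diff_filter_only_removes_calls(self):
        rng = np.random.default_rng(3)
        qa, qb = [], []
        for i in range(200):
            pa, pb = rng.random() * 0.8 + 0.1, rng.random() * 0.8 + 0.1
            qa.append(pooled_quant(f"r{i}", int(500 * pa), 500 - int(500 * pa)))
            qb.append(pooled_quant(f"r{i}", int(500 * pb), 500 - int(500 * pb)))
        strict = call_dmrs_pooled(qa, qb, min_abs_diff=10.0)
        loose = call_dmrs_pooled(qa, qb, min_abs_diff=0.0)
        passing_strict = {r.region_id for r in strict if r.passes}
        passing_loose = {r.region_id for r in loose if r.passes}
        assert passing_strict <= passing_loose


class TestCallDmrsReplicates:
    def test_no_region_tested_gives_empty_list(self):
        assert call_dmrs_replicates([], [], []) == []

    def test_regions_without_two_cells_excluded(self):
        out = call_dmrs_replicates(["r"], [[50.0, None]], [[60.0, 62.0]])
        assert out == []

    def test_clear_effect_is_bh_significant(self):
        ids = [f"r{i}" for i in range(20)]
        rng = np.random.default_rng(5)
        pa = [[float(50 + rng.normal(0, 3)) for _ in range(8)] for _ in ids]
        pb = [[float(50 + rng.normal(0, 3)) for _ in range(8)] for _ in ids]
        pa[0] = [90.0 + float(rng.normal(0, 2)) for _ in range(8)]
        out = call_dmrs_replicates(ids, pa, pb)
        by_id = {r.region_id: r for r in out}
        assert by_id["r0"].passes
        assert sum(r.passes for r in out) <= 3


class TestVennPartition:
    def test_identical_classifications_all_common(self):
        cls = {i: "hyper" for i in range(5)}
        v = venn_partition(cls, cls)["hyper"]
        assert (v.n_common, v.n_a_only, v.n_b_only) == (5, 0, 0)

    def test_disjoint_sets_share_nothing(self):
        a = {1: "hypo", 2: "hypo"}
        b = {3: "hypo"}
        v = venn_partition(a, b)["hypo"]
        assert v.n_common == 0 and v.n_a_only == 2 and v.n_b_only == 1

    def test_exclusive_counts_satisfy_set_identity(self):
        v = VennPartition("hypo", n_a_total=9139, n_b_total=10421, n_common=8193)
        assert v.n_a_only + v.n_common == v.n_a_total
        assert v.n_b_only + v.n_common == v.n_b_total

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError, match="outside the shared universe"):
            venn_partition({1: "hyper"}, {2: "hyper"}, universe={1})

    def test_significance_filter_applies_to_exclusive_tiles(self):
        a = {1: "hyper", 2: "hyper"}
        b = {2: "hyper"}
        dmrs = {1: DMRResult("1", 90, 60, passes=True)}
        v = venn_partition(a, b, dmrs)["hyper"]
        assert v.n_a_only_significant == 1 and v.n_b_only_significant == 0


class TestPanelAnalysis:
    def make_inputs(self):
        # ten CGs per feature at positions f*1000 .. f*1000+90
        feats = [Feature("chr1", f * 1000, f * 1000 + 100, f"f{f}") for f in range(8)]
        pos = np.concatenate([np.arange(f * 1000, f * 1000 + 100, 10) for f in range(8)])
        index = GenomeIndex(positions={"chr1": np.sort(pos)}, lengths={"chr1": 10_000})
        rng = np.random.default_rng(17)

        def group_libs(levels, n_cells=6, depth=10):
            libs = []
            for c in range(n_cells):
                recs = []
                for f, level in enumerate(levels):
                    for p in range(f * 1000, f * 1000 + 100, 10):
                        m = int(rng.binomial(depth, level / 100))
                        recs.append(("chr1", p, m, depth - m))
                libs.append(make_library(recs, f"lib{c}"))
            return libs

        return feats, index, group_libs

    def test_injected_effect_is_the_only_significant_feature(self):
        feats, index, group_libs = self.make_inputs()
        levels_a = [80, 10, 90, 5, 50, 30, 70, 95]
        levels_b = list(levels_a)
        levels_b[3] = 46  # injected 41-point shift
        df = panel_analysis(feats, group_libs(levels_a), group_libs(levels_b), index)
        sig = set(df.loc[df["significant"], "feature"])
        assert sig == {"f3"}

    def test_read_cgs_fraction(self):
        feats = [Feature("chr1", 0, 100, "f")]
        index = GenomeIndex(
            positions={"chr1": np.arange(0, 100, 10)}, lengths={"chr1": 200}
        )
        lib = make_library([("chr1", p, 1, 0) for p in range(0, 60, 10)])
        df = panel_analysis(feats, [lib], [lib], index)
        assert df["read_cgs_NS"][0] == pytest.approx(60.0)

    def test_feature_unquantified_in_one_group_excluded_from_family(self):
        feats = [Feature("chr1", 0, 100, "covered"), Feature("chr1", 500, 600, "uncovered")]
        index = GenomeIndex(
            positions={"chr1": np.concatenate([np.arange(0, 100, 10), np.arange(500, 600, 10)])},
            lengths={"chr1": 1000},
        )
        a = make_library([("chr1", p, 1, 1) for p in range(0, 100, 10)], "a")
        b = make_library(
            [("chr1", p, 1, 1) for p in range(0, 100, 10)]
            + [("chr1", p, 1, 1) for p in range(500, 600, 10)],
            "b",
        )
        df = panel_analysis(feats, [a], [b], index)
        row = df.set_index("feature").loc["uncovered"]
        assert np.isnan(row["fdr"]) and row["flags"] == "insufficient_coverage"

    def test_m_override_inflates_adjustment(self):
        feats, index, group_libs = self.make_inputs()
        levels_a = [80, 10, 90, 5, 50, 30, 70, 95]
        levels_b = list(levels_a)
        levels_b[3] = 46
        libs_a, libs_b = group_libs(levels_a), group_libs(levels_b)
        df8 = panel_analysis(feats, libs_a, libs_b, index)
        df16 = panel_analysis(feats, libs_a, libs_b, index, m_override=16)
        f3 = df8["feature"] == "f3"
        assert df16.loc[f3, "fdr"].iloc[0] == pytest.approx(
            2 * df8.loc[f3, "fdr"].iloc[0], rel=1e-9
        )


class TestExportGeneLists:
    def track(self):
        return AnnotationTrack(
            "genes",
            [
                Feature("chr1", 100, 300, "GENE_A"),
                Feature("chr1", 250, 500, "GENE_B"),
                Feature("chr2", 0, 100, "GENE_C"),
            ],
        )

    def test_no_dmrs_give_empty_files(self, tmp_path):
        paths = export_gene_lists([], self.track(), tmp_path)
        assert all(p.read_text() == "" for p in paths.values())

    def test_dmr_overlapping_two_genes_yields_both_symbols(self, tmp_path):
        dmr = DMRResult("chr1:200-320", 90, 40, passes=True, chrom="chr1", start=200, end=320)
        paths = export_gene_lists([dmr], self.track(), tmp_path)
        assert paths["NS"].read_text().split() == ["GENE_A", "GENE_B"]
        assert paths["S"].read_text() == ""

    def test_intergenic_dmr_yields_no_symbols(self, tmp_path):
        dmr = DMRResult("chr1:600-700", 20, 80, passes=True, chrom="chr1", start=600, end=700)
        paths = export_gene_lists([dmr], self.track(), tmp_path)
        assert all(p.read_text() == "" for p in paths.values())
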