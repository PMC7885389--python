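"""Gene-list builders, panel split, intersection and co-expression."""

import numpy as np
import pandas as pd
import pytest

from cox2prio.cohortio import (
    CellLinePanel,
    ClinicalTable,
    CopyNumberTable,
    ExpressionMatrix,
    GeneList,
    zscore,
)
from cox2prio.prioritize import (
    alteration_profiles,
    build_gl1,
    build_gl2,
    build_gl3,
    build_gl4,
    build_gl5,
    build_gl6,
    classify_panel,
    classify_panel_series,
    coexpression_confirm,
    intersect_all,
    load_table1_lists,
)
from cox2prio.synthetic import PanelSpec, simulate_panel


def _zscore_matrix_with_counts(n_samples: int, n_above: int, gene: str = "GA"):
    """An expression matrix whose z-scores put exactly n_above samples > 1."""
    # build log2 values: n_above at a high plateau, the rest spread low
    rng = np.random.default_rng(0)
    low = rng.uniform(1.0, 2.0, size=n_samples - n_above)
    high = np.full(n_above, 30.0)
    log2 = np.concatenate([low, high])
    cols = [f"S{i}" for i in range(n_samples)]
    m = ExpressionMatrix(pd.DataFrame([np.exp2(log2) - 1], index=[gene],
                                      columns=cols))
    z = zscore(m)
    assert int((z.values.loc[gene] > 1.0).sum()) == n_above
    return z


class TestGL1:
    def test_literal_sum_rule_double_counts(self):
        """10 samples: 2 amplified, 3 with z > 1 -> rate 20 + 30 = 50."""
        z = _zscore_matrix_with_counts(10, 3)
        calls = [2, 2] + [0] * 8
        cna = CopyNumberTable(pd.DataFrame([calls], index=["GA"],
                                           columns=z.samples))
        candidates = GeneList(name="c", symbols=("GA",))
        profiles = alteration_profiles(candidates, cna, z)
        assert profiles[0].pct_amplified == pytest.approx(20.0)
        assert profiles[0].pct_mrna_up == pytest.approx(30.0)
        assert profiles[0].alteration_rate == pytest.approx(50.0)
        assert "GA" in build_gl1(candidates, cna, z, threshold=10.0)

    def test_zero_alteration_excluded_even_at_threshold_zero(self):
        # a constant gene has all-zero z-scores, so no sample counts as up
        cols = [f"S{i}" for i in range(10)]
        m = ExpressionMatrix(pd.DataFrame([[7.0] * 10], index=["GA"],
                                          columns=cols))
        z = zscore(m)
        cna = CopyNumberTable(pd.DataFrame([[0] * 10], index=["GA"],
                                           columns=cols))
        candidates = GeneList(name="c", symbols=("GA",))
        assert len(build_gl1(candidates, cna, z, threshold=0.0)) == 0

    def test_threshold_monotonicity(self):
        z = _zscore_matrix_with_counts(10, 3)
        cna = CopyNumberTable(pd.DataFrame([[2, 0, 0, 0, 0, 0, 0, 0, 0, 0]],
                                           index=["GA"], columns=z.samples))
        candidates = GeneList(name="c", symbols=("GA",))
        sizes = [len(build_gl1(candidates, cna, z, threshold=th))
                 for th in (60.0, 30.0, 10.0, 0.0)]
        assert sizes == sorted(sizes)

    def test_missing_gene_listed_in_error(self):
        z = _zscore_matrix_with_counts(10, 3)
        cna = CopyNumberTable(pd.DataFrame([[0] * 10], index=["GA"],
                                           columns=z.samples))
        with pytest.raises(KeyError, match="MISSING"):
            build_gl1(GeneList(name="c", symbols=("GA", "MISSING")), cna, z)


class TestGL2:
    def _cna(self, n_amplified: int, n: int = 180):
        calls = [2] * n_amplified + [0] * (n - n_amplified)
        return CopyNumberTable(pd.DataFrame([calls], index=["GA"],
                                            columns=[f"S{i}" for i in range(n)]))

    def test_two_of_180_passes_one_percent(self):
        gl = build_gl2(GeneList(name="c", symbols=("GA",)), self._cna(2))
        assert "GA" in gl  # 2/180 = 1.11% > 1%

    def test_one_of_180_excluded(self):
        gl = build_gl2(GeneList(name="c", symbols=("GA",)), self._cna(1))
        assert "GA" not in gl  # 0.56% < 1%

    def test_no_amplification_gives_empty_list(self):
        gl = build_gl2(GeneList(name="c", symbols=("GA",)), self._cna(0))
        assert len(gl) == 0


class TestGL3:
    def _setup(self, basal, luma, lumb, her2e, normal):
        """One gene with given per-subtype log2 means, 2 samples each."""
        means = {"Basal": basal, "LumA": luma, "LumB": lumb, "HER2E": her2e,
                 "Normal-like": normal}
        cols, vals, pam = [], [], []
        for subtype, mu in means.items():
            for r in range(2):
                cols.append(f"{subtype}_{r}")
                vals.append(mu)
                pam.append(subtype)
        expr = ExpressionMatrix(pd.DataFrame([np.exp2(vals) - 1.0],
                                             index=["GA"], columns=cols))
        clinical = ClinicalTable(pd.DataFrame(
            {
                "ER": "negative", "PR": "negative", "HER2": "negative",
                "PAM50": pam,
                "OS_time": 10.0, "OS_event": 1,
                "DMFS_time": 10.0, "DMFS_event": 1,
            },
            index=pd.Index(cols, name="sample"),
        ))
        return expr, clinical

    def test_strict_basal_maximum_included(self):
        expr, clin = self._setup(5.0, 4.0, 3.0, 2.0, 1.0)
        gl = build_gl3(GeneList(name="c", symbols=("GA",)), expr, clin)
        assert "GA" in gl

    def test_uniform_gene_excluded(self):
        expr, clin = self._setup(3.0, 3.0, 3.0, 3.0, 3.0)
        gl = build_gl3(GeneList(name="c", symbols=("GA",)), expr, clin)
        assert "GA" not in gl

    def test_tie_with_luma_excluded(self):
        expr, clin = self._setup(5.0, 5.0, 3.0, 2.0, 1.0)
        gl = build_gl3(GeneList(name="c", symbols=("GA",)), expr, clin)
        assert "GA" not in gl

    def test_missing_subtype_is_an_error(self):
        expr, clin = self._setup(5.0, 4.0, 3.0, 2.0, 1.0)
        df = clin.values.copy()
        df.loc[df["PAM50"] == "Normal-like", "PAM50"] = "LumA"
        with pytest.raises(ValueError, match="Normal-like"):
            build_gl3(GeneList(name="c", symbols=("GA",)), expr,
                      ClinicalTable(df))


class TestGL4:
    def _fixture(self, shift: float, n: int = 40, seed: int = 0):
        rng = np.random.default_rng(seed)
        log2 = rng.normal(4.0, 0.5, size=n)
        log2[: n // 2] += shift  # first half are the TNBC samples
        cols = [f"S{i}" for i in range(n)]
        expr = ExpressionMatrix(pd.DataFrame([np.exp2(log2) - 1.0],
                                             index=["GA"], columns=cols))
        flags = pd.Series([True] * (n // 2) + [False] * (n // 2), index=cols)
        return expr, flags

    def test_tnbc_high_gene_included(self):
        expr, flags = self._fixture(shift=2.0)
        gl = build_gl4(GeneList(name="c", symbols=("GA",)), expr, flags)
        assert "GA" in gl

    def test_tnbc_low_gene_excluded_one_sided(self):
        expr, flags = self._fixture(shift=-2.0)
        gl = build_gl4(GeneList(name="c", symbols=("GA",)), expr, flags)
        assert "GA" not in gl

    def test_single_class_is_an_error(self):
        expr, flags = self._fixture(shift=0.0)
        with pytest.raises(ValueError):
            build_gl4(GeneList(name="c", symbols=("GA",)), expr,
                      pd.Series(True, index=flags.index))


class TestGL5:
    def _cohort(self, high_worse: bool, seed: int = 0, n: int = 120):
        """Expression splits the cohort in half; one arm has faster events."""
        rng = np.random.default_rng(seed)
        cols = [f"S{i:03d}" for i in range(n)]
        log2 = np.concatenate([np.full(n // 2, 6.0), np.full(n // 2, 2.0)])
        expr = ExpressionMatrix(pd.DataFrame(
            [np.exp2(log2 + rng.normal(0, 0.05, n)) - 1.0],
            index=["GA"], columns=cols))
        rate_high = 1 / 20.0 if high_worse else 1 / 80.0
        times = np.concatenate([
            rng.exponential(1 / rate_high, n // 2),
            rng.exponential(80.0, n // 2),
        ])
        clinical = ClinicalTable(pd.DataFrame(
            {
                "ER": "negative", "PR": "negative", "HER2": "negative",
                "PAM50": "Basal",
                "OS_time": times, "OS_event": 1,
                "DMFS_time": times, "DMFS_event": 1,
            },
            index=pd.Index(cols, name="sample"),
        ))
        return expr, clinical

    def test_high_expression_worse_survival_included(self):
        expr, clin = self._cohort(high_worse=True)
        gl = build_gl5(GeneList(name="c", symbols=("GA",)), expr, clin)
        assert "GA" in gl

    def test_high_expression_better_survival_excluded(self):
        """Direction gate: significance alone is not enough."""
        expr, clin = self._cohort(high_worse=False)
        gl = build_gl5(GeneList(name="c", symbols=("GA",)), expr, clin)
        assert "GA" not in gl

    def test_fully_censored_cohort_is_an_error(self):
        expr, clin = self._cohort(high_worse=True)
        df = clin.values.copy()
        df["OS_event"] = 0
        with pytest.raises(ValueError, match="censored"):
            build_gl5(GeneList(name="c", symbols=("GA",)), expr,
                      ClinicalTable(df))


class TestPanelSplit:
    def test_37_lines_split_18_19(self):
        ec50 = pd.Series(np.linspace(1, 37, 37),
                         index=[f"L{i:02d}" for i in range(37)])
        ms, ls = classify_panel_series(ec50)
        assert (len(ms), len(ls)) == (18, 19)
        assert max(ec50[ms]) < min(ec50[ls])

    def test_four_lines_lowest_two_sensitive(self):
        ec50 = pd.Series([3.0, 1.0, 4.0, 2.0], index=["a", "b", "c", "d"])
        ms, ls = classify_panel_series(ec50)
        assert set(ms) == {"b", "d"}

    def test_two_lines_split_one_one(self):
        ec50 = pd.Series([2.0, 1.0], index=["a", "b"])
        ms, ls = classify_panel_series(ec50)
        assert (ms, ls) == (["b"], ["a"])

    def test_ties_break_by_line_id(self):
        ec50 = pd.Series([1.0, 1.0, 2.0, 2.0], index=["d", "c", "b", "a"])
        ms, _ = classify_panel_series(ec50)
        assert ms == ["c", "d"]


class TestGL6:
    def test_planted_resistance_gene_included(self):
        panel = simulate_panel(PanelSpec(resistance_genes=("G0005",),
                                         delta_panel=3.0, seed=4))
        gl = build_gl6(GeneList(name="c", symbols=("G0005", "G0006")), panel)
        assert "G0005" in gl

    def test_flat_gene_excluded(self):
        lines = [f"L{i}" for i in range(10)]
        panel = CellLinePanel(
            ec50=pd.Series(np.linspace(1, 10, 10), index=lines),
            expression=pd.DataFrame([[5.0] * 10], index=["GA"], columns=lines),
        )
        gl = build_gl6(GeneList(name="c", symbols=("GA",)), panel)
        assert "GA" not in gl

    def test_gene_higher_in_sensitive_lines_excluded(self):
        lines = [f"L{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.1, 10)
        vals[:5] += 3.0  # elevated in the SENSITIVE half
        panel = CellLinePanel(
            ec50=pd.Series(np.linspace(1, 10, 10), index=lines),
            expression=pd.DataFrame([vals], index=["GA"], columns=lines),
        )
        gl = build_gl6(GeneList(name="c", symbols=("GA",)), panel)
        assert "GA" not in gl

    def test_tiny_class_is_an_error(self):
        lines = ["L1", "L2", "L3"]
        panel = CellLinePanel(
            ec50=pd.Series([1.0, 2.0, 3.0], index=lines),
            expression=pd.DataFrame([[1.0, 2.0, 3.0]], index=["GA"],
                                    columns=lines),
        )
        with pytest.raises(ValueError, match="at least 2"):
            build_gl6(GeneList(name="c", symbols=("GA",)), panel)


class TestIntersection:
    def test_table1_fixture_yields_the_ten_candidates(self):
        lists = load_table1_lists()
        inter = intersect_all(*lists.values())
        assert set(inter) == {
            "TPM4", "RGS2", "LAMC2", "SERPINB5", "KLK7",
            "MFGE8", "KLK5", "ID4", "RBP1", "SLC2A1",
        }

    def test_order_follows_first_list(self):
        a = GeneList(name="a", symbols=("X", "Y", "Z"))
        b = GeneList(name="b", symbols=("Z", "X"))
        assert intersect_all(a, b).symbols == ("X", "Z")

    def test_empty_list_gives_empty_intersection(self):
        a = GeneList(name="a", symbols=("X",))
        b = GeneList(name="b", symbols=())
        assert len(intersect_all(a, b)) == 0

    def test_idempotence(self):
        a = GeneList(name="a", symbols=("X", "Y"))
        assert intersect_all(a, a).symbols == a.symbols

    def test_adding_a_list_never_grows_intersection(self):
        a = GeneList(name="a", symbols=("X", "Y", "Z"))
        b = GeneList(name="b", symbols=("Y", "Z"))
        c = GeneList(name="c", symbols=("Z",))
        assert set(intersect_all(a, b, c)) <= set(intersect_all(a, b))


class TestCoexpression:
    def _expr(self, seed: int = 0, n: int = 60):
        rng = np.random.default_rng(seed)
        cols = [f"S{i}" for i in range(n)]
        marker = rng.normal(5, 1, n)
        follower = marker + rng.normal(0, 0.5, n)   # correlated
        noise = rng.normal(5, 1, n)                  # independent
        flat = np.full(n, 4.0)                       # zero variance
        data = np.exp2(np.vstack([marker, follower, noise, flat])) - 1.0
        return ExpressionMatrix(pd.DataFrame(
            data, index=["PTGS2", "FOLLOW", "NOISE", "FLAT"], columns=cols))

    def test_marker_itself_always_passes(self):
        expr = self._expr()
        gl = coexpression_confirm(GeneList(name="c", symbols=("PTGS2",)),
                                  expr, "PTGS2")
        assert "PTGS2" in gl

    def test_correlated_follower_passes_independent_noise_fails(self):
        expr = self._expr()
        gl = coexpression_confirm(
            GeneList(name="c", symbols=("FOLLOW", "NOISE")), expr, "PTGS2")
        assert "FOLLOW" in gl
        assert "NOISE" not in gl

    def test_zero_variance_gene_fails_with_warning(self, caplog):
        expr = self._expr()
        with caplog.at_level("WARNING"):
            gl = coexpression_confirm(GeneList(name="c", symbols=("FLAT",)),
                                      expr, "PTGS2")
        assert "FLAT" not in gl
        assert any("FLAT" in rec.message for rec in caplog.records)
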