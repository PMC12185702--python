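"""Normalisation, batch correction, imputation and differential filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oiswaves import preprocess as pp


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        m = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        np.testing.assert_allclose(pp.size_factors(m), [1.0, 1.0])

    def test_doubled_sample_gives_factor_ratio_two(self):
        m = pd.DataFrame({"a": [5, 9, 2], "b": [10, 18, 4]})
        f = pp.size_factors(m)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_hand_oracle_on_toy_matrix(self, toy_counts):
        # brute-force median-of-ratios on the 4x3 fixture
        mat = toy_counts.to_numpy(dtype=float)
        geo = np.exp(np.log(mat).mean(axis=1))
        expect = np.median(mat / geo[:, None], axis=0)
        np.testing.assert_allclose(pp.size_factors(toy_counts), expect)

    def test_feature_permutation_invariance(self, toy_counts, rng):
        perm = toy_counts.iloc[rng.permutation(len(toy_counts))]
        np.testing.assert_allclose(pp.size_factors(toy_counts),
                                   pp.size_factors(perm))

    def test_no_common_feature_errors(self):
        m = pd.DataFrame({"a": [5, 0], "b": [0, 9]})
        with pytest.raises(ValueError, match="pseudocount"):
            pp.size_factors(m)


class TestTransformCounts:
    def test_zero_maps_to_zero_and_log2_scale(self):
        m = pd.DataFrame({"a": [0, 3]})
        out = pp.transform_counts(m, pd.Series({"a": 1.0}))
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[1, 0] == pytest.approx(2.0)  # log2(3/1 + 1)

    def test_monotone_in_counts(self, toy_counts):
        out = pp.transform_counts(toy_counts)
        for c in toy_counts.columns:
            order = toy_counts[c].argsort()
            assert out[c].iloc[order].is_monotonic_increasing


class TestRemoveBatch:
    def test_single_batch_is_identity(self, toy_counts):
        out = pp.remove_batch(toy_counts, ["b1"] * 3)
        pd.testing.assert_frame_equal(out, toy_counts, check_dtype=False)

    def test_additive_offset_removed(self, rng):
        # batch B duplicates batch A's base values, so the +5 offset is the
        # exact least-squares batch coefficient and correction restores base
        half = rng.normal(size=(20, 4))
        base = pd.DataFrame(np.hstack([half, half]),
                            columns=[f"s{i}" for i in range(8)])
        batch = ["A"] * 4 + ["B"] * 4
        shifted = base.copy()
        shifted.iloc[:, 4:] += 5.0
        out = pp.remove_batch(shifted, batch)
        np.testing.assert_allclose(out.to_numpy(), base.to_numpy(), atol=1e-8)

    def test_condition_effects_preserved(self, rng):
        cond = ["c0", "c0", "c1", "c1", "c0", "c0", "c1", "c1"]
        batch = ["A"] * 4 + ["B"] * 4
        # analytic fixture: values are exact condition means per feature
        cmeans = {"c0": rng.normal(size=10), "c1": rng.normal(size=10) + 3.0}
        base = pd.DataFrame(np.column_stack([cmeans[c] for c in cond]),
                            columns=[f"s{i}" for i in range(8)])
        withb = base.copy()
        withb.iloc[:, 4:] += 5.0                            # batch offset
        out = pp.remove_batch(withb, batch, preserve=cond)
        for c in ("c0", "c1"):
            sel = [x == c for x in cond]
            np.testing.assert_allclose(
                out.loc[:, sel].mean(axis=1) - base.loc[:, sel].mean(axis=1),
                np.zeros(10), atol=1e-8)

    def test_confounded_design_rejected(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="confounded|aliased"):
            pp.remove_batch(m, ["A", "A", "B", "B"],
                            preserve=["x", "x", "y", "y"])


class TestNormalizeAbundance:
    def test_medians_recentred_with_missing(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 6)) + rng.normal(size=6))
        m[m > 1.2] = np.nan
        out = pp.normalize_abundance(m)
        np.testing.assert_allclose(np.nanmedian(out, axis=0),
                                   np.zeros(6), atol=1e-12)

    def test_all_missing_sample_errors(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            pp.normalize_abundance(m)


class TestImpute:
    def test_complete_matrix_identity(self, rng):
        m = pd.DataFrame(rng.normal(size=(10, 4)))
        out = pp.impute(m, ["a", "a", "b", "b"])
        pd.testing.assert_frame_equal(out, m)

    def test_degenerate_condition_imputes_exact_value(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0, np.nan]],
                         columns=["s1", "s2", "s3", "s4"])
        out = pp.impute(m, ["c"] * 4, min_observed_frac=0.5)
        assert out.iloc[0, 3] == pytest.approx(5.0)

    def test_observed_entries_bitwise_unchanged(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 8)))
        mask = rng.uniform(size=m.shape) < 0.3
        m[mask] = np.nan
        out = pp.impute(m, ["a"] * 4 + ["b"] * 4, seed=1)
        obs = ~mask
        assert (out.to_numpy()[obs] == m.to_numpy()[obs]).all()
        assert not out.isna().any().any()

    def test_tail_imputation_sits_below_observed_mean(self, rng):
        lows = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            m = pd.DataFrame(r.normal(10.0, 2.0, size=(60, 6)))
            # whole conditions missing -> only tail-stage applies
            m.iloc[:15, :3] = np.nan
            out = pp.impute(m, ["a"] * 3 + ["b"] * 3,
                            min_observed_frac=0.9, seed=seed)
            lows.append(out.iloc[:15, :3].to_numpy().mean()
                        < m.iloc[15:, :].to_numpy().mean())
        assert np.mean(lows) == 1.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            pp.impute(pd.DataFrame([[1.0]]), ["a"], min_observed_frac=0.0)


def _meta(times, reps):
    rows = []
    for t in times:
        for r in range(reps):
            rows.append((f"t{t}_r{r}", float(t)))
    return pd.DataFrame(rows, columns=["sample", "time"]).set_index("sample")


class TestDifferential:
    def test_identical_groups_null_result(self):
        meta = _meta([0, 60], 3)
        view = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
                            index=["f"], columns=meta.index)
        res = pp.differential(view, meta)
        assert res["log2FC"].iloc[0] == 0.0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_clear_separation_with_tiny_jitter(self):
        meta = _meta([0, 60], 3)
        jit = np.array([0, 1e-6, -1e-6])
        view = pd.DataFrame([np.concatenate([jit, 1.0 + jit])],
                            index=["f"], columns=meta.index)
        res = pp.differential(view, meta)
        assert res["log2FC"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert res["p"].iloc[0] < 1e-6

    def test_matches_welch_oracle(self, rng):
        meta = _meta([0, 60, 360], 4)
        view = pd.DataFrame(rng.normal(size=(10, 12)), columns=meta.index,
                            index=[f"f{i}" for i in range(10)])
        res = pp.differential(view, meta)
        ctrl = view.iloc[:, :4].to_numpy()
        for t, block in ((60.0, view.iloc[:, 4:8]), (360.0, view.iloc[:, 8:])):
            sub = res[res["time"] == t]
            tt = stats.ttest_ind(block.to_numpy(), ctrl, axis=1,
                                 equal_var=False)
            np.testing.assert_allclose(sub["p"], tt.pvalue, rtol=1e-12)
            np.testing.assert_allclose(
                sub["log2FC"], block.mean(axis=1) - ctrl.mean(axis=1))

    def test_single_replicate_rejected(self):
        meta = _meta([0, 60], 1)
        view = pd.DataFrame([[1.0, 2.0]], index=["f"], columns=meta.index)
        with pytest.raises(ValueError):
            pp.differential(view, meta)

    def test_null_pvalues_uniform(self):
        """Exchangeable groups: pooled Welch p-values pass a KS uniformity
        check across 500 independent null features."""
        r = np.random.default_rng(42)
        meta = _meta([0, 60], 4)
        view = pd.DataFrame(r.normal(size=(500, 8)), columns=meta.index,
                            index=[f"f{i}" for i in range(500)])
        res = pp.differential(view, meta)
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01


class TestFilterRegulated:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["feature", "time", "log2FC", "p"])

    def test_boundary_lfc_excluded_rna(self):
        res = self._results([("f", 60.0, 1.0, 0.001)])
        assert pp.filter_regulated(res, "rna") == []

    def test_protein_layer_ignores_p(self):
        res = self._results([("f", 60.0, -1.3, 0.9)])
        assert pp.filter_regulated(res, "protein") == ["f"]
        assert pp.filter_regulated(res, "rna") == []

    def test_toy_table_matches_manual_application(self):
        res = self._results([
            ("a", 60.0, 1.5, 0.01),    # rna: in (lfc>1, p<0.05)
            ("b", 60.0, 1.5, 0.2),     # rna: out (p), protein: in
            ("c", 60.0, 0.9, 0.001),   # out everywhere (lfc)
            ("d", 60.0, -2.0, 0.04),   # in
            ("e", 60.0, -1.0, 0.01),   # boundary: out
            ("f", 360.0, 1.1, 0.03),   # in at later time point
        ])
        assert pp.filter_regulated(res, "rna") == ["a", "d", "f"]
        assert pp.filter_regulated(res, "protein") == ["a", "b", "d", "f"]

    def test_coding_flag_applies_to_rna_only(self):
        res = self._results([("a", 60.0, 2.0, 0.01), ("b", 60.0, 2.0, 0.01)])
        fmeta = pd.DataFrame({"is_coding": [True, False]}, index=["a", "b"])
        assert pp.filter_regulated(res, "rna", feature_meta=fmeta) == ["a"]

    def test_unknown_layer_rejected(self):
        with pytest.raises(ValueError):
            pp.filter_regulated(self._results([]), "metabolome")

    @given(st.floats(0.1, 3.0), st.floats(0.001, 0.5))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_thresholds(self, lfc, p):
        r = np.random.default_rng(0)
        res = pd.DataFrame({
            "feature": [f"f{i}" for i in range(50)], "time": 60.0,
            "log2FC": r.normal(scale=1.5, size=50),
            "p": r.uniform(size=50)})
        strict = set(pp.filter_regulated(res, "rna", lfc_thresh=lfc,
                                         p_thresh=p))
        loose = set(pp.filter_regulated(res, "rna", lfc_thresh=lfc * 0.5,
                                        p_thresh=min(1.0, p * 2)))
        assert strict <= loose


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "group", "ct"])

    def test_identical_groups_give_unit_expression(self):
        rows = [(g, grp, ct) for grp in ("ctrl", "trt")
                for g, ct in [("ACTB", 18.0), ("TBP", 26.0), ("IL6", 24.0)]]
        out = pp.ddct(self._table(rows), ["ACTB", "TBP"], "ctrl")
        il6 = out[(out.gene == "IL6") & (out.group == "trt")]
        assert il6["relative_expression"].iloc[0] == pytest.approx(1.0)

    def test_ddct_of_two_gives_quarter(self):
        rows = [("ACTB", "ctrl", 18.0), ("IL6", "ctrl", 24.0),
                ("ACTB", "trt", 18.0), ("IL6", "trt", 26.0)]
        out = pp.ddct(self._table(rows), ["ACTB"], "ctrl")
        trt = out[(out.gene == "IL6") & (out.group == "trt")]
        assert trt["relative_expression"].iloc[0] == pytest.approx(0.25)

    def test_three_gene_hand_fixture(self):
        rows = [("ACTB", "ctrl", 18.0), ("TBP", "ctrl", 26.0),
                ("JUN", "ctrl", 22.0), ("FOS", "ctrl", 25.0),
                ("ACTB", "trt", 19.0), ("TBP", "trt", 27.0),
                ("JUN", "trt", 26.0), ("FOS", "trt", 24.0)]
        out = pp.ddct(self._table(rows), ["ACTB", "TBP"], "ctrl").set_index(
            ["gene", "group"])["relative_expression"]
        # hand: hk mean ctrl 22, trt 23; dCt JUN: 0 -> 3, ddCt 3 -> 2^-3
        assert out[("JUN", "trt")] == pytest.approx(0.125)
        # FOS: dCt 3 -> 1, ddCt -2 -> 4
        assert out[("FOS", "trt")] == pytest.approx(4.0)

    def test_missing_housekeeping_errors(self):
        rows = [("IL6", "ctrl", 24.0), ("IL6", "trt", 25.0)]
        with pytest.raises(ValueError):
            pp.ddct(self._table(rows), ["ACTB"], "ctrl")
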