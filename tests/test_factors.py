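"""Multi-view factor model: exactness, selection rules, wave assignment."""

import numpy as np
import pandas as pd
import pytest

from oiswaves import factors
from oiswaves.factors import (FactorModel, VarianceDecomposition, assign_waves,
                              factor_correlation, fit_tfa, scale_views,
                              select_factors, select_features,
                              variance_explained)


def _times(n_rep=3, points=(0.0, 15.0, 60.0, 360.0, 1440.0)):
    idx, vals = [], []
    for t in points:
        for r in range(n_rep):
            idx.append(f"t{int(t)}_r{r}")
            vals.append(t)
    return pd.Series(vals, index=idx)


class TestScaleViews:
    def test_standardized_input_unchanged(self, rng):
        m = rng.normal(size=(30, 10))
        m = (m - m.mean(axis=1, keepdims=True)) / m.std(axis=1, keepdims=True)
        df = pd.DataFrame(m)
        out = scale_views({"v": df})["v"]
        np.testing.assert_allclose(out.to_numpy(), m, atol=1e-12)

    def test_constant_feature_dropped(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                          index=["flat", "var"])
        out = scale_views({"v": df})["v"]
        assert list(out.index) == ["var"]

    def test_random_fixture_moments(self, rng):
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 8)))
        out = scale_views({"v": df})["v"].to_numpy()
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            scale_views({"v": pd.DataFrame([[1.0]])})


class TestFitTfa:
    def test_noiseless_rank_one_is_exact(self, rng):
        time = _times()
        z = np.sin(np.arange(len(time)))
        w = rng.normal(size=40)
        Y = pd.DataFrame(np.outer(w, z), columns=time.index)
        model = fit_tfa({"v": Y}, time, K=1, lam=0.0)
        rec = model.W["v"].to_numpy() @ model.Z.to_numpy().T
        np.testing.assert_allclose(rec, Y.to_numpy(), atol=1e-6)
        corr = np.corrcoef(model.Z.iloc[:, 0], z)[0, 1]
        assert abs(corr) > 0.999

    def test_objective_nonincreasing(self, rng):
        time = _times()
        Y = pd.DataFrame(rng.normal(size=(50, len(time))), columns=time.index)
        model = fit_tfa({"v": Y}, time, K=3, lam=0.5)
        trace = np.array(model.objective_trace)
        assert (np.diff(trace) <= 1e-9 * trace[:-1]).all()

    def test_reconstruction_improves_with_k(self, rng):
        time = _times()
        Y = pd.DataFrame(rng.normal(size=(50, len(time))), columns=time.index)
        errs = []
        for K in (1, 2, 3):
            m = fit_tfa({"v": Y}, time, K=K, lam=0.0)
            rec = m.W["v"].to_numpy() @ m.Z.to_numpy().T
            errs.append(np.sum((Y.to_numpy() - rec) ** 2))
        assert errs[2] <= errs[1] <= errs[0]

    def test_huge_smoothness_flattens_scores(self, rng):
        time = _times()
        Y = rng.normal(size=(30, len(time)))
        Y = pd.DataFrame(Y - Y.mean(axis=1, keepdims=True),
                         columns=time.index)
        model = fit_tfa({"v": Y}, time, K=2, lam=1e8)
        # in the lambda -> inf limit nothing beyond the per-feature mean
        # (zero, after scaling) is explained: residual ~ total variance
        assert model.objective_trace[-1] >= 0.99 * np.sum(Y.to_numpy() ** 2)

    def test_k_larger_than_features_rejected(self, rng):
        time = _times()
        Y = pd.DataFrame(rng.normal(size=(3, len(time))), columns=time.index)
        with pytest.raises(ValueError):
            fit_tfa({"v": Y}, time, K=5)


def _toy_model(rng, K=2, n_feat=30):
    time = _times()
    Z = rng.normal(size=(len(time), K))
    W = rng.normal(size=(n_feat, K))
    Y = pd.DataFrame(W @ Z.T + 0.1 * rng.normal(size=(n_feat, len(time))),
                     columns=time.index)
    model = fit_tfa({"v": Y}, time, K=K, lam=0.0)
    return model, {"v": Y}


class TestVarianceExplained:
    def test_rank_one_total_is_one(self, rng):
        time = _times()
        z = rng.normal(size=len(time))
        Y = pd.DataFrame(np.outer(rng.normal(size=20), z), columns=time.index)
        model = fit_tfa({"v": Y}, time, K=1, lam=0.0)
        vd = variance_explained(model, {"v": Y})
        assert vd.per_view_total["v"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_weight_view_has_zero_r2(self, rng):
        time = _times()
        z1, z2 = rng.normal(size=len(time)), rng.normal(size=len(time))
        Ya = pd.DataFrame(np.outer(rng.normal(size=20), z1), columns=time.index)
        Yb = pd.DataFrame(np.outer(rng.normal(size=20), z2), columns=time.index)
        model = fit_tfa({"a": Ya, "b": Yb}, time, K=2, lam=0.0)
        vd = variance_explained(model, {"a": Ya, "b": Yb})
        # each view is rank-1: its weaker factor explains ~nothing
        assert vd.per_view_factor.min(axis=1).max() < 0.02

    def test_agrees_with_direct_residual_norms(self, rng):
        model, views = _toy_model(rng)
        vd = variance_explained(model, views)
        Y = views["v"].to_numpy()
        W = model.W["v"].to_numpy()
        Z = model.Z.to_numpy()
        denom = np.sum(Y ** 2)
        for k in range(2):
            direct = 1 - np.sum((Y - np.outer(W[:, k], Z[:, k])) ** 2) / denom
            assert vd.per_view_factor.iloc[0, k] == pytest.approx(
                max(direct, 0.0), abs=1e-9)
        direct_tot = 1 - np.sum((Y - W @ Z.T) ** 2) / denom
        assert vd.per_view_total["v"] == pytest.approx(direct_tot, abs=1e-9)


class TestSelectFactors:
    @staticmethod
    def _vd(r2_row):
        perf = pd.DataFrame([r2_row], index=["v"],
                            columns=[f"factor{i+1}" for i in range(len(r2_row))])
        mu, sd = perf.mean(axis=1), perf.std(axis=1, ddof=1)
        z = perf.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
        return VarianceDecomposition(
            per_view_total=pd.Series({"v": sum(r2_row)}),
            per_view_factor=perf, zscores=z)

    def test_dominant_factors_kept(self):
        kept = select_factors(self._vd([0.30, 0.20, 0.01, 0.01]))
        assert kept == ["factor1", "factor2"]

    def test_equal_variance_keeps_none(self):
        assert select_factors(self._vd([0.1, 0.1, 0.1, 0.1])) == []

    def test_single_factor_rejected(self):
        with pytest.raises(ValueError):
            select_factors(self._vd([0.5]))


class TestFactorCorrelation:
    def test_single_factor_trivial(self, rng):
        time = _times()
        Y = pd.DataFrame(rng.normal(size=(20, len(time))), columns=time.index)
        m = fit_tfa({"v": Y}, time, K=1, lam=0.0)
        np.testing.assert_allclose(factor_correlation(m).to_numpy(), [[1.0]])

    def test_duplicated_column_perfectly_correlated(self):
        time = _times()
        z = np.sin(np.arange(len(time)))
        Z = pd.DataFrame({"factor1": z, "factor2": z}, index=time.index)
        m = FactorModel(W={}, Z=Z, time=time, K=2, lam=0.0, converged=True)
        assert factor_correlation(m).iloc[0, 1] == pytest.approx(1.0)

    def test_planted_orthogonal_factors_weakly_correlated(self, small_dataset):
        from oiswaves import pipeline
        from oiswaves.config import make_config
        cfg = make_config({"tfa": {"k_max": 5}})
        processed, _, regulated = pipeline.preprocess_stage(
            small_dataset, cfg, seed=7)
        fit = pipeline.factor_stage(processed, regulated,
                                    small_dataset.sample_meta, cfg)
        corr = factor_correlation(fit["model"]).to_numpy()
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.abs(off).max() < 0.3


class TestSelectFeatures:
    @staticmethod
    def _model_with_weights(w, time=None):
        time = time if time is not None else _times()
        W = pd.DataFrame({"factor1": w},
                         index=[f"f{i}" for i in range(len(w))])
        Z = pd.DataFrame({"factor1": np.zeros(len(time))}, index=time.index)
        return FactorModel(W={"v": W}, Z=Z, time=time, K=1, lam=0.0,
                           converged=True)

    def test_equal_weights_select_nothing(self):
        m = self._model_with_weights(np.ones(50))
        assert len(select_features(m, "v", "factor1")) == 0

    def test_single_outlier_selected(self):
        w = np.zeros(100)
        w[17] = 10.0
        m = self._model_with_weights(w)
        sel = select_features(m, "v", "factor1")
        assert list(sel["feature"]) == ["f17"]
        assert list(sel["direction"]) == [1]

    def test_planted_support_recovered(self, clean_recovery_fit):
        """Weight z-score selection attains Jaccard >= 0.7 with the planted
        loading support at the default effect size (recovery harness without
        dropout/batch, which isolates loading recovery from imputation)."""
        ds, fit = clean_recovery_fit
        model = fit["model"]
        truth = ds.truth
        Zt = truth["Z"].to_numpy()
        Zf = model.Z.to_numpy()
        C = np.abs(np.corrcoef(Zt.T, Zf.T)[:Zt.shape[1], Zt.shape[1]:])
        members = truth["members"]
        jaccards = []
        for k in range(Zt.shape[1]):
            fname = model.factor_names[int(np.argmax(C[k]))]
            for view in ("rna", "protein", "phospho"):
                planted = set(members[(members.factor == k)
                                      & (members.view == view)]["feature"])
                planted &= set(model.W[view].index)
                if not planted:
                    continue
                sel = set(select_features(model, view, fname)["feature"])
                jaccards.append(len(planted & sel)
                                / max(len(planted | sel), 1))
        assert np.mean(jaccards) >= 0.7


class TestAssignWaves:
    @staticmethod
    def _model(profile_by_time, r2=None):
        time = _times()
        z = time.map(profile_by_time).astype(float)
        Z = pd.DataFrame({"factor1": z, "factor2": -z}, index=time.index)
        perf = pd.DataFrame(r2 if r2 is not None
                            else {"factor1": [0.3, 0.3, 0.3],
                                  "factor2": [0.3, 0.3, 0.3]},
                            index=["rna", "protein", "phospho"])
        mu, sd = perf.mean(axis=1), perf.std(axis=1, ddof=1)
        vd = VarianceDecomposition(
            per_view_total=perf.sum(axis=1),
            per_view_factor=perf,
            zscores=perf.sub(mu, axis=0).div(sd.replace(0, np.nan),
                                             axis=0).fillna(0.0))
        m = FactorModel(W={}, Z=Z, time=time, K=2, lam=0.0, converged=True)
        return m, vd

    def test_step_at_six_hours(self):
        m, vd = self._model({0.0: 0, 15.0: 0, 60.0: 0, 360.0: 1, 1440.0: 1})
        wa = assign_waves(m, vd)
        assert wa.wave_time["factor1"] == 360.0

    def test_monotone_decay_from_fifteen_minutes(self):
        m, vd = self._model({0.0: 1.0, 15.0: 0.5, 60.0: 0.25,
                             360.0: 0.125, 1440.0: 0.0625})
        wa = assign_waves(m, vd)
        assert wa.wave_time["factor1"] == 15.0

    def test_flat_trajectory_unassigned(self):
        m, vd = self._model({t: 1.0 for t in (0.0, 15.0, 60.0, 360.0, 1440.0)})
        wa = assign_waves(m, vd)
        assert "factor1" in wa.unassigned

    def test_weak_view_excluded(self):
        r2 = pd.DataFrame({"factor1": [0.005, 0.3, 0.25],
                           "factor2": [0.3, 0.01, 0.3]},
                          index=["rna", "protein", "phospho"])
        m, vd = self._model({0.0: 0, 15.0: 1, 60.0: 1, 360.0: 1, 1440.0: 1},
                            r2=r2)
        wa = assign_waves(m, vd)
        assert "rna" in wa.excluded_views["factor1"]
        assert "rna" not in wa.excluded_views["factor2"]
        assert "protein" in wa.excluded_views["factor2"]
        assert "protein" not in wa.excluded_views["factor1"]

    def test_rna_excluded_for_phospho_only_factor(self, clean_recovery_fit):
        """A factor planted only on protein/phospho (the 15-min wave) gets
        the RNA view excluded in its dissection."""
        ds, fit = clean_recovery_fit
        model = fit["model"]
        C = np.abs(np.corrcoef(ds.truth["Z"].to_numpy().T,
                               model.Z.to_numpy().T)[:4, 4:])
        wave1_factor = model.factor_names[int(np.argmax(C[0]))]
        assert "rna" in fit["waves"].excluded_views[wave1_factor]
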