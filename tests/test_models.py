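"""Polynomial latency models, scoring, grid search, transfer and ARX."""

import numpy as np
import pandas as pd
import pytest
import sklearn.metrics

from adslow.errors import EmptyInputError, ValidationError
from adslow.features import FeatureMatrix, WindowScheme, featurize
from adslow.models import (
    cross_validate,
    fit_arx,
    fit_poly,
    grid_search,
    predict,
    predict_arx,
    r2_score,
    select_best,
    transfer_evaluate,
)
from adslow.records import LatencySeries, ProtocolSegment

from conftest import make_record


def _feature_matrix(counts, targets, scheme=None):
    counts = np.asarray(counts)
    scheme = scheme or WindowScheme(0.5, counts.shape[1])
    return FeatureMatrix(
        scheme,
        "unit",
        np.arange(len(counts), dtype=float),
        counts,
        np.asarray(targets, dtype=float),
    )


class TestFitPoly:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(50, 3))
        fm = _feature_matrix(counts, 1.0 + 0.01 * counts[:, 0])
        model = fit_poly(fm, degree=1)
        assert model.intercept == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(model.coefficients, [0.01, 0, 0], atol=1e-8)

    def test_constant_targets(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, size=(30, 2))
        model = fit_poly(_feature_matrix(counts, np.full(30, 1.3)), degree=1)
        assert model.intercept == pytest.approx(1.3, abs=1e-10)
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-10)

    def test_quadratic_recovery(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 30, size=(200, 2))
        targets = 1.0 + 0.001 * counts[:, 0] ** 2
        model = fit_poly(_feature_matrix(counts, targets), degree=2)
        names = ["s_1", "s_2", "s_1^2", "s_1*s_2", "s_2^2"]
        coef = dict(zip(names, model.coefficients))
        assert coef["s_1^2"] == pytest.approx(0.001, abs=1e-6)

    def test_zero_variance_column_gets_zero_weight(self):
        rng = np.random.default_rng(3)
        counts = np.column_stack(
            [rng.integers(0, 20, 40), np.zeros(40, dtype=int)]
        )
        model = fit_poly(_feature_matrix(counts, 1 + 0.01 * counts[:, 0]), degree=1)
        assert model.coefficients[1] == 0.0

    def test_too_few_rows(self):
        fm = _feature_matrix(np.arange(6).reshape(2, 3), [1.0, 1.1])
        with pytest.raises(EmptyInputError):
            fit_poly(fm, degree=1)

    def test_clip_range_comes_from_training_targets(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 9, size=(20, 2))
        targets = 1 + 0.02 * counts[:, 0]
        model = fit_poly(_feature_matrix(counts, targets), degree=1)
        assert model.clip_range == (targets.min(), targets.max())


class TestPredict:
    def _model(self):
        counts = np.arange(40).reshape(20, 2)
        return fit_poly(_feature_matrix(counts, np.linspace(1.0, 1.5, 20)), 1)

    def test_clamps_and_flags(self):
        counts = np.arange(40).reshape(20, 2)
        fm = _feature_matrix(counts, np.linspace(1.0, 1.5, 20))
        model = fit_poly(fm, 1)
        model.clip_range = (1.1, 1.4)
        pred = predict(model, fm)
        assert pred.values.min() >= 1.1 and pred.values.max() <= 1.4
        assert pred.clipped[0] and pred.clipped[-1]
        inside = ~pred.clipped
        np.testing.assert_array_equal(pred.values[inside], pred.raw[inside])

    def test_all_zero_row_predicts_intercept(self):
        model = self._model()
        fm = _feature_matrix(np.zeros((1, 2), dtype=int), [1.0], scheme=model.scheme)
        pred = predict(model, fm)
        lo, hi = model.clip_range
        assert pred.raw[0] == pytest.approx(model.intercept)
        assert pred.values[0] == np.clip(model.intercept, lo, hi)

    def test_scheme_mismatch_rejected(self):
        model = self._model()
        fm = _feature_matrix(np.zeros((1, 3), dtype=int), [1.0])
        with pytest.raises(ValidationError, match="scheme"):
            predict(model, fm)

    def test_clipping_never_hurts_on_training_data(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            counts = rng.integers(0, 15, size=(30, 2))
            targets = 1 + 0.01 * counts[:, 0] + rng.normal(0, 0.3, 30)
            targets = np.abs(targets) + 0.1
            fm = _feature_matrix(counts, targets)
            model = fit_poly(fm, 1)
            pred = predict(model, fm)
            ss_clip = np.sum((targets - pred.values) ** 2)
            ss_raw = np.sum((targets - pred.raw) ** 2)
            assert ss_clip <= ss_raw + 1e-12


class TestR2Score:
    def test_perfect_fit(self):
        assert r2_score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r2_score(obs, np.full(3, obs.mean())) == 0.0

    def test_direct_formula(self):
        assert r2_score([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_constant_observations_warn_and_score_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert r2_score([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]) == 0.0

    def test_matches_sklearn(self):
        rng = np.random.default_rng(6)
        obs, pred = rng.normal(size=100), rng.normal(size=100)
        assert r2_score(obs, pred) == pytest.approx(
            sklearn.metrics.r2_score(obs, pred), abs=1e-12
        )


def _poly_record(seed=0, n=120, coef=(1.0, 0.01)):
    """Small record whose latency is linear in spike counts, for CV tests."""
    rng = np.random.default_rng(seed)
    t = 10.0 + 4.0 * np.arange(n)
    spikes = np.sort(rng.uniform(0, t[-1], 4 * n))
    rec = make_record(
        t, np.full(n, 250.0), norm=np.full(n, 1.0),
        spikes=spikes, segments=[ProtocolSegment(0.0, t[-1] + 1, 0.25)],
    )
    scheme = WindowScheme(0.5, 3)
    fm = featurize(rec, scheme)
    norm = coef[0] + coef[1] * fm.counts[:, 0] + 0.002 * fm.counts[:, 2]
    rec.latencies = LatencySeries(t, 250.0 * norm, norm)
    return rec, scheme


class TestCrossValidate:
    def test_truth_in_model_class_scores_one(self):
        rec, scheme = _poly_record()
        # with the clip range drawn from all latencies nothing is clamped
        # and the noiseless fit is exact out of sample
        res_all = cross_validate(rec, scheme, 1, clip_source="all")
        assert res_all.mean_r2 == pytest.approx(1.0, abs=1e-9)
        # train-only clipping may clamp test-fold extremes, costing a little
        res = cross_validate(rec, scheme, 1)
        assert res.mean_r2 > 0.99
        assert res.mean_r2 == pytest.approx(np.mean(res.per_fold_r2))

    def test_rotation_bookkeeping(self):
        rec, scheme = _poly_record(n=9)
        res = cross_validate(rec, scheme, 1)
        assert len(res.models) == 3
        assert len(res.per_fold_r2) == 3


class TestGridSearch:
    def test_singleton_grid_returns_it(self):
        rec, _ = _poly_record()
        gs = grid_search(rec, t_min_grid=(0.5,), n_grid=(3,), d_grid=(1,))
        assert (gs.best_scheme.t_min, gs.best_scheme.n, gs.best_degree) == (0.5, 3, 1)
        assert len(gs.table) == 1

    def test_tie_breaks_prefer_simpler_models(self):
        table = pd.DataFrame(
            {
                "T_min": [0.25, 0.5, 0.25],
                "N": [6, 5, 5],
                "d": [2, 1, 1],
                "r2_fold1": 0.9, "r2_fold2": 0.9, "r2_fold3": 0.9,
                "r2_mean": [0.8, 0.8, 0.8],
            }
        )
        best = select_best(table)
        # smaller d first, then smaller N, then larger T_min
        assert (best["d"], best["N"], best["T_min"]) == (1, 5, 0.5)

    def test_best_is_brute_force_argmax_of_table(self):
        rec, _ = _poly_record(seed=9)
        gs = grid_search(
            rec, t_min_grid=(0.25, 0.5), n_grid=(2, 3), d_grid=(1, 2)
        )
        finite = gs.table[np.isfinite(gs.table.r2_mean)]
        assert gs.best_result.mean_r2 == finite.r2_mean.max()


class TestTransfer:
    def test_self_transfer_equals_in_sample(self):
        rec, scheme = _poly_record()
        r2 = transfer_evaluate(rec, rec, scheme, 1)
        fm = featurize(rec, scheme)
        model = fit_poly(fm, 1)
        in_sample = r2_score(fm.targets, predict(model, fm).values)
        assert r2 == pytest.approx(in_sample, abs=1e-12)

    def test_rescaled_test_fiber_scores_negative(self):
        rec, scheme = _poly_record()
        lat = rec.latencies
        scaled = rec.replace(
            latencies=LatencySeries(lat.stimulus_times, lat.raw * 2, lat.norm * 2)
        )
        assert transfer_evaluate(rec, scaled, scheme, 1) < 0


class TestARX:
    def _arx_record(self, a=(0.3, 0.2, 0.1), b=0.002, c=0.4, n=300, seed=0):
        rng = np.random.default_rng(seed)
        t = 4.0 * np.arange(n)
        spikes = np.sort(rng.uniform(0, t[-1], 2 * n))
        rec = make_record(
            t, np.full(n, 250.0), norm=np.full(n, 1.0),
            spikes=spikes, segments=[ProtocolSegment(0.0, t[-1] + 1, 0.25)],
        )
        from adslow.features import count_history

        exo = np.array([count_history(rec.spikes, ti, 8.1) for ti in t])
        norm = np.empty(n)
        norm[:3] = 1.0
        for i in range(3, n):
            norm[i] = c + sum(a[j] * norm[i - 1 - j] for j in range(3)) + b * exo[i]
        rec.latencies = LatencySeries(t, 250.0 * norm, norm)
        return rec, (a, b, c)

    def test_exact_coefficient_recovery(self):
        rec, (a, b, c) = self._arx_record()
        model = fit_arx(rec)
        np.testing.assert_allclose(model.lag_coefficients, a, atol=1e-6)
        assert model.exo_coefficient == pytest.approx(b, abs=1e-6)
        assert model.intercept == pytest.approx(c, abs=1e-6)

    def test_constant_generator_predicts_constant(self):
        rec, _ = self._arx_record(a=(0.0, 0.0, 0.0), b=0.0, c=1.0)
        model = fit_arx(rec)
        pred = predict_arx(model, rec)
        np.testing.assert_allclose(pred, 1.0, atol=1e-9)

    def test_first_lags_carry_no_prediction(self):
        rec, _ = self._arx_record(n=50)
        model = fit_arx(rec)
        assert len(predict_arx(model, rec)) == 50 - model.n_lags

    def test_insufficient_history(self):
        rec, _ = self._arx_record(n=50)
        short = rec.replace(
            latencies=LatencySeries(
                rec.latencies.stimulus_times[:4],
                rec.latencies.raw[:4],
                rec.latencies.norm[:4],
            )
        )
        with pytest.raises(EmptyInputError):
            fit_arx(short)
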