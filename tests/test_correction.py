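"""ACF, white-noise gate, and the recursive correction chain."""

import json

import numpy as np
import pytest

from resicast import (
    SplitSpec,
    StopPolicy,
    TimeSeries,
    acf,
    ann_correction_factory,
    chain_forecast,
    fit_correction_chain,
    gen_ar,
    gen_white_noise,
    mlp_base_factory,
    normalize_minmax,
    white_noise_test,
)
from resicast.forecast import FittedForecaster
from resicast.mlp import TrainOptions
from resicast.series import InsufficientDataError


def _brute_force_acf(x, max_lag):
    n = len(x)
    xbar = sum(x) / n
    gamma0 = sum((v - xbar) ** 2 for v in x) / n
    out = []
    for k in range(1, max_lag + 1):
        g = sum((x[t] - xbar) * (x[t + k] - xbar) for t in range(n - k)) / n
        out.append(g / gamma0)
    return out


class TestACF:
    def test_four_point_example(self):
        res = acf(TimeSeries(np.array([1.0, 2.0, 3.0, 4.0])), 2)
        assert res.rho[0] == pytest.approx(0.25, abs=1e-12)
        assert res.rho[1] == pytest.approx(-0.3, abs=1e-12)

    def test_lag_zero_is_one_by_construction(self):
        # rho_0 = gamma_0/gamma_0; the stored lags start at 1
        x = np.random.default_rng(0).normal(size=50)
        res = acf(TimeSeries(x), 5)
        assert res.lags[0] == 1
        xc = x - x.mean()
        assert float(xc @ xc) / float(xc @ xc) == 1.0

    def test_matches_brute_force_oracle(self):
        x = gen_white_noise(500, 1.0, seed=12).values
        res = acf(x, 20)
        np.testing.assert_allclose(res.rho, _brute_force_acf(list(x), 20), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.tsa.stattools import acf as sm_acf

        x = gen_ar(300, (0.7,), 1.0, seed=4).values
        res = acf(x, 10)
        np.testing.assert_allclose(res.rho, sm_acf(x, nlags=10, adjusted=False)[1:], atol=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            acf(np.full(50, 2.0), 5)

    def test_rho_bounded(self):
        x = gen_ar(200, (0.9,), 1.0, seed=1).values
        res = acf(x, 20)
        assert np.all(np.abs(res.rho) <= 1.0 + 1e-12)


class TestWhiteNoiseTest:
    def test_all_zero_rho_is_white(self):
        from resicast.correction import ACFResult

        res = ACFResult(np.zeros(10), np.full(10, 0.1), 100, True, 0)
        assert white_noise_test(res)

    def test_strong_ar1_is_not_white(self):
        res = acf(gen_ar(500, (0.9,), 1.0, seed=23).values, 20)
        assert not white_noise_test(res)

    def test_iid_noise_passes_with_tolerance(self):
        # with 20 lags, tolerance 0.05 allows one exceedance; under the
        # ~4.6% per-lag exceedance of the 2/sqrt(N) band the pass
        # probability is P(Bin(20, 0.046) <= 1) ~ 0.77, so ~38/50 runs
        # are expected to pass
        passes = 0
        for seed in range(50):
            res = acf(gen_white_noise(1000, 1.0, seed=seed).values, 20)
            passes += white_noise_test(res, tolerance_fraction=0.05)
        assert passes >= 35


OPTS = TrainOptions(max_iterations=120)


def _weak_base():
    return mlp_base_factory(1, 2, "lm", OPTS)


def _ann_corr():
    return ann_correction_factory(hidden_sweep=(1, 2, 4), train_opts=OPTS)


class TestChain:
    def test_white_noise_input_stops_at_base(self):
        series, _ = normalize_minmax(gen_white_noise(400, 1.0, seed=31))
        chain = fit_correction_chain(
            series, _weak_base(), _ann_corr(), SplitSpec(0.8, 0.1, 0.1),
            StopPolicy(max_corrections=3), seed=1, acf_tolerance=0.05,
        )
        assert chain.depth == 0
        assert chain.stop_reason == "white_noise"

    def test_max_corrections_zero_returns_base_only(self, composite_norm):
        chain = fit_correction_chain(
            composite_norm, _weak_base(), _ann_corr(), SplitSpec(0.8, 0.1, 0.1),
            StopPolicy(max_corrections=0), seed=2,
        )
        assert chain.depth == 0
        assert chain.stop_reason == "max_corrections"

    def test_residual_reconstruction(self, composite_norm):
        chain = fit_correction_chain(
            composite_norm, _weak_base(), _ann_corr(), SplitSpec(0.8, 0.1, 0.1),
            StopPolicy(max_corrections=2), seed=3,
        )
        x = chain.series_values
        inputs = [x] + chain.residuals[:-1]
        for inp, pred, resid in zip(inputs, chain.stage_preds, chain.residuals):
            ok = np.isfinite(pred)
            np.testing.assert_allclose(resid[ok], (inp - pred)[ok], atol=1e-10)

    def test_additivity_from_persisted_models(self, composite_norm):
        # reload every stage from its serialized form and recompute its
        # output in isolation; the chain's combined prediction must equal
        # the elementwise sum exactly
        chain = fit_correction_chain(
            composite_norm, _weak_base(), _ann_corr(), SplitSpec(0.8, 0.1, 0.1),
            StopPolicy(max_corrections=2), seed=4,
        )
        x = chain.series_values
        total = np.zeros_like(x)
        cur = x.copy()
        for f in chain.forecasters:
            f2 = FittedForecaster.from_dict(json.loads(json.dumps(f.to_dict())))
            offset = int(np.argmax(np.isfinite(cur)))
            pred = np.full(x.size, np.nan)
            pred[offset:] = f2.predict_series(cur[offset:])
            total = total + pred
            cur = cur - pred
        combined = chain.combined_prediction(chain.depth)
        ok = np.isfinite(combined)
        np.testing.assert_allclose(combined[ok], total[ok], atol=1e-12)

    def test_chain_forecast_matches_stored_predictions(self, composite_norm):
        chain = fit_correction_chain(
            composite_norm, _weak_base(), _ann_corr(), SplitSpec(0.8, 0.1, 0.1),
            StopPolicy(max_corrections=2), seed=5,
        )
        combined = chain.combined_prediction()
        x = chain.series_values
        for t in (560, 580, 599):
            assert chain_forecast(chain, x[:t]) == pytest.approx(combined[t], abs=1e-12)

    def test_chain_forecast_depth_zero_equals_base(self, composite_norm):
        chain = fit_correction_chain(
            composite_norm, _weak_base(), _ann_corr(), SplitSpec(0.8, 0.1, 0.1),
            StopPolicy(max_corrections=0), seed=6,
        )
        x = chain.series_values
        f = chain_forecast(chain, x[:590])
        assert f == pytest.approx(chain.forecasters[0].predict_next(x[:590]), abs=1e-15)

    def test_constant_output_stages_sum(self):
        # two stages with hand-set constant outputs: additivity is a sum
        from resicast.mlp import MLPConfig, init_model
        from resicast.correction import CorrectionChain

        def const_forecaster(value):
            m = init_model(MLPConfig(1, 1, seed=0))
            m.w1[:] = 0.0
            m.b1[:] = 0.0
            m.w2[:] = 0.0
            m.b2 = value
            return FittedForecaster(m, (1,))

        x = np.linspace(0.0, 1.0, 20)
        chain = CorrectionChain(
            forecasters=[const_forecaster(5.0), const_forecaster(0.5)],
            stage_preds=[], residuals=[], records=[], stop_reason="max_corrections",
            selected_depth=1, train_end=16, val_end=18, series_values=x,
        )
        assert chain_forecast(chain, x[:10]) == pytest.approx(5.5)

    def test_insufficient_history_raises(self, composite_norm):
        chain = fit_correction_chain(
            composite_norm, _weak_base(), _ann_corr(), SplitSpec(0.8, 0.1, 0.1),
            StopPolicy(max_corrections=2), seed=7,
        )
        if chain.selected_depth >= 1:
            with pytest.raises(InsufficientDataError):
                chain_forecast(chain, chain.series_values[:2])

    def test_mape_increase_excludes_offending_stages(self, composite_norm):
        chain = fit_correction_chain(
            composite_norm, _weak_base(), _ann_corr(), SplitSpec(0.8, 0.1, 0.1),
            StopPolicy(mape_increase_threshold=1e-6, patience=1, max_corrections=4),
            seed=8,
        )
        if chain.stop_reason == "mape_increase":
            assert chain.selected_depth < chain.depth
            assert chain.records[-1].mape_increased
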