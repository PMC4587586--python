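"""The six evaluation metrics, the fitness score and metric ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resicast.metrics import (
    MetricError,
    arv,
    evaluate_all,
    fitness,
    ia,
    mape,
    mape_with_exclusions,
    metric_ratio,
    mse,
    pocid,
    theil_u,
)


def _loop_mse(t, o):
    return sum((a - b) ** 2 for a, b in zip(t, o)) / len(t)


def _loop_arv(t, o):
    tbar = sum(t) / len(t)
    return sum((b - a) ** 2 for a, b in zip(t, o)) / sum((b - tbar) ** 2 for b in o)


def _loop_ia(t, o):
    tbar = sum(t) / len(t)
    num = sum((b - a) ** 2 for a, b in zip(t, o))
    den = sum((abs(b - tbar) + abs(a - tbar)) ** 2 for a, b in zip(t, o))
    return 1 - num / den


def _loop_theil(t, o):
    num = sum((a - b) ** 2 for a, b in zip(t, o))
    den = sum((o[j] - o[j + 1]) ** 2 for j in range(len(o) - 1))
    return num / den


def _loop_pocid(t, o):
    hits = sum(
        1 for j in range(1, len(t)) if (t[j] - t[j - 1]) * (o[j] - o[j - 1]) > 0
    )
    return 100.0 * hits / (len(t) - 1)


class TestWorkedExamples:
    def test_mse(self):
        assert mse([0, 1], [1, 1]) == 0.5
        assert mse([3.0, 4.0], [3.0, 4.0]) == 0.0

    def test_mape_by_hand(self):
        assert mape([1, 2], [1.1, 1.8]) == pytest.approx(10.0)
        val, excl = mape_with_exclusions([0, 1], [0, 1])
        assert val == 0.0 and excl == 1

    def test_mape_all_zero_targets_undefined(self):
        with pytest.raises(MetricError):
            mape([0.0, 0.0], [1.0, 1.0])

    def test_theil_u_by_hand(self):
        assert theil_u([1, 1, 2], [1, 2, 2]) == pytest.approx(1.0)
        assert theil_u([1, 2, 3], [1, 2, 3]) == 0.0
        with pytest.raises(MetricError):
            theil_u([1, 2, 3], [2, 2, 2])

    def test_arv_by_hand(self):
        assert arv([0, 1], [0, 0]) == pytest.approx(2.0)
        assert arv([0, 1], [0, 1]) == 0.0

    def test_pocid_by_hand(self):
        assert pocid([1, 2, 3], [1.1, 2.2, 3.3]) == 100.0
        assert pocid([1, 2, 1], [1, 1.5, 1.8]) == 50.0
        assert pocid([1, 1, 1], [1, 2, 3]) == 0.0

    def test_ia_by_hand(self):
        assert ia([0, 1], [0, 0]) == pytest.approx(0.5)
        assert ia([0, 1, 2], [0, 1, 2]) == 1.0

    def test_fitness_published_rows(self):
        # printed metric rows recombine to the printed fitness (2 d.p.)
        assert round(fitness(97.16, 6.00e-4, 35.93, 0.0969, 0.3077), 2) == 2.60
        assert round(fitness(87.74, 2.95e-4, 19.18, 0.0510, 0.0888), 2) == 4.32
        assert fitness(0.0, 1.0, 1.0, 1.0, 1.0) == 0.0

    def test_ratio_published_rows(self):
        assert 19.18 / 27.41 == pytest.approx(0.700, abs=5e-4)
        assert 4.32 / 3.40 == pytest.approx(1.271, abs=5e-4)


class TestLoopOracles:
    @settings(max_examples=80, deadline=None)
    @given(st.integers(2, 200), st.integers(0, 10_000))
    def test_all_metrics_match_loop_oracles(self, n, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(1.0, 1.0, size=n)
        o = t + rng.normal(0.0, 0.5, size=n)
        assert mse(t, o) == pytest.approx(_loop_mse(t, o), abs=1e-12)
        assert arv(t, o) == pytest.approx(_loop_arv(t, o), abs=1e-12)
        assert ia(t, o) == pytest.approx(_loop_ia(t, o), abs=1e-12)
        if not np.allclose(np.diff(o), 0):
            assert theil_u(t, o) == pytest.approx(_loop_theil(t, o), abs=1e-12)
        assert pocid(t, o) == pytest.approx(_loop_pocid(t, o), abs=1e-12)


class TestFitnessShape:
    def test_monotone_in_each_component(self):
        base = fitness(80.0, 0.1, 20.0, 0.5, 0.3)
        assert fitness(81.0, 0.1, 20.0, 0.5, 0.3) > base
        for bump in (
            (80.0, 0.2, 20.0, 0.5, 0.3),
            (80.0, 0.1, 21.0, 0.5, 0.3),
            (80.0, 0.1, 20.0, 0.6, 0.3),
            (80.0, 0.1, 20.0, 0.5, 0.4),
        ):
            assert fitness(*bump) < base


class TestEvaluateAll:
    def test_perfect_forecast(self):
        rep = evaluate_all([1, 2, 3, 4], [1, 2, 3, 4])
        assert rep.mse == 0 and rep.mape == 0 and rep.theil_u == 0 and rep.arv == 0
        assert rep.pocid == 100 and rep.ia == 1
        assert rep.fitness == pytest.approx(100.0)

    def test_matches_component_metrics_and_internal_consistency(self, rng):
        t = rng.normal(2.0, 1.0, size=50)
        o = t + rng.normal(0.0, 0.3, size=50)
        rep = evaluate_all(t, o)
        assert rep.mse == mse(t, o)
        assert rep.mape == mape(t, o)
        assert rep.theil_u == theil_u(t, o)
        assert rep.arv == arv(t, o)
        assert rep.pocid == pocid(t, o)
        assert rep.ia == ia(t, o)
        assert rep.fitness == pytest.approx(
            fitness(rep.pocid, rep.mse, rep.mape, rep.theil_u, rep.arv), abs=1e-12
        )

    def test_undefined_components_are_flagged_not_fatal(self):
        rep = evaluate_all([1, 2, 3], [2, 2, 2])  # constant outputs: U undefined
        assert "theil_u" in rep.flags and math.isnan(rep.theil_u)
        assert "fitness" in rep.flags


class TestRatios:
    def test_self_ratio_is_one(self, rng):
        t = rng.normal(2.0, 1.0, size=40)
        o = t + rng.normal(0.0, 0.3, size=40)
        rep = evaluate_all(t, o)
        r = metric_ratio(rep, rep)
        for name in ("mse", "pocid", "theil_u", "mape", "arv", "ia", "fitness"):
            assert getattr(r, name) == pytest.approx(1.0, abs=1e-12)

    def test_multiplicative_chain(self, rng):
        t = rng.normal(2.0, 1.0, size=40)
        reps = [evaluate_all(t, t + rng.normal(0.0, s, size=40)) for s in (0.2, 0.4, 0.8)]
        ab = metric_ratio(reps[0], reps[1])
        bc = metric_ratio(reps[1], reps[2])
        ac = metric_ratio(reps[0], reps[2])
        for name in ("mse", "mape", "fitness"):
            assert getattr(ab, name) * getattr(bc, name) == pytest.approx(
                getattr(ac, name), rel=1e-9
            )

    def test_zero_uncorrected_flagged(self):
        perfect = evaluate_all([1, 2, 3], [1, 2, 3])
        noisy = evaluate_all([1, 2, 3], [1.2, 1.9, 3.1])
        r = metric_ratio(noisy, perfect)
        assert "mse" in r.undefined and math.isnan(r.mse)


class TestBounds:
    @settings(max_examples=40, deadline=None)
    @given(st.integers(3, 50), st.integers(0, 999))
    def test_pocid_and_ia_ranges(self, n, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(size=n)
        o = rng.normal(size=n)
        assert 0.0 <= pocid(t, o) <= 100.0
        assert ia(t, o) <= 1.0
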