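"""Parameter estimation: probabilities, waiting-time fits, full calibration."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from drinksim import (
    COHORT_RANGES,
    Bout,
    Drink,
    TooFewEventsError,
    calibrate,
    estimate_bout_probability,
    estimate_transition_probabilities,
    fit_inter_bout,
    fit_waiting_time,
    population_mean_parameters,
    sample_parameters,
    segment_bouts_by_day,
)
from helpers import simulate_at_least


def _classed_drinks(counts: dict[str, int]) -> list[Drink]:
    drinks, t = [], 0.0
    for cls, n in counts.items():
        for _ in range(n):
            drinks.append(Drink(t, t + 10.0, 5.0, rate_class=cls))
            t += 400.0
    return drinks


def _bout_of(n_drinks: int, t0: float) -> Bout:
    drinks = tuple(
        Drink(t0 + 40.0 * i, t0 + 40.0 * i + 10.0, 5.0) for i in range(n_drinks)
    )
    return Bout(drinks)


class TestTransitionProbabilities:
    def test_fractions_by_definition(self):
        drinks = _classed_drinks({"low": 5, "medium": 3, "high": 2})
        assert estimate_transition_probabilities(drinks) == (0.5, 0.3, 0.2)

    def test_degenerate_all_low(self):
        drinks = _classed_drinks({"low": 4})
        assert estimate_transition_probabilities(drinks) == (1.0, 0.0, 0.0)

    def test_sums_to_one_in_rational_arithmetic(self, rng):
        n = {c: int(rng.integers(1, 50)) for c in ("low", "medium", "high")}
        p = estimate_transition_probabilities(_classed_drinks(n))
        total = sum(n.values())
        assert sum(Fraction(v, total) for v in n.values()) == 1
        assert sum(p) == pytest.approx(1.0, abs=1e-12)

    def test_sampling_recovery_within_binomial_bound(self, rng):
        # 10,000 categorical draws at (0.6, 0.3, 0.1): 3 sigma ~ 0.015 < 0.02
        classes = rng.choice(
            np.array(["low", "medium", "high"]), size=10_000, p=np.array([0.6, 0.3, 0.1])
        )
        drinks = [
            Drink(400.0 * i, 400.0 * i + 10.0, 5.0, rate_class=c)
            for i, c in enumerate(classes)
        ]
        est = estimate_transition_probabilities(drinks)
        for got, want in zip(est, (0.6, 0.3, 0.1)):
            assert got == pytest.approx(want, abs=0.02)

    def test_empty_and_unclassed_rejected(self):
        with pytest.raises(ValueError):
            estimate_transition_probabilities([])
        with pytest.raises(ValueError, match="rate class"):
            estimate_transition_probabilities([Drink(0.0, 10.0, 5.0)])


class TestBoutProbability:
    def test_fraction_of_multidrink_bouts(self):
        bouts = [_bout_of(3, 10_000.0 * i) for i in range(3)] + [
            _bout_of(1, 10_000.0 * (3 + i)) for i in range(7)
        ]
        assert estimate_bout_probability(bouts) == pytest.approx(0.3)

    def test_all_single_drinks(self):
        bouts = [_bout_of(1, 10_000.0 * i) for i in range(5)]
        assert estimate_bout_probability(bouts) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_bout_probability([])


class TestFitWaitingTime:
    def test_weibull_mle_recovery(self, rng):
        x = 20.0 * rng.weibull(1.2, size=10_000)
        fit = fit_waiting_time(x, family_policy="weibull")
        assert fit.family == "weibull"
        assert fit.shape == pytest.approx(1.2, rel=0.05)
        assert fit.scale_s == pytest.approx(20.0, rel=0.05)

    def test_exponential_data_collapses_to_exponential(self, rng):
        x = rng.exponential(141.45, size=10_000)
        fit = fit_waiting_time(x, family_policy="auto")
        assert fit.family == "exponential" and fit.shape == 1.0
        assert fit.scale_s == pytest.approx(141.45, rel=0.05)

    def test_forced_exponential_scale_is_sample_mean(self, rng):
        x = rng.exponential(50.0, size=200)
        fit = fit_waiting_time(x, family_policy="exponential")
        assert fit.scale_s == float(np.mean(x))

    def test_clearly_non_exponential_shape_is_kept(self, rng):
        x = 20.0 * rng.weibull(2.5, size=5_000)
        fit = fit_waiting_time(x, family_policy="auto")
        assert fit.family == "weibull" and fit.shape > 2.0

    def test_rejections(self, rng):
        with pytest.raises(TooFewEventsError, match="too few events"):
            fit_waiting_time(rng.exponential(10.0, size=29))
        with pytest.raises(ValueError, match="positive"):
            fit_waiting_time(np.concatenate([rng.exponential(10.0, 40), [0.0]]))
        with pytest.raises(ValueError, match="degenerate"):
            fit_waiting_time(np.full(100, 7.0))

    def test_mle_matches_likelihood_grid_oracle(self, rng):
        """The fitted optimum sits within one cell of a brute grid search."""
        k_grid = np.linspace(0.5, 2.5, 20)
        for _ in range(100):
            k_true = float(rng.uniform(0.8, 1.6))
            scale_true = float(rng.uniform(5.0, 50.0))
            x = scale_true * rng.weibull(k_true, size=60)
            fit = fit_waiting_time(x, family_policy="weibull")
            s_grid = np.linspace(np.mean(x) / 3.0, 3.0 * np.mean(x), 20)
            ll = stats.weibull_min.logpdf(
                x[None, None, :], k_grid[:, None, None], scale=s_grid[None, :, None]
            ).sum(axis=2)
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            assert abs(fit.shape - k_grid[i]) <= np.diff(k_grid)[0] + 1e-12
            assert abs(fit.scale_s - s_grid[j]) <= np.diff(s_grid)[0] + 1e-12


class TestFitInterBout:
    def test_lapse_subtracted_before_fitting(self):
        fit = fit_inter_bout([400.0, 500.0, 700.0], min_n=1)
        assert fit.offset_s == 300.0
        assert fit.scale_s == pytest.approx(np.mean([100.0, 200.0, 400.0]))

    def test_sampling_contract_adds_the_lapse_back(self, rng):
        fit = fit_inter_bout([400.0, 500.0, 700.0], min_n=1)
        assert np.all(fit.sample(rng, size=100) > 300.0)

    def test_gap_at_or_below_lapse_rejected(self):
        with pytest.raises(ValueError, match="300"):
            fit_inter_bout([400.0, 300.0, 500.0], min_n=1)

    def test_degenerate_constant_gaps_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_inter_bout([350.0] * 40)

    def test_shifted_exponential_recovery(self, rng):
        gaps = 300.0 + rng.exponential(3_000.0, size=10_000)
        fit = fit_inter_bout(gaps)
        assert fit.scale_s == pytest.approx(3_000.0, rel=0.05)


def _oracle_intra_gap_mean(params, rng, min_gaps: int = 20_000) -> float:
    """Mean accepted intra-bout gap by an independent event-loop replay."""
    laws = {
        "low": params.drink_low,
        "medium": params.drink_medium,
        "high": params.drink_high,
    }
    probs = np.cumsum([params.p_low, params.p_medium])
    accepted: list[float] = []
    while len(accepted) < min_gaps:
        span = rng.exponential(params.bout_length.scale_s)
        cls = ("low", "medium", "high")[np.searchsorted(probs, rng.random(), "right")]
        t = float(laws[cls].sample(rng))
        while True:
            gap = rng.exponential(params.intra_bout_gap.scale_s)
            while gap >= 300.0:
                gap = rng.exponential(params.intra_bout_gap.scale_s)
            cls = ("low", "medium", "high")[
                np.searchsorted(probs, rng.random(), "right")
            ]
            dur = float(laws[cls].sample(rng))
            if t + gap + dur > span:
                break
            accepted.append(gap)
            t += gap + dur
    return float(np.mean(accepted))


class TestCalibrate:
    def test_roundtrip_recovery(self):
        """Simulate from a known vector and re-estimate it.

        Transition probabilities recover within sampling error; drink-length
        Weibulls within 10%; the shifted inter-bout exponential within 10%;
        the bout probability equals the realised fraction of multi-drink
        bouts (the estimator's own definition); and the intra-bout scale
        matches the closed-form mean of the generating exponential truncated
        at the 300 s lapse.
        """
        truth = sample_parameters(np.random.default_rng(42))
        series = simulate_at_least(truth, 5_000, seed=421)
        bouts = segment_bouts_by_day(series.drinks)
        est = calibrate(series.drinks, bouts, weight_kg=truth.weight_kg)

        for got, want in zip(est.state_probabilities, truth.state_probabilities):
            assert got == pytest.approx(want, abs=0.03)
        for attr in ("drink_low", "drink_medium", "drink_high"):
            t, e = getattr(truth, attr), getattr(est, attr)
            assert e.shape == pytest.approx(t.shape, rel=0.10)
            assert e.scale_s == pytest.approx(t.scale_s, rel=0.10)
        assert est.inter_bout_gap.scale_s == pytest.approx(
            truth.inter_bout_gap.scale_s, rel=0.10
        )
        realised_p = sum(b.n_drinks >= 2 for b in bouts) / len(bouts)
        assert est.p_bout == realised_p
        # observed intra-bout gaps are doubly selected: rejected at the
        # 300 s lapse and required to fit inside the remaining bout span, so
        # the right oracle is an independent replay of the emission rule
        oracle_mean = _oracle_intra_gap_mean(truth, np.random.default_rng(5150))
        assert est.intra_bout_gap.scale_s == pytest.approx(oracle_mean, rel=0.05)
        assert est.absent == ()

    def test_no_multidrink_bouts_marks_intra_gap_absent(self, mean_params):
        import dataclasses

        solo = dataclasses.replace(mean_params, p_bout=0.0)
        series = simulate_at_least(solo, 200, seed=7)
        bouts = segment_bouts_by_day(series.drinks)
        est = calibrate(series.drinks, bouts, weight_kg=solo.weight_kg)
        assert est.p_bout == 0.0
        assert "intra_bout_gap" in est.absent
        # the absent component falls back to the population mean
        assert est.intra_bout_gap == population_mean_parameters().intra_bout_gap

    def test_cohort_mean_streams_fit_inside_cohort_ranges(self, mean_params):
        series = simulate_at_least(mean_params, 5_000, seed=99)
        bouts = segment_bouts_by_day(series.drinks)
        est = calibrate(series.drinks, bouts, weight_kg=mean_params.weight_kg)
        for attr in ("drink_low", "drink_medium", "drink_high"):
            lo_k, hi_k = COHORT_RANGES[attr]["shape"]
            lo_s, hi_s = COHORT_RANGES[attr]["scale"]
            e = getattr(est, attr)
            assert lo_k - 0.05 <= e.shape <= hi_k + 0.05
            assert lo_s <= e.scale_s <= hi_s

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            calibrate([], [], weight_kg=8.5)
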