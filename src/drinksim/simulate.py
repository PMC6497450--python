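"""Forward simulation of drinking time series.

Each session day is an independent renewal loop on ``[0, session_length)``:
after an inter-bout delay (300 s lapse plus an exponential excess), the
next drinking event is a bout with probability ``p_bout``, otherwise a
single drink.  A bout draws its span from the bout-length law and emits
drinks — state, duration, rate — separated by intra-bout gaps until the
next drink would overrun the span (always at least one drink).

Rates are the per-bin medians; with noise on, a Gaussian perturbation with
sd equal to half the distance from the bin median to the bin edge is
resampled until the draw stays inside its bin, so the emitted rate class
is always consistent with the drawn state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .calibration import MonkeyParameters
from .segmentation import BOUT_LAPSE_S, Drink, RateBinning

__all__ = [
    "SimulationConfig",
    "SimulatedSeries",
    "draw_state",
    "draw_rate",
    "simulate_bout",
    "simulate_series",
]

#: Seconds in a 22-hour open-access session.
DEFAULT_SESSION_LENGTH_S = 79_200.0


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration for a simulated open-access period.

    Defaults mirror the experimental protocol: 180 simulated days of
    22 h/day access to 4% (w/v) ethanol, i.e. 0.04 g of ethanol per mL.
    """

    n_days: int = 180
    session_length_s: float = DEFAULT_SESSION_LENGTH_S
    seed: int = 0
    ethanol_concentration_g_per_ml: float = 0.04
    noise: bool = True

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        if not 0 < self.session_length_s <= 86_400:
            raise ValueError(
                f"session length must lie in (0, 86400] s, got {self.session_length_s}"
            )
        if not self.ethanol_concentration_g_per_ml > 0:
            raise ValueError("ethanol concentration must be positive")


@dataclass(frozen=True)
class SimulatedSeries:
    """A simulated drink record with its generating parameters and config.

    ``event_sizes`` records, per day, how many drinks each emitted event
    (single drink or bout) contributed after session-end truncation; these
    are the simulator's own bout boundaries, which re-segmentation at the
    300 s lapse must reproduce exactly.
    """

    drinks: tuple[Drink, ...]
    parameters: MonkeyParameters
    config: SimulationConfig
    event_sizes: tuple[tuple[int, ...], ...] = ()

    def day(self, day: int) -> tuple[Drink, ...]:
        return tuple(d for d in self.drinks if d.session_day == day)


def draw_state(params: MonkeyParameters, rng: np.random.Generator) -> str:
    """Draw the rate state of the next drink.

    The chain always returns to the non-drinking state after a drink, so
    successive states are independent categorical draws with probabilities
    (p_low, p_medium, p_high).
    """
    u = rng.random()
    if u < params.p_low:
        return "low"
    if u < params.p_low + params.p_medium:
        return "medium"
    return "high"


def draw_rate(
    state: str,
    bins: RateBinning,
    noise_on: bool,
    rng: np.random.Generator,
    high_clip_factor: float = 3.0,
) -> float:
    """Draw a consumption rate (mL/s) for a drink in ``state``.

    Noise off returns the bin median exactly.  Noise on draws
    Normal(median, sd) with sd = half the distance from the median to the
    bin edge (for the unbounded high bin, the lower edge by symmetry),
    resampled until the draw lies strictly inside the bin — above the upper
    cut and below ``high_clip_factor`` x median for the high bin — so the
    rate class of the emitted drink always matches the drawn state.
    """
    median = bins.median(state)
    if not noise_on:
        return median
    if state == "low":
        sd = (bins.cut_low_med - bins.median_low) / 2.0
        lo, hi = 0.0, bins.cut_low_med
    elif state == "medium":
        sd = (bins.cut_med_high - bins.median_medium) / 2.0
        lo, hi = bins.cut_low_med, bins.cut_med_high
    else:
        sd = (bins.median_high - bins.cut_med_high) / 2.0
        lo, hi = bins.cut_med_high, high_clip_factor * bins.median_high
    while True:
        r = rng.normal(median, sd)
        if state == "medium":
            # medium is a closed bin; accept the edges
            if lo <= r <= hi:
                return r
        elif lo < r < hi:
            return r


def _draw_drink(
    params: MonkeyParameters, rng: np.random.Generator, noise_on: bool
) -> tuple[str, float, float]:
    """(state, duration s, rate mL/s) of one drink."""
    state = draw_state(params, rng)
    duration = float(params.drink_duration(state).sample(rng))
    rate = draw_rate(state, params.bins, noise_on, rng)
    return state, duration, rate


def _draw_intra_gap(params: MonkeyParameters, rng: np.random.Generator) -> float:
    """Intra-bout gap, rejection-sampled below the 300 s lapse."""
    while True:
        g = float(params.intra_bout_gap.sample(rng))
        if g < BOUT_LAPSE_S:
            return g


def simulate_bout(
    params: MonkeyParameters,
    rng: np.random.Generator,
    noise_on: bool = True,
) -> list[Drink]:
    """Simulate one bout; drink times are relative to the bout start.

    The bout's span L is drawn from the bout-length law; drinks are then
    emitted until gap + duration of the next one would push the elapsed
    time past L.  The first drink is always emitted, even if longer than L,
    so a short draw yields a single-drink bout.
    """
    span = float(params.bout_length.sample(rng))
    drinks: list[Drink] = []
    t = 0.0
    while True:
        if not drinks:
            state, duration, rate = _draw_drink(params, rng, noise_on)
            drinks.append(
                Drink(t, t + duration, rate * duration, rate_class=state)
            )
            t += duration
        else:
            gap = _draw_intra_gap(params, rng)
            state, duration, rate = _draw_drink(params, rng, noise_on)
            if t + gap + duration > span:
                break
            drinks.append(
                Drink(t + gap, t + gap + duration, rate * duration, rate_class=state)
            )
            t += gap + duration
    return drinks


def simulate_series(
    params: MonkeyParameters,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedSeries:
    """Simulate a full open-access period.

    Each day runs independently: starting from an initial inter-bout delay
    (renewal convention — the day does not begin mid-drink), events
    alternate with inter-bout gaps of 300 s plus an exponential excess.
    With probability ``p_bout`` an event is a bout, otherwise a single
    drink.  Drinks crossing the session end are truncated there, keeping
    their rate (volume shrinks with the lost duration).

    Identical (params, config) always reproduce the same series; pass an
    explicit ``rng`` to draw from a shared stream instead of
    ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    session = config.session_length_s
    out: list[Drink] = []
    all_sizes: list[tuple[int, ...]] = []
    for day in range(config.n_days):
        sizes: list[int] = []
        t = float(params.inter_bout_gap.sample(rng))
        while t < session:
            if rng.random() < params.p_bout:
                event = simulate_bout(params, rng, config.noise)
            else:
                state, duration, rate = _draw_drink(params, rng, config.noise)
                event = [Drink(0.0, duration, rate * duration, rate_class=state)]
            event_end = t + event[-1].end
            emitted = 0
            for d in event:
                start = t + d.start
                if start >= session:
                    break
                end = min(t + d.end, session)
                out.append(
                    Drink(
                        start,
                        end,
                        d.rate * (end - start),
                        rate_class=d.rate_class,
                        session_day=day,
                    )
                )
                emitted += 1
            if emitted:
                sizes.append(emitted)
            t = event_end + float(params.inter_bout_gap.sample(rng))
        all_sizes.append(tuple(sizes))
    return SimulatedSeries(tuple(out), params, config, tuple(all_sizes))
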