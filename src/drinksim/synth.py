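"""Synthetic raw intake streams with known ground truth.

The real acquisition system samples a drinking-panel scale at 0.1 s
resolution with 0.1 mL (= 0.1 g) granularity.  :func:`emit_raw_stream`
emulates it: a drinking series is simulated, snapped to the tick grid, and
each drink is spread over its ticks as 0.1 mL increments by
largest-remainder rounding.  The returned :class:`GroundTruth` records the
*observable* drinks — the intervals and volumes a perfect segmenter would
read back from the emitted ticks, computed by direct interval arithmetic,
independent of the segmentation module's record-walking code path — so the
stream → segmentation round trip can be checked exactly.

Optional distractors: balance artifacts (1 s, 0.2 mL events) and a water
channel generated from an independent parameter vector.

:func:`sample_parameters` draws parameter vectors uniformly inside the
published cohort ranges (23 male rhesus macaques), giving a plausibility
prior for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calibration import MonkeyParameters, WaitingTime
from .segmentation import (
    BOUT_LAPSE_S,
    DEFAULT_BINS,
    DRINK_MERGE_GAP_S,
    Bout,
    Drink,
    IntakeRecord,
    RateBinning,
    segment_bouts,
)
from .simulate import SimulatedSeries, SimulationConfig, simulate_series

__all__ = [
    "GroundTruth",
    "COHORT_RANGES",
    "emit_raw_stream",
    "sample_parameters",
]

#: Instrument granularity: one scale count is 0.1 g = 0.1 mL.
VOLUME_QUANTUM_ML = 0.1

#: Seconds per calendar day, used to place consecutive session days on one
#: absolute time axis.
SECONDS_PER_DAY = 86_400.0

#: Published cohort min-max ranges for the waiting-time parameters
#: (shape, scale in seconds).  The intra-bout gap is printed as a rate
#: (0.01-0.03 per s) and converted to scale; the inter-bout rate is printed
#: as 0.00 per s, which only bounds the scale below (>= ~200 s) - the range
#: here spans sparse night-time gaps seen in light drinkers.
COHORT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "drink_low": {"shape": (1.00, 1.35), "scale": (1.97, 40.80)},
    "drink_medium": {"shape": (1.00, 1.49), "scale": (3.42, 49.83)},
    "drink_high": {"shape": (1.00, 1.73), "scale": (1.28, 40.94)},
    "bout_length": {"shape": (1.00, 1.00), "scale": (47.59, 341.84)},
    "intra_bout_gap": {"shape": (1.00, 1.00), "scale": (1.0 / 0.03, 1.0 / 0.01)},
    "inter_bout_gap": {"shape": (1.00, 1.00), "scale": (500.0, 8000.0)},
}


@dataclass(frozen=True)
class GroundTruth:
    """Everything known about a synthetic stream.

    ``true_drinks``/``true_bouts`` are the observable segmentation of the
    emitted records (ethanol channel, artifacts excluded); ``series`` keeps
    the continuous simulated drinks for conservation checks.
    """

    params: MonkeyParameters
    true_drinks: tuple[Drink, ...]
    true_bouts: tuple[Bout, ...]
    seed: int
    n_artifacts: int
    series: SimulatedSeries


def _spread_units(n_units: int, n_ticks: int) -> np.ndarray:
    """Distribute ``n_units`` quanta over ``n_ticks`` ticks, evenly.

    Largest-remainder style: every tick gets the base share and the
    remainder goes to evenly spaced ticks including the first and last, so
    the emitted support spans the whole drink and internal quiet gaps are
    as short as possible.
    """
    counts = np.full(n_ticks, n_units // n_ticks, dtype=int)
    rem = n_units % n_ticks
    if rem:
        idx = np.round(np.linspace(0, n_ticks - 1, rem)).astype(int)
        np.add.at(counts, idx, 1)
    if counts[0] == 0 or counts[-1] == 0:
        # pin the endpoints so the observable interval matches the drink
        inner = np.argmax(counts)
        for edge in (0, n_ticks - 1):
            if counts[edge] == 0 and counts[inner] > 1:
                counts[inner] -= 1
                counts[edge] += 1
                inner = np.argmax(counts)
    return counts


def _drink_records(
    drink: Drink, day_offset: float, resolution_s: float, fluid: str
) -> tuple[list[IntakeRecord], tuple[float, float, float] | None]:
    """Records for one drink; returns (records, observable interval+volume)."""
    n_ticks = max(1, int(round(drink.duration / resolution_s)))
    n_units = int(round(drink.volume / VOLUME_QUANTUM_ML))
    if n_units == 0:
        n_units = 1  # a drink below half a quantum still trips the scale once
    start = round((day_offset + drink.start) / resolution_s) * resolution_s
    counts = _spread_units(n_units, n_ticks)
    recs = [
        IntakeRecord(start + i * resolution_s, c * VOLUME_QUANTUM_ML, fluid)
        for i, c in enumerate(counts)
        if c > 0
    ]
    first, last = recs[0].time, recs[-1].time
    return recs, (first, last + resolution_s, n_units * VOLUME_QUANTUM_ML)


def _merge_observables(
    intervals: list[tuple[float, float, float]],
    days: list[int],
    gap_threshold: float,
) -> list[Drink]:
    """Interval-level 5 s merge of observable drink supports (truth oracle)."""
    merged: list[Drink] = []
    for (s, e, v), day in zip(intervals, days):
        if merged and s - merged[-1].end < gap_threshold:
            prev = merged[-1]
            merged[-1] = Drink(
                prev.start, e, prev.volume + v, session_day=prev.session_day
            )
        else:
            merged.append(Drink(s, e, v, session_day=day))
    return merged


def emit_raw_stream(
    params: MonkeyParameters,
    config: SimulationConfig,
    resolution_s: float = 0.1,
    n_artifacts: int = 0,
    water_params: MonkeyParameters | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[IntakeRecord], GroundTruth]:
    """Simulate a series and emit it as tick-level scale records.

    Times are absolute seconds, day ``d`` occupying
    ``[d * 86400, d * 86400 + session_length)``.  Volumes are conserved to
    the 0.1 mL instrument quantum per drink (half a quantum of rounding,
    except for rare sub-0.05 mL drinks which still emit one count).

    Parameters
    ----------
    n_artifacts : int
        Number of 1 s / 0.2 mL balance-artifact events to inject into quiet
        gaps (≥ 5 s clearance from real drinks, so they survive merging as
        distinct drinks and are exactly what the artifact filter removes).
    water_params : MonkeyParameters, optional
        When given, a water channel is simulated independently and its
        records interleaved as distractors.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    series = simulate_series(params, config, rng=rng)

    records: list[IntakeRecord] = []
    observables: list[tuple[float, float, float]] = []
    days: list[int] = []
    for d in series.drinks:
        recs, obs = _drink_records(
            d, d.session_day * SECONDS_PER_DAY, resolution_s, "ethanol"
        )
        records.extend(recs)
        observables.append(obs)
        days.append(d.session_day)

    true_drinks = _merge_observables(observables, days, DRINK_MERGE_GAP_S)
    true_bouts = segment_bouts(true_drinks)

    injected = 0
    if n_artifacts > 0:
        art_records, injected = _inject_artifacts(
            true_drinks, n_artifacts, resolution_s, rng
        )
        records.extend(art_records)

    if water_params is not None:
        water_series = simulate_series(water_params, config, rng=rng)
        for d in water_series.drinks:
            recs, _ = _drink_records(
                d, d.session_day * SECONDS_PER_DAY, resolution_s, "water"
            )
            records.extend(recs)

    records.sort(key=lambda r: (r.time, r.fluid))
    records = _coalesce_ticks(records)
    truth = GroundTruth(
        params=params,
        true_drinks=tuple(true_drinks),
        true_bouts=tuple(true_bouts),
        seed=config.seed,
        n_artifacts=injected,
        series=series,
    )
    return records, truth


def _coalesce_ticks(records: list[IntakeRecord]) -> list[IntakeRecord]:
    """Sum increments landing on the same (time, fluid) tick.

    Snapping two abutting drinks to the grid can collide on a tick; the
    physical scale would report one combined increment, and downstream
    readers require strictly increasing times per fluid.
    """
    out: list[IntakeRecord] = []
    for r in records:
        if out and out[-1].time == r.time and out[-1].fluid == r.fluid:
            out[-1] = IntakeRecord(r.time, out[-1].volume + r.volume, r.fluid)
        else:
            out.append(r)
    return out


def _inject_artifacts(
    true_drinks: Sequence[Drink],
    n_artifacts: int,
    resolution_s: float,
    rng: np.random.Generator,
) -> tuple[list[IntakeRecord], int]:
    """Place 1 s / 0.2 mL artifact events into gaps between real drinks.

    Each artifact sits at least one merge gap (5 s) away from both
    neighbours, so merging reconstructs it as its own drink of exactly
    1.0 s and 0.2 mL.  Returns the records and the number actually placed
    (limited by the available gaps).
    """
    clearance = DRINK_MERGE_GAP_S + resolution_s
    slots: list[float] = []
    for prev, nxt in zip(true_drinks, true_drinks[1:]):
        lo = prev.end + clearance
        hi = nxt.start - clearance - 1.0
        if hi > lo:
            slots.append(lo + rng.random() * (hi - lo))
        if len(slots) == n_artifacts:
            break
    records: list[IntakeRecord] = []
    n_ticks = int(round(1.0 / resolution_s))
    for t0 in slots:
        start = round(t0 / resolution_s) * resolution_s
        # one 0.1 mL count at each end: duration 1.0 s, volume 0.2 mL
        records.append(IntakeRecord(start, VOLUME_QUANTUM_ML, "ethanol"))
        records.append(
            IntakeRecord(start + (n_ticks - 1) * resolution_s, VOLUME_QUANTUM_ML, "ethanol")
        )
    return records, len(slots)


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    return float(lo + (hi - lo) * rng.random())


def sample_parameters(
    rng: np.random.Generator,
    bins: RateBinning = DEFAULT_BINS,
    weight_range_kg: tuple[float, float] = (7.5, 10.5),
) -> MonkeyParameters:
    """Draw a plausible parameter vector from the cohort ranges.

    Shapes and scales are uniform inside :data:`COHORT_RANGES`; the state
    probabilities come from a flat simplex (Dirichlet(1,1,1)) and the bout
    probability from U(0, 1).  Body weight is uniform over a range
    bracketing the cohort means (8.0-9.4 kg).
    """
    def law(name: str, offset: float = 0.0) -> WaitingTime:
        shape = _uniform(rng, COHORT_RANGES[name]["shape"])
        scale = _uniform(rng, COHORT_RANGES[name]["scale"])
        family = "exponential" if shape == 1.0 else "weibull"
        return WaitingTime(family, shape, scale, offset_s=offset)

    simplex = rng.dirichlet((1.0, 1.0, 1.0))
    p_low, p_medium = float(simplex[0]), float(simplex[1])
    # pin the sum to 1 exactly despite float round-off
    p_high = max(0.0, 1.0 - p_low - p_medium)
    return MonkeyParameters(
        p_low=p_low,
        p_medium=p_medium,
        p_high=p_high,
        p_bout=float(rng.random()),
        drink_low=law("drink_low"),
        drink_medium=law("drink_medium"),
        drink_high=law("drink_high"),
        bout_length=law("bout_length"),
        intra_bout_gap=law("intra_bout_gap"),
        inter_bout_gap=law("inter_bout_gap", offset=BOUT_LAPSE_S),
        bins=bins,
        weight_kg=_uniform(rng, weight_range_kg),
    )
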