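"""Shared test utilities: fixture builders and independent oracles.

The oracles here are deliberately naive re-derivations (brute-force gap
scans, literal rule evaluators, step-by-step event loops) kept independent
of the library code paths they check.
"""

from __future__ import annotations

import numpy as np

from drinksim import Drink, IntakeRecord


def episode_records(
    episodes: list[tuple[float, float, float]],
    resolution: float = 0.1,
    fluid: str = "ethanol",
) -> list[IntakeRecord]:
    """Tick-level records for continuous intake episodes (start, end, volume)."""
    records: list[IntakeRecord] = []
    for start, end, volume in episodes:
        n = max(1, int(round((end - start) / resolution)))
        for i in range(n):
            records.append(IntakeRecord(start + i * resolution, volume / n, fluid))
    return records


def drinks_from_gaps(
    durations: list[float], gaps: list[float], volume_per_s: float = 0.5
) -> list[Drink]:
    """Build a time-ordered drink list from durations and the gaps between them."""
    assert len(gaps) == len(durations) - 1
    drinks = []
    t = 0.0
    for i, dur in enumerate(durations):
        drinks.append(Drink(t, t + dur, volume_per_s * dur))
        if i < len(gaps):
            t += dur + gaps[i]
    return drinks


def brute_force_bout_sizes(drinks: list[Drink], lapse: float = 300.0) -> list[int]:
    """Oracle: bout sizes by a pairwise gap scan marking boundaries at >= lapse."""
    if not drinks:
        return []
    sizes = [1]
    for prev, nxt in zip(drinks, drinks[1:]):
        if nxt.start - prev.end >= lapse:
            sizes.append(1)
        else:
            sizes[-1] += 1
    return sizes


def brute_force_category(doses: list[float]) -> str:
    """Oracle: literal re-statement of the drinking-category rules.

    Evaluates each rule clause independently on the daily g/kg doses and
    applies the VHD > HD > BD > LD precedence.
    """
    n = len(doses)
    adei = sum(doses) / n
    days_over = lambda thr: sum(1 for d in doses if d > thr)
    is_vhd = adei > 3.0 and days_over(4.0) / n > 0.10
    is_hd = days_over(3.0) / n > 0.20
    is_bd = days_over(2.0) / n > 0.55
    if is_vhd:
        return "VHD"
    if is_hd:
        return "HD"
    if is_bd:
        return "BD"
    return "LD"


def random_drink_instance(
    rng: np.random.Generator, max_drinks: int = 50
) -> list[Drink]:
    """A random non-overlapping drink sequence with gaps straddling 300 s."""
    n = int(rng.integers(1, max_drinks + 1))
    drinks = []
    t = float(rng.uniform(0, 60))
    for _ in range(n):
        dur = float(rng.uniform(0.5, 120))
        drinks.append(Drink(t, t + dur, float(rng.uniform(0.1, 50))))
        # gaps concentrated around the 300 s lapse to stress the boundary
        gap = float(rng.choice([rng.uniform(0.1, 299.9), 300.0, rng.uniform(300.1, 2000)]))
        t += dur + gap
    return drinks


def simulate_at_least(params, n_drinks: int, seed: int, noise: bool = True):
    """Simulate whole days until the series holds at least ``n_drinks`` drinks."""
    from drinksim import SimulationConfig, simulate_series

    per_day = max(1.0, 79_200.0 / (params.inter_bout_gap.mean + 120.0))
    n_days = int(np.ceil(n_drinks / per_day))
    for _ in range(20):
        cfg = SimulationConfig(n_days=n_days, seed=seed, noise=noise)
        series = simulate_series(params, cfg)
        if len(series.drinks) >= n_drinks:
            return series
        n_days = int(np.ceil(n_days * 1.6)) + 1
    raise AssertionError("could not reach the requested drink count")
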