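"""Daily intake aggregation and drinking-category assignment.

Categories follow the open-access self-administration literature, using
average daily ethanol intake (ADEI, g of ethanol per kg body weight per
day) and day-fraction threshold rules:

* **VHD** (very heavy): ADEI > 3 g/kg and more than 10% of days over
  4 g/kg;
* **HD** (heavy): more than 20% of days over 3 g/kg;
* **BD** (binge): not HD/VHD, and more than 2 g/kg on more than 55% of
  days (the blood-ethanol clause of the laboratory definition is dropped —
  the model does not predict BEC, so the intake-only surrogate is used);
* **LD** (light): everything else.

Precedence is VHD, HD, BD, LD; all inequalities are strict.  HD and VHD
collapse to *heavy*, LD and BD to *non-heavy*.  Days with zero intake
count in every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calibration import MonkeyParameters
from .segmentation import Drink
from .simulate import SimulatedSeries, SimulationConfig, simulate_series

__all__ = [
    "DailyIntake",
    "CategoryLabel",
    "ReplicateResult",
    "CATEGORIES",
    "daily_intake",
    "classify",
    "classify_series",
    "replicate_classification",
]

CATEGORIES = ("LD", "BD", "HD", "VHD")
HEAVY = frozenset({"HD", "VHD"})

#: g/kg thresholds of the category rules.
VHD_ADEI_THRESHOLD = 3.0
VHD_DAY_THRESHOLD = 4.0
VHD_DAY_FRACTION = 0.10
HD_DAY_THRESHOLD = 3.0
HD_DAY_FRACTION = 0.20
BD_DAY_THRESHOLD = 2.0
BD_DAY_FRACTION = 0.55


@dataclass(frozen=True)
class DailyIntake:
    """One day's ethanol intake: volume, grams, and weight-normalised dose."""

    day: int
    volume_ml: float
    grams: float
    g_per_kg: float


@dataclass(frozen=True)
class CategoryLabel:
    """A drinking-category assignment with its supporting evidence.

    ``evidence`` holds the ADEI and the day fractions over the 2/3/4 g/kg
    thresholds that the rules quantify over.
    """

    category: str
    collapsed: str
    evidence: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        expected = "heavy" if self.category in HEAVY else "non_heavy"
        if self.collapsed != expected:
            raise ValueError(
                f"collapsed label {self.collapsed!r} inconsistent with {self.category}"
            )


def daily_intake(
    drinks: Sequence[Drink],
    weight_kg: float,
    concentration_g_per_ml: float = 0.04,
    n_days: int | None = None,
) -> list[DailyIntake]:
    """Aggregate drinks into per-day ethanol intake.

    Parameters
    ----------
    drinks : sequence of Drink
        Each drink carries its ``session_day``.
    weight_kg : float
        Body weight; doses are reported in g/kg.
    concentration_g_per_ml : float
        Grams of ethanol per mL of solution (0.04 for 4% w/v).
    n_days : int, optional
        Number of session days; defaults to the largest day index + 1.
        Days without drinks appear with zeros.
    """
    if not weight_kg > 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if n_days is None:
        n_days = max((d.session_day for d in drinks), default=-1) + 1
    volumes = np.zeros(max(n_days, 0))
    for d in drinks:
        if not 0 <= d.session_day < n_days:
            raise ValueError(
                f"drink on day {d.session_day} outside 0..{n_days - 1}"
            )
        volumes[d.session_day] += d.volume
    return [
        DailyIntake(
            day=i,
            volume_ml=float(v),
            grams=float(v) * concentration_g_per_ml,
            g_per_kg=float(v) * concentration_g_per_ml / weight_kg,
        )
        for i, v in enumerate(volumes)
    ]


def classify(daily: Sequence[DailyIntake]) -> CategoryLabel:
    """Assign the drinking category of a daily-intake series.

    Applies the VHD → HD → BD → LD precedence with strict inequalities.
    """
    if len(daily) == 0:
        raise ValueError("cannot classify an empty daily series")
    doses = np.array([d.g_per_kg for d in daily])
    n = doses.size
    adei = float(doses.mean())
    frac_over_2 = float(np.count_nonzero(doses > BD_DAY_THRESHOLD)) / n
    frac_over_3 = float(np.count_nonzero(doses > HD_DAY_THRESHOLD)) / n
    frac_over_4 = float(np.count_nonzero(doses > VHD_DAY_THRESHOLD)) / n

    if adei > VHD_ADEI_THRESHOLD and frac_over_4 > VHD_DAY_FRACTION:
        category = "VHD"
    elif frac_over_3 > HD_DAY_FRACTION:
        category = "HD"
    elif frac_over_2 > BD_DAY_FRACTION:
        category = "BD"
    else:
        category = "LD"

    return CategoryLabel(
        category=category,
        collapsed="heavy" if category in HEAVY else "non_heavy",
        evidence={
            "adei_g_per_kg": adei,
            "frac_days_over_2": frac_over_2,
            "frac_days_over_3": frac_over_3,
            "frac_days_over_4": frac_over_4,
            "n_days": float(n),
        },
    )


def classify_series(series: SimulatedSeries) -> CategoryLabel:
    """Convenience: aggregate and classify a simulated series."""
    daily = daily_intake(
        series.drinks,
        series.parameters.weight_kg,
        series.config.ethanol_concentration_g_per_ml,
        n_days=series.config.n_days,
    )
    return classify(daily)


@dataclass(frozen=True)
class ReplicateResult:
    """Category counts over repeated simulations of one parameter vector.

    ``accuracy4`` is the fraction of replicates matching the reference
    label across all four categories; ``accuracy2`` the fraction matching
    after the heavy/non-heavy collapse.  Both are ``None`` without a
    reference.
    """

    counts: Mapping[str, int]
    n_replicates: int
    reference: str | None = None
    accuracy4: float | None = None
    accuracy2: float | None = None


def replicate_classification(
    params: MonkeyParameters,
    config: SimulationConfig,
    n_replicates: int = 100,
    reference: str | None = None,
) -> ReplicateResult:
    """Simulate and classify ``n_replicates`` independent series.

    Replicate seeds are derived from ``config.seed`` via
    ``numpy.random.SeedSequence.spawn``, so the whole experiment is
    reproducible from one integer.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    if reference is not None and reference not in CATEGORIES:
        raise ValueError(f"unknown reference category {reference!r}")
    counts = {c: 0 for c in CATEGORIES}
    children = np.random.SeedSequence(config.seed).spawn(n_replicates)
    for child in children:
        series = simulate_series(params, config, rng=np.random.default_rng(child))
        counts[classify_series(series).category] += 1

    acc4 = acc2 = None
    if reference is not None:
        acc4 = counts[reference] / n_replicates
        heavy_ref = reference in HEAVY
        acc2 = (
            sum(v for c, v in counts.items() if (c in HEAVY) == heavy_ref)
            / n_replicates
        )
    return ReplicateResult(
        counts=counts,
        n_replicates=n_replicates,
        reference=reference,
        accuracy4=acc4,
        accuracy2=acc2,
    )
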