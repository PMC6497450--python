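"""File interchange: intake CSV/TSV streams, drink tables, parameter JSON.

Intake streams are flat tables with columns ``time_s, volume_ml, fluid``;
``#`` lines are comments.  Drink tables carry the segmented record
(``session_day, start_s, end_s, duration_s, volume_ml, rate_ml_s,
rate_class, bout_id``).  Parameter files are schema-versioned JSON whose
distribution entries are ``{"family", "shape", "scale_s"}``; scales may be
declared as rates (per second) via ``lambda_convention`` and are converted
to seconds on read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calibration import MonkeyParameters, WaitingTime
from .segmentation import (
    BOUT_LAPSE_S,
    Bout,
    Drink,
    IntakeRecord,
    RateBinning,
    segment_bouts,
)

__all__ = [
    "read_intake_csv",
    "write_intake_csv",
    "read_drinks_csv",
    "write_drinks_csv",
    "read_params_json",
    "write_params_json",
    "PARAMS_SCHEMA_VERSION",
]

PARAMS_SCHEMA_VERSION = 1

_INTAKE_COLUMNS = ("time_s", "volume_ml", "fluid")
_DRINK_COLUMNS = (
    "session_day",
    "start_s",
    "end_s",
    "duration_s",
    "volume_ml",
    "rate_ml_s",
    "rate_class",
    "bout_id",
)
_FLUIDS = {"ethanol", "water"}

#: JSON keys of the distribution components, mapped to the parameter
#: attributes they serialise.
_DIST_KEYS = {
    "Q1": "drink_low",
    "Q2": "drink_medium",
    "Q3": "drink_high",
    "Qb": "bout_length",
    "Td": "intra_bout_gap",
    "Tb": "inter_bout_gap",
}


def _sep(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_intake_csv(path, delimiter: str | None = None) -> list[IntakeRecord]:
    """Read an intake stream (``time_s, volume_ml, fluid``).

    The delimiter follows the file extension (``.tsv`` → tab) unless given
    explicitly.  Comment lines starting with ``#`` are skipped.  Times must
    be strictly increasing within each fluid and volumes non-negative;
    violations raise with the offending column or row index named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path, delimiter), comment="#")
    missing = [c for c in _INTAKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intake file {path} is missing column(s): {missing}")
    fluids = df["fluid"].astype(str).str.strip().str.lower()
    unknown = sorted(set(fluids) - _FLUIDS)
    if unknown:
        raise ValueError(f"unknown fluid label(s) in {path}: {unknown}")
    if (df["volume_ml"] < 0).any():
        idx = int(df.index[df["volume_ml"] < 0][0])
        raise ValueError(f"negative volume at row index {idx}")
    for fluid in sorted(set(fluids)):
        t = df.loc[fluids == fluid, "time_s"]
        bad = t.diff() <= 0
        if bad.any():
            idx = int(t.index[bad][0])
            raise ValueError(
                f"times not strictly increasing for {fluid} at row index {idx}"
            )
    return [
        IntakeRecord(float(t), float(v), f)
        for t, v, f in zip(df["time_s"], df["volume_ml"], fluids)
    ]


def write_intake_csv(records: Sequence[IntakeRecord], path, delimiter: str | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": [r.time for r in records],
            "volume_ml": [r.volume for r in records],
            "fluid": [r.fluid for r in records],
        }
    )
    df.to_csv(path, sep=_sep(path, delimiter), index=False, lineterminator="\r\n")


def write_drinks_csv(
    drinks: Sequence[Drink],
    path,
    bouts: Sequence[Bout] | None = None,
    delimiter: str | None = None,
) -> None:
    """Write a segmented drink table; bout ids are per-session-day indices.

    ``bouts`` defaults to re-segmenting ``drinks`` with the 300 s lapse.
    """
    path = Path(path)
    if bouts is None:
        bouts = segment_bouts(drinks)
    bout_of = {id(d): i for i, b in enumerate(bouts) for d in b.drinks}
    df = pd.DataFrame(
        {
            "session_day": [d.session_day for d in drinks],
            "start_s": [d.start for d in drinks],
            "end_s": [d.end for d in drinks],
            "duration_s": [d.duration for d in drinks],
            "volume_ml": [d.volume for d in drinks],
            "rate_ml_s": [d.rate for d in drinks],
            "rate_class": [d.rate_class or "" for d in drinks],
            "bout_id": [bout_of.get(id(d), -1) for d in drinks],
        }
    )
    df.to_csv(path, sep=_sep(path, delimiter), index=False, lineterminator="\r\n")


def read_drinks_csv(path, delimiter: str | None = None) -> list[Drink]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path, delimiter), comment="#")
    missing = [c for c in _DRINK_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"drink table {path} is missing column(s): {missing}")
    out = []
    for row in df.itertuples(index=False):
        cls = getattr(row, "rate_class", "") or None
        if isinstance(cls, float):  # NaN from an empty cell
            cls = None
        out.append(
            Drink(
                start=float(row.start_s),
                end=float(row.end_s),
                volume=float(row.volume_ml),
                rate_class=cls,
                session_day=int(row.session_day),
            )
        )
    return out


def _dist_to_json(w: WaitingTime) -> dict:
    return {"family": w.family, "shape": w.shape, "scale_s": w.scale_s}


def _dist_from_json(obj: dict, convention: str, offset_s: float = 0.0) -> WaitingTime:
    scale = float(obj["scale_s"])
    if convention == "rate":
        if scale <= 0:
            raise ValueError("rate-convention scale must be a positive rate")
        scale = 1.0 / scale
    return WaitingTime(
        family=obj["family"], shape=float(obj["shape"]), scale_s=scale, offset_s=offset_s
    )


def write_params_json(params: MonkeyParameters, path) -> None:
    """Serialise a parameter vector (schema v1, scales in seconds)."""
    obj = {
        "schema_version": PARAMS_SCHEMA_VERSION,
        "lambda_convention": "scale",
        "P_nl": params.p_low,
        "P_nm": params.p_medium,
        "P_nh": params.p_high,
        "p": params.p_bout,
        **{key: _dist_to_json(getattr(params, attr)) for key, attr in _DIST_KEYS.items()},
        "bins": {
            "cut_low_med": params.bins.cut_low_med,
            "cut_med_high": params.bins.cut_med_high,
            "median_low": params.bins.median_low,
            "median_medium": params.bins.median_medium,
            "median_high": params.bins.median_high,
        },
        "weight_kg": params.weight_kg,
        "absent": list(params.absent),
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_params_json(path) -> MonkeyParameters:
    """Read a parameter vector; round-trips :func:`write_params_json` losslessly.

    ``lambda_convention: "rate"`` declares the distribution scales as rates
    per second; they are inverted to seconds on read.  Unknown schema
    versions are rejected.
    """
    obj = json.loads(Path(path).read_text())
    version = obj.get("schema_version")
    if version != PARAMS_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported parameter schema version {version!r} "
            f"(expected {PARAMS_SCHEMA_VERSION})"
        )
    convention = obj.get("lambda_convention", "scale")
    if convention not in ("scale", "rate"):
        raise ValueError(f"unknown lambda_convention {convention!r}")
    dists = {
        attr: _dist_from_json(
            obj[key], convention,
            offset_s=BOUT_LAPSE_S if key == "Tb" else 0.0,
        )
        for key, attr in _DIST_KEYS.items()
    }
    return MonkeyParameters(
        p_low=float(obj["P_nl"]),
        p_medium=float(obj["P_nm"]),
        p_high=float(obj["P_nh"]),
        p_bout=float(obj["p"]),
        bins=RateBinning(**obj["bins"]),
        weight_kg=float(obj["weight_kg"]),
        absent=tuple(obj.get("absent", ())),
        **dists,
    )
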