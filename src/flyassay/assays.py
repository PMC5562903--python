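"""Scalar assay computations.

Climbing index (negative geotaxis), evaporation-corrected capillary-feeding
(CAFE) intake, respirometry rate, and body composition from wet/dry/lean-dry
masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    InsufficientDataError,
    InvalidMeasurementError,
    MalformedReadingError,
    OrderingError,
)

__all__ = [
    "climbing_index",
    "cafe_intake",
    "IntakeResult",
    "vco2_rate",
    "body_composition",
    "extract_metrics",
    "CLIMB_FAIL",
]

#: In-memory sentinel for a fly that never reached the top mark; serialised as
#: an empty CSV field.
CLIMB_FAIL = np.inf


def climbing_index(times_s: Sequence[float], cutoff_s: float = 60.0) -> float:
    """Fraction of flies reaching the top mark within the cutoff.

    Each fly scores 1 if its climb time is <= cutoff (60 s by default) and 0
    otherwise; failures may be encoded as +inf or NaN (empty CSV field).
    Trial-level indices are averaged across trials by the caller.
    """
    times = np.asarray(times_s, dtype=float)
    if times.size < 1:
        raise InsufficientDataError("climbing index requires at least one fly")
    finite = times[np.isfinite(times)]
    if np.any(finite < 0):
        raise InvalidMeasurementError("negative climb time")
    scores = np.where(np.isnan(times), 0.0, (times <= cutoff_s).astype(float))
    return float(scores.mean())


@dataclass(frozen=True)
class IntakeResult:
    """Evaporation-corrected intake per fly; negative values kept but flagged."""

    intake_ul: float
    flagged: bool
    duration_h: float

    def __float__(self) -> float:
        return self.intake_ul


def cafe_intake(
    level_drop_exp_ul: float,
    level_drop_control_ul: float,
    n_flies: int = 1,
    duration_h: float = 6.0,
) -> IntakeResult:
    """Per-fly CAFE intake: (experimental drop − fly-free evaporation drop) / n.

    Negative corrected intakes are retained and flagged rather than clamped so
    the estimation layer sees unbiased values.
    """
    if n_flies < 1:
        raise InvalidMeasurementError("n_flies must be >= 1")
    if duration_h <= 0:
        raise InvalidMeasurementError("duration must be positive")
    if level_drop_exp_ul < 0 or level_drop_control_ul < 0:
        raise MalformedReadingError("capillary level drops cannot be negative")
    intake = (level_drop_exp_ul - level_drop_control_ul) / n_flies
    return IntakeResult(intake_ul=float(intake), flagged=intake <= 0, duration_h=duration_h)


def vco2_rate(volume_ul: float, duration_h: float = 1.0, n_flies: int = 1) -> float:
    """CO2 production rate in µl per fly per hour from capillary displacement."""
    if duration_h <= 0:
        raise InvalidMeasurementError("duration must be positive")
    if n_flies < 1:
        raise InvalidMeasurementError("n_flies must be >= 1")
    if volume_ul < 0:
        raise MalformedReadingError("negative CO2 volume")
    return float(volume_ul / (duration_h * n_flies))


def body_composition(
    wet_mg: float, dry_mg: float, lean_dry_mg: float, pct_denominator: str = "dry"
) -> dict:
    """Water, lipid and lipid percentage from a wet/dry/lean-dry mass panel.

    Lipid is dry minus lean-dry mass (ether-extractable fraction); water is
    wet minus dry.  The lipid-percentage denominator defaults to dry mass and
    is echoed in the output so downstream consumers can see the convention.
    """
    if not (wet_mg >= dry_mg >= lean_dry_mg >= 0):
        raise OrderingError(
            f"mass ordering violated: wet={wet_mg}, dry={dry_mg}, lean_dry={lean_dry_mg}"
        )
    if pct_denominator not in ("dry", "wet"):
        raise InvalidMeasurementError(f"unknown percentage denominator {pct_denominator!r}")
    lipid = dry_mg - lean_dry_mg
    water = wet_mg - dry_mg
    denom = dry_mg if pct_denominator == "dry" else wet_mg
    lipid_pct = 100.0 * lipid / denom if denom > 0 else 0.0
    return {
        "water_mg": water,
        "lipid_mg": lipid,
        "lipid_pct": lipid_pct,
        "pct_denominator": pct_denominator,
    }


# ---------------------------------------------------------------------------
# raw-assay CSV -> tidy metric table


def _cafe_tidy(sub, metric: str, n_flies: int, duration_h: float) -> list[dict]:
    rows = []
    sub = sub[sub["metric"].str.startswith(f"{metric}_level_")]
    wide = sub.pivot_table(index="fly_id", columns="metric", values="value")
    for uid, rec in wide.iterrows():
        drop_exp = rec[f"{metric}_level_start_exp"] - rec[f"{metric}_level_end_exp"]
        drop_ctrl = rec[f"{metric}_level_start_ctrl"] - rec[f"{metric}_level_end_ctrl"]
        result = cafe_intake(drop_exp, drop_ctrl, n_flies=n_flies, duration_h=duration_h)
        rows.append({"unit_id": uid, "metric": metric, "value": result.intake_ul})
    return rows


def extract_metrics(raw, meta: dict):
    """Convert a raw-assay table to the tidy metric table.

    Applies the assay computations per experimental unit: evaporation-corrected
    CAFE intake per chamber/vial, trial-level climbing index, respirometry rate
    per fly, lipid percentage per mass panel, and body-mass pass-through.
    Returns a DataFrame with columns
    driver, condition, feeding_state, unit_id, metric, value.
    """
    import pandas as pd

    out: list[dict] = []
    duration = float(meta.get("cafe_duration_h", 6.0))
    group_flies = int(meta.get("cafe_group_flies", 10))
    resp_duration = float(meta.get("respirometry_duration_h", 1.0))
    cutoff = float(meta.get("climbing_cutoff_s", 60.0))
    denom = meta.get("lipid_pct_denominator", "dry")
    for (driver, condition, feeding_state), sub in raw.groupby(
        ["driver", "condition", "feeding_state"], sort=False
    ):
        ctx = {"driver": driver, "condition": condition, "feeding_state": feeding_state}
        metrics_here = set(sub["metric"])
        for cafe_metric, nf in (
            ("food_intake_single", 1),
            ("food_intake_group", group_flies),
        ):
            if f"{cafe_metric}_level_start_exp" in metrics_here:
                out += [
                    {**ctx, **row}
                    for row in _cafe_tidy(sub, cafe_metric, nf, duration)
                ]
        if "climb_time" in metrics_here:
            climb = sub[sub["metric"] == "climb_time"].copy()
            climb["trial"] = climb["fly_id"].str.split("_fly").str[0]
            for trial, grp in climb.groupby("trial", sort=True):
                out.append(
                    {**ctx, "unit_id": trial, "metric": "climbing",
                     "value": climbing_index(grp["value"].to_numpy(), cutoff_s=cutoff)}
                )
        if "co2_volume" in metrics_here:
            name = "vco2_fed" if feeding_state == "fed" else "vco2_starved"
            for _, rec in sub[sub["metric"] == "co2_volume"].iterrows():
                out.append(
                    {**ctx, "unit_id": rec["fly_id"], "metric": name,
                     "value": vco2_rate(rec["value"], duration_h=resp_duration, n_flies=1)}
                )
        if "dry_mass" in metrics_here:
            name = "lipid_fed" if feeding_state == "fed" else "lipid_starved"
            wide = sub[sub["metric"].isin(["wet_mass", "dry_mass", "lean_dry_mass"])].pivot_table(
                index="fly_id", columns="metric", values="value"
            )
            for uid, rec in wide.iterrows():
                comp = body_composition(
                    rec["wet_mass"], rec["dry_mass"], rec["lean_dry_mass"], pct_denominator=denom
                )
                out.append({**ctx, "unit_id": uid, "metric": name, "value": comp["lipid_pct"]})
        if "body_mass" in metrics_here:
            name = "weight_fed" if feeding_state == "fed" else "weight_starved"
            for _, rec in sub[sub["metric"] == "body_mass"].iterrows():
                out.append({**ctx, "unit_id": rec["fly_id"], "metric": name, "value": rec["value"]})
    return pd.DataFrame(
        out, columns=["driver", "condition", "feeding_state", "unit_id", "metric", "value"]
    )
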