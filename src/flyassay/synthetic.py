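"""Synthetic raw-assay data with known ground-truth effect structure.

Every downstream stage (metric extraction, effect estimation, reporting) is
testable against data whose true standardized effects are set by
configuration.  The generator emulates the two-arm silencing design —
uninduced controls versus warm-induced Kir2.1 flies — for five driver lines
across the full assay panel:

* two-state (move/pause) correlated random walks in a 20 x 22 mm arena with
  reflective walls, for the activity index and path metrics;
* epoch-structured SNAC foraging sessions (six 100 s food presentations
  separated by 120 s) with a tunable heading bias toward the feeding alcove;
* capillary feeding (CAFE) level readings contaminated by evaporation that is
  measured in a paired fly-free chamber;
* climbing times with a 60 s failure sentinel, respirometry volumes, and
  wet/dry/lean-dry mass panels.

All random draws flow from a single root seed through per-(driver, metric)
substreams, so adding one assay never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import atan2, cos, sin
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats as sps
from shapely.geometry import Point, Polygon, box

from .errors import ConfigError, GeometryError, InvalidParameterError, UnattainableShiftError
from .registry import DRIVERS, METRIC_INDEX, METRICS
from .trajectory import SnacSession, Trajectory

__all__ = [
    "WalkParams",
    "ScenarioConfig",
    "AssayBundle",
    "gen_two_group",
    "calibrate_latent_shift",
    "gen_trajectory",
    "gen_snac_session",
    "gen_assay_bundle",
    "default_alcove",
]

CAFE_START_LEVEL_UL = 5.0


@dataclass
class WalkParams:
    """Parameters of the two-state correlated random walk."""

    sample_rate: float = 10.0          # Hz
    move_speed_mean: float = 8.0       # mm/s while moving
    pause_probability: float = 0.3    # per-step probability of not moving
    heading_persistence: float = 0.8  # 1 = straight line, 0 = uniform turning
    arena_width: float = 20.0          # mm
    arena_height: float = 22.0         # mm

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        if self.arena_width <= 0 or self.arena_height <= 0:
            raise InvalidParameterError("arena dimensions must be positive")
        if not 0.0 <= self.pause_probability <= 1.0:
            raise InvalidParameterError("pause_probability must be in [0, 1]")
        if not 0.0 <= self.heading_persistence <= 1.0:
            raise InvalidParameterError("heading_persistence must be in [0, 1]")
        if self.move_speed_mean < 0:
            raise InvalidParameterError("move_speed_mean must be non-negative")


class ScenarioConfig(BaseModel):
    """Scenario definition for a full assay-bundle simulation.

    ``true_smd`` maps metric names to the ground-truth standardized effect of
    induction (Hedges'-g scale for interval metrics, Cliff's-delta scale for
    the ordinal alcove-entry metric); values may be a single float or a
    per-driver mapping.  ``baseline_offset`` shifts both arms of every driver
    for a metric, emulating baseline differences between driver genotypes and
    driverless controls without taking a position on their mechanism.
    """

    drivers: list[str] = Field(default_factory=lambda: list(DRIVERS))
    n_c: int = Field(default=50, ge=1)
    n_t: int = Field(default=50, ge=1)
    true_smd: dict[str, float | dict[str, float]] = Field(default_factory=dict)
    baseline: dict[str, float] = Field(default_factory=dict)
    sd: dict[str, float] = Field(default_factory=dict)
    baseline_offset: dict[str, float] = Field(default_factory=dict)
    seed: int = 0
    bootstrap_reps: int = Field(default=10_000, ge=1000)
    cafe_duration_h: float = Field(default=6.0, gt=0)
    cafe_group_flies: int = Field(default=10, ge=1)
    evaporation_mean_ul: float = Field(default=0.05, ge=0)
    evaporation_sd_ul: float = Field(default=0.01, ge=0)
    climbing_flies_per_trial: int = Field(default=5, ge=1)

    @field_validator("drivers")
    @classmethod
    def _nonempty_drivers(cls, v: list[str]) -> list[str]:
        if not v:
            raise ValueError("at least one driver line is required")
        return v

    @field_validator("sd")
    @classmethod
    def _positive_sd(cls, v: dict[str, float]) -> dict[str, float]:
        for k, s in v.items():
            if s <= 0:
                raise ValueError(f"sd for {k!r} must be positive")
        return v

    @model_validator(mode="after")
    def _known_metrics(self) -> "ScenarioConfig":
        for field in ("true_smd", "baseline", "sd", "baseline_offset"):
            for key in getattr(self, field):
                if key not in METRICS:
                    raise ValueError(
                        f"{field} names unknown metric {key!r}; known metrics: "
                        + ", ".join(METRICS)
                    )
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text())
            return cls.model_validate(doc or {})
        except Exception as exc:  # surface the offending key path
            raise ConfigError(str(exc)) from exc

    def smd_for(self, metric: str, driver: str) -> float:
        value = self.true_smd.get(metric, 0.0)
        if isinstance(value, dict):
            return float(value.get(driver, 0.0))
        return float(value)

    def baseline_for(self, metric: str) -> float:
        return self.baseline.get(metric, METRICS[metric].baseline) + self.baseline_offset.get(
            metric, 0.0
        )

    def sd_for(self, metric: str) -> float:
        return self.sd.get(metric, METRICS[metric].sd)


# ---------------------------------------------------------------------------
# elementary generators


def gen_two_group(
    n_c: int,
    n_t: int,
    true_smd: float,
    sd: float = 1.0,
    baseline: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two normal samples whose true standardized mean difference is known.

    Control ~ Normal(baseline, sd); treatment ~ Normal(baseline + smd*sd, sd).
    """
    if n_c < 1 or n_t < 1:
        raise InvalidParameterError("group sizes must be at least 1")
    if sd <= 0:
        raise InvalidParameterError("sd must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    control = rng.normal(baseline, sd, size=n_c)
    treatment = rng.normal(baseline + true_smd * sd, sd, size=n_t)
    return control, treatment


def calibrate_latent_shift(target_delta: float) -> float:
    """Latent normal shift d realising a target Cliff's delta.

    For X ~ N(0,1) and Y ~ N(d,1), Cliff's delta = 2*P(Y > X) - 1
    = 2*Phi(d/sqrt(2)) - 1, hence d = sqrt(2) * Phi^-1((delta + 1)/2).
    """
    if not -1.0 < target_delta < 1.0:
        raise UnattainableShiftError(
            f"|target delta| must be < 1 (got {target_delta}); +/-1 needs an infinite shift"
        )
    return float(np.sqrt(2.0) * sps.norm.ppf((target_delta + 1.0) / 2.0))


# ---------------------------------------------------------------------------
# random-walk trajectories


def _advance(
    x: float,
    y: float,
    heading: float,
    rng: np.random.Generator,
    p: WalkParams,
    target: tuple[float, float] | None = None,
    bias: float = 0.0,
) -> tuple[float, float, float]:
    """One time step of the move/pause walk with reflective walls."""
    if rng.random() < p.pause_probability:
        return x, y, heading
    heading = heading + rng.normal(0.0, (1.0 - p.heading_persistence) * np.pi)
    if target is not None and bias > 0.0:
        w = min(bias, 1.0)
        bearing = atan2(target[1] - y, target[0] - x)
        vx = (1.0 - w) * cos(heading) + w * cos(bearing)
        vy = (1.0 - w) * sin(heading) + w * sin(bearing)
        if vx != 0.0 or vy != 0.0:
            heading = atan2(vy, vx)
    step = p.move_speed_mean / p.sample_rate
    nx, ny = x, y
    for _ in range(4):
        nx = x + step * cos(heading)
        ny = y + step * sin(heading)
        if 0.0 <= nx <= p.arena_width and 0.0 <= ny <= p.arena_height:
            break
        if nx < 0.0 or nx > p.arena_width:
            heading = np.pi - heading
        elif ny < 0.0 or ny > p.arena_height:
            heading = -heading
    nx = min(max(nx, 0.0), p.arena_width)
    ny = min(max(ny, 0.0), p.arena_height)
    return nx, ny, heading


def gen_trajectory(
    duration_s: float,
    params: WalkParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    start_xy: tuple[float, float] | None = None,
) -> Trajectory:
    """Simulate a free walk of the given duration (reflective arena walls)."""
    if duration_s <= 0:
        raise InvalidParameterError("duration must be positive")
    p = params or WalkParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration_s * p.sample_rate))
    dt = 1.0 / p.sample_rate
    x = p.arena_width / 2.0 if start_xy is None else start_xy[0]
    y = p.arena_height / 2.0 if start_xy is None else start_xy[1]
    heading = rng.uniform(-np.pi, np.pi)
    xs, ys = np.empty(n), np.empty(n)
    for i in range(n):
        xs[i], ys[i] = x, y
        x, y, heading = _advance(x, y, heading, rng, p)
    return Trajectory(np.arange(n) * dt, xs, ys)


def default_alcove(params: WalkParams | None = None) -> Polygon:
    """Feeding alcove: a recess centred on the far (top) arena wall."""
    p = params or WalkParams()
    cx = p.arena_width / 2.0
    return box(cx - 2.0, p.arena_height - 2.5, cx + 2.0, p.arena_height)


def gen_snac_session(
    walk: WalkParams | None = None,
    alcove_bias: float = 0.3,
    n_epochs: int = 6,
    epoch_timeout_s: float = 100.0,
    inter_epoch_s: float = 120.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    alcove: Polygon | None = None,
    start_xy: tuple[float, float] | None = None,
    fly_id: str = "",
    debounce: int = 2,
) -> SnacSession:
    """Simulate an epoch-structured foraging session in the SNAC arena.

    Food is presented at each epoch start; presentation ends at the first
    debounced alcove entry or at the timeout, whichever is earlier, and the
    next epoch begins after the inter-epoch interval.  ``alcove_bias`` in
    [0, 1] mixes the random-walk heading with the bearing to the alcove while
    food is on (1 = deterministic beeline).
    """
    if n_epochs < 1:
        raise InvalidParameterError("n_epochs must be at least 1")
    if epoch_timeout_s <= 0 or inter_epoch_s < 0:
        raise InvalidParameterError("epoch timeout must be positive, interval non-negative")
    p = walk or WalkParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    arena = box(0.0, 0.0, p.arena_width, p.arena_height)
    alc = alcove if alcove is not None else default_alcove(p)
    if not arena.buffer(1e-9).contains(alc):
        raise GeometryError("alcove region lies outside the arena")
    target = (alc.centroid.x, alc.centroid.y)
    dt = 1.0 / p.sample_rate

    x = p.arena_width / 2.0 if start_xy is None else start_xy[0]
    y = 3.0 if start_xy is None else start_xy[1]
    heading = rng.uniform(-np.pi, np.pi)

    ts: list[float] = [0.0]
    xs: list[float] = [x]
    ys: list[float] = [y]
    t = 0.0
    epochs: list[tuple[float, float, float]] = []

    minx, miny, maxx, maxy = alc.bounds

    def inside(px: float, py: float) -> bool:
        # cheap bbox rejection before the exact polygon test
        if not (minx <= px <= maxx and miny <= py <= maxy):
            return False
        return bool(alc.covers(Point(px, py)))

    for k in range(n_epochs):
        food_on = t
        entry_time: float | None = None
        run = 0
        for _ in range(int(round(epoch_timeout_s / dt))):
            x, y, heading = _advance(x, y, heading, rng, p, target=target, bias=alcove_bias)
            t += dt
            ts.append(t)
            xs.append(x)
            ys.append(y)
            run = run + 1 if inside(x, y) else 0
            if run >= debounce:
                entry_time = t - (debounce - 1) * dt
                break
        if entry_time is not None:
            food_off = min(entry_time + dt, food_on + epoch_timeout_s)
        else:
            food_off = food_on + epoch_timeout_s
            t = food_off  # guard against float drift in the step accumulation
        epochs.append((food_on, food_on, food_off))
        if k < n_epochs - 1:
            next_start = food_off + inter_epoch_s
            while t < next_start - dt / 2.0:
                x, y, heading = _advance(x, y, heading, rng, p)
                t += dt
                ts.append(t)
                xs.append(x)
                ys.append(y)
            t = next_start

    traj = Trajectory(np.asarray(ts), np.asarray(xs), np.asarray(ys))
    return SnacSession(trajectory=traj, epochs=epochs, alcove=alc, arena=arena, fly_id=fly_id)


# ---------------------------------------------------------------------------
# the full assay bundle


@dataclass
class AssayBundle:
    """In-memory raw-assay file set plus tracking-derived metric rows."""

    raw: pd.DataFrame          # driver,condition,feeding_state,fly_id,metric,value,unit
    behavioural: pd.DataFrame  # driver,condition,feeding_state,unit_id,metric,value
    meta: dict

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        raw_path = out / "raw_assays.csv"
        beh_path = out / "behavioural_metrics.csv"
        meta_path = out / "bundle_meta.json"
        self.raw.to_csv(raw_path, index=False, float_format="%.6f")
        self.behavioural.to_csv(beh_path, index=False, float_format="%.6f")
        meta_path.write_text(json.dumps(self.meta, indent=1, sort_keys=True))
        return {"raw": raw_path.name, "behavioural": beh_path.name, "meta": meta_path.name}


def _substream(config: ScenarioConfig, driver: str, metric: str) -> np.random.Generator:
    d_idx = config.drivers.index(driver)
    return np.random.default_rng([config.seed & 0x7FFFFFFF, d_idx, METRIC_INDEX[metric]])


def _arm_values(
    rng: np.random.Generator, n: int, base: float, sd: float, shift: float
) -> np.ndarray:
    return rng.normal(base + shift, sd, size=n)


def gen_assay_bundle(config: ScenarioConfig) -> AssayBundle:
    """Generate the full raw-assay file set for one scenario.

    Scalar assays (CAFE, climbing, respirometry, mass panels) are emitted as
    raw readings constructed so that the extracted metric reproduces the
    configured per-metric distribution; tracking-derived metrics are emitted
    at metric level (see docs for the rationale).
    """
    raw_rows: list[dict] = []
    beh_rows: list[dict] = []
    for driver in config.drivers:
        for metric, spec in METRICS.items():
            rng = _substream(config, driver, metric)
            smd = config.smd_for(metric, driver)
            base = config.baseline_for(metric)
            sd = config.sd_for(metric)
            for condition, n in (("uninduced", config.n_c), ("induced", config.n_t)):
                shift = smd * sd if condition == "induced" else 0.0
                ctx = dict(driver=driver, condition=condition, feeding_state=spec.feeding_state)
                if spec.assay in ("cafe_single", "cafe_group"):
                    n_flies = 1 if spec.assay == "cafe_single" else config.cafe_group_flies
                    raw_rows += _cafe_rows(rng, n, base, sd, shift, n_flies, config, metric, ctx)
                elif spec.assay == "climbing":
                    raw_rows += _climbing_rows(rng, n, base, sd, shift, config, ctx)
                elif spec.assay == "respirometry":
                    vols = np.clip(_arm_values(rng, n, base, sd, shift), 0.0, None)
                    raw_rows += [
                        {**ctx, "fly_id": f"fly{i:04d}", "metric": "co2_volume",
                         "value": v, "unit": "ul"}
                        for i, v in enumerate(vols)
                    ]
                elif spec.assay == "body_composition":
                    raw_rows += _mass_rows(rng, n, base, sd, shift, ctx)
                elif spec.assay == "body_weight":
                    masses = np.clip(_arm_values(rng, n, base, sd, shift), 0.05, None)
                    raw_rows += [
                        {**ctx, "fly_id": f"fly{i:04d}", "metric": "body_mass",
                         "value": m, "unit": "mg"}
                        for i, m in enumerate(masses)
                    ]
                else:  # tracking-derived metrics, emitted at metric level
                    beh_rows += _behavioural_rows(rng, n, base, sd, smd, metric, spec, ctx)
    raw = pd.DataFrame(
        raw_rows, columns=["driver", "condition", "feeding_state", "fly_id", "metric", "value", "unit"]
    )
    beh = pd.DataFrame(
        beh_rows, columns=["driver", "condition", "feeding_state", "unit_id", "metric", "value"]
    )
    meta = {
        "cafe_duration_h": config.cafe_duration_h,
        "cafe_group_flies": config.cafe_group_flies,
        "respirometry_duration_h": 1.0,
        "climbing_cutoff_s": 60.0,
        "climbing_flies_per_trial": config.climbing_flies_per_trial,
        "lipid_pct_denominator": "dry",
        "seed": config.seed,
        "n_c": config.n_c,
        "n_t": config.n_t,
        "drivers": config.drivers,
    }
    return AssayBundle(raw=raw, behavioural=beh, meta=meta)


def _cafe_rows(rng, n, base, sd, shift, n_flies, config, metric, ctx) -> list[dict]:
    # evaporation hits both chambers in distribution; the fly-attributable SD is
    # compensated so the corrected metric keeps exactly the configured SD/SMD
    evap_var = 2.0 * config.evaporation_sd_ul**2 / n_flies**2
    if sd**2 <= evap_var:
        raise ConfigError(
            f"{metric}: sd {sd} too small for evaporation sd {config.evaporation_sd_ul}"
        )
    sd_fly = float(np.sqrt(sd**2 - evap_var))
    intakes = _arm_values(rng, n, base, sd_fly, shift)
    evap_exp = rng.normal(config.evaporation_mean_ul, config.evaporation_sd_ul, size=n)
    evap_ctrl = rng.normal(config.evaporation_mean_ul, config.evaporation_sd_ul, size=n)
    rows = []
    tag = "chamber" if n_flies == 1 else "vial"
    for i in range(n):
        drop_exp = max(intakes[i] * n_flies + evap_exp[i], 0.0)
        drop_ctrl = max(evap_ctrl[i], 0.0)
        uid = f"{tag}{i:04d}"
        for name, drop in (("exp", drop_exp), ("ctrl", drop_ctrl)):
            rows.append({**ctx, "fly_id": uid, "metric": f"{metric}_level_start_{name}",
                         "value": CAFE_START_LEVEL_UL, "unit": "ul"})
            rows.append({**ctx, "fly_id": uid, "metric": f"{metric}_level_end_{name}",
                         "value": CAFE_START_LEVEL_UL - drop, "unit": "ul"})
    return rows


def _climbing_rows(rng, n_trials, base, sd, shift, config, ctx) -> list[dict]:
    per_trial = config.climbing_flies_per_trial
    rows = []
    for trial in range(n_trials):
        index = float(np.clip(rng.normal(base + shift, sd), 0.0, 1.0))
        k = int(round(index * per_trial))
        times = np.full(per_trial, np.nan)
        times[:k] = rng.uniform(5.0, 55.0, size=k)
        rng.shuffle(times)
        for j, tval in enumerate(times):
            rows.append({**ctx, "fly_id": f"trial{trial:03d}_fly{j}", "metric": "climb_time",
                         "value": tval, "unit": "s"})
    return rows


def _mass_rows(rng, n, base, sd, shift, ctx) -> list[dict]:
    # per-replicate pooled masses of five flies; lean-dry back-constructed so the
    # extracted lipid percentage equals the drawn value exactly
    pct = np.clip(_arm_values(rng, n, base, sd, shift), 0.5, 80.0)
    dry = np.clip(rng.normal(1.5, 0.1, size=n), 0.3, None)
    water = np.clip(rng.normal(3.3, 0.25, size=n), 0.2, None)
    rows = []
    for i in range(n):
        lean = dry[i] * (1.0 - pct[i] / 100.0)
        uid = f"rep{i:04d}"
        for metric, value in (
            ("wet_mass", dry[i] + water[i]),
            ("dry_mass", dry[i]),
            ("lean_dry_mass", lean),
        ):
            rows.append({**ctx, "fly_id": uid, "metric": metric, "value": value, "unit": "mg"})
    return rows


def _behavioural_rows(rng, n, base, sd, smd, metric, spec, ctx) -> list[dict]:
    if spec.ordinal:
        # effect configured on the Cliff's-delta scale; realised through a
        # latent normal shift, then discretized to the 0..6 entry count
        d = calibrate_latent_shift(smd) if smd != 0.0 else 0.0
        shift = d if ctx["condition"] == "induced" else 0.0
        z = rng.normal(shift, 1.0, size=n)
        values = np.clip(np.round(base + sd * z), 0, 6)
    else:
        shift = smd * sd if ctx["condition"] == "induced" else 0.0
        values = _arm_values(rng, n, base, sd, shift)
        if metric == "activity":
            values = np.clip(values, 0.0, 1.0)
        elif metric == "path_efficiency":
            values = np.clip(values, 0.01, 1.0)
        elif metric == "time_to_alcove":
            values = np.clip(values, 1.0, 100.0)
        elif metric == "distance_travelled":
            values = np.clip(values, 20.0, None)
    return [
        {**ctx, "unit_id": f"fly{i:04d}", "metric": metric, "value": float(v)}
        for i, v in enumerate(values)
    ]
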