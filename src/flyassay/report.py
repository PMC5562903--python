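"""Pipeline orchestration and the driver-by-metric effect matrix.

``run_pipeline`` chains simulate -> extract -> estimate -> report, writing
every intermediate as a plain-text file plus a manifest that records the
configuration hash, seeds and package version, so each number in the rendered
matrix is traceable to its inputs.  The matrix emphasises moderate-and-larger
effects (|g| > 0.50 or |Cliff's delta| > 0.47, strict) the way the source
assays are conventionally summarised; emphasis is descriptive, not a test.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assays import extract_metrics
from .errors import CollisionError, ConfigError
from .estimation import EffectEstimate, GroupData, estimate_effect
from .registry import METRIC_ORDER, METRICS
from .synthetic import ScenarioConfig, gen_assay_bundle

__all__ = ["EffectMatrix", "effect_matrix", "estimate_all", "run_pipeline"]

G_EMPHASIS = 0.50
DELTA_EMPHASIS = 0.47
MISSING_CELL = "·"  # middle dot for absent (driver, metric) cells


def _emphasised(effect: float, kind: str) -> bool:
    if kind == "delta":
        return abs(effect) > DELTA_EMPHASIS
    return abs(effect) > G_EMPHASIS


@dataclass
class EffectMatrix:
    """Metric-by-driver matrix of effect estimates with emphasis flags."""

    drivers: list[str]
    metrics: list[str]
    cells: dict[tuple[str, str], EffectEstimate] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.metrics), len(self.drivers))

    def cell(self, metric: str, driver: str) -> EffectEstimate | None:
        return self.cells.get((metric, driver))

    def emphasis(self, metric: str, driver: str) -> bool:
        est = self.cell(metric, driver)
        return est is not None and _emphasised(est.effect, est.kind)

    def n_emphasised(self) -> int:
        return sum(
            self.emphasis(m, d) for m in self.metrics for d in self.drivers
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-form frame, one row per populated cell."""
        rows = []
        for (metric, driver), est in self.cells.items():
            rows.append(
                {
                    "metric": metric,
                    "driver": driver,
                    "estimator": est.kind,
                    "delta_raw": est.delta_raw,
                    "effect": est.effect,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p_proforma": est.p_proforma,
                    "n_c": est.n_c,
                    "n_t": est.n_t,
                    "magnitude": est.magnitude,
                    "emphasis": _emphasised(est.effect, est.kind),
                    "B": est.bootstrap_reps,
                    "seed": est.seed,
                }
            )
        df = pd.DataFrame(rows)
        if df.empty:
            return df
        df["metric"] = pd.Categorical(df["metric"], categories=self.metrics, ordered=True)
        df["driver"] = pd.Categorical(df["driver"], categories=self.drivers, ordered=True)
        return df.sort_values(["metric", "driver"]).reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "drivers": self.drivers,
            "metrics": self.metrics,
            "cells": [
                {"metric": m, "driver": d, **est.to_dict()}
                for (m, d), est in sorted(
                    self.cells.items(),
                    key=lambda kv: (self.metrics.index(kv[0][0]), self.drivers.index(kv[0][1])),
                )
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EffectMatrix":
        if isinstance(source, Path) or (len(str(source)) < 4096 and Path(str(source)).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        matrix = cls(drivers=doc["drivers"], metrics=doc["metrics"])
        for cell in doc["cells"]:
            est = EffectEstimate(
                metric=cell["metric"],
                kind=cell["estimator"],
                delta_raw=cell["delta_raw"],
                effect=cell["effect"],
                ci_low=cell["ci_low"],
                ci_high=cell["ci_high"],
                p_proforma=cell["p_proforma"],
                n_c=cell["n_c"],
                n_t=cell["n_t"],
                magnitude=cell["magnitude"],
                bootstrap_reps=cell.get("B", 0),
                seed=cell.get("seed"),
                ci_method=cell.get("ci_method", "percentile-bootstrap"),
            )
            matrix.cells[(cell["metric"], cell["driver"])] = est
        return matrix

    def to_markdown(self) -> str:
        """Rendered matrix: Cliff's-delta cells prefixed with the Greek Delta,
        moderate-and-larger effects in bold, missing cells as a middle dot."""
        lines = ["| metric | " + " | ".join(self.drivers) + " |"]
        lines.append("|" + "---|" * (len(self.drivers) + 1))
        for metric in self.metrics:
            cells = []
            for driver in self.drivers:
                est = self.cell(metric, driver)
                if est is None:
                    cells.append(MISSING_CELL)
                    continue
                prefix = "Δ" if est.kind == "delta" else ""
                text = f"{prefix}{est.effect:+.2f}"
                cells.append(f"**{text}**" if _emphasised(est.effect, est.kind) else text)
            lines.append(f"| {metric} | " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"


def effect_matrix(
    estimates: list[tuple[str, EffectEstimate]],
    drivers: list[str] | None = None,
    metrics: list[str] | None = None,
) -> EffectMatrix:
    """Assemble (driver, estimate) pairs into the effect matrix.

    Raises on duplicate (driver, metric) cells; absent cells stay missing and
    are excluded from emphasis counts.
    """
    drivers = drivers or sorted({d for d, _ in estimates})
    metrics = metrics or [m for m in METRIC_ORDER if any(e.metric == m for _, e in estimates)]
    matrix = EffectMatrix(drivers=list(drivers), metrics=list(metrics))
    for driver, est in estimates:
        key = (est.metric, driver)
        if key in matrix.cells:
            raise CollisionError(f"duplicate estimate for driver={driver}, metric={est.metric}")
        matrix.cells[key] = est
    return matrix


def estimate_all(
    tidy: pd.DataFrame,
    B: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> list[tuple[str, EffectEstimate]]:
    """One effect estimate per (driver, metric): induced minus uninduced.

    Ordinal metrics get Cliff's delta, interval metrics Hedges' g; every cell
    uses its own derived bootstrap substream so cells are independent of each
    other and of matrix layout.
    """
    out: list[tuple[str, EffectEstimate]] = []
    for (driver, metric), sub in tidy.groupby(["driver", "metric"], sort=False):
        spec = METRICS.get(metric)
        control = sub.loc[sub["condition"] == "uninduced", "value"].to_numpy(dtype=float)
        treatment = sub.loc[sub["condition"] == "induced", "value"].to_numpy(dtype=float)
        if control.size < 2 or treatment.size < 2:
            continue
        def _stable(label: str) -> int:
            return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big") % (2**31)

        cell_seed = int(
            np.random.SeedSequence(
                [seed & 0x7FFFFFFF, _stable(driver), _stable(metric)]
            ).generate_state(1)[0]
            % (2**31)
        )
        g = GroupData(control, treatment, metric=metric, ordinal=bool(spec and spec.ordinal))
        out.append((driver, estimate_effect(g, B=B, seed=cell_seed, level=level)))
    return out


def run_pipeline(
    config: ScenarioConfig,
    out_dir: str | Path,
    B: int | None = None,
    formats: tuple[str, ...] = ("csv", "json", "md"),
) -> EffectMatrix:
    """Generate raw data, extract metrics, estimate effects, render the matrix.

    Writes raw assay CSVs, the tidy metric table, the estimate table, the
    effect matrix in the requested formats, and a manifest tying everything to
    the configuration hash and seed.  Output data are identical for identical
    (config, seed).
    """
    if not isinstance(config, ScenarioConfig):
        raise ConfigError("run_pipeline expects a validated ScenarioConfig")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    B = B or config.bootstrap_reps

    bundle = gen_assay_bundle(config)
    files = bundle.write(out)

    tidy = pd.concat(
        [extract_metrics(bundle.raw, bundle.meta), bundle.behavioural], ignore_index=True
    )
    tidy_path = out / "tidy_metrics.csv"
    tidy.to_csv(tidy_path, index=False, float_format="%.6f")
    files["tidy"] = tidy_path.name

    estimates = estimate_all(tidy, B=B, seed=config.seed)
    est_frame = pd.DataFrame(
        [{"driver": d, **e.to_dict()} for d, e in estimates]
    )
    est_path = out / "estimates.csv"
    est_frame.to_csv(est_path, index=False)
    files["estimates"] = est_path.name

    matrix = effect_matrix(estimates, drivers=config.drivers, metrics=list(METRIC_ORDER))
    if "csv" in formats:
        matrix.to_csv(out / "effect_matrix.csv")
        files["matrix_csv"] = "effect_matrix.csv"
    if "json" in formats:
        matrix.to_json(out / "effect_matrix.json")
        files["matrix_json"] = "effect_matrix.json"
    if "md" in formats:
        (out / "effect_matrix.md").write_text(matrix.to_markdown())
        files["matrix_md"] = "effect_matrix.md"

    config_doc = config.model_dump()
    manifest = {
        "config": config_doc,
        "config_sha256": hashlib.sha256(
            json.dumps(config_doc, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "bootstrap_reps": B,
        "flyassay_version": __version__,
        "generated_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return matrix
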