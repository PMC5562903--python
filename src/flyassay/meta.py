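"""Summary-level standardized mean differences and the forest table.

Systematic-review records arrive as digitized per-group summary statistics
(mean, SD or SEM, n per arm).  Because raw data are unavailable for such
records, confidence intervals use the normal-theory (Wald) large-sample
variance of the SMD rather than the bootstrap used on this package's own raw
data; the CI method is labelled in every output row.  No meta-analytic
pooling or heterogeneity statistics are computed — experiments are presented
side by side.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError
from scipy import stats as sps

from .errors import InvalidRecordError
from .estimation import EffectEstimate, classify_magnitude

__all__ = ["ExtractedExperiment", "smd_from_summary", "forest_table", "read_extracted_csv", "forest_plot"]


class ExtractedExperiment(BaseModel):
    """One digitized two-group experiment from the reviewed literature."""

    # CSV readers deliver bare numbers for labels like a figure panel "1"
    model_config = ConfigDict(coerce_numbers_to_str=True)

    study: str
    figure_panel: str = ""
    neuromodulator: str
    manipulation: str = Field(pattern="^(activator|inhibitor)$")
    assay: str
    mean_c: float
    mean_t: float
    dispersion_c: float = Field(gt=0)
    dispersion_t: float = Field(gt=0)
    dispersion_kind: str = Field(default="SD", pattern="^(SD|SEM)$")
    n_c: int = Field(ge=2)
    n_t: int = Field(ge=2)
    digitized_from: str

    def sds(self) -> tuple[float, float]:
        """Arm SDs, converting SEM via SD = SEM * sqrt(n) when needed."""
        if self.dispersion_kind == "SEM":
            return (
                self.dispersion_c * np.sqrt(self.n_c),
                self.dispersion_t * np.sqrt(self.n_t),
            )
        return self.dispersion_c, self.dispersion_t


def smd_from_summary(rec: ExtractedExperiment, level: float = 0.95) -> EffectEstimate:
    """Hedges' g with a Wald CI from per-group summary statistics.

    g = J * (mean_t - mean_c) / s_p with the df-weighted pooled SD and
    J = 1 - 3/(4*df - 1); var(g) = J^2 * [(n_c + n_t)/(n_c*n_t)
    + d^2 / (2*(n_c + n_t))].
    """
    sd_c, sd_t = rec.sds()
    n_c, n_t = rec.n_c, rec.n_t
    df = n_c + n_t - 2
    s_p = np.sqrt(((n_c - 1) * sd_c**2 + (n_t - 1) * sd_t**2) / df)
    if s_p <= 0:
        raise InvalidRecordError(f"{rec.study}: pooled SD is not positive")
    d = (rec.mean_t - rec.mean_c) / s_p
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = correction * d
    var_g = correction**2 * ((n_c + n_t) / (n_c * n_t) + d**2 / (2.0 * (n_c + n_t)))
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var_g)
    return EffectEstimate(
        metric=rec.assay,
        kind="g",
        delta_raw=rec.mean_t - rec.mean_c,
        effect=float(g),
        ci_low=float(g - half),
        ci_high=float(g + half),
        p_proforma=float("nan"),
        n_c=n_c,
        n_t=n_t,
        magnitude=classify_magnitude(float(g), "g"),
        ci_method="wald-summary",
        extra={
            "study": rec.study,
            "figure_panel": rec.figure_panel,
            "neuromodulator": rec.neuromodulator,
            "manipulation": rec.manipulation,
            "digitized_from": rec.digitized_from,
        },
    )


def forest_table(records: list[ExtractedExperiment]) -> pd.DataFrame:
    """Forest-plot rows: one SMD per experiment, no pooling.

    Rows are grouped by neuromodulator and sub-grouped by manipulation
    (activators before inhibitors); the sort is stable so input order breaks
    ties, and the output is invariant to input permutation up to that order.
    """
    rows = []
    for rec in records:
        est = smd_from_summary(rec)
        rows.append(
            {
                "neuromodulator": rec.neuromodulator,
                "manipulation": rec.manipulation,
                "study": rec.study,
                "figure_panel": rec.figure_panel,
                "assay": rec.assay,
                "g": est.effect,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_c": rec.n_c,
                "n_t": rec.n_t,
                "magnitude": est.magnitude,
                "ci_method": est.ci_method,
                "digitized_from": rec.digitized_from,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "neuromodulator", "manipulation", "study", "figure_panel", "assay",
            "g", "ci_low", "ci_high", "n_c", "n_t", "magnitude", "ci_method",
            "digitized_from",
        ],
    )
    if df.empty:
        return df
    return df.sort_values(
        ["neuromodulator", "manipulation", "study", "figure_panel"], kind="stable"
    ).reset_index(drop=True)


def read_extracted_csv(path: str | Path) -> list[ExtractedExperiment]:
    """Load digitized records; the provenance column ``digitized_from`` is mandatory."""
    df = pd.read_csv(path)
    if "digitized_from" not in df.columns:
        raise InvalidRecordError("input CSV must carry a 'digitized_from' provenance column")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(ExtractedExperiment.model_validate(row.to_dict()))
        except ValidationError as exc:
            raise InvalidRecordError(f"row {i}: {exc}") from exc
    return records


def forest_plot(table: pd.DataFrame, path: str | Path) -> None:
    """Render a basic forest plot (point estimates with 95% CI bars) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.5 * max(len(table), 4) + 1))
    ypos = np.arange(len(table))[::-1]
    ax.errorbar(
        table["g"], ypos,
        xerr=[table["g"] - table["ci_low"], table["ci_high"] - table["g"]],
        fmt="o", color="k", ecolor="gray", capsize=3,
    )
    ax.axvline(0.0, color="0.6", linestyle="--", linewidth=0.8)
    labels = table["neuromodulator"] + " / " + table["manipulation"] + " / " + table["study"]
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("Hedges' g (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
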