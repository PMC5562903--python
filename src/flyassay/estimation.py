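"""Estimation-statistics engine.

Two-group contrasts are summarised without null-hypothesis significance
testing: the raw mean difference, a standardized effect size (Hedges' g for
interval data, Cliff's delta for ordinal data), a seeded percentile-bootstrap
95% confidence interval, a pro-forma Mann-Whitney P value, and a conventional
magnitude label.

Conventions
-----------
* Effect direction is treatment − control throughout (induced − uninduced in
  the silencing design).
* Hedges' g = J · (mean_t − mean_c) / s_p with the df-weighted pooled SD
  (df = n_c + n_t − 2) and small-sample correction J = 1 − 3 / (4·df − 1).
* Cliff's delta = (#{t > c} − #{t < c}) / (n_t · n_c); ties contribute zero.
* Bootstrap resamples each group with replacement at its own n; the interval
  is the percentile interval by default, BCa behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "GroupData",
    "EffectEstimate",
    "mean_difference",
    "hedges_g",
    "cliffs_delta",
    "bootstrap_ci",
    "mann_whitney_p",
    "classify_magnitude",
    "estimate_effect",
]


def _as_sample(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise InvalidParameterError(f"{name} sample must be one-dimensional")
    if arr.size and not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} sample contains non-finite values")
    return arr


@dataclass
class GroupData:
    """A two-group dataset in native units.

    ``ordinal`` marks count-valued metrics (e.g. alcove entries) for which
    Cliff's delta is the appropriate standardized effect.
    """

    control: np.ndarray
    treatment: np.ndarray
    metric: str = ""
    ordinal: bool = False

    def __post_init__(self) -> None:
        self.control = _as_sample(self.control, "control")
        self.treatment = _as_sample(self.treatment, "treatment")

    @property
    def n_c(self) -> int:
        return self.control.size

    @property
    def n_t(self) -> int:
        return self.treatment.size

    def swapped(self) -> "GroupData":
        return GroupData(self.treatment, self.control, self.metric, self.ordinal)


@dataclass
class EffectEstimate:
    """One estimated contrast: raw difference, standardized effect, CI, pro-forma P."""

    metric: str
    kind: str                   # "g" or "delta"
    delta_raw: float
    effect: float
    ci_low: float
    ci_high: float
    p_proforma: float
    n_c: int
    n_t: int
    magnitude: str
    bootstrap_reps: int = 0
    seed: int | None = None
    ci_method: str = "percentile-bootstrap"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "estimator": self.kind,
            "delta_raw": self.delta_raw,
            "effect": self.effect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_proforma": self.p_proforma,
            "n_c": self.n_c,
            "n_t": self.n_t,
            "magnitude": self.magnitude,
            "B": self.bootstrap_reps,
            "seed": self.seed,
            "ci_method": self.ci_method,
            **self.extra,
        }


# ---------------------------------------------------------------------------
# point estimators


def _require_nonempty(g: GroupData) -> None:
    if g.n_c < 1 or g.n_t < 1:
        raise InsufficientDataError(
            f"both samples must be non-empty (got n_c={g.n_c}, n_t={g.n_t})"
        )


def mean_difference(g: GroupData) -> float:
    """Raw mean difference, treatment − control, in native units."""
    _require_nonempty(g)
    return float(g.treatment.mean() - g.control.mean())


def hedges_g(g: GroupData) -> float:
    """Bias-corrected standardized mean difference (Hedges' g)."""
    n_c, n_t = g.n_c, g.n_t
    if n_c < 2 or n_t < 2:
        raise InsufficientDataError("Hedges' g requires at least 2 observations per arm")
    df = n_c + n_t - 2
    var_p = ((n_c - 1) * g.control.var(ddof=1) + (n_t - 1) * g.treatment.var(ddof=1)) / df
    diff = g.treatment.mean() - g.control.mean()
    if var_p == 0.0:
        if diff == 0.0:
            return 0.0
        raise DegenerateVarianceError("pooled SD is zero but the means differ")
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float(correction * diff / np.sqrt(var_p))


def cliffs_delta(g: GroupData) -> float:
    """Ordinal dominance statistic in [−1, 1].

    Computed in O((n+m) log n) by ranking treatment values against the sorted
    control sample; tied pairs contribute zero.
    """
    _require_nonempty(g)
    c = np.sort(g.control)
    gt = np.searchsorted(c, g.treatment, side="left").sum()      # pairs with t > c
    lt = (g.n_c - np.searchsorted(c, g.treatment, side="right")).sum()  # t < c
    return float((int(gt) - int(lt)) / (g.n_t * g.n_c))


# ---------------------------------------------------------------------------
# bootstrap

def _mean_diff_rows(c: np.ndarray, t: np.ndarray) -> np.ndarray:
    return t.mean(axis=1) - c.mean(axis=1)


def _hedges_rows(c: np.ndarray, t: np.ndarray) -> np.ndarray:
    n_c, n_t = c.shape[1], t.shape[1]
    df = n_c + n_t - 2
    var_p = ((n_c - 1) * c.var(axis=1, ddof=1) + (n_t - 1) * t.var(axis=1, ddof=1)) / df
    diff = t.mean(axis=1) - c.mean(axis=1)
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = correction * diff / np.sqrt(var_p)
    # degenerate resamples (all values tied in both arms) have g = 0 by convention
    out[np.isnan(out)] = 0.0
    out[np.isinf(out)] = 0.0
    return out


def _cliffs_rows(c: np.ndarray, t: np.ndarray) -> np.ndarray:
    n_c, n_t = c.shape[1], t.shape[1]
    cs = np.sort(c, axis=1)
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        gt = np.searchsorted(cs[i], t[i], side="left").sum()
        lt = (n_c - np.searchsorted(cs[i], t[i], side="right")).sum()
        out[i] = (int(gt) - int(lt)) / (n_t * n_c)
    return out


# row-wise fast paths for the canonical statistics
_ROWWISE: dict[Callable[[GroupData], float], Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    mean_difference: _mean_diff_rows,
    hedges_g: _hedges_rows,
    cliffs_delta: _cliffs_rows,
}


def _bootstrap_distribution(
    statistic: Callable[[GroupData], float],
    g: GroupData,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    idx_c = rng.integers(0, g.n_c, size=(B, g.n_c))
    idx_t = rng.integers(0, g.n_t, size=(B, g.n_t))
    rowwise = _ROWWISE.get(statistic)
    if rowwise is not None:
        return rowwise(g.control[idx_c], g.treatment[idx_t])
    vals = np.empty(B)
    for b in range(B):
        vals[b] = statistic(
            GroupData(g.control[idx_c[b]], g.treatment[idx_t[b]], g.metric, g.ordinal)
        )
    return vals


def bootstrap_ci(
    statistic: Callable[[GroupData], float],
    g: GroupData,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    method: str = "percentile",
) -> tuple[float, float]:
    """Seeded two-sample bootstrap confidence interval.

    Each group is resampled with replacement at its own n; the default
    interval is the percentile interval, ``method="bca"`` applies the
    bias-corrected-and-accelerated adjustment.
    """
    if B < 1000:
        raise InvalidParameterError("B must be at least 1000")
    if not 0.0 < level < 1.0:
        raise InvalidParameterError("level must be in (0, 1)")
    if g.n_c < 2 or g.n_t < 2:
        raise InsufficientDataError("bootstrap requires at least 2 observations per arm")
    rng = np.random.default_rng(seed)
    vals = _bootstrap_distribution(statistic, g, B, rng)
    alpha = 1.0 - level
    if method == "percentile":
        lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
        return float(lo), float(hi)
    if method == "bca":
        return _bca_interval(statistic, g, vals, alpha)
    raise InvalidParameterError(f"unknown bootstrap method {method!r}")


def _bca_interval(
    statistic: Callable[[GroupData], float],
    g: GroupData,
    vals: np.ndarray,
    alpha: float,
) -> tuple[float, float]:
    theta = statistic(g)
    prop = np.mean(vals < theta)
    prop = min(max(prop, 1.0 / (vals.size + 1)), 1.0 - 1.0 / (vals.size + 1))
    z0 = sps.norm.ppf(prop)
    # jackknife over every observation in either arm
    jack = []
    for i in range(g.n_c):
        jack.append(statistic(GroupData(np.delete(g.control, i), g.treatment)))
    for i in range(g.n_t):
        jack.append(statistic(GroupData(g.control, np.delete(g.treatment, i))))
    jack = np.asarray(jack)
    dev = jack.mean() - jack
    denom = 6.0 * (dev**2).sum() ** 1.5
    accel = (dev**3).sum() / denom if denom > 0 else 0.0
    z_lo, z_hi = sps.norm.ppf([alpha / 2.0, 1.0 - alpha / 2.0])

    def adj(z: float) -> float:
        return float(sps.norm.cdf(z0 + (z0 + z) / (1.0 - accel * (z0 + z))))

    lo, hi = np.quantile(vals, [adj(z_lo), adj(z_hi)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# pro-forma P and magnitude labels

_EXACT_PAIR_LIMIT = 400


def mann_whitney_p(g: GroupData) -> float:
    """Two-sided Mann-Whitney U P value, reported pro forma only.

    Exact enumeration when n_t·n_c <= 400 with no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    _require_nonempty(g)
    pooled = np.concatenate([g.control, g.treatment])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and g.n_c * g.n_t <= _EXACT_PAIR_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(g.treatment, g.control, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


_G_BINS = ((0.2, "negligible"), (0.5, "small"), (0.8, "moderate"), (np.inf, "large"))
_DELTA_BINS = ((0.147, "negligible"), (0.33, "small"), (0.47, "medium"), (np.inf, "large"))


def classify_magnitude(effect: float, kind: str = "g") -> str:
    """Conventional magnitude label on |effect|, with half-open bins.

    Hedges' g: [0, 0.2) negligible, [0.2, 0.5) small, [0.5, 0.8) moderate,
    [0.8, ∞) large.  Cliff's delta: [0, 0.147) negligible, [0.147, 0.33)
    small, [0.33, 0.47) medium, [0.47, ∞) large.
    """
    if not np.isfinite(effect):
        raise InvalidParameterError("effect must be finite")
    if kind == "g":
        bins = _G_BINS
    elif kind == "delta":
        bins = _DELTA_BINS
    else:
        raise InvalidParameterError(f"unknown effect kind {kind!r}")
    mag = abs(effect)
    for upper, label in bins:
        if mag < upper:
            return label
    raise AssertionError("unreachable")


def estimate_effect(
    g: GroupData,
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    method: str = "percentile",
) -> EffectEstimate:
    """Full estimation-statistics summary of one two-group contrast.

    Interval data get Hedges' g, ordinal data Cliff's delta; the CI is the
    seeded bootstrap interval of the chosen standardized effect.
    """
    kind = "delta" if g.ordinal else "g"
    statistic = cliffs_delta if g.ordinal else hedges_g
    effect = statistic(g)
    lo, hi = bootstrap_ci(statistic, g, B=B, level=level, seed=seed, method=method)
    return EffectEstimate(
        metric=g.metric,
        kind=kind,
        delta_raw=mean_difference(g),
        effect=effect,
        ci_low=lo,
        ci_high=hi,
        p_proforma=mann_whitney_p(g),
        n_c=g.n_c,
        n_t=g.n_t,
        magnitude=classify_magnitude(effect, kind),
        bootstrap_reps=B,
        seed=seed,
        ci_method=f"{method}-bootstrap",
    )
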