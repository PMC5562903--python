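"""Canonical metric and driver registry.

The effect matrix has 14 metric rows drawn from 11 assays (respirometry, lipid
and weight each contribute a fed and a starved variant) crossed with 5 Gal4
driver lines.  Each metric carries its assay of origin, native unit, the
effect-size family used for it (Hedges' g for interval data, Cliff's delta for
the ordinal alcove-entry count), the feeding state it is measured in, and
simulation baselines.

Baseline means and SDs are chosen so that the printed raw differences and
standardized effects are mutually consistent (SD ~ |raw difference| / |g| for
the largest reported contrast of each assay); they are simulation defaults, not
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass


DRIVERS: tuple[str, ...] = ("TH", "Ddc", "Tdc2", "Trh", "NPF")

CONDITIONS: tuple[str, ...] = ("uninduced", "induced")


@dataclass(frozen=True)
class MetricSpec:
    """Static description of one effect-matrix metric."""

    name: str
    assay: str
    unit: str
    estimator: str          # "g" or "delta"
    feeding_state: str      # "fed" or "starved"
    baseline: float
    sd: float
    ordinal: bool = False


# Row order matches the effect-matrix layout: behaviour, feeding, foraging,
# then physiology.
METRICS: dict[str, MetricSpec] = {
    m.name: m
    for m in (
        MetricSpec("activity", "activity", "fraction", "g", "fed", 0.55, 0.20),
        MetricSpec("climbing", "climbing", "index", "g", "fed", 0.80, 0.29),
        MetricSpec("food_intake_single", "cafe_single", "ul", "g", "starved", 0.30, 0.13),
        MetricSpec("food_intake_group", "cafe_group", "ul", "g", "starved", 0.50, 0.10),
        MetricSpec("alcove_entries", "snac", "count", "delta", "starved", 3.0, 1.2, ordinal=True),
        MetricSpec("time_to_alcove", "snac", "s", "g", "starved", 30.0, 15.0),
        MetricSpec("path_efficiency", "snac", "fraction", "g", "starved", 0.50, 0.15),
        MetricSpec("distance_travelled", "snac", "mm", "g", "starved", 300.0, 103.0),
        MetricSpec("vco2_fed", "respirometry", "ul/fly/h", "g", "fed", 4.0, 1.4),
        MetricSpec("vco2_starved", "respirometry", "ul/fly/h", "g", "starved", 3.0, 2.8),
        MetricSpec("lipid_fed", "body_composition", "%", "g", "fed", 18.0, 4.4),
        MetricSpec("lipid_starved", "body_composition", "%", "g", "starved", 12.0, 4.4),
        MetricSpec("weight_fed", "body_weight", "mg", "g", "fed", 0.90, 0.14),
        MetricSpec("weight_starved", "body_weight", "mg", "g", "starved", 0.85, 0.14),
    )
}

METRIC_ORDER: tuple[str, ...] = tuple(METRICS)
METRIC_INDEX: dict[str, int] = {name: i for i, name in enumerate(METRIC_ORDER)}
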