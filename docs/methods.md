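# Methods

This note documents the models, rules and numerical choices behind
`flyassay`, in the spirit of a statistical-software methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Study design encoded by the package

Every contrast is a two-arm comparison: an *uninduced* control group against
an *induced* treatment group of the same driver genotype (warm-induced
Kir2.1 silencing). Effects are always reported as treatment − control, so a
negative Δ or *g* means the silenced flies score lower. Five driver lines
(TH, Ddc, Tdc2, Trh, NPF) crossed with fourteen metrics from eleven assays
give the 14 × 5 effect matrix; respirometry, lipid content and body weight
each contribute a fed and a starved variant.

## Effect estimators

* **Raw difference** Δ = m̄_T − m̄_C in native units.
* **Hedges' g** = *J* · (m̄_T − m̄_C)/s_p, with the df-weighted pooled SD
  s_p² = [(n_C−1)s_C² + (n_T−1)s_T²]/df, df = n_C + n_T − 2, and the
  small-sample correction *J* = 1 − 3/(4·df − 1) applied always. *J* is the
  standard rational approximation to the exact gamma-function correction;
  its residual bias is far below the Monte-Carlo resolution of any check in
  this package (relative error < 10⁻³ even at df = 18).
* **Cliff's delta** δ = (#{t > c} − #{t < c})/(n_T·n_C), ties contributing
  zero; computed in O((n+m)·log n) via ranking against the sorted control
  sample, and cross-checked in the tests against an independent brute-force
  enumeration of all pairs. Used for the ordinal alcove-entry count; *g*
  for all interval-valued metrics.
* **Magnitude labels** use half-open bins on |effect|: for *g*,
  [0, 0.2) negligible, [0.2, 0.5) small, [0.5, 0.8) moderate, [0.8, ∞)
  large; for δ, cut points 0.147, 0.33, 0.47. Matrix emphasis is strict:
  |g| > 0.50 or |δ| > 0.47. These are descriptive conventions, not tests.

## Uncertainty

Confidence intervals on the package's own raw data come from a seeded
two-sample bootstrap: each arm is resampled with replacement at its own n,
B = 10 000 by default (B ≥ 1000 enforced), percentile interval by default
with BCa behind a flag; B, level and seed are logged in every output row.
The canonical statistics have vectorised resampling paths; arbitrary
user statistics fall back to a per-replicate loop under the same contract.
At small n the percentile interval under-covers mildly (the suite measures
≈ 93.7 % long-run coverage for the mean difference at n = 30/arm against
the 95 % nominal level); this is a known property of the method, which was
chosen for transparency and faithfulness to standard estimation-statistics
practice rather than for exact coverage.

Cliff's-delta CIs use the same bootstrap engine rather than the analytic
consistent-variance formula found in some ordinal-dominance
implementations; the two approaches agree asymptotically but can differ at
small n.

Mann–Whitney *P* values are attached *pro forma* only (the workflow takes
no accept/reject decisions): exact enumeration when n_T·n_C ≤ 400 with no
ties, tie-corrected normal approximation otherwise.

For digitized summary records (meta-review), raw resampling is impossible,
so SMDs get normal-theory Wald intervals with
var(g) = J²·[(n_C+n_T)/(n_C·n_T) + d²/(2(n_C+n_T))] and SEM → SD conversion
by SD = SEM·√n; every such row is labelled `wald-summary`. No pooling or
heterogeneity statistics are computed — reviewed experiments are presented
side by side.

## Trajectory metrics

* **Activity index**: fraction of complete 0.5 s bins in which the fly
  moved ≥ 1 mm. Bins are aligned to the trajectory start; a trailing
  partial bin is discarded. The mobility criterion is summed within-bin
  path length by default — the stricter reading of "moved less than 1 mm",
  appropriate when tracking jitter has already been removed — with net
  displacement available behind `mode="net"`. A step from sample *i* to
  *i*+1 is attributed to the bin containing *t_i*.
* **Windowed distance** uses the same step-attribution rule over half-open
  [start, end) windows, which makes distances exactly additive over
  adjacent windows.
* **SNAC foraging**: an epoch's entry is the first sample inside the
  alcove polygon during the food window, debounced over two consecutive
  samples (the confirmation sample may fall just past the window end, since
  food retracts at entry); boundary contact counts as inside. Latency is
  entry time minus food onset; path efficiency is the straight-line
  distance from the fly's position at food onset to the alcove divided by
  the walked path length, capped at 1 (degenerate zero-length paths score
  1). Epochs without an entry contribute a censored latency and no path
  metrics; censored epochs are excluded from latency summaries. The
  per-epoch exclusion rule drops an epoch when walked distance < 200 mm or
  activity index < 0.10 (strict inequalities: the boundary values are
  kept), and the reason is recorded.

## Scalar assays

* **Climbing**: each fly scores 1 if it reaches the top mark within 60 s,
  else 0 (failures are +∞ in memory, empty fields in CSV); the trial index
  is the mean score and trials are the experimental units.
* **CAFE intake**: (experimental level drop − fly-free evaporation drop)/n
  flies; negative corrected intakes are flagged, never clamped, so the
  estimation layer sees unbiased values. Group vials (10 flies, one
  capillary) are treated as single experimental units.
* **Respirometry**: VCO₂ = volume/(duration·n) in µl·fly⁻¹·h⁻¹. The
  metric name follows the CO₂-production definition of the assay.
* **Body composition**: lipid = dry − lean-dry, water = wet − dry, so
  water + lipid + lean-dry = wet identically. The lipid percentage uses
  dry mass as denominator by default — the choice that makes a −6
  percentage-point change commensurate with a ~50 % relative fat loss —
  and the denominator is echoed in every output.

## Synthetic-data generator

The generator's job is to produce raw files whose *extracted* metrics have
a known distribution, so estimator recovery and pipeline behaviour can be
tested without any external data.

* **Locomotion** is a two-state (move/pause) correlated random walk:
  per-step pause probability, heading evolving by wrapped-normal
  increments scaled by (1 − persistence), fixed step speed, reflective
  walls, 10 Hz default sampling. This is the simplest model that makes the
  activity index and path metrics non-degenerate; it does not attempt
  realistic fly kinematics (no saccades, no wall-following, no circadian
  structure).
* **Foraging sessions** impose the 6 × 100 s epoch schedule with 120 s
  inter-epoch intervals; a bias parameter in [0, 1] mixes the walk heading
  with the bearing to the alcove while food is on (1 = beeline). Food
  presentation ends at the first debounced entry or at timeout, and the
  next epoch starts 120 s after food-off.
* **Two-group draws**: control ~ N(μ, σ), treatment ~ N(μ + g·σ, σ).
  For the ordinal entry count, the configured effect is a Cliff's delta,
  realised through the latent-shift calibration
  d = √2·Φ⁻¹((δ+1)/2) (so that 2·P(Y > X) − 1 = δ for unit normals) and
  then discretized to 0..6; discretization attenuates the realised δ
  slightly and is exact under the null.
* **CAFE back-construction**: experimental and fly-free chambers receive
  independent evaporation draws from a common distribution
  (N(0.05, 0.01) µl by default), reflecting the paired-control design; the
  fly-attributable intake SD is compensated
  (σ_fly² = σ² − 2σ_evap²/n²) so the evaporation-corrected metric keeps
  exactly the configured SD and SMD.
* **Climbing** draws a latent trial index from a clipped normal and rounds
  to k/5 successes, so bundled climbing SMDs carry small discretization
  error (exact under the null). Bounded metrics (activity, efficiency,
  percentages, masses, volumes) are clipped to their physical ranges;
  with the default baselines these clips are rare tail events.
* **Seeding**: one root seed; every (driver, metric) cell draws from its
  own derived substream keyed by stable indices, so adding a driver or
  assay never perturbs existing streams, and identical (config, seed)
  yields byte-identical files.
* **Tracking-derived metrics** (activity, entries, latency, efficiency,
  distance) are emitted by the bundle at metric level from calibrated
  draws; full trajectory synthesis is exercised through
  `gen_trajectory`/`gen_snac_session` and the trajectory-metrics tests.
  Simulating hundreds of full 10 Hz sessions per matrix cell would
  dominate pipeline runtime without changing what the downstream stages
  see.

Default baselines/SDs per metric live in `flyassay.registry`; where a
published contrast fixes the Δ/g ratio the SD was set to match it
(e.g. activity SD 0.20 ≈ 0.25/1.24), otherwise values are plausible
field magnitudes. They are simulation defaults, not measurements.

What passing tests on these data do **not** show: robustness to tracking
noise and identity swaps, non-normal or heteroscedastic raw measurements,
circadian and arousal structure in locomotion, or capillary meniscus
reading error — real-data features the generator deliberately omits.

## Pipeline and reproducibility

`run_pipeline` chains simulate → extract → estimate → report and writes
every intermediate as plain text (CSV/JSON/Markdown) plus a manifest with
the config hash, seed, bootstrap settings and package version; outputs are
identical for identical (config, seed). Per-cell bootstrap seeds derive
from the root seed and stable SHA-256-based label hashes, making estimates
independent of matrix layout and of Python's per-process string hashing.
Missing matrix cells render as "·" and never count toward emphasis.

## Problem sizes used in the validation suite

Estimator-recovery checks use 2000 replicate datasets per published
contrast at the published per-arm sample sizes; the latent-shift
calibration identity is checked at n = 10⁴/arm (±0.02); bootstrap null
coverage at n = 30/arm over 6000 replicate datasets with B = 2000; the
end-to-end null scenario runs all five drivers at n = 500/arm with
B = 2000, where no emphasis flag may appear. These sizes make Monte-Carlo
error small relative to each tolerance while keeping the default suite
fast.

## Known limitations

* The bootstrap is the only uncertainty treatment for raw data; no
  analytic variance formulas are offered there.
* Ordinal metrics other than the entry count (e.g. the k/5-valued climbing
  index) are still summarised with Hedges' g, following field practice of
  treating trial-level indices as interval data.
* The walk model's activity distribution is controlled by pause
  probability and speed only; it cannot reproduce arbitrary joint
  distributions of activity and path metrics.
* Summary-level (Wald) and raw-data (bootstrap) CIs are not numerically
  interchangeable at small n; rows are labelled so the two never mix
  silently.
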