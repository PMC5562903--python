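"""Tests for the synthetic-data generators: determinism, calibration, geometry."""

import numpy as np
import pytest
from scipy import stats as sps

from flyassay import (
    GroupData,
    ScenarioConfig,
    WalkParams,
    activity_index,
    calibrate_latent_shift,
    cliffs_delta,
    gen_assay_bundle,
    gen_snac_session,
    gen_trajectory,
    gen_two_group,
    hedges_g,
)
from flyassay.errors import GeometryError, InvalidParameterError, UnattainableShiftError
from flyassay.registry import METRICS


class TestTwoGroup:
    def test_seeded_determinism(self):
        a = gen_two_group(5, 5, 0.0, sd=1.0, seed=42)
        b = gen_two_group(5, 5, 0.0, sd=1.0, seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_large_sample_smd_recovery(self):
        c, t = gen_two_group(10_000, 10_000, 2.0, sd=1.0, seed=7)
        assert hedges_g(GroupData(c, t)) == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("bad", [dict(sd=-1.0), dict(sd=0.0), dict(n_c=0), dict(n_t=0)])
    def test_invalid_parameters(self, bad):
        kwargs = dict(n_c=5, n_t=5, true_smd=0.0, sd=1.0, seed=0)
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            gen_two_group(**kwargs)


class TestLatentShiftCalibration:
    def test_zero_maps_to_zero(self):
        assert calibrate_latent_shift(0.0) == 0.0

    def test_half_delta_closed_form(self):
        # oracle: sqrt(2) * Phi^-1(0.75) computed independently
        assert calibrate_latent_shift(0.5) == pytest.approx(
            np.sqrt(2) * sps.norm.ppf(0.75), abs=1e-12
        )
        assert calibrate_latent_shift(0.5) == pytest.approx(0.9539, abs=1e-4)

    @pytest.mark.parametrize("bad", [1.0, -1.0, 1.5])
    def test_unattainable_delta(self, bad):
        with pytest.raises(UnattainableShiftError):
            calibrate_latent_shift(bad)

    @pytest.mark.parametrize("target", [-0.62, -0.3, 0.0, 0.24, 0.8])
    def test_calibration_identity_monte_carlo(self, target):
        """Sample Cliff's delta at n=10^4/arm recovers the target within 0.02."""
        d = calibrate_latent_shift(target)
        c, t = gen_two_group(10_000, 10_000, d, sd=1.0, seed=abs(int(target * 100)) + 1)
        assert cliffs_delta(GroupData(c, t)) == pytest.approx(target, abs=0.02)


class TestTrajectory:
    def test_sample_count_and_bounds(self):
        traj = gen_trajectory(10.0, WalkParams(sample_rate=10.0), seed=5)
        assert len(traj) == 100
        assert traj.x.min() >= 0 and traj.x.max() <= 20
        assert traj.y.min() >= 0 and traj.y.max() <= 22
        assert np.allclose(np.diff(traj.t), 0.1)

    def test_always_paused_is_immobile(self):
        traj = gen_trajectory(10.0, WalkParams(pause_probability=1.0), seed=1)
        assert np.all(traj.x == traj.x[0]) and np.all(traj.y == traj.y[0])
        assert activity_index(traj) == 0.0

    def test_never_paused_fast_walk_is_fully_active(self):
        params = WalkParams(pause_probability=0.0, move_speed_mean=5.0, sample_rate=10.0)
        traj = gen_trajectory(20.0, params, seed=2)
        assert activity_index(traj) == 1.0

    def test_invalid_duration(self):
        with pytest.raises(InvalidParameterError):
            gen_trajectory(0.0, seed=0)

    def test_walk_params_validation(self):
        with pytest.raises(InvalidParameterError):
            WalkParams(pause_probability=1.5)
        with pytest.raises(InvalidParameterError):
            WalkParams(sample_rate=0)


class TestSnacSession:
    def test_default_epoch_structure(self):
        """Six food presentations of at most 100 s separated by 120 s."""
        session = gen_snac_session(seed=11)
        assert len(session.epochs) == 6
        for start, on, off in session.epochs:
            assert start == on
            assert 0 < off - on <= 100.0
        for k in range(5):
            gap = session.epochs[k + 1][0] - session.epochs[k][2]
            assert gap == pytest.approx(120.0)

    def test_beeline_enters_every_epoch(self):
        from flyassay import snac_metrics

        session = gen_snac_session(alcove_bias=1.0, seed=2)
        metrics = snac_metrics(session)
        assert metrics.entries == 6
        assert metrics.task_performance == 1.0

    def test_paused_fly_never_enters(self):
        from flyassay import snac_metrics

        session = gen_snac_session(
            walk=WalkParams(pause_probability=1.0), alcove_bias=0.0, seed=3
        )
        metrics = snac_metrics(session)
        assert metrics.entries == 0
        assert all(r.censored for r in metrics.records)

    def test_alcove_outside_arena_rejected(self):
        from shapely.geometry import box

        with pytest.raises(GeometryError):
            gen_snac_session(seed=0, alcove=box(25, 25, 30, 30))


class TestAssayBundle:
    def test_fixed_seed_reproducible(self, tmp_path):
        cfg = ScenarioConfig(n_c=8, n_t=8, seed=5, drivers=["TH"])
        for sub in ("a", "b"):
            gen_assay_bundle(cfg).write(tmp_path / sub)
        for name in ("raw_assays.csv", "behavioural_metrics.csv", "bundle_meta.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_all_metrics_present(self):
        bundle = gen_assay_bundle(ScenarioConfig(n_c=5, n_t=5, seed=1, drivers=["TH", "Trh"]))
        from flyassay.assays import extract_metrics

        tidy = extract_metrics(bundle.raw, bundle.meta)
        produced = set(tidy["metric"]) | set(bundle.behavioural["metric"])
        assert produced == set(METRICS)

    def test_adding_a_driver_does_not_perturb_existing_streams(self):
        one = gen_assay_bundle(ScenarioConfig(n_c=6, n_t=6, seed=9, drivers=["TH"]))
        two = gen_assay_bundle(ScenarioConfig(n_c=6, n_t=6, seed=9, drivers=["TH", "Ddc"]))
        th_one = one.raw[one.raw.driver == "TH"].reset_index(drop=True)
        th_two = two.raw[two.raw.driver == "TH"].reset_index(drop=True)
        assert th_one.equals(th_two)

    def test_zero_group_size_rejected(self):
        with pytest.raises(Exception):
            ScenarioConfig(n_c=0, n_t=5)

    def test_unknown_metric_key_rejected(self):
        with pytest.raises(Exception):
            ScenarioConfig(true_smd={"not_a_metric": 1.0})

    def test_null_config_recovers_no_effects_at_large_n(self):
        """Zero-effect scenario at n=2000/arm: |g-hat| < 0.1 for all 14 metrics."""
        from flyassay.assays import extract_metrics

        cfg = ScenarioConfig(n_c=2000, n_t=2000, seed=13, drivers=["TH"])
        bundle = gen_assay_bundle(cfg)
        import pandas as pd

        tidy = pd.concat(
            [extract_metrics(bundle.raw, bundle.meta), bundle.behavioural], ignore_index=True
        )
        for metric, sub in tidy.groupby("metric"):
            c = sub.loc[sub.condition == "uninduced", "value"].to_numpy(float)
            t = sub.loc[sub.condition == "induced", "value"].to_numpy(float)
            assert abs(hedges_g(GroupData(c, t))) < 0.1, metric

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text("n_c: 12\nn_t: 9\nseed: 3\ntrue_smd:\n  activity: -1.24\n")
        cfg = ScenarioConfig.from_yaml(path)
        assert (cfg.n_c, cfg.n_t, cfg.seed) == (12, 9, 3)
        assert cfg.smd_for("activity", "TH") == -1.24
        assert cfg.smd_for("climbing", "TH") == 0.0
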