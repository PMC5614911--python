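"""Derived metrics and the scenario registry."""

import math

import numpy as np
import pytest

from myomirnet.engines import Trajectory
from myomirnet.scenarios import (
    CLAIM_MANIFEST,
    DAY,
    NO_SWITCH,
    NOT_RECOVERED,
    SCENARIOS,
    UndefinedMetricError,
    anti_correlation,
    parameter_scan,
    percent_reduction,
    recovery_time,
    run_scenario,
    switch_detector,
)


def _traj(times, **series):
    arrs = {k: np.asarray(v, dtype=float) for k, v in series.items()}
    return Trajectory(np.asarray(times, dtype=float), arrs)


class TestPercentReduction:
    def test_identity_is_zero(self):
        t = [0.0, 10.0]
        ref = _traj(t, X=[400, 400])
        alt = _traj(t, X=[400, 400])
        assert percent_reduction(ref, alt, "X", 10.0) == 0.0

    def test_hand_arithmetic(self):
        t = [0.0, 10.0]
        ref = _traj(t, X=[400, 400])
        alt = _traj(t, X=[400, 240])
        assert percent_reduction(ref, alt, "X", 10.0) == pytest.approx(40.0)

    def test_increase_is_negative(self):
        t = [0.0, 10.0]
        assert percent_reduction(
            _traj(t, X=[1, 100]), _traj(t, X=[1, 150]), "X", 10.0
        ) == pytest.approx(-50.0)

    def test_zero_reference_is_undefined(self):
        t = [0.0, 10.0]
        with pytest.raises(UndefinedMetricError):
            percent_reduction(_traj(t, X=[1, 0]), _traj(t, X=[1, 1]), "X", 10.0)


class TestAntiCorrelation:
    def test_exact_anti_correlation(self):
        t = np.linspace(0, 9, 10)
        a = np.linspace(0, 100, 10)
        traj = _traj(t, A=a, B=500.0 - a)
        assert anti_correlation(traj, "A", "B") == pytest.approx(-1.0)

    def test_identical_series_is_plus_one(self):
        t = np.linspace(0, 9, 10)
        a = np.sin(t) * 10 + 20
        traj = _traj(t, A=a, B=a.copy())
        assert anti_correlation(traj, "A", "B") == pytest.approx(1.0)

    def test_constant_series_is_undefined(self):
        t = np.linspace(0, 9, 10)
        traj = _traj(t, A=np.ones(10), B=np.arange(10))
        with pytest.raises(UndefinedMetricError):
            anti_correlation(traj, "A", "B")

    def test_window_restricts_the_sample(self):
        t = np.linspace(0, 9, 10)
        a = np.r_[np.linspace(0, 4, 5), np.linspace(4, 0, 5)]
        traj = _traj(t, A=a, B=-a)
        assert anti_correlation(traj, "A", "B", (0.0, 4.0)) == pytest.approx(
            -1.0
        )


class TestRecoveryTime:
    def test_constant_at_baseline_returns_zero(self):
        t = np.linspace(0, 9, 10)
        traj = _traj(t, X=np.full(10, 500.0))
        assert recovery_time(traj, "X", 500.0, 0.9) == 0.0

    def test_dip_and_recovery_at_known_index(self):
        t = np.linspace(0, 9, 10)
        x = [500, 300, 100, 60, 80, 200, 430, 460, 470, 480]
        traj = _traj(t, X=x)
        # minimum at index 3; first >= 0.9*500=450 afterwards is index 7
        assert recovery_time(traj, "X", 500.0, 0.9) == 7.0

    def test_never_recovered_sentinel(self):
        t = np.linspace(0, 9, 10)
        traj = _traj(t, X=np.linspace(500, 10, 10))
        assert recovery_time(traj, "X", 500.0, 0.9) is NOT_RECOVERED

    def test_invalid_inputs(self):
        t = [0.0, 1.0]
        traj = _traj(t, X=[1.0, 1.0])
        with pytest.raises(UndefinedMetricError):
            recovery_time(traj, "X", 0.0, 0.9)
        with pytest.raises(UndefinedMetricError):
            recovery_time(traj, "X", 1.0, 1.5)


class TestSwitchDetector:
    def test_monotone_pair_crosses_at_known_grid_time(self):
        t = np.linspace(0, 9, 10)
        off = np.linspace(1000, 0, 10)   # below 100 from index 10*0.9+... ->
        on = np.linspace(0, 200, 10)     # above 0.5*200 from index 6
        traj = _traj(t, OFF=off, ON=on)
        # off < 100 first at index 9 (off[9]=0); on > 100 from index 6
        assert switch_detector(traj, "OFF", "ON") == 9.0

    def test_no_switch_sentinel(self):
        t = np.linspace(0, 9, 10)
        traj = _traj(t, OFF=np.full(10, 900.0), ON=np.linspace(0, 10, 10))
        assert switch_detector(traj, "OFF", "ON") is NO_SWITCH

    def test_custom_thresholds(self):
        t = np.linspace(0, 9, 10)
        off = np.linspace(1000, 400, 10)
        on = np.linspace(0, 100, 10)
        traj = _traj(t, OFF=off, ON=on)
        assert switch_detector(traj, "OFF", "ON", (0.5, 0.5)) == 8.0


class TestParameterScan:
    def test_identical_values_identical_rows(self, birth_death):
        tab = parameter_scan(
            "mir378", "k_synmiR378", [0.02, 0.02], "ode",
            horizon=2 * DAY, readouts=("miR378",),
        )
        assert tab["miR378"].iloc[0] == tab["miR378"].iloc[1]

    def test_requires_two_nonnegative_values(self):
        with pytest.raises(ValueError):
            parameter_scan("mir378", "k_synmiR378", [0.02], "ode")
        with pytest.raises(ValueError):
            parameter_scan("mir378", "k_synmiR378", [0.02, -1.0], "ode")

    def test_ssa_rows_carry_dispersion(self):
        tab = parameter_scan(
            "mir378", "k_synmiR378", [0.01, 0.02], "ssa",
            horizon=1 * DAY, readouts=("miR378",), n_runs=3, seed=5,
            n_points=11,
        )
        assert {"miR378", "miR378_sd"} <= set(tab.columns)


class TestRegistry:
    REQUIRED = {
        "mir1_validation", "mir1_low_pax3", "mir1_high_pax3", "mir1_switch",
        "mir181_low", "mir181_high", "mir181_mrna_signature",
        "mir378_timecourse", "mir378_ensemble100", "mir378_msc_scan",
        "mir378_myod_scan", "mir143_transient", "mir143_sustained",
        "mir143_synth_scan_transient", "mir143_synth_scan_sustained",
        "integrated_default", "integrated_high_mir181",
        "integrated_high_mir378", "integrated_high_both",
        "integrated_high_pax3_low_mirs", "integrated_high_pax3_high_mirs",
        "integrated_mir1_boost", "integrated_mir143_scan",
        "integrated_mir378_scan",
    }

    def test_all_required_keys_registered(self):
        assert self.REQUIRED <= set(SCENARIOS)

    def test_unknown_key_error_lists_known_keys(self):
        from myomirnet.core import NetworkConfigError

        with pytest.raises(NetworkConfigError, match="mir1_validation"):
            run_scenario("not_a_scenario")

    def test_every_claim_maps_to_declared_metrics(self):
        """Coverage manifest: each published claim has asserted metrics."""
        for claim in CLAIM_MANIFEST:
            sc = SCENARIOS[claim["scenario"]]
            for metric in claim["metrics"]:
                assert metric in sc.metrics, (claim["claim"], metric)

    def test_ode_scenario_metrics_reproducible(self):
        a = run_scenario("mir1_validation").metrics
        b = run_scenario("mir1_validation").metrics
        for k in a:
            assert math.isclose(a[k], b[k], rel_tol=1e-8)

    def test_ssa_scenario_metrics_exact_under_fixed_seed(self):
        a = run_scenario("mir378_timecourse", seed=4).metrics
        b = run_scenario("mir378_timecourse", seed=4).metrics
        assert a == b

    def test_every_declared_metric_is_computed(self):
        # cheap scenarios only; the expensive ones run in the acceptance suite
        for key in ("mir1_low_pax3", "mir181_low", "mir143_transient"):
            res = run_scenario(key)
            assert set(SCENARIOS[key].metrics) <= set(res.metrics)

    def test_scenario_artifacts_written(self, tmp_path):
        res = run_scenario("mir1_low_pax3", outdir=tmp_path)
        files = {p.name for p in tmp_path.iterdir()}
        assert "mir1_low_pax3_main.csv" in files
        assert "mir1_low_pax3_metrics.txt" in files
        assert res.metrics

    def test_registry_serializes_to_plain_config(self):
        from myomirnet.scenarios import registry_to_config
        import yaml

        cfg = registry_to_config()
        text = yaml.safe_dump(cfg)
        assert "mir1_validation" in text
        back = yaml.safe_load(text)
        assert back["mir1_switch"]["overrides"]["k_synmiR1"] == 1e-3
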