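"""Named in-silico experiments and their derived metrics.

Every published simulation experiment is encoded as a registry entry:
model key, parameter/initial overrides, engine, horizon and a set of
named metrics.  Results are deterministic for ODE scenarios and
seed-reproducible for SSA/ensemble scenarios.

Metric conventions ("no effect" bands used by the claim manifest):
relative change <10% counts as unaffected, 10-30% as slight, and the
scans report final-time values on the scenario horizon (the source
figures plot time courses, not fixed points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import NetworkConfigError
from .engines import (
    EnsembleSummary,
    SolverSettings,
    Trajectory,
    run_ensemble,
    simulate_ode,
    simulate_ssa,
)
from .models import get_model

__all__ = [
    "HOUR",
    "DAY",
    "UndefinedMetricError",
    "percent_reduction",
    "anti_correlation",
    "recovery_time",
    "switch_detector",
    "parameter_scan",
    "Scenario",
    "ScenarioResult",
    "SCENARIOS",
    "run_scenario",
    "NOT_RECOVERED",
    "NO_SWITCH",
    "CLAIM_MANIFEST",
    "registry_to_config",
]

HOUR = 3600.0
DAY = 86400.0

#: sentinels (exported so callers can test against them)
NOT_RECOVERED = math.inf
NO_SWITCH = math.inf


class UndefinedMetricError(ValueError):
    """A metric's preconditions do not hold (zero reference, constant series)."""


# ---------------------------------------------------------------------------
# metric operations
# ---------------------------------------------------------------------------


def percent_reduction(
    ref: Trajectory, alt: Trajectory, species: str, t: float
) -> float:
    """100*(1 - alt(t)/ref(t)); negative values mean an increase."""
    r = ref.at(species, t)
    if r == 0:
        raise UndefinedMetricError(
            f"reference value of {species!r} at t={t} is 0"
        )
    return 100.0 * (1.0 - alt.at(species, t) / r)


def anti_correlation(
    traj: Trajectory,
    a: str,
    b: str,
    window: tuple[float, float] | None = None,
) -> float:
    """Pearson correlation of two series over a time window, in [-1, 1]."""
    t0, t1 = window if window else (traj.times[0], traj.times[-1])
    mask = (traj.times >= t0) & (traj.times <= t1)
    xa = np.asarray(traj.series(a), dtype=float)[mask]
    xb = np.asarray(traj.series(b), dtype=float)[mask]
    if xa.std() == 0 or xb.std() == 0:
        raise UndefinedMetricError(
            f"constant series in window for {a!r}/{b!r}"
        )
    return float(np.corrcoef(xa, xb)[0, 1])


def recovery_time(
    traj: Trajectory, species: str, baseline: float, fraction: float
) -> float:
    """First grid time after the series minimum with value >= fraction*baseline.

    Returns :data:`NOT_RECOVERED` (inf) if the level is never regained
    within the trajectory.  A series that never dips returns 0.
    """
    if baseline <= 0:
        raise UndefinedMetricError("baseline must be > 0")
    if not 0 < fraction <= 1:
        raise UndefinedMetricError("fraction must be in (0, 1]")
    vals = np.asarray(traj.series(species), dtype=float)
    i_min = int(np.argmin(vals))
    after = vals[i_min:]
    hits = np.nonzero(after >= fraction * baseline)[0]
    if hits.size == 0:
        return NOT_RECOVERED
    return float(traj.times[i_min + hits[0]])


def switch_detector(
    traj: Trajectory,
    off_species: str,
    on_species: str,
    thresholds: tuple[float, float] = (0.1, 0.5),
) -> float:
    """Earliest time the circuit has flipped state.

    ``off_species`` must have fallen below ``thresholds[0]`` of its
    initial level while ``on_species`` has risen above ``thresholds[1]``
    of its trajectory maximum.  Returns :data:`NO_SWITCH` (inf) when the
    condition is never met.
    """
    off_frac, on_frac = thresholds
    off = np.asarray(traj.series(off_species), dtype=float)
    on = np.asarray(traj.series(on_species), dtype=float)
    off0 = off[0]
    on_max = on.max()
    if off0 <= 0 or on_max <= 0:
        return NO_SWITCH
    flipped = (off < off_frac * off0) & (on > on_frac * on_max)
    idx = np.nonzero(flipped)[0]
    if idx.size == 0:
        return NO_SWITCH
    return float(traj.times[idx[0]])


def parameter_scan(
    model_key: str,
    parameter: str,
    values: Sequence[float],
    engine: str = "ode",
    horizon: float = 10 * DAY,
    readouts: Sequence[str] = (),
    base_overrides: Mapping[str, float] | None = None,
    n_points: int = 201,
    n_runs: int = 5,
    seed: int = 1,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Endpoint readouts at the scan horizon, one row per parameter value.

    Deterministic for the ODE engine; for SSA each row carries the mean
    and standard deviation over ``n_runs`` replicates.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 scan values")
    if any(v < 0 for v in values):
        raise ValueError("scan values must be >= 0")
    rows = []
    for v in values:
        ov = dict(base_overrides or {})
        ov[parameter] = v
        net = get_model(model_key, ov)
        row: dict[str, float] = {parameter: v}
        if engine == "ode":
            traj = simulate_ode(net, horizon, n_points, settings)
            for r in readouts:
                row[r] = traj.at(r, horizon)
        elif engine == "ssa":
            ends = {r: [] for r in readouts}
            for i in range(n_runs):
                traj = simulate_ssa(
                    net, horizon, n_points=n_points, seed=seed + i
                )
                for r in readouts:
                    ends[r].append(traj.at(r, horizon))
            for r in readouts:
                row[r] = float(np.mean(ends[r]))
                row[f"{r}_sd"] = float(np.std(ends[r]))
        else:
            raise ValueError(f"unknown scan engine {engine!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def _monotone(series: Sequence[float], direction: str, tol: float = 0.0) -> bool:
    d = np.diff(np.asarray(series, dtype=float))
    if direction == "nonincreasing":
        return bool(np.all(d <= tol))
    if direction == "nondecreasing":
        return bool(np.all(d >= -tol))
    raise ValueError(direction)


# ---------------------------------------------------------------------------
# scenario registry
# ---------------------------------------------------------------------------

HIGH_PAX3 = {
    "Pax3": 1000, "Pax3_mRNA": 400, "k_synPax3": 6.0e-5,
    "k_synPax3mRNA": 0.08,
}
HIGH_MIR181 = {"miR181": 1000, "k_synmiR181": 6e-4}
HIGH_MIR378 = {"miR378": 3000, "k_synmiR378basal": 6e-4}
SUSTAINED_IL6 = {"k_degIL6": 1e-6}
MIR1_NULL = {"miR1": 0, "k_synmiR1": 0.0, "k_synmiR1MyoD": 0.0}
MIR143_SCAN_VALUES = (1.25e-3, 2.5e-3, 5e-3, 1e-2, 2e-2)
MIR143_INT_SCAN_VALUES = (2.5e-3, 5e-3, 1e-2, 2e-2, 4e-2)
BINDING_SCAN_VALUES = (5e-7, 1e-6, 2e-6, 4e-6, 8e-6)
MIR378_SYN_SCAN_VALUES = (2.5e-3, 5e-3, 1e-2, 2e-2, 4e-2)


@dataclass(frozen=True)
class Scenario:
    """A named experiment: model + overrides + engine + declared metrics."""

    key: str
    model: str
    engine: str  # "ode" | "ssa" | "ensemble"
    horizon: float
    overrides: Mapping[str, float] = field(default_factory=dict)
    ref_overrides: Mapping[str, float] | None = None
    readouts: tuple[str, ...] = ()
    metrics: tuple[str, ...] = ()
    n_points: int = 201
    n_runs: int = 1
    description: str = ""


@dataclass
class ScenarioResult:
    key: str
    trajectories: dict[str, Trajectory]
    metrics: dict[str, float]
    provenance: dict
    ensemble: EnsembleSummary | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, traj in self.trajectories.items():
            traj.to_csv(out / f"{self.key}_{name}.csv")
        if self.ensemble is not None:
            self.ensemble.to_csv(out / f"{self.key}_ensemble.csv")
        for name, tab in self.tables.items():
            tab.to_csv(out / f"{self.key}_{name}.csv", index=False)
        report = out / f"{self.key}_metrics.txt"
        with report.open("w") as fh:
            for k in sorted(self.metrics):
                fh.write(f"{k}\t{self.metrics[k]!r}\n")


def _S(**kw) -> Scenario:
    return Scenario(**kw)


SCENARIOS: dict[str, Scenario] = {
    s.key: s
    for s in [
        _S(
            key="mir1_validation", model="mir1", engine="ode",
            horizon=48 * HOUR, overrides={}, ref_overrides=MIR1_NULL,
            readouts=("Pax3", "Pax3_mRNA_total", "miR1", "MyoD"),
            metrics=(
                "pax3_mrna_reduction_48h_pct",
                "pax3_protein_reduction_48h_pct",
            ),
            description="miR-1 present (MyoD-induced) vs absent, 48 h readout",
        ),
        _S(
            key="mir1_low_pax3", model="mir1", engine="ode",
            horizon=10 * DAY,
            readouts=("Pax3", "MyoD", "miR1"),
            metrics=(
                "pax3_end", "myod_end", "mir1_end", "pax3_end_over_initial"
            ),
            description="default parameters: low-Pax3 / high-MyoD regime",
        ),
        _S(
            key="mir1_high_pax3", model="mir1", engine="ode",
            horizon=10 * DAY, overrides=HIGH_PAX3,
            readouts=("Pax3", "MyoD", "miR1"),
            metrics=(
                "pax3_end", "myod_end", "mir1_end", "pax3_end_over_initial",
                "switch_time_s",
            ),
            description="high Pax3: MyoD and miR-1 stay low, no switch",
        ),
        _S(
            key="mir1_switch", model="mir1", engine="ode",
            horizon=10 * DAY, overrides={**HIGH_PAX3, "k_synmiR1": 1e-3},
            readouts=("Pax3", "MyoD", "miR1"),
            metrics=(
                "switch_time_s", "pax3_end_over_initial", "myod_end",
                "mir1_end", "pax3_monotone_after_peak",
            ),
            description="high Pax3 + raised basal miR-1: switch to"
            " differentiation",
        ),
        _S(
            key="mir181_low", model="mir181", engine="ode",
            horizon=10 * DAY,
            readouts=("HoxA11_protein", "Sirt1_protein", "MyoD", "Mafbx"),
            metrics=("hoxa11_end", "sirt1_end", "myod_end", "mafbx_end"),
            description="default: Hox-A11/Sirt-1 high, MyoD and Mafbx low",
        ),
        _S(
            key="mir181_high", model="mir181", engine="ode",
            horizon=10 * DAY, overrides=HIGH_MIR181,
            readouts=("HoxA11_protein", "Sirt1_protein", "MyoD", "Mafbx"),
            metrics=("hoxa11_end", "sirt1_end", "myod_end", "mafbx_end"),
            description="high miR-181: Hox-A11/Sirt-1 fall, MyoD/Mafbx rise",
        ),
        _S(
            key="mir181_mrna_signature", model="mir181", engine="ode",
            horizon=10 * DAY, overrides=HIGH_MIR181, ref_overrides={},
            readouts=(
                "HoxA11_protein", "Sirt1_protein", "HoxA11_mRNA_total",
                "Sirt1_mRNA_total", "MyoD", "Mafbx",
            ),
            metrics=(
                "hoxa11_protein_reduction_pct", "sirt1_protein_reduction_pct",
                "hoxa11_mrna_change_pct", "sirt1_mrna_change_pct",
                "myod_change_pct", "mafbx_change_pct",
            ),
            description="protein falls, transcript untouched (the published"
            " mRNA/protein signature)",
        ),
        _S(
            key="mir378_timecourse", model="mir378", engine="ssa",
            horizon=10 * DAY,
            readouts=("miR378", "Msc", "Msc_mRNA_total"),
            metrics=("anti_correlation", "mir378_end", "msc_end"),
            description="single stochastic run: miR-378 up, Msc down",
        ),
        _S(
            key="mir378_ensemble100", model="mir378", engine="ensemble",
            horizon=10 * DAY, n_runs=100,
            readouts=("miR378", "Msc"),
            metrics=(
                "ensemble_ode_coverage_mir378", "ensemble_ode_coverage_msc",
                "n_runs",
            ),
            description="100-run ensemble mean/sd vs the deterministic run",
        ),
        _S(
            key="mir378_msc_scan", model="mir378", engine="ode",
            horizon=10 * DAY,
            readouts=("miR378", "Msc_mRNA_total"),
            metrics=(
                "mir378_monotone_nonincreasing",
                "msc_mrna_monotone_nondecreasing",
            ),
            description="raising the Msc:promoter binding rate lowers miR-378",
        ),
        _S(
            key="mir378_myod_scan", model="mir378", engine="ode",
            horizon=10 * DAY,
            readouts=("miR378", "Msc_mRNA_total"),
            metrics=(
                "mir378_monotone_nondecreasing",
                "msc_mrna_monotone_nonincreasing",
            ),
            description="raising the MyoD:promoter binding rate raises miR-378",
        ),
        _S(
            key="mir143_transient", model="mir143", engine="ode",
            horizon=21 * DAY,
            readouts=("miR143", "IL6", "Igfbp5_protein", "Myogenin"),
            metrics=(
                "mir143_baseline", "recovery_time_days",
                "mir143_day21_over_baseline", "myogenin_end",
            ),
            description="injury pulse of IL-6; miR-143 dips then recovers",
        ),
        _S(
            key="mir143_sustained", model="mir143", engine="ode",
            horizon=21 * DAY, overrides=SUSTAINED_IL6,
            readouts=("miR143", "IL6", "Igfbp5_protein", "Myogenin"),
            metrics=(
                "mir143_baseline", "recovery_time_days",
                "mir143_day21_over_baseline", "myogenin_end",
            ),
            description="chronic IL-6 (k_degIL6=1e-6): miR-143 stays low",
        ),
        _S(
            key="mir143_synth_scan_transient", model="mir143", engine="ode",
            horizon=21 * DAY,
            readouts=("miR143",),
            metrics=(
                "mir143_endpoint_spread_over_baseline",
                "mir143_monotone_nondecreasing",
            ),
            description="k_synmiR143 scan with transient IL-6: responsive",
        ),
        _S(
            key="mir143_synth_scan_sustained", model="mir143", engine="ode",
            horizon=21 * DAY, overrides=SUSTAINED_IL6,
            readouts=("miR143",),
            metrics=(
                "mir143_endpoint_spread_over_baseline",
                "mir143_monotone_nondecreasing",
            ),
            description="k_synmiR143 scan with sustained IL-6: flat",
        ),
        _S(
            key="integrated_default", model="integrated", engine="ode",
            horizon=21 * DAY,
            readouts=("Pax3", "MyoD", "miR1", "HoxA11_protein", "Msc_protein"),
            metrics=(
                "myod_end", "pax3_end", "hoxa11_end", "mir1_end", "msc_end"
            ),
            description="all defaults: MyoD low despite low Pax3 (Hox-A11 high)",
        ),
        _S(
            key="integrated_high_mir181", model="integrated", engine="ode",
            horizon=21 * DAY, overrides=HIGH_MIR181,
            readouts=(
                "Pax3", "MyoD", "miR1", "HoxA11_protein", "Msc_protein",
                "miR378", "miR143",
            ),
            metrics=(
                "myod_end", "pax3_end", "hoxa11_end", "mir1_end", "msc_end",
                "mir378_end", "mir143_end",
            ),
            description="high miR-181 restores MyoD and raises miR-1",
        ),
        _S(
            key="integrated_high_mir378", model="integrated", engine="ode",
            horizon=21 * DAY, overrides=HIGH_MIR378,
            readouts=("Pax3", "MyoD", "miR1", "HoxA11_protein", "Msc_protein"),
            metrics=("myod_end", "mir1_end", "msc_end", "hoxa11_end"),
            description="high miR-378 with low miR-181: modest miR-1 gain",
        ),
        _S(
            key="integrated_high_both", model="integrated", engine="ode",
            horizon=21 * DAY, overrides={**HIGH_MIR181, **HIGH_MIR378},
            readouts=("Pax3", "MyoD", "miR1", "Msc_protein"),
            metrics=("myod_end", "mir1_end", "msc_end"),
            description="high miR-181 + miR-378: miR-1 highest",
        ),
        _S(
            key="integrated_high_pax3_low_mirs", model="integrated",
            engine="ode", horizon=21 * DAY, overrides=HIGH_PAX3,
            readouts=("Pax3", "MyoD", "miR1"),
            metrics=("myod_end", "pax3_end", "mir1_end"),
            description="high Pax3, low miR-181/miR-378: MyoD very low",
        ),
        _S(
            key="integrated_high_pax3_high_mirs", model="integrated",
            engine="ode", horizon=21 * DAY,
            overrides={**HIGH_PAX3, **HIGH_MIR181, **HIGH_MIR378},
            readouts=("Pax3", "MyoD", "miR1", "miR378", "miR143"),
            metrics=(
                "myod_end", "pax3_end", "mir1_end", "mir143_end",
                "pax3_day2", "myod_day2",
            ),
            description="high Pax3 rescued by miR-181 + miR-378",
        ),
        _S(
            key="integrated_mir1_boost", model="integrated", engine="ode",
            horizon=21 * DAY,
            overrides={
                **HIGH_PAX3, **HIGH_MIR181, **HIGH_MIR378,
                "miR1": 1000, "k_synmiR1": 1e-3,
            },
            readouts=("Pax3", "MyoD", "miR1"),
            metrics=("myod_end", "pax3_day2", "myod_day2", "mir1_end"),
            description="extra miR-1 at t=0: faster Pax3 decline and"
            " earlier MyoD recovery",
        ),
        _S(
            key="integrated_mir143_scan", model="integrated", engine="ode",
            horizon=21 * DAY, overrides={**HIGH_MIR181, **HIGH_MIR378},
            readouts=("miR143",),
            metrics=(
                "transient_monotone_nondecreasing",
                "transient_spread_over_baseline",
                "sustained_monotone_flat_spread",
            ),
            description="k_synmiR143MyoD scan in both IL-6 regimes (high"
            " miR-181/miR-378 background)",
        ),
        _S(
            key="integrated_mir378_scan", model="integrated", engine="ode",
            horizon=21 * DAY, overrides=HIGH_MIR181,
            readouts=("Msc_protein", "miR1", "MyoD", "miR181", "miR143"),
            metrics=(
                "msc_low_vs_default_pct", "mir1_low_vs_default_pct",
                "myod_low_vs_default_pct", "mir181_low_vs_default_pct",
                "mir1_monotone_nondecreasing",
            ),
            description="k_synmiR378 scan: Msc up / miR-1 down when miR-378"
            " transcription falls, MyoD and miR-181 unchanged",
        ),
    ]
}


# ---------------------------------------------------------------------------
# scenario execution
# ---------------------------------------------------------------------------


def _run_engine(
    sc: Scenario,
    overrides: Mapping[str, float],
    seed: int,
    settings: SolverSettings | None,
) -> Trajectory:
    net = get_model(sc.model, overrides)
    if sc.engine in ("ode",):
        return simulate_ode(
            net, sc.horizon, sc.n_points, settings,
            overrides_meta=overrides,
        )
    if sc.engine == "ssa":
        return simulate_ssa(
            net, sc.horizon, n_points=sc.n_points, seed=seed,
            overrides_meta=overrides,
        )
    raise ValueError(f"scenario {sc.key!r}: unsupported engine {sc.engine!r}")


def _pct_change(ref: Trajectory, alt: Trajectory, name: str, t: float) -> float:
    """Signed percent change alt vs ref at time t (+ = increase)."""
    r = ref.at(name, t)
    if r == 0:
        raise UndefinedMetricError(f"reference {name!r} is 0 at t={t}")
    return 100.0 * (alt.at(name, t) / r - 1.0)


def _monotone_after_peak(traj: Trajectory, name: str, rel_tol: float = 1e-6) -> float:
    """1.0 if the series is non-increasing after its global maximum."""
    v = np.asarray(traj.series(name), dtype=float)
    i = int(np.argmax(v))
    tail = v[i:]
    ok = bool(np.all(np.diff(tail) <= rel_tol * max(v.max(), 1.0)))
    return 1.0 if ok else 0.0


def _half_time_days(traj: Trajectory, name: str) -> float:
    v = np.asarray(traj.series(name), dtype=float)
    if v[0] <= 0:
        raise UndefinedMetricError(f"{name!r} starts at 0")
    idx = np.nonzero(v < 0.5 * v[0])[0]
    return float(traj.times[idx[0]] / DAY) if idx.size else math.inf


def run_scenario(
    key: str,
    seed: int = 1,
    settings: SolverSettings | None = None,
    outdir: str | Path | None = None,
) -> ScenarioResult:
    """Execute a registered scenario and compute its declared metrics.

    Deterministic: ODE metrics are reproducible to solver precision,
    SSA/ensemble metrics exactly reproducible for a fixed ``seed``.
    """
    try:
        sc = SCENARIOS[key]
    except KeyError:
        raise NetworkConfigError(
            f"unknown scenario {key!r}; known: {sorted(SCENARIOS)}"
        ) from None

    trajectories: dict[str, Trajectory] = {}
    tables: dict[str, pd.DataFrame] = {}
    ensemble: EnsembleSummary | None = None
    m: dict[str, float] = {}

    if sc.engine in ("ode", "ssa"):
        traj = _run_engine(sc, sc.overrides, seed, settings)
        trajectories["main"] = traj
    if sc.ref_overrides is not None:
        ref = _run_engine(sc, sc.ref_overrides, seed + 1, settings)
        trajectories["reference"] = ref

    H = sc.horizon

    if key == "mir1_validation":
        ref, alt = trajectories["reference"], trajectories["main"]
        m["pax3_mrna_reduction_48h_pct"] = percent_reduction(
            ref, alt, "Pax3_mRNA_total", 48 * HOUR
        )
        m["pax3_protein_reduction_48h_pct"] = percent_reduction(
            ref, alt, "Pax3", 48 * HOUR
        )
    elif key in ("mir1_low_pax3", "mir1_high_pax3", "mir1_switch"):
        traj = trajectories["main"]
        m["pax3_end"] = traj.at("Pax3", H)
        m["myod_end"] = traj.at("MyoD", H)
        m["mir1_end"] = traj.at("miR1", H)
        m["pax3_end_over_initial"] = traj.at("Pax3", H) / traj.series("Pax3")[0]
        if key in ("mir1_high_pax3", "mir1_switch"):
            m["switch_time_s"] = switch_detector(traj, "Pax3", "MyoD")
        if key == "mir1_switch":
            m["pax3_monotone_after_peak"] = _monotone_after_peak(traj, "Pax3")
    elif key in ("mir181_low", "mir181_high"):
        traj = trajectories["main"]
        m["hoxa11_end"] = traj.at("HoxA11_protein", H)
        m["sirt1_end"] = traj.at("Sirt1_protein", H)
        m["myod_end"] = traj.at("MyoD", H)
        m["mafbx_end"] = traj.at("Mafbx", H)
    elif key == "mir181_mrna_signature":
        ref, alt = trajectories["reference"], trajectories["main"]
        m["hoxa11_protein_reduction_pct"] = percent_reduction(
            ref, alt, "HoxA11_protein", H
        )
        m["sirt1_protein_reduction_pct"] = percent_reduction(
            ref, alt, "Sirt1_protein", H
        )
        m["hoxa11_mrna_change_pct"] = _pct_change(ref, alt, "HoxA11_mRNA_total", H)
        m["sirt1_mrna_change_pct"] = _pct_change(ref, alt, "Sirt1_mRNA_total", H)
        m["myod_change_pct"] = _pct_change(ref, alt, "MyoD", H)
        m["mafbx_change_pct"] = _pct_change(ref, alt, "Mafbx", H)
    elif key == "mir378_timecourse":
        traj = trajectories["main"]
        m["anti_correlation"] = anti_correlation(traj, "miR378", "Msc")
        m["mir378_end"] = traj.at("miR378", H)
        m["msc_end"] = traj.at("Msc", H)
    elif key == "mir378_ensemble100":
        net = get_model(sc.model, sc.overrides)
        grid = np.linspace(0.0, H, sc.n_points)
        ensemble = run_ensemble(
            net, H, grid, n_runs=sc.n_runs, base_seed=seed
        )
        ode = simulate_ode(net, H, sc.n_points, settings)
        for label, species in (("mir378", "miR378"), ("msc", "Msc")):
            band = 3.0 * ensemble.sd[species] / math.sqrt(sc.n_runs)
            dev = np.abs(ensemble.mean[species] - ode.series(species))
            m[f"ensemble_ode_coverage_{label}"] = float(
                np.mean(dev <= band + 1e-12)
            )
        m["n_runs"] = float(sc.n_runs)
    elif key in ("mir378_msc_scan", "mir378_myod_scan"):
        param = (
            "k_binMscmiR378gene"
            if key == "mir378_msc_scan"
            else "k_binMyoDmiR378gene"
        )
        tab = parameter_scan(
            sc.model, param, BINDING_SCAN_VALUES, "ode", H,
            ("miR378", "Msc_mRNA_total"), settings=settings,
        )
        tables["scan"] = tab
        if key == "mir378_msc_scan":
            m["mir378_monotone_nonincreasing"] = float(
                _monotone(tab["miR378"], "nonincreasing")
            )
            m["msc_mrna_monotone_nondecreasing"] = float(
                _monotone(tab["Msc_mRNA_total"], "nondecreasing")
            )
        else:
            m["mir378_monotone_nondecreasing"] = float(
                _monotone(tab["miR378"], "nondecreasing")
            )
            m["msc_mrna_monotone_nonincreasing"] = float(
                _monotone(tab["Msc_mRNA_total"], "nonincreasing")
            )
    elif key in ("mir143_transient", "mir143_sustained"):
        traj = trajectories["main"]
        net = get_model(sc.model, sc.overrides)
        baseline = (
            net.parameters["k_synmiR143"] / net.parameters["k_degmiR143"]
        )
        m["mir143_baseline"] = baseline
        rec = recovery_time(traj, "miR143", baseline, 0.9)
        m["recovery_time_days"] = rec / DAY if math.isfinite(rec) else rec
        m["mir143_day21_over_baseline"] = traj.at("miR143", 21 * DAY) / baseline
        m["myogenin_end"] = traj.at("Myogenin", H)
    elif key in ("mir143_synth_scan_transient", "mir143_synth_scan_sustained"):
        tab = parameter_scan(
            sc.model, "k_synmiR143", MIR143_SCAN_VALUES, "ode", H,
            ("miR143",), base_overrides=sc.overrides, settings=settings,
        )
        tables["scan"] = tab
        net = get_model(sc.model, sc.overrides)
        baseline = (
            net.parameters["k_synmiR143"] / net.parameters["k_degmiR143"]
        )
        spread = float(tab["miR143"].max() - tab["miR143"].min())
        m["mir143_endpoint_spread_over_baseline"] = spread / baseline
        m["mir143_monotone_nondecreasing"] = float(
            _monotone(tab["miR143"], "nondecreasing")
        )
    elif key in (
        "integrated_default", "integrated_high_mir181",
        "integrated_high_mir378", "integrated_high_both",
        "integrated_high_pax3_low_mirs", "integrated_high_pax3_high_mirs",
        "integrated_mir1_boost",
    ):
        traj = trajectories["main"]
        getters = {
            "myod_end": "MyoD", "pax3_end": "Pax3", "mir1_end": "miR1",
            "hoxa11_end": "HoxA11_protein", "msc_end": "Msc_protein",
            "mir378_end": "miR378", "mir143_end": "miR143",
        }
        for mk in sc.metrics:
            if mk in getters:
                m[mk] = traj.at(getters[mk], H)
            elif mk == "pax3_half_time_days":
                m[mk] = _half_time_days(traj, "Pax3")
            elif mk == "pax3_day2":
                m[mk] = traj.at("Pax3", 2 * DAY)
            elif mk == "myod_day2":
                m[mk] = traj.at("MyoD", 2 * DAY)
    elif key == "integrated_mir143_scan":
        out = {}
        for regime, extra in (
            ("transient", {}), ("sustained", SUSTAINED_IL6)
        ):
            tab = parameter_scan(
                sc.model, "k_synmiR143MyoD", MIR143_INT_SCAN_VALUES, "ode",
                H, ("miR143",),
                base_overrides={**sc.overrides, **extra}, settings=settings,
            )
            tables[f"scan_{regime}"] = tab
            out[regime] = tab
        net = get_model(sc.model, sc.overrides)
        baseline = (
            net.parameters["k_synmiR143MyoD"] / net.parameters["k_degmiR143"]
        )
        m["transient_monotone_nondecreasing"] = float(
            _monotone(out["transient"]["miR143"], "nondecreasing")
        )
        m["transient_spread_over_baseline"] = float(
            out["transient"]["miR143"].max()
            - out["transient"]["miR143"].min()
        ) / baseline
        m["sustained_monotone_flat_spread"] = float(
            out["sustained"]["miR143"].max()
            - out["sustained"]["miR143"].min()
        ) / baseline
    elif key == "integrated_mir378_scan":
        tab = parameter_scan(
            sc.model, "k_synmiR378", MIR378_SYN_SCAN_VALUES, "ode", H,
            ("Msc_protein", "miR1", "MyoD", "miR181", "miR143"),
            base_overrides=sc.overrides, settings=settings,
        )
        tables["scan"] = tab
        default_val = get_model(sc.model).parameters["k_synmiR378"]
        i_def = int(
            np.argmin(np.abs(tab["k_synmiR378"].to_numpy() - default_val))
        )
        lo, de = tab.iloc[0], tab.iloc[i_def]
        for label, col in (
            ("msc", "Msc_protein"), ("mir1", "miR1"), ("myod", "MyoD"),
            ("mir181", "miR181"),
        ):
            m[f"{label}_low_vs_default_pct"] = float(
                100.0 * (lo[col] / de[col] - 1.0)
            )
        m["mir1_monotone_nondecreasing"] = float(
            _monotone(tab["miR1"], "nondecreasing")
        )
    else:  # pragma: no cover
        raise NotImplementedError(key)

    missing = [mk for mk in sc.metrics if mk not in m]
    if missing:  # invariant: every declared metric must be computed
        raise RuntimeError(f"scenario {key!r}: metrics not computed {missing}")

    result = ScenarioResult(
        key=key,
        trajectories=trajectories,
        metrics=m,
        provenance={
            "seed": seed,
            "overrides": dict(sc.overrides),
            "engine": sc.engine,
            "horizon_s": sc.horizon,
            "settings": settings or SolverSettings(),
        },
        ensemble=ensemble,
        tables=tables,
    )
    if outdir is not None:
        result.write(outdir)
    return result


def registry_to_config() -> dict:
    """Registry as a plain dict (YAML/JSON-serializable)."""
    return {
        k: {
            "model": s.model,
            "engine": s.engine,
            "horizon_s": s.horizon,
            "overrides": dict(s.overrides),
            "ref_overrides": (
                dict(s.ref_overrides) if s.ref_overrides is not None else None
            ),
            "readouts": list(s.readouts),
            "metrics": list(s.metrics),
            "n_points": s.n_points,
            "n_runs": s.n_runs,
            "description": s.description,
        }
        for k, s in SCENARIOS.items()
    }


#: Published-claim coverage manifest: each textual claim of the source
#: study's simulation results maps to at least one asserted metric, with
#: the quantitative band used by the test suite ("unaffected" < 10 %,
#: "slight" 10-30 %).
CLAIM_MANIFEST: tuple[dict, ...] = (
    {
        "claim": "miR-1 reduces Pax3 transcript and protein by 30-50% at 48 h",
        "scenario": "mir1_validation",
        "metrics": (
            "pax3_mrna_reduction_48h_pct", "pax3_protein_reduction_48h_pct"
        ),
        "band": "both within [30, 50]",
    },
    {
        "claim": "low Pax3 goes with high MyoD and miR-1",
        "scenario": "mir1_low_pax3",
        "metrics": ("pax3_end_over_initial", "myod_end", "mir1_end"),
        "band": "Pax3 ends <20% of start; MyoD > 500; miR-1 > 200",
    },
    {
        "claim": "high Pax3 keeps MyoD and miR-1 low; no switch",
        "scenario": "mir1_high_pax3",
        "metrics": ("switch_time_s", "pax3_end_over_initial"),
        "band": "no switch in 10 days; Pax3 ends above its start",
    },
    {
        "claim": "raised basal miR-1 flips the switch within 10 days",
        "scenario": "mir1_switch",
        "metrics": ("switch_time_s", "pax3_end_over_initial"),
        "band": "switch in (0, 10 d); Pax3 ends <10% of start",
    },
    {
        "claim": "high miR-181 halves Hox-A11/Sirt-1 protein, mRNA untouched",
        "scenario": "mir181_mrna_signature",
        "metrics": (
            "hoxa11_protein_reduction_pct", "sirt1_protein_reduction_pct",
            "hoxa11_mrna_change_pct", "sirt1_mrna_change_pct",
        ),
        "band": "protein >50% down; |mRNA change| <10%",
    },
    {
        "claim": "high miR-181 raises MyoD and Mafbx",
        "scenario": "mir181_mrna_signature",
        "metrics": ("myod_change_pct", "mafbx_change_pct"),
        "band": "both positive",
    },
    {
        "claim": "miR-378 and Msc are approximately anti-correlated",
        "scenario": "mir378_timecourse",
        "metrics": ("anti_correlation",),
        "band": "<= -0.8",
    },
    {
        "claim": "ensemble mean of 100 runs tracks the deterministic result",
        "scenario": "mir378_ensemble100",
        "metrics": (
            "ensemble_ode_coverage_mir378", "ensemble_ode_coverage_msc"
        ),
        "band": ">= 90% of grid points within 3*sd/sqrt(100)",
    },
    {
        "claim": "more Msc:promoter binding -> less miR-378, more Msc mRNA",
        "scenario": "mir378_msc_scan",
        "metrics": (
            "mir378_monotone_nonincreasing", "msc_mrna_monotone_nondecreasing"
        ),
        "band": "monotone over a 5-point scan",
    },
    {
        "claim": "more MyoD:promoter binding -> more miR-378, less Msc mRNA",
        "scenario": "mir378_myod_scan",
        "metrics": (
            "mir378_monotone_nondecreasing", "msc_mrna_monotone_nonincreasing"
        ),
        "band": "monotone over a 5-point scan",
    },
    {
        "claim": "transient IL-6: miR-143 back to >=90% of baseline by day 21",
        "scenario": "mir143_transient",
        "metrics": ("recovery_time_days",),
        "band": "<= 21 days",
    },
    {
        "claim": "sustained IL-6: miR-143 still <50% of baseline at day 21",
        "scenario": "mir143_sustained",
        "metrics": ("recovery_time_days", "mir143_day21_over_baseline"),
        "band": "not recovered; <0.5",
    },
    {
        "claim": "miR-143 synthesis scan: flat under sustained IL-6,"
        " responsive under transient",
        "scenario": "mir143_synth_scan_sustained",
        "metrics": ("mir143_endpoint_spread_over_baseline",),
        "band": "sustained spread <10% of baseline; transient >50%",
    },
    {
        "claim": "integrated defaults: MyoD low despite low Pax3 (Hox-A11"
        " high)",
        "scenario": "integrated_default",
        "metrics": ("myod_end", "hoxa11_end"),
        "band": "MyoD <5% of its high-miR-181 value",
    },
    {
        "claim": "high miR-181: Hox-A11 falls, MyoD recovers, miR-1 rises",
        "scenario": "integrated_high_mir181",
        "metrics": ("hoxa11_end", "myod_end", "mir1_end"),
        "band": ">=10x MyoD and miR-1 gain vs default",
    },
    {
        "claim": "high miR-378 alone: Msc falls, modest miR-1 gain",
        "scenario": "integrated_high_mir378",
        "metrics": ("msc_end", "mir1_end"),
        "band": "Msc down >50%; miR-1 strictly above default",
    },
    {
        "claim": "both high: miR-1 above either single overexpression",
        "scenario": "integrated_high_both",
        "metrics": ("mir1_end",),
        "band": "strictly greater",
    },
    {
        "claim": "lower miR-378 transcription: Msc protein up, miR-1 down,"
        " MyoD and miR-181 unaffected",
        "scenario": "integrated_mir378_scan",
        "metrics": (
            "msc_low_vs_default_pct", "mir1_low_vs_default_pct",
            "myod_low_vs_default_pct", "mir181_low_vs_default_pct",
        ),
        "band": "Msc >+20%; miR-1 negative; |MyoD| and |miR-181| <10%",
    },
    {
        "claim": "integrated k_synmiR143 scan mirrors the individual model"
        " per IL-6 regime",
        "scenario": "integrated_mir143_scan",
        "metrics": (
            "transient_monotone_nondecreasing",
            "transient_spread_over_baseline",
            "sustained_monotone_flat_spread",
        ),
        "band": "same monotonicity pattern; sustained flat <10%",
    },
    {
        "claim": "high Pax3 with both miRNAs high: modest MyoD recovery",
        "scenario": "integrated_high_pax3_high_mirs",
        "metrics": ("myod_end", "mir1_end"),
        "band": "above the low-miRNA state",
    },
    {
        "claim": "extra miR-1 at start: faster Pax3 decline, earlier MyoD"
        " recovery",
        "scenario": "integrated_mir1_boost",
        "metrics": ("pax3_day2", "myod_day2"),
        "band": "day-2 Pax3 lower and day-2 MyoD higher than the"
        " un-boosted rescue",
    },
)
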