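"""Deterministic (LSODA) and stochastic (Gillespie direct) engines.

Both engines consume the same :class:`~myomirnet.core.ReactionNetwork`;
the ODE engine reads counts as continuous concentrations in molecule
units, the SSA engine as integer copy numbers.  Time is seconds
throughout; the scenario layer converts to hours/days for reporting.

Solver defaults mirror the COPASI defaults used for this model family:
relative tolerance 1e-6, absolute tolerance 1e-13, maximum internal
step 10000 s, with LSODA's automatic stiff/non-stiff switching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import ReactionNetwork, validate_network

__all__ = [
    "SolverSettings",
    "Trajectory",
    "EnsembleSummary",
    "SimulationError",
    "simulate_ode",
    "simulate_ssa",
    "run_ensemble",
]


class SimulationError(RuntimeError):
    """Solver failure, carrying the solver's diagnostic message."""


@dataclass(frozen=True)
class SolverSettings:
    rel_tol: float = 1e-6
    abs_tol: float = 1e-13
    max_internal_step: float = 10000.0

    def __post_init__(self) -> None:
        if min(self.rel_tol, self.abs_tol, self.max_internal_step) <= 0:
            raise ValueError("solver settings must be strictly positive")


@dataclass
class Trajectory:
    """Time grid plus per-species abundance series from one run."""

    times: np.ndarray
    values: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)
    readouts: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        """Series for a species id or a registered readout alias (sum)."""
        if name in self.values:
            return self.values[name]
        if name in self.readouts:
            parts = [self.values[s] for s in self.readouts[name]]
            return np.sum(parts, axis=0)
        raise KeyError(f"unknown species or readout {name!r}")

    def at(self, name: str, t: float) -> float:
        """Value of ``name`` at grid time nearest to ``t`` (seconds)."""
        i = int(np.argmin(np.abs(self.times - t)))
        return float(self.series(name)[i])

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV form: columns time_s, species, value."""
        frames = []
        for sid, vals in self.values.items():
            frames.append(
                pd.DataFrame(
                    {"time_s": self.times, "species": sid, "value": vals}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


@dataclass
class EnsembleSummary:
    """Pointwise mean and population standard deviation over N SSA runs."""

    times: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    n_runs: int
    seeds: tuple[int, ...]
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for sid in self.mean:
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": self.times,
                        "species": sid,
                        "mean": self.mean[sid],
                        "sd": self.sd[sid],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


# ---------------------------------------------------------------------------
# network compilation to arrays
# ---------------------------------------------------------------------------


def _compile(net: ReactionNetwork):
    """Flatten a network into arrays for fast propensity evaluation.

    Returns (species ids, r1, r2, homodimer flag, k, stoich delta matrix).
    r1/r2 are reactant indices (-1 when absent).
    """
    issues = validate_network(net)
    if issues:
        raise SimulationError(
            f"network {net.name!r} failed validation: " + "; ".join(issues)
        )
    sidx = net.species_index()
    n_s = len(net.species)
    n_r = len(net.reactions)
    r1 = np.full(n_r, -1, dtype=np.int64)
    r2 = np.full(n_r, -1, dtype=np.int64)
    homo = np.zeros(n_r, dtype=np.bool_)
    k = np.zeros(n_r, dtype=np.float64)
    delta = np.zeros((n_r, n_s), dtype=np.int64)
    for j, rxn in enumerate(net.reactions):
        k[j] = net.parameters[rxn.rate_constant_name]
        if len(rxn.reactants) >= 1:
            r1[j] = sidx[rxn.reactants[0]]
        if len(rxn.reactants) == 2:
            r2[j] = sidx[rxn.reactants[1]]
            homo[j] = rxn.reactants[0] == rxn.reactants[1]
        for sid in rxn.reactants:
            delta[j, sidx[sid]] -= 1
        for sid in rxn.products:
            delta[j, sidx[sid]] += 1
    return net.species_ids, r1, r2, homo, k, delta


# ---------------------------------------------------------------------------
# deterministic engine
# ---------------------------------------------------------------------------


def simulate_ode(
    net: ReactionNetwork,
    t_end: float,
    n_points: int = 201,
    settings: SolverSettings | None = None,
    overrides_meta: Mapping | None = None,
) -> Trajectory:
    """Integrate the mass-action ODEs on an even grid with LSODA.

    The right-hand side is the stoichiometry-weighted sum of mass-action
    propensities.  ``settings.rel_tol`` is treated as a target for
    *global* relative accuracy: LSODA's per-step error control receives
    a 0.1 safety factor so that accumulated error stays within the
    requested tolerance (local tolerances alone only bound the error
    per step).  Tiny negative excursions within ``abs_tol`` are clipped
    to 0 on output; larger negativity raises :class:`SimulationError`.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    settings = settings or SolverSettings()
    ids, r1, r2, homo, k, delta = _compile(net)
    stoich = delta.T.astype(np.float64)  # (n_s, n_r)
    y0 = np.array(
        [s.initial_amount for s in net.species], dtype=np.float64
    )
    order1 = r1 >= 0
    order2 = r2 >= 0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        w = k.copy()
        w[order1] *= y[r1[order1]]
        w[order2] *= y[r2[order2]]
        # continuous homodimer convention k*x^2/2 (x*(x-1)/2 at integer x
        # differs by O(x); unused by the shipped models)
        w[homo] *= 0.5
        return stoich @ w

    grid = np.linspace(0.0, float(t_end), int(n_points))
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=0.1 * settings.rel_tol,  # local-vs-global safety factor
        atol=settings.abs_tol,
        max_step=settings.max_internal_step,
    )
    if not sol.success:
        raise SimulationError(
            f"LSODA failed on {net.name!r}: {sol.message}"
        )
    y = sol.y
    if y.min() < -1e-6:
        raise SimulationError(
            f"ODE solution for {net.name!r} went negative "
            f"(min {y.min():.3g}); model or tolerances are inconsistent"
        )
    y = np.clip(y, 0.0, None)
    values = {sid: y[i].copy() for i, sid in enumerate(ids)}
    meta = {
        "model": net.name,
        "method": "ode",
        "settings": settings,
        "overrides": dict(overrides_meta or {}),
    }
    return Trajectory(grid, values, meta, dict(net.readouts))


# ---------------------------------------------------------------------------
# stochastic engine (Gillespie direct method)
# ---------------------------------------------------------------------------


def _ssa_core_py(x0, r1, r2, homo, k, delta, grid, seed):
    """Pure-Python direct method; same algorithm as the jitted core."""
    np.random.seed(seed)
    n_r = k.shape[0]
    n_g = grid.shape[0]
    x = x0.copy()
    out = np.empty((n_g, x0.shape[0]), dtype=np.int64)
    t = 0.0
    g = 0
    a = np.empty(n_r, dtype=np.float64)
    while g < n_g:
        a0 = 0.0
        for j in range(n_r):
            w = k[j]
            if r1[j] >= 0:
                w *= x[r1[j]]
            if r2[j] >= 0:
                if homo[j]:
                    w *= (x[r2[j]] - 1) * 0.5
                else:
                    w *= x[r2[j]]
            if w < 0.0:
                w = 0.0
            a[j] = w
            a0 += w
        if a0 <= 0.0:
            while g < n_g:  # absorbing state: freeze remaining grid
                out[g] = x
                g += 1
            break
        tau = -np.log(np.random.random()) / a0
        t_next = t + tau
        while g < n_g and grid[g] < t_next:
            out[g] = x
            g += 1
        if g >= n_g:
            break
        u = np.random.random() * a0
        acc = 0.0
        j = n_r - 1
        for jj in range(n_r):
            acc += a[jj]
            if u < acc:
                j = jj
                break
        x += delta[j]
        t = t_next
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _ssa_core = njit(cache=True)(_ssa_core_py)
except Exception:  # pragma: no cover
    _ssa_core = _ssa_core_py


def simulate_ssa(
    net: ReactionNetwork,
    t_end: float,
    record_grid: Sequence[float] | np.ndarray | None = None,
    seed: int = 0,
    n_points: int = 201,
    overrides_meta: Mapping | None = None,
) -> Trajectory:
    """Exact SSA (direct method) sampled onto ``record_grid``.

    Waiting times are exponential with rate equal to the total
    propensity; the next reaction is chosen with probability
    propensity/total.  The state is recorded by zero-order hold (the
    state just before the first event past each grid time).  A total
    propensity of 0 freezes the remaining grid (absorbing state).

    Reproducibility: identical (network, grid, seed) gives an identical
    trajectory.
    """
    if record_grid is None:
        if t_end <= 0:
            raise ValueError("t_end must be > 0")
        record_grid = np.linspace(0.0, float(t_end), int(n_points))
    grid = np.asarray(record_grid, dtype=np.float64)
    if grid.ndim != 1 or grid.shape[0] < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("record_grid must be strictly increasing")
    ids, r1, r2, homo, k, delta = _compile(net)
    x0 = np.array([s.initial_amount for s in net.species], dtype=np.int64)
    out = _ssa_core(x0, r1, r2, homo, k, delta, grid, int(seed))
    values = {sid: out[:, i].copy() for i, sid in enumerate(ids)}
    meta = {
        "model": net.name,
        "method": "ssa",
        "seed": int(seed),
        "overrides": dict(overrides_meta or {}),
    }
    return Trajectory(grid.copy(), values, meta, dict(net.readouts))


def run_ensemble(
    net: ReactionNetwork,
    t_end: float,
    record_grid: Sequence[float] | np.ndarray | None = None,
    n_runs: int = 100,
    base_seed: int = 1,
    n_points: int = 201,
) -> EnsembleSummary:
    """Pointwise mean and population SD over ``n_runs`` SSA replicates.

    Seeds are ``base_seed .. base_seed + n_runs - 1`` (one independent,
    explicitly seeded stream per run); the summary is deterministic
    given ``base_seed``.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if record_grid is None:
        record_grid = np.linspace(0.0, float(t_end), int(n_points))
    grid = np.asarray(record_grid, dtype=np.float64)
    ids = net.species_ids
    n_g, n_s = grid.shape[0], len(ids)
    acc = np.zeros((n_g, n_s))
    acc2 = np.zeros((n_g, n_s))
    seeds = tuple(int(base_seed) + i for i in range(n_runs))
    for i, seed in enumerate(seeds):
        try:
            traj = simulate_ssa(net, t_end, grid, seed=seed)
        except Exception as exc:  # attach run index per contract
            raise SimulationError(f"ensemble run {i} (seed {seed}): {exc}")
        mat = np.column_stack([traj.values[sid] for sid in ids]).astype(float)
        acc += mat
        acc2 += mat * mat
    mean = acc / n_runs
    var = np.clip(acc2 / n_runs - mean * mean, 0.0, None)
    sd = np.sqrt(var)
    return EnsembleSummary(
        times=grid.copy(),
        mean={sid: mean[:, j].copy() for j, sid in enumerate(ids)},
        sd={sid: sd[:, j].copy() for j, sid in enumerate(ids)},
        n_runs=n_runs,
        seeds=seeds,
        meta={"model": net.name, "method": "ensemble"},
    )
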