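"""Compile a SystemSpec into a derivative function and integrate it.

Two solvers are provided: adaptive Runge-Kutta 4(5) via SciPy (default), and
a fixed-step explicit Euler used as a brute-force cross-validation oracle.
Intervention onsets/offsets and forcing discontinuities are handled as hard
integration breakpoints, never stepped over.  Clamped components are held at
their clamp value exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .interventions import InterventionPlan
from .system_spec import SpecError, SystemSpec

__all__ = [
    "Trajectory",
    "DynamicsError",
    "compile_rhs",
    "evaluate_rhs",
    "integrate",
    "EULER_DT",
]

#: Fixed Euler step used by the oracle solver.
EULER_DT = 1e-4

_GRID_TOL = 1e-9


class DynamicsError(RuntimeError):
    """Raised when integration fails (NaN in RHS, solver failure)."""


@dataclass
class Trajectory:
    """Simulated time grid and state/exogenous values with run metadata."""

    times: np.ndarray
    states: np.ndarray          # (n_times, n_state), spec component order
    exogenous: np.ndarray       # (n_times, n_exo)
    state_names: list[str]
    exogenous_names: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def t_max(self) -> float:
        return float(self.times[-1])

    def series(self, name: str) -> np.ndarray:
        """Values of one component (state or exogenous) over time."""
        if name in self.state_names:
            return self.states[:, self.state_names.index(name)]
        if name in self.exogenous_names:
            return self.exogenous[:, self.exogenous_names.index(name)]
        raise KeyError(f"unknown component {name!r}")

    def component_names(self) -> list[str]:
        return list(self.state_names) + list(self.exogenous_names)

    def to_csv_text(self) -> str:
        """CSV: header ``time,<states...>,<exogenous...>``, 10 significant digits."""
        header = ",".join(["time"] + self.state_names + self.exogenous_names)
        lines = [header]
        for i in range(len(self.times)):
            row = [self.times[i], *self.states[i], *self.exogenous[i]]
            lines.append(",".join(format(v, ".10g") for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# RHS compilation
# ---------------------------------------------------------------------------

def compile_rhs(
    spec: SystemSpec, plan: InterventionPlan | None = None
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build a fast ``f(t, y) -> dy`` closure from the declarative spec."""
    state_names = spec.state_names
    n = len(state_names)
    index = {name: i for i, name in enumerate(state_names)}
    exo_profiles = []
    for i, comp in enumerate(spec.exogenous_components):
        profile = spec.forcings.get(comp.name)
        if profile is None:
            raise SpecError(f"exogenous component {comp.name!r} has no forcing profile")
        index[comp.name] = n + i
        exo_profiles.append(profile)

    lower = np.full(n, -np.inf)
    upper = np.full(n, np.inf)
    for i, comp in enumerate(spec.state_components):
        lb = comp.lower_bound
        if spec.nonneg_clip:
            lb = 0.0 if lb is None else max(lb, 0.0)
        lower[i] = -np.inf if lb is None else lb
        upper[i] = np.inf if comp.upper_bound is None else comp.upper_bound

    # flatten terms to tuples for a tight evaluation loop
    compiled = []
    for term in spec.terms:
        tgt = index[term.target]
        coeff = float(term.sign) * spec.parameters[term.coefficient]
        srcs = tuple(index[s] for s in term.sources)
        mods: list[tuple[int, float]] = []
        if term.form == "modulated_linear":
            srcs = (index[term.sources[0]],)
            mods.append((index[term.sources[1]], spec.parameters[term.gain]))
        for m in term.modulators:
            mods.append((index[m.source], float(m.sign) * spec.parameters[m.gain]))
        compiled.append((tgt, coeff, srcs, tuple(mods)))

    # exposure handling
    clamp = None
    growth_disable = None
    if plan is not None and plan.exposure.active:
        if "Rb" not in index or index["Rb"] >= n:
            raise SpecError("exposure requires a state component 'Rb'")
        rb = index["Rb"]
        onset = plan.exposure.onset
        offset = math.inf if plan.exposure.offset is None else plan.exposure.offset
        if plan.exposure.mode == "clamp":
            clamp = (rb, onset, offset, plan.exposure.clamp_value)
        else:  # disable_growth: suppress positive terms feeding Rb from onset
            skip = {
                k for k, (tgt, coeff, _, _) in enumerate(compiled)
                if tgt == rb and coeff > 0
            }
            growth_disable = (skip, onset, offset)

    lower_l = lower.tolist()
    upper_l = upper.tolist()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        vals = [min(max(float(v), lower_l[i]), upper_l[i]) for i, v in enumerate(y)]
        if clamp is not None and clamp[1] <= t < clamp[2]:
            vals[clamp[0]] = clamp[3]
        for profile in exo_profiles:
            vals.append(profile.value(t))
        d = [0.0] * n
        skip_set = (
            growth_disable[0]
            if growth_disable is not None and growth_disable[1] <= t < growth_disable[2]
            else None
        )
        for k, (tgt, coeff, srcs, mods) in enumerate(compiled):
            if skip_set is not None and k in skip_set:
                continue
            v = coeff
            for s in srcs:
                v *= vals[s]
            if mods:
                fac = 1.0
                for mi, g in mods:
                    fac += g * vals[mi]
                v *= fac if fac > 0.0 else 0.0
            d[tgt] += v
        # keep bounded states from being pushed outside their box
        for i in range(n):
            if (y[i] >= upper_l[i] and d[i] > 0.0) or (y[i] <= lower_l[i] and d[i] < 0.0):
                d[i] = 0.0
        if clamp is not None and clamp[1] <= t < clamp[2]:
            d[clamp[0]] = 0.0
        return np.asarray(d)

    return rhs


def evaluate_rhs(
    spec: SystemSpec,
    state: Sequence[float],
    t: float,
    plan: InterventionPlan | None = None,
) -> np.ndarray:
    """Evaluate the derivative vector at one state and time."""
    state = np.asarray(state, dtype=float)
    n = len(spec.state_names)
    if state.shape != (n,):
        raise SpecError(
            f"state length {state.shape} does not match {n} state components"
        )
    d = compile_rhs(spec, plan)(float(t), state)
    if not np.all(np.isfinite(d)):
        bad = spec.state_names[int(np.argmax(~np.isfinite(d)))]
        raise DynamicsError(f"non-finite derivative for component {bad!r} at t={t}")
    return d


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _segment_edges(spec: SystemSpec, plan: InterventionPlan | None, t_max: float) -> list[float]:
    pts: set[float] = set()
    if plan is not None:
        pts.update(plan.breakpoints(t_max))
    for profile in spec.forcings.values():
        pts.update(p for p in profile.discontinuities() if 0.0 < p < t_max)
    edges = [0.0] + sorted(pts) + [t_max]
    out = [edges[0]]
    for e in edges[1:]:
        if e - out[-1] > _GRID_TOL:
            out.append(e)
    return out


def integrate(
    spec: SystemSpec,
    plan: InterventionPlan | None = None,
    t_max: float = 50.0,
    dt_out: float = 0.05,
    solver: str = "rk_adaptive",
    tol: float = 1e-8,
    euler_dt: float = EULER_DT,
) -> Trajectory:
    """Integrate the system over [0, t_max] on a uniform output grid.

    Deterministic given its inputs.  Intervention onsets and forcing jumps
    split the horizon into segments; the clamp transformation is applied at
    the segment edge, never stepped over.
    """
    if t_max <= 0 or dt_out <= 0:
        raise SpecError("t_max and dt_out must be positive")
    if solver not in ("rk_adaptive", "euler"):
        raise SpecError(f"unknown solver {solver!r}")
    if plan is not None:
        problems = plan.validate(t_max)
        if problems:
            raise SpecError("invalid intervention plan: " + "; ".join(problems))

    n_out = int(round(t_max / dt_out))
    if abs(n_out * dt_out - t_max) > 1e-6 * max(1.0, t_max):
        raise SpecError("dt_out must evenly divide t_max")
    times = np.linspace(0.0, t_max, n_out + 1)

    rhs = compile_rhs(spec, plan)
    state_names = spec.state_names
    n = len(state_names)
    y = np.asarray(spec.initial_state(), dtype=float)
    states = np.empty((n_out + 1, n))
    states[0] = y

    clamp_active = (
        plan is not None and plan.exposure.active and plan.exposure.mode == "clamp"
    )
    onset = plan.exposure.onset if clamp_active else math.inf
    offset = (
        (math.inf if plan.exposure.offset is None else plan.exposure.offset)
        if clamp_active
        else math.inf
    )

    grid_pos = 1  # next output index to fill
    edges = _segment_edges(spec, plan, t_max)
    for t0, t1 in zip(edges[:-1], edges[1:]):
        if clamp_active and onset - _GRID_TOL <= t0 < offset:
            y = y.copy()
            y[state_names.index("Rb")] = plan.exposure.clamp_value
        seg_idx = []
        while grid_pos <= n_out and times[grid_pos] <= t1 + _GRID_TOL:
            seg_idx.append(grid_pos)
            grid_pos += 1
        if solver == "rk_adaptive":
            t_eval = [times[i] for i in seg_idx]
            if not t_eval or abs(t_eval[-1] - t1) > _GRID_TOL:
                t_eval = t_eval + [t1]
                extra_end = True
            else:
                extra_end = False
            sol = solve_ivp(
                rhs, (t0, t1), y, method="RK45", rtol=tol, atol=tol, t_eval=t_eval
            )
            if not sol.success:
                raise DynamicsError(
                    f"adaptive solver failed in segment [{t0}, {t1}]: {sol.message}"
                )
            ys = sol.y.T
            for j, i in enumerate(seg_idx):
                states[i] = ys[j]
            y = ys[-1].copy() if extra_end else ys[len(seg_idx) - 1].copy()
        else:
            n_steps = max(1, int(round((t1 - t0) / euler_dt)))
            h = (t1 - t0) / n_steps
            record = {}
            for i in seg_idx:
                k = int(round((times[i] - t0) / h))
                record[k] = i
            t = t0
            y = y.copy()
            for k in range(1, n_steps + 1):
                y = y + h * rhs(t, y)
                t = t0 + k * h
                if k in record:
                    states[record[k]] = y
        if not np.all(np.isfinite(y)):
            bad = state_names[int(np.argmax(~np.isfinite(y)))]
            raise DynamicsError(
                f"non-finite state for component {bad!r} near t={t1}"
            )

    # clip sampled output into bounds (interpolants may overshoot slightly)
    lower = np.full(n, -np.inf)
    upper = np.full(n, np.inf)
    for i, comp in enumerate(spec.state_components):
        lb = comp.lower_bound
        if spec.nonneg_clip:
            lb = 0.0 if lb is None else max(lb, 0.0)
        lower[i] = -np.inf if lb is None else lb
        upper[i] = np.inf if comp.upper_bound is None else comp.upper_bound
    np.clip(states, lower, upper, out=states)

    # clamp exactness on the output grid
    if clamp_active:
        rb = state_names.index("Rb")
        mask = (times >= onset - _GRID_TOL) & (times < offset + _GRID_TOL)
        states[mask, rb] = plan.exposure.clamp_value

    if not np.all(np.isfinite(states)):
        raise DynamicsError("non-finite values in trajectory")

    exo_names = spec.exogenous_names
    exogenous = np.empty((n_out + 1, len(exo_names)))
    for j, name in enumerate(exo_names):
        profile = spec.forcings[name]
        exogenous[:, j] = [profile.value(t) for t in times]

    meta = {
        "spec_hash": spec.spec_hash(),
        "plan": plan.to_dict() if plan is not None else None,
        "solver": solver,
        "t_max": float(t_max),
        "dt_out": float(dt_out),
        "tol": float(tol),
    }
    if solver == "euler":
        meta["euler_dt"] = float(euler_dt)
    return Trajectory(times, states, exogenous, list(state_names), list(exo_names), meta)
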