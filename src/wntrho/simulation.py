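"""Time-course integration with events, steady-state detection, scenario runs.

The integrator is SciPy's stiff-capable ``solve_ivp`` (LSODA by default) with
the analytic Jacobian produced at compile time. Events are realised as hard
integrator restarts: the state is integrated up to each event time, the named
species is reset, and integration resumes — matching the stepwise set/reset
protocol used for the pathway inputs (e.g. Wnt 0 -> 1 nM at t = 4000 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .reaction_network import CompiledODE, Event, NetworkModel, compile_odes

__all__ = [
    "Schedule",
    "Trajectory",
    "SteadyState",
    "Simulator",
    "simulate",
    "find_steady_state",
    "percent_difference",
]

#: default integration tolerances (relative, absolute in nM)
RTOL = 1e-8
ATOL = 1e-10
#: steady state: max_i |dy_i/dt| / max(y_i, FLOOR) <= SS_TOL
SS_TOL = 1e-9
SS_FLOOR = 1e-6
#: equilibration horizon cap (min)
T_MAX = 1e6


@dataclass
class Schedule:
    """Integration window plus timed events and an optional output grid."""

    t_start: float = 0.0
    t_end: float = 1.0
    events: list[Event] = field(default_factory=list)
    output_times: np.ndarray | None = None

    def grid(self, n: int = 500) -> np.ndarray:
        if self.output_times is not None:
            t = np.asarray(self.output_times, dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError("output times must be sorted")
            return t
        return np.linspace(self.t_start, self.t_end, n)


@dataclass
class Trajectory:
    """Simulation output sampled on a time grid, keyed by species name."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species)
    species: list[str]
    diagnostics: dict = field(default_factory=dict)

    def series(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def final_state(self) -> dict[str, float]:
        return dict(zip(self.species, self.values[-1]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.species)
        df.insert(0, "time", self.times)
        return df


@dataclass
class SteadyState:
    """A converged state: concentrations, residual metric, time of attainment."""

    concentrations: dict[str, float]
    residual: float
    time: float
    converged: bool

    def __getitem__(self, name: str) -> float:
        return self.concentrations[name]

    def vector(self, species: list[str]) -> np.ndarray:
        return np.array([self.concentrations[s] for s in species])


class SteadyStateError(RuntimeError):
    """Raised when equilibration does not converge within the horizon."""


class Simulator:
    """Reusable wrapper holding a compiled model.

    Compiling (sympy lambdify) costs a second or two for the larger models, so
    operations that scan many inputs (PG titration, condition matrices, MPSA)
    construct one ``Simulator`` and reuse it with different initial states and
    parameter vectors.
    """

    def __init__(self, model: NetworkModel, compiled: CompiledODE | None = None):
        self.model = model
        self.compiled = compiled if compiled is not None else compile_odes(model)
        self.species = self.compiled.species_names
        self._index = {s: i for i, s in enumerate(self.species)}
        self._boundary = model.boundary_mask()

    # -- state helpers -----------------------------------------------------
    def state_vector(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        y = self.model.initial_state()
        if overrides:
            for name, value in overrides.items():
                y[self._index[name]] = value
        return y

    def residual(self, y: np.ndarray, p: np.ndarray) -> float:
        dy = self.compiled.rhs(0.0, y, p)
        scale = np.maximum(np.abs(y), SS_FLOOR)
        return float(np.max(np.abs(dy) / scale))

    # -- time course -------------------------------------------------------
    def simulate(
        self,
        schedule: Schedule,
        *,
        y0: np.ndarray | None = None,
        p: np.ndarray | None = None,
        rtol: float = RTOL,
        atol: float = ATOL,
        method: str = "LSODA",
        n_out: int = 500,
    ) -> Trajectory:
        p = self.compiled.p0 if p is None else p
        y = self.model.initial_state() if y0 is None else np.array(y0, dtype=float)
        grid = schedule.grid(n_out)

        events = [e for e in schedule.events if schedule.t_start <= e.time <= schedule.t_end]
        events = sorted(enumerate(events), key=lambda ie: (ie[1].time, ie[0]))
        breakpoints = sorted({schedule.t_start, schedule.t_end, *(e.time for _, e in events)})

        out = np.empty((len(grid), len(self.species)))
        filled = np.zeros(len(grid), dtype=bool)
        nfev = 0
        for a, b in zip(breakpoints[:-1], breakpoints[1:]):
            for _, e in events:
                if e.time == a:
                    y[self._index[e.species]] = e.new_value
            # sample the left endpoint with post-event values; the right
            # endpoint of each segment is deferred to the next segment so
            # grid points at event times report the post-event state
            at_a = np.isclose(grid, a) & ~filled
            out[at_a] = y
            filled |= at_a
            inside = (grid > a) & (grid < b) & ~filled
            t_eval = grid[inside]
            sol = solve_ivp(
                self.compiled.rhs,
                (a, b),
                y,
                method=method,
                t_eval=t_eval if t_eval.size else None,
                args=(p,),
                rtol=rtol,
                atol=atol,
                jac=self.compiled.jac,
                dense_output=False,
            )
            if not sol.success:
                raise RuntimeError(
                    f"integration failed at t={sol.t[-1] if sol.t.size else a:.6g}: {sol.message}"
                )
            nfev += sol.nfev
            if t_eval.size:
                out[inside] = sol.y.T
                filled |= inside
            y = sol.y[:, -1].copy()
        # trailing events exactly at t_end
        for _, e in events:
            if e.time == schedule.t_end:
                y[self._index[e.species]] = e.new_value
        at_end = np.isclose(grid, schedule.t_end) & ~filled
        out[at_end] = y
        return Trajectory(
            times=grid,
            values=out,
            species=list(self.species),
            diagnostics={"nfev": nfev, "rtol": rtol, "atol": atol, "method": method},
        )

    # -- steady state --------------------------------------------------
    def steady_state(
        self,
        *,
        inputs: dict[str, float] | None = None,
        y0: np.ndarray | None = None,
        p: np.ndarray | None = None,
        tol: float = SS_TOL,
        t_max: float = T_MAX,
        t_chunk: float = 2e4,
        rtol: float = RTOL,
        atol: float = ATOL,
        method: str = "LSODA",
        raise_on_failure: bool = True,
    ) -> SteadyState:
        """Integrate until the relative derivative metric falls below ``tol``.

        ``inputs`` pins boundary species (and may override any species' start
        level). Non-convergence within ``t_max`` raises ``SteadyStateError``
        unless ``raise_on_failure`` is false, in which case the state is
        returned flagged unconverged; a cycling residual (oscillatory system)
        is reported the same way rather than silently truncated.
        """
        p = self.compiled.p0 if p is None else p
        y = self.state_vector(inputs) if y0 is None else np.array(y0, dtype=float)
        if y0 is not None and inputs:
            for name, value in inputs.items():
                y[self._index[name]] = value
        t = 0.0
        chunk = t_chunk
        res = self.residual(y, p)
        history: list[float] = [res]
        while res > tol and t < t_max:
            sol = solve_ivp(
                self.compiled.rhs,
                (t, t + chunk),
                y,
                method=method,
                args=(p,),
                rtol=rtol,
                atol=atol,
                jac=self.compiled.jac,
                t_eval=[t + chunk],
            )
            if not sol.success:
                raise SteadyStateError(f"integration failed during equilibration: {sol.message}")
            y = sol.y[:, -1]
            t += chunk
            chunk = min(chunk * 2, t_max - t) if t_max - t > 0 else chunk
            res = self.residual(y, p)
            history.append(res)
        converged = res <= tol
        if not converged:
            oscillatory = len(history) >= 4 and history[-1] > 0.5 * history[-3]
            msg = (
                f"no steady state within t={t_max:g} min (residual {res:.3g}"
                + (", residual not decaying — possibly oscillatory)" if oscillatory else ")")
            )
            if raise_on_failure:
                raise SteadyStateError(msg)
        return SteadyState(
            concentrations=dict(zip(self.species, np.asarray(y, dtype=float))),
            residual=res,
            time=t,
            converged=converged,
        )


def simulate(model: NetworkModel, schedule: Schedule, **kwargs) -> Trajectory:
    """Integrate ``model`` over ``schedule`` (stiff solver, event restarts)."""
    return Simulator(model).simulate(schedule, **kwargs)


def find_steady_state(
    model: NetworkModel, inputs: dict[str, float] | None = None, tol: float = SS_TOL, **kwargs
) -> SteadyState:
    """Equilibrate ``model`` under the given boundary-input levels."""
    return Simulator(model).steady_state(inputs=inputs, tol=tol, **kwargs)


def percent_difference(
    off_state: float,
    on_state: float,
    mode: str = "off_referenced",
    reference: float | None = None,
) -> float:
    """Percent difference between pathway-off and pathway-on readout levels.

    ``off_referenced``: (off - on) / off * 100.
    ``range_referenced``: (off - on) / reference * 100, where ``reference`` is
    the normalising level (e.g. the maximum readout over a titration grid).
    """
    if mode == "off_referenced":
        if off_state == 0:
            raise ValueError("off-referenced percent difference undefined for off_state = 0")
        return (off_state - on_state) / off_state * 100.0
    if mode == "range_referenced":
        if reference is None:
            raise ValueError("range_referenced mode requires a reference value")
        if reference == 0:
            raise ValueError("zero reference")
        return (off_state - on_state) / reference * 100.0
    raise ValueError(f"unknown mode {mode!r}")
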