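"""ODE assembly and integration for logic network models.

Each state species Y relaxes with first-order kinetics toward a drive set by
the logic gates of its incoming reactions:

    dY/dt = (1/tau_Y) * (drive_Y * Ymax_Y - Y)

where ``drive_Y`` OR-combines (probabilistic sum) the contributions of the
activating/mixed reactions targeting Y — each contribution being
W * prod f_act(activators) * prod f_inhib(negated terms) — and is then
multiplied by (1 - W * prod f_act(X)) for every purely inhibitory reaction
(all terms negated).  Constant-source reactions (empty left side) contribute
their weight W as an OR term.

Input species are not ODE states: they are clamped algebraic signals whose
value is the stimulus-schedule level times the species' Ymax.  This makes an
input's Ymax a well-defined perturbation target for sensitivity analysis.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .kernels import HillParams, kernel_variant
from .model import NetworkModel

__all__ = [
    "StimulusSchedule",
    "SolverConfig",
    "Trajectory",
    "SteadyStateResult",
    "assemble_rhs",
    "simulate",
    "steady_state",
    "SolverFailure",
]


class SolverFailure(RuntimeError):
    """Adaptive integration failed; carries solver context."""


# ---------------------------------------------------------------------------
# stimulus schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSchedule:
    """Piecewise-constant input levels over time.

    ``segments`` maps input name -> tuple of (t_start, t_end, level) with
    level in [0, 1]; times not covered by any segment give level 0.
    """

    segments: Mapping[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        norm = {}
        for name, segs in dict(self.segments).items():
            segs = tuple(sorted((float(a), float(b), float(v)) for a, b, v in segs))
            for (a0, b0, v0) in segs:
                if not a0 < b0:
                    raise ValueError(f"{name}: empty segment ({a0}, {b0})")
                if not 0.0 <= v0 <= 1.0:
                    raise ValueError(f"{name}: level {v0} outside [0, 1]")
            for (_, b0, _), (a1, _, _) in zip(segs, segs[1:]):
                if a1 < b0:
                    raise ValueError(f"{name}: overlapping segments")
            norm[name] = segs
        object.__setattr__(self, "segments", norm)

    @classmethod
    def constant(cls, levels: Mapping[str, float], t_end: float = np.inf) -> "StimulusSchedule":
        return cls({k: ((0.0, t_end, float(v)),) for k, v in levels.items()})

    def level(self, name: str, t: float) -> float:
        for a, b, v in self.segments.get(name, ()):
            if a <= t < b:
                return v
        return 0.0

    def levels(self, names: Sequence[str], t: float) -> np.ndarray:
        return np.array([self.level(n, t) for n in names])

    def breakpoints(self, t0: float, t1: float) -> list[float]:
        """Segment edges inside (t0, t1), used to restart the solver."""
        pts = set()
        for segs in self.segments.values():
            for a, b, _ in segs:
                for t in (a, b):
                    if t0 < t < t1:
                        pts.add(float(t))
        return sorted(pts)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for integration and steady-state detection."""

    rtol: float = 1e-6
    atol: float = 1e-8
    max_step: float = np.inf
    theta_ss: float = 1e-6  # steady state: max |dY/dt| below this
    t_max: float = 1e4  # integration horizon for steady-state search
    method: str = "RK23"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.theta_ss <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class Trajectory:
    """One simulation: a time grid and per-species activation series."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species), model species order
    species: tuple[str, ...]
    inputs_applied: StimulusSchedule

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=list(self.species)).assign(
            time=self.times
        )[["time", *self.species]]

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SteadyStateResult:
    """Final state of a constant-input run (all species, model order)."""

    state: np.ndarray
    converged: bool
    t_reached: float
    species: tuple[str, ...]

    def __getitem__(self, name: str) -> float:
        return float(self.state[self.species.index(name)])


# ---------------------------------------------------------------------------
# compiled right-hand side
# ---------------------------------------------------------------------------

class _Compiled:
    """Vectorized evaluator for the logic-ODE right-hand side."""

    def __init__(self, model: NetworkModel):
        self.model = model
        names = model.species_names
        self.index = {n: i for i, n in enumerate(names)}
        self.n_species = len(names)
        self.state_idx = np.array(
            [i for i, s in enumerate(model.species) if s.role == "state"], dtype=int
        )
        self.input_idx = np.array(
            [i for i, s in enumerate(model.species) if s.role == "input"], dtype=int
        )
        self.input_names = tuple(names[i] for i in self.input_idx)
        self.tau = np.array([model.species[i].tau for i in self.state_idx])
        self.ymax_state = np.array([model.species[i].Ymax for i in self.state_idx])
        self.ymax_input = np.array([model.species[i].Ymax for i in self.input_idx])
        self.y0 = np.array([model.species[i].y0 for i in self.state_idx])
        state_pos = {int(i): k for k, i in enumerate(self.state_idx)}

        kern = model.kernel
        normalized = kern.tag == "normalized_hill"

        # OR-combined rows (mixed/activating and constant sources) and
        # purely inhibitory rows are compiled into flat term arrays with
        # per-reaction segment products.
        or_t_sp, or_t_neg, or_t_B, or_t_K, or_t_n = [], [], [], [], []
        or_starts, or_W, or_target = [], [], []
        src_W, src_target = [], []
        pu_t_sp, pu_t_B, pu_t_K, pu_t_n = [], [], [], []
        pu_starts, pu_W, pu_target = [], [], []

        for r in model.reactions:
            tpos = state_pos[self.index[r.target]]
            if r.is_source:
                src_W.append(r.weight)
                src_target.append(tpos)
                continue
            if normalized:
                p = HillParams.from_n_ec50(r.n, r.EC50)
                B, K, nn = p.B, p.K, p.n
            else:
                B, K, nn = 1.0, 1.0, 1.0  # unused; kernel_variant applies
            if r.is_pure_inhibitory:
                pu_starts.append(len(pu_t_sp))
                for name, _ in r.terms:
                    pu_t_sp.append(self.index[name])
                    pu_t_B.append(B)
                    pu_t_K.append(K)
                    pu_t_n.append(nn)
                pu_W.append(r.weight)
                pu_target.append(tpos)
            else:
                or_starts.append(len(or_t_sp))
                for name, neg in r.terms:
                    or_t_sp.append(self.index[name])
                    or_t_neg.append(neg)
                    or_t_B.append(B)
                    or_t_K.append(K)
                    or_t_n.append(nn)
                or_W.append(r.weight)
                or_target.append(tpos)

        as_f = lambda x: np.asarray(x, dtype=float)
        as_i = lambda x: np.asarray(x, dtype=int)
        self.or_t_sp, self.or_t_neg = as_i(or_t_sp), np.asarray(or_t_neg, dtype=bool)
        self.or_t_B, self.or_t_K, self.or_t_n = as_f(or_t_B), as_f(or_t_K), as_f(or_t_n)
        self.or_starts, self.or_W, self.or_target = as_i(or_starts), as_f(or_W), as_i(or_target)
        self.src_W, self.src_target = as_f(src_W), as_i(src_target)
        self.pu_t_sp = as_i(pu_t_sp)
        self.pu_t_B, self.pu_t_K, self.pu_t_n = as_f(pu_t_B), as_f(pu_t_K), as_f(pu_t_n)
        self.pu_starts, self.pu_W, self.pu_target = as_i(pu_starts), as_f(pu_W), as_i(pu_target)
        self.kern = kern
        self.normalized = normalized

    def _f_act(self, x, B, K, n):
        if self.normalized:
            interior = (x > 0.0) & (x < 1.0)
            xn = np.where(interior, x, 0.5) ** n
            core = B * xn / (K**n + xn)
            return np.where(x <= 0.0, 0.0, np.where(x >= 1.0, 1.0, core))
        return np.asarray(kernel_variant(x, self.kern))

    def drive(self, values: np.ndarray) -> np.ndarray:
        """Total gated drive per state species given all species values."""
        g = np.ones(len(self.state_idx))
        if len(self.or_starts):
            fa = self._f_act(values[self.or_t_sp], self.or_t_B, self.or_t_K, self.or_t_n)
            ft = np.where(self.or_t_neg, 1.0 - fa, fa)
            prod = np.multiply.reduceat(ft, self.or_starts)
            np.multiply.at(g, self.or_target, 1.0 - self.or_W * prod)
        if len(self.src_target):
            np.multiply.at(g, self.src_target, 1.0 - self.src_W)
        d = 1.0 - g
        if len(self.pu_starts):
            fa = self._f_act(values[self.pu_t_sp], self.pu_t_B, self.pu_t_K, self.pu_t_n)
            prod = np.multiply.reduceat(fa, self.pu_starts)
            h = np.ones(len(self.state_idx))
            np.multiply.at(h, self.pu_target, 1.0 - self.pu_W * prod)
            d = d * h
        return d

    def full_values(self, y: np.ndarray, input_levels: np.ndarray) -> np.ndarray:
        values = np.empty(self.n_species)
        values[self.state_idx] = y
        values[self.input_idx] = input_levels * self.ymax_input
        return values

    def rhs(self, y: np.ndarray, input_levels: np.ndarray) -> np.ndarray:
        values = self.full_values(y, input_levels)
        return (self.drive(values) * self.ymax_state - y) / self.tau


def assemble_rhs(model: NetworkModel, schedule: StimulusSchedule | None = None):
    """Compile ``model`` into a rate function ``f(t, y) -> dy/dt``.

    ``y`` ranges over the model's *state* species in species-table order;
    input values are taken from ``schedule`` (all zero if omitted).
    """
    comp = _Compiled(model)
    sched = schedule or StimulusSchedule()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return comp.rhs(np.asarray(y, dtype=float), sched.levels(comp.input_names, t))

    rhs.compiled = comp  # type: ignore[attr-defined]
    return rhs


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _integrate_segment(comp, levels, y0, t0, t1, config, t_eval=None, events=None):
    sol = solve_ivp(
        lambda t, y: comp.rhs(y, levels),
        (t0, t1),
        y0,
        method=config.method,
        rtol=config.rtol,
        atol=config.atol,
        max_step=config.max_step,
        t_eval=t_eval,
        events=events,
        dense_output=events is not None,
    )
    if not sol.success:
        raise SolverFailure(f"integration failed on [{t0}, {t1}]: {sol.message}")
    return sol


def simulate(
    model: NetworkModel,
    schedule: StimulusSchedule | None = None,
    t_end: float = 40.0,
    config: SolverConfig | None = None,
    n_report: int = 401,
) -> Trajectory:
    """Integrate the model under a stimulus schedule.

    The solver restarts at every schedule breakpoint so input steps are not
    smeared, and the solution is sampled on a uniform grid of ``n_report``
    points.  The returned trajectory reports all species (inputs included,
    as their clamped values).
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    config = config or SolverConfig()
    schedule = schedule or StimulusSchedule()
    comp = _Compiled(model)

    grid = np.linspace(0.0, t_end, n_report)
    edges = [0.0, *schedule.breakpoints(0.0, t_end), t_end]
    ys = np.empty((len(grid), len(comp.state_idx)))
    y = comp.y0.copy()
    filled = 0
    for t0, t1 in zip(edges, edges[1:]):
        # sample inside the half-open segment [t0, t1); final point at t_end
        hi = bisect.bisect_left(grid, t1) if t1 < t_end else len(grid)
        t_eval = grid[filled:hi]
        levels = schedule.levels(comp.input_names, (t0 + t1) / 2.0)
        need_eval = list(t_eval)
        if not need_eval or need_eval[-1] < t1:
            need_eval.append(t1)
        sol = _integrate_segment(comp, levels, y, t0, t1, config, t_eval=np.array(need_eval))
        take = len(t_eval)
        ys[filled : filled + take] = sol.y[:, :take].T
        y = sol.y[:, -1]
        filled = hi if t1 < t_end else len(grid)

    values = np.empty((len(grid), comp.n_species))
    values[:, comp.state_idx] = ys
    for k, t in enumerate(grid):
        values[k, comp.input_idx] = (
            schedule.levels(comp.input_names, t) * comp.ymax_input
        )
    return Trajectory(
        times=grid, values=values, species=model.species_names, inputs_applied=schedule
    )


def steady_state(
    model: NetworkModel,
    constant_inputs: Mapping[str, float] | None = None,
    config: SolverConfig | None = None,
    y_init: np.ndarray | None = None,
) -> SteadyStateResult:
    """Run the model to steady state under constant input levels.

    Integrates until max_i |dY_i/dt| < ``theta_ss`` (confirmed over a short
    follow-up window so a turning point of a damped oscillation is not
    mistaken for convergence) or until ``t_max``.  A non-converged run
    returns the time-average of the last 10% of the horizon with
    ``converged=False`` — oscillatory regimes are reported, never silently
    accepted.

    ``y_init`` optionally overrides the state species' initial values (used
    to continue from a previously computed baseline).
    """
    config = config or SolverConfig()
    comp = _Compiled(model)
    levels = np.zeros(len(comp.input_idx))
    for name, lv in (constant_inputs or {}).items():
        if name not in comp.input_names:
            raise KeyError(f"{name!r} is not an input species")
        if not 0.0 <= lv <= 1.0:
            raise ValueError(f"input level {lv} outside [0, 1]")
        levels[comp.input_names.index(name)] = lv

    y = comp.y0.copy() if y_init is None else np.asarray(y_init, dtype=float).copy()

    def event(t, yv):
        return float(np.max(np.abs(comp.rhs(yv, levels)))) - config.theta_ss

    event.terminal = True
    event.direction = -1.0

    t = 0.0
    confirm = 5.0  # time units the derivative must stay small
    t_search = 0.9 * config.t_max
    while t < t_search:
        if event(t, y) >= 0.0:
            sol = _integrate_segment(comp, levels, y, t, t_search, config, events=[event])
            y, t = sol.y[:, -1], sol.t[-1]
            if not sol.t_events[0].size:
                break  # reached t_search without the derivative norm dropping
        # candidate steady state: confirm over a short follow-up window so a
        # turning point of a damped oscillation is not mistaken for rest
        sol = _integrate_segment(comp, levels, y, t, t + confirm, config)
        y, t = sol.y[:, -1], sol.t[-1]
        if event(t, y) < 0.0:
            return SteadyStateResult(
                state=comp.full_values(y, levels),
                converged=True,
                t_reached=t,
                species=model.species_names,
            )

    # not converged: report the time-average over the last 10% of the horizon
    tw = np.linspace(t_search, config.t_max, 200)
    sol = _integrate_segment(comp, levels, y, t_search, config.t_max, config, t_eval=tw)
    return SteadyStateResult(
        state=comp.full_values(sol.y.mean(axis=1), levels),
        converged=False,
        t_reached=config.t_max,
        species=model.species_names,
    )
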