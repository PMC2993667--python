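"""Bounded least-squares refinement of model parameters.

A fit frees a named set of parameters — time constants, reaction weights,
EC50s, Hill coefficients, maximal activities, or a basal (constitutive)
drive added to one species — and minimizes the sum of squared differences
between simulated trajectories and target time courses.  Randomized
multi-restart (seeded) replaces manual tuning: each restart draws an initial
point uniformly inside the bounds and the best final residual wins, making
results reproducible bit-for-bit for a given seed and restart count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .engine import SolverConfig, StimulusSchedule, simulate
from .model import ModelValidationError, NetworkModel, make_reaction

__all__ = ["FitParameter", "FitSpec", "FitResult", "add_basal", "fit"]

PARAM_KINDS = ("tau", "weight", "EC50", "n", "Ymax", "basal")

# default box constraints by parameter kind
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "tau": (1e-3, 1e2),
    "weight": (1e-9, 1.0),
    "EC50": (1e-3, 0.999),
    "n": (1.01, 4.0),
    "Ymax": (1e-3, 2.0),
    "basal": (0.0, 1.0),
}

_PENALTY = 1e3  # residual magnitude substituted when a simulation fails


@dataclass(frozen=True)
class FitParameter:
    """One free parameter: its kind and the species/reaction that owns it."""

    kind: str
    owner: str
    bounds: tuple[float, float] | None = None
    guess: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in PARAM_KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")

    def box(self) -> tuple[float, float]:
        return self.bounds if self.bounds is not None else DEFAULT_BOUNDS[self.kind]


@dataclass
class FitSpec:
    """A set of free parameters plus restart policy."""

    parameters: tuple[FitParameter, ...]
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.parameters = tuple(self.parameters)
        for p in self.parameters:
            lo, hi = p.box()
            if not lo < hi:
                raise ValueError(f"{p.kind}/{p.owner}: empty bounds ({lo}, {hi})")
            if p.guess is not None and not lo <= p.guess <= hi:
                raise ValueError(f"{p.kind}/{p.owner}: guess {p.guess} outside bounds")

    def validate_against(self, model: NetworkModel) -> None:
        for p in self.parameters:
            if p.kind in ("tau", "Ymax", "basal"):
                model.get_species(p.owner)
            else:
                model.get_reaction(p.owner)

    @classmethod
    def from_dicts(cls, items: Sequence[Mapping], restarts: int = 10, seed: int = 0) -> "FitSpec":
        """Build from YAML-style dicts: {kind, owner, [bounds], [guess]}."""
        params = tuple(
            FitParameter(
                kind=d["kind"],
                owner=d["owner"],
                bounds=tuple(d["bounds"]) if d.get("bounds") is not None else None,
                guess=d.get("guess"),
            )
            for d in items
        )
        return cls(parameters=params, restarts=restarts, seed=seed)


@dataclass
class FitResult:
    """Outcome of a multi-restart fit."""

    values: dict[str, float]  # "kind:owner" -> fitted value
    ssr: float
    converged: bool
    restarts: list[dict]  # per-restart {x0, x, ssr, status}
    model: NetworkModel  # model with fitted values applied


def add_basal(model: NetworkModel, species: str, basal: float) -> NetworkModel:
    """Add a constitutive (constant-source) drive to one state species.

    The new reaction OR-combines with the species' existing drive, so a
    basal of 0 leaves the model unchanged and a basal of 1 pins the species
    at Ymax.  Adding a second basal term to the same species is an error.
    """
    sp = model.get_species(species)
    if sp.role != "state":
        raise ModelValidationError(f"{species} is an input; basal drive needs a state species")
    rid = f"basal_{species}"
    if any(r.id == rid for r in model.reactions):
        raise ModelValidationError(f"{species} already has a basal term")
    return model.with_reactions(
        (*model.reactions, make_reaction(rid, f"=> {species}", weight=float(basal)))
    )


def _apply(model: NetworkModel, params: Sequence[FitParameter], x: np.ndarray) -> NetworkModel:
    species = {s.name: s for s in model.species}
    reactions = {r.id: r for r in model.reactions}
    for p, v in zip(params, x):
        v = float(v)
        if p.kind == "tau":
            species[p.owner] = replace(species[p.owner], tau=v)
        elif p.kind == "Ymax":
            s = species[p.owner]
            species[p.owner] = replace(s, Ymax=v, y0=min(s.y0, v))
        elif p.kind == "basal":
            reactions[f"basal_{p.owner}"] = replace(
                reactions[f"basal_{p.owner}"], weight=v
            )
        elif p.kind == "weight":
            reactions[p.owner] = replace(reactions[p.owner], weight=v)
        elif p.kind == "EC50":
            reactions[p.owner] = replace(reactions[p.owner], EC50=v)
        elif p.kind == "n":
            reactions[p.owner] = replace(reactions[p.owner], n=v)
    return NetworkModel(
        species=tuple(species.values()),
        reactions=tuple(reactions.values()),
        sensitivity_set=model.sensitivity_set,
        kernel=model.kernel,
        name=model.name,
    )


def fit(
    model: NetworkModel,
    spec: FitSpec,
    targets: pd.DataFrame,
    schedule: StimulusSchedule | None = None,
    config: SolverConfig | None = None,
) -> FitResult:
    """Fit the free parameters of ``spec`` to target time courses.

    ``targets`` is a table with a ``time`` column plus one column per fitted
    species (values normalized to [0, 1]).  Targets are linearly
    interpolated onto the simulation reporting grid and the summed squared
    residual over all (species, grid point) pairs is minimized with bounded
    trust-region least squares.  A simulation failure inside the objective
    contributes a large constant penalty instead of aborting the fit.
    """
    spec.validate_against(model)
    config = config or SolverConfig()
    if "time" not in targets.columns:
        raise ValueError("target table must have a 'time' column")
    target_species = [c for c in targets.columns if c != "time"]
    unknown = [c for c in target_species if c not in model.species_names]
    if unknown:
        raise ValueError(f"target column(s) not in model: {unknown}")

    # ensure basal reactions exist before parameters are applied
    work = model
    for p in spec.parameters:
        if p.kind == "basal" and not any(
            r.id == f"basal_{p.owner}" for r in work.reactions
        ):
            work = add_basal(work, p.owner, 0.0)

    t_end = float(targets["time"].max())
    grid_n = max(101, 2 * len(targets))
    t_grid = np.linspace(0.0, t_end, grid_n)
    y_target = np.column_stack(
        [
            np.interp(t_grid, targets["time"].to_numpy(), targets[c].to_numpy())
            for c in target_species
        ]
    )

    params = spec.parameters
    lo = np.array([p.box()[0] for p in params])
    hi = np.array([p.box()[1] for p in params])

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            m = _apply(work, params, x)
            traj = simulate(m, schedule, t_end=t_end, config=config, n_report=grid_n)
            sim = np.column_stack([traj[c] for c in target_species])
        except Exception:
            return np.full(y_target.size, _PENALTY)
        return (sim - y_target).ravel()

    if not params:
        r = residuals(np.empty(0))
        return FitResult(values={}, ssr=float(r @ r), converged=True, restarts=[], model=work)

    rng = np.random.default_rng(spec.seed)
    x0_list = [
        np.array([p.guess if p.guess is not None else (p.box()[0] + p.box()[1]) / 2 for p in params])
    ]
    for _ in range(max(0, spec.restarts - 1)):
        x0_list.append(lo + (hi - lo) * rng.random(len(params)))

    best = None
    records = []
    for x0 in x0_list:
        sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        ssr = float(sol.fun @ sol.fun)
        records.append(
            {"x0": x0.tolist(), "x": sol.x.tolist(), "ssr": ssr, "status": int(sol.status)}
        )
        if best is None or ssr < best[0]:
            best = (ssr, sol.x, sol.status)

    ssr, x_best, status = best
    fitted_model = _apply(work, params, x_best)
    values = {f"{p.kind}:{p.owner}": float(v) for p, v in zip(params, x_best)}
    return FitResult(
        values=values,
        ssr=ssr,
        converged=status > 0,
        restarts=records,
        model=fitted_model,
    )
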