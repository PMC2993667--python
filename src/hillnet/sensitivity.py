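"""All-against-all steady-state sensitivity analysis.

Each column of the sensitivity matrix is one numerical experiment: a single
species' maximal activity Ymax is reduced by a fraction dP (by default
-25%), the model is re-run to steady state, and the normalized sensitivity
of every measured species is computed as

    S_ij = (dY_i / dP_j) * (P_o,j / Y_o,i)

where dY_i is the change in species i's steady state, dP_j = Ymax_j * dP,
P_o,j = Ymax_j and Y_o,i is the unperturbed steady state.  Normalizing by
the baseline output and parameter makes entries comparable across species.
Entries with a near-zero baseline (|Y_o,i| < 1e-9) are undefined and are
NaN-masked rather than set to zero; comparisons exclude them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SolverConfig, steady_state
from .model import NetworkModel

__all__ = [
    "SensitivityMatrix",
    "QualitativeMatrix",
    "ComparisonReport",
    "sensitivity_matrix",
    "qualitative_classify",
    "compare_matrices",
    "robustness_scan",
]

_ZERO_BASELINE = 1e-9
DEFAULT_DP = -0.25
DEFAULT_THRESHOLD = 0.003


@dataclass
class SensitivityMatrix:
    """Labeled S_ij matrix (rows: measured i, columns: perturbed j)."""

    S: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    dP_frac: float
    baseline_inputs: dict
    nan_mask: np.ndarray
    non_converged_cols: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=list(self.row_labels), columns=list(self.col_labels))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, na_rep="")


@dataclass
class QualitativeMatrix:
    """Sign matrix in {-1, 0, +1} with the dead-zone threshold used."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    threshold: float
    nan_mask: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class ComparisonReport:
    """Element-wise agreement between two sensitivity matrices."""

    pearson_r: float
    n_compared: int
    n_match: int
    n_opposite: int
    threshold: float

    @property
    def match_fraction(self) -> float:
        return self.n_match / self.n_compared if self.n_compared else float("nan")

    def to_text(self) -> str:
        return (
            "sensitivity-matrix comparison\n"
            f"pearson_r={self.pearson_r:.6f}\n"
            f"n_compared={self.n_compared}\n"
            f"n_match={self.n_match}\n"
            f"n_opposite={self.n_opposite}\n"
            f"match_fraction={self.match_fraction:.6f}\n"
            f"threshold={self.threshold}\n"
        )


def _measure(result, labels: Sequence[str]) -> np.ndarray:
    return np.array([result[name] for name in labels])


def sensitivity_matrix(
    model: NetworkModel,
    baseline_inputs: Mapping[str, float],
    dP_frac: float = DEFAULT_DP,
    config: SolverConfig | None = None,
) -> SensitivityMatrix:
    """Compute the all-against-all sensitivity matrix of a model.

    Rows and columns run over ``model.sensitivity_set`` in species order.
    Perturbed runs continue from the cached baseline steady state, which is
    both faster and selects the physically continued branch in multistable
    regimes.  Non-converged runs fall back to the engine's last-10%
    time-average and are flagged in ``non_converged_cols``.
    """
    if not -1.0 < dP_frac < 0.0:
        raise ValueError(f"dP_frac must lie in (-1, 0), got {dP_frac}")
    config = config or SolverConfig()
    labels = tuple(model.sensitivity_set)
    name_to_i = {n: i for i, n in enumerate(model.species_names)}

    base = steady_state(model, baseline_inputs, config)
    bad_cols = []
    if not base.converged:
        warnings.warn("baseline run did not converge; using time-averaged state")
        bad_cols.append("__baseline__")
    y_base = _measure(base, labels)
    state_names = model.state_names
    base_states = np.array([base[n] for n in state_names])

    S = np.zeros((len(labels), len(labels)))
    for jcol, pname in enumerate(labels):
        perturbed_species = []
        for s in model.species:
            if s.name == pname:
                s = type(s)(
                    name=s.name, role=s.role, tau=s.tau,
                    Ymax=s.Ymax * (1.0 + dP_frac), y0=min(s.y0, s.Ymax * (1.0 + dP_frac)),
                )
            perturbed_species.append(s)
        pmodel = model.with_species(perturbed_species)
        # continue from the baseline steady state (clipped into the new box)
        y_init = np.minimum(
            base_states,
            np.array([pmodel.get_species(n).Ymax for n in state_names]),
        )
        res = steady_state(pmodel, baseline_inputs, config, y_init=y_init)
        if not res.converged:
            bad_cols.append(pname)
            warnings.warn(
                f"perturbed run for column {pname!r} did not converge; "
                "using time-averaged state"
            )
        y_pert = _measure(res, labels)
        with np.errstate(divide="ignore", invalid="ignore"):
            S[:, jcol] = (y_pert - y_base) / (dP_frac * y_base)

    nan_mask = np.abs(y_base)[:, None] < _ZERO_BASELINE
    nan_mask = np.broadcast_to(nan_mask, S.shape).copy()
    S[nan_mask] = np.nan
    return SensitivityMatrix(
        S=S,
        row_labels=labels,
        col_labels=labels,
        dP_frac=dP_frac,
        baseline_inputs=dict(baseline_inputs),
        nan_mask=nan_mask,
        non_converged_cols=tuple(bad_cols),
    )


def qualitative_classify(
    S: SensitivityMatrix, threshold: float = DEFAULT_THRESHOLD
) -> QualitativeMatrix:
    """Classify each sensitivity as activating (+1), inhibiting (-1) or
    neutral (0) with a dead-zone of ``threshold`` around zero.  NaN entries
    classify as 0 but keep their mask."""
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    vals = np.where(
        np.isnan(S.S), 0, np.where(S.S > threshold, 1, np.where(S.S < -threshold, -1, 0))
    ).astype(int)
    return QualitativeMatrix(
        values=vals,
        row_labels=S.row_labels,
        col_labels=S.col_labels,
        threshold=threshold,
        nan_mask=S.nan_mask.copy(),
    )


def compare_matrices(
    Sa: SensitivityMatrix,
    Sb: SensitivityMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    label_map: Mapping[str, str] | None = None,
) -> ComparisonReport:
    """Element-wise comparison of two sensitivity matrices.

    Pearson r is computed over the flattened, jointly finite entries;
    qualitative agreement counts matching signs after classification with
    ``threshold``.  ``label_map`` optionally renames Sb's labels onto Sa's
    before alignment; any label mismatch after mapping is an error.
    """
    rows_b, cols_b = Sb.row_labels, Sb.col_labels
    if label_map:
        rows_b = tuple(label_map.get(x, x) for x in rows_b)
        cols_b = tuple(label_map.get(x, x) for x in cols_b)
    if set(rows_b) != set(Sa.row_labels) or set(cols_b) != set(Sa.col_labels):
        raise ValueError("sensitivity matrices have mismatched labels")
    # align Sb onto Sa's ordering
    ri = [rows_b.index(x) for x in Sa.row_labels]
    ci = [cols_b.index(x) for x in Sa.col_labels]
    Sb_aligned = Sb.S[np.ix_(ri, ci)]

    a, b = Sa.S.ravel(), Sb_aligned.ravel()
    finite = np.isfinite(a) & np.isfinite(b)
    r = float(stats.pearsonr(a[finite], b[finite]).statistic)

    qa = qualitative_classify(Sa, threshold).values.ravel()
    qb_full = np.where(
        np.isnan(Sb_aligned), 0,
        np.where(Sb_aligned > threshold, 1, np.where(Sb_aligned < -threshold, -1, 0)),
    ).astype(int).ravel()
    n_match = int(np.sum(qa == qb_full))
    n_opposite = int(np.sum(qa * qb_full == -1))
    return ComparisonReport(
        pearson_r=r,
        n_compared=int(finite.sum()),
        n_match=n_match,
        n_opposite=n_opposite,
        threshold=threshold,
    )


def robustness_scan(
    model: NetworkModel,
    baseline_inputs: Mapping[str, float],
    axis: str,
    grid: Sequence[float],
    config: SolverConfig | None = None,
    reference: SensitivityMatrix | None = None,
) -> list[tuple[float, float]]:
    """Correlate sensitivity matrices across a parameter sweep.

    ``axis`` is one of ``dP_frac`` (perturbation magnitude), ``default_n``
    or ``default_EC50`` (applied to every reaction).  The reference matrix
    is computed at the defaults (dP=-0.25, n=1.4, EC50=0.5) unless given.
    Returns [(value, pearson r vs reference), ...]; a grid point whose
    (n, EC50) pair is invalid (non-real K) yields (value, nan).
    """
    if axis not in ("dP_frac", "default_n", "default_EC50"):
        raise ValueError(f"unknown scan axis {axis!r}")
    if not len(grid):
        raise ValueError("grid must be non-empty")
    config = config or SolverConfig()
    if reference is None:
        reference = sensitivity_matrix(model, baseline_inputs, DEFAULT_DP, config)

    out = []
    for value in grid:
        try:
            if axis == "dP_frac":
                mat = sensitivity_matrix(model, baseline_inputs, float(value), config)
            elif axis == "default_n":
                mat = sensitivity_matrix(
                    model.with_defaults(n=float(value)), baseline_inputs, DEFAULT_DP, config
                )
            else:
                mat = sensitivity_matrix(
                    model.with_defaults(ec50=float(value)), baseline_inputs, DEFAULT_DP, config
                )
        except ValueError as exc:
            warnings.warn(f"scan point {axis}={value} invalid: {exc}")
            out.append((float(value), float("nan")))
            continue
        out.append((float(value), compare_matrices(reference, mat).pearson_r))
    return out
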