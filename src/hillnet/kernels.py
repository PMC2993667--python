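"""Scalar activation kernels and logic-gate algebra.

The core kernel is the *normalized Hill function*: a Hill curve rescaled by
two derived constants ``B`` and ``K`` so that it passes exactly through
f(0) = 0, f(EC50) = 0.5 and f(1) = 1.  This keeps fractional activations on
a common [0, 1] scale as a signal propagates down a pathway, avoiding the
systematic amplification or attenuation that an unnormalized Hill curve
introduces at every step.

Three comparison kernels (traditional Hill, piecewise step, linear) share
the same interface so that a whole network model can be re-run with a
different scalar kernel while keeping weights, time constants and gate
logic identical.

Crosstalk between reactions converging on one species uses continuous
analogues of Boolean gates: AND is the product, OR is the probabilistic sum
(noisy-OR) ``1 - prod(1 - v_i)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "HillParams",
    "KernelKind",
    "SingularParameterError",
    "NonRealKError",
    "solve_bk",
    "f_act",
    "f_inhib",
    "gate_and",
    "gate_or",
    "kernel_variant",
]


class SingularParameterError(ValueError):
    """Raised when 2*EC50^n == 1, where the gain B is undefined."""


class NonRealKError(ValueError):
    """Raised when EC50^n >= 0.5, where K would not be real."""


def solve_bk(n: float, ec50: float) -> tuple[float, float]:
    """Solve for the normalization constants (B, K) of the Hill kernel.

    The constants are the unique closed-form solution of the three
    constraints f(0) = 0, f(EC50) = 0.5, f(1) = 1 applied to
    f(X) = B*X^n / (K^n + X^n):

        B = (EC50^n - 1) / (2*EC50^n - 1)
        K = (B - 1)^(1/n)

    Parameters
    ----------
    n : Hill coefficient, > 0.
    ec50 : half-maximal fractional activation, in (0, 1).

    Raises
    ------
    SingularParameterError
        If 2*EC50^n == 1 (denominator vanishes; e.g. n=1, EC50=0.5).
    NonRealKError
        If EC50^n >= 0.5, in which case B <= 1 and K is not real.
        Validity therefore requires EC50 < 0.5**(1/n).
    """
    if not n > 0:
        raise ValueError(f"Hill coefficient n must be > 0, got {n}")
    if not 0.0 < ec50 < 1.0:
        raise ValueError(f"EC50 must lie in (0, 1), got {ec50}")
    en = ec50**n
    denom = 2.0 * en - 1.0
    if denom == 0.0:
        raise SingularParameterError(
            f"2*EC50^n = 1 for n={n}, EC50={ec50}: gain B is undefined"
        )
    if en >= 0.5:
        raise NonRealKError(
            f"EC50^n = {en:.6g} >= 0.5 for n={n}, EC50={ec50}: "
            f"K is not real (need EC50 < 0.5**(1/n) = {0.5 ** (1.0 / n):.6g})"
        )
    b = (en - 1.0) / denom
    k = (b - 1.0) ** (1.0 / n)
    return b, k


@dataclass(frozen=True)
class HillParams:
    """Validated parameter set of one normalized Hill kernel.

    ``B`` and ``K`` are derived from ``(n, ec50)``; construct via
    :meth:`from_n_ec50` unless you already have a consistent tuple.
    """

    n: float
    ec50: float
    B: float
    K: float

    @classmethod
    def from_n_ec50(cls, n: float, ec50: float) -> "HillParams":
        b, k = solve_bk(n, ec50)
        return cls(n=n, ec50=ec50, B=b, K=k)


def f_act(x, params: HillParams):
    """Normalized activating Hill function, clamped to [0, 1].

    Returns B*x^n / (K^n + x^n) for 0 <= x < 1, exactly 1 for x >= 1 and
    exactly 0 for x <= 0.  The upper clamp keeps species activities limited
    to their maximal value; the lower clamp guards against transient solver
    undershoot.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    xn = np.where((x > 0.0) & (x < 1.0), x, 0.5) ** params.n
    core = params.B * xn / (params.K**params.n + xn)
    out = np.where(x <= 0.0, 0.0, np.where(x >= 1.0, 1.0, core))
    return float(out) if out.ndim == 0 else out


def f_inhib(x, params: HillParams):
    """Normalized inhibiting Hill function: exactly ``1 - f_act(x)``."""
    return 1.0 - f_act(x, params)


def _check_fractions(values: Iterable[float]) -> list[float]:
    vals = [float(v) for v in values]
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"gate input {v} outside [0, 1]")
    return vals


def gate_and(values: Sequence[float]) -> float:
    """Logical AND of fractional activities: the product.

    The empty gate returns 1 (the identity of the product).
    """
    return float(math.prod(_check_fractions(values)))


def gate_or(values: Sequence[float]) -> float:
    """Logical OR of fractional activities: the probabilistic sum.

    For two inputs this is f(x) + f(y) - f(x)f(y); the n-ary form
    1 - prod(1 - v_i) is its unique associative extension.  The empty gate
    returns 0.
    """
    return float(1.0 - math.prod(1.0 - v for v in _check_fractions(values)))


@dataclass(frozen=True)
class KernelKind:
    """Selector for the scalar activation kernel of a whole model.

    tag:
        ``normalized_hill``  — per-reaction (n, EC50) with derived (B, K);
            the ``n``/``ec50`` here are only defaults.
        ``traditional_hill`` — x^n / (K^n + x^n), no normalization; the
            global (n, K) here override per-reaction parameters.
        ``piecewise``        — step: 0 below ``threshold``, 1 at or above.
        ``linear``           — identity on [0, 1].
    """

    tag: str = "normalized_hill"
    n: float = 1.4
    ec50: float = 0.5
    K: float = 0.5
    threshold: float = 0.5

    TAGS = ("normalized_hill", "traditional_hill", "piecewise", "linear")

    def __post_init__(self) -> None:
        if self.tag not in self.TAGS:
            raise ValueError(f"unknown kernel kind {self.tag!r}; expected one of {self.TAGS}")

    # Common presets from the comparison study.
    @classmethod
    def traditional_hill_n3_k03(cls) -> "KernelKind":
        return cls(tag="traditional_hill", n=3.0, K=0.3)

    @classmethod
    def traditional_hill_n2_ec50_05(cls) -> "KernelKind":
        # for the unnormalized Hill form, K equals the EC50
        return cls(tag="traditional_hill", n=2.0, K=0.5)


def kernel_variant(x, kind: KernelKind):
    """Evaluate a comparison activation kernel (scalar or array input)."""
    x = np.asarray(x, dtype=float)
    if kind.tag == "linear":
        out = np.clip(x, 0.0, 1.0)
    elif kind.tag == "piecewise":
        out = np.where(x >= kind.threshold, 1.0, 0.0)
    elif kind.tag == "traditional_hill":
        xp = np.where(x > 0.0, x, 0.0)
        out = xp**kind.n / (kind.K**kind.n + xp**kind.n)
    elif kind.tag == "normalized_hill":
        out = np.asarray(f_act(x, HillParams.from_n_ec50(kind.n, kind.ec50)))
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown kernel kind {kind.tag!r}")
    return float(out) if out.ndim == 0 else out
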