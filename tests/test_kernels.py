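"""Normalized Hill kernels, comparison kernels, and gate algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import hillnet as hn
from hillnet.kernels import NonRealKError, SingularParameterError


def bk_oracle(n, ec50):
    """Independent (B, K): root-finding on the raw constraints
    f(EC50)=0.5 and f(1)=1 for f(x)=B*x^n/(K^n+x^n).

    f(1)=1 fixes B = K^n + 1; the remaining constraint in u = log K is
    solved by bracketed bisection (brentq), with no use of the closed form.
    """
    en = ec50**n

    def g(u):
        kn = np.exp(u * n)
        return (kn + 1.0) * en / (kn + en) - 0.5

    u = brentq(g, -40.0, 40.0, xtol=1e-15, rtol=8.9e-16)
    k = float(np.exp(u))
    return k**n + 1.0, k


class TestSolveBK:
    def test_matches_constraint_oracle_on_grid(self):
        for n in [1.01, 1.2, 1.4, 2.0, 3.0]:
            for frac in [0.1, 0.3, 0.5, 0.7, 0.9]:
                ec50 = frac * 0.5 ** (1.0 / n)  # stay inside validity region
                b, k = hn.solve_bk(n, ec50)
                b0, k0 = bk_oracle(n, ec50)
                assert b == pytest.approx(b0, abs=1e-10)
                assert k == pytest.approx(k0, abs=1e-10)

    def test_default_parameters(self):
        b, k = hn.solve_bk(1.4, 0.5)
        b0, k0 = bk_oracle(1.4, 0.5)
        assert (b, k) == pytest.approx((b0, k0), abs=1e-10)

    def test_singular_denominator(self):
        with pytest.raises(SingularParameterError):
            hn.solve_bk(1.0, 0.5)

    def test_non_real_K(self):
        # 0.7**1.4 ~ 0.607 >= 0.5, so B - 1 < 0 and K would be complex
        with pytest.raises(NonRealKError):
            hn.solve_bk(1.4, 0.7)

    @pytest.mark.parametrize("n,ec50", [(1.4, -0.1), (1.4, 1.0), (0.0, 0.3)])
    def test_domain_errors(self, n, ec50):
        with pytest.raises(ValueError):
            hn.solve_bk(n, ec50)


class TestNormalizedHill:
    @pytest.mark.parametrize("n", [1.01, 1.4, 2.0, 3.0])
    @pytest.mark.parametrize("frac", [0.2, 0.5, 0.8])
    def test_normalization_constraints_exact(self, n, frac):
        ec50 = frac * 0.5 ** (1.0 / n)
        p = hn.HillParams.from_n_ec50(n, ec50)
        assert hn.f_act(0.0, p) == pytest.approx(0.0, abs=1e-12)
        assert hn.f_act(ec50, p) == pytest.approx(0.5, abs=1e-12)
        assert hn.f_act(1.0, p) == pytest.approx(1.0, abs=1e-12)

    def test_half_activation_at_ec50_default(self):
        p = hn.HillParams.from_n_ec50(1.4, 0.5)
        assert hn.f_act(0.5, p) == pytest.approx(0.5, abs=1e-12)

    def test_clamps(self):
        p = hn.HillParams.from_n_ec50(1.4, 0.5)
        assert hn.f_act(1.3, p) == 1.0
        assert hn.f_act(-0.2, p) == 0.0
        assert hn.f_inhib(1.3, p) == 0.0
        assert hn.f_inhib(-0.2, p) == 1.0
        assert hn.f_inhib(0.0, p) == 1.0

    def test_quarter_activation_value(self):
        # direct evaluation of the kernel with oracle-verified (B, K)
        b, k = bk_oracle(1.4, 0.5)
        x = 0.25
        expected = b * x**1.4 / (k**1.4 + x**1.4)
        p = hn.HillParams.from_n_ec50(1.4, 0.5)
        assert hn.f_act(x, p) == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.2155, abs=5e-4)

    @pytest.mark.parametrize("n", [1.01, 1.4, 2.5])
    def test_monotone_nondecreasing(self, n):
        ec50 = 0.6 * 0.5 ** (1.0 / n)
        p = hn.HillParams.from_n_ec50(n, ec50)
        grid = np.linspace(0.0, 1.0, 2001)
        vals = hn.f_act(grid, p)
        assert np.all(np.diff(vals) >= -1e-15)
        assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_act_plus_inhib_is_one(self):
        p = hn.HillParams.from_n_ec50(1.7, 0.4)
        grid = np.linspace(-0.5, 1.5, 401)
        assert np.allclose(hn.f_act(grid, p) + hn.f_inhib(grid, p), 1.0, atol=0)


fractions = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestGates:
    def test_and_examples(self):
        assert hn.gate_and([1.0, 0.7]) == pytest.approx(0.7)
        assert hn.gate_and([0.5, 0.5]) == pytest.approx(0.25)
        assert hn.gate_and([]) == 1.0

    def test_or_examples(self):
        assert hn.gate_or([0.3, 0.4]) == pytest.approx(0.58)
        assert hn.gate_or([1.0, 0.123]) == 1.0
        assert hn.gate_or([0.37, 0.0]) == pytest.approx(0.37)
        assert hn.gate_or([]) == 0.0

    def test_or_matches_binary_formula(self):
        x, y = 0.21, 0.68
        assert hn.gate_or([x, y]) == pytest.approx(x + y - x * y, abs=1e-15)

    @pytest.mark.parametrize("gate", [hn.gate_and, hn.gate_or])
    def test_out_of_range_rejected(self, gate):
        with pytest.raises(ValueError):
            gate([0.5, 1.2])
        with pytest.raises(ValueError):
            gate([-0.1])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(fractions, min_size=2, max_size=5))
    def test_or_commutative_bounded(self, vals):
        assert hn.gate_or(vals) == pytest.approx(hn.gate_or(vals[::-1]), abs=1e-12)
        assert 0.0 <= hn.gate_or(vals) <= 1.0

    @settings(derandomize=True, max_examples=60)
    @given(fractions, fractions, fractions)
    def test_or_associative(self, x, y, z):
        left = hn.gate_or([hn.gate_or([x, y]), z])
        right = hn.gate_or([x, hn.gate_or([y, z])])
        assert left == pytest.approx(right, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(fractions, min_size=1, max_size=5))
    def test_and_below_min(self, vals):
        assert hn.gate_and(vals) <= min(vals) + 1e-15


class TestKernelVariants:
    def test_piecewise_step(self):
        kind = hn.KernelKind(tag="piecewise")
        assert hn.kernel_variant(0.49, kind) == 0.0
        assert hn.kernel_variant(0.5, kind) == 1.0

    def test_linear_identity(self):
        kind = hn.KernelKind(tag="linear")
        assert hn.kernel_variant(0.37, kind) == pytest.approx(0.37)

    def test_traditional_hill_half_max_at_K(self):
        kind = hn.KernelKind.traditional_hill_n3_k03()
        assert hn.kernel_variant(0.3, kind) == pytest.approx(0.5)
        # no normalization: does not reach 1 at x=1
        assert hn.kernel_variant(1.0, kind) < 1.0

    def test_traditional_hill_n2_preset(self):
        kind = hn.KernelKind.traditional_hill_n2_ec50_05()
        assert hn.kernel_variant(0.5, kind) == pytest.approx(0.5)

    def test_all_variants_map_unit_interval(self):
        grid = np.linspace(0.0, 1.0, 101)
        for kind in [
            hn.KernelKind(tag="linear"),
            hn.KernelKind(tag="piecewise"),
            hn.KernelKind.traditional_hill_n3_k03(),
            hn.KernelKind(tag="normalized_hill"),
        ]:
            vals = hn.kernel_variant(grid, kind)
            assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            hn.KernelKind(tag="sigmoid")
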