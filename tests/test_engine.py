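"""ODE assembly and integration against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import fsolve

import hillnet as hn


def _hill(x, n=1.4, ec50=0.5):
    """Independent normalized-Hill evaluation: (B, K) from a root-finder on
    the raw constraints, clamped like the model kernel."""

    def eqs(v):
        b, k = v
        return [
            b * ec50**n / (k**n + ec50**n) - 0.5,
            b / (k**n + 1.0) - 1.0,
        ]

    b, k = fsolve(eqs, [2.0, 1.0])
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    return b * x**n / (k**n + x**n)


def toy_rhs_oracle(a, b, c, d, e):
    """Hand-coded toy-network rate equations (states C, D, E)."""
    f = _hill
    dc = (f(a) + f(e) - f(a) * f(e)) - c
    dd = f(b) - d
    de = f(c) * (1.0 - f(d)) - e
    return np.array([dc, dd, de])


class TestAssembleRHS:
    def test_matches_hand_coded_oracle_at_random_states(self, toy):
        rng = np.random.default_rng(20240117)
        n_draws = 1000
        # each draw gets its own one-unit window of constant input levels
        draws = rng.random((n_draws, 5))
        sched = hn.StimulusSchedule(
            {
                "A": tuple((float(k), float(k) + 1.0, float(v)) for k, v in enumerate(draws[:, 0])),
                "B": tuple((float(k), float(k) + 1.0, float(v)) for k, v in enumerate(draws[:, 1])),
            }
        )
        rhs = hn.assemble_rhs(toy, sched)
        for k, (a, b, c, d, e) in enumerate(draws):
            got = rhs(k + 0.5, np.array([c, d, e]))
            want = toy_rhs_oracle(a, b, c, d, e)
            assert np.allclose(got, want, atol=1e-9), f"draw {k}"

    def test_fixed_point_has_zero_rate(self, toy):
        # with zero inputs the drive of every state is zero at the origin
        rhs = hn.assemble_rhs(toy)
        assert np.allclose(rhs(0.0, np.zeros(3)), 0.0)

    def test_state_at_drive_is_stationary(self, two_node_chain):
        sched = hn.StimulusSchedule.constant({"A": 1.0})
        rhs = hn.assemble_rhs(two_node_chain, sched)
        # drive of B is f_act(1) = 1, so y = 1 is the fixed point
        assert rhs(0.0, np.array([1.0])) == pytest.approx(0.0, abs=1e-12)


class TestSimulate:
    def test_toy_bistable_memory_and_erasure(self, toy):
        sched = hn.StimulusSchedule({"A": ((2.0, 12.0, 1.0),), "B": ((25.0, 35.0, 1.0),)})
        traj = hn.simulate(toy, sched, t_end=40.0, n_report=801)
        t = traj.times
        e_after_A = traj["E"][np.searchsorted(t, 20.0)]
        assert e_after_A > 0.5  # E latched on by the positive feedback loop
        assert traj["E"][-1] < 0.1  # memory erased by the B pulse

    def test_zero_inputs_stay_at_origin(self, toy):
        traj = hn.simulate(toy, t_end=10.0)
        assert np.allclose(traj.values, 0.0, atol=1e-9)

    def test_forward_invariance_betaAR(self, betaAR):
        sched = hn.StimulusSchedule({"NE": ((2.0, 12.0, 1.0),)})
        traj = hn.simulate(betaAR, sched, t_end=40.0)
        ymax = np.array([betaAR.get_species(n).Ymax for n in traj.species])
        assert np.all(traj.values >= -1e-6)
        assert np.all(traj.values <= ymax + 1e-6)

    def test_input_echoed_in_trajectory(self, toy):
        sched = hn.StimulusSchedule({"A": ((1.0, 3.0, 0.8),)})
        traj = hn.simulate(toy, sched, t_end=5.0, n_report=501)
        t = traj.times
        assert traj["A"][np.searchsorted(t, 2.0)] == pytest.approx(0.8)
        assert traj["A"][0] == 0.0

    def test_trajectory_csv_round_trip(self, toy, tmp_path):
        import pandas as pd

        traj = hn.simulate(toy, hn.StimulusSchedule.constant({"A": 1.0}), t_end=5.0)
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", *toy.species_names]
        assert np.allclose(df["E"].to_numpy(), traj["E"])

    def test_rejects_nonpositive_horizon(self, toy):
        with pytest.raises(ValueError):
            hn.simulate(toy, t_end=0.0)


class TestSteadyState:
    def test_chain_saturating_input(self, two_node_chain):
        res = hn.steady_state(two_node_chain, {"A": 1.0})
        assert res.converged
        assert res["B"] == pytest.approx(1.0, abs=1e-5)

    def test_chain_half_activation(self, two_node_chain):
        res = hn.steady_state(two_node_chain, {"A": 0.5})
        assert res["B"] == pytest.approx(0.5, abs=1e-5)

    def test_linear_chain_iterated_map_oracle(self):
        # A -> B -> C with unit weights: C_ss = f(f(u))
        m = hn.NetworkModel(
            species=(
                hn.SpeciesSpec("A", "input"),
                hn.SpeciesSpec("B", "state"),
                hn.SpeciesSpec("C", "state"),
            ),
            reactions=(hn.make_reaction("ab", "A => B"), hn.make_reaction("bc", "B => C")),
        )
        u = 0.7
        res = hn.steady_state(m, {"A": u})
        assert res["B"] == pytest.approx(_hill(u), abs=1e-5)
        assert res["C"] == pytest.approx(_hill(_hill(u)), abs=1e-5)

    def test_betaAR_baseline_interior(self, betaAR, baseline_inputs):
        res = hn.steady_state(betaAR, baseline_inputs)
        assert res.converged
        assert np.all(res.state >= 0.0) and np.all(res.state <= 1.0)
        for name in ["B1AR", "GsaGTP", "cAMP", "PKAC", "PLB"]:
            assert 0.0 < res[name] < 1.0

    def test_tau_rescales_transient_not_steady_state(self, two_node_chain):
        fast = two_node_chain.with_species(
            s if s.name != "B" else hn.SpeciesSpec("B", "state", tau=0.5)
            for s in two_node_chain.species
        )
        ss_slow = hn.steady_state(two_node_chain, {"A": 0.6})
        ss_fast = hn.steady_state(fast, {"A": 0.6})
        assert ss_fast["B"] == pytest.approx(ss_slow["B"], abs=1e-5)
        # but the transient differs: the fast variant is closer to its
        # asymptote at a fixed early time
        sched = hn.StimulusSchedule.constant({"A": 0.6})
        early = np.searchsorted(np.linspace(0, 10, 101), 1.0)
        slow_t = hn.simulate(two_node_chain, sched, t_end=10.0, n_report=101)
        fast_t = hn.simulate(fast, sched, t_end=10.0, n_report=101)
        assert fast_t["B"][early] > slow_t["B"][early]

    def test_unknown_input_rejected(self, two_node_chain):
        with pytest.raises(KeyError):
            hn.steady_state(two_node_chain, {"Z": 1.0})

    def test_dose_response_monotone_in_NE(self, betaAR):
        doses = np.linspace(0.0, 1.0, 6)
        curves = {"GsaGTP": [], "cAMP": [], "PLB": []}
        for ne in doses:
            res = hn.steady_state(betaAR, {"NE": float(ne)})
            for k in curves:
                curves[k].append(res[k])
        for k, vals in curves.items():
            assert np.all(np.diff(vals) >= -1e-6), f"{k} not nondecreasing"
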