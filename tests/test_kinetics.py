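"""Markov gating schemes: rate law, generator matrices, steady states,
occupancy integration, detailed balance, and the shipped channel library."""

import math

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from cgcell.kinetics import (
    GateSet,
    KineticScheme,
    RateLaw,
    SchemeError,
    check_detailed_balance,
    inactivated_fraction,
    integrate_occupancy,
    open_fraction,
    rate_at_voltage,
    steady_state,
    transition_matrix,
)
from cgcell.library import channel_library, dump_channel, load_channel


class TestRateLaw:
    @pytest.mark.parametrize(
        "k0,a,em,expected",
        [
            (0.37, 0.08, 0.0, 0.37),       # Em = 0 returns the base rate
            (1.0, 0.0, -120.0, 1.0),       # voltage-independent transition
            (0.2, 0.04, 25.0, 0.2 * math.e),  # direct exponential evaluation
        ],
    )
    def test_examples(self, k0, a, em, expected):
        assert rate_at_voltage(RateLaw(k0, a), em) == pytest.approx(expected, rel=1e-12)

    def test_extreme_voltage_saturates(self):
        law = RateLaw(1.0, 10.0)
        assert math.isfinite(rate_at_voltage(law, 1e6))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RateLaw(-1.0, 0.0)
        with pytest.raises(ValueError):
            RateLaw(1.0, math.nan)

    @given(
        k0=st.floats(0, 1e3),
        a=st.floats(-0.5, 0.5),
        em=st.floats(-150, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_nonnegative(self, k0, a, em):
        assert rate_at_voltage(RateLaw(k0, a), em) >= 0.0


class TestTransitionMatrix:
    def test_two_state_symmetric(self, two_state):
        q = transition_matrix(two_state, -50.0)
        k = 0.3
        assert np.allclose(q, [[-k, k], [k, -k]])

    def test_columns_sum_to_zero(self, three_chain, test_voltages):
        for v in test_voltages:
            q = transition_matrix(three_chain, v)
            assert np.abs(q.sum(axis=0)).max() < 1e-12

    def test_three_state_hand_assembled(self, three_chain):
        em = -30.0
        a = 0.5 * math.exp(0.02 * em)
        b = 0.2 * math.exp(-0.01 * em)
        c = 0.05 * math.exp(0.03 * em)
        d = 0.01 * math.exp(-0.04 * em)
        expected = np.array(
            [[-a, b, 0.0], [a, -(b + c), d], [0.0, c, -d]]
        )
        assert np.allclose(transition_matrix(three_chain, em), expected, atol=1e-14)

    def test_disconnected_scheme_rejected(self):
        with pytest.raises(SchemeError, match="disconnected"):
            KineticScheme(
                [("A", "closed"), ("B", "open"), ("X", "closed"), ("Y", "open")],
                [
                    ("A", "B", RateLaw(1.0)),
                    ("B", "A", RateLaw(1.0)),
                    ("X", "Y", RateLaw(1.0)),
                    ("Y", "X", RateLaw(1.0)),
                ],
            )


class TestSteadyState:
    def test_symmetric_two_state(self, two_state):
        assert np.allclose(steady_state(two_state, 0.0), [0.5, 0.5])

    def test_normalized_and_nonnegative(self, three_chain, test_voltages):
        for v in test_voltages:
            p = steady_state(three_chain, v)
            assert abs(p.sum() - 1.0) < 1e-12
            assert p.min() >= 0.0

    def test_matches_long_integration(self, three_chain):
        em = -60.0
        q = transition_matrix(three_chain, em)
        taus = 1.0 / np.abs(np.linalg.eigvals(q).real[np.abs(np.linalg.eigvals(q).real) > 1e-12])
        t_end = 100.0 * taus.max()
        dt = taus.min() / 20
        n = int(t_end / dt)
        p0 = np.array([1.0, 0.0, 0.0])
        traj = integrate_occupancy(three_chain, np.full(n, em), p0, dt)
        assert np.abs(traj[-1] - steady_state(three_chain, em)).max() < 1e-6


class TestIntegrateOccupancy:
    def test_steady_state_is_fixed_point(self, three_chain):
        em = -70.0
        p0 = steady_state(three_chain, em)
        traj = integrate_occupancy(three_chain, np.full(2000, em), p0, 0.025)
        assert np.abs(traj - p0).max() < 1e-9

    def test_conservation_along_varying_voltage(self, three_chain):
        t = np.arange(4000) * 0.025
        em = -80.0 + 40.0 * np.sin(2 * math.pi * t / 20.0)
        traj = integrate_occupancy(three_chain, em, None, 0.025)
        assert np.abs(traj.sum(axis=1) - 1.0).max() < 1e-9
        assert traj.min() >= -1e-12

    def test_expm_method_matches_direct_exponential(self, three_chain):
        # step from -90 to -20: the expm integration path must agree with a
        # directly computed matrix-exponential propagation
        em = np.concatenate([np.full(50, -90.0), np.full(50, -20.0)])
        p0 = steady_state(three_chain, -90.0)
        dt = 0.1
        ex = integrate_occupancy(three_chain, em, p0, dt, method="expm")
        p = p0.copy()
        ref = [p0]
        for v in em[1:]:
            p = scipy.linalg.expm(dt * transition_matrix(three_chain, v)) @ p
            ref.append(p)
        assert np.abs(ex - np.array(ref)).max() < 1e-6

    def test_backward_euler_first_order_convergence(self, three_chain):
        # backward Euler converges to the exponential reference linearly in dt
        errs = []
        for dt in (0.04, 0.02, 0.01):
            n = int(round(4.0 / dt))
            em = np.full(n, -20.0)
            p0 = steady_state(three_chain, -90.0)
            be = integrate_occupancy(three_chain, em, p0, dt, method="backward-euler")
            ex = integrate_occupancy(three_chain, em, p0, dt, method="expm")
            errs.append(np.abs(be - ex).max())
        assert errs[0] < 5e-3
        assert errs[2] < errs[0] / 2.5  # roughly linear reduction

    def test_gateset_gates_independent(self, two_state, three_chain):
        gs = GateSet((two_state, three_chain))
        em = np.full(100, -50.0)
        trajs = integrate_occupancy(gs, em, None, 0.025)
        solo = integrate_occupancy(three_chain, em, None, 0.025)
        assert np.allclose(trajs[1], solo)


class TestOpenAndInactivatedFraction:
    def test_product_of_gates(self, two_state):
        gs = GateSet((two_state, two_state))
        occ = [np.array([0.4, 0.6]), np.array([0.5, 0.5])]
        assert open_fraction(occ, gs) == pytest.approx(0.3)

    def test_all_open_and_any_zero(self, two_state):
        gs = GateSet((two_state, two_state))
        assert open_fraction([np.array([0.0, 1.0])] * 2, gs) == pytest.approx(1.0)
        assert open_fraction(
            [np.array([0.0, 1.0]), np.array([1.0, 0.0])], gs
        ) == pytest.approx(0.0)

    def test_multiplicity_exponent(self, two_state):
        gs = GateSet((two_state,), (3,))
        assert open_fraction([np.array([0.5, 0.5])], gs) == pytest.approx(0.125)

    def test_inactivated_sum(self):
        s = KineticScheme(
            [("C", "closed"), ("O", "open"), ("I1", "inactivated"), ("I2", "inactivated")],
            [
                ("C", "O", RateLaw(1.0)), ("O", "C", RateLaw(1.0)),
                ("O", "I1", RateLaw(1.0)), ("I1", "O", RateLaw(1.0)),
                ("I1", "I2", RateLaw(1.0)), ("I2", "I1", RateLaw(1.0)),
            ],
        )
        occ = np.array([0.3, 0.2, 0.4, 0.1])
        assert inactivated_fraction(occ, s) == pytest.approx(0.5)

    def test_no_inactivated_states_rejected(self, two_state):
        with pytest.raises(SchemeError):
            inactivated_fraction(np.array([0.5, 0.5]), two_state)


def _four_cycle(scale_one_rate=1.0):
    rates = {
        ("A", "B"): 1.0, ("B", "A"): 2.0,
        ("B", "C"): 3.0, ("C", "B"): 1.5,
        ("C", "D"): 0.5, ("D", "C"): 1.0,
        ("D", "A"): 2.0 * scale_one_rate, ("A", "D"): 1.0,
    }
    # forward product = 1*3*0.5*2 = 3 ; reverse = 2*1.5*1*1 = 3  (balanced)
    return KineticScheme(
        [("A", "closed"), ("B", "closed"), ("C", "open"), ("D", "closed")],
        [(s, t, RateLaw(k)) for (s, t), k in rates.items()],
    )


class TestDetailedBalance:
    def test_acyclic_scheme_has_no_cycles(self, three_chain):
        assert check_detailed_balance(three_chain, -60.0) == {}

    def test_balanced_cycle(self):
        res = check_detailed_balance(_four_cycle(), 0.0)
        assert len(res) == 1
        assert next(iter(res.values())) < 1e-10

    def test_one_rate_doubled_gives_log2(self):
        res = check_detailed_balance(_four_cycle(scale_one_rate=2.0), 0.0)
        assert next(iter(res.values())) == pytest.approx(math.log(2.0), abs=1e-10)

    def test_missing_reverse_rate_reported_infinite(self):
        s = KineticScheme(
            [("A", "closed"), ("B", "open"), ("C", "closed")],
            [
                ("A", "B", RateLaw(1.0)), ("B", "A", RateLaw(1.0)),
                ("B", "C", RateLaw(1.0)), ("C", "B", RateLaw(1.0)),
                ("C", "A", RateLaw(1.0)),  # no A -> C back rate
            ],
        )
        res = check_detailed_balance(s, 0.0)
        assert math.isinf(next(iter(res.values())))


class TestChannelLibrary:
    def test_all_entries_load(self, library):
        assert set(library) == {
            "ISA_control", "ISA_rnai", "TASK3", "K2P", "leak_Na",
            "Na", "Ca", "Kdr", "KCa",
        }

    def test_scheme_files_round_trip(self, library, tmp_path):
        for name in ("ISA_control", "TASK3", "Na"):
            p = tmp_path / f"{name}.yaml"
            dump_channel(library[name], p)
            again = load_channel(p)
            orig = library[name]
            assert again.g_max == orig.g_max
            assert again.e_rev_mV == orig.e_rev_mV
            if isinstance(orig.gating, KineticScheme):
                for t1, t2 in zip(orig.gating.transitions, again.gating.transitions):
                    assert t1.law.k0 == t2.law.k0  # bit-exact floats
                    assert t1.law.a == t2.law.a

    def test_isa_schemes_satisfy_detailed_balance(self, library, test_voltages):
        for name in ("ISA_control", "ISA_rnai"):
            scheme = library[name].gating
            for v in test_voltages:
                for residual in check_detailed_balance(scheme, v).values():
                    assert residual < 1e-6

    def test_steady_state_matches_long_integration_all_schemes(self, library, test_voltages):
        # the implicit integrator is A-stable, so at constant voltage a step of
        # a tenth of the slowest time constant reaches the fixed point; run to
        # 100x the slowest tau
        for name in ("ISA_control", "ISA_rnai", "TASK3", "K2P"):
            gating = library[name].gating
            gates = gating.gates if isinstance(gating, GateSet) else (gating,)
            for gate in gates:
                for v in test_voltages:
                    q = transition_matrix(gate, v)
                    ev = np.linalg.eigvals(q).real
                    tau_slow = 1.0 / np.abs(ev[np.abs(ev) > 1e-9]).min()
                    dt = tau_slow / 10.0
                    n = 1000  # = 100 * tau_slow / dt
                    p0 = np.zeros(gate.n_states)
                    p0[0] = 1.0
                    traj = integrate_occupancy(gate, np.full(n, v), p0, dt)
                    assert np.abs(traj[-1] - steady_state(gate, v)).max() < 1e-6

    def test_k2p_family_open_fraction_monotone(self, library):
        vs = np.arange(-120.0, 40.1, 5.0)
        for name in ("TASK3", "K2P"):
            gating = library[name].gating
            p = [
                np.prod(
                    [
                        steady_state(g, v)[g.conducting_index].sum() ** m
                        for g, m in zip(gating.gates, gating.multiplicities)
                    ]
                )
                for v in vs
            ]
            assert np.all(np.diff(p) >= -1e-12)

    def test_isa_availability_monotone_decreasing(self, library):
        vs = np.arange(-120.0, 40.1, 5.0)
        for name in ("ISA_control", "ISA_rnai"):
            scheme = library[name].gating
            avail = [
                1.0 - inactivated_fraction(steady_state(scheme, v), scheme) for v in vs
            ]
            assert np.all(np.diff(avail) <= 1e-12)

    def test_rnai_scheme_inactivates_only_through_closed_states(self, library):
        scheme = library["ISA_rnai"].gating
        for t in scheme.transitions:
            if scheme.roles[t.source] == "open":
                assert scheme.roles[t.target] != "inactivated"
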