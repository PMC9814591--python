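"""Schedules, time grids, instantaneous assembly and Trotter propagation."""

import math

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, strategies as st

from aspsim import (
    SCHEDULES,
    PauliTerm,
    QubitHamiltonian,
    ScheduleSpec,
    StateVector,
    apply_pauli_rotation,
    build_fock_hamiltonian,
    build_full_hamiltonian,
    build_s2_operator,
    instantaneous_hamiltonian,
    jordan_wigner,
    make_time_grid,
    order_terms,
    schedule_value,
    to_matrix,
    trotter_step,
)
from aspsim.schedule_propagator import CompiledPropagator


class TestSchedules:
    def test_sinusoidal_midpoint_value(self):
        assert schedule_value("Sin", 0.5) == pytest.approx(0.7071067811865476, abs=1e-15)

    @pytest.mark.parametrize("name", sorted(SCHEDULES))
    def test_endpoints(self, name):
        assert schedule_value(name, 0.0) == pytest.approx(0.0, abs=1e-15)
        assert schedule_value(name, 1.0) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("name", ["Squ", "Cub"])
    def test_odd_symmetry_about_midpoint(self, name):
        assert schedule_value(name, 0.5) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize(
        "name,slope", [("Lin", 1.0), ("Squ", 0.0), ("SinCub", 0.0), ("Cub", 0.0)]
    )
    def test_initial_gradient_by_finite_differences(self, name, slope):
        h = 1e-6
        fd = (schedule_value(name, h) - schedule_value(name, 0.0)) / h
        assert fd == pytest.approx(slope, abs=1e-4)

    @pytest.mark.parametrize("name", sorted(SCHEDULES))
    @given(x=st.floats(min_value=0.0, max_value=1.0), d=st.floats(min_value=0.0, max_value=1.0))
    def test_bounded_and_monotone(self, name, x, d):
        x2 = min(1.0, x + d)
        v1, v2 = schedule_value(name, x), schedule_value(name, x2)
        assert -1e-12 <= v1 <= 1.0 + 1e-12
        assert v2 >= v1 - 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            schedule_value("Sin", 1.2)
        with pytest.raises(KeyError):
            schedule_value("Quintic", 0.5)


class TestTimeGrid:
    @pytest.mark.parametrize(
        "T,M", [(10.0, 20), (0.4, 1), (10.25, 21), (50.0, 100), (70.0, 140)]
    )
    def test_ceil_rule(self, T, M):
        m, dt = make_time_grid(T)
        assert m == M
        assert dt == pytest.approx(T / M)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            make_time_grid(0.0)

    def test_spec_defaults(self):
        spec = ScheduleSpec(name="Sin", T=10.0)
        assert spec.M == 20 and spec.dt == 0.5 and spec.trotter_order == 2


@pytest.fixture(scope="module")
def toy_operators(toy_dissociation):
    n = 4
    h_full = jordan_wigner(build_full_hamiltonian(toy_dissociation), n).realified()
    h_fock = jordan_wigner(build_fock_hamiltonian(toy_dissociation), n).realified()
    s2 = jordan_wigner(build_s2_operator(np.eye(2), 2), n).realified()
    return h_fock, h_full, s2


class TestInstantaneousHamiltonian:
    def test_endpoint_limits(self, toy_operators):
        h_fock, h_full, s2 = toy_operators
        spec = ScheduleSpec(name="Lin", T=5.0, penalty_c=0.5)
        h_end = instantaneous_hamiltonian(h_fock, h_full, s2, spec, spec.M)
        direct = h_full + 0.5 * s2
        assert max(abs(c) for c in (h_end - direct).mask_terms.values()) < 1e-12

    @pytest.mark.parametrize("name", sorted(SCHEDULES))
    def test_subset_assembly_equals_convex_combination(self, toy_operators, name):
        """Fock strings held at full weight + s-scaled rest == (1-s) H_I + s H_P."""
        h_fock, h_full, s2 = toy_operators
        spec = ScheduleSpec(name=name, T=7.0, penalty_c=0.5)
        for m in (1, spec.M // 2, spec.M):
            s = spec.s(m)
            h_m = instantaneous_hamiltonian(h_fock, h_full, s2, spec, m)
            direct = (1 - s) * h_fock + s * h_full + (s * 0.5) * s2
            diff = h_m - direct
            assert max(abs(c) for c in diff.mask_terms.values()) < 1e-12

    def test_unscaled_penalty_switch(self, toy_operators):
        h_fock, h_full, s2 = toy_operators
        spec = ScheduleSpec(name="Lin", T=5.0, penalty_c=0.5, penalty_scaled=False)
        h_1 = instantaneous_hamiltonian(h_fock, h_full, s2, spec, 1)
        s = spec.s(1)
        direct = (1 - s) * h_fock + s * h_full + 0.5 * s2
        assert max(abs(c) for c in (h_1 - direct).mask_terms.values()) < 1e-12

    def test_foreign_fock_string_rejected(self, toy_operators):
        h_fock, h_full, _ = toy_operators
        bad = h_fock + QubitHamiltonian.from_terms(4, [PauliTerm(0.1, "XXXX")])
        spec = ScheduleSpec(name="Lin", T=5.0)
        with pytest.raises(ValueError, match="absent"):
            instantaneous_hamiltonian(bad, h_full, None, spec, 1)


class TestOrdering:
    def test_magnitude_descending(self):
        h = QubitHamiltonian.from_terms(
            2, [PauliTerm(0.1, "XI"), PauliTerm(-0.5, "IZ"), PauliTerm(0.3, "ZZ")]
        )
        coeffs = [t.coefficient for t in order_terms(h, "magnitude")]
        assert coeffs == [-0.5, 0.3, 0.1]

    def test_tie_break_is_lexicographic(self):
        h = QubitHamiltonian.from_terms(2, [PauliTerm(0.5, "XI"), PauliTerm(0.5, "IZ")])
        assert [t.string for t in order_terms(h, "magnitude")] == ["IZ", "XI"]

    def test_stable_under_input_shuffle(self, rng):
        terms = [PauliTerm(c, s) for c, s in
                 [(0.3, "XY"), (-0.3, "ZI"), (0.1, "IX"), (0.7, "YY"), (0.1, "ZZ")]]
        ref = None
        for _ in range(5):
            perm = rng.permutation(len(terms))
            h = QubitHamiltonian.from_terms(2, [terms[i] for i in perm])
            out = [(t.coefficient, t.string) for t in order_terms(h, "magnitude")]
            if ref is None:
                ref = out
            assert out == ref

    def test_lexicographic_strategy(self):
        h = QubitHamiltonian.from_terms(2, [PauliTerm(1.0, "ZI"), PauliTerm(0.1, "IX")])
        assert [t.string for t in order_terms(h, "lexicographic")] == ["IX", "ZI"]


class TestRotations:
    def test_zero_angle_is_identity(self, rng):
        psi = StateVector(rng.normal(size=8) + 1j * rng.normal(size=8), 3)
        out = apply_pauli_rotation(psi, "XYZ", 0.0)
        assert np.array_equal(out.amplitudes, psi.amplitudes)

    def test_z_eigenstate_acquires_phase(self):
        psi = StateVector.basis_state([], 1)  # |0>, Z eigenvalue +1
        out = apply_pauli_rotation(psi, "Z", 0.3)
        assert out.amplitudes[0] == pytest.approx(np.exp(-0.3j))

    @given(
        st.lists(st.sampled_from("IXYZ"), min_size=3, max_size=3),
        st.floats(min_value=-3.0, max_value=3.0),
    )
    def test_matches_matrix_exponential_oracle(self, chars, theta):
        s = "".join(chars)
        rng = np.random.default_rng(7)
        amp = rng.normal(size=8) + 1j * rng.normal(size=8)
        amp /= np.linalg.norm(amp)
        psi = StateVector(amp, 3)
        h = QubitHamiltonian.from_terms(3, [PauliTerm(1.0, s)])
        expected = sla.expm(-1j * theta * to_matrix(h)) @ amp
        out = apply_pauli_rotation(psi, s, theta)
        assert np.abs(out.amplitudes - expected).max() < 1e-12
        assert out.norm == pytest.approx(1.0, abs=1e-12)


@pytest.fixture
def noncommuting_h():
    return QubitHamiltonian.from_terms(
        2, [PauliTerm(1.0, "ZI"), PauliTerm(0.6, "XX"), PauliTerm(0.4, "IZ")]
    )


class TestTrotterStep:
    def test_commuting_terms_are_exact(self):
        h = QubitHamiltonian.from_terms(
            2, [PauliTerm(0.7, "ZI"), PauliTerm(-0.4, "IZ"), PauliTerm(0.2, "ZZ")]
        )
        amp = np.full(4, 0.5, dtype=complex)
        psi = StateVector(amp, 2)
        spec = ScheduleSpec(name="Lin", T=1.0)
        out = trotter_step(psi, h, 0.37, spec)
        expected = sla.expm(-1j * to_matrix(h) * 0.37) @ amp
        assert np.abs(out.amplitudes - expected).max() < 1e-12

    def test_second_order_error_scaling(self, noncommuting_h):
        """Error of one order-2 step falls ~8x when dt is halved."""
        amp = np.full(4, 0.5, dtype=complex)
        psi = StateVector(amp, 2)
        spec = ScheduleSpec(name="Lin", T=1.0)
        hmat = to_matrix(noncommuting_h)

        def err(dt):
            exact = sla.expm(-1j * hmat * dt) @ amp
            approx = trotter_step(psi, noncommuting_h, dt, spec).amplitudes
            return np.linalg.norm(exact - approx)

        assert err(0.1) / err(0.05) == pytest.approx(8.0, rel=0.08)
        assert err(0.05) / err(0.025) == pytest.approx(8.0, rel=0.04)

    def test_first_order_error_scaling(self, noncommuting_h):
        """Local error of one forward-product step is O(dt^2): 4x per halving."""
        amp = np.full(4, 0.5, dtype=complex)
        psi = StateVector(amp, 2)
        spec = ScheduleSpec(name="Lin", T=1.0, trotter_order=1)
        hmat = to_matrix(noncommuting_h)

        def err(dt):
            exact = sla.expm(-1j * hmat * dt) @ amp
            return np.linalg.norm(exact - trotter_step(psi, noncommuting_h, dt, spec).amplitudes)

        assert err(0.1) / err(0.05) == pytest.approx(4.0, rel=0.1)

    def test_palindromic_reversibility(self, noncommuting_h, rng):
        amp = rng.normal(size=4) + 1j * rng.normal(size=4)
        amp /= np.linalg.norm(amp)
        psi = StateVector(amp.copy(), 2)
        spec = ScheduleSpec(name="Lin", T=1.0)
        fwd = trotter_step(psi, noncommuting_h, 0.4, spec)
        back = trotter_step(fwd, noncommuting_h, -0.4, spec)
        assert np.abs(back.amplitudes - amp).max() < 1e-10

    def test_repetitions_reduce_error(self, noncommuting_h):
        amp = np.full(4, 0.5, dtype=complex)
        psi = StateVector(amp, 2)
        hmat = to_matrix(noncommuting_h)
        exact = sla.expm(-1j * hmat * 0.5) @ amp
        errs = []
        for L in (1, 4):
            spec = ScheduleSpec(name="Lin", T=1.0, L=L)
            errs.append(np.linalg.norm(exact - trotter_step(psi, noncommuting_h, 0.5, spec).amplitudes))
        assert errs[1] < errs[0] / 4


class TestCompiledPropagator:
    def test_identical_to_reference_stepper(self, toy_operators):
        """Fast path reproduces trotter_step on the assembled Hamiltonian bitwise."""
        h_fock, h_full, s2 = toy_operators
        spec = ScheduleSpec(name="Squ", T=6.0, penalty_c=0.5)
        psi_fast = StateVector.basis_state([0, 1], 4)
        psi_slow = StateVector.basis_state([0, 1], 4)
        prop = CompiledPropagator(4, h_fock, h_full, s2, spec)
        for m in range(1, spec.M + 1):
            psi_fast = prop.step(psi_fast, m)
            h_m = instantaneous_hamiltonian(h_fock, h_full, s2, spec, m)
            psi_slow = trotter_step(psi_slow, h_m, spec.dt, spec)
        assert np.array_equal(psi_fast.amplitudes, psi_slow.amplitudes)

    def test_norm_conserved_over_full_sweep(self, toy_operators):
        h_fock, h_full, s2 = toy_operators
        spec = ScheduleSpec(name="Sin", T=25.0)
        prop = CompiledPropagator(4, h_fock, h_full, s2, spec)
        psi = StateVector.basis_state([0, 1], 4)
        for m in range(1, spec.M + 1):
            psi = prop.step(psi, m)
        assert psi.norm == pytest.approx(1.0, abs=1e-8)
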