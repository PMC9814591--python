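"""Sector bases, exact diagonalization, metrics, landscapes, spin analysis."""

import math

import numpy as np
import pytest

from aspsim import (
    ScheduleSpec,
    StateVector,
    ToyModelSpec,
    adiabatic_bound,
    build_fock_hamiltonian,
    build_full_hamiltonian,
    build_s2_operator,
    casci_solve,
    expectation,
    gap_landscape,
    jordan_wigner,
    prepare_determinant,
    sector_basis,
    spin_component_weights,
    square_overlap,
    to_matrix,
    toy_closed_form,
    toy_integrals,
)


class TestSectorBasis:
    def test_two_electron_ms0_combinatorics(self):
        basis = sector_basis(4, 2, 0.0)
        assert len(basis) == 4  # one alpha choice x one beta choice per orbital

    def test_vacuum_sector(self):
        assert list(sector_basis(4, 0, 0.0)) == [0]

    def test_partition_completeness(self):
        n = 6
        total = 0
        for n_elec in range(n + 1):
            for twice_ms in range(-n_elec, n_elec + 1):
                total += len(sector_basis(n, n_elec, twice_ms / 2.0))
        assert total == 1 << n

    def test_infeasible_sector_is_empty(self):
        assert len(sector_basis(4, 1, 1.0)) == 0


class TestCasciSolve:
    def test_single_determinant_sector(self, toy_equilibrium):
        h = jordan_wigner(build_full_hamiltonian(toy_equilibrium), 4).realified()
        basis = sector_basis(4, 2, 1.0)  # two alpha electrons: one determinant...
        assert len(basis) == 1
        sol = casci_solve(h, basis, k=1)
        det = StateVector(np.zeros(16, complex), 4)
        det.amplitudes[basis[0]] = 1.0
        assert sol.ground_energy == pytest.approx(expectation(h, det), abs=1e-12)

    def test_toy_closed_form(self, toy_dissociation):
        h = jordan_wigner(build_full_hamiltonian(toy_dissociation), 4).realified()
        sol = casci_solve(h, sector_basis(4, 2, 0.0), k=2)
        cf = toy_closed_form(ToyModelSpec.dissociation())
        assert sol.ground_energy == pytest.approx(cf["E0"], abs=1e-10)

    def test_sector_solve_matches_dense_diagonalization(self, toy_dissociation):
        h = jordan_wigner(build_full_hamiltonian(toy_dissociation), 4).realified()
        full = np.linalg.eigvalsh(to_matrix(h).real)
        basis = sector_basis(4, 2, 0.0)
        sol = casci_solve(h, basis, k=len(basis))
        for e in sol.energies:
            assert np.min(np.abs(full - e)) < 1e-10

    def test_states_orthonormal(self, toy_dissociation):
        h = jordan_wigner(build_full_hamiltonian(toy_dissociation), 4).realified()
        sol = casci_solve(h, sector_basis(4, 2, 0.0), k=4)
        for i, a in enumerate(sol.states):
            for j, b in enumerate(sol.states):
                assert a.overlap(b) == pytest.approx(float(i == j), abs=1e-10)

    def test_spin_projection_resolves_degeneracies(self, toy_dissociation):
        """Covalent singlet and triplet are degenerate at dissociation; the
        projected solve must return the spin-pure singlet."""
        h = jordan_wigner(build_full_hamiltonian(toy_dissociation), 4).realified()
        s2 = jordan_wigner(build_s2_operator(np.eye(2), 2), 4).realified()
        basis = sector_basis(4, 2, 0.0)
        sol = casci_solve(h, basis, k=2, project_spin=(s2, 0.0))
        assert expectation(s2, sol.ground_state) == pytest.approx(0.0, abs=1e-10)


class TestMetrics:
    def test_self_overlap_and_orthogonality(self):
        a = StateVector.basis_state([0], 2)
        b = StateVector.basis_state([1], 2)
        assert square_overlap(a, a) == pytest.approx(1.0)
        assert square_overlap(a, b) == pytest.approx(0.0)

    def test_overlap_phase_invariance_and_symmetry(self, rng):
        x = rng.normal(size=8) + 1j * rng.normal(size=8)
        y = rng.normal(size=8) + 1j * rng.normal(size=8)
        x /= np.linalg.norm(x)
        y /= np.linalg.norm(y)
        a, b = StateVector(x, 3), StateVector(y, 3)
        direct = abs(np.vdot(x, y)) ** 2
        assert square_overlap(a, b) == pytest.approx(direct, abs=1e-12)
        assert square_overlap(b, a) == pytest.approx(direct, abs=1e-12)
        assert square_overlap(StateVector(np.exp(0.7j) * x, 3), b) == pytest.approx(
            direct, abs=1e-12
        )

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            square_overlap(StateVector.basis_state([], 2), StateVector.basis_state([], 3))

    def test_identity_expectation(self, rng):
        from aspsim import PauliTerm, QubitHamiltonian

        x = rng.normal(size=4) + 1j * rng.normal(size=4)
        x /= np.linalg.norm(x)
        h = QubitHamiltonian.from_terms(2, [PauliTerm(1.0, "II")])
        assert expectation(h, StateVector(x, 2)) == pytest.approx(1.0, abs=1e-12)

    def test_hf_energy_matches_closed_form(self, toy_equilibrium):
        h = jordan_wigner(build_full_hamiltonian(toy_equilibrium), 4).realified()
        hf = prepare_determinant([0, 1], 4)
        cf = toy_closed_form(ToyModelSpec.equilibrium())
        assert expectation(h, hf) == pytest.approx(cf["E_hf"], abs=1e-10)


@pytest.fixture(scope="module")
def toy_system(toy_dissociation):
    n = 4
    h_full = jordan_wigner(build_full_hamiltonian(toy_dissociation), n).realified()
    h_fock = jordan_wigner(build_fock_hamiltonian(toy_dissociation), n).realified()
    s2 = jordan_wigner(build_s2_operator(np.eye(2), 2), n).realified()
    basis = sector_basis(n, 2, 0.0)
    return h_fock, h_full, s2, basis


class TestGapLandscape:
    def test_flat_when_initial_equals_final(self, toy_system):
        _, h_full, s2, basis = toy_system
        spec = ScheduleSpec(name="Lin", T=5.0)
        df = gap_landscape(h_full, h_full, s2, spec, [0.0, 0.5, 1.0], basis, k=4)
        gaps = df["gap"].to_numpy()
        assert np.nanmax(gaps) - np.nanmin(gaps) < 1e-10

    def test_endpoints_match_direct_diagonalization(self, toy_system):
        h_fock, h_full, s2, basis = toy_system
        spec = ScheduleSpec(name="Lin", T=5.0, penalty_c=0.5)
        df = gap_landscape(h_fock, h_full, s2, spec, [0.0, 1.0], basis, k=4)
        for h_end, row in ((h_fock, df.iloc[0]), (h_full + 0.5 * s2, df.iloc[1])):
            sol = casci_solve(h_end, basis, k=4)
            sol.attach_s2(s2)
            singlets = [e for e, v in zip(sol.energies, sol.s2_values) if v < 0.1]
            assert row["gap"] == pytest.approx(singlets[1] - singlets[0], abs=1e-10)

    def test_toy_two_level_closed_form(self, toy_system):
        """Avoided-crossing gap matches the analytic 2x2 expression.

        Restricted to the closed-shell pair {|g g-bar>, |u u-bar>}, the
        interpolated Hamiltonian is a 2x2 matrix with diagonal (H_gg,
        s * H_uu) (the Fock operator annihilates |u u-bar>) and off-diagonal
        s * K_gu, so the gap is sqrt((H_gg - s H_uu)^2 + 4 s^2 K_gu^2).
        """
        h_fock, h_full, _, _ = toy_system
        spec = ToyModelSpec.dissociation()
        cf_hgg = 2 * spec.eps_g + spec.j_gg
        cf_huu = 2 * spec.eps_u + spec.j_uu
        closed_shell = np.array([0b0011, 0b1100])
        sspec = ScheduleSpec(name="Lin", T=5.0)
        grid = [0.25, 0.5, 0.75]
        df = gap_landscape(h_fock, h_full, None, sspec, grid, closed_shell, k=2)
        for s, row in zip(grid, df.itertuples()):
            gap = math.hypot(cf_hgg - s * cf_huu, 2 * s * spec.k_gu)
            assert row.gap == pytest.approx(gap, abs=1e-10)


class TestAdiabaticBound:
    def test_zero_when_hamiltonians_coincide(self, toy_system):
        _, h_full, _, basis = toy_system
        out = adiabatic_bound(h_full, h_full, [0.2, 0.5, 0.8], basis)
        assert out["max"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_matrix_evaluation(self, toy_equilibrium):
        """Each grid value equals the direct dense-matrix formula."""
        h_full = jordan_wigner(build_full_hamiltonian(toy_equilibrium), 4).realified()
        h_fock = jordan_wigner(build_fock_hamiltonian(toy_equilibrium), 4).realified()
        basis = sector_basis(4, 2, 0.0)
        grid = [0.3, 0.7, 1.0]
        out = adiabatic_bound(h_fock, h_full, grid, basis)
        from aspsim.reference import sector_matrix

        h_mat = sector_matrix(h_full, basis).real
        f_mat = sector_matrix(h_fock, basis).real
        for s, got in zip(grid, out["values"]):
            vals, vecs = np.linalg.eigh(f_mat + s * (h_mat - f_mat))
            expected = abs(vecs[:, 0] @ (h_mat - f_mat) @ vecs[:, 1]) / (
                vals[1] - vals[0]
            ) ** 2
            assert got == pytest.approx(expected, rel=1e-9)

    def test_decreases_with_weaker_coupling_at_fixed_gap(self):
        """Two-level family with the final gap held exactly fixed.

        H_I = (gap/2) Z and H_P its rotation by angle alpha in the Z-X
        plane: the coupling |<g| dH/ds |e>| shrinks with alpha while the
        eigenvalue gap stays constant, so the bound must decrease.
        """
        from aspsim import PauliTerm, QubitHamiltonian

        gap = 0.8
        basis = np.array([0, 1])
        maxima = []
        for alpha in (0.9, 0.5, 0.2):
            h_i = QubitHamiltonian.from_terms(1, [PauliTerm(gap / 2, "Z")])
            h_p = QubitHamiltonian.from_terms(
                1,
                [PauliTerm(gap / 2 * math.cos(alpha), "Z"),
                 PauliTerm(gap / 2 * math.sin(alpha), "X")],
            )
            out = adiabatic_bound(h_i, h_p, [1.0], basis)
            # closed form at s = 1: |<g|H_P - H_I|e>| / gap^2
            expected = (gap / 2) * math.sin(alpha) / gap**2
            assert out["max"] == pytest.approx(expected, rel=1e-9)
            maxima.append(out["max"])
        assert maxima[0] > maxima[1] > maxima[2]


class TestSpinComponentWeights:
    def test_four_spin_bs_determinant(self):
        """|a a b b> decomposes with weights 1/6, 1/2, 1/3 (quintet, triplet,
        singlet)."""
        s2 = jordan_wigner(build_s2_operator(np.eye(4), 4), 8).realified()
        det = prepare_determinant([0, 2, 5, 7], 8)
        w = spin_component_weights(det, s2)
        assert w[2.0] == pytest.approx(1 / 6, abs=1e-10)
        assert w[1.0] == pytest.approx(1 / 2, abs=1e-10)
        assert w[0.0] == pytest.approx(1 / 3, abs=1e-10)

    def test_six_spin_bs_determinant(self):
        s2 = jordan_wigner(build_s2_operator(np.eye(6), 6), 12).realified()
        det = prepare_determinant([0, 2, 4, 7, 9, 11], 12)
        w = spin_component_weights(det, s2)
        assert w[3.0] == pytest.approx(1 / 20, abs=1e-10)
        assert w[2.0] == pytest.approx(1 / 4, abs=1e-10)
        assert w[1.0] == pytest.approx(9 / 20, abs=1e-10)
        assert w[0.0] == pytest.approx(1 / 4, abs=1e-10)

    def test_closed_shell_is_pure_singlet(self):
        s2 = jordan_wigner(build_s2_operator(np.eye(2), 2), 4).realified()
        det = prepare_determinant([0, 1], 4)
        w = spin_component_weights(det, s2)
        assert w == pytest.approx({0.0: 1.0})

    def test_weighted_spin_identity(self, rng):
        """sum_S w(S) S(S+1) equals <S^2> for an arbitrary state."""
        n = 6
        s2 = jordan_wigner(build_s2_operator(np.eye(3), 3), n).realified()
        amp = rng.normal(size=1 << n) + 1j * rng.normal(size=1 << n)
        amp /= np.linalg.norm(amp)
        psi = StateVector(amp, n)
        w = spin_component_weights(psi, s2)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-10)
        mean = sum(wt * s * (s + 1) for s, wt in w.items())
        assert mean == pytest.approx(expectation(s2, psi), abs=1e-10)
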