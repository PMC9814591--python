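"""Exact diagonalization references and wave-function metrics.

The physical states of an N-spin-orbital register live in sectors of fixed
electron number and S_z projection; all reference quantities (CASCI
energies and states, instantaneous-gap landscapes, the adiabatic-condition
diagnostic, spin-component decompositions) are computed by dense
diagonalization restricted to such a sector.  Dense solves are used up to a
configurable dimension, a sparse iterative solver above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mapping import QubitHamiltonian, pauli_action
from .schedule_propagator import ScheduleSpec, StateVector, instantaneous_hamiltonian

__all__ = [
    "ReferenceSolution",
    "sector_basis",
    "sector_matrix",
    "casci_solve",
    "square_overlap",
    "expectation",
    "gap_landscape",
    "adiabatic_bound",
    "spin_component_weights",
]

DENSE_CAP = 4096
SINGLET_S2_CUTOFF = 0.1


def sector_basis(n_qubits: int, n_elec: int, m_s: float) -> np.ndarray:
    """Basis states (integers) with the given electron count and S_z.

    Alpha spin orbitals sit on even qubits, beta on odd ones, so
    S_z = (n_alpha - n_beta) / 2 over the set bits.  An infeasible sector
    yields an empty array.
    """
    if not 0 <= n_elec <= n_qubits:
        raise ValueError(f"electron count {n_elec} outside 0..{n_qubits}")
    basis = np.arange(1 << n_qubits, dtype=np.int64)
    alpha_mask = sum(1 << q for q in range(0, n_qubits, 2))
    beta_mask = sum(1 << q for q in range(1, n_qubits, 2))
    n_a = np.bitwise_count(np.bitwise_and(basis, alpha_mask)).astype(np.int64)
    n_b = np.bitwise_count(np.bitwise_and(basis, beta_mask)).astype(np.int64)
    keep = (n_a + n_b == n_elec) & (n_a - n_b == int(round(2 * m_s)))
    return basis[keep]


def sector_matrix(h: QubitHamiltonian, basis: np.ndarray) -> np.ndarray:
    """Dense matrix of ``h`` restricted to (and closed within) ``basis``."""
    dim = len(basis)
    pos = np.full(1 << h.n_qubits, -1, dtype=np.int64)
    pos[basis] = np.arange(dim)
    mat = np.zeros((dim, dim), dtype=complex)
    for (x, z), c in h.mask_terms.items():
        idx, phase = pauli_action(x, z, h.n_qubits, basis)
        rows = pos[basis]          # = arange(dim)
        cols = pos[idx]
        ok = cols >= 0
        mat[rows[ok], cols[ok]] += c * phase[ok]
    return mat


@dataclass
class ReferenceSolution:
    """Lowest eigenpairs of a Hamiltonian within one (n_elec, m_s) sector."""

    sector: tuple[int, float]
    energies: np.ndarray
    states: list[StateVector]
    s2_values: np.ndarray | None = None

    @property
    def ground_energy(self) -> float:
        return float(self.energies[0])

    @property
    def ground_state(self) -> StateVector:
        return self.states[0]

    def attach_s2(self, s2: QubitHamiltonian) -> "ReferenceSolution":
        self.s2_values = np.array([expectation(s2, v) for v in self.states])
        return self

    def lowest_with_s2_below(self, cutoff: float = SINGLET_S2_CUTOFF) -> int | None:
        """Index of the lowest state that is (nearly) spin pure, or None."""
        if self.s2_values is None:
            raise ValueError("call attach_s2 first")
        idx = np.nonzero(self.s2_values < cutoff)[0]
        return int(idx[0]) if idx.size else None


def casci_solve(
    h: QubitHamiltonian,
    basis: np.ndarray,
    k: int = 1,
    dense_cap: int = DENSE_CAP,
    sector: tuple[int, float] | None = None,
    project_spin: tuple[QubitHamiltonian, float] | None = None,
) -> ReferenceSolution:
    """Lowest ``k`` eigenpairs of ``h`` restricted to a sector basis.

    When ``h`` is the full electronic Hamiltonian, the ground state is the
    CASCI wave function of the active space.  With ``project_spin=(s2, S)``
    the Hamiltonian is first projected onto the total-spin-S eigenspace of
    the given S^2 operator; because the electronic Hamiltonian is spin-free
    this resolves exact singlet/triplet degeneracies (e.g. covalent states
    at dissociation) instead of returning arbitrary mixtures.
    """
    dim = len(basis)
    if dim == 0:
        raise ValueError("empty sector basis")
    if k > dim:
        raise ValueError(f"requested {k} states from a sector of dimension {dim}")
    if project_spin is not None and dim <= dense_cap:
        s2_op, s_target = project_spin
        s2_mat = sector_matrix(s2_op, basis)
        vals2, vecs2 = np.linalg.eigh(s2_mat.real)
        keep = np.abs(vals2 - s_target * (s_target + 1.0)) < 0.5
        if not keep.any():
            raise ValueError(f"no S = {s_target} states in this sector")
        v = vecs2[:, keep]
        mat = v.T @ sector_matrix(h, basis).real @ v
        k = min(k, mat.shape[0])
        vals, sub = np.linalg.eigh(mat)
        vals, vecs = vals[:k], v @ sub[:, :k]
    elif dim <= dense_cap:
        mat = sector_matrix(h, basis)
        if np.abs(mat.imag).max() > 1e-9:
            raise ValueError("sector Hamiltonian is not real; check input Hermiticity")
        vals, vecs = np.linalg.eigh(mat.real)
        vals, vecs = vals[:k], vecs[:, :k]
    else:
        mat = sp.csr_matrix(sector_matrix_sparse(h, basis))
        try:
            vals, vecs = spla.eigsh(mat, k=k, which="SA")
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                f"sparse eigensolver failed to converge (dim={dim}, k={k}): {exc}"
            ) from exc
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    states = []
    n_qubits = h.n_qubits
    for col in range(vals.size):
        full = np.zeros(1 << n_qubits, dtype=complex)
        full[basis] = vecs[:, col]
        states.append(StateVector(full, n_qubits))
    if sector is None:
        bits = int(basis[0])
        n_elec = bits.bit_count()
        alpha = sum((bits >> q) & 1 for q in range(0, n_qubits, 2))
        sector = (n_elec, (2 * alpha - n_elec) / 2.0)
    return ReferenceSolution(sector, vals, states)


def sector_matrix_sparse(h: QubitHamiltonian, basis: np.ndarray) -> sp.coo_matrix:
    dim = len(basis)
    pos = np.full(1 << h.n_qubits, -1, dtype=np.int64)
    pos[basis] = np.arange(dim)
    rows, cols, vals = [], [], []
    for (x, z), c in h.mask_terms.items():
        idx, phase = pauli_action(x, z, h.n_qubits, basis)
        tgt = pos[idx]
        ok = tgt >= 0
        rows.append(np.arange(dim)[ok])
        cols.append(tgt[ok])
        vals.append((c * phase[ok]))
    return sp.coo_matrix(
        (np.concatenate(vals).real, (np.concatenate(rows), np.concatenate(cols))),
        shape=(dim, dim),
    )


def square_overlap(a: StateVector, b: StateVector) -> float:
    """|<a|b>|^2; symmetric and invariant under global phases."""
    if a.n_qubits != b.n_qubits:
        raise ValueError("register size mismatch")
    return float(abs(np.vdot(a.amplitudes, b.amplitudes)) ** 2)


def expectation(h: QubitHamiltonian, psi: StateVector) -> float:
    """<psi|h|psi>, returned as a real number for Hermitian input."""
    amp = psi.amplitudes
    val = 0.0 + 0.0j
    for (x, z), c in h.mask_terms.items():
        idx, phase = pauli_action(x, z, psi.n_qubits)
        val += c * np.vdot(amp, phase * amp[idx])
    if abs(val.imag) > 1e-8 * max(1.0, abs(val)):
        raise ValueError(f"expectation has imaginary part {val.imag:.2e}")
    return float(val.real)


def gap_landscape(
    h_fock: QubitHamiltonian,
    h_full: QubitHamiltonian,
    s2: QubitHamiltonian | None,
    spec: ScheduleSpec,
    grid,
    basis: np.ndarray,
    k: int = 8,
    s2_cutoff: float = SINGLET_S2_CUTOFF,
) -> pd.DataFrame:
    """S1 - S0 gap of the instantaneous Hamiltonian along an s grid.

    At each grid value of s the lowest ``k`` sector eigenstates are computed
    and the two lowest states with <S^2> below ``s2_cutoff`` define the
    singlet gap; rows with fewer than two such states carry NaN.  At s = 0
    and s = 1 the gap is that of the Fock operator and of the full
    (penalized) Hamiltonian respectively.
    """
    probe = ScheduleSpec(
        name=spec.name, T=spec.T, M=spec.M, penalty_c=spec.penalty_c,
        penalty_scaled=spec.penalty_scaled, trotter_order=spec.trotter_order,
        L=spec.L, ordering=spec.ordering,
    )
    rows = []
    s2_for_filter = s2
    for s in grid:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"grid value {s} outside [0, 1]")
        h_s = _interpolate_at_s(h_fock, h_full, s2, probe, s)
        sol = casci_solve(h_s, basis, k=min(k, len(basis)))
        if s2_for_filter is not None:
            sol.attach_s2(s2_for_filter)
            idx = np.nonzero(sol.s2_values < s2_cutoff)[0]
        else:
            idx = np.arange(len(sol.energies))
        row = {"s": s, "E0": np.nan, "E1": np.nan, "gap": np.nan,
               "s2_0": np.nan, "s2_1": np.nan}
        if idx.size >= 1:
            row["E0"] = sol.energies[idx[0]]
            if sol.s2_values is not None:
                row["s2_0"] = sol.s2_values[idx[0]]
        if idx.size >= 2:
            row["E1"] = sol.energies[idx[1]]
            row["gap"] = sol.energies[idx[1]] - sol.energies[idx[0]]
            if sol.s2_values is not None:
                row["s2_1"] = sol.s2_values[idx[1]]
        rows.append(row)
    return pd.DataFrame(rows)


def _interpolate_at_s(h_fock, h_full, s2, spec, s):
    """Instantaneous Hamiltonian at an arbitrary s in [0, 1]."""
    if s == 0.0:
        return h_fock
    acc = dict(h_fock.mask_terms)
    for key, c in h_full.mask_terms.items():
        acc[key] = acc.get(key, 0.0) + s * (c - h_fock.mask_terms.get(key, 0.0))
    if s2 is not None and spec.penalty_c:
        w = spec.penalty_c * (s if spec.penalty_scaled else 1.0)
        for key, c in s2.mask_terms.items():
            acc[key] = acc.get(key, 0.0) + w * c
    return QubitHamiltonian(h_full.n_qubits, acc)


def adiabatic_bound(
    h_fock: QubitHamiltonian,
    h_full: QubitHamiltonian,
    grid,
    basis: np.ndarray,
    degeneracy_tol: float = 1e-10,
) -> dict:
    """Grid maximum of |<g| dH/ds |e>| / (eps_e - eps_g)^2 along the sweep.

    dH/ds = H_P - H_I is formed analytically (string-wise difference).  The
    result is a lower-bound guide for the evolution time T: the sweep is
    adiabatic when the returned maximum is much smaller than T.  Grid points
    where the two lowest states are degenerate within ``degeneracy_tol`` are
    flagged and excluded from the maximum.
    """
    d_h = h_full - h_fock
    if all(abs(c) < 1e-12 for c in d_h.mask_terms.values()):
        grid = list(grid)
        return {"max": 0.0, "argmax_s": float(grid[0]),
                "values": np.zeros(len(grid)), "degenerate_points": []}
    d_mat = sector_matrix(d_h, basis)
    values, flagged = [], []
    for s in grid:
        h_s = _interpolate_at_s(h_fock, h_full, None,
                                ScheduleSpec(name="Lin", T=1.0), s)
        sol = casci_solve(h_s, basis, k=min(2, len(basis)))
        if len(sol.energies) < 2:
            values.append(0.0)
            continue
        gap = sol.energies[1] - sol.energies[0]
        if gap < degeneracy_tol:
            flagged.append(s)
            values.append(np.nan)
            continue
        g = sol.states[0].amplitudes[basis]
        e = sol.states[1].amplitudes[basis]
        num = abs(np.vdot(g, d_mat @ e))
        values.append(num / gap**2)
    values = np.asarray(values)
    finite = np.nan_to_num(values, nan=-np.inf)
    arg = int(np.argmax(finite))
    return {
        "max": float(values[arg]) if np.isfinite(finite[arg]) else float("nan"),
        "argmax_s": float(list(grid)[arg]),
        "values": values,
        "degenerate_points": flagged,
    }


def spin_component_weights(psi: StateVector, s2: QubitHamiltonian,
                           tol: float = 1e-8) -> dict[float, float]:
    """Squared projections of |psi> onto total-spin eigenspaces.

    S^2 is diagonalized within each (n_elec, m_s) sector supporting |psi>;
    eigenvalues S(S+1) are rounded to the nearest valid total spin.  The
    weights sum to 1 for a normalized state.
    """
    n = psi.n_qubits
    amp = psi.amplitudes
    weights: dict[float, float] = {}
    support = np.nonzero(np.abs(amp) > 1e-14)[0]
    sectors = set()
    alpha_mask = sum(1 << q for q in range(0, n, 2))
    for b in support:
        bits = int(b)
        na = (bits & alpha_mask).bit_count()
        ne = bits.bit_count()
        sectors.add((ne, (2 * na - ne) / 2.0))
    for ne, ms in sorted(sectors):
        basis = sector_basis(n, ne, ms)
        comp = amp[basis]
        if np.linalg.norm(comp) < 1e-14:
            continue
        mat = sector_matrix(s2, basis)
        vals, vecs = np.linalg.eigh(mat.real)
        proj = vecs.conj().T @ comp
        for lam, w in zip(vals, np.abs(proj) ** 2):
            if w < 1e-12:
                continue
            s_val = 0.5 * (-1.0 + np.sqrt(max(0.0, 1.0 + 4.0 * lam)))
            s_round = round(2 * s_val) / 2.0
            if abs(s_val - s_round) > 1e-6:
                raise ValueError(f"S^2 eigenvalue {lam} is not S(S+1) within tolerance")
            weights[s_round] = weights.get(s_round, 0.0) + float(w)
    return weights
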