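"""Annealing schedules, time discretization and Trotterized propagation.

The interpolated Hamiltonian at step m of M is

    H_m = (1 - s(m/M)) H_I + s(m/M) H_P [+ s(m/M) c S^2]

evaluated at the *end* of the step, with s one of five monotone schedules
(linear, square, sinusoidal, sinusoidal-cubic, cubic).  Because every
Pauli string of the initial (Fock) Hamiltonian also appears in the full
Hamiltonian, H_m is assembled string-wise as the Fock sum held at full
weight plus the remainder scaled by s; this is numerically identical to the
direct convex combination and is cross-checked in the tests.

Time evolution uses the second-order (palindromic) Trotter-Suzuki product
by default, with the term order re-derived at every step from the
instantaneous (s-scaled) coefficients: descending |coefficient| with an
ascending-lexicographic tie-break on the Pauli string, or plain
lexicographic ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mapping import (
    PauliTerm,
    QubitHamiltonian,
    masks_to_string,
    pauli_action,
    string_to_masks,
)

__all__ = [
    "SCHEDULES",
    "ScheduleSpec",
    "StateVector",
    "schedule_value",
    "make_time_grid",
    "instantaneous_hamiltonian",
    "order_terms",
    "apply_pauli_rotation",
    "trotter_step",
    "CompiledPropagator",
]

SCHEDULES = {
    "Lin": lambda x: x,
    "Squ": lambda x: 3.0 * x**2 - 2.0 * x**3,
    "Sin": lambda x: math.sin(math.pi * x / 2.0),
    "SinCub": lambda x: math.sin(math.pi * x / 2.0) ** 3,
    "Cub": lambda x: 6.0 * x**5 - 15.0 * x**4 + 10.0 * x**3,
}


def schedule_value(name: str, x: float) -> float:
    """Evaluate schedule ``name`` at normalized time x in [0, 1]."""
    if name not in SCHEDULES:
        raise KeyError(f"unknown schedule {name!r}; choose from {sorted(SCHEDULES)}")
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"normalized time {x} outside [0, 1]")
    return SCHEDULES[name](x)


def make_time_grid(T: float) -> tuple[int, float]:
    """Default discretization: M = ceil(2 T) steps of dt = T / M."""
    if T <= 0:
        raise ValueError("evolution time must be positive")
    m = math.ceil(2.0 * T)
    return m, T / m


@dataclass
class ScheduleSpec:
    """Run conditions for one adiabatic sweep.

    Attributes
    ----------
    name: schedule function name (Lin, Squ, Sin, SinCub, Cub).
    T: total evolution time, atomic units.
    M: number of Trotterized steps; defaults to ceil(2 T).
    penalty_c: strength of the S^2 penalty (0.5 for broken-symmetry runs).
    penalty_scaled: multiply the penalty by s(t) (the printed form); when
        false the penalty is applied at constant strength c.
    trotter_order: 1 (forward product) or 2 (palindromic product).
    L: repetitions of the product formula per time step.
    ordering: "magnitude" (re-derived from the instantaneous coefficients
        every step) or "lexicographic".
    """

    name: str = "Sin"
    T: float = 10.0
    M: int | None = None
    penalty_c: float = 0.0
    penalty_scaled: bool = True
    trotter_order: int = 2
    L: int = 1
    ordering: str = "magnitude"

    def __post_init__(self):
        if self.name not in SCHEDULES:
            raise KeyError(f"unknown schedule {self.name!r}")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.M is None:
            self.M = make_time_grid(self.T)[0]
        if self.M < 1:
            raise ValueError("M must be at least 1")
        if self.trotter_order not in (1, 2):
            raise ValueError("trotter_order must be 1 or 2")
        if self.L < 1:
            raise ValueError("L must be at least 1")
        if self.ordering not in ("magnitude", "lexicographic"):
            raise ValueError("ordering must be 'magnitude' or 'lexicographic'")

    @property
    def dt(self) -> float:
        return self.T / self.M

    def s(self, m: int) -> float:
        return schedule_value(self.name, m / self.M)


@dataclass
class StateVector:
    """2^N complex amplitudes over the Jordan-Wigner occupation basis."""

    amplitudes: np.ndarray
    n_qubits: int

    @classmethod
    def basis_state(cls, occupied_qubits, n_qubits: int) -> "StateVector":
        occ = list(occupied_qubits)
        if len(set(occ)) != len(occ):
            raise ValueError("duplicate qubit index in occupation list")
        idx = 0
        for q in occ:
            if not 0 <= q < n_qubits:
                raise ValueError(f"qubit index {q} outside register of {n_qubits}")
            idx |= 1 << q
        amp = np.zeros(1 << n_qubits, dtype=complex)
        amp[idx] = 1.0
        return cls(amp, n_qubits)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def overlap(self, other: "StateVector") -> complex:
        return complex(np.vdot(self.amplitudes, other.amplitudes))


# ---------------------------------------------------------------------------
# instantaneous Hamiltonian and term ordering
# ---------------------------------------------------------------------------


def instantaneous_hamiltonian(
    h_fock: QubitHamiltonian,
    h_full: QubitHamiltonian,
    s2: QubitHamiltonian | None,
    spec: ScheduleSpec,
    m: int,
) -> QubitHamiltonian:
    """Assemble H_m with Fock strings at full weight and the rest scaled by s.

    Every Pauli string of the Fock Hamiltonian must occur in the full
    Hamiltonian (the fermionic Fock terms are a subset of the electronic
    Hamiltonian's terms); the remainder H_P - H_I is scaled by s(m/M) and the
    optional S^2 penalty enters with weight s*c (or c if not scheduled).
    """
    if not 1 <= m <= spec.M:
        raise ValueError(f"step index {m} outside 1..{spec.M}")
    full = h_full.mask_terms
    for key in h_fock.mask_terms:
        if key not in full:
            raise ValueError(
                "Fock-operator Pauli string "
                f"{masks_to_string(*key, h_fock.n_qubits)} absent from the full "
                "Hamiltonian"
            )
    s = spec.s(m)
    acc = dict(h_fock.mask_terms)
    for key, c in full.items():
        acc[key] = acc.get(key, 0.0) + s * (c - h_fock.mask_terms.get(key, 0.0))
    if s2 is not None and spec.penalty_c != 0.0:
        w = spec.penalty_c * (s if spec.penalty_scaled else 1.0)
        for key, c in s2.mask_terms.items():
            acc[key] = acc.get(key, 0.0) + w * c
    return QubitHamiltonian(h_full.n_qubits, acc)


def order_terms(h: QubitHamiltonian, strategy: str = "magnitude") -> list[PauliTerm]:
    """Deterministic Trotter term order; identity (constant) strings last.

    ``magnitude``: descending |coefficient|, ties broken by ascending
    lexicographic Pauli string.  ``lexicographic``: ascending string.
    """
    terms = [t for t in h.terms if set(t.string) != {"I"}]
    if strategy == "magnitude":
        terms.sort(key=lambda t: (-abs(t.coefficient), t.string))
    elif strategy == "lexicographic":
        terms.sort(key=lambda t: t.string)
    else:
        raise ValueError(f"unknown ordering strategy {strategy!r}")
    return terms


# ---------------------------------------------------------------------------
# statevector propagation
# ---------------------------------------------------------------------------


def apply_pauli_rotation(psi: StateVector, string: str, theta: float) -> StateVector:
    """Return exp(-i theta P) |psi> = cos(theta)|psi> - i sin(theta) P|psi>."""
    if len(string) != psi.n_qubits:
        raise ValueError("Pauli string length does not match register size")
    x, z = string_to_masks(string)
    idx, phase = pauli_action(x, z, psi.n_qubits)
    p_psi = phase * psi.amplitudes[idx]
    return StateVector(
        math.cos(theta) * psi.amplitudes - 1j * math.sin(theta) * p_psi, psi.n_qubits
    )


def trotter_step(
    psi: StateVector, h_m: QubitHamiltonian, dt: float, spec: ScheduleSpec
) -> StateVector:
    """One Trotterized step exp(-i H_m dt) applied to |psi>.

    The constant (identity) part of H_m contributes an exact global phase;
    the remaining terms are applied in the order given by ``spec.ordering``,
    as a forward product (order 1) or the palindromic half-angle product
    (order 2), repeated ``spec.L`` times.
    """
    if spec.trotter_order not in (1, 2):
        raise ValueError("unsupported Trotter order")
    ordered = order_terms(h_m, spec.ordering)
    const = complex(h_m.coefficient("I" * h_m.n_qubits))
    out = psi
    for _ in range(spec.L):
        if spec.trotter_order == 1:
            for t in ordered:
                out = apply_pauli_rotation(out, t.string, t.coefficient.real * dt / spec.L)
        else:
            half = dt / (2.0 * spec.L)
            for t in ordered:
                out = apply_pauli_rotation(out, t.string, t.coefficient.real * half)
            for t in reversed(ordered):
                out = apply_pauli_rotation(out, t.string, t.coefficient.real * half)
    amp = out.amplitudes * np.exp(-1j * const.real * dt)
    return StateVector(amp, psi.n_qubits)


class CompiledPropagator:
    """Fast path for full adiabatic sweeps on a fixed Pauli-string union.

    Precomputes, for every string, the basis permutation and sign pattern of
    its statevector action, so each rotation is three vector operations.
    Produces bit-identical results to repeated :func:`trotter_step` on the
    union Hamiltonian (same ordering rules, same arithmetic).
    """

    def __init__(
        self,
        n_qubits: int,
        h_fock: QubitHamiltonian,
        h_full: QubitHamiltonian,
        s2: QubitHamiltonian | None,
        spec: ScheduleSpec,
    ):
        self.n_qubits = n_qubits
        self.spec = spec
        union: dict[tuple[int, int], None] = {}
        for h in (h_fock, h_full) + ((s2,) if s2 is not None else ()):
            for key in h.mask_terms:
                union.setdefault(key, None)
        keys = [k for k in union if k != (0, 0)]
        self.keys = keys
        self.labels = np.array([masks_to_string(x, z, n_qubits) for x, z in keys])
        get = lambda h, k: complex(h.mask_terms.get(k, 0.0)).real
        self.c_fock = np.array([get(h_fock, k) for k in keys])
        self.c_full = np.array([get(h_full, k) for k in keys])
        self.c_s2 = np.array(
            [get(s2, k) for k in keys] if s2 is not None else [0.0] * len(keys)
        )
        self.k_fock = get(h_fock, (0, 0))
        self.k_full = get(h_full, (0, 0))
        self.k_s2 = get(s2, (0, 0)) if s2 is not None else 0.0
        basis = np.arange(1 << n_qubits, dtype=np.int64)
        self._idx = np.empty((len(keys), basis.size), dtype=np.int64)
        self._sign = np.empty((len(keys), basis.size), dtype=np.int8)
        self._iy = np.empty(len(keys), dtype=complex)
        for t, (x, z) in enumerate(keys):
            idx, phase = pauli_action(x, z, n_qubits, basis)
            self._idx[t] = idx
            iy = (1.0, 1.0j, -1.0, -1.0j)[int(x & z).bit_count() % 4]
            self._iy[t] = iy
            self._sign[t] = np.real(phase / iy).astype(np.int8)

    def step_coefficients(self, m: int) -> tuple[np.ndarray, float]:
        s = self.spec.s(m)
        w = self.spec.penalty_c * (s if self.spec.penalty_scaled else 1.0)
        coeffs = self.c_fock + s * (self.c_full - self.c_fock) + w * self.c_s2
        const = self.k_fock + s * (self.k_full - self.k_fock) + w * self.k_s2
        return coeffs, const

    def _order(self, coeffs: np.ndarray) -> np.ndarray:
        if self.spec.ordering == "magnitude":
            return np.lexsort((self.labels, -np.abs(coeffs)))
        return np.argsort(self.labels, kind="stable")

    def _rotate(self, amp: np.ndarray, t: int, theta: float) -> np.ndarray:
        p_amp = self._sign[t] * amp[self._idx[t]]
        return math.cos(theta) * amp + (-1j * math.sin(theta) * self._iy[t]) * p_amp

    def step(self, psi: StateVector, m: int) -> StateVector:
        spec = self.spec
        coeffs, const = self.step_coefficients(m)
        order = self._order(coeffs)
        dt = spec.dt
        amp = psi.amplitudes
        for _ in range(spec.L):
            if spec.trotter_order == 1:
                for t in order:
                    amp = self._rotate(amp, t, coeffs[t] * dt / spec.L)
            else:
                half = dt / (2.0 * spec.L)
                for t in order:
                    amp = self._rotate(amp, t, coeffs[t] * half)
                for t in order[::-1]:
                    amp = self._rotate(amp, t, coeffs[t] * half)
        amp = amp * np.exp(-1j * const * dt)
        return StateVector(amp, psi.n_qubits)
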