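"""Jordan-Wigner transformation and Pauli-string linear algebra.

Qubit p stores the occupation number of spin orbital p (alpha of spatial
orbital k on qubit 2k, beta on qubit 2k + 1), with little-endian basis-state
indexing: computational basis state ``b`` has qubit q occupied iff bit q of
the integer ``b`` is set.  Ladder operators map as

    a_p^+ = 1/2 (X_p - i Y_p) (x) prod_{r<p} Z_r
    a_p   = 1/2 (X_p + i Y_p) (x) prod_{r<p} Z_r

Pauli strings are represented internally by a pair of bit masks ``(x, z)``
through P = i^{|x & z|} X^x Z^z, which makes products, matrix elements and
statevector action O(1) bit arithmetic per string.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hamiltonians import COEFF_TOL, FermionTermSum

__all__ = [
    "PauliTerm",
    "QubitHamiltonian",
    "jordan_wigner",
    "simplify",
    "to_matrix",
    "export_text",
    "parse_text",
]

_I_POW = (1.0, 1.0j, -1.0, -1.0j)

#: largest register for which dense-matrix oracles are constructed
MATRIX_CAP = 14


class MappingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mask-level Pauli algebra
# ---------------------------------------------------------------------------


def _popcount(v: int) -> int:
    return int(v).bit_count()


def mask_multiply(x1: int, z1: int, x2: int, z2: int) -> tuple[int, int, complex]:
    """Product of two Pauli strings in (x, z) representation.

    Returns ``(x3, z3, phase)`` with P1 P2 = phase * P3.
    """
    x3, z3 = x1 ^ x2, z1 ^ z2
    # from P = i^{|x&z|} X^x Z^z and Z^z X^x = (-1)^{|z&x|} X^x Z^z
    exp = (
        _popcount(x1 & z1)
        + _popcount(x2 & z2)
        - _popcount(x3 & z3)
        + 2 * _popcount(z1 & x2)
    ) % 4
    return x3, z3, _I_POW[exp]


def masks_to_string(x: int, z: int, n_qubits: int) -> str:
    out = []
    for q in range(n_qubits):
        xb, zb = (x >> q) & 1, (z >> q) & 1
        out.append("IXZY"[xb + 2 * zb] if xb + 2 * zb != 3 else "Y")
    return "".join(out)


def string_to_masks(s: str) -> tuple[int, int]:
    x = z = 0
    for q, ch in enumerate(s):
        if ch == "X":
            x |= 1 << q
        elif ch == "Z":
            z |= 1 << q
        elif ch == "Y":
            x |= 1 << q
            z |= 1 << q
        elif ch != "I":
            raise MappingError(f"invalid Pauli character {ch!r}")
    return x, z


def pauli_action(x: int, z: int, n_qubits: int, basis: np.ndarray | None = None):
    """Vectorized action of one Pauli string on the computational basis.

    Returns ``(idx, phase)`` such that ``(P psi)[b] = phase[b] * psi[idx[b]]``.
    """
    if basis is None:
        basis = np.arange(1 << n_qubits, dtype=np.int64)
    idx = basis ^ x
    par = np.bitwise_count(np.bitwise_and(idx, z)) & 1
    phase = _I_POW[_popcount(x & z) % 4] * (1.0 - 2.0 * par)
    return idx, phase


# ---------------------------------------------------------------------------
# public containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PauliTerm:
    """One weighted Pauli string; ``string[q]`` acts on qubit q."""

    coefficient: complex
    string: str

    @property
    def masks(self) -> tuple[int, int]:
        return string_to_masks(self.string)


class QubitHamiltonian:
    """A weighted sum of Pauli strings on a fixed register."""

    def __init__(self, n_qubits: int, terms: dict[tuple[int, int], complex] | None = None):
        self.n_qubits = int(n_qubits)
        self._terms: dict[tuple[int, int], complex] = dict(terms or {})

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_terms(cls, n_qubits: int, terms) -> "QubitHamiltonian":
        acc: dict[tuple[int, int], complex] = {}
        for t in terms:
            key = t.masks if isinstance(t, PauliTerm) else string_to_masks(t[1])
            coeff = t.coefficient if isinstance(t, PauliTerm) else t[0]
            acc[key] = acc.get(key, 0.0) + coeff
        return cls(n_qubits, acc)

    def copy(self) -> "QubitHamiltonian":
        return QubitHamiltonian(self.n_qubits, self._terms)

    # -- views --------------------------------------------------------------

    @property
    def terms(self) -> list[PauliTerm]:
        return [
            PauliTerm(c, masks_to_string(x, z, self.n_qubits))
            for (x, z), c in self._terms.items()
        ]

    @property
    def mask_terms(self) -> dict[tuple[int, int], complex]:
        return self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def coefficient(self, string: str) -> complex:
        return self._terms.get(string_to_masks(string), 0.0)

    # -- algebra -------------------------------------------------------------

    def __add__(self, other: "QubitHamiltonian") -> "QubitHamiltonian":
        if other.n_qubits != self.n_qubits:
            raise MappingError("register size mismatch")
        acc = dict(self._terms)
        for k, c in other._terms.items():
            acc[k] = acc.get(k, 0.0) + c
        return QubitHamiltonian(self.n_qubits, acc)

    def __sub__(self, other: "QubitHamiltonian") -> "QubitHamiltonian":
        return self + other * (-1.0)

    def __mul__(self, scalar: complex) -> "QubitHamiltonian":
        return QubitHamiltonian(
            self.n_qubits, {k: scalar * c for k, c in self._terms.items()}
        )

    __rmul__ = __mul__

    def max_imag(self) -> float:
        return max((abs(complex(c).imag) for c in self._terms.values()), default=0.0)

    def realified(self, tol: float = 1e-10) -> "QubitHamiltonian":
        """Drop imaginary parts after checking they are below ``tol``."""
        if self.max_imag() > tol:
            raise MappingError(
                f"coefficients have imaginary parts up to {self.max_imag():.2e}"
            )
        return QubitHamiltonian(
            self.n_qubits, {k: complex(c).real for k, c in self._terms.items()}
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def jordan_wigner(op: FermionTermSum, n_qubits: int) -> QubitHamiltonian:
    """Map a fermionic operator to a simplified Pauli-string sum."""
    if op.max_index() >= n_qubits:
        raise MappingError(
            f"spin-orbital index {op.max_index()} outside register of {n_qubits}"
        )
    acc: dict[tuple[int, int], complex] = {}
    if op.constant:
        acc[(0, 0)] = complex(op.constant)
    cache: dict[tuple[int, int], list[tuple[complex, int, int]]] = {}

    def ladder(p: int, dag: int) -> list[tuple[complex, int, int]]:
        key = (p, dag)
        if key not in cache:
            zstr = (1 << p) - 1
            sign = -1.0j if dag else 1.0j
            cache[key] = [
                (0.5, 1 << p, zstr),          # X_p (x) Z-chain
                (0.5 * sign, 1 << p, zstr | (1 << p)),  # -+ i/2 Y_p (x) Z-chain
            ]
        return cache[key]

    for coeff, ladder_string in op.terms:
        partial: list[tuple[complex, int, int]] = [(complex(coeff), 0, 0)]
        for p, dag in ladder_string:
            factors = ladder(p, dag)
            nxt: list[tuple[complex, int, int]] = []
            for c1, x1, z1 in partial:
                for c2, x2, z2 in factors:
                    x3, z3, ph = mask_multiply(x1, z1, x2, z2)
                    nxt.append((c1 * c2 * ph, x3, z3))
            partial = nxt
        for c, x, z in partial:
            key = (x, z)
            acc[key] = acc.get(key, 0.0) + c
    return simplify(QubitHamiltonian(n_qubits, acc))


def simplify(h: QubitHamiltonian, tol: float = COEFF_TOL) -> QubitHamiltonian:
    """Merge like strings and drop coefficients below ``tol``."""
    return QubitHamiltonian(
        h.n_qubits, {k: c for k, c in h.mask_terms.items() if abs(c) >= tol}
    )


def to_matrix(h: QubitHamiltonian, cap: int = MATRIX_CAP) -> np.ndarray:
    """Dense matrix of a Pauli sum; an oracle for small registers."""
    n = h.n_qubits
    if n > cap:
        raise MappingError(f"to_matrix on {n} qubits exceeds the cap of {cap}")
    dim = 1 << n
    basis = np.arange(dim, dtype=np.int64)
    mat = np.zeros((dim, dim), dtype=complex)
    for (x, z), c in h.mask_terms.items():
        idx, phase = pauli_action(x, z, n, basis)
        # (P psi)[b] = phase[b] psi[idx[b]]  =>  P[b, idx[b]] = phase[b]
        mat[basis, idx] += c * phase
    return mat


def export_text(h: QubitHamiltonian) -> str:
    """One term per line: ``coefficient pauli_string`` (qubit 0 leftmost)."""
    lines = []
    for t in sorted(h.terms, key=lambda t: t.string):
        c = complex(t.coefficient)
        val = f"{c.real:.16e}" if abs(c.imag) < 1e-14 else f"{c.real:.16e}{c.imag:+.16e}j"
        lines.append(f"{val} {t.string}")
    return "\n".join(lines)


def parse_text(text: str, n_qubits: int | None = None) -> QubitHamiltonian:
    terms = []
    for ln in text.splitlines():
        if not ln.strip():
            continue
        val, s = ln.split()
        terms.append(PauliTerm(complex(val), s))
        if n_qubits is None:
            n_qubits = len(s)
    return QubitHamiltonian.from_terms(n_qubits or 0, terms)
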