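"""Independent oracles used across the test suite.

These deliberately avoid the package's Pauli-mask machinery: fermionic
operators are built combinatorially on occupation bitstrings, and Pauli
matrices by explicit Kronecker products of the printed 2x2 matrices.
"""

import numpy as np

PAULI_2X2 = {
    "I": np.eye(2),
    "X": np.array([[0.0, 1.0], [1.0, 0.0]]),
    "Y": np.array([[0.0, -1.0j], [1.0j, 0.0]]),
    "Z": np.array([[1.0, 0.0], [0.0, -1.0]]),
}


def ladder_matrix(p: int, dag: bool, n: int) -> np.ndarray:
    """a_p or a_p^+ on n spin orbitals, built from occupation-list signs.

    The sign convention counts occupied orbitals with index below p, which
    matches a Jordan-Wigner Z chain on qubits r < p.
    """
    dim = 1 << n
    m = np.zeros((dim, dim))
    for b in range(dim):
        occupied = (b >> p) & 1
        sign = (-1) ** bin(b & ((1 << p) - 1)).count("1")
        if dag and not occupied:
            m[b | (1 << p), b] = sign
        elif not dag and occupied:
            m[b & ~(1 << p), b] = sign
    return m


def fermion_matrix(op, n: int) -> np.ndarray:
    """Dense matrix of a FermionTermSum via the combinatorial ladder oracle."""
    dim = 1 << n
    total = complex(op.constant) * np.eye(dim, dtype=complex)
    for coeff, ladder in op.terms:
        m = np.eye(dim, dtype=complex)
        for p, dag in ladder:
            m = m @ ladder_matrix(p, bool(dag), n)
        total += coeff * m
    return total


def pauli_string_matrix(string: str) -> np.ndarray:
    """Kronecker product with qubit 0 as the least significant factor."""
    m = np.eye(1)
    for ch in string:  # qubit index increases along the string
        m = np.kron(PAULI_2X2[ch], m)
    return m
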