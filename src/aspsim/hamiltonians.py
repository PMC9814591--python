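"""Active-space integrals and second-quantized operator assembly.

This module owns the electronic-structure inputs of the simulator: one- and
two-electron molecular-orbital integrals over an active space (read and
written in the Molpro FCIDUMP convention, with an unrestricted dialect for
broken-symmetry orbital sets), and the three fermionic operators the
adiabatic interpolation needs:

* the full electronic Hamiltonian
      H = sum_pq h_pq a_p^+ a_q + 1/2 sum_pqrs h_pqrs a_p^+ a_q^+ a_r a_s,
* the Fock-like initial Hamiltonian built from the terms of H that involve
  only the spin orbitals occupied in the starting determinant, and
* the total-spin operator S^2 = S_- S_+ + S_z (S_z + 1), with the
  alpha-beta spatial-orbital overlap matrix entering the ladder operators so
  that broken-symmetry (spin-unrestricted) orbital sets are handled.

Index conventions
-----------------
Spatial orbital k carries two spin orbitals: alpha -> 2k, beta -> 2k + 1.
The two-electron coefficient follows the charge-density pairing

    h_pqrs = (P S | Q R) * delta(sigma_p, sigma_s) * delta(sigma_q, sigma_r)

where (ab|cd) is a chemists'-notation spatial integral and capital letters
are spatial indices of the corresponding spin orbitals.  With this
convention H is written exactly as 1/2 sum h_pqrs a_p^+ a_q^+ a_r a_s.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpinOrbitalIntegrals",
    "FermionTermSum",
    "read_fcidump",
    "write_fcidump",
    "build_full_hamiltonian",
    "build_fock_hamiltonian",
    "build_s2_operator",
]

#: coefficients below this magnitude are dropped when operators are simplified
COEFF_TOL = 1e-12


class FcidumpError(ValueError):
    """Malformed or inconsistent FCIDUMP content."""


# ---------------------------------------------------------------------------
# integral container
# ---------------------------------------------------------------------------


@dataclass
class SpinOrbitalIntegrals:
    """Active-space MO integrals for one (possibly spin-unrestricted) system.

    Spatial-orbital blocks are stored; the spin-orbital tensors used by the
    Hamiltonian builders are expanded on demand.  Energies in Hartree.

    Parameters
    ----------
    n_spatial:
        Number of active spatial orbitals (the register has ``2 * n_spatial``
        qubits).
    core_energy:
        Nuclear repulsion plus frozen-core contribution, added to the
        Hamiltonian as a constant.
    h_aa, h_bb:
        One-electron integrals over alpha / beta spatial orbitals.
    eri_aaaa, eri_bbbb, eri_aabb:
        Chemists'-notation two-electron integrals ``(pq|rs)``; in the mixed
        block the first pair is alpha, the second beta.
    ab_overlap:
        Overlap matrix between alpha and beta spatial orbitals; the identity
        for spin-restricted orbital sets.
    occupied:
        Spin-orbital indices occupied in the starting determinant
        (alpha of spatial k -> 2k, beta -> 2k+1).
    """

    n_spatial: int
    core_energy: float
    h_aa: np.ndarray
    h_bb: np.ndarray
    eri_aaaa: np.ndarray
    eri_bbbb: np.ndarray
    eri_aabb: np.ndarray
    ab_overlap: np.ndarray
    restricted: bool
    occupied: tuple[int, ...]
    _two_body_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_restricted(
        cls,
        h: np.ndarray,
        eri: np.ndarray,
        core_energy: float,
        n_elec: int,
        ms2: int = 0,
    ) -> "SpinOrbitalIntegrals":
        """Build from a single spatial-orbital integral set (RHF case)."""
        h = np.asarray(h, dtype=float)
        eri = np.asarray(eri, dtype=float)
        n = h.shape[0]
        occ = _aufbau_occupation(n_elec, ms2)
        return cls(
            n_spatial=n,
            core_energy=float(core_energy),
            h_aa=h,
            h_bb=h.copy(),
            eri_aaaa=eri,
            eri_bbbb=eri.copy(),
            eri_aabb=eri.copy(),
            ab_overlap=np.eye(n),
            restricted=True,
            occupied=occ,
        )

    # -- derived quantities -------------------------------------------------

    @property
    def n_so(self) -> int:
        return 2 * self.n_spatial

    @property
    def n_elec(self) -> int:
        return len(self.occupied)

    @property
    def m_s(self) -> float:
        n_a = sum(1 for p in self.occupied if p % 2 == 0)
        return 0.5 * (2 * n_a - len(self.occupied))

    @property
    def one_body(self) -> np.ndarray:
        """Spin-orbital one-electron matrix, shape (2n, 2n)."""
        n = self.n_spatial
        out = np.zeros((2 * n, 2 * n))
        out[0::2, 0::2] = self.h_aa
        out[1::2, 1::2] = self.h_bb
        return out

    @property
    def two_body(self) -> np.ndarray:
        """Spin-orbital tensor h_pqrs in the 1/2 a+ a+ a a convention."""
        if self._two_body_cache is None:
            n = self.n_spatial
            out = np.zeros((2 * n,) * 4)
            out[0::2, 0::2, 0::2, 0::2] = np.einsum("psqr->pqrs", self.eri_aaaa)
            out[1::2, 1::2, 1::2, 1::2] = np.einsum("psqr->pqrs", self.eri_bbbb)
            # (p, s) alpha with (q, r) beta and the spin-swapped block
            out[0::2, 1::2, 1::2, 0::2] = np.einsum("psqr->pqrs", self.eri_aabb)
            out[1::2, 0::2, 0::2, 1::2] = np.einsum("qrps->pqrs", self.eri_aabb)
            object.__setattr__(self, "_two_body_cache", out)
        return self._two_body_cache

    # -- validation ---------------------------------------------------------

    def validate(self, tol: float = 1e-10) -> None:
        """Raise ``ValueError`` if any container invariant is violated."""
        n = self.n_spatial
        for name, blk in (("h_aa", self.h_aa), ("h_bb", self.h_bb)):
            if blk.shape != (n, n):
                raise ValueError(f"{name} has shape {blk.shape}, expected {(n, n)}")
            if np.abs(blk - blk.T).max() > tol:
                raise ValueError(f"{name} is not Hermitian within {tol}")
        for name, eri in (
            ("eri_aaaa", self.eri_aaaa),
            ("eri_bbbb", self.eri_bbbb),
            ("eri_aabb", self.eri_aabb),
        ):
            if eri.shape != (n, n, n, n):
                raise ValueError(f"{name} has wrong shape {eri.shape}")
            # real orbitals: (pq|rs) = (qp|rs) = (pq|sr)
            if np.abs(eri - np.einsum("qprs->pqrs", eri)).max() > tol:
                raise ValueError(f"{name} violates within-pair permutation symmetry")
            if np.abs(eri - np.einsum("pqsr->pqrs", eri)).max() > tol:
                raise ValueError(f"{name} violates within-pair permutation symmetry")
        for name, eri in (("eri_aaaa", self.eri_aaaa), ("eri_bbbb", self.eri_bbbb)):
            if np.abs(eri - np.einsum("rspq->pqrs", eri)).max() > tol:
                raise ValueError(f"{name} violates pair-exchange symmetry")
        if self.ab_overlap.shape != (n, n):
            raise ValueError("ab_overlap has wrong shape")
        is_identity = np.abs(self.ab_overlap - np.eye(n)).max() <= tol
        if self.restricted and not is_identity:
            raise ValueError("restricted integrals must carry an identity ab_overlap")
        if not self.restricted and is_identity:
            raise ValueError("unrestricted integrals with identity ab_overlap; "
                             "set restricted=True instead")
        if np.linalg.svd(self.ab_overlap, compute_uv=False).max() > 1 + 1e-10:
            raise ValueError("ab_overlap has a singular value above 1")
        occ = self.occupied
        if len(set(occ)) != len(occ) or (occ and max(occ) >= 2 * n):
            raise ValueError("occupied spin-orbital indices must be distinct and < 2n")


def _aufbau_occupation(n_elec: int, ms2: int) -> tuple[int, ...]:
    n_a = (n_elec + ms2) // 2
    n_b = n_elec - n_a
    return tuple(sorted([2 * k for k in range(n_a)] + [2 * k + 1 for k in range(n_b)]))


# ---------------------------------------------------------------------------
# fermionic operators
# ---------------------------------------------------------------------------


@dataclass
class FermionTermSum:
    """A linear combination of products of ladder operators plus a constant.

    Each term is ``(coefficient, ladder)`` with ``ladder`` a tuple of
    ``(spin_orbital_index, dagger_flag)`` applied right-to-left, i.e.
    ``((p, 1), (q, 0))`` means ``a_p^+ a_q``.
    """

    terms: list[tuple[complex, tuple[tuple[int, int], ...]]]
    constant: complex = 0.0

    def __add__(self, other: "FermionTermSum") -> "FermionTermSum":
        return FermionTermSum(self.terms + other.terms, self.constant + other.constant)

    def scaled(self, factor: complex) -> "FermionTermSum":
        return FermionTermSum(
            [(factor * c, l) for c, l in self.terms], factor * self.constant
        )

    def simplified(self, tol: float = COEFF_TOL) -> "FermionTermSum":
        """Merge identical ladder strings and drop negligible coefficients."""
        acc: dict[tuple, complex] = {}
        for c, ladder in self.terms:
            acc[ladder] = acc.get(ladder, 0.0) + c
        terms = [(c, l) for l, c in acc.items() if abs(c) >= tol]
        return FermionTermSum(terms, self.constant)

    def hermiticity_defect(self) -> float:
        """Max deviation of the term set from closure under conjugation."""
        acc: dict[tuple, complex] = {}
        for c, ladder in self.simplified().terms:
            acc[ladder] = acc.get(ladder, 0.0) + c
        defect = abs(complex(self.constant).imag)
        for ladder, c in acc.items():
            conj = tuple((p, 1 - d) for p, d in reversed(ladder))
            defect = max(defect, abs(np.conj(c) - acc.get(conj, 0.0)))
        return defect

    def max_index(self) -> int:
        return max((p for _, l in self.terms for p, _ in l), default=-1)


def build_full_hamiltonian(ints: SpinOrbitalIntegrals, tol: float = COEFF_TOL) -> FermionTermSum:
    """Assemble the full electronic Hamiltonian from spin-orbital integrals."""
    terms: list[tuple[complex, tuple[tuple[int, int], ...]]] = []
    h1 = ints.one_body
    for p, q in zip(*np.nonzero(np.abs(h1) > tol)):
        terms.append((h1[p, q], ((int(p), 1), (int(q), 0))))
    h2 = ints.two_body
    for p, q, r, s in zip(*np.nonzero(np.abs(h2) > tol)):
        terms.append(
            (0.5 * h2[p, q, r, s], ((int(p), 1), (int(q), 1), (int(r), 0), (int(s), 0)))
        )
    return FermionTermSum(terms, ints.core_energy)


def build_fock_hamiltonian(ints: SpinOrbitalIntegrals, tol: float = COEFF_TOL) -> FermionTermSum:
    """Initial Hamiltonian: the subset of H whose indices are all occupied.

    F = sum_i h_ii a_i^+ a_i
        + 1/2 sum_ij ( h_ijji a_i^+ a_j^+ a_j a_i + h_ijij a_i^+ a_j^+ a_i a_j )

    with i, j running over the spin orbitals occupied in the starting
    determinant.  Every term is, by construction, a term of the full
    Hamiltonian with an identical coefficient, so the interpolated
    Hamiltonian can hold these terms at full weight while the remainder is
    scaled by the schedule.  The i = j two-electron contribution vanishes
    identically (a_i^+ a_i^+ = 0) and is skipped so the coefficient-level
    subset property against the full Hamiltonian holds exactly.
    """
    occ = ints.occupied
    if not occ:
        raise ValueError("starting determinant has no occupied spin orbitals")
    h1 = ints.one_body
    h2 = ints.two_body
    terms: list[tuple[complex, tuple[tuple[int, int], ...]]] = []
    for i in occ:
        if abs(h1[i, i]) > tol:
            terms.append((h1[i, i], ((i, 1), (i, 0))))
    for i in occ:
        for j in occ:
            if i == j:
                continue
            c_coul = 0.5 * h2[i, j, j, i]
            if abs(c_coul) > tol:
                terms.append((c_coul, ((i, 1), (j, 1), (j, 0), (i, 0))))
            c_exch = 0.5 * h2[i, j, i, j]
            if abs(c_exch) > tol:
                terms.append((c_exch, ((i, 1), (j, 1), (i, 0), (j, 0))))
    return FermionTermSum(terms, 0.0)


def build_s2_operator(ab_overlap: np.ndarray, n_spatial: int) -> FermionTermSum:
    """Second-quantized total-spin operator S^2 = S_- S_+ + S_z (S_z + 1).

    The spin-raising operator carries the alpha-beta spatial-orbital overlap,
    S_+ = sum_pq <phi_p^a|phi_q^b> a_{p,alpha}^+ a_{q,beta}, which reduces to
    the textbook same-orbital form when the two spatial sets coincide
    (identity overlap).  Acting on an M_S = 0 determinant with k unpaired
    alpha and k unpaired beta electrons in mutually orthogonal localized
    orbitals its expectation value is k, e.g. 2.0 for |a a b b> and 3.0 for
    |a a a b b b>.
    """
    o = np.asarray(ab_overlap, dtype=float)
    if o.ndim != 2 or o.shape[0] != o.shape[1]:
        raise ValueError(f"ab_overlap must be square, got shape {o.shape}")
    if o.shape[0] != n_spatial:
        raise ValueError("ab_overlap size does not match n_spatial")
    terms: list[tuple[complex, tuple[tuple[int, int], ...]]] = []
    # S_- S_+ = sum_{pq,rs} O*_pq O_rs  a^+_{q b} a_{p a} a^+_{r a} a_{s b}
    for p in range(n_spatial):
        for q in range(n_spatial):
            if abs(o[p, q]) < COEFF_TOL:
                continue
            for r in range(n_spatial):
                for s in range(n_spatial):
                    c = o[p, q] * o[r, s]
                    if abs(c) < COEFF_TOL:
                        continue
                    terms.append(
                        (c, ((2 * q + 1, 1), (2 * p, 0), (2 * r, 1), (2 * s + 1, 0)))
                    )
    # S_z = 1/2 sum_p (n_{p a} - n_{p b});  S_z^2 expanded as number products
    for p in range(n_spatial):
        for sp, sgn_p in ((2 * p, 0.5), (2 * p + 1, -0.5)):
            terms.append((sgn_p, ((sp, 1), (sp, 0))))
            for q in range(n_spatial):
                for sq, sgn_q in ((2 * q, 0.5), (2 * q + 1, -0.5)):
                    terms.append(
                        (sgn_p * sgn_q, ((sp, 1), (sp, 0), (sq, 1), (sq, 0)))
                    )
    return FermionTermSum(terms, 0.0).simplified()


# ---------------------------------------------------------------------------
# FCIDUMP I/O
# ---------------------------------------------------------------------------

_SENTINEL = " 0.000000000000000E+00    0    0    0    0\n"


def write_fcidump(ints: SpinOrbitalIntegrals, path: str | Path, tol: float = 1e-14) -> None:
    """Write integrals in the Molpro FCIDUMP convention.

    Restricted sets produce a standard single-block file.  Unrestricted sets
    use the Molpro IUHF dialect: aa, bb and ab two-electron blocks, then the
    alpha and beta one-electron blocks, each separated by an all-zero
    sentinel record, with the core energy last.  The alpha-beta orbital
    overlap goes to a companion plain-text matrix file ``<path>.ovlp``.
    """
    path = Path(path)
    n = ints.n_spatial
    ms2 = int(round(2 * ints.m_s))
    with open(path, "w") as fh:
        header = f"&FCI NORB={n},NELEC={ints.n_elec},MS2={ms2},\n"
        fh.write(header)
        fh.write("  ORBSYM=" + "1," * n + "\n")
        fh.write("  ISYM=1," + ("IUHF=1,\n" if not ints.restricted else "\n"))
        fh.write(" &END\n")

        def dump_eri(eri: np.ndarray, symmetric_pairs: bool) -> None:
            seen = set()
            for p in range(n):
                for q in range(p + 1):
                    for r in range(n):
                        for s in range(r + 1):
                            if symmetric_pairs and (r, s, p, q) in seen:
                                continue
                            v = eri[p, q, r, s]
                            seen.add((p, q, r, s))
                            if abs(v) > tol:
                                fh.write(
                                    f"{v:23.16E} {p + 1:4d} {q + 1:4d} {r + 1:4d} {s + 1:4d}\n"
                                )

        def dump_h(h: np.ndarray) -> None:
            for p in range(n):
                for q in range(p + 1):
                    if abs(h[p, q]) > tol:
                        fh.write(f"{h[p, q]:23.16E} {p + 1:4d} {q + 1:4d}    0    0\n")

        if ints.restricted:
            dump_eri(ints.eri_aaaa, True)
            dump_h(ints.h_aa)
            fh.write(f"{ints.core_energy:23.16E}    0    0    0    0\n")
        else:
            dump_eri(ints.eri_aaaa, True)
            fh.write(_SENTINEL)
            dump_eri(ints.eri_bbbb, True)
            fh.write(_SENTINEL)
            dump_eri(ints.eri_aabb, False)
            fh.write(_SENTINEL)
            dump_h(ints.h_aa)
            fh.write(_SENTINEL)
            dump_h(ints.h_bb)
            fh.write(_SENTINEL)
            fh.write(f"{ints.core_energy:23.16E}    0    0    0    0\n")
    if not ints.restricted:
        np.savetxt(str(path) + ".ovlp", ints.ab_overlap, fmt="%23.16E")


def read_fcidump(path: str | Path, ovlp_path: str | Path | None = None) -> SpinOrbitalIntegrals:
    """Read a (restricted or IUHF-dialect unrestricted) FCIDUMP file.

    For unrestricted files the alpha-beta overlap matrix is read from
    ``ovlp_path`` (default: ``<path>.ovlp``), a plain whitespace-delimited
    matrix.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header_lines: list[str] = []
    body_start = None
    for i, ln in enumerate(lines):
        header_lines.append(ln)
        if "&END" in ln.upper() or ln.strip() == "/" or ln.strip().endswith("/"):
            body_start = i + 1
            break
    if body_start is None:
        raise FcidumpError(f"{path}: no &END terminator found in header")
    header = " ".join(header_lines).upper()

    def get_int(key: str, required: bool = True, default: int = 0) -> int:
        m = re.search(rf"{key}\s*=\s*(-?\d+)", header)
        if not m:
            if required:
                raise FcidumpError(f"{path}: header is missing {key} (line 1)")
            return default
        return int(m.group(1))

    norb = get_int("NORB")
    nelec = get_int("NELEC")
    ms2 = get_int("MS2")
    iuhf = get_int("IUHF", required=False)

    n = norb
    blocks: list[list[tuple[float, int, int, int, int]]] = [[]]
    for lineno, ln in enumerate(lines[body_start:], start=body_start + 1):
        parts = ln.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise FcidumpError(f"{path}:{lineno}: expected 'value i j k l'")
        try:
            v = float(parts[0].replace("D", "E").replace("d", "e"))
            i, j, k, l = (int(x) for x in parts[1:])
        except ValueError as exc:
            raise FcidumpError(f"{path}:{lineno}: unparsable record") from exc
        if (i, j, k, l) == (0, 0, 0, 0) and v == 0.0:
            blocks.append([])  # sentinel: next block
        else:
            blocks[-1].append((v, i, j, k, l))

    def fill_eri(records, eightfold: bool) -> np.ndarray:
        eri = np.full((n, n, n, n), np.nan)

        def put(p, q, r, s, v):
            old = eri[p, q, r, s]
            if not np.isnan(old) and abs(old - v) > 1e-8:
                raise FcidumpError(
                    f"{path}: symmetry-violating duplicate entry for "
                    f"({p + 1},{q + 1},{r + 1},{s + 1}): {old} vs {v}"
                )
            eri[p, q, r, s] = v

        for v, i, j, k, l in records:
            p, q, r, s = i - 1, j - 1, k - 1, l - 1
            for a, b in ((p, q), (q, p)):
                for c, d in ((r, s), (s, r)):
                    put(a, b, c, d, v)
                    if eightfold:
                        put(c, d, a, b, v)
        eri = np.nan_to_num(eri, nan=0.0)
        return eri

    def fill_h(records) -> np.ndarray:
        h = np.zeros((n, n))
        for v, i, j, k, l in records:
            if (k, l) != (0, 0):
                raise FcidumpError(f"{path}: one-electron record with 4 indices")
            if j == 0:
                continue  # orbital-energy record (i, 0, 0, 0): not used here
            h[i - 1, j - 1] = v
            h[j - 1, i - 1] = v
        return h

    if not iuhf:
        two, one, core = [], [], 0.0
        for rec in blocks[0] + sum(blocks[1:], []):
            v, i, j, k, l = rec
            if k != 0:
                two.append(rec)
            elif i != 0:
                one.append(rec)
            else:
                core = v
        eri = fill_eri(two, eightfold=True)
        h = fill_h(one)
        out = SpinOrbitalIntegrals.from_restricted(h, eri, core, nelec, ms2)
        out.validate()
        return out

    # unrestricted dialect: aa | bb | ab | h_a | h_b | core
    if len(blocks) < 6:
        raise FcidumpError(f"{path}: IUHF file needs 6 sentinel-separated blocks")
    eri_aa = fill_eri(blocks[0], eightfold=True)
    eri_bb = fill_eri(blocks[1], eightfold=True)
    eri_ab = fill_eri(blocks[2], eightfold=False)
    h_a = fill_h(blocks[3])
    h_b = fill_h(blocks[4])
    core = blocks[5][0][0] if blocks[5] else 0.0
    ovlp_file = Path(ovlp_path) if ovlp_path is not None else Path(str(path) + ".ovlp")
    if not ovlp_file.exists():
        raise FcidumpError(
            f"{path}: unrestricted integrals need the overlap companion file "
            f"{ovlp_file} (alpha-beta spatial orbital overlap matrix)"
        )
    ab_overlap = np.loadtxt(ovlp_file).reshape(n, n)
    out = SpinOrbitalIntegrals(
        n_spatial=n,
        core_energy=core,
        h_aa=h_a,
        h_bb=h_b,
        eri_aaaa=eri_aa,
        eri_bbbb=eri_bb,
        eri_aabb=eri_ab,
        ab_overlap=ab_overlap,
        restricted=False,
        occupied=_aufbau_occupation(nelec, ms2),
    )
    out.validate()
    return out
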