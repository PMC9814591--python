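#!/usr/bin/env python
"""Generate the packaged active-space integral fixtures (N2 and BeH2, STO-3G).

A self-contained minimal Hartree-Fock code: McMurchie-Davidson one- and
two-electron integrals over contracted s/p Gaussians, restricted and
unrestricted SCF with DIIS, four-index AO->MO transformation, frozen-core
active-space reduction, and FCIDUMP export through aspsim's writer.  It also
computes the metadata the protocol layer consumes: RHF orbital energies and
HOMO-LUMO gaps, broken-symmetry UHF natural-orbital occupations and the
derived diradical characters, and the occupied/virtual pairing (by largest
exchange integral) used to manufacture broken-symmetry determinants.

Run from the repository root:

    python scripts/generate_integrals.py

Sanity anchors (printed during generation): H2/STO-3G at R = 1.4 bohr gives
E(RHF) = -1.1167 Eh; N2/STO-3G near equilibrium gives E(RHF) about -107.50 Eh.

This script is a generation-time tool; the aspsim package never imports it.
"""

from __future__ import annotations

import math
import sys
from functools import lru_cache
from pathlib import Path

import numpy as np
import yaml
from scipy.special import hyp1f1

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from aspsim.hamiltonians import SpinOrbitalIntegrals, write_fcidump  # noqa: E402

ANGSTROM = 1.0 / 0.529177210903  # to bohr

# ---------------------------------------------------------------------------
# STO-3G basis (canonical exponents/coefficients; 2s and 2p share exponents)
# ---------------------------------------------------------------------------

STO3G = {
    "H": [("s", [3.42525091, 0.62391373, 0.16885540],
           [0.15432897, 0.53532814, 0.44463454])],
    "Be": [
        ("s", [30.1678710, 5.4951153, 1.4871927],
         [0.15432897, 0.53532814, 0.44463454]),
        ("s", [1.3148331, 0.3055389, 0.0993707],
         [-0.09996723, 0.39951283, 0.70011547]),
        ("p", [1.3148331, 0.3055389, 0.0993707],
         [0.15591627, 0.60768372, 0.39195739]),
    ],
    "N": [
        ("s", [99.1061690, 18.0523120, 4.8856602],
         [0.15432897, 0.53532814, 0.44463454]),
        ("s", [3.7804559, 0.8784966, 0.2857144],
         [-0.09996723, 0.39951283, 0.70011547]),
        ("p", [3.7804559, 0.8784966, 0.2857144],
         [0.15591627, 0.60768372, 0.39195739]),
    ],
}

CHARGE = {"H": 1, "Be": 4, "N": 7}


def double_factorial(n: int) -> int:
    return 1 if n <= 1 else n * double_factorial(n - 2)


class BasisFunction:
    def __init__(self, center, lmn, exps, coeffs):
        self.center = np.asarray(center, float)
        self.lmn = tuple(lmn)
        self.exps = np.asarray(exps, float)
        l, m, n = lmn
        norms = np.sqrt(
            (2 * self.exps / np.pi) ** 1.5
            * (4 * self.exps) ** (l + m + n)
            / (double_factorial(2 * l - 1)
               * double_factorial(2 * m - 1)
               * double_factorial(2 * n - 1))
        )
        self.coeffs = np.asarray(coeffs, float) * norms
        s_self = 0.0
        for a, ca in zip(self.exps, self.coeffs):
            for b, cb in zip(self.exps, self.coeffs):
                s_self += ca * cb * _overlap_prim(a, self.lmn, self.center,
                                                 b, self.lmn, self.center)
        self.coeffs /= math.sqrt(s_self)


def build_basis(atoms):
    """Basis functions plus axial-symmetry labels (molecules on the z axis).

    For linear molecules aligned with z the AO space splits into sigma
    (s, p_z) and pi_x / p_y blocks; enforcing this block structure on the
    Fock matrix keeps the SCF on the symmetry-adapted solution branch and
    the pi orbitals exactly degenerate, as a production code's point-group
    handling would.
    """
    basis, labels = [], []
    for el, xyz in atoms:
        for shell, exps, coeffs in STO3G[el]:
            if shell == "s":
                basis.append(BasisFunction(xyz, (0, 0, 0), exps, coeffs))
                labels.append("sigma")
            else:
                for lmn, lab in (((1, 0, 0), "x"), ((0, 1, 0), "y"),
                                 ((0, 0, 1), "sigma")):
                    basis.append(BasisFunction(xyz, lmn, exps, coeffs))
                    labels.append(lab)
    return basis, labels


def symmetrize_fock(F, labels):
    """Zero symmetry-forbidden blocks and average the x/y blocks."""
    F = F.copy()
    lab = np.asarray(labels)
    mask = lab[:, None] != lab[None, :]
    F[mask] = 0.0
    ix = np.nonzero(lab == "x")[0]
    iy = np.nonzero(lab == "y")[0]
    if ix.size and ix.size == iy.size:
        avg = 0.5 * (F[np.ix_(ix, ix)] + F[np.ix_(iy, iy)])
        F[np.ix_(ix, ix)] = avg
        F[np.ix_(iy, iy)] = avg
    return F


# ---------------------------------------------------------------------------
# McMurchie-Davidson primitive integrals
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _E(i, j, t, Q, a, b):
    """Hermite expansion coefficient for a 1D Gaussian product."""
    p = a + b
    q = a * b / p
    if t < 0 or t > i + j:
        return 0.0
    if i == j == t == 0:
        return math.exp(-q * Q * Q)
    if j == 0:
        return (
            _E(i - 1, j, t - 1, Q, a, b) / (2 * p)
            - q * Q / a * _E(i - 1, j, t, Q, a, b)
            + (t + 1) * _E(i - 1, j, t + 1, Q, a, b)
        )
    return (
        _E(i, j - 1, t - 1, Q, a, b) / (2 * p)
        + q * Q / b * _E(i, j - 1, t, Q, a, b)
        + (t + 1) * _E(i, j - 1, t + 1, Q, a, b)
    )


def _overlap_prim(a, lmn1, A, b, lmn2, B):
    s = 1.0
    for k in range(3):
        s *= _E(lmn1[k], lmn2[k], 0, A[k] - B[k], a, b)
    return s * (math.pi / (a + b)) ** 1.5


def _kinetic_prim(a, lmn1, A, b, lmn2, B):
    l2, m2, n2 = lmn2
    term0 = b * (2 * (l2 + m2 + n2) + 3) * _overlap_prim(a, lmn1, A, b, lmn2, B)
    term1 = -2 * b**2 * (
        _overlap_prim(a, lmn1, A, b, (l2 + 2, m2, n2), B)
        + _overlap_prim(a, lmn1, A, b, (l2, m2 + 2, n2), B)
        + _overlap_prim(a, lmn1, A, b, (l2, m2, n2 + 2), B)
    )
    term2 = -0.5 * (
        l2 * (l2 - 1) * _overlap_prim(a, lmn1, A, b, (l2 - 2, m2, n2), B)
        + m2 * (m2 - 1) * _overlap_prim(a, lmn1, A, b, (l2, m2 - 2, n2), B)
        + n2 * (n2 - 1) * _overlap_prim(a, lmn1, A, b, (l2, m2, n2 - 2), B)
    )
    return term0 + term1 + term2


def _boys(n, x):
    return hyp1f1(n + 0.5, n + 1.5, -x) / (2.0 * n + 1.0)


def _R(t, u, v, n, p, PC, rpc2, cache):
    key = (t, u, v, n)
    if key in cache:
        return cache[key]
    if t == u == v == 0:
        val = (-2.0 * p) ** n * _boys(n, p * rpc2)
    elif t > 0:
        val = (t - 1) * _R(t - 2, u, v, n + 1, p, PC, rpc2, cache) if t > 1 else 0.0
        val += PC[0] * _R(t - 1, u, v, n + 1, p, PC, rpc2, cache)
    elif u > 0:
        val = (u - 1) * _R(t, u - 2, v, n + 1, p, PC, rpc2, cache) if u > 1 else 0.0
        val += PC[1] * _R(t, u - 1, v, n + 1, p, PC, rpc2, cache)
    else:
        val = (v - 1) * _R(t, u, v - 2, n + 1, p, PC, rpc2, cache) if v > 1 else 0.0
        val += PC[2] * _R(t, u, v - 1, n + 1, p, PC, rpc2, cache)
    cache[key] = val
    return val


def _nuclear_prim(a, lmn1, A, b, lmn2, B, C):
    p = a + b
    P = (a * A + b * B) / p
    PC = P - C
    rpc2 = float(PC @ PC)
    cache: dict = {}
    val = 0.0
    for t in range(lmn1[0] + lmn2[0] + 1):
        et = _E(lmn1[0], lmn2[0], t, A[0] - B[0], a, b)
        for u in range(lmn1[1] + lmn2[1] + 1):
            eu = _E(lmn1[1], lmn2[1], u, A[1] - B[1], a, b)
            for v in range(lmn1[2] + lmn2[2] + 1):
                ev = _E(lmn1[2], lmn2[2], v, A[2] - B[2], a, b)
                val += et * eu * ev * _R(t, u, v, 0, p, PC, rpc2, cache)
    return 2.0 * math.pi / p * val


def _eri_prim(a, lmn1, A, b, lmn2, B, c, lmn3, C, d, lmn4, D):
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    PQ = P - Q
    rpq2 = float(PQ @ PQ)
    cache: dict = {}
    val = 0.0
    for t in range(lmn1[0] + lmn2[0] + 1):
        e1t = _E(lmn1[0], lmn2[0], t, A[0] - B[0], a, b)
        for u in range(lmn1[1] + lmn2[1] + 1):
            e1u = _E(lmn1[1], lmn2[1], u, A[1] - B[1], a, b)
            for v in range(lmn1[2] + lmn2[2] + 1):
                e1v = _E(lmn1[2], lmn2[2], v, A[2] - B[2], a, b)
                f1 = e1t * e1u * e1v
                if f1 == 0.0:
                    continue
                for tt in range(lmn3[0] + lmn4[0] + 1):
                    e2t = _E(lmn3[0], lmn4[0], tt, C[0] - D[0], c, d)
                    for uu in range(lmn3[1] + lmn4[1] + 1):
                        e2u = _E(lmn3[1], lmn4[1], uu, C[1] - D[1], c, d)
                        for vv in range(lmn3[2] + lmn4[2] + 1):
                            e2v = _E(lmn3[2], lmn4[2], vv, C[2] - D[2], c, d)
                            f2 = e2t * e2u * e2v
                            if f2 == 0.0:
                                continue
                            val += (
                                f1 * f2 * (-1.0) ** (tt + uu + vv)
                                * _R(t + tt, u + uu, v + vv, 0, alpha, PQ, rpq2, cache)
                            )
    return val * 2.0 * math.pi**2.5 / (p * q * math.sqrt(p + q))


def _contract2(f, bf1, bf2, *extra):
    val = 0.0
    for a, ca in zip(bf1.exps, bf1.coeffs):
        for b, cb in zip(bf2.exps, bf2.coeffs):
            val += ca * cb * f(a, bf1.lmn, bf1.center, b, bf2.lmn, bf2.center, *extra)
    return val


def integrals(atoms):
    basis, sym_labels = build_basis(atoms)
    n = len(basis)
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            S[i, j] = S[j, i] = _contract2(_overlap_prim, basis[i], basis[j])
            T[i, j] = T[j, i] = _contract2(_kinetic_prim, basis[i], basis[j])
            v = 0.0
            for el, xyz in atoms:
                v -= CHARGE[el] * _contract2(
                    _nuclear_prim, basis[i], basis[j], np.asarray(xyz, float)
                )
            V[i, j] = V[j, i] = v
    eri = np.zeros((n, n, n, n))
    pairs = [(i, j) for i in range(n) for j in range(i + 1)]
    for ij, (i, j) in enumerate(pairs):
        for k, l in pairs[: ij + 1]:
            val = 0.0
            for a, ca in zip(basis[i].exps, basis[i].coeffs):
                for b, cb in zip(basis[j].exps, basis[j].coeffs):
                    for c, cc in zip(basis[k].exps, basis[k].coeffs):
                        for d, cd in zip(basis[l].exps, basis[l].coeffs):
                            val += ca * cb * cc * cd * _eri_prim(
                                a, basis[i].lmn, basis[i].center,
                                b, basis[j].lmn, basis[j].center,
                                c, basis[k].lmn, basis[k].center,
                                d, basis[l].lmn, basis[l].center,
                            )
            for p, q in ((i, j), (j, i)):
                for r, s in ((k, l), (l, k)):
                    eri[p, q, r, s] = eri[r, s, p, q] = val
    e_nuc = 0.0
    for ii, (el1, x1) in enumerate(atoms):
        for el2, x2 in atoms[:ii]:
            e_nuc += CHARGE[el1] * CHARGE[el2] / np.linalg.norm(
                np.asarray(x1) - np.asarray(x2)
            )
    return S, T + V, eri, e_nuc, sym_labels


# ---------------------------------------------------------------------------
# SCF
# ---------------------------------------------------------------------------


def _diis_extrapolate(focks, errs):
    m = len(focks)
    B = -np.ones((m + 1, m + 1))
    B[m, m] = 0.0
    for i in range(m):
        for j in range(m):
            B[i, j] = np.sum(errs[i] * errs[j])
    rhs = np.zeros(m + 1)
    rhs[m] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:m]
    except np.linalg.LinAlgError:
        return focks[-1]
    return sum(ci * f for ci, f in zip(c, focks))


def mo_block(C, sym_labels):
    """Symmetry block of each MO (the Fock matrix is block diagonal)."""
    lab = np.asarray(sym_labels)
    return [lab[int(np.argmax(np.abs(C[:, i])))] for i in range(C.shape[1])]


def select_occupied(eps, C, sym_labels, occ_by_block, nocc):
    """Occupied MO indices: lowest per symmetry block, or plain aufbau."""
    if occ_by_block is None:
        return list(range(nocc))
    blocks = mo_block(C, sym_labels)
    occ = []
    for blk, cnt in occ_by_block.items():
        idx = [i for i, b in enumerate(blocks) if b == blk]
        occ.extend(idx[:cnt])
    return sorted(occ)


def rhf(S, hcore, eri, n_elec, e_nuc, sym_labels=None, occ_by_block=None,
        max_iter=200, tol=1e-11):
    n = S.shape[0]
    x = np.linalg.inv(np.linalg.cholesky(S))  # lower-triangular orthogonalizer
    nocc = n_elec // 2
    sym = (lambda f: symmetrize_fock(f, sym_labels)) if sym_labels else (lambda f: f)
    eps, C = _solve_fock(sym(hcore), x)
    focks, errs = [], []
    e_old = 0.0
    for it in range(max_iter):
        occ = select_occupied(eps, C, sym_labels, occ_by_block, nocc)
        D = 2.0 * C[:, occ] @ C[:, occ].T
        J = np.einsum("pqrs,rs->pq", eri, D)
        K = np.einsum("prqs,rs->pq", eri, D)
        F = hcore + J - 0.5 * K
        err = F @ D @ S - S @ D @ F
        focks.append(F)
        errs.append(err)
        if len(focks) > 8:
            focks.pop(0)
            errs.pop(0)
        F_use = _diis_extrapolate(focks, errs) if len(focks) > 1 else F
        eps, C = _solve_fock(sym(F_use), x)
        e_elec = 0.5 * np.sum(D * (hcore + F))
        if abs(e_elec - e_old) < tol and np.abs(err).max() < 1e-8:
            occ = select_occupied(eps, C, sym_labels, occ_by_block, nocc)
            return e_elec + e_nuc, eps, C, occ
        e_old = e_elec
    raise RuntimeError("RHF did not converge")


def _solve_fock(F, x):
    fp = x @ F @ x.T
    eps, cp = np.linalg.eigh(fp)
    return eps, x.T @ cp


def uhf(S, hcore, eri, n_a, n_b, e_nuc, C0=None, mix_pairs=(), mix_angle=math.pi / 4,
        sym_labels=None, kw_occ_by_block=None, max_iter=500, tol=1e-11):
    """UHF with an optional broken-symmetry initial guess.

    ``mix_pairs`` lists (occupied, virtual) MO index pairs of the RHF guess
    ``C0``; alpha orbitals are rotated by +angle, beta by -angle.
    """
    n = S.shape[0]
    x = np.linalg.inv(np.linalg.cholesky(S))
    sym = (lambda f: symmetrize_fock(f, sym_labels)) if sym_labels else (lambda f: f)
    if C0 is None:
        _, C0 = _solve_fock(hcore, x)
    Ca = C0.copy()
    Cb = C0.copy()
    for occ, vir in mix_pairs:
        for C, ang in ((Ca, mix_angle), (Cb, -mix_angle)):
            o, v = C[:, occ].copy(), C[:, vir].copy()
            C[:, occ] = math.cos(ang) * o + math.sin(ang) * v
            C[:, vir] = -math.sin(ang) * o + math.cos(ang) * v
    fock_hist, err_hist = [], []
    e_old = 0.0
    occ_by_block = kw_occ_by_block
    epsa = epsb = None
    for it in range(max_iter):
        if it == 0 or occ_by_block is None:
            occa, occb = list(range(n_a)), list(range(n_b))
        else:
            occa = select_occupied(epsa, Ca, sym_labels, occ_by_block, n_a)
            occb = select_occupied(epsb, Cb, sym_labels, occ_by_block, n_b)
        Da = Ca[:, occa] @ Ca[:, occa].T
        Db = Cb[:, occb] @ Cb[:, occb].T
        Dt = Da + Db
        J = np.einsum("pqrs,rs->pq", eri, Dt)
        Ka = np.einsum("prqs,rs->pq", eri, Da)
        Kb = np.einsum("prqs,rs->pq", eri, Db)
        Fa = hcore + J - Ka
        Fb = hcore + J - Kb
        err = np.concatenate(
            [(Fa @ Da @ S - S @ Da @ Fa).ravel(), (Fb @ Db @ S - S @ Db @ Fb).ravel()]
        )
        fock_hist.append((Fa, Fb))
        err_hist.append(err)
        if len(fock_hist) > 8:
            fock_hist.pop(0)
            err_hist.pop(0)
        if len(fock_hist) > 1:
            Fa_u = _diis_extrapolate([f[0] for f in fock_hist], err_hist)
            Fb_u = _diis_extrapolate([f[1] for f in fock_hist], err_hist)
        else:
            Fa_u, Fb_u = Fa, Fb
        epsa, Ca = _solve_fock(sym(Fa_u), x)
        epsb, Cb = _solve_fock(sym(Fb_u), x)
        e_elec = 0.5 * (np.sum(Dt * hcore) + np.sum(Da * Fa) + np.sum(Db * Fb))
        if abs(e_elec - e_old) < tol and np.abs(err).max() < 1e-7:
            return e_elec + e_nuc, Ca, Cb, Da, Db
        e_old = e_elec
    raise RuntimeError("UHF did not converge")


# ---------------------------------------------------------------------------
# active space + metadata
# ---------------------------------------------------------------------------


def active_space_integrals(hcore, eri, C, n_core, n_act):
    """Frozen-core effective integrals over the active MO window."""
    Cc = C[:, :n_core]
    Ca = C[:, n_core:n_core + n_act]
    Dc = 2.0 * Cc @ Cc.T
    Jc = np.einsum("pqrs,rs->pq", eri, Dc)
    Kc = np.einsum("prqs,rs->pq", eri, Dc)
    veff = Jc - 0.5 * Kc
    h_act = Ca.T @ (hcore + veff) @ Ca
    e_core = np.sum(Dc * (hcore + 0.5 * veff))
    eri_act = np.einsum("pqrs,pa,qb,rc,sd->abcd", eri, Ca, Ca, Ca, Ca, optimize=True)
    return h_act, eri_act, e_core


def uhf_active_space_integrals(S, hcore, eri, Ca, Cb, n_core, n_act):
    """Frozen-core effective integrals over the UHF alpha/beta active windows."""
    Cca, Cva = Ca[:, :n_core], Ca[:, n_core:n_core + n_act]
    Ccb, Cvb = Cb[:, :n_core], Cb[:, n_core:n_core + n_act]
    Dca = Cca @ Cca.T
    Dcb = Ccb @ Ccb.T
    Jc = np.einsum("pqrs,rs->pq", eri, Dca + Dcb)
    Kca = np.einsum("prqs,rs->pq", eri, Dca)
    Kcb = np.einsum("prqs,rs->pq", eri, Dcb)
    h_a = Cva.T @ (hcore + Jc - Kca) @ Cva
    h_b = Cvb.T @ (hcore + Jc - Kcb) @ Cvb
    e_core = (
        np.sum((Dca + Dcb) * hcore)
        + 0.5 * np.sum((Dca + Dcb) * Jc)
        - 0.5 * np.sum(Dca * Kca)
        - 0.5 * np.sum(Dcb * Kcb)
    )
    tr = lambda C1, C2: np.einsum(
        "pqrs,pa,qb,rc,sd->abcd", eri, C1, C1, C2, C2, optimize=True
    )
    return h_a, h_b, tr(Cva, Cva), tr(Cvb, Cvb), tr(Cva, Cvb), e_core


def bs_pairing(eri_act, n_occ_act, n_act):
    """Greedy occupied/virtual pairing by largest exchange integral (ov|vo)."""
    occs = list(range(n_occ_act))
    virs = list(range(n_occ_act, n_act))
    pairs = []
    k = np.array([[abs(eri_act[o, v, v, o]) for v in virs] for o in occs])
    # pair the highest occupied orbitals first (HOMO - i with LUMO + j)
    for o_idx in sorted(range(len(occs)), reverse=True):
        if not virs:
            break
        best = int(np.argmax(k[o_idx]))
        pairs.append((occs[o_idx], virs[best]))
        k[:, best] = -1.0
    return sorted(pairs)


def uno_occupations(S, Da, Db):
    """Natural-orbital occupations of the UHF total density (descending)."""
    w, v = np.linalg.eigh(S)
    s_half = v @ np.diag(np.sqrt(w)) @ v.T
    occ = np.linalg.eigvalsh(s_half @ (Da + Db) @ s_half)
    return np.sort(occ)[::-1]


def diradical_y(n_luno):
    return 1.0 - 2.0 * (1.0 - n_luno) / (1.0 + (1.0 - n_luno) ** 2)


# ---------------------------------------------------------------------------
# systems
# ---------------------------------------------------------------------------


def n2_geometry(r_angstrom):
    r = r_angstrom * ANGSTROM
    return [("N", (0.0, 0.0, 0.0)), ("N", (0.0, 0.0, r))]


def beh2_geometry(r_angstrom):
    r = r_angstrom * ANGSTROM
    return [("Be", (0.0, 0.0, 0.0)), ("H", (0.0, 0.0, r)), ("H", (0.0, 0.0, -r))]


def process(name, atoms, n_elec, n_core, n_act, n_bs_pairs, out_dir, meta,
            occ_by_block=None):
    print(f"=== {name}")
    S, hcore, eri, e_nuc, sym_labels = integrals(atoms)
    e_rhf, eps, C, occ = rhf(S, hcore, eri, n_elec, e_nuc, sym_labels=sym_labels,
                             occ_by_block=occ_by_block)
    nocc = n_elec // 2
    vir = [i for i in range(C.shape[1]) if i not in occ]
    gap = float(min(eps[i] for i in vir) - max(eps[i] for i in occ))
    print(f"  E(RHF) = {e_rhf:.8f} Eh   HOMO-LUMO gap = {gap:.6f} Eh")
    # frozen core: the n_core lowest occupied; active orbitals ordered
    # occupied-first so the aufbau determinant of the FCIDUMP is the RHF one
    occ_sorted = sorted(occ, key=lambda i: eps[i])
    core_idx = occ_sorted[:n_core]
    act_occ = occ_sorted[n_core:]
    act_vir = sorted(vir, key=lambda i: eps[i])[: n_act - len(act_occ)]
    order = core_idx + act_occ + act_vir
    C = C[:, order]
    eps = eps[order]
    h_act, eri_act, e_core = active_space_integrals(hcore, eri, C, n_core, n_act)
    ints = SpinOrbitalIntegrals.from_restricted(
        h_act, eri_act, e_core + e_nuc, n_elec - 2 * n_core
    )
    ints.validate()
    fname = f"{name}.fcidump"
    write_fcidump(ints, out_dir / fname)
    n_occ_act = nocc - n_core
    pairs = bs_pairing(eri_act, n_occ_act, n_act)[-n_bs_pairs:] if n_bs_pairs else []
    # broken-symmetry UHF for natural-orbital occupations
    mix = [(n_core + o, n_core + v) for o, v in pairs]
    y_vals, n_lunos, e_uhf = [], [], None
    meta_bs_fcidump = None
    if mix:
        try:
            e_uhf, Ca, Cb, Da, Db = uhf(S, hcore, eri, nocc, nocc, e_nuc,
                                        C0=C, mix_pairs=mix, sym_labels=sym_labels,
                                        kw_occ_by_block=occ_by_block)
            occs = uno_occupations(S, Da, Db)
            n_lunos = [float(occs[nocc + i]) for i in range(len(pairs))]
            y_vals = [float(diradical_y(v)) for v in n_lunos]
            print(f"  E(BS-UHF) = {e_uhf:.8f} Eh  n_LUNO = "
                  f"{[round(v, 4) for v in n_lunos]}  y = {[round(v, 4) for v in y_vals]}")
            # spin-polarized solutions also get an unrestricted active-space
            # dump (the broken-symmetry propagation basis)
            if e_rhf - e_uhf > 1e-6:
                ha, hb, eaa, ebb, eab, ec = uhf_active_space_integrals(
                    S, hcore, eri, Ca, Cb, n_core, n_act)
                from aspsim.hamiltonians import _aufbau_occupation
                bs_ints = SpinOrbitalIntegrals(
                    n_spatial=n_act, core_energy=ec + e_nuc,
                    h_aa=ha, h_bb=hb, eri_aaaa=eaa, eri_bbbb=ebb, eri_aabb=eab,
                    ab_overlap=Ca[:, n_core:n_core + n_act].T @ S
                    @ Cb[:, n_core:n_core + n_act],
                    restricted=False,
                    occupied=_aufbau_occupation(n_elec - 2 * n_core, 0),
                )
                bs_ints.validate()
                write_fcidump(bs_ints, out_dir / f"{name}_bs.fcidump")
                meta_bs_fcidump = f"{name}_bs.fcidump"
            else:
                meta_bs_fcidump = None
        except RuntimeError as exc:
            print(f"  UHF failed: {exc}")
            meta_bs_fcidump = None
    meta[name] = {
        "fcidump": fname,
        "atoms": [[el, list(map(float, xyz))] for el, xyz in atoms],
        "units": "bohr",
        "basis": "STO-3G",
        "n_elec_active": n_elec - 2 * n_core,
        "n_orb_active": n_act,
        "e_rhf": float(e_rhf),
        "e_bs_uhf": float(e_uhf) if e_uhf is not None else None,
        "delta_eps": gap,
        "mo_energies": [float(x) for x in eps],
        "bs_pairs": [list(p) for p in pairs],
        "bs_fcidump": meta_bs_fcidump,
        "n_luno": n_lunos,
        "y": y_vals,
    }


def main():
    out_dir = Path(__file__).resolve().parents[1] / "src" / "aspsim" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)
    meta: dict = {}

    # quick anchor: H2 at 1.4 bohr
    S, h, eri, enuc, lab = integrals([("H", (0, 0, 0)), ("H", (0, 0, 1.4))])
    e = rhf(S, h, eri, 2, enuc, sym_labels=lab)[0]
    print(f"anchor H2/STO-3G @1.4a0: E(RHF) = {e:.5f} Eh (literature -1.11671)")

    # sigma^5 pi_x^1 pi_y^1 keeps N2 on the Sigma-g+ closed-shell branch
    for r in (1.0, 2.0, 3.0):
        process(f"n2_r{r:.2f}", n2_geometry(r), n_elec=14, n_core=4, n_act=6,
                n_bs_pairs=3, out_dir=out_dir, meta=meta,
                occ_by_block={"sigma": 5, "x": 1, "y": 1})
    for r in (0.7, 1.326, 2.0, 2.5, 3.0, 4.0):
        process(f"beh2_r{r:.2f}", beh2_geometry(r), n_elec=6, n_core=1, n_act=6,
                n_bs_pairs=1, out_dir=out_dir, meta=meta,
                occ_by_block={"sigma": 3})

    with open(out_dir / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    print(f"wrote {out_dir}/metadata.yaml")


if __name__ == "__main__":
    main()
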