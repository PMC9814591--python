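"""Self-contained test inputs: an analytic two-orbital model, the
broken-symmetry orbital rotation, and molecular recipes with packaged
active-space integrals.

The two-orbital, two-electron model is the smallest system with the
structure the simulator targets: a bonding (g) and an antibonding (u)
spatial orbital whose closed-shell determinants couple through one exchange
integral, giving a 2x2 singlet CI problem with closed-form ground energy

    E0 = core + (H_gg + H_uu)/2 - sqrt(((H_gg - H_uu)/2)^2 + K_gu^2),
    H_gg = 2 eps_g + J_gg,   H_uu = 2 eps_u + J_uu,

and a Hartree-Fock/CASCI squared overlap with the matching closed form.
The "dissociation" preset (degenerate g/u, sizeable K) emulates a covalent
bond at large separation, where the HF determinant carries only half the
ground state; the "equilibrium" preset has a large gap and a nearly pure HF
ground state.

Broken-symmetry determinants are manufactured by rotating each chosen
occupied/virtual spatial pair by +angle for the alpha orbitals and -angle
for the beta orbitals (the textbook HOMO-i / LUMO+i mixing); at angle pi/4
in the degenerate limit the rotated orbitals are fully localized and the
determinant carries <S^2> = 1 per broken pair.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .hamiltonians import SpinOrbitalIntegrals, read_fcidump

__all__ = [
    "ToyModelSpec",
    "MoleculeRecipe",
    "toy_integrals",
    "toy_closed_form",
    "rotate_to_bs",
    "emit_recipe",
    "packaged_systems",
    "load_packaged",
]


@dataclass
class ToyModelSpec:
    """Parameters (Hartree) of the analytic two-orbital model."""

    eps_g: float = -0.5
    eps_u: float = -0.5
    j_gg: float = 0.35
    j_uu: float = 0.35
    j_gu: float = 0.35
    k_gu: float = 0.35
    core: float = 0.0
    bs_angle: float = 0.0

    @classmethod
    def dissociation(cls) -> "ToyModelSpec":
        """Degenerate orbitals with on-site repulsion U = 0.7 split over the
        delocalized pair; the HF/CASCI squared overlap is exactly 1/2."""
        return cls()

    @classmethod
    def equilibrium(cls) -> "ToyModelSpec":
        """Large-gap, weakly correlated preset."""
        return cls(eps_g=-1.2, eps_u=-0.2, j_gg=0.6, j_uu=0.55, j_gu=0.5, k_gu=0.12)


def toy_integrals(spec: ToyModelSpec) -> SpinOrbitalIntegrals:
    """Two-spatial-orbital integrals realizing the analytic model."""
    if spec.k_gu < 0:
        raise ValueError("exchange integral K_gu must be non-negative")
    h = np.diag([spec.eps_g, spec.eps_u])
    eri = np.zeros((2, 2, 2, 2))
    eri[0, 0, 0, 0] = spec.j_gg
    eri[1, 1, 1, 1] = spec.j_uu
    eri[0, 0, 1, 1] = eri[1, 1, 0, 0] = spec.j_gu
    for p, q, r, s in ((0, 1, 0, 1), (1, 0, 0, 1), (0, 1, 1, 0), (1, 0, 1, 0)):
        eri[p, q, r, s] = spec.k_gu
    ints = SpinOrbitalIntegrals.from_restricted(h, eri, spec.core, n_elec=2)
    if spec.bs_angle:
        ints = rotate_to_bs(ints, [(0, 1)], spec.bs_angle)
    ints.validate()
    return ints


def toy_closed_form(spec: ToyModelSpec) -> dict[str, float]:
    """Closed-form singlet CI solution of the model (2x2 block)."""
    h_gg = 2 * spec.eps_g + spec.j_gg
    h_uu = 2 * spec.eps_u + spec.j_uu
    delta = 0.5 * (h_gg - h_uu)
    root = math.hypot(delta, spec.k_gu)
    e0 = spec.core + 0.5 * (h_gg + h_uu) - root
    if root == 0.0:
        overlap_sq = 1.0  # fully degenerate, uncoupled: HF state is stationary
    else:
        # ground eigenvector of the traceless part [[delta, K], [K, -delta]]
        overlap_sq = 0.5 * (1.0 - delta / root)
    return {
        "E0": e0,
        "overlap_sq_hf": overlap_sq,
        "E_hf": spec.core + h_gg,
        "gap_ci": 2 * root,
    }


def rotate_to_bs(
    ints: SpinOrbitalIntegrals, pairs, angle: float
) -> SpinOrbitalIntegrals:
    """Rotate occupied/virtual spatial pairs by +-angle to break spin symmetry.

    Alpha orbitals are rotated by ``+angle`` within each ``(occupied,
    virtual)`` spatial pair, beta orbitals by ``-angle``; all integral blocks
    and the alpha-beta overlap are transformed consistently.  ``angle = 0``
    returns the input unchanged.
    """
    pairs = [tuple(p) for p in pairs]
    flat = [i for p in pairs for i in p]
    if len(set(flat)) != len(flat):
        raise ValueError("broken-symmetry pairs must be disjoint")
    if not ints.restricted:
        raise ValueError("broken-symmetry rotation starts from restricted integrals")
    if angle == 0.0:
        return ints
    n = ints.n_spatial
    r_a = np.eye(n)
    for occ, vir in pairs:
        c, s = math.cos(angle), math.sin(angle)
        r_a[np.ix_([occ, vir], [occ, vir])] = [[c, -s], [s, c]]
    r_b = np.eye(n)
    for occ, vir in pairs:
        c, s = math.cos(-angle), math.sin(-angle)
        r_b[np.ix_([occ, vir], [occ, vir])] = [[c, -s], [s, c]]

    def rot1(h, r):
        return r.T @ h @ r

    def rot4(eri, r1, r2):
        # chemists (pq|rs): first pair with r1, second with r2
        tmp = np.einsum("pqrs,pa->aqrs", eri, r1)
        tmp = np.einsum("aqrs,qb->abrs", tmp, r1)
        tmp = np.einsum("abrs,rc->abcs", tmp, r2)
        return np.einsum("abcs,sd->abcd", tmp, r2)

    out = SpinOrbitalIntegrals(
        n_spatial=n,
        core_energy=ints.core_energy,
        h_aa=rot1(ints.h_aa, r_a),
        h_bb=rot1(ints.h_bb, r_b),
        eri_aaaa=rot4(ints.eri_aaaa, r_a, r_a),
        eri_bbbb=rot4(ints.eri_bbbb, r_b, r_b),
        eri_aabb=rot4(ints.eri_aabb, r_a, r_b),
        ab_overlap=r_a.T @ r_b,
        restricted=False,
        occupied=ints.occupied,
    )
    out.validate()
    return out


# ---------------------------------------------------------------------------
# molecular recipes and packaged integrals
# ---------------------------------------------------------------------------

#: C2v insertion pathway of Be into H2: H-atom coordinates in bohr, Be at the
#: origin; the two H atoms sit at (0, +y, z) and (0, -y, z).
BE_H2_PATHWAY_BOHR = {
    "A": (2.540, 0.000),
    "B": (2.080, 1.000),
    "C": (1.620, 2.000),
    "D": (1.390, 2.500),
    "E": (1.275, 2.750),
    "F": (1.160, 3.000),
    "G": (0.930, 3.500),
    "H": (0.700, 4.000),
    "I": (0.700, 6.000),
}


@dataclass
class MoleculeRecipe:
    """Geometry grid plus basis / active-space metadata for one scan."""

    name: str
    basis: str
    active_space: tuple[int, int]  # (n_elec, n_orb)
    reference: str                 # RHF | BS-UHF
    geometries: dict[str, list[tuple[str, float, float, float]]] = field(
        default_factory=dict
    )  # label -> [(element, x, y, z)] in Angstrom unless noted
    units: str = "angstrom"
    notes: str = ""

    def to_yaml(self) -> str:
        data = {
            "name": self.name,
            "basis": self.basis,
            "active_space": list(self.active_space),
            "reference": self.reference,
            "units": self.units,
            "notes": self.notes,
            "geometries": {
                k: [[el, float(x), float(y), float(z)] for el, x, y, z in v]
                for k, v in self.geometries.items()
            },
        }
        return yaml.safe_dump(data, sort_keys=False)


_SCRIPT_STUB = """\
# Regenerate the FCIDUMP inputs for recipe {name!r} with any SCF backend:
#   1. run a {ref} calculation in the {basis} basis at each geometry below,
#   2. transform AO integrals to the {nact} active molecular orbitals
#      (freeze the remaining core orbitals into the core energy),
#   3. write Molpro-convention FCIDUMP files (see aspsim.hamiltonians).
# The repository's scripts/generate_integrals.py does this with its own
# minimal STO-3G Hartree-Fock implementation.
"""


def emit_recipe(name: str) -> tuple[MoleculeRecipe, str]:
    """Packaged geometry recipe plus a generation script stub.

    Known names: ``N2_scan``, ``BeH2_scan``, ``BeH2_C2v_pathway``.
    """
    bohr = 0.529177210903
    if name == "N2_scan":
        grid = [round(r, 2) for r in np.arange(1.0, 3.01, 0.1)]
        rec = MoleculeRecipe(
            name=name, basis="STO-3G", active_space=(6, 6), reference="RHF",
            geometries={
                f"R{r:.2f}": [("N", 0.0, 0.0, 0.0), ("N", 0.0, 0.0, r)] for r in grid
            },
            notes="triple-bond dissociation; representative points 1.0, 2.0, 3.0 A",
        )
    elif name == "BeH2_scan":
        grid = [round(r, 2) for r in np.arange(0.7, 4.01, 0.1)]
        rec = MoleculeRecipe(
            name=name, basis="STO-3G", active_space=(4, 6), reference="RHF",
            geometries={
                f"R{r:.2f}": [
                    ("Be", 0.0, 0.0, 0.0),
                    ("H", 0.0, 0.0, r),
                    ("H", 0.0, 0.0, -r),
                ]
                for r in grid
            },
            notes="symmetric linear dissociation, R(Be-H) from 0.7 to 4.0 A",
        )
    elif name == "BeH2_C2v_pathway":
        rec = MoleculeRecipe(
            name=name,
            basis="Purvis (10s3p)/[3s1p] on Be, (4s)/[2s] on H",
            active_space=(4, 9),
            reference="RHF",
            geometries={
                label: [
                    ("Be", 0.0, 0.0, 0.0),
                    ("H", 0.0, y * bohr, z * bohr),
                    ("H", 0.0, -y * bohr, z * bohr),
                ]
                for label, (y, z) in BE_H2_PATHWAY_BOHR.items()
            },
            notes=(
                "C2v insertion pathway; source coordinates in bohr, converted "
                "to Angstrom here. Active-space selection via CISD natural "
                "orbitals is recommended for larger bases."
            ),
        )
    else:
        raise KeyError(f"unknown recipe {name!r}")
    stub = _SCRIPT_STUB.format(
        name=name, ref=rec.reference, basis=rec.basis, nact=rec.active_space[1]
    )
    return rec, stub


def _data_dir() -> Path:
    return Path(str(importlib.resources.files("aspsim") / "data"))


def packaged_systems() -> dict:
    """Metadata for the integral sets shipped with the package."""
    meta_file = _data_dir() / "metadata.yaml"
    with open(meta_file) as fh:
        return yaml.safe_load(fh)


def load_packaged(name: str) -> tuple[SpinOrbitalIntegrals, dict]:
    """Load one packaged FCIDUMP by name (e.g. ``n2_r2.00``).

    Returns the integrals and the system's metadata record (orbital
    energies, HOMO-LUMO gap, natural-orbital occupations, diradical
    characters, broken-symmetry pairing).
    """
    meta = packaged_systems()
    if name not in meta:
        raise KeyError(f"unknown packaged system {name!r}; have {sorted(meta)}")
    rec = meta[name]
    ints = read_fcidump(_data_dir() / rec["fcidump"])
    return ints, rec
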