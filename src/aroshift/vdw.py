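"""Lennard-Jones energy of an alanine amide approaching a phenylalanine ring.

A rigid ALA residue is placed with its amide N on the ring normal of a
rigid PHE, N-H pointing at the ring centroid, and the 12-6 van der Waals
interaction energy is scanned as a function of the N-to-centroid distance.
Because both residues are rigid, subtracting the isolated-residue energies
from the complex energy leaves exactly the sum over inter-residue atom
pairs, which is what is computed.

Nonbonded parameters are the AMBER parm99 well depths (kcal/mol) and
Rmin/2 radii (A) for the nine atom classes the two templates need, with
the standard combining rules eps_ij = sqrt(eps_i eps_j) and
Rmin_ij = Rmin_i/2 + Rmin_j/2.  Only the van der Waals term is computed;
no electrostatics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LJAtomParams:
    atom_class: str
    epsilon: float   # kcal/mol
    rmin_half: float  # A

    def __post_init__(self) -> None:
        if self.epsilon < 0 or not (self.rmin_half > 0):
            raise ValueError(f"invalid LJ parameters for {self.atom_class}")


#: AMBER parm99 nonbonded parameters (Rmin/2 in A, epsilon in kcal/mol).
LJ_PARAMS: Dict[str, LJAtomParams] = {
    cls: LJAtomParams(cls, eps, rmin_half)
    for cls, rmin_half, eps in [
        ("N",  1.8240, 0.1700),   # amide nitrogen
        ("H",  0.6000, 0.0157),   # H on amide nitrogen
        ("CT", 1.9080, 0.1094),   # sp3 carbon
        ("H1", 1.3870, 0.0157),   # sp3 H, one electronegative neighbour
        ("HC", 1.4870, 0.0157),   # sp3 H on plain carbon
        ("CA", 1.9080, 0.0860),   # aromatic carbon
        ("HA", 1.4590, 0.0150),   # aromatic hydrogen
        ("C",  1.9080, 0.0860),   # carbonyl carbon
        ("O",  1.6612, 0.2100),   # carbonyl oxygen
    ]
}


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    atom_class: str
    xyz: Tuple[float, float, float]


@dataclass(frozen=True)
class ResidueTemplate:
    residue_type: str
    atoms: Tuple[TemplateAtom, ...]

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def params(self) -> List[LJAtomParams]:
        return [LJ_PARAMS[a.atom_class] for a in self.atoms]


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position of atom D bonded to C, with angle B-C-D and dihedral A-B-C-D."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    basis = np.column_stack([bc, m, n])
    return c + basis @ d_local


def ala_template() -> ResidueTemplate:
    """Idealized alanine in a local frame: N at origin, N->H along -z."""
    xyz: Dict[str, np.ndarray] = {}
    xyz["N"] = np.zeros(3)
    xyz["H"] = np.array([0.0, 0.0, -1.01])
    ang = math.radians(118.0)  # H-N-CA
    xyz["CA"] = 1.458 * np.array([math.sin(ang), 0.0, -math.cos(ang)])
    xyz["C"] = _place(xyz["H"], xyz["N"], xyz["CA"], 1.525, 110.4, 180.0)
    xyz["O"] = _place(xyz["N"], xyz["CA"], xyz["C"], 1.229, 120.5, -30.0)
    xyz["CB"] = _place(xyz["H"], xyz["N"], xyz["CA"], 1.526, 110.5, -60.0)
    xyz["HA"] = _place(xyz["H"], xyz["N"], xyz["CA"], 1.090, 109.5, 60.0)
    for i, dih in enumerate((60.0, 180.0, -60.0), start=1):
        xyz[f"HB{i}"] = _place(xyz["N"], xyz["CA"], xyz["CB"], 1.090, 109.5, dih)
    classes = {"N": "N", "H": "H", "CA": "CT", "HA": "H1", "CB": "CT",
               "HB1": "HC", "HB2": "HC", "HB3": "HC", "C": "C", "O": "O"}
    return ResidueTemplate(
        "ALA",
        tuple(TemplateAtom(n, classes[n], tuple(map(float, xyz[n])))
              for n in classes),
    )


def phe_template() -> ResidueTemplate:
    """Idealized phenylalanine: ring centroid at origin, ring in the xy-plane.

    Backbone atoms sit on the -z side so an approach down the +z axis meets
    only the ring face.
    """
    xyz: Dict[str, np.ndarray] = {}
    ring_r = 1.40   # aromatic C-C bond == hexagon circumradius
    ring_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    for i, name in enumerate(ring_names):
        ang = math.radians(60.0 * i)
        xyz[name] = ring_r * np.array([math.cos(ang), math.sin(ang), 0.0])
    for name in ring_names[1:]:
        xyz["H" + name[1:]] = xyz[name] * ((ring_r + 1.08) / ring_r)
    xyz["CB"] = np.array([ring_r + 1.51, 0.0, 0.0])
    xyz["CA"] = _place(xyz["CD1"], xyz["CG"], xyz["CB"], 1.526, 114.0, -90.0)
    if xyz["CA"][2] > 0:  # keep the backbone below the ring plane
        xyz["CA"][2] = -xyz["CA"][2]
    xyz["N"] = _place(xyz["CG"], xyz["CB"], xyz["CA"], 1.458, 110.5, 180.0)
    xyz["H"] = _place(xyz["CB"], xyz["CA"], xyz["N"], 1.010, 118.0, 60.0)
    xyz["C"] = _place(xyz["CG"], xyz["CB"], xyz["CA"], 1.525, 111.0, -63.0)
    xyz["O"] = _place(xyz["CB"], xyz["CA"], xyz["C"], 1.229, 120.5, 0.0)
    xyz["HA"] = _place(xyz["CG"], xyz["CB"], xyz["CA"], 1.090, 109.0, 58.0)
    xyz["HB2"] = _place(xyz["CA"], xyz["CG"], xyz["CB"], 1.090, 109.5, 120.0)
    xyz["HB3"] = _place(xyz["CA"], xyz["CG"], xyz["CB"], 1.090, 109.5, -120.0)
    classes = {"N": "N", "H": "H", "CA": "CT", "HA": "H1", "CB": "CT",
               "HB2": "HC", "HB3": "HC", "C": "C", "O": "O",
               "CG": "CA", "CD1": "CA", "CD2": "CA", "CE1": "CA",
               "CE2": "CA", "CZ": "CA",
               "HD1": "HA", "HD2": "HA", "HE1": "HA", "HE2": "HA", "HZ": "HA"}
    return ResidueTemplate(
        "PHE",
        tuple(TemplateAtom(n, classes[n], tuple(map(float, xyz[n])))
              for n in classes),
    )


def place_complex(d: float) -> Tuple[np.ndarray, np.ndarray]:
    """PHE fixed (centroid at origin, ring in xy), ALA N at (0, 0, d), H below.

    Returns (ala_coords, phe_coords) in one frame.
    """
    if not d > 0:
        raise ValueError("separation d must be positive")
    ala = ala_template().coords() + np.array([0.0, 0.0, d])
    phe = phe_template().coords()
    return ala, phe


def lj_pair_energy(r: float, p1: LJAtomParams, p2: LJAtomParams) -> float:
    """12-6 energy eps_ij [(Rmin_ij/r)^12 - 2 (Rmin_ij/r)^6] in kcal/mol."""
    if not r > 0:
        raise ValueError("pair distance must be positive")
    eps = math.sqrt(p1.epsilon * p2.epsilon)
    x = (p1.rmin_half + p2.rmin_half) / r
    x6 = x**6
    return eps * (x6 * x6 - 2.0 * x6)


def _lj_matrix(
    t1: ResidueTemplate, t2: ResidueTemplate
) -> Tuple[np.ndarray, np.ndarray]:
    eps1 = np.array([p.epsilon for p in t1.params()])
    eps2 = np.array([p.epsilon for p in t2.params()])
    rm1 = np.array([p.rmin_half for p in t1.params()])
    rm2 = np.array([p.rmin_half for p in t2.params()])
    return np.sqrt(np.outer(eps1, eps2)), rm1[:, None] + rm2[None, :]


def interaction_energy(d: float) -> float:
    """Inter-residue 12-6 sum at N-to-centroid separation d (kcal/mol).

    Identical to subtracting the isolated-residue energies from the
    complex energy, since intra-residue terms cancel for rigid templates.
    """
    ala, phe = place_complex(d)
    eps, rmin = _lj_matrix(ala_template(), phe_template())
    r = np.linalg.norm(ala[:, None, :] - phe[None, :, :], axis=2)
    x6 = (rmin / r) ** 6
    return float(np.sum(eps * (x6 * x6 - 2.0 * x6)))


@dataclass
class ScanResult:
    table: pd.DataFrame          # columns d_A, dE_kcal_mol
    d_min_A: float               # grid location of the energy minimum
    e_min_kcal_mol: float


def scan(d_min: float = 2.5, d_max: float = 8.0, step: float = 0.01) -> ScanResult:
    """Scan the approach distance on an inclusive grid and locate the minimum."""
    if not (0 < d_min <= d_max) or not step > 0:
        raise ValueError("require 0 < d_min <= d_max and step > 0")
    n = int(round((d_max - d_min) / step)) + 1
    grid = d_min + step * np.arange(n)
    ala0 = ala_template().coords()
    phe = phe_template().coords()
    eps, rmin = _lj_matrix(ala_template(), phe_template())
    energies = np.empty(n)
    for i, d in enumerate(grid):
        ala = ala0 + np.array([0.0, 0.0, d])
        r = np.linalg.norm(ala[:, None, :] - phe[None, :, :], axis=2)
        x6 = (rmin / r) ** 6
        energies[i] = np.sum(eps * (x6 * x6 - 2.0 * x6))
    imin = int(np.argmin(energies))
    table = pd.DataFrame({"d_A": grid, "dE_kcal_mol": energies})
    return ScanResult(table, float(grid[imin]), float(energies[imin]))
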