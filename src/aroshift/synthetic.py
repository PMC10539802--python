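"""Synthetic structure/shift/restraint generation with known ground truth.

The generator emits the three inputs the pipeline consumes — a multi-model
mmCIF ensemble, an NMR-STAR chemical-shift list, and an NMR-STAR distance
restraint list — for a fictitious single-chain protein in which selected
amide protons are planted at exact (r, theta) geometries relative to
aromatic rings.  Shifts are the per-residue reference mean plus the
dipole ring-current perturbation at the planted geometry plus Gaussian
noise; restraints mirror NOE observability (emitted iff an amide-H to
ring-H distance falls below a cutoff).

Structures are geometric scaffolds, not folded proteins: rings are ideal
planar polygons, backbones are minimal N/H/CA/C/O sets, and the only
steric guarantee is a clash check at 1.5 A.  Everything is a deterministic
function of the spec, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np
import pandas as pd

from .geometry import (
    RING_ATOMS,
    AmideRingGeometry,
    AromaticRing,
    EntryMeta,
    ModelResidue,
    PolymerInfo,
    StructureEnsemble,
    StructureModel,
)
from .nmrstar import write_restraints_star, write_shifts_star
from .reference_stats import AmideShiftRecord, ReferenceStats
from .restraints import RING_H_NAMES, RestraintRecord, Member
from .ring_current import RingCurrentParams, geometric_factor

CHAIN_ID = "A"
CLASH_DISTANCE_A = 1.5

#: Residue types cycled through for non-aromatic positions.
_FILLER_TYPES = ("ALA", "GLY", "ASP", "LEU", "SER", "VAL", "LYS", "THR")


class GenerationError(ValueError):
    """Geometrically unrealizable synthetic request."""


@dataclass(frozen=True)
class AmideTarget:
    """Plant an amide proton at (r, theta) relative to the ring of a residue."""

    ring_seq_id: int
    r_A: float
    theta_deg: float
    ring_label: Optional[str] = None  # Trp only; default "five"


@dataclass
class SyntheticSpec:
    """Full description of one synthetic entry.

    ``amide_geometries`` maps seq_id to an :class:`AmideTarget` or the
    string ``"far"``; unlisted residues default to "far" (placed >= 100 A
    from every ring).  ``n_models`` jittered copies of the exact scaffold
    form the ensemble.  The seed fully determines every output byte.
    """

    n_residues: int = 40
    aromatic_positions: Dict[int, str] = field(default_factory=dict)
    amide_geometries: Dict[int, Union[AmideTarget, str]] = field(default_factory=dict)
    n_models: int = 20
    coordinate_jitter_A: float = 0.2
    shift_noise_ppm: float = 0.3
    ring_current_params: RingCurrentParams = field(default_factory=RingCurrentParams)
    noe_cutoff_A: float = 5.0
    noe_margin_A: float = 0.5
    seed: int = 0
    entry_id: str = "SYN1"

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise GenerationError("n_models must be >= 1")
        if self.coordinate_jitter_A < 0 or self.shift_noise_ppm < 0:
            raise GenerationError("jitter and noise must be non-negative")
        for seq, rtype in self.aromatic_positions.items():
            if rtype not in ("PHE", "TYR", "TRP", "HIS"):
                raise GenerationError(f"residue {seq}: {rtype} is not aromatic")
        for seq, target in self.amide_geometries.items():
            if isinstance(target, str):
                if target != "far":
                    raise GenerationError(f"residue {seq}: unknown target {target!r}")
                continue
            if target.ring_seq_id not in self.aromatic_positions:
                raise GenerationError(
                    f"residue {seq}: target ring {target.ring_seq_id} is not aromatic"
                )
            if target.r_A < CLASH_DISTANCE_A:
                raise GenerationError(
                    f"residue {seq}: target r={target.r_A} A places the amide "
                    "inside the ring"
                )
            if not (0.0 <= target.theta_deg <= 90.0):
                raise GenerationError(f"residue {seq}: theta must be in [0, 90]")


# ---------------------------------------------------------------------------
# ideal planar ring layouts (local frame: ring centre at origin, normal +z)


def _polygon(names: Sequence[str], radius: float) -> Dict[str, np.ndarray]:
    n = len(names)
    return {
        name: radius * np.array([
            math.cos(2 * math.pi * i / n), math.sin(2 * math.pi * i / n), 0.0
        ])
        for i, name in enumerate(names)
    }


def _with_ring_h(
    atoms: Dict[str, np.ndarray], h_for: Mapping[str, str], bond: float = 1.08
) -> Dict[str, np.ndarray]:
    out = dict(atoms)
    center = np.mean([atoms[n] for n in atoms], axis=0)
    for heavy, hname in h_for.items():
        v = atoms[heavy] - center
        out[hname] = atoms[heavy] + bond * v / np.linalg.norm(v)
    return out


def _sidechain_layout(residue_type: str) -> Dict[str, np.ndarray]:
    """Planar ring atoms (plus ring H) in the local ring frame."""
    if residue_type in ("PHE", "TYR"):
        ring = _polygon(("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), 1.40)
        h_for = {"CD1": "HD1", "CE1": "HE1", "CE2": "HE2", "CD2": "HD2"}
        if residue_type == "PHE":
            h_for["CZ"] = "HZ"
        return _with_ring_h(ring, h_for)
    if residue_type == "HIS":
        ring = _polygon(("CG", "ND1", "CE1", "NE2", "CD2"), 1.19)
        return _with_ring_h(
            ring, {"ND1": "HD1", "CE1": "HE1", "NE2": "HE2", "CD2": "HD2"}
        )
    if residue_type == "TRP":
        five = _polygon(("CG", "CD1", "NE1", "CE2", "CD2"), 1.19)
        # fuse the six-membered ring on the CD2-CE2 edge, on the far side;
        # pentagon side (2 * 1.19 * sin 36 = 1.40) equals the hexagon side,
        # so CD2/CE2 are exact vertices of both rings
        edge_mid = 0.5 * (five["CD2"] + five["CE2"])
        out_dir = edge_mid / np.linalg.norm(edge_mid)
        hex_center = edge_mid + out_dir * 1.40 * math.sqrt(3) / 2
        atoms = dict(five)
        ref = five["CD2"] - hex_center
        ang0 = math.atan2(ref[1], ref[0])
        step = -1.0 if np.cross(ref, five["CE2"] - hex_center)[2] > 0 else 1.0
        hex_names = ("CD2", "CE3", "CZ3", "CH2", "CZ2", "CE2")
        for i, name in enumerate(hex_names[1:-1], start=1):
            ang = ang0 + step * 2 * math.pi * i / 6
            atoms[name] = hex_center + 1.40 * np.array(
                [math.cos(ang), math.sin(ang), 0.0]
            )
        center5 = np.mean([five[n] for n in five], axis=0)
        for heavy, hname in (("CD1", "HD1"), ("NE1", "HE1")):
            v = atoms[heavy] - center5
            atoms[hname] = atoms[heavy] + 1.08 * v / np.linalg.norm(v)
        for heavy, hname in (("CE3", "HE3"), ("CZ3", "HZ3"),
                             ("CH2", "HH2"), ("CZ2", "HZ2")):
            v = atoms[heavy] - hex_center
            atoms[hname] = atoms[heavy] + 1.08 * v / np.linalg.norm(v)
        return atoms
    raise GenerationError(f"no ring layout for {residue_type}")


# ---------------------------------------------------------------------------
# scaffold construction


def _ring_center_local(residue_type: str, ring_label: str) -> np.ndarray:
    """Centroid of the labelled ring in the sidechain's local frame."""
    layout = _sidechain_layout(residue_type)
    names = RING_ATOMS[(residue_type, ring_label)]
    return np.mean([layout[n] for n in names], axis=0)


def _default_label(residue_type: str) -> str:
    return "five" if residue_type in ("TRP", "HIS") else "six"


def _residue_type_plan(spec: SyntheticSpec) -> Dict[int, str]:
    plan: Dict[int, str] = {}
    filler = 0
    for seq in range(1, spec.n_residues + 1):
        if seq in spec.aromatic_positions:
            plan[seq] = spec.aromatic_positions[seq]
        else:
            plan[seq] = _FILLER_TYPES[filler % len(_FILLER_TYPES)]
            filler += 1
    return plan


def _backbone(
    anchor: np.ndarray,
    direction: np.ndarray,
    tangent: Optional[np.ndarray] = None,
) -> Dict[str, np.ndarray]:
    """Minimal N/H/CA/C/O set: N at anchor, H opposite ``direction``.

    The rest of the residue extends mostly along ``direction`` (away from
    whatever the amide is pointing at) with a small lateral offset along
    ``tangent``, so residues planted on the same ring fan apart.
    """
    d = direction / np.linalg.norm(direction)
    if tangent is None:
        t = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(t) < 1e-6:
            t = np.cross(d, [1.0, 0.0, 0.0])
    else:
        t = tangent - np.dot(tangent, d) * d
    t = t / np.linalg.norm(t)
    n = anchor
    ca = n + 1.458 * (math.sqrt(0.75) * d + 0.5 * t)
    c = ca + 1.525 * d
    return {"N": n, "H": n - 1.01 * d, "CA": ca, "C": c, "O": c + 1.229 * t}


def build_base_model(spec: SyntheticSpec) -> StructureModel:
    """The exact (jitter-free) scaffold realizing every planted geometry."""
    plan = _residue_type_plan(spec)
    ring_centers: Dict[int, np.ndarray] = {}
    residues: Dict[Tuple[str, int], ModelResidue] = {}

    aromatic_seqs = sorted(spec.aromatic_positions)
    for k, seq in enumerate(aromatic_seqs):
        ring_centers[seq] = np.array([40.0 * k, 0.0, 0.0])

    per_ring_count: Dict[int, int] = {seq: 0 for seq in aromatic_seqs}
    far_count = 0
    for seq in range(1, spec.n_residues + 1):
        rtype = plan[seq]
        atoms: Dict[str, np.ndarray] = {}
        if seq in spec.aromatic_positions:
            center = ring_centers[seq]
            for name, xyz in _sidechain_layout(rtype).items():
                atoms[name] = center + xyz
            # backbone parked well below/behind its own ring
            atoms.update(_backbone(center + np.array([0.0, -12.0, -3.0]),
                                   np.array([0.0, -1.0, 0.0])))
        else:
            target = spec.amide_geometries.get(seq, "far")
            if isinstance(target, AmideTarget):
                ring_type = spec.aromatic_positions[target.ring_seq_id]
                label = target.ring_label or _default_label(ring_type)
                center = ring_centers[target.ring_seq_id] + _ring_center_local(
                    ring_type, label
                )
                j = per_ring_count[target.ring_seq_id]
                per_ring_count[target.ring_seq_id] += 1
                phi = math.radians((j * 137.5) % 360.0)
                theta = math.radians(target.theta_deg)
                direction = np.array([
                    math.sin(theta) * math.cos(phi),
                    math.sin(theta) * math.sin(phi),
                    math.cos(theta),
                ])
                h = center + target.r_A * direction
                e_phi = np.array([-math.sin(phi), math.cos(phi), 0.0])
                atoms.update(_backbone(h + 1.01 * direction, direction, e_phi))
            else:
                anchor = np.array([6.0 * far_count, 150.0, 0.0])
                far_count += 1
                atoms.update(_backbone(anchor, np.array([0.0, 1.0, 0.0])))
        residues[(CHAIN_ID, seq)] = ModelResidue(CHAIN_ID, seq, rtype, atoms)

    _check_clashes(residues)
    return StructureModel(residues)


def _check_clashes(residues: Mapping[Tuple[str, int], ModelResidue]) -> None:
    keys = list(residues)
    coords = [np.vstack(list(residues[k].atoms.values())) for k in keys]
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            # cheap reject on bounding distance
            ci, cj = coords[i], coords[j]
            if np.linalg.norm(ci.mean(axis=0) - cj.mean(axis=0)) > 30.0:
                continue
            d = np.linalg.norm(ci[:, None, :] - cj[None, :, :], axis=2)
            if d.min() < CLASH_DISTANCE_A:
                raise GenerationError(
                    f"steric clash ({d.min():.2f} A) between residues "
                    f"{keys[i][1]} and {keys[j][1]}"
                )


def _jitter_model(
    base: StructureModel, sd: float, rng: np.random.Generator
) -> StructureModel:
    residues: Dict[Tuple[str, int], ModelResidue] = {}
    for key, res in base.residues.items():
        atoms = {
            name: xyz + rng.normal(0.0, sd, size=3) if sd > 0 else xyz.copy()
            for name, xyz in res.atoms.items()
        }
        residues[key] = ModelResidue(res.chain, res.seq_id, res.residue_type, atoms)
    return StructureModel(residues)


def _meta_for(spec: SyntheticSpec) -> EntryMeta:
    plan = _residue_type_plan(spec)
    return EntryMeta(
        entry_id=spec.entry_id,
        polymers=[PolymerInfo(
            polymer_type="polypeptide",
            sequence=tuple(plan[s] for s in sorted(plan)),
            chains=(CHAIN_ID,),
        )],
        nonpolymer_names=[],
    )


def generate_ensemble(spec: SyntheticSpec) -> StructureEnsemble:
    """``n_models`` jittered copies of the exact scaffold."""
    base = build_base_model(spec)
    rng = np.random.default_rng([spec.seed % 2**31, 0])
    models = [
        _jitter_model(base, spec.coordinate_jitter_A, rng)
        for _ in range(spec.n_models)
    ]
    return StructureEnsemble(entry_id=spec.entry_id, models=models,
                             meta=_meta_for(spec))


_ELEMENTS = {"N": "N", "O": "O", "C": "C", "H": "H", "S": "S"}


def write_ensemble_cif(
    ensemble: StructureEnsemble, path: Union[str, Path]
) -> None:
    """Write the ensemble as a multi-model mmCIF file (via gemmi)."""
    st = gemmi.Structure()
    st.name = ensemble.entry_id
    for i, model in enumerate(ensemble.models, start=1):
        gm = gemmi.Model(i)
        chains: Dict[str, gemmi.Chain] = {}
        for key in sorted(model.residues, key=lambda k: (k[0], k[1])):
            res = model.residues[key]
            chain = chains.get(res.chain)
            if chain is None:
                chain = gemmi.Chain(res.chain)
                chains[res.chain] = chain
            gr = gemmi.Residue()
            gr.name = res.residue_type
            gr.seqid = gemmi.SeqId(res.seq_id, " ")
            for name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(_ELEMENTS.get(name[0], "C"))
                atom.pos = gemmi.Position(*xyz)
                gr.add_atom(atom)
            chain.add_residue(gr)
        for chain in chains.values():
            gm.add_chain(chain)
        st.add_model(gm)
    st.setup_entities()
    st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# ground-truth geometry and shifts


def planted_geometry(spec: SyntheticSpec, seq_id: int) -> Optional[AmideRingGeometry]:
    """The exact planted (r, theta) for a targeted amide; None otherwise."""
    target = spec.amide_geometries.get(seq_id)
    if not isinstance(target, AmideTarget):
        return None
    rtype = _residue_type_plan(spec)[seq_id]
    ring_type = spec.aromatic_positions[target.ring_seq_id]
    label = target.ring_label or _default_label(ring_type)
    ring = AromaticRing(CHAIN_ID, target.ring_seq_id, ring_type, label)
    return AmideRingGeometry(
        CHAIN_ID, seq_id, rtype, ring=ring,
        distance_A=target.r_A, azimuth_deg=target.theta_deg,
    )


def planted_perturbation(spec: SyntheticSpec, seq_id: int) -> float:
    """Ring-current perturbation (ppm) planted at a residue's amide."""
    geom = planted_geometry(spec, seq_id)
    if geom is None:
        return 0.0
    assert geom.ring is not None
    const = spec.ring_current_params.constant_for(
        geom.ring.residue_type, geom.ring.ring_label
    )
    return const * geometric_factor(geom.distance_A, geom.azimuth_deg)


def generate_shifts(
    spec: SyntheticSpec, stats: ReferenceStats
) -> List[AmideShiftRecord]:
    """Shift = residue mean + planted dipole perturbation + Gaussian noise."""
    plan = _residue_type_plan(spec)
    rng = np.random.default_rng([spec.seed % 2**31, 1])
    records: List[AmideShiftRecord] = []
    for seq in range(1, spec.n_residues + 1):
        rtype = plan[seq]
        if rtype not in stats:
            continue
        mean = stats.for_residue(rtype).mean_ppm
        noise = rng.normal(0.0, spec.shift_noise_ppm) if spec.shift_noise_ppm > 0 else 0.0
        records.append(AmideShiftRecord(
            entry_id=spec.entry_id, chain_id=CHAIN_ID, seq_id=seq,
            residue_type=rtype,
            shift_ppm=mean + planted_perturbation(spec, seq) + noise,
        ))
    return records


def generate_restraints(spec: SyntheticSpec) -> List[RestraintRecord]:
    """NOE-style restraints for every close amide-H / ring-H contact.

    Uses jitter-free distances: a restraint is emitted iff the scaffold
    amide H sits within ``noe_cutoff_A`` of a ring proton on a different
    residue, with upper bound distance + ``noe_margin_A`` and lower 1.8 A.
    """
    base = build_base_model(spec)
    records: List[RestraintRecord] = []
    rid = 0
    for key in sorted(base.residues):
        res = base.residues[key]
        h = res.atoms.get("H")
        if h is None:
            continue
        for rkey in sorted(base.residues):
            ring_res = base.residues[rkey]
            if rkey == key or ring_res.residue_type not in RING_H_NAMES:
                continue
            for hname in sorted(RING_H_NAMES[ring_res.residue_type]):
                xyz = ring_res.atoms.get(hname)
                if xyz is None:
                    continue
                dist = float(np.linalg.norm(h - xyz))
                if dist < spec.noe_cutoff_A:
                    rid += 1
                    records.append(RestraintRecord(
                        restraint_id=rid,
                        members=[
                            Member(res.chain, res.seq_id, res.residue_type, "H"),
                            Member(ring_res.chain, ring_res.seq_id,
                                   ring_res.residue_type, hname),
                        ],
                        lower_A=1.8,
                        upper_A=dist + spec.noe_margin_A,
                        origin="NOE",
                    ))
    return records


def write_restraints(
    records: Sequence[RestraintRecord], path: Union[str, Path], entry_id: str
) -> None:
    rows = []
    for rec in records:
        m1, m2 = rec.members[0], rec.members[1]
        rows.append({
            "id": rec.restraint_id,
            "chain_1": m1.chain, "seq_1": m1.seq_id, "comp_1": m1.residue_type,
            "atom_1": m1.atom_name,
            "chain_2": m2.chain, "seq_2": m2.seq_id, "comp_2": m2.residue_type,
            "atom_2": m2.atom_name,
            "lower": rec.lower_A, "upper": rec.upper_A,
        })
    write_restraints_star(rows, path, entry_id)


def truth_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Planted ground truth per residue: target ring, r, theta, perturbation."""
    plan = _residue_type_plan(spec)
    rows = []
    for seq in range(1, spec.n_residues + 1):
        geom = planted_geometry(spec, seq)
        rows.append({
            "seq_id": seq,
            "residue_type": plan[seq],
            "ring_seq_id": geom.ring.seq_id if geom else pd.NA,
            "ring_label": geom.ring.ring_label if geom else "",
            "r_A": geom.distance_A if geom else np.nan,
            "theta_deg": geom.azimuth_deg if geom else np.nan,
            "perturbation_ppm": planted_perturbation(spec, seq),
        })
    df = pd.DataFrame(rows)
    df["ring_seq_id"] = df["ring_seq_id"].astype("Int64")
    return df


def write_entry(spec: SyntheticSpec, out_dir: Union[str, Path],
                stats: Optional[ReferenceStats] = None) -> Dict[str, Path]:
    """Emit structure.cif, shifts.str, restraints.str, truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats = stats or ReferenceStats.default()
    paths = {
        "structure": out / "structure.cif",
        "shifts": out / "shifts.str",
        "restraints": out / "restraints.str",
        "truth": out / "truth.csv",
    }
    write_ensemble_cif(generate_ensemble(spec), paths["structure"])
    write_shifts_star(generate_shifts(spec, stats), paths["shifts"], spec.entry_id)
    write_restraints(generate_restraints(spec), paths["restraints"], spec.entry_id)
    truth_table(spec).to_csv(paths["truth"], index=False)
    return paths
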