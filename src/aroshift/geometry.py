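"""Amide-to-aromatic-ring geometry from multi-model structure ensembles.

Parses mmCIF coordinate files (via gemmi), locates aromatic rings
(Phe/Tyr/His and both rings of Trp), and computes, for each backbone amide
proton, the distance to the centre of its nearest ring and the azimuth
angle between the ring normal and the proton-to-centre vector.  Both
quantities are averaged over the members of the deposited ensemble.

The azimuth is folded to [0, 90] degrees so that the arbitrary sign of the
ring normal (a cross product of two in-plane vectors) cannot influence any
downstream statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import gemmi
import numpy as np

from .reference_stats import AMIDE_H_NAMES

logger = logging.getLogger("aroshift")

ResidueKey = Tuple[str, int]  # (auth chain id, auth seq id)

AROMATIC_TYPES = frozenset({"PHE", "TYR", "TRP", "HIS"})

#: Ordered ring-atom names per (residue type, ring label).  Trp contributes
#: two fused rings that are scored as independent candidates.
RING_ATOMS: Dict[Tuple[str, str], Tuple[str, ...]] = {
    ("PHE", "six"): ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    ("TYR", "six"): ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    ("HIS", "five"): ("CG", "ND1", "CD2", "CE1", "NE2"),
    ("TRP", "five"): ("CG", "CD1", "CD2", "NE1", "CE2"),
    ("TRP", "six"): ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}

N_H_BOND_A = 1.01  # amide N-H bond length used for H reconstruction


class StructureFormatError(ValueError):
    """Input file lacks the categories needed for parsing."""


class EnsembleConsistencyError(ValueError):
    """Models of one ensemble do not share an atom identity set."""


class GeometryError(ValueError):
    """A geometric computation is impossible on the given coordinates."""


@dataclass
class ModelResidue:
    chain: str
    seq_id: int
    residue_type: str
    atoms: Dict[str, np.ndarray]


@dataclass
class StructureModel:
    """One coordinate set: residues keyed by (chain, seq_id), in file order."""

    residues: Dict[ResidueKey, ModelResidue]

    def identity_set(self) -> frozenset:
        return frozenset(
            (key, res.residue_type, name)
            for key, res in self.residues.items()
            for name in res.atoms
        )


@dataclass
class PolymerInfo:
    polymer_type: str        # "polypeptide" | "nucleic_acid" | "other"
    sequence: Tuple[str, ...]
    chains: Tuple[str, ...]  # auth chain ids carrying this entity


@dataclass
class EntryMeta:
    """Composition metadata used for entry-eligibility filtering."""

    entry_id: str
    polymers: List[PolymerInfo] = field(default_factory=list)
    nonpolymer_names: List[str] = field(default_factory=list)  # waters excluded
    parsed: bool = True


@dataclass
class StructureEnsemble:
    entry_id: str
    models: List[StructureModel]
    meta: EntryMeta

    def __post_init__(self) -> None:
        if not self.models:
            raise EnsembleConsistencyError(f"{self.entry_id}: ensemble has no models")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residue_types(self) -> Dict[ResidueKey, str]:
        return {
            key: res.residue_type for key, res in self.models[0].residues.items()
        }

    def chains(self) -> Tuple[str, ...]:
        seen: Dict[str, None] = {}
        for key in self.models[0].residues:
            seen.setdefault(key[0])
        return tuple(seen)


@dataclass(frozen=True)
class AromaticRing:
    """One aromatic ring identified by residue and ring label."""

    chain: str
    seq_id: int
    residue_type: str
    ring_label: str

    @property
    def atom_names(self) -> Tuple[str, ...]:
        return RING_ATOMS[(self.residue_type, self.ring_label)]

    def sort_key(self) -> Tuple[str, int, str]:
        return (self.chain, self.seq_id, self.ring_label)


@dataclass(frozen=True)
class AmideRingGeometry:
    """Ensemble-averaged link from an amide proton to its nearest ring.

    ``ring is None`` is the explicit "no aromatic ring in the structure"
    sentinel; the distance and azimuth are then ``None`` as well.
    """

    amide_chain: str
    amide_seq_id: int
    amide_residue_type: str
    ring: Optional[AromaticRing]
    distance_A: Optional[float]
    azimuth_deg: Optional[float]

    @property
    def has_ring(self) -> bool:
        return self.ring is not None


# ---------------------------------------------------------------------------
# parsing

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


def _classify_polymer(ptype: gemmi.PolymerType) -> str:
    PT = gemmi.PolymerType
    if ptype in (PT.PeptideL, PT.PeptideD):
        return "polypeptide"
    if ptype in (PT.Dna, PT.Rna, PT.DnaRnaHybrid, PT.Pna):
        return "nucleic_acid"
    return "other"


def _extract_meta(st: gemmi.Structure) -> EntryMeta:
    meta = EntryMeta(entry_id=st.name or "")
    try:
        if not st.entities:
            st.setup_entities()
        if not st.entities:
            meta.parsed = False
            return meta
        model0 = st[0]
        sub_to_chain: Dict[str, str] = {}
        sub_to_seq: Dict[str, Tuple[str, ...]] = {}
        for chain in model0:
            for span in chain.subchains():
                sid = span.subchain_id()
                sub_to_chain[sid] = chain.name
                sub_to_seq[sid] = tuple(r.name for r in span)
        for ent in st.entities:
            if ent.entity_type == gemmi.EntityType.Water:
                continue
            subs = [s for s in ent.subchains if s in sub_to_chain]
            if ent.entity_type == gemmi.EntityType.Polymer:
                seq = sub_to_seq.get(subs[0], ()) if subs else ()
                meta.polymers.append(
                    PolymerInfo(
                        polymer_type=_classify_polymer(ent.polymer_type),
                        sequence=seq,
                        chains=tuple(sub_to_chain[s] for s in subs),
                    )
                )
            else:
                for s in subs:
                    for name in sub_to_seq.get(s, ()):
                        if name not in _WATER_NAMES:
                            meta.nonpolymer_names.append(name)
    except Exception:  # metadata failure must not kill coordinate parsing
        meta.parsed = False
    return meta


def parse_structure(path: Union[str, Path]) -> StructureEnsemble:
    """Read a (possibly multi-model) mmCIF file into a :class:`StructureEnsemble`.

    Author-assigned chain ids and sequence numbers are retained so the
    ensemble can be joined with chemical-shift files.  All models must share
    one atom identity set.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0 or all(len(m) == 0 for m in st):
        raise StructureFormatError(f"{path}: no atom_site records found")
    meta = _extract_meta(st)
    models: List[StructureModel] = []
    for model in st:
        residues: Dict[ResidueKey, ModelResidue] = {}
        for chain in model:
            for res in chain:
                key = (chain.name, res.seqid.num)
                mr = residues.get(key)
                if mr is None:
                    mr = ModelResidue(chain.name, res.seqid.num, res.name, {})
                    residues[key] = mr
                for atom in res:
                    if atom.name not in mr.atoms:  # first altloc wins
                        mr.atoms[atom.name] = np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                        )
        models.append(StructureModel(residues))
    ref = models[0].identity_set()
    for i, model in enumerate(models[1:], start=2):
        ident = model.identity_set()
        if ident != ref:
            diff = sorted(ref.symmetric_difference(ident))[0]
            raise EnsembleConsistencyError(
                f"{path}: model {i} atom set differs from model 1 "
                f"(first mismatch: {diff})"
            )
    entry_id = st.name or Path(path).stem
    meta.entry_id = entry_id
    return StructureEnsemble(entry_id=entry_id, models=models, meta=meta)


# ---------------------------------------------------------------------------
# per-model geometry


def find_rings(ensemble: StructureEnsemble) -> List[AromaticRing]:
    """All aromatic rings whose atoms are complete in every model."""
    rings: List[AromaticRing] = []
    rtypes = ensemble.residue_types()
    for key, rtype in rtypes.items():
        if rtype not in AROMATIC_TYPES:
            continue
        for (rt, label), names in RING_ATOMS.items():
            if rt != rtype:
                continue
            complete = all(
                all(n in m.residues[key].atoms for n in names)
                for m in ensemble.models
            )
            if complete:
                rings.append(AromaticRing(key[0], key[1], rtype, label))
            else:
                logger.warning(
                    "%s: incomplete %s ring at %s %s%d, skipped",
                    ensemble.entry_id, label, rtype, key[0], key[1],
                )
    rings.sort(key=AromaticRing.sort_key)
    return rings


def _ring_coords(ring: AromaticRing, model: StructureModel) -> np.ndarray:
    res = model.residues.get((ring.chain, ring.seq_id))
    if res is None:
        raise GeometryError(
            f"residue {ring.chain}{ring.seq_id} absent from model"
        )
    coords = []
    for name in ring.atom_names:
        if name not in res.atoms:
            raise GeometryError(
                f"ring atom {name} missing on {ring.residue_type} "
                f"{ring.chain}{ring.seq_id}"
            )
        coords.append(res.atoms[name])
    return np.vstack(coords)


def ring_center(ring: AromaticRing, model: StructureModel) -> np.ndarray:
    """Arithmetic mean of the ring-atom coordinates (Angstrom)."""
    return _ring_coords(ring, model).mean(axis=0)


def ring_normal(ring: AromaticRing, model: StructureModel) -> np.ndarray:
    """Unit normal of the ring plane.

    Cross product of the centre-to-first-atom and centre-to-second-atom
    vectors; the sign is arbitrary and must not carry meaning downstream.
    """
    coords = _ring_coords(ring, model)
    center = coords.mean(axis=0)
    v1 = coords[0] - center
    v2 = coords[1] - center
    n = np.cross(v1, v2)
    norm = np.linalg.norm(n)
    if norm < 1e-9 * max(np.linalg.norm(v1) * np.linalg.norm(v2), 1e-30):
        raise GeometryError(
            f"degenerate (collinear) ring geometry on {ring.residue_type} "
            f"{ring.chain}{ring.seq_id}"
        )
    return n / norm


def amide_proton_position(
    residue: ModelResidue, model: StructureModel
) -> Optional[np.ndarray]:
    """Coordinates of the backbone amide proton, reconstructed if absent.

    Deposited H/HN/H1 atoms are returned unchanged.  Otherwise H is placed
    1.01 A from N, in the C(prev)-N-CA plane, opposing the bisector of the
    two bond directions.  Returns ``None`` (caller skips, no exception) for
    a first residue with neither a deposited H nor a preceding carbonyl C.
    """
    for name in ("H", "HN", "H1"):
        if name in residue.atoms:
            return residue.atoms[name]
    if "N" not in residue.atoms:
        raise GeometryError(
            f"backbone N missing on {residue.residue_type} "
            f"{residue.chain}{residue.seq_id}"
        )
    prev = model.residues.get((residue.chain, residue.seq_id - 1))
    if prev is None or "C" not in prev.atoms or "CA" not in residue.atoms:
        logger.warning(
            "cannot reconstruct H for %s %s%d (no preceding C); skipped",
            residue.residue_type, residue.chain, residue.seq_id,
        )
        return None
    n = residue.atoms["N"]
    u_c = prev.atoms["C"] - n
    u_ca = residue.atoms["CA"] - n
    u_c /= np.linalg.norm(u_c)
    u_ca /= np.linalg.norm(u_ca)
    bisector = u_c + u_ca
    norm = np.linalg.norm(bisector)
    if norm < 1e-9:
        raise GeometryError(
            f"degenerate C-N-CA geometry at {residue.chain}{residue.seq_id}"
        )
    return n - N_H_BOND_A * bisector / norm


def azimuth_angle(
    h_xyz: np.ndarray, center_xyz: np.ndarray, normal: np.ndarray
) -> float:
    """Angle (deg, folded to [0, 90]) between ring normal and H-to-centre vector."""
    v = np.asarray(h_xyz, dtype=float) - np.asarray(center_xyz, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise GeometryError("amide proton coincides with ring centre")
    cos_t = abs(float(np.dot(v, normal)) / norm)
    return math.degrees(math.acos(min(1.0, cos_t)))


def nearest_ring(
    amide_key: ResidueKey,
    rings: Sequence[AromaticRing],
    ensemble: StructureEnsemble,
) -> AmideRingGeometry:
    """Ensemble-mean distance/azimuth to every candidate ring; keep the nearest.

    Distance and azimuth are each averaged over models; the ring minimising
    the mean distance wins, ties broken by (chain, seq_id, ring_label).
    """
    rtype = ensemble.residue_types()[amide_key]
    h_per_model: List[np.ndarray] = []
    for model in ensemble.models:
        h = amide_proton_position(model.residues[amide_key], model)
        if h is None:
            raise GeometryError(
                f"amide proton unresolvable for {amide_key} in some model"
            )
        h_per_model.append(h)
    if not rings:
        return AmideRingGeometry(
            amide_key[0], amide_key[1], rtype, ring=None,
            distance_A=None, azimuth_deg=None,
        )
    best: Optional[Tuple[float, float, AromaticRing]] = None
    for ring in sorted(rings, key=AromaticRing.sort_key):
        dists, azims = [], []
        for h, model in zip(h_per_model, ensemble.models):
            center = ring_center(ring, model)
            normal = ring_normal(ring, model)
            dists.append(float(np.linalg.norm(h - center)))
            azims.append(azimuth_angle(h, center, normal))
        d_mean = float(np.mean(dists))
        a_mean = float(np.mean(azims))
        if best is None or d_mean < best[0]:
            best = (d_mean, a_mean, ring)
    assert best is not None
    return AmideRingGeometry(
        amide_key[0], amide_key[1], rtype,
        ring=best[2], distance_A=best[0], azimuth_deg=best[1],
    )
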