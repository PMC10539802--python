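"""Joining shifts with geometry into the survey table.

One row per assigned backbone amide proton that matches a structure
residue: its shift, Z score, ensemble-mean distance and azimuth to the
nearest aromatic ring, and the identity of that ring.  Rows in structures
without any aromatic ring carry empty ring fields (the sentinel) and are
excluded from distance-binned outputs.

Entry eligibility mirrors the survey's inclusion rules: exactly one
polypeptide entity, present as a single chain, with no non-water
non-polymer entities (reason codes: nucleic_acid, ligand, oligomer,
complex, unparseable).
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .geometry import (
    EntryMeta,
    StructureEnsemble,
    amide_proton_position,
    find_rings,
    nearest_ring,
)
from .reference_stats import AmideShiftRecord, ReferenceStats, z_score

logger = logging.getLogger("aroshift")

SURVEY_COLUMNS = [
    "entry_id", "chain", "seq_id", "residue_type", "shift_ppm", "z",
    "distance_A", "azimuth_deg",
    "ring_chain", "ring_seq_id", "ring_residue_type", "ring_label",
]

UPFIELD, DOWNFIELD, NORMAL = "upfield", "downfield", "normal"


def classify(z: float, threshold: float = 2.0) -> str:
    """Outlier class of a Z score: upfield (Z <= -t), downfield (Z >= t), normal.

    The printed class boundaries overlap at |Z| = t; the partition here is
    disjoint, with "normal" the open interval (-t, t).
    """
    if z <= -threshold:
        return UPFIELD
    if z >= threshold:
        return DOWNFIELD
    return NORMAL


def entry_is_eligible(meta: EntryMeta) -> Tuple[bool, Optional[str]]:
    """Single-chain, single-entity, ligand-free protein check.

    Returns ``(True, None)`` or ``(False, reason)`` with reason one of
    nucleic_acid | ligand | oligomer | complex | unparseable.
    """
    if not meta.parsed or not meta.polymers:
        return False, "unparseable"
    if any(p.polymer_type == "nucleic_acid" for p in meta.polymers):
        return False, "nucleic_acid"
    peptides = [p for p in meta.polymers if p.polymer_type == "polypeptide"]
    others = [p for p in meta.polymers if p.polymer_type == "other"]
    if not peptides:
        return False, "unparseable"
    if len(peptides) > 1 or others:
        sequences = {p.sequence for p in peptides}
        if len(sequences) == 1 and not others:
            return False, "oligomer"
        return False, "complex"
    if len(peptides[0].chains) > 1:
        return False, "oligomer"
    if meta.nonpolymer_names:
        return False, "ligand"
    return True, None


def _match_chain(record_chain: str, chains: Sequence[str]) -> Optional[str]:
    if record_chain in chains:
        return record_chain
    if len(chains) == 1:
        return chains[0]
    return None


def build_survey(
    shifts: Sequence[AmideShiftRecord],
    ensemble: StructureEnsemble,
    stats: ReferenceStats,
) -> pd.DataFrame:
    """Join shift records to structure residues and compute the survey table.

    Joining follows sequence number with residue-type agreement required;
    type mismatches are dropped and logged.  Amides whose proton position
    cannot be resolved in every model are skipped.
    """
    rings = find_rings(ensemble)
    rtypes = ensemble.residue_types()
    chains = ensemble.chains()
    rows: List[dict] = []
    for rec in shifts:
        chain = _match_chain(rec.chain_id, chains)
        key = (chain, rec.seq_id) if chain is not None else None
        if key is None or key not in rtypes:
            logger.warning(
                "%s: shift for %s %s%d has no structure residue; dropped",
                rec.entry_id, rec.residue_type, rec.chain_id, rec.seq_id,
            )
            continue
        if rtypes[key] != rec.residue_type:
            logger.warning(
                "%s: residue type mismatch at %s%d (shift %s vs structure %s); dropped",
                rec.entry_id, key[0], key[1], rec.residue_type, rtypes[key],
            )
            continue
        h0 = amide_proton_position(
            ensemble.models[0].residues[key], ensemble.models[0]
        )
        if h0 is None:
            continue
        geom = nearest_ring(key, rings, ensemble)
        z = z_score(rec.shift_ppm, stats.for_residue(rec.residue_type))
        rows.append({
            "entry_id": rec.entry_id,
            "chain": key[0],
            "seq_id": key[1],
            "residue_type": rec.residue_type,
            "shift_ppm": rec.shift_ppm,
            "z": z,
            "distance_A": geom.distance_A if geom.has_ring else np.nan,
            "azimuth_deg": geom.azimuth_deg if geom.has_ring else np.nan,
            "ring_chain": geom.ring.chain if geom.has_ring else "",
            "ring_seq_id": geom.ring.seq_id if geom.has_ring else pd.NA,
            "ring_residue_type": geom.ring.residue_type if geom.has_ring else "",
            "ring_label": geom.ring.ring_label if geom.has_ring else "",
        })
    if not rows:
        logger.warning("%s: no shift records joined to the structure",
                       ensemble.entry_id)
        return pd.DataFrame(columns=SURVEY_COLUMNS)
    df = pd.DataFrame(rows, columns=SURVEY_COLUMNS)
    df["ring_seq_id"] = df["ring_seq_id"].astype("Int64")
    return df


def survey_to_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def survey_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"entry_id": str, "chain": str, "ring_chain": str,
               "ring_residue_type": str, "ring_label": str},
        keep_default_na=False,
        na_values=[""],
    )
    df["ring_seq_id"] = df["ring_seq_id"].astype("Int64")
    for col in ("ring_chain", "ring_residue_type", "ring_label"):
        df[col] = df[col].fillna("")
    return df[SURVEY_COLUMNS]


def azimuth_distribution(
    df: pd.DataFrame,
    z_cut: float = 3.0,
    d_max: float = 8.0,
    bin_width_deg: float = 10.0,
) -> Dict[Tuple[str, str], np.ndarray]:
    """Azimuth histograms of shift outliers near rings.

    Rows with |Z| > ``z_cut`` and distance < ``d_max`` are split by the
    sign of Z (upfield/downfield) and by the nearest ring's residue type,
    then binned over [0, 90] degrees.  Returns ``{(ring_type, side):
    counts}``; bin edges are ``np.arange(0, 90 + w, w)``.
    """
    edges = np.arange(0.0, 90.0 + bin_width_deg, bin_width_deg)
    sel = df[
        (df["z"].abs() > z_cut)
        & df["distance_A"].notna()
        & (df["distance_A"] < d_max)
    ]
    out: Dict[Tuple[str, str], np.ndarray] = {}
    for ring_type in ("PHE", "TYR", "TRP", "HIS"):
        for side, mask in ((UPFIELD, sel["z"] < 0), (DOWNFIELD, sel["z"] > 0)):
            sub = sel[(sel["ring_residue_type"] == ring_type) & mask]
            counts, _ = np.histogram(sub["azimuth_deg"].to_numpy(), bins=edges)
            out[(ring_type, side)] = counts
    return out


def shift_vs_distance_table(
    df: pd.DataFrame, d_max: Optional[float] = None
) -> Dict[str, pd.DataFrame]:
    """(distance, Z) pairs per nearest-ring residue type.

    Sentinel rows (no ring) are excluded; ``d_max`` (e.g. 8 A) restricts to
    close approaches.
    """
    sel = df[df["distance_A"].notna()]
    if d_max is not None:
        sel = sel[sel["distance_A"] < d_max]
    out: Dict[str, pd.DataFrame] = {}
    for ring_type, grp in sel.groupby("ring_residue_type"):
        out[str(ring_type)] = grp[["distance_A", "z"]].reset_index(drop=True)
    return out
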