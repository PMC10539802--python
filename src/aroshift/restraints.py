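"""NOE distance-restraint parsing, conformity filtering, and cross-tabulation.

Restraints corroborate close amide-to-ring contacts independently of the
deposited coordinates.  Parsing keeps every member selection and both
bounds; a separate filter then discards restraints that (a) lack an upper
bound, (b) have an upper bound greater than 6 A (inconsistent with an
observable NOE), or (c) are ambiguous across more than two distinct
residues.  Surviving restraints linking a backbone amide proton to an
aromatic ring proton on a different residue are aggregated into
amide-ring pairs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .nmrstar import NULL_VALUES, Loop, parse_star_file
from .reference_stats import AMIDE_H_NAMES
from .survey import NORMAL, classify

logger = logging.getLogger("aroshift")

#: Ring-attached proton names per aromatic residue type.
RING_H_NAMES: Dict[str, FrozenSet[str]] = {
    "PHE": frozenset({"HD1", "HD2", "HE1", "HE2", "HZ"}),
    "TYR": frozenset({"HD1", "HD2", "HE1", "HE2", "HZ"}),
    "TRP": frozenset({"HD1", "HE1", "HE3", "HZ2", "HZ3", "HH2"}),
    "HIS": frozenset({"HD1", "HD2", "HE1", "HE2"}),
}

#: Pseudoatom expansions (per residue type) to ring protons.  Unknown
#: pseudoatoms cause the whole record to be skipped, never guessed.
_DEGENERATE = {
    "QD": ("HD1", "HD2"), "HD*": ("HD1", "HD2"), "HD%": ("HD1", "HD2"),
    "HD#": ("HD1", "HD2"),
    "QE": ("HE1", "HE2"), "HE*": ("HE1", "HE2"), "HE%": ("HE1", "HE2"),
    "HE#": ("HE1", "HE2"),
    "QR": ("HD1", "HD2", "HE1", "HE2", "HZ"),
}
PSEUDOATOMS: Dict[str, Dict[str, Tuple[str, ...]]] = {
    rtype: {
        pseudo: tuple(n for n in names if n in RING_H_NAMES[rtype])
        for pseudo, names in _DEGENERATE.items()
        if any(n in RING_H_NAMES[rtype] for n in names)
    }
    for rtype in RING_H_NAMES
}


class RestraintParseError(ValueError):
    """Restraint file could not be parsed; carries a coarse reason code."""

    def __init__(self, message: str, reason: str = "unparseable"):
        super().__init__(message)
        self.reason = reason


@dataclass(frozen=True)
class Member:
    """One atom selection of a restraint."""

    chain: str
    seq_id: int
    residue_type: str
    atom_name: str

    @property
    def residue(self) -> Tuple[str, int]:
        return (self.chain, self.seq_id)


@dataclass
class RestraintRecord:
    restraint_id: int
    members: List[Member]
    lower_A: Optional[float]
    upper_A: Optional[float]
    origin: str  # "NOE" or "simple"

    def distinct_residues(self) -> FrozenSet[Tuple[str, int]]:
        return frozenset(m.residue for m in self.members)


@dataclass(frozen=True)
class RestrainedPair:
    """An amide proton and an aromatic residue with >= 1 restraint between them."""

    amide_chain: str
    amide_seq_id: int
    amide_residue_type: str
    ring_chain: str
    ring_seq_id: int
    ring_residue_type: str
    n_restraints: int


def _float_or_none(value: str) -> Optional[float]:
    if value in NULL_VALUES:
        return None
    return float(value)


def _loop_members(loop: Loop, row: List[str]) -> List[Member]:
    members = []
    for suffix in ("1", "2"):
        col_seq = loop.column(f"Comp_index_ID_{suffix}")
        col_comp = loop.column(f"Comp_ID_{suffix}")
        col_atom = loop.column(f"Atom_ID_{suffix}")
        col_chain = loop.column(f"Auth_asym_ID_{suffix}")
        if col_chain is None:
            col_chain = loop.column(f"Entity_assembly_ID_{suffix}")
        if None in (col_seq, col_comp, col_atom):
            raise RestraintParseError("constraint loop missing member tags")
        chain = row[col_chain] if col_chain is not None else "."
        members.append(
            Member(
                chain=chain if chain not in NULL_VALUES else ".",
                seq_id=int(row[col_seq]),
                residue_type=row[col_comp].upper(),
                atom_name=row[col_atom].upper(),
            )
        )
    return members


def parse_restraints(path: Union[str, Path]) -> List[RestraintRecord]:
    """Parse general-distance-constraint loops from an NMR-STAR file.

    Rows sharing a constraint ID are one (possibly ambiguous) restraint;
    all member selections are retained.  The save frame's declared
    constraint type decides ``origin``: NOE-typed lists are "NOE",
    anything else (notably lists filed as plain distance restraints) is
    "simple" — both are analysed identically downstream.
    """
    try:
        blocks = parse_star_file(path)
    except ValueError as exc:
        raise RestraintParseError(f"{path}: {exc}") from exc
    records: List[RestraintRecord] = []
    next_id = 0
    found_loop = False
    for block in blocks:
        for frame in block.all_frames():
            ctype = (frame.tag("Constraint_type") or "").lower()
            origin = "NOE" if "noe" in ctype else "simple"
            for loop in frame.loops_of("_Gen_dist_constraint"):
                found_loop = True
                col_id = loop.column("ID")
                col_lo = loop.column("Distance_lower_bound_val")
                col_up = loop.column("Distance_upper_bound_val")
                if col_id is None:
                    raise RestraintParseError(f"{path}: constraint loop has no ID tag")
                grouped: Dict[int, RestraintRecord] = {}
                try:
                    for row in loop.rows:
                        rid = int(row[col_id])
                        members = _loop_members(loop, row)
                        lower = _float_or_none(row[col_lo]) if col_lo is not None else None
                        upper = _float_or_none(row[col_up]) if col_up is not None else None
                        rec = grouped.get(rid)
                        if rec is None:
                            next_id += 1
                            rec = RestraintRecord(rid, [], lower, upper, origin)
                            grouped[rid] = rec
                        for m in members:
                            if m not in rec.members:
                                rec.members.append(m)
                except (ValueError, IndexError) as exc:
                    raise RestraintParseError(f"{path}: {exc}") from exc
                records.extend(grouped[rid] for rid in sorted(grouped))
    if not found_loop:
        raise RestraintParseError(
            f"{path}: no general-distance-constraint loop found"
        )
    for rec in records:
        if rec.lower_A is not None and rec.upper_A is not None:
            if rec.lower_A > rec.upper_A:
                raise RestraintParseError(
                    f"{path}: restraint {rec.restraint_id} has lower > upper"
                )
    return records


def filter_restraints(
    records: Sequence[RestraintRecord], max_upper_A: float = 6.0
) -> List[RestraintRecord]:
    """Keep restraints with an upper bound <= 6 A spanning <= 2 residues.

    Discards restraints reporting only a lower bound, an upper bound
    greater than ``max_upper_A`` (strict), or ambiguity across more than
    two distinct residues.  Order-preserving and idempotent.
    """
    return [
        rec for rec in records
        if rec.upper_A is not None
        and rec.upper_A <= max_upper_A
        and len(rec.distinct_residues()) <= 2
    ]


def _resolve_member(
    member: Member,
    residue_types: Mapping[Tuple[str, int], str],
    chains: Sequence[str],
) -> Optional[Tuple[Tuple[str, int], str]]:
    """Map a member to a structure residue; None if unresolvable."""
    chain = member.chain if member.chain in chains else (
        chains[0] if len(chains) == 1 else None
    )
    if chain is None:
        return None
    key = (chain, member.seq_id)
    rtype = residue_types.get(key)
    if rtype is None or rtype != member.residue_type:
        return None
    return key, rtype


def amide_aromatic_restraints(
    records: Sequence[RestraintRecord],
    residue_types: Mapping[Tuple[str, int], str],
) -> List[RestrainedPair]:
    """Aggregate surviving restraints into amide/aromatic-residue pairs.

    A record contributes iff one member resolves to a backbone amide H and
    another to a ring proton (directly or through a known pseudoatom) on a
    different residue.  Records with unresolvable members or unknown
    pseudoatoms are skipped and logged.
    """
    chains = tuple(dict.fromkeys(key[0] for key in residue_types))
    counts: Dict[Tuple[Tuple[str, int], Tuple[str, int]], int] = defaultdict(int)
    types: Dict[Tuple[str, int], str] = {}
    for rec in records:
        amide: Optional[Tuple[str, int]] = None
        ring: Optional[Tuple[str, int]] = None
        skip = False
        for member in rec.members:
            resolved = _resolve_member(member, residue_types, chains)
            if resolved is None:
                logger.warning(
                    "restraint %d: member %s unresolvable against structure; "
                    "record skipped", rec.restraint_id, member,
                )
                skip = True
                break
            key, rtype = resolved
            name = member.atom_name
            if name in AMIDE_H_NAMES:
                amide = key
            elif rtype in RING_H_NAMES:
                if name in RING_H_NAMES[rtype]:
                    ring = key
                elif name in PSEUDOATOMS.get(rtype, {}):
                    ring = key  # expands to a subset of the ring H set
                elif name.startswith("Q") or name[-1] in "*%#":
                    logger.warning(
                        "restraint %d: unknown pseudoatom %s on %s; record "
                        "skipped", rec.restraint_id, name, rtype,
                    )
                    skip = True
                    break
            types[key] = rtype
        if skip or amide is None or ring is None or amide == ring:
            continue
        counts[(amide, ring)] += 1
    pairs = [
        RestrainedPair(
            amide_chain=amide[0], amide_seq_id=amide[1],
            amide_residue_type=types[amide],
            ring_chain=ring[0], ring_seq_id=ring[1],
            ring_residue_type=types[ring],
            n_restraints=n,
        )
        for (amide, ring), n in sorted(counts.items())
    ]
    return pairs


def _z_bin(z: float) -> int:
    return int(np.floor(z + 0.5))


def proportion_with_restraint_vs_z(
    survey_by_entry: Mapping[str, pd.DataFrame],
    pairs_by_entry: Mapping[str, Sequence[RestrainedPair]],
    by_ring_type: bool = False,
) -> pd.DataFrame:
    """Proportion of amides with >= 1 amide-aromatic restraint, per Z bin.

    Only entries with at least one amide-aromatic restraint enter the
    denominators.  Z is binned to the nearest integer.  Columns:
    ``z_bin, ring_type, n_amides, n_restrained, proportion`` (ring_type is
    "all" unless ``by_ring_type``); bins with no amides are simply absent.
    """
    num: Dict[Tuple[int, str], int] = defaultdict(int)
    den: Dict[int, int] = defaultdict(int)
    for entry_id, pairs in pairs_by_entry.items():
        if not pairs:
            continue  # entry contributes to neither numerator nor denominator
        df = survey_by_entry.get(entry_id)
        if df is None or df.empty:
            continue
        restrained: Dict[Tuple[str, int], set] = defaultdict(set)
        for p in pairs:
            restrained[(p.amide_chain, p.amide_seq_id)].add(p.ring_residue_type)
        for row in df.itertuples():
            zb = _z_bin(row.z)
            den[zb] += 1
            ring_types = restrained.get((row.chain, row.seq_id))
            if ring_types:
                if by_ring_type:
                    for rt in ring_types:
                        num[(zb, rt)] += 1
                else:
                    num[(zb, "all")] += 1
    rows = []
    for zb in sorted(den):
        keys = sorted(rt for (b, rt) in num if b == zb) if by_ring_type else ["all"]
        if not keys:
            keys = ["all"]
        for rt in keys:
            n_r = num.get((zb, rt), 0)
            rows.append({
                "z_bin": zb, "ring_type": rt,
                "n_amides": den[zb], "n_restrained": n_r,
                "proportion": n_r / den[zb],
            })
    return pd.DataFrame(
        rows, columns=["z_bin", "ring_type", "n_amides", "n_restrained",
                       "proportion"],
    )


def pair_class_table(
    pairs: Sequence[RestrainedPair],
    survey: pd.DataFrame,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Counts of restrained pairs by (ring type, Z class, n_restraints).

    The full category skeleton (4 ring types x 3 classes x observed
    restraint multiplicities) is emitted, absent combinations as 0.  Pairs
    whose amide lacks a survey row are dropped and logged.
    """
    z_lookup = {
        (row.chain, row.seq_id): row.z for row in survey.itertuples()
    }
    n_values = sorted({p.n_restraints for p in pairs}) or [1]
    counts: Dict[Tuple[str, str, int], int] = defaultdict(int)
    for p in pairs:
        z = z_lookup.get((p.amide_chain, p.amide_seq_id))
        if z is None:
            logger.warning(
                "pair (%s%d -> %s %s%d) has no survey row; dropped",
                p.amide_chain, p.amide_seq_id,
                p.ring_residue_type, p.ring_chain, p.ring_seq_id,
            )
            continue
        counts[(p.ring_residue_type, classify(z, z_threshold), p.n_restraints)] += 1
    rows = [
        {
            "ring_residue_type": rt, "z_class": cls, "n_restraints": n,
            "count": counts.get((rt, cls, n), 0),
        }
        for rt in ("PHE", "TYR", "TRP", "HIS")
        for cls in ("upfield", NORMAL, "downfield")
        for n in n_values
    ]
    return pd.DataFrame(
        rows, columns=["ring_residue_type", "z_class", "n_restraints", "count"]
    )


def pairs_to_frame(pairs: Sequence[RestrainedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "amide_chain": p.amide_chain, "amide_seq_id": p.amide_seq_id,
                "amide_residue_type": p.amide_residue_type,
                "ring_chain": p.ring_chain, "ring_seq_id": p.ring_seq_id,
                "ring_residue_type": p.ring_residue_type,
                "n_restraints": p.n_restraints,
            }
            for p in pairs
        ],
        columns=["amide_chain", "amide_seq_id", "amide_residue_type",
                 "ring_chain", "ring_seq_id", "ring_residue_type",
                 "n_restraints"],
    )
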