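"""Minimal NMR-STAR 3.1 reading and writing.

Covers the subset of STAR needed here: data blocks, save frames, free
tags, and loops, with single/double-quoted and semicolon-delimited values.
Exposes loaders for assigned chemical-shift lists (``_Atom_chem_shift``
loops) and plain writers used by the synthetic-data generator.  This is a
purpose-built reader for well-formed archival files, not a general STAR
validator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .reference_stats import AMIDE_H_NAMES, STANDARD_AA, AmideShiftRecord

logger = logging.getLogger("aroshift")

NULL_VALUES = {".", "?", ""}


class StarSyntaxError(ValueError):
    pass


@dataclass
class Loop:
    tags: List[str]
    rows: List[List[str]]

    def category(self) -> str:
        return self.tags[0].split(".")[0] if self.tags else ""

    def column(self, tag_suffix: str) -> Optional[int]:
        """Index of the tag whose part after '.' equals ``tag_suffix``."""
        for i, tag in enumerate(self.tags):
            if tag.split(".", 1)[-1] == tag_suffix:
                return i
        return None


@dataclass
class Saveframe:
    name: str
    tags: Dict[str, str] = field(default_factory=dict)
    loops: List[Loop] = field(default_factory=list)

    def tag(self, suffix: str) -> Optional[str]:
        for key, val in self.tags.items():
            if key.split(".", 1)[-1] == suffix:
                return val
        return None

    def loops_of(self, category: str) -> List[Loop]:
        return [lp for lp in self.loops if lp.category() == category]


@dataclass
class DataBlock:
    name: str
    saveframes: List[Saveframe] = field(default_factory=list)
    tags: Dict[str, str] = field(default_factory=dict)
    loops: List[Loop] = field(default_factory=list)

    def all_frames(self) -> List[Saveframe]:
        """Save frames plus a pseudo-frame for block-level tags/loops."""
        frames = list(self.saveframes)
        if self.tags or self.loops:
            frames.append(Saveframe("", dict(self.tags), list(self.loops)))
        return frames


def _tokenize(text: str):
    """Yield STAR tokens; semicolon-delimited text becomes one token."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            chunk: List[str] = [line[1:]]
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                chunk.append(lines[i])
                i += 1
            if i >= len(lines):
                raise StarSyntaxError("unterminated semicolon-delimited value")
            if chunk and chunk[0] == "":
                chunk = chunk[1:]
            yield "\n".join(chunk)
            i += 1
            continue
        pos = 0
        n = len(line)
        while pos < n:
            ch = line[pos]
            if ch in " \t":
                pos += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                quote = ch
                end = pos + 1
                while True:
                    end = line.find(quote, end)
                    if end == -1:
                        raise StarSyntaxError(f"unterminated quote: {line!r}")
                    # closing quote must be followed by whitespace or EOL
                    if end + 1 >= n or line[end + 1] in " \t":
                        break
                    end += 1
                yield line[pos + 1 : end]
                pos = end + 1
                continue
            end = pos
            while end < n and line[end] not in " \t":
                end += 1
            yield line[pos:end]
            pos = end
        i += 1


def parse_star(text: str) -> List[DataBlock]:
    blocks: List[DataBlock] = []
    block: Optional[DataBlock] = None
    frame: Optional[Saveframe] = None
    tokens = list(_tokenize(text))
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        low = tok.lower()
        if low.startswith("data_"):
            block = DataBlock(tok[5:])
            blocks.append(block)
            frame = None
            i += 1
        elif low == "save_":
            frame = None
            i += 1
        elif low.startswith("save_"):
            if block is None:
                raise StarSyntaxError("save frame outside data block")
            frame = Saveframe(tok[5:])
            block.saveframes.append(frame)
            i += 1
        elif low == "loop_":
            tags: List[str] = []
            i += 1
            while i < len(tokens) and tokens[i].startswith("_"):
                tags.append(tokens[i])
                i += 1
            values: List[str] = []
            while i < len(tokens) and tokens[i].lower() not in (
                "stop_",
            ) and not tokens[i].lower().startswith(("loop_", "save_", "data_")):
                values.append(tokens[i])
                i += 1
            if i < len(tokens) and tokens[i].lower() == "stop_":
                i += 1
            if not tags:
                raise StarSyntaxError("loop_ with no tags")
            if len(values) % len(tags) != 0:
                raise StarSyntaxError(
                    f"loop {tags[0]}: {len(values)} values not a multiple of "
                    f"{len(tags)} tags"
                )
            loop = Loop(tags, [
                values[j : j + len(tags)]
                for j in range(0, len(values), len(tags))
            ])
            target = frame if frame is not None else block
            if target is None:
                raise StarSyntaxError("loop outside data block")
            target.loops.append(loop)
        elif tok.startswith("_"):
            if i + 1 >= len(tokens):
                raise StarSyntaxError(f"tag {tok} has no value")
            target = frame if frame is not None else block
            if target is None:
                raise StarSyntaxError("tag outside data block")
            target.tags[tok] = tokens[i + 1]
            i += 2
        else:
            raise StarSyntaxError(f"unexpected token {tok!r}")
    return blocks


def parse_star_file(path: Union[str, Path]) -> List[DataBlock]:
    return parse_star(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# chemical-shift loading


def load_shifts(path: Union[str, Path]) -> List[AmideShiftRecord]:
    """Backbone amide proton shifts from the first assigned-shift list.

    Only rows whose atom name is an accepted backbone amide H name (H, HN,
    H1) are returned; sidechain NH/NH2 protons are excluded by construction.
    If the file holds several shift lists, the first is used and the event
    logged.
    """
    blocks = parse_star_file(path)
    if not blocks:
        raise StarSyntaxError(f"{path}: no data block")
    block = blocks[0]
    entry_id = block.tags.get("_Entry.ID") or block.name
    shift_loops: List[Loop] = []
    for frame in block.all_frames():
        eid = frame.tag("Entry.ID")
        if eid and eid not in NULL_VALUES:
            entry_id = entry_id or eid
        shift_loops.extend(frame.loops_of("_Atom_chem_shift"))
    if not shift_loops:
        raise StarSyntaxError(f"{path}: no _Atom_chem_shift loop")
    if len(shift_loops) > 1:
        logger.warning(
            "%s: %d assigned shift lists; using the first",
            path, len(shift_loops),
        )
    loop = shift_loops[0]
    col_seq = loop.column("Comp_index_ID")
    col_comp = loop.column("Comp_ID")
    col_atom = loop.column("Atom_ID")
    col_val = loop.column("Val")
    col_chain = loop.column("Auth_asym_ID")
    if col_chain is None:
        col_chain = loop.column("Entity_assembly_ID")
    if None in (col_seq, col_comp, col_atom, col_val):
        raise StarSyntaxError(f"{path}: shift loop missing required tags")
    records: List[AmideShiftRecord] = []
    for row in loop.rows:
        atom = row[col_atom]
        if atom not in AMIDE_H_NAMES:
            continue
        comp = row[col_comp].upper()
        if comp not in STANDARD_AA:
            logger.warning("%s: skipping non-standard residue %s", path, comp)
            continue
        val = row[col_val]
        if val in NULL_VALUES:
            continue
        chain = row[col_chain] if col_chain is not None else "."
        records.append(
            AmideShiftRecord(
                entry_id=str(entry_id),
                chain_id=chain if chain not in NULL_VALUES else ".",
                seq_id=int(row[col_seq]),
                residue_type=comp,
                shift_ppm=float(val),
            )
        )
    return records


# ---------------------------------------------------------------------------
# writing (used by the synthetic generator)


def _fmt(value) -> str:
    if value is None:
        return "."
    s = str(value)
    if s == "" or any(c in s for c in " \t'\""):
        return f'"{s}"'
    return s


def write_loop(tags: Sequence[str], rows: Sequence[Sequence]) -> str:
    out = ["   loop_"]
    out.extend(f"      {t}" for t in tags)
    out.append("")
    for row in rows:
        out.append("      " + " ".join(_fmt(v) for v in row))
    out.append("   stop_")
    return "\n".join(out)


def write_shifts_star(
    records: Sequence[AmideShiftRecord], path: Union[str, Path], entry_id: str
) -> None:
    tags = [
        "_Atom_chem_shift.ID",
        "_Atom_chem_shift.Entity_assembly_ID",
        "_Atom_chem_shift.Comp_index_ID",
        "_Atom_chem_shift.Comp_ID",
        "_Atom_chem_shift.Atom_ID",
        "_Atom_chem_shift.Atom_type",
        "_Atom_chem_shift.Val",
        "_Atom_chem_shift.Auth_asym_ID",
    ]
    rows = [
        [i + 1, 1, r.seq_id, r.residue_type, "H", "H",
         f"{r.shift_ppm:.3f}", r.chain_id]
        for i, r in enumerate(records)
    ]
    text = "\n".join([
        f"data_{entry_id}",
        "",
        "save_assigned_chemical_shifts_1",
        "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_framecode  assigned_chemical_shifts_1",
        f"   _Assigned_chem_shift_list.Entry_ID      {entry_id}",
        "",
        write_loop(tags, rows),
        "save_",
        "",
    ])
    Path(path).write_text(text, encoding="utf-8")


def write_restraints_star(
    rows: Sequence[dict], path: Union[str, Path], entry_id: str,
    constraint_type: str = "NOE",
) -> None:
    """Write a general-distance-constraint save frame.

    Each row dict needs: id, chain_1, seq_1, comp_1, atom_1, chain_2,
    seq_2, comp_2, atom_2, lower, upper.  Ambiguous restraints repeat an id
    over several rows.
    """
    tags = [
        "_Gen_dist_constraint.ID",
        "_Gen_dist_constraint.Auth_asym_ID_1",
        "_Gen_dist_constraint.Comp_index_ID_1",
        "_Gen_dist_constraint.Comp_ID_1",
        "_Gen_dist_constraint.Atom_ID_1",
        "_Gen_dist_constraint.Auth_asym_ID_2",
        "_Gen_dist_constraint.Comp_index_ID_2",
        "_Gen_dist_constraint.Comp_ID_2",
        "_Gen_dist_constraint.Atom_ID_2",
        "_Gen_dist_constraint.Distance_lower_bound_val",
        "_Gen_dist_constraint.Distance_upper_bound_val",
    ]
    body = [
        [r["id"], r["chain_1"], r["seq_1"], r["comp_1"], r["atom_1"],
         r["chain_2"], r["seq_2"], r["comp_2"], r["atom_2"],
         "." if r["lower"] is None else f"{r['lower']:.2f}",
         "." if r["upper"] is None else f"{r['upper']:.2f}"]
        for r in rows
    ]
    text = "\n".join([
        f"data_{entry_id}",
        "",
        "save_general_distance_constraints_1",
        "   _Gen_dist_constraint_list.Sf_category      general_distance_constraints",
        "   _Gen_dist_constraint_list.Sf_framecode     general_distance_constraints_1",
        f"   _Gen_dist_constraint_list.Constraint_type  {constraint_type}",
        f"   _Gen_dist_constraint_list.Entry_ID         {entry_id}",
        "",
        write_loop(tags, body),
        "save_",
        "",
    ])
    Path(path).write_text(text, encoding="utf-8")
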