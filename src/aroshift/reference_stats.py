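"""Per-residue-type amide proton reference statistics and shift Z scores.

An amide proton whose chemical shift sits far from the mean for its residue
type is a candidate for a structural perturbation such as a ring-current
shift from a nearby aromatic sidechain.  The deviation is expressed as a
Z score,

    Z = (delta - mean) / sd,

where ``mean`` and ``sd`` are the archive-wide mean and standard deviation
of the backbone amide (H) shift for that residue type.  A pinned snapshot of
BMRB-style statistics ships with the package; proline is absent because it
has no backbone amide proton.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, Union

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Backbone amide hydrogen names accepted across deposition conventions.
AMIDE_H_NAMES = frozenset({"H", "HN", "H1"})


class ReferenceStatsError(ValueError):
    """Malformed or invalid reference-statistics input."""


class MissingResidueTypeError(LookupError):
    """No reference statistics available for a residue type."""


@dataclass(frozen=True)
class ResidueShiftStats:
    """Mean and standard deviation of the amide H shift for one residue type."""

    residue_type: str
    mean_ppm: float
    sd_ppm: float

    def __post_init__(self) -> None:
        if self.residue_type not in STANDARD_AA:
            raise ReferenceStatsError(
                f"non-standard residue type {self.residue_type!r}"
            )
        if not (self.sd_ppm > 0):
            raise ReferenceStatsError(
                f"sd must be positive for {self.residue_type}, got {self.sd_ppm}"
            )


@dataclass(frozen=True)
class AmideShiftRecord:
    """One assigned backbone amide proton shift."""

    entry_id: str
    chain_id: str
    seq_id: int
    residue_type: str
    shift_ppm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.shift_ppm):
            raise ValueError(
                f"non-finite shift for {self.residue_type} {self.seq_id}"
            )


class ReferenceStats:
    """Lookup table of :class:`ResidueShiftStats`, one entry per residue type."""

    def __init__(self, stats: Dict[str, ResidueShiftStats]):
        self._stats = dict(stats)

    def __len__(self) -> int:
        return len(self._stats)

    def __contains__(self, residue_type: str) -> bool:
        return residue_type in self._stats

    def __iter__(self) -> Iterator[ResidueShiftStats]:
        return iter(self._stats.values())

    def for_residue(self, residue_type: str) -> ResidueShiftStats:
        try:
            return self._stats[residue_type]
        except KeyError:
            raise MissingResidueTypeError(
                f"no reference statistics for residue type {residue_type!r}"
            ) from None

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ReferenceStats":
        """Load a ``residue_type,mean_ppm,sd_ppm`` CSV.

        Missing residue types raise only on later lookup; malformed rows and
        non-positive sd raise here, naming the offending line.
        """
        stats: Dict[str, ResidueShiftStats] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return cls({})
            required = {"residue_type", "mean_ppm", "sd_ppm"}
            if not required.issubset(reader.fieldnames):
                raise ReferenceStatsError(
                    f"{path}: header must contain {sorted(required)}"
                )
            for row in reader:
                line = reader.line_num
                try:
                    rt = row["residue_type"].strip().upper()
                    entry = ResidueShiftStats(
                        residue_type=rt,
                        mean_ppm=float(row["mean_ppm"]),
                        sd_ppm=float(row["sd_ppm"]),
                    )
                except ReferenceStatsError as exc:
                    raise ReferenceStatsError(f"{path}, line {line}: {exc}") from None
                except (TypeError, ValueError, AttributeError):
                    raise ReferenceStatsError(
                        f"{path}, line {line}: malformed row {row!r}"
                    ) from None
                if entry.residue_type in stats:
                    raise ReferenceStatsError(
                        f"{path}, line {line}: duplicate residue type {rt}"
                    )
                stats[entry.residue_type] = entry
        return cls(stats)

    @classmethod
    def default(cls) -> "ReferenceStats":
        """The packaged snapshot of per-residue amide H statistics."""
        source = resources.files("aroshift.data").joinpath("bmrb_amide_stats.csv")
        with resources.as_file(source) as path:
            return cls.from_csv(path)


def z_score(shift_ppm: float, stats: ResidueShiftStats) -> float:
    """Z score of a shift against its residue type's reference statistics."""
    return (shift_ppm - stats.mean_ppm) / stats.sd_ppm
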