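"""Point-dipole ring-current shift model.

The magnetic field of the ring's circulating pi electrons is approximated
by a point dipole at the ring centre, giving a perturbation proportional to

    (1 - 3 cos^2 theta) / r^3,

with r the proton-to-centre distance and theta the azimuth from the ring
normal.  The factor vanishes at the magic angle arccos(1/sqrt(3)) = 54.74
deg, is negative (shielding, upfield) above the ring and positive
(deshielding, downfield) in the plane, with a 2:1 axial-to-in-plane
anisotropy at equal r.

The proportionality constant i*B (ppm*A^3) folds the ring-type intensity
and the dipole constant into one number per ring.  Defaults are calibrated
to two in-model anchors: a 1.5 ppm upfield shift 3 A above a Phe/Tyr ring,
and a 0.5 ppm downfield shift 3.4 A in the plane of a His ring; Trp rings
are taken 1.3x stronger than Phe.  The dipole approximation is quantitative
only beyond roughly 3 A above the plane and 5 A in the plane; closer
geometries trigger a warning, not an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

from .geometry import AmideRingGeometry

#: theta = arccos(1/sqrt(3)); boundary between upfield and downfield cones.
MAGIC_ANGLE_DEG = math.degrees(math.acos(1.0 / math.sqrt(3.0)))

RingKey = Tuple[str, str]  # (residue type, ring label)

DEFAULT_CONSTANTS: Dict[RingKey, float] = {
    ("PHE", "six"): 20.25,
    ("TYR", "six"): 20.25,
    ("TRP", "five"): 1.3 * 20.25,
    ("TRP", "six"): 1.3 * 20.25,
    ("HIS", "five"): 19.65,
}


class RingCurrentValidityWarning(UserWarning):
    """Geometry inside the region where the dipole approximation degrades."""


class PredictionError(ValueError):
    """Prediction requested for a sentinel (ring-less) geometry."""


def magic_angle() -> float:
    """The magic angle in degrees (arccos(1/sqrt 3) = 54.7356)."""
    return MAGIC_ANGLE_DEG


def geometric_factor(r, theta_deg):
    """Dipole geometric factor (1 - 3 cos^2 theta) / r^3 in 1/A^3.

    Accepts scalars or arrays; r must be strictly positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance r must be positive")
    cos_t = np.cos(np.deg2rad(np.asarray(theta_deg, dtype=float)))
    out = (1.0 - 3.0 * cos_t**2) / r**3
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RingCurrentParams:
    """Effective dipole constants i*B per ring, in ppm*A^3 (all > 0)."""

    constants: Dict[RingKey, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSTANTS)
    )

    def __post_init__(self) -> None:
        for key, value in self.constants.items():
            if not (value > 0):
                raise ValueError(f"dipole constant for {key} must be > 0")

    def constant_for(self, residue_type: str, ring_label: str) -> float:
        try:
            return self.constants[(residue_type, ring_label)]
        except KeyError:
            raise KeyError(
                f"no ring-current constant for ({residue_type}, {ring_label})"
            ) from None


def predict_shift(
    geometry: AmideRingGeometry, params: RingCurrentParams
) -> float:
    """Predicted ring-current perturbation in ppm (negative = upfield)."""
    if not geometry.has_ring:
        raise PredictionError(
            f"no aromatic ring for amide "
            f"{geometry.amide_chain}{geometry.amide_seq_id}"
        )
    r = geometry.distance_A
    theta = geometry.azimuth_deg
    assert geometry.ring is not None and r is not None and theta is not None
    if (theta < MAGIC_ANGLE_DEG and r < 3.0) or (
        theta >= MAGIC_ANGLE_DEG and r < 5.0
    ):
        warnings.warn(
            f"geometry (r={r:.2f} A, theta={theta:.1f} deg) is inside the "
            "region where the point-dipole approximation degrades",
            RingCurrentValidityWarning,
            stacklevel=2,
        )
    const = params.constant_for(geometry.ring.residue_type, geometry.ring.ring_label)
    return const * geometric_factor(r, theta)
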