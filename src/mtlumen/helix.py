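"""Helical lattice geometry: twist/rise symmetry, subunit lattices, Euler
triplets and polarity flips.

A filament is modelled as a 1-start helix: subunit *k* is obtained from
subunit 0 by rotating ``k * twist_deg`` about the helix axis (z) and
translating ``k * rise_ang`` along it.  All filaments handled here are
left-handed (negative twist), as is the actin genetic helix.

Angles are degrees throughout; radians appear only transiently inside
trigonometric calls.  Lengths at this level are Angstrom.

The closed-form cross-over relation implemented here serves as the
independent oracle for the Fourier layer-line measurement: a helix whose
per-subunit twist is between 90 and 180 degrees in magnitude appears in
projection as two strands that cross every

    c = rise * 180 / (180 - |twist|)

along the axis.  Cofilin decoration reduces |twist| of actin from ~167 to
~162 degrees and therefore shortens the cross-over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "HelicalSymmetry",
    "EulerTriplet",
    "SubunitLattice",
    "COFILACTIN",
    "F_ACTIN",
    "crossover_from_symmetry",
    "build_subunit_lattice",
    "flip_polarity",
]


@dataclass(frozen=True)
class HelicalSymmetry:
    """Per-subunit twist (deg, signed) and rise (Angstrom) of a 1-start helix."""

    twist_deg: float
    rise_ang: float

    def __post_init__(self) -> None:
        if not self.rise_ang > 0:
            raise ValueError(f"rise must be positive, got {self.rise_ang}")
        if not -360.0 < self.twist_deg < 0.0:
            raise ValueError(
                f"twist must lie in (-360, 0) deg (left-handed helix), got {self.twist_deg}"
            )


#: Refined symmetry of the cofilin-decorated luminal filament.
COFILACTIN = HelicalSymmetry(twist_deg=-161.8, rise_ang=28.5)
#: Canonical bare F-actin symmetry.
F_ACTIN = HelicalSymmetry(twist_deg=-167.0, rise_ang=27.5)


@dataclass(frozen=True)
class EulerTriplet:
    """Intrinsic Z-Y-Z Euler angles (rot, tilt, psi) in degrees.

    Normalization: tilt in [0, 180]; rot and psi in (-180, 180].
    """

    rot: float
    tilt: float
    psi: float

    def as_matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on column vectors."""
        return Rotation.from_euler(
            "ZYZ", [self.rot, self.tilt, self.psi], degrees=True
        ).as_matrix()

    def direction(self) -> np.ndarray:
        """Unit vector the rotation sends +z to (the particle's axial direction)."""
        return self.as_matrix() @ np.array([0.0, 0.0, 1.0])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "EulerTriplet":
        """Extract a canonical triplet from a rotation matrix.

        At the gimbal-locked poles (tilt = 0 or 180) rot carries the full
        in-plane angle and psi is set to 0.
        """
        import warnings

        with warnings.catch_warnings():
            # gimbal lock is handled explicitly below
            warnings.simplefilter("ignore", UserWarning)
            rot, tilt, psi = Rotation.from_matrix(m).as_euler("ZYZ", degrees=True)
        if abs(np.sin(np.radians(tilt))) < 1e-9:
            # degenerate: only rot +/- psi is determined
            if tilt > 90.0:  # tilt ~ 180: matrix fixes rot - psi
                rot, psi = rot - psi, 0.0
            else:  # tilt ~ 0: matrix fixes rot + psi
                rot, psi = rot + psi, 0.0
            tilt = 180.0 if tilt > 90.0 else 0.0
        return cls(_wrap_half_open(rot), float(np.clip(tilt, 0.0, 180.0)), _wrap_half_open(psi))


def _wrap_half_open(angle: float) -> float:
    """Wrap an angle into (-180, 180]."""
    a = (float(angle) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class SubunitLattice:
    """Realized helical lattice: one row per subunit.

    positions : (n, 3) float array, Angstrom, axis along z.
    orientations : length-n scipy Rotation, frame of each subunit.
    radius : Angstrom from the helix axis to each subunit center.
    """

    symmetry: HelicalSymmetry
    positions: np.ndarray
    orientations: Rotation
    radius: float

    def __len__(self) -> int:
        return self.positions.shape[0]


def crossover_from_symmetry(sym: HelicalSymmetry) -> float:
    """Axial distance (Angstrom) between successive two-strand cross-overs.

    Valid for 90 < |twist| < 180 deg, where the 1-start helix appears in
    projection as two long-pitch strands.
    """
    t = abs(sym.twist_deg)
    if t == 180.0:
        raise ValueError("strands never cross: |twist| = 180 deg")
    if t <= 90.0 or t > 180.0:
        raise ValueError(f"not a two-start-appearing helix: |twist| = {t} deg")
    return sym.rise_ang * 180.0 / (180.0 - t)


def build_subunit_lattice(
    sym: HelicalSymmetry,
    n_subunits: int,
    radius: float,
    phase0: float = 0.0,
) -> SubunitLattice:
    """Place ``n_subunits`` on the helix defined by ``sym``.

    Subunit k sits at azimuth ``phase0 + k * twist`` (deg) and height
    ``k * rise`` (Angstrom); its frame is the reference frame rotated by the
    same azimuth about the axis.
    """
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    k = np.arange(n_subunits)
    az = np.radians(phase0 + k * sym.twist_deg)
    positions = np.column_stack(
        [radius * np.cos(az), radius * np.sin(az), k * sym.rise_ang]
    )
    orientations = Rotation.from_euler(
        "z", (phase0 + k * sym.twist_deg)[:, None], degrees=True
    )
    return SubunitLattice(sym, positions, orientations, float(radius))


_FLIP_Y = Rotation.from_euler("y", 180.0, degrees=True).as_matrix()


def flip_polarity(e: EulerTriplet) -> EulerTriplet:
    """Compose with a 180-degree rotation about the triplet's second (Y) axis.

    This is the standard polarity flip for filament particles: the image of
    +z (the particle's axial direction) is exactly reversed.  Implemented by
    matrix composition and canonical re-extraction, so it is well defined
    even at tilt 0/180.
    """
    return EulerTriplet.from_matrix(e.as_matrix() @ _FLIP_Y)
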