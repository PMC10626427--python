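"""Filament-trace geometry.

Traces are ordered 3D polylines in nanometres, as produced by manual
picking of microtubules and luminal filaments in tomogram slices.  This
module turns them into the quantities the pipeline needs: contour lengths,
equally spaced particle positions with smoothly varying orthonormal frames
(parallel transport, so straight segments and inflections do not flip or
spin the frame), and the mapping of each luminal filament to the
microtubule whose lumen contains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "FilamentTrace",
    "contour_length",
    "resample_trace",
    "assign_host_microtubule",
    "read_traces",
    "write_traces",
    "point_to_polyline_distance",
]

#: default lumen containment radius, nm (the microtubule lumen is ~15 nm wide)
DEFAULT_LUMEN_RADIUS = 8.0


@dataclass
class FilamentTrace:
    """Ordered 3D points (nm) tracing one filament."""

    points: np.ndarray
    id: str = ""
    kind: Literal["microtubule", "luminal", "cytoplasmic"] = "microtubule"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise ValueError("trace needs at least one point")
        if len(self.points) > 1:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(seg == 0):
                raise ValueError("consecutive trace points must be distinct")

    def contour_length(self) -> float:
        return contour_length(self)


def contour_length(t: FilamentTrace) -> float:
    """Polyline arc length in nm (0 for a single point)."""
    if len(t.points) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(t.points, axis=0), axis=1)))


def _arc_interpolate(points: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Positions at arc lengths ``s`` along the polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty((len(s), 3))
    for d in range(3):
        out[:, d] = np.interp(s, cum, points[:, d])
    return out


def resample_trace(
    t: FilamentTrace, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Particle positions every ``spacing`` nm along the trace, with frames.

    Positions sit at arc lengths 0, spacing, 2*spacing, ... from the first
    point.  Each position carries a right-handed orthonormal frame (3x3
    rotation, columns = x/y/z axes) whose z axis is the local tangent; the
    transverse axes are parallel-transported along the trace so the frame
    never spins about the tangent or flips between samples.  A trace
    shorter than ``spacing`` yields a single particle at its midpoint.

    Returns (positions (n, 3) nm, frames (n, 3, 3)).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    length = contour_length(t)
    if length < spacing:
        s = np.array([length / 2.0])
    else:
        s = np.arange(0.0, length + 1e-9, spacing)
        s = s[s <= length + 1e-9]
    positions = _arc_interpolate(t.points, s)
    tangents = _tangents_at(t.points, s)
    frames = _parallel_transport_frames(tangents)
    return positions, frames


def _tangents_at(points: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Unit tangents at arc lengths ``s`` (per-segment constant tangent)."""
    if len(points) < 2:
        return np.tile(np.array([0.0, 0.0, 1.0]), (len(s), 1))
    seg_vec = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    seg_dir = seg_vec / seg_len[:, None]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_dir) - 1)
    return seg_dir[idx]


def _parallel_transport_frames(tangents: np.ndarray) -> np.ndarray:
    """Minimal-rotation frames along a sequence of unit tangents."""
    n = len(tangents)
    frames = np.empty((n, 3, 3))
    z = tangents[0]
    # seed transverse axis: anything not parallel to z
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, z)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    x = probe - np.dot(probe, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    frames[0] = np.column_stack([x, y, z])
    for i in range(1, n):
        z_new = tangents[i]
        # rotate the previous frame by the minimal rotation taking z -> z_new
        axis = np.cross(z, z_new)
        s_ = np.linalg.norm(axis)
        c_ = float(np.clip(np.dot(z, z_new), -1.0, 1.0))
        if s_ < 1e-12:
            rot = np.eye(3) if c_ > 0 else -np.eye(3) + 2 * np.outer(z, z)
        else:
            axis = axis / s_
            k = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            rot = np.eye(3) + s_ * k + (1 - c_) * (k @ k)
        x = rot @ x
        y = np.cross(z_new, x)
        x = np.cross(y, z_new)  # re-orthogonalize against drift
        x /= np.linalg.norm(x)
        y /= np.linalg.norm(y)
        frames[i] = np.column_stack([x, y, z_new])
        z = z_new
    return frames


def point_to_polyline_distance(p: np.ndarray, polyline: np.ndarray) -> float:
    """Shortest distance from point ``p`` to a polyline (nm)."""
    p = np.asarray(p, dtype=float)
    pts = np.asarray(polyline, dtype=float).reshape(-1, 3)
    if len(pts) == 1:
        return float(np.linalg.norm(p - pts[0]))
    a, b = pts[:-1], pts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    tpar = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
    proj = a + tpar[:, None] * ab
    return float(np.min(np.linalg.norm(p - proj, axis=1)))


def assign_host_microtubule(
    filament: FilamentTrace,
    microtubules: Sequence[FilamentTrace],
    lumen_radius: float = DEFAULT_LUMEN_RADIUS,
) -> str | None:
    """Map a luminal filament to its surrounding microtubule.

    The host is the microtubule whose axis polyline has the smallest mean
    perpendicular distance to the filament's points, provided that mean
    distance is at most ``lumen_radius`` nm; otherwise ``None``.
    """
    if lumen_radius <= 0:
        raise ValueError("lumen_radius must be positive")
    best_id, best_d = None, np.inf
    for mt in microtubules:
        d = float(
            np.mean(
                [point_to_polyline_distance(p, mt.points) for p in filament.points]
            )
        )
        if d < best_d:
            best_id, best_d = mt.id, d
    if best_id is None or best_d > lumen_radius:
        return None
    return best_id


# ---------------------------------------------------------------------------
# plain-text trace files: one point per line, "filament_id x y z" in nm
# ---------------------------------------------------------------------------


def read_traces(
    path: str | Path, kind: Literal["microtubule", "luminal", "cytoplasmic"] = "microtubule"
) -> list[FilamentTrace]:
    """Read traces from a plain-text point file.

    Lines are "filament_id x y z" (nm, whitespace separated); lines
    starting with '#' are comments.
    """
    groups: dict[str, list[list[float]]] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise ValueError(f"bad trace line (need 'id x y z'): {line!r}")
        fid = fields[0]
        if fid not in groups:
            groups[fid] = []
            order.append(fid)
        groups[fid].append([float(v) for v in fields[1:]])
    return [FilamentTrace(np.array(groups[f]), id=f, kind=kind) for f in order]


def write_traces(traces: Sequence[FilamentTrace], path: str | Path) -> None:
    lines = ["# filament_id x_nm y_nm z_nm"]
    for t in traces:
        for p in t.points:
            lines.append(f"{t.id} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
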