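"""Synthetic cryo-ET scene generation with ground truth.

Three generators mirror the three kinds of experimental input the analysis
pipeline consumes:

``render_scene``
    3D density volumes of microtubule / luminal-filament scenes (Gaussian
    blob subunits on helical lattices), corrupted by additive white noise
    and a tomographic missing wedge, together with per-filament ground
    truth (traces, protofilament number, polarity, helical symmetry).

``simulate_vote_table``
    Per-particle classification-vote tables emulating the output of a
    multireference subtomogram alignment: each filament has a true
    (protofilament-number, polarity) class, each particle votes for it
    with probability ``p_correct``, and cross-correlation scores are drawn
    from class-conditional normals.

``simulate_morphology_set``
    2D side-view projections of short filament segments with cofilactin,
    bare F-actin or featureless-rod morphology, for the template
    classification surrogate.

All randomness flows from the single integer seed carried by each spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .helix import COFILACTIN, F_ACTIN, HelicalSymmetry, build_subunit_lattice
from .trace import FilamentTrace, resample_trace

__all__ = [
    "DensityVolume",
    "MicrotubuleSpec",
    "LuminalFilamentSpec",
    "SceneSpec",
    "VoteSimSpec",
    "render_scene",
    "render_helical_filament",
    "apply_missing_wedge",
    "simulate_vote_table",
    "simulate_morphology_set",
    "PF_CLASSES",
    "POLARITIES",
]

# ---------------------------------------------------------------------------
# geometry constants of the synthetic lattices (Angstrom)
# ---------------------------------------------------------------------------

#: lateral protofilament spacing in the microtubule wall
MT_LATERAL_SPACING = 50.0
#: tubulin monomer spacing along a protofilament
MT_MONOMER_SPACING = 40.95
#: blob widths (Gaussian sigma).  Subunit blobs must be narrow relative to
#: the helical rise (~28 A) or the axial density modulation that the
#: twist/rise search keys on is smeared away; these widths keep individual
#: subunits visible at bin4 sampling while preserving the filaments'
#: relative diameters.
SIGMA_TUBULIN = 16.0
SIGMA_ACTIN = 12.0
SIGMA_COFILIN = 9.0
#: radii from the filament axis
RADIUS_ACTIN = 25.0
RADIUS_COFILIN = 45.0
#: axial offset and relative weight of the polarity-marker blob
POLARITY_OFFSET = 12.0
POLARITY_WEIGHT = 0.4

PF_CLASSES = (12, 13, 14, 15)
POLARITIES = ("plus", "minus")


# ---------------------------------------------------------------------------
# density volume container
# ---------------------------------------------------------------------------


@dataclass
class DensityVolume:
    """Cubic voxel grid with physical voxel size.

    ``grid`` is indexed (z, y, x); position of voxel (i, j, k) is
    (k, j, i) * apix Angstrom from the corner origin (0-based).
    """

    grid: np.ndarray
    apix: float = 11.81

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.grid.shape}")
        if self.grid.shape[0] < 16:
            raise ValueError("cubic box side must be >= 16 voxels")
        if not self.apix > 0:
            raise ValueError("apix must be positive")

    @property
    def box(self) -> int:
        return self.grid.shape[0]

    @property
    def extent_ang(self) -> float:
        return self.box * self.apix


# ---------------------------------------------------------------------------
# scene specification
# ---------------------------------------------------------------------------


@dataclass
class MicrotubuleSpec:
    """One microtubule: axis polyline (nm), protofilament count, polarity."""

    trace_nm: np.ndarray
    n_pf: int
    polarity: Literal["plus", "minus"]

    def __post_init__(self) -> None:
        self.trace_nm = np.asarray(self.trace_nm, dtype=float).reshape(-1, 3)
        if self.n_pf not in PF_CLASSES:
            raise ValueError(f"protofilament count must be one of {PF_CLASSES}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")


@dataclass
class LuminalFilamentSpec:
    """A helical filament inside the lumen of a host microtubule.

    ``start_nm``/``end_nm`` are arc-length positions along the host axis;
    ``cofilin`` switches the outer decoration blobs on.
    """

    host: int
    start_nm: float
    end_nm: float
    symmetry: HelicalSymmetry = COFILACTIN
    polarity: Literal["plus", "minus"] = "plus"
    cofilin: bool = True

    def __post_init__(self) -> None:
        if not self.end_nm > self.start_nm:
            raise ValueError("end_nm must exceed start_nm")


@dataclass
class SceneSpec:
    microtubules: Sequence[MicrotubuleSpec] = field(default_factory=list)
    luminal_filaments: Sequence[LuminalFilamentSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    wedge_halfangle: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.luminal_filaments:
            if not 0 <= f.host < len(self.microtubules):
                raise ValueError(f"luminal filament host {f.host} out of range")
            mt = self.microtubules[f.host]
            mt_len = float(
                np.sum(np.linalg.norm(np.diff(mt.trace_nm, axis=0), axis=1))
            )
            if f.start_nm < 0 or f.end_nm > mt_len + 1e-9:
                raise ValueError(
                    "luminal filament axial extent must lie within its host microtubule"
                )


# ---------------------------------------------------------------------------
# blob stamping
# ---------------------------------------------------------------------------


def _stamp_blobs(
    grid: np.ndarray,
    apix: float,
    centers_ang: np.ndarray,
    sigma_ang: float,
    amplitude: float = 1.0,
) -> None:
    """Add isotropic 3D Gaussian blobs in place.

    Each blob is evaluated on its local +/- 4 sigma cube only, which keeps
    stamping linear in the number of subunits rather than in box volume.
    """
    if len(centers_ang) == 0:
        return
    box = np.array(grid.shape)  # (z, y, x)
    half = max(2, int(np.ceil(4.0 * sigma_ang / apix)))
    inv2s2 = 1.0 / (2.0 * sigma_ang**2)
    for cx, cy, cz in np.asarray(centers_ang, dtype=float):
        # voxel-space center, (z, y, x) order
        c = np.array([cz, cy, cx]) / apix
        lo = np.maximum(np.floor(c).astype(int) - half, 0)
        hi = np.minimum(np.floor(c).astype(int) + half + 2, box)
        if np.any(lo >= hi):
            continue
        zz = (np.arange(lo[0], hi[0]) - c[0]) ** 2
        yy = (np.arange(lo[1], hi[1]) - c[1]) ** 2
        xx = (np.arange(lo[2], hi[2]) - c[2]) ** 2
        r2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
        grid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (
            amplitude * np.exp(-r2 * apix**2 * inv2s2)
        ).astype(np.float32)


# ---------------------------------------------------------------------------
# filament renderers
# ---------------------------------------------------------------------------


def _helical_blob_layout(
    sym: HelicalSymmetry,
    n_subunits: int,
    decorated: bool,
    polar: bool,
    phase0: float = 0.0,
) -> list[tuple[np.ndarray, float, float]]:
    """Blob centers for one filament in its local frame (axis = +z).

    Returns a list of (centers (n,3) Angstrom, sigma, amplitude) groups.
    """
    lat = build_subunit_lattice(sym, n_subunits, RADIUS_ACTIN, phase0)
    groups: list[tuple[np.ndarray, float, float]] = [
        (lat.positions, SIGMA_ACTIN, 1.0)
    ]
    if polar:
        # small axial asymmetry: a lighter blob shifted along +z marks polarity
        marker = lat.positions + np.array([0.0, 0.0, POLARITY_OFFSET])
        groups.append((marker, SIGMA_ACTIN * 0.6, POLARITY_WEIGHT))
    if decorated:
        outer = build_subunit_lattice(sym, n_subunits, RADIUS_COFILIN, phase0)
        groups.append((outer.positions, SIGMA_COFILIN, 0.8))
    return groups


def render_helical_filament(
    sym: HelicalSymmetry,
    box: int,
    apix: float,
    decorated: bool = True,
    polar: bool = False,
    phase0: float = 0.0,
) -> DensityVolume:
    """Render one straight helical filament along z through the box center.

    Subunits span the full z extent of the box; used for symmetry-search
    and layer-line test objects.
    """
    grid = np.zeros((box, box, box), dtype=np.float32)
    n_sub = int(np.floor(box * apix / sym.rise_ang)) + 1
    center = (box * apix) / 2.0
    for centers, sigma, amp in _helical_blob_layout(
        sym, n_sub, decorated, polar, phase0
    ):
        shifted = centers + np.array([center, center, 0.0])
        _stamp_blobs(grid, apix, shifted, sigma, amp)
    return DensityVolume(grid, apix)


#: 180-degree rotation about the local x axis: reverses the lattice's axial
#: direction (proper rotation, so handedness is preserved)
_POLARITY_FLIP = np.diag([1.0, -1.0, -1.0])


def _render_microtubule(
    grid: np.ndarray,
    apix: float,
    mt: MicrotubuleSpec,
) -> float:
    """Stamp a microtubule: N protofilament tubes of tubulin blobs.

    Lattice approximation: protofilaments at center radius N*s/(2 pi) with
    lateral spacing s = 50 A, monomer spacing 40.95 A along each
    protofilament, inter-protofilament axial stagger 3*40.95/N (3-start);
    no seam.  Polarity is encoded by a light marker blob offset along the
    lattice plus direction; "minus" microtubules carry the whole local
    lattice rotated 180 deg about a perpendicular axis.
    """
    n = mt.n_pf
    radius = n * MT_LATERAL_SPACING / (2.0 * np.pi)
    trace = FilamentTrace(points=mt.trace_nm, id="mt", kind="microtubule")
    length_ang = trace.contour_length() * 10.0
    # frames every monomer row along the axis
    positions, frames = resample_trace(trace, MT_MONOMER_SPACING / 10.0)
    flip = np.eye(3) if mt.polarity == "plus" else _POLARITY_FLIP
    pf_az = 2.0 * np.pi * np.arange(n) / n
    stagger = 3.0 * MT_MONOMER_SPACING / n  # 3-start helix approximation
    tub_centers = []
    marker_centers = []
    marker = np.array([0.0, 0.0, POLARITY_OFFSET])
    for j, az in enumerate(pf_az):
        dz = (stagger * j) % MT_MONOMER_SPACING
        local = np.array([radius * np.cos(az), radius * np.sin(az), dz])
        for pos_nm, rot in zip(positions, frames):
            c = pos_nm * 10.0 + rot @ (flip @ local)
            tub_centers.append(c)
            marker_centers.append(pos_nm * 10.0 + rot @ (flip @ (local + marker)))
    _stamp_blobs(grid, apix, np.array(tub_centers), SIGMA_TUBULIN, 1.0)
    _stamp_blobs(
        grid, apix, np.array(marker_centers), SIGMA_TUBULIN * 0.6, POLARITY_WEIGHT
    )
    return length_ang


def _render_luminal(
    grid: np.ndarray,
    apix: float,
    spec: LuminalFilamentSpec,
    host: MicrotubuleSpec,
) -> None:
    """Stamp a luminal filament along the host axis between start and end."""
    trace = FilamentTrace(points=host.trace_nm, id="host", kind="microtubule")
    spacing_nm = spec.symmetry.rise_ang / 10.0
    positions, frames = resample_trace(trace, spacing_nm)
    arc = np.arange(len(positions)) * spacing_nm
    keep = (arc >= spec.start_nm) & (arc <= spec.end_nm)
    positions, frames = positions[keep], frames[keep]
    n_sub = len(positions)
    if n_sub == 0:
        return
    flip = np.eye(3) if spec.polarity == "plus" else _POLARITY_FLIP
    lat = build_subunit_lattice(spec.symmetry, n_sub, RADIUS_ACTIN)
    local_actin = lat.positions.copy()
    local_actin[:, 2] = 0.0  # axial placement comes from the resampled frames
    groups = [(local_actin, SIGMA_ACTIN, 1.0)]
    marker = local_actin + np.array([0.0, 0.0, POLARITY_OFFSET])
    groups.append((marker, SIGMA_ACTIN * 0.6, POLARITY_WEIGHT))
    if spec.cofilin:
        outer = build_subunit_lattice(spec.symmetry, n_sub, RADIUS_COFILIN)
        local_cof = outer.positions.copy()
        local_cof[:, 2] = 0.0
        groups.append((local_cof, SIGMA_COFILIN, 0.8))
    for local, sigma, amp in groups:
        centers = np.array(
            [p * 10.0 + r @ flip @ l for p, r, l in zip(positions, frames, local)]
        )
        _stamp_blobs(grid, apix, centers, sigma, amp)


# ---------------------------------------------------------------------------
# corruption: noise + missing wedge
# ---------------------------------------------------------------------------


def apply_missing_wedge(
    grid: np.ndarray, wedge_halfangle: float = 60.0
) -> np.ndarray:
    """Zero the tomographic missing wedge in Fourier space.

    Single tilt axis along y: a frequency (kx, ky, kz) is retained iff the
    angle of its (kx, kz) component from the x-y plane is at most
    ``wedge_halfangle`` degrees (the +/-60 deg tilt range of acquisition).
    The mask depends only on |kx|, |kz| and is therefore Hermitian
    symmetric: the corrupted volume stays real.
    """
    if not 0.0 < wedge_halfangle <= 90.0:
        raise ValueError("wedge_halfangle must lie in (0, 90] degrees")
    nz, ny, nx = grid.shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    angle = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
    mask = (angle <= wedge_halfangle) | ((kz == 0) & (kx == 0))
    ft = np.fft.fftn(grid)
    out = np.fft.ifftn(ft * mask)
    return np.real(out).astype(np.float32)


def render_scene(
    spec: SceneSpec, box: int = 96, apix: float = 11.81
) -> tuple[DensityVolume, dict[str, pd.DataFrame]]:
    """Render a full scene with ground truth.

    Returns the corrupted volume plus ground-truth tables:

    ``microtubules`` — id, n_pf, polarity, length_nm
    ``luminal``      — id, host_mt, start/end/length_nm, twist/rise, polarity,
                       cofilin flag
    ``traces``       — filament id, kind, point index, x/y/z in nm
    """
    grid = np.zeros((box, box, box), dtype=np.float32)
    margin = 2 * apix / 10.0  # nm
    extent = box * apix / 10.0
    rows_mt, rows_lum, rows_tr = [], [], []
    for i, mt in enumerate(spec.microtubules):
        pts = mt.trace_nm
        if np.any(pts < margin) or np.any(pts > extent - margin):
            raise ValueError(f"microtubule {i} does not fit in the box with margin")
        length_ang = _render_microtubule(grid, apix, mt)
        rows_mt.append(
            {
                "mt_id": i,
                "n_pf": mt.n_pf,
                "polarity": mt.polarity,
                "length_nm": length_ang / 10.0,
            }
        )
        for j, p in enumerate(pts):
            rows_tr.append(
                {"filament_id": f"mt{i}", "kind": "microtubule", "point": j,
                 "x_nm": p[0], "y_nm": p[1], "z_nm": p[2]}
            )
    from .trace import _arc_interpolate

    for i, lf in enumerate(spec.luminal_filaments):
        _render_luminal(grid, apix, lf, spec.microtubules[lf.host])
        host_pts = spec.microtubules[lf.host].trace_nm
        arc = np.linspace(lf.start_nm, lf.end_nm, 5)
        for j, p in enumerate(_arc_interpolate(host_pts, arc)):
            rows_tr.append(
                {"filament_id": f"lf{i}", "kind": "luminal", "point": j,
                 "x_nm": p[0], "y_nm": p[1], "z_nm": p[2]}
            )
        rows_lum.append(
            {
                "filament_id": i,
                "host_mt": lf.host,
                "start_nm": lf.start_nm,
                "end_nm": lf.end_nm,
                "length_nm": lf.end_nm - lf.start_nm,
                "twist_deg": lf.symmetry.twist_deg,
                "rise_ang": lf.symmetry.rise_ang,
                "polarity": lf.polarity,
                "cofilin": lf.cofilin,
            }
        )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        peak = float(grid.max()) if grid.max() > 0 else 1.0
        grid = grid + rng.normal(
            0.0, spec.noise_sigma * peak, grid.shape
        ).astype(np.float32)
        grid = apply_missing_wedge(grid, spec.wedge_halfangle)
    elif spec.microtubules or spec.luminal_filaments:
        grid = apply_missing_wedge(grid, spec.wedge_halfangle)
    truth = {
        "microtubules": pd.DataFrame(rows_mt),
        "luminal": pd.DataFrame(rows_lum),
        "traces": pd.DataFrame(rows_tr),
    }
    return DensityVolume(grid, apix), truth


# ---------------------------------------------------------------------------
# classification-vote simulation
# ---------------------------------------------------------------------------


@dataclass
class VoteSimSpec:
    """Statistical stand-in for multireference-alignment output.

    ``class_fractions`` maps (n_pf, polarity) to the probability that a
    filament truly belongs to that class; each particle votes for its
    filament's true class with probability ``p_correct`` and otherwise
    uniformly among the remaining classes.  Cross-correlation scores are
    class-conditional normals truncated at 0.
    """

    class_fractions: dict[tuple[int, str], float]
    n_filaments: int = 544
    particles_per_filament: int = 40
    p_correct: float = 0.85
    cc_correct: tuple[float, float] = (0.15, 0.03)
    cc_wrong: tuple[float, float] = (0.10, 0.03)
    filaments_per_protrusion: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must lie in [0, 1]")
        if self.particles_per_filament < 1:
            raise ValueError("particles_per_filament must be >= 1")
        if self.n_filaments < 1:
            raise ValueError("n_filaments must be >= 1")


def fractions_over_pf(pf_fractions: dict[int, float]) -> dict[tuple[int, str], float]:
    """Expand per-protofilament-number fractions to (N, polarity) classes,
    splitting each equally between the two polarities."""
    return {
        (n, pol): f / 2.0 for n, f in pf_fractions.items() for pol in POLARITIES
    }


def simulate_vote_table(spec: VoteSimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a particle table and its filament-level ground truth.

    The returned particle table carries the columns the vote caller needs
    (particle/filament/protrusion ids, positions nm, ZYZ Euler angles,
    class_n, class_polarity, cc, subset); truth carries one row per
    filament with its generating class.
    """
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_fractions.keys())
    probs = np.array([spec.class_fractions[c] for c in classes])
    true_idx = rng.choice(len(classes), size=spec.n_filaments, p=probs)
    m = spec.particles_per_filament
    n_total = spec.n_filaments * m

    fil_ids = np.repeat(np.arange(spec.n_filaments), m)
    true_per_particle = true_idx[fil_ids]
    correct = rng.random(n_total) < spec.p_correct
    votes = true_per_particle.copy()
    n_cls = len(classes)
    if n_cls > 1:
        wrong = ~correct
        # uniform over the remaining classes
        offs = rng.integers(1, n_cls, size=wrong.sum())
        votes[wrong] = (true_per_particle[wrong] + offs) % n_cls
    else:
        correct[:] = True
    mu = np.where(correct, spec.cc_correct[0], spec.cc_wrong[0])
    sd = np.where(correct, spec.cc_correct[1], spec.cc_wrong[1])
    cc = np.maximum(rng.normal(mu, sd), 0.0)

    # straight filaments along x, particles every 8 nm, identity orientations
    within = np.tile(np.arange(m), spec.n_filaments)
    table = pd.DataFrame(
        {
            "particle_id": np.arange(n_total),
            "filament_id": fil_ids,
            "protrusion_id": fil_ids // spec.filaments_per_protrusion,
            "x_nm": within * 8.0,
            "y_nm": fil_ids * 30.0,
            "z_nm": np.zeros(n_total),
            "rot": np.zeros(n_total),
            "tilt": np.zeros(n_total),
            "psi": np.zeros(n_total),
            "class_n": [classes[v][0] for v in votes],
            "class_polarity": [classes[v][1] for v in votes],
            "cc": cc,
            "subset": (fil_ids % 2) + 1,  # whole filaments share a half-set
        }
    )
    truth = pd.DataFrame(
        {
            "filament_id": np.arange(spec.n_filaments),
            "true_n": [classes[t][0] for t in true_idx],
            "true_polarity": [classes[t][1] for t in true_idx],
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# morphology particle simulation (2D side-view projections)
# ---------------------------------------------------------------------------

MORPHOLOGIES = ("cofilactin", "f-actin", "other")


def _project_filament_image(
    sym: HelicalSymmetry | None,
    decorated: bool,
    box: int,
    apix: float,
    phase0: float,
) -> np.ndarray:
    """Noise-free side-view projection (axis vertical) of a segment.

    Projection of an isotropic 3D Gaussian along the viewing axis is a 2D
    Gaussian of the same sigma, so the image is built directly from the
    lattice's (y, z) coordinates.  ``sym=None`` renders the featureless
    rod used for the "other" morphology.
    """
    img = np.zeros((box, box), dtype=np.float32)
    extent = box * apix
    if sym is None:
        n_sub = int(extent / 27.5) + 1
        groups = [
            (np.column_stack(
                [np.zeros(n_sub), np.zeros(n_sub), np.arange(n_sub) * 27.5]
            ), SIGMA_ACTIN, 1.0)
        ]
    else:
        n_sub = int(extent / sym.rise_ang) + 1
        groups = _helical_blob_layout(sym, n_sub, decorated, polar=False,
                                      phase0=phase0)
    zz = np.arange(box)[:, None]
    yy = np.arange(box)[None, :]
    for centers, sigma, amp in groups:
        inv2s2 = apix**2 / (2.0 * sigma**2)
        for _, cy, cz in centers:
            img += amp * np.exp(
                -((zz - cz / apix) ** 2 + (yy - (cy + extent / 2) / apix) ** 2)
                * inv2s2
            )
    return img


def morphology_template(
    morphology: str, box: int = 64, apix: float = 5.9, phase0: float = 0.0
) -> np.ndarray:
    """Noise-free reference projection for one morphology class."""
    if morphology == "cofilactin":
        return _project_filament_image(COFILACTIN, True, box, apix, phase0)
    if morphology == "f-actin":
        return _project_filament_image(F_ACTIN, False, box, apix, phase0)
    if morphology == "other":
        return _project_filament_image(None, False, box, apix, phase0)
    raise ValueError(f"unknown morphology {morphology!r}")


def simulate_morphology_set(
    composition: Sequence[float],
    n: int,
    snr: float = 10.0,
    seed: int = 0,
    box: int = 64,
    apix: float = 5.9,
    condition: str = "control",
    n_replicates: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate side-view particle projections of the three morphologies.

    ``composition`` gives (cofilactin, f-actin, other) probabilities; the
    helical phase of each particle is uniform, so particles of one
    morphology differ by the axial position of the cross-over pattern.
    Noise sd = signal peak / snr.  Returns (images (n, box, box), metadata
    with truth labels, condition and replicate).
    """
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (3,) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 3 probabilities summing to 1")
    if n == 0:
        return np.zeros((0, box, box), dtype=np.float32), pd.DataFrame(
            columns=["particle_id", "morphology", "condition", "replicate"]
        )
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n, p=comp)
    phases = rng.uniform(0.0, 360.0, size=n)
    images = np.empty((n, box, box), dtype=np.float32)
    for i in range(n):
        img = morphology_template(MORPHOLOGIES[labels[i]], box, apix, phases[i])
        peak = float(img.max()) if img.max() > 0 else 1.0
        if np.isfinite(snr):
            img = img + rng.normal(0.0, peak / snr, img.shape).astype(np.float32)
        images[i] = img
    meta = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "morphology": [MORPHOLOGIES[k] for k in labels],
            "condition": condition,
            "replicate": (np.arange(n) % n_replicates) + 1,
        }
    )
    return images, meta
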