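"""File formats and configuration.

Volumes travel as MRC mode-2 (32-bit float) maps with the voxel size in
the header; particle tables as STAR files (one data block with a loop of
named ``_rln``-style columns) or plain TSV; traces as plain-text point
files (see :mod:`mtlumen.trace`); configuration as a flat key=value text
file.  STAR/CIF and CCP4/MRC parsing is delegated to gemmi.

Unit conventions at the I/O boundary: trace coordinates and filament
lengths are nm; voxel sizes, helical rises and resolutions are Angstrom.
Column headers carry the unit suffix (``x_nm``, ``rise_ang``) so the two
scales cannot be mixed silently.  Voxel indexing is 0-based everywhere.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .synth import DensityVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_particles",
    "write_particles",
    "PipelineConfig",
    "read_config",
    "write_config",
    "log_invocation",
]

logger = logging.getLogger("mtlumen")

#: canonical STAR column names for the particle-table fields
_STAR_COLUMNS = {
    "x_nm": "_mtCoordinateXnm",
    "y_nm": "_mtCoordinateYnm",
    "z_nm": "_mtCoordinateZnm",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
    "class_n": "_mtClassProtofilaments",
    "class_polarity": "_mtClassPolarity",
    "cc": "_mtCrossCorrelation",
    "particle_id": "_mtParticleId",
    "filament_id": "_mtFilamentId",
    "protrusion_id": "_mtProtrusionId",
    "subset": "_rlnRandomSubset",
}
_STAR_REVERSE = {v: k for k, v in _STAR_COLUMNS.items()}

REQUIRED_PARTICLE_COLUMNS = (
    "particle_id",
    "filament_id",
    "x_nm",
    "y_nm",
    "z_nm",
    "rot",
    "tilt",
    "psi",
    "class_n",
    "class_polarity",
    "cc",
)


# ---------------------------------------------------------------------------
# MRC volumes
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> DensityVolume:
    """Read an MRC mode-2 volume; cubic float maps only."""
    try:
        m = gemmi.read_ccp4_map(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on truncation
        raise ValueError(f"cannot parse MRC file {path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode != 2:
        raise ValueError(f"unsupported MRC mode {mode} (header word 4); need mode 2")
    grid = np.array(m.grid, copy=True).astype(np.float32)
    if len(set(grid.shape)) != 1:
        raise ValueError(
            f"non-cubic volume {grid.shape} (header words 1-3 NX/NY/NZ differ)"
        )
    sp = m.grid.spacing
    if max(sp) - min(sp) > 1e-4:
        raise ValueError(f"anisotropic voxel size {sp} in unit-cell header")
    return DensityVolume(grid, apix=float(sp[0]))


def write_volume(vol: DensityVolume, path: str | Path) -> None:
    """Write a volume as MRC mode 2, voxel size in the cell header."""
    g = gemmi.FloatGrid(np.ascontiguousarray(vol.grid, dtype=np.float32))
    side = vol.box * vol.apix
    g.set_unit_cell(gemmi.UnitCell(side, side, side, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# particle tables: STAR and TSV
# ---------------------------------------------------------------------------

_INT_COLUMNS = {"particle_id", "filament_id", "protrusion_id", "class_n", "subset"}


def _finalize_types(df: pd.DataFrame) -> pd.DataFrame:
    for c in df.columns:
        if c in _INT_COLUMNS:
            try:
                df[c] = df[c].astype(int)
                continue
            except (ValueError, TypeError):
                pass
        if c not in ("class_polarity",):
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError):
                pass
    return df


def read_particles(path: str | Path) -> pd.DataFrame:
    """Read a particle table from STAR (.star) or TSV.

    Missing required columns raise with the offending names listed; extra
    columns are passed through untouched.
    """
    path = Path(path)
    if path.suffix.lower() == ".star":
        doc = gemmi.cif.read_file(str(path))
        block = doc[0]
        data: dict[str, list[str]] = {}
        for item in block:
            if item.loop is not None:
                loop = item.loop
                w = loop.width()
                vals = loop.values
                for i, tag in enumerate(loop.tags):
                    col = _STAR_REVERSE.get(tag, tag.lstrip("_"))
                    data[col] = vals[i::w] if w else []
        df = pd.DataFrame(data)
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_PARTICLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"particle table {path} missing required columns: {missing}")
    return _finalize_types(df)


def write_particles(table: pd.DataFrame, path: str | Path) -> None:
    """Write a particle table as STAR (.star) or TSV, preserving columns
    and row order."""
    path = Path(path)
    if path.suffix.lower() == ".star":
        doc = gemmi.cif.Document()
        block = doc.add_new_block("particles")
        tags = [_STAR_COLUMNS.get(c, f"_{c}") for c in table.columns]
        loop = block.init_loop("", tags)
        for _, row in table.iterrows():
            loop.add_row([_star_value(v) for v in row])
        doc.write_file(str(path))
    else:
        table.to_csv(path, sep="\t", index=False)


def _star_value(v: object) -> str:
    if isinstance(v, float):
        return f"{v:.6f}"
    s = str(v)
    return gemmi.cif.quote(s) if (" " in s or s == "") else s


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Flat pipeline configuration, serializable to key=value text."""

    seed: int = 0
    verbosity: str = "info"
    # vote caller
    keep_fraction: float = 0.80
    f_major: float = 0.65
    f_minor: float = 0.50
    cc_min: float = 0.13
    cc_stat: str = "mean"
    clean_scope: str = "global"
    # trace / containment
    lumen_radius_nm: float = 8.0
    mt_particle_spacing_nm: float = 8.0
    luminal_particle_spacing_nm: float = 6.0
    # fourier
    mask_diameter_nm: float = 28.0
    fft_box: int = 512
    bin_to: int = 256
    twist_min: float = -200.0
    twist_max: float = -100.0
    rise_min: float = 1.0
    rise_max: float = 40.0
    outer_diameter_ang: float = 120.0
    fsc_threshold: float = 0.143
    # synthesis
    apix: float = 11.81
    wedge_halfangle: float = 60.0

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        return "\n".join(lines) + "\n"

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(cfg.to_text())


def read_config(path: str | Path) -> PipelineConfig:
    """Parse a key=value config file; unknown keys are rejected."""
    known = {f.name: f.type for f in fields(PipelineConfig)}
    kwargs: dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line (need 'key = value'): {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(PipelineConfig(), key)
        kwargs[key] = type(current)(val) if not isinstance(current, str) else val
    return PipelineConfig(**kwargs)


def log_invocation(command: str, cfg: PipelineConfig) -> None:
    """Record config hash, seed and package version for reproducibility."""
    from . import __version__

    logger.info(
        "%s: config=%s seed=%d version=%s",
        command, cfg.digest(), cfg.seed, __version__,
    )
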