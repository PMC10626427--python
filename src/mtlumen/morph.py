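"""Morphology discrimination of luminal-filament particles.

Cofilin decoration changes an actin filament in two visible ways: the
filament gets wider (outer cofilin density) and its helical cross-over
gets shorter (twist -162 deg vs -167 deg for bare F-actin).  Experimental
pipelines separate the two by repeated 3D classification; here a
template-correlation surrogate does the same job on projection images:

* ``classify_by_template`` labels each particle by its best normalized
  cross-correlation against phase banks of the three reference
  projections (cofilactin / f-actin / other).

* ``run_classification`` emulates one classification run: particles are
  clustered into the run's class count by seeded k-means on their log
  power spectra (phase-invariant, so a class collects one morphology
  rather than one helical phase), and each class is mapped to a
  morphology automatically from its members' template labels.

* ``consensus_percentages`` averages per-condition/replicate morphology
  percentages over a set of runs (default protocol: 9 runs = class counts
  {5, 10, 20} x reference twists {-162, -165, -167} deg).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .synth import MORPHOLOGIES, morphology_template

__all__ = [
    "RunConfig",
    "MorphologyRunSet",
    "default_run_configs",
    "template_bank",
    "classify_by_template",
    "run_classification",
    "consensus_percentages",
]


@dataclass(frozen=True)
class RunConfig:
    """One classification run: class count and reference twist (deg)."""

    n_classes: int
    reference_twist: float

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


def default_run_configs() -> list[RunConfig]:
    """The nine-run protocol: {5, 10, 20} classes x {-162, -165, -167} deg."""
    return [
        RunConfig(k, t) for k in (5, 10, 20) for t in (-162.0, -165.0, -167.0)
    ]


@dataclass
class MorphologyRunSet:
    """Per-run class assignments and class->morphology maps over one
    particle set."""

    runs: list[RunConfig]
    assignments: list[np.ndarray]  # per run: class index per particle
    class_maps: list[dict[int, str]]  # per run: class -> morphology
    meta: pd.DataFrame  # particle_id, condition, replicate


def template_bank(
    box: int, apix: float, n_phases: int = 12
) -> dict[str, np.ndarray]:
    """Noise-free reference projections at ``n_phases`` helical phases.

    Returns {morphology: (n_phases, box, box)} with each image normalized
    to zero mean / unit norm, ready for NCC.
    """
    bank = {}
    for morph in MORPHOLOGIES:
        imgs = np.stack(
            [
                _normalize(morphology_template(morph, box, apix, phase))
                for phase in np.linspace(0.0, 360.0, n_phases, endpoint=False)
            ]
        )
        bank[morph] = imgs
    return bank


def _normalize(img: np.ndarray) -> np.ndarray:
    flat = img.astype(np.float64) - img.mean()
    norm = np.linalg.norm(flat)
    return flat / norm if norm > 0 else flat


def _ncc_to_bank(img: np.ndarray, bank: dict[str, np.ndarray]) -> dict[str, float]:
    """Max normalized cross-correlation over each morphology's phase bank."""
    x = _normalize(img)
    return {
        morph: float(np.max(np.tensordot(refs, x, axes=([1, 2], [0, 1]))))
        for morph, refs in bank.items()
    }


def classify_by_template(
    particles: np.ndarray,
    bank: dict[str, np.ndarray] | None = None,
    apix: float = 5.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Label each particle image by its best-matching morphology template.

    ``particles`` is (n, box, box); the template bank must share the grid.
    Returns (labels (n,) str array, winning correlation scores (n,)).
    """
    if particles.ndim != 3:
        raise ValueError("particles must be a (n, box, box) image stack")
    box = particles.shape[1]
    if bank is None:
        bank = template_bank(box, apix)
    ref_shape = next(iter(bank.values())).shape[1:]
    if ref_shape != particles.shape[1:]:
        raise ValueError(
            f"grid mismatch: particles {particles.shape[1:]} vs templates {ref_shape}"
        )
    labels = np.empty(len(particles), dtype=object)
    scores = np.empty(len(particles))
    for i, img in enumerate(particles):
        ncc = _ncc_to_bank(img, bank)
        labels[i] = max(ncc, key=ncc.get)
        scores[i] = ncc[labels[i]]
    return labels, scores


def run_classification(
    particles: np.ndarray,
    config: RunConfig,
    bank: dict[str, np.ndarray],
    seed: int = 0,
    class_map_method: str = "majority",
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[int, str]]:
    """One surrogate classification run.

    Particles are clustered into ``config.n_classes`` classes by k-means
    on their log power spectra (seeded from ``seed`` and the run
    configuration, which is where run-to-run variability of the consensus
    comes from).  Each class is then mapped to a morphology
    automatically: by the majority of its members' per-particle template
    labels (default), or by correlating the class average against the
    templates (``class_map_method="average"``; phase-mixed classes smear
    the average, so majority is the more reliable mapping).
    """
    n = len(particles)
    k = min(config.n_classes, n)
    run_seed = (seed * 1_000_003 + config.n_classes * 101
                + int(round(-config.reference_twist))) % (2**31 - 1)
    feats = np.log1p(
        np.abs(np.fft.rfft2(particles.astype(np.float64))) ** 2
    ).reshape(n, -1)
    km = KMeans(n_clusters=k, n_init=4, random_state=run_seed)
    assign = km.fit_predict(feats)
    if class_map_method == "majority":
        if labels is None:
            labels, _ = classify_by_template(particles, bank)
    elif class_map_method != "average":
        raise ValueError("class_map_method must be 'majority' or 'average'")
    class_map = {}
    for c in range(k):
        sel = assign == c
        if sel.sum() == 0:
            class_map[c] = "other"
            continue
        if class_map_method == "majority":
            vals, counts = np.unique(labels[sel], return_counts=True)
            class_map[c] = str(vals[np.argmax(counts)])
        else:
            ncc = _ncc_to_bank(particles[sel].mean(axis=0), bank)
            class_map[c] = max(ncc, key=ncc.get)
    return assign, class_map


def build_runset(
    particles: np.ndarray,
    meta: pd.DataFrame,
    configs: Sequence[RunConfig] | None = None,
    apix: float = 5.9,
    seed: int = 0,
) -> MorphologyRunSet:
    """Run the full multi-run protocol on one particle set."""
    configs = list(configs) if configs is not None else default_run_configs()
    bank = template_bank(particles.shape[1], apix)
    labels, _ = classify_by_template(particles, bank)
    assignments, class_maps = [], []
    for cfg in configs:
        assign, cmap = run_classification(particles, cfg, bank, seed, labels=labels)
        assignments.append(assign)
        class_maps.append(cmap)
    return MorphologyRunSet(configs, assignments, class_maps, meta.copy())


def consensus_percentages(runset: MorphologyRunSet) -> pd.DataFrame:
    """Mean +/- s.d. morphology percentages across runs, per condition and
    replicate.

    Within each run the three morphology percentages sum to 100; the s.d.
    column is the run-to-run sample s.d. (0 when all runs agree).
    """
    n = len(runset.meta)
    for assign in runset.assignments:
        if len(assign) != n:
            raise ValueError("every run must cover the same particle set")
    rows = []
    for run_idx, (assign, cmap) in enumerate(
        zip(runset.assignments, runset.class_maps)
    ):
        morph_per_particle = pd.Series(
            [cmap[int(c)] for c in assign], index=runset.meta.index
        )
        df = runset.meta.assign(morphology=morph_per_particle)
        for (cond, rep), g in df.groupby(["condition", "replicate"], sort=True):
            counts = g["morphology"].value_counts()
            for morph in MORPHOLOGIES:
                rows.append(
                    {
                        "run": run_idx,
                        "condition": cond,
                        "replicate": rep,
                        "morphology": morph,
                        "percent": 100.0 * counts.get(morph, 0) / len(g),
                    }
                )
    per_run = pd.DataFrame(rows)
    out = (
        per_run.groupby(["condition", "replicate", "morphology"], sort=True)["percent"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "mean_percent", "std": "sd_percent"})
    )
    return out
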