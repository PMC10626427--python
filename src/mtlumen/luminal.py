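"""Luminal-filament quantifications.

Given microtubules and the luminal filaments mapped into them, this module
computes the summary statistics reported per biological replicate:
occupancy (fraction of microtubules hosting at least one filament),
coverage (summed filament length over microtubule length), orientation
concordance (fraction of filaments whose barbed end points towards the
microtubule plus end), and the fraction of total filament length with
cofilactin morphology.  Technical replicates are pooled before
percentages; biological replicates are summarized as mean +/- sample s.d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LuminalRecord",
    "occupancy",
    "coverage_fraction",
    "orientation_concordance",
    "morphology_length_fraction",
    "replicate_summary",
    "records_to_frame",
]


@dataclass
class LuminalRecord:
    """One luminal filament mapped to its host microtubule.

    ``orientation`` is the direction of the filament's barbed (plus) end
    along the host axis: "towards-plus" | "towards-minus" | None if
    unresolved.  ``segments`` is a list of (morphology, length_nm) pieces
    for filaments that change morphology along their length; a uniform
    filament has a single segment.
    """

    filament_id: object
    host_mt: object
    length_nm: float
    orientation: str | None = None
    segments: Sequence[tuple[str, float]] = ()
    replicate: object = 1
    condition: str = "control"

    def __post_init__(self) -> None:
        if not self.length_nm > 0:
            raise ValueError("filament length must be positive")
        if self.host_mt is None:
            raise ValueError("record requires an assigned host microtubule")
        if not self.segments:
            self.segments = (("cofilactin", self.length_nm),)


def records_to_frame(records: Sequence[LuminalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "filament_id": [r.filament_id for r in records],
            "host_mt": [r.host_mt for r in records],
            "length_nm": [r.length_nm for r in records],
            "orientation": [r.orientation for r in records],
            "replicate": [r.replicate for r in records],
            "condition": [r.condition for r in records],
        }
    )


def occupancy(
    microtubules: pd.DataFrame,
    records: Sequence[LuminalRecord] | pd.DataFrame,
    group_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Percentage of microtubules containing at least one luminal filament.

    ``microtubules`` needs an ``mt_id`` column plus any grouping columns;
    a microtubule hosting several filaments counts once.  Groups with no
    microtubules are flagged with NaN.
    """
    recs = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if "mt_id" not in microtubules.columns:
        raise ValueError("microtubule table needs an mt_id column")
    unknown = set(recs["host_mt"]) - set(microtubules["mt_id"])
    if unknown:
        raise ValueError(f"records reference unknown microtubules: {sorted(unknown)[:5]}")
    occupied = set(recs["host_mt"])
    mts = microtubules.copy()
    mts["occupied"] = mts["mt_id"].isin(occupied)
    if not group_cols:
        n = len(mts)
        pct = 100.0 * mts["occupied"].sum() / n if n else np.nan
        return pd.DataFrame(
            [{"n_microtubules": n, "n_occupied": int(mts["occupied"].sum()),
              "occupancy_percent": pct}]
        )
    rows = []
    for key, g in mts.groupby(list(group_cols), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(g)
        rows.append(
            dict(zip(group_cols, key))
            | {
                "n_microtubules": n,
                "n_occupied": int(g["occupied"].sum()),
                "occupancy_percent": 100.0 * g["occupied"].sum() / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def coverage_fraction(mt_length_nm: float, filament_lengths_nm: Sequence[float]) -> float:
    """Fraction of a microtubule's length covered by its luminal filaments.

    Multiple filaments are summed before division; 0 with no filaments and
    1 for full coverage.  A sum exceeding the microtubule length by more
    than 5 % indicates a tracing inconsistency: warned and clamped to 1.
    """
    if not mt_length_nm > 0:
        raise ValueError("microtubule length must be positive")
    total = float(np.sum(filament_lengths_nm)) if len(filament_lengths_nm) else 0.0
    frac = total / mt_length_nm
    if frac > 1.05:
        warnings.warn(
            f"luminal filament length {total:.1f} nm exceeds microtubule "
            f"length {mt_length_nm:.1f} nm by more than 5%; clamping coverage to 1",
            stacklevel=2,
        )
    return min(1.0, frac)


def orientation_concordance(
    records: Sequence[LuminalRecord] | pd.DataFrame,
) -> tuple[float, int]:
    """Fraction of luminal filaments with barbed end towards the
    microtubule plus end, among records with resolved orientation.

    Returns (fraction, n resolved); raises if no record is resolved.
    """
    recs = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    resolved = recs[recs["orientation"].isin(["towards-plus", "towards-minus"])]
    if len(resolved) == 0:
        raise ValueError("no records with resolved orientation")
    frac = float((resolved["orientation"] == "towards-plus").mean())
    return frac, int(len(resolved))


def morphology_length_fraction(
    records: Sequence[LuminalRecord],
    group_cols: tuple[str, ...] = ("replicate",),
    morphology: str = "cofilactin",
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Percent of total luminal-filament length with the given morphology.

    Per group: 100 * sum(matching segment lengths) / sum(all segment
    lengths); then mean +/- sample s.d. across groups.  Groups with zero
    total length raise.
    """
    rows = []
    for r in records:
        for morph, ln in r.segments:
            rows.append(
                {"replicate": r.replicate, "condition": r.condition,
                 "morphology": morph, "length_nm": float(ln)}
            )
    seg = pd.DataFrame(rows)
    out = []
    group_iter = seg.groupby(list(group_cols), sort=True) if group_cols else [((), seg)]
    for key, g in group_iter:
        key = key if isinstance(key, tuple) else (key,)
        total = g["length_nm"].sum()
        if total <= 0:
            raise ValueError(f"zero total filament length in group {key}")
        pct = 100.0 * g.loc[g["morphology"] == morphology, "length_nm"].sum() / total
        out.append(dict(zip(group_cols, key)) | {"percent": pct, "total_nm": total})
    per_group = pd.DataFrame(out)
    mean, sd = replicate_summary(per_group["percent"].to_numpy())
    return per_group, (mean, sd)


def replicate_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample s.d. (n-1) across replicates.

    With a single replicate the s.d. is undefined and reported as NaN.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one replicate")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    return mean, sd
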