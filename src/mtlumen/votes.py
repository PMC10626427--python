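"""Per-filament classification-vote calling.

Multireference subtomogram alignment leaves each particle with a class
label (protofilament number 12-15 x polarity) and a cross-correlation (CC)
score.  Microtubules are then called filament by filament:

1. the particle table is cleaned by retaining the best-scoring 80 % of
   particles (globally across the table);
2. a filament is assigned to its modal class if at least 65 % of its
   retained particles voted for it, or if at least 50 % did and the
   filament's overall CC score is at least 0.13; otherwise it remains
   undetermined and is excluded from all downstream quantifications;
3. particles of minus-called filaments are rotated 180 deg about the
   second Euler angle so all filaments share one polarity;
4. protrusion-level summaries (orientation uniformity, protofilament
   mixing) and per-replicate protofilament-number distributions follow.

"Overall cross-correlation score" is taken as the mean CC of the
filament's retained particles (median available via ``cc_stat``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .helix import EulerTriplet, flip_polarity

__all__ = [
    "AssignmentRule",
    "FilamentCall",
    "clean_by_cc",
    "call_filament",
    "call_table",
    "summarize_protrusions",
    "unify_polarity",
    "pf_distribution",
]

REQUIRED_COLUMNS = (
    "particle_id",
    "filament_id",
    "class_n",
    "class_polarity",
    "cc",
)


@dataclass(frozen=True)
class AssignmentRule:
    """Thresholds of the cleaning + assignment procedure."""

    keep_fraction: float = 0.80
    f_major: float = 0.65
    f_minor: float = 0.50
    cc_min: float = 0.13
    cc_stat: Literal["mean", "median"] = "mean"
    clean_scope: Literal["global", "per-filament"] = "global"

    def __post_init__(self) -> None:
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must lie in (0, 1]")
        if not 0.5 <= self.f_minor <= self.f_major <= 1.0:
            raise ValueError("need 0.5 <= f_minor <= f_major <= 1")


@dataclass(frozen=True)
class FilamentCall:
    """Outcome of calling one filament."""

    filament_id: object
    assigned: bool
    n_pf: int | None = None
    polarity: str | None = None
    winning_fraction: float = 0.0
    mean_cc: float = float("nan")

    def __post_init__(self) -> None:
        if not self.assigned and (self.n_pf is not None or self.polarity is not None):
            raise ValueError("undetermined call cannot carry a class")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"particle table missing required columns: {missing}")


def clean_by_cc(table: pd.DataFrame, rule: AssignmentRule = AssignmentRule()) -> pd.DataFrame:
    """Retain the top ``ceil(keep_fraction * n)`` particles by CC score.

    Applied globally across the table by default (``clean_scope``
    "per-filament" cleans within each filament instead).  Equal scores at
    the retention boundary are resolved deterministically: among ties the
    lowest particle ids are dropped first.
    """
    _check_table(table)
    if len(table) == 0:
        raise ValueError("cannot clean an empty particle table")

    def _top(df: pd.DataFrame) -> pd.DataFrame:
        k = math.ceil(rule.keep_fraction * len(df))
        order = df.sort_values(
            ["cc", "particle_id"], ascending=[False, False], kind="mergesort"
        )
        return order.iloc[:k]

    if rule.clean_scope == "global":
        kept = _top(table)
    else:
        kept = pd.concat(
            [_top(g) for _, g in table.groupby("filament_id", sort=False)]
        )
    return kept.sort_index()


def call_filament(
    particles: pd.DataFrame, rule: AssignmentRule = AssignmentRule()
) -> FilamentCall:
    """Call one filament from its retained particles' votes.

    The winning class is the modal (protofilament number, polarity) label;
    the filament is assigned iff the winning fraction reaches ``f_major``,
    or reaches ``f_minor`` while the filament's overall CC score is at
    least ``cc_min``.  Exact modal ties yield an undetermined call.
    """
    fid = particles["filament_id"].iloc[0] if len(particles) else None
    if len(particles) == 0:
        return FilamentCall(fid, assigned=False)
    votes = particles.groupby(["class_n", "class_polarity"], sort=True).size()
    top = votes.max()
    winners = votes[votes == top]
    frac = float(top) / float(len(particles))
    stat = np.mean if rule.cc_stat == "mean" else np.median
    cc_overall = float(stat(particles["cc"].to_numpy()))
    if len(winners) > 1:  # modal tie: neither criterion can pick a class
        return FilamentCall(fid, assigned=False, winning_fraction=frac, mean_cc=cc_overall)
    (n_pf, polarity) = winners.index[0]
    ok = frac >= rule.f_major or (frac >= rule.f_minor and cc_overall >= rule.cc_min)
    if not ok:
        return FilamentCall(fid, assigned=False, winning_fraction=frac, mean_cc=cc_overall)
    return FilamentCall(
        fid, assigned=True, n_pf=int(n_pf), polarity=str(polarity),
        winning_fraction=frac, mean_cc=cc_overall,
    )


def call_table(
    table: pd.DataFrame, rule: AssignmentRule = AssignmentRule()
) -> pd.DataFrame:
    """Clean the whole table, call every filament, return a calls table.

    Filaments whose every particle was removed by cleaning are reported as
    undetermined.  Extra per-filament metadata columns (protrusion_id,
    replicate, ...) that are constant within a filament are carried over.
    """
    _check_table(table)
    cleaned = clean_by_cc(table, rule)
    rows = []
    meta_cols = [
        c for c in ("protrusion_id", "replicate", "condition") if c in table.columns
    ]
    for fid, group in table.groupby("filament_id", sort=True):
        kept = cleaned[cleaned["filament_id"] == fid]
        call = (
            call_filament(kept, rule)
            if len(kept)
            else FilamentCall(fid, assigned=False)
        )
        row = {
            "filament_id": fid,
            "assigned": call.assigned,
            "n_pf": call.n_pf,
            "polarity": call.polarity,
            "winning_fraction": call.winning_fraction,
            "mean_cc": call.mean_cc,
        }
        for c in meta_cols:
            row[c] = group[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_protrusions(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-protrusion orientation uniformity and protofilament mixing.

    Protrusions with fewer than 2 assigned microtubules are excluded;
    among the rest, orientation is "uniform" iff all assigned microtubules
    share polarity, and pf_mix is "mixed" iff two or more distinct
    protofilament numbers occur.
    """
    if "protrusion_id" not in calls.columns:
        raise ValueError("calls table lacks a protrusion_id column")
    rows = []
    for pid, group in calls.groupby("protrusion_id", sort=True):
        assigned = group[group["assigned"]]
        if len(assigned) < 2:
            rows.append(
                {"protrusion_id": pid, "n_assigned": len(assigned),
                 "orientation": "excluded", "pf_mix": "excluded"}
            )
            continue
        rows.append(
            {
                "protrusion_id": pid,
                "n_assigned": len(assigned),
                "orientation": "uniform"
                if assigned["polarity"].nunique() == 1
                else "mixed",
                "pf_mix": "single" if assigned["n_pf"].nunique() == 1 else "mixed",
            }
        )
    return pd.DataFrame(rows)


def unify_polarity(table: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Rotate particles of minus-called filaments 180 deg about the second
    Euler angle so every retained filament points the same way.

    Applied to the particles' original Euler angles; particles of
    undetermined filaments are dropped.  Calling this on an already
    unified table (all calls plus) is the identity.
    """
    for col in ("rot", "tilt", "psi"):
        if col not in table.columns:
            raise ValueError(f"particle table lacks Euler column {col!r}")
    call_map = calls.set_index("filament_id")
    missing = set(table["filament_id"]) - set(call_map.index)
    if missing:
        raise ValueError(f"filaments without a call: {sorted(missing)[:5]} ...")
    keep = table["filament_id"].map(call_map["assigned"]).to_numpy(dtype=bool)
    out = table[keep].copy()
    minus = out["filament_id"].map(call_map["polarity"]).to_numpy() == "minus"
    if minus.any():
        idx = np.flatnonzero(minus)
        rots = out["rot"].to_numpy(float)
        tilts = out["tilt"].to_numpy(float)
        psis = out["psi"].to_numpy(float)
        for i in idx:
            e = flip_polarity(EulerTriplet(rots[i], tilts[i], psis[i]))
            rots[i], tilts[i], psis[i] = e.rot, e.tilt, e.psi
        out["rot"], out["tilt"], out["psi"] = rots, tilts, psis
    return out


def pf_distribution(
    calls: pd.DataFrame,
    group_cols: tuple[str, ...] = ("replicate",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protofilament-number percentages per group, then mean +/- s.d.
    across replicates.

    Undetermined filaments are excluded.  Returns (per-group table with
    columns group..., n_pf, count, percent; summary table with n_pf,
    mean_percent, sd_percent).  Groups with zero assigned filaments are
    flagged with NaN percentages.
    """
    assigned = calls[calls["assigned"]]
    pf_values = (12, 13, 14, 15)
    rows = []
    group_iter = (
        assigned.groupby(list(group_cols), sort=True)
        if group_cols
        else [((), assigned)]
    )
    all_groups = (
        calls.groupby(list(group_cols), sort=True).groups.keys()
        if group_cols
        else [()]
    )
    per_group = {}
    for key, group in group_iter:
        key = key if isinstance(key, tuple) else (key,)
        total = len(group)
        counts = group["n_pf"].value_counts().to_dict()
        per_group[key] = {
            n: 100.0 * counts.get(n, 0) / total if total else np.nan
            for n in pf_values
        }
    for key in all_groups:
        key = key if isinstance(key, tuple) else (key,)
        fracs = per_group.get(key, {n: np.nan for n in pf_values})
        counts_group = assigned
        for col, val in zip(group_cols, key):
            counts_group = counts_group[counts_group[col] == val]
        counts = counts_group["n_pf"].value_counts().to_dict()
        for n in pf_values:
            rows.append(
                dict(zip(group_cols, key))
                | {"n_pf": n, "count": int(counts.get(n, 0)), "percent": fracs[n]}
            )
    per_group_df = pd.DataFrame(rows)
    summary_rows = []
    for n in pf_values:
        vals = per_group_df[per_group_df["n_pf"] == n]["percent"].dropna()
        summary_rows.append(
            {
                "n_pf": n,
                "mean_percent": float(vals.mean()) if len(vals) else np.nan,
                "sd_percent": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n_groups": int(len(vals)),
            }
        )
    return per_group_df, pd.DataFrame(summary_rows)
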