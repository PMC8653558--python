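"""Radiographic disc height, disc height index and percent DHI.

Lateral radiographs yield three height measurements per disc — anterior
(Ha), middle (Hm) and posterior (Hp) — calibrated against a 10-mm wire
marker imaged alongside the spine.  Derived quantities:

    DH   = (Ha + Hm + Hp) / 3                       (mm)
    DHI  = DH(level) / DH(reference NI level)       (same animal & week)
    %DHI = 100 * DHI(week) / DHI(baseline week 0)

Calibration is per-image (each radiograph carries its own marker), so DH is
in absolute millimetres and %DHI is invariant to any per-session change in
magnification.  Missing timepoints are never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study_design import StudyDesign

__all__ = [
    "HeightTriplet",
    "calibrate",
    "disc_height",
    "disc_height_index",
    "percent_dhi",
    "process_measurements",
]


@dataclass(frozen=True)
class HeightTriplet:
    """Calibrated anterior/middle/posterior disc heights in mm."""

    Ha: float
    Hm: float
    Hp: float

    def __post_init__(self) -> None:
        if min(self.Ha, self.Hm, self.Hp) <= 0:
            raise ValueError("disc heights must be positive")


def calibrate(raw_length_px: float, marker_px: float, marker_mm: float = 10.0) -> float:
    """Convert a pixel length to mm via the in-image marker of known length."""
    if marker_px <= 0:
        raise ValueError("marker length must be positive")
    return raw_length_px * marker_mm / marker_px


def disc_height(t: HeightTriplet) -> float:
    """DH = (Ha + Hm + Hp) / 3."""
    return (t.Ha + t.Hm + t.Hp) / 3.0


def disc_height_index(dh: float, dh_reference: float) -> float:
    """DHI of a disc against the non-injected reference disc of the same
    animal and timepoint."""
    if dh_reference <= 0:
        raise ValueError("reference disc height must be positive")
    return dh / dh_reference


def percent_dhi(dhi_post: float, dhi_baseline: float) -> float:
    """%DHI = 100 * post-injection DHI / baseline (week 0) DHI."""
    if dhi_baseline <= 0:
        raise ValueError("baseline DHI must be positive")
    return 100.0 * dhi_post / dhi_baseline


def process_measurements(
    df: pd.DataFrame,
    design: StudyDesign,
    baseline_week: int = 0,
) -> pd.DataFrame:
    """Run the full DH -> DHI -> %DHI chain on a tidy measurement table.

    Parameters
    ----------
    df
        One row per (animal, week, level) with either pixel columns
        ``Ha_px, Hm_px, Hp_px, marker_px`` (calibrated per image using
        ``marker_mm``, default 10) or pre-calibrated ``Ha_mm, Hm_mm, Hp_mm``.
    design
        Supplies the reference (NI) level.

    Returns a tidy frame with DH for every level and DHI/%DHI for the
    non-reference levels; timepoints absent from the input are flagged in
    the ``absent`` column of a full animal x week x level scaffold.
    """
    df = df.copy()
    if "Ha_mm" not in df.columns:
        marker_px = df["marker_px"].to_numpy(float)
        if (marker_px <= 0).any():
            raise ValueError("marker length must be positive")
        marker_mm = float(df["marker_mm"].iloc[0]) if "marker_mm" in df.columns else 10.0
        for c in ("Ha", "Hm", "Hp"):
            df[f"{c}_mm"] = df[f"{c}_px"].to_numpy(float) * marker_mm / marker_px
    if (df[["Ha_mm", "Hm_mm", "Hp_mm"]].to_numpy() <= 0).any():
        raise ValueError("non-positive calibrated height encountered")
    df["DH_mm"] = df[["Ha_mm", "Hm_mm", "Hp_mm"]].mean(axis=1)

    ref = design.reference_level
    ref_dh = (
        df.loc[df["level"] == ref, ["animal", "week", "DH_mm"]]
        .rename(columns={"DH_mm": "DH_ref_mm"})
    )
    out = df.merge(ref_dh, on=["animal", "week"], how="left")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["DHI"] = np.where(
            out["level"] == ref, np.nan, out["DH_mm"] / out["DH_ref_mm"]
        )
    base = (
        out.loc[out["week"] == baseline_week, ["animal", "level", "DHI"]]
        .rename(columns={"DHI": "DHI_baseline"})
    )
    out = out.merge(base, on=["animal", "level"], how="left")
    out["pct_DHI"] = 100.0 * out["DHI"] / out["DHI_baseline"]
    out["absent"] = False

    # flag timepoints the schedule expects but the table lacks
    scaffold = pd.MultiIndex.from_product(
        [sorted(out["animal"].unique()), design.radiograph_weeks, design.levels],
        names=["animal", "week", "level"],
    ).to_frame(index=False)
    out = scaffold.merge(out, on=["animal", "week", "level"], how="left")
    out["absent"] = out["DH_mm"].isna()
    keep = [
        "animal", "week", "level", "Ha_mm", "Hm_mm", "Hp_mm",
        "DH_mm", "DHI", "pct_DHI", "absent",
    ]
    return out[keep]
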