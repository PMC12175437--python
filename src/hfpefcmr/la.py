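"""Left-atrial volumetry and phasic strain.

The left atrium acts in three phases per cardiac cycle: it fills while the
ventricle contracts (reservoir), empties passively in early diastole
(conduit), and contracts actively just before ventricular systole
(booster). From a per-frame trajectory of LA long-axis lengths the package
computes Lagrangian length strain referenced to LV end-diastole and splits
it into the three phasic components, with the identity

    reservoir = conduit + booster

holding by construction. Volumes use the biplane area-length formula over
2- and 4-chamber views. Contours themselves are inputs: no image feature
tracking is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LATrajectory",
    "PhasicStrains",
    "LAVolumes",
    "biplane_volume",
    "la_volume_extrema",
    "strain_curve",
    "phasic_strains",
    "average_views_and_visits",
    "trajectory_mechanics",
]

_MM3_PER_ML = 1000.0


@dataclass
class LATrajectory:
    """Per-frame LA lengths (mm) and optional areas (mm^2) in two views.

    ``ref_frame`` is the LV end-diastolic frame (strain reference,
    0-based); ``pre_a_frame`` marks the onset of atrial contraction.
    """

    frame_times: np.ndarray
    lengths_2ch: np.ndarray
    lengths_4ch: np.ndarray
    ref_frame: int
    pre_a_frame: int
    areas_2ch: np.ndarray | None = None
    areas_4ch: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.lengths_2ch = np.asarray(self.lengths_2ch, dtype=float)
        self.lengths_4ch = np.asarray(self.lengths_4ch, dtype=float)
        n = self.frame_times.size
        for name in ("lengths_2ch", "lengths_4ch"):
            arr = getattr(self, name)
            if arr.size != n:
                raise ValueError(f"{name} length {arr.size} != {n} frames")
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in ("areas_2ch", "areas_4ch"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                setattr(self, name, arr)
                if arr.size != n:
                    raise ValueError(f"{name} length {arr.size} != {n} frames")
                if np.any(arr < 0):
                    raise ValueError(f"{name} must be non-negative")
        for name in ("ref_frame", "pre_a_frame"):
            idx = getattr(self, name)
            if not 0 <= idx < n:
                raise ValueError(f"{name}={idx} outside 0..{n - 1}")

    @property
    def n_frames(self) -> int:
        return int(self.frame_times.size)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "frame": np.arange(self.n_frames),
            "length_2ch_mm": self.lengths_2ch,
            "length_4ch_mm": self.lengths_4ch,
        }
        if self.areas_2ch is not None:
            data["area_2ch_mm2"] = self.areas_2ch
        if self.areas_4ch is not None:
            data["area_4ch_mm2"] = self.areas_4ch
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path, ref_frame: int, pre_a_frame: int) -> "LATrajectory":
        df = pd.read_csv(path)
        need = {"frame", "length_2ch_mm", "length_4ch_mm"}
        if need - set(df.columns):
            raise ValueError(f"trajectory file lacks columns {sorted(need - set(df.columns))}")
        return cls(
            frame_times=df["frame"].to_numpy(dtype=float),
            lengths_2ch=df["length_2ch_mm"].to_numpy(),
            lengths_4ch=df["length_4ch_mm"].to_numpy(),
            areas_2ch=df["area_2ch_mm2"].to_numpy() if "area_2ch_mm2" in df else None,
            areas_4ch=df["area_4ch_mm2"].to_numpy() if "area_4ch_mm2" in df else None,
            ref_frame=ref_frame,
            pre_a_frame=pre_a_frame,
        )


@dataclass(frozen=True)
class PhasicStrains:
    """Reservoir, conduit and booster strain in percent."""

    reservoir: float
    conduit: float
    booster: float

    def __post_init__(self) -> None:
        if self.reservoir < 0:
            raise ValueError("reservoir strain must be non-negative")
        if abs(self.reservoir - (self.conduit + self.booster)) > 1e-9:
            raise ValueError("phasic strains violate reservoir = conduit + booster")


@dataclass(frozen=True)
class LAVolumes:
    """Volume extrema (mL) and the per-frame volume curve."""

    min_volume: float
    max_volume: float
    volume_curve: np.ndarray

    def __post_init__(self) -> None:
        if self.min_volume < 0 or self.max_volume < self.min_volume:
            raise ValueError("require 0 <= min_volume <= max_volume")


def biplane_volume(area_2ch, area_4ch, length):
    """Biplane area-length LA volume in mL.

    V = (8 / 3π) * A_2ch * A_4ch / L, with areas in mm^2 and length in mm,
    converted from mm^3 to mL. A zero area gives the degenerate V = 0 with
    a warning; negative inputs or a non-positive length are rejected.
    Accepts scalars or arrays (broadcast elementwise).
    """
    a2 = np.asarray(area_2ch, dtype=float)
    a4 = np.asarray(area_4ch, dtype=float)
    ln = np.asarray(length, dtype=float)
    if np.any(a2 < 0) or np.any(a4 < 0):
        raise ValueError("areas must be non-negative")
    if np.any(ln <= 0):
        raise ValueError("length must be strictly positive")
    if np.any(a2 == 0) or np.any(a4 == 0):
        warnings.warn("zero LA area: degenerate volume 0 mL", stacklevel=2)
    v = (8.0 / (3.0 * np.pi)) * a2 * a4 / ln / _MM3_PER_ML
    return float(v) if v.ndim == 0 else v


def la_volume_extrema(traj: LATrajectory) -> LAVolumes:
    """Per-frame biplane volumes and their extrema.

    Uses the mean of the two view lengths frame by frame; both views must
    provide areas on the same frame grid.
    """
    if traj.areas_2ch is None or traj.areas_4ch is None:
        raise ValueError("volume computation requires areas for both views")
    length = 0.5 * (traj.lengths_2ch + traj.lengths_4ch)
    vols = biplane_volume(traj.areas_2ch, traj.areas_4ch, length)
    return LAVolumes(
        min_volume=float(np.min(vols)),
        max_volume=float(np.max(vols)),
        volume_curve=np.asarray(vols),
    )


def strain_curve(lengths: np.ndarray, ref_frame: int) -> np.ndarray:
    """Lagrangian length strain in percent, zero at ``ref_frame``.

    ε(t) = 100 · (L(t) − L_ref) / L_ref. Dimensionless in the length unit,
    so any common unit change leaves the curve untouched.
    """
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be strictly positive")
    if not 0 <= ref_frame < lengths.size:
        raise ValueError(f"ref_frame {ref_frame} outside 0..{lengths.size - 1}")
    l_ref = lengths[ref_frame]
    return 100.0 * (lengths - l_ref) / l_ref


def phasic_strains(curve: np.ndarray, pre_a_frame: int) -> PhasicStrains:
    """Split a strain curve into reservoir, conduit and booster components.

    Reservoir is the curve maximum (peak atrial expansion), booster is the
    value at the pre-atrial-contraction frame, and conduit is their
    difference — the standard feature-tracking convention with an LV
    end-diastolic reference. A pre-A frame preceding the peak is
    physiologically inverted timing and triggers a warning.
    """
    curve = np.asarray(curve, dtype=float)
    if not 0 <= pre_a_frame < curve.size:
        raise ValueError(f"pre_a_frame {pre_a_frame} outside 0..{curve.size - 1}")
    peak_idx = int(np.argmax(curve))  # earliest frame on ties
    reservoir = float(curve[peak_idx])
    booster = float(curve[pre_a_frame])
    if pre_a_frame < peak_idx:
        warnings.warn(
            f"pre-atrial-contraction frame {pre_a_frame} precedes the strain "
            f"peak at frame {peak_idx}: inverted phase timing",
            stacklevel=2,
        )
    return PhasicStrains(reservoir=reservoir, conduit=reservoir - booster, booster=booster)


def trajectory_mechanics(traj: LATrajectory) -> dict:
    """Full LA analysis of one trajectory: view-averaged phasic strains
    plus volume extrema (when areas are available).

    Strain is computed per view and the phasic components averaged across
    the 2- and 4-chamber views.
    """
    per_view = [
        phasic_strains(strain_curve(lengths, traj.ref_frame), traj.pre_a_frame)
        for lengths in (traj.lengths_2ch, traj.lengths_4ch)
    ]
    out = {
        "reservoir": float(np.mean([s.reservoir for s in per_view])),
        "conduit": float(np.mean([s.conduit for s in per_view])),
        "booster": float(np.mean([s.booster for s in per_view])),
    }
    if traj.areas_2ch is not None and traj.areas_4ch is not None:
        vols = la_volume_extrema(traj)
        out["min_volume"] = vols.min_volume
        out["max_volume"] = vols.max_volume
    return out


def average_views_and_visits(
    results: pd.DataFrame,
    value_cols: list[str],
    view_col: str = "view",
    visit_col: str = "visit_day",
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Average per-view, per-visit measurements up to the subject level.

    Arithmetic mean first over views within each visit, then over visits.
    Missing entries (NaN) are skipped; a subject with no valid entry for a
    column at all raises. The number of entries averaged is reported in
    ``<col>_n`` columns.
    """
    if results.empty:
        raise ValueError("no measurements to average")
    cols = [c for c in value_cols if c in results.columns]
    if not cols:
        raise ValueError(f"none of {value_cols} present in results")
    group_visit = [subject_col] + ([visit_col] if visit_col in results.columns else [])
    per_visit = results.groupby(group_visit, sort=True)[cols].mean().reset_index()
    agg = per_visit.groupby(subject_col, sort=True)[cols].agg(["mean", "count"])
    out = pd.DataFrame(index=agg.index)
    for c in cols:
        out[c] = agg[(c, "mean")]
        out[f"{c}_n"] = agg[(c, "count")].astype(int)
        if out[c].isna().any():
            bad = out.index[out[c].isna()].tolist()
            raise ValueError(f"all entries missing for {c} in subjects {bad}")
    return out.reset_index()
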