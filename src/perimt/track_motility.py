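"""Fiducial-mark track segmentation and motility classification.

Tracks of marks bound to the MT lattice are resampled onto a common time
grid, segmented into non-overlapping 5 s windows, and the net Euclidean
displacement of each window is computed. Displacements strictly below
0.15 µm per 5 s (the resolution limit) are stationary, strictly above
0.3 µm motile, the rest intermediate; each window is one observation.
Displacements are additionally binned at 0.05 µm for per-cell
distribution histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import AnalysisParameters, DEFAULT_PARAMETERS
from .synthetic.tracks import TrackSet

logger = logging.getLogger(__name__)

_POSITION_SCALE_TO_UM = {"um": 1.0, "µm": 1.0, "micron": 1.0, "nm": 1e-3, "mm": 1e3}
_TIME_SCALE_TO_S = {"s": 1.0, "ms": 1e-3, "min": 60.0}


def read_tracks_csv(
    path: str | Path,
    position_unit: str = "um",
    time_unit: str = "s",
    column_map: dict[str, str] | None = None,
) -> TrackSet:
    """Read a spot-tracker export (CSV) into a TrackSet in µm and s.

    Expected columns ``track_id, t, x, y`` (optionally ``intensity``,
    ``cell_id``); ``column_map`` renames nonstandard headers. Missing
    required columns raise a schema error naming them; duplicate
    (track_id, t) rows raise.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ("track_id", "t", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV {path} missing required columns: {missing}")
    if position_unit not in _POSITION_SCALE_TO_UM:
        raise ValueError(f"unknown position unit {position_unit!r}")
    if time_unit not in _TIME_SCALE_TO_S:
        raise ValueError(f"unknown time unit {time_unit!r}")

    ps = _POSITION_SCALE_TO_UM[position_unit]
    ts = _TIME_SCALE_TO_S[time_unit]
    out = pd.DataFrame(
        {
            "track_id": df["track_id"],
            "t_s": df["t"] * ts,
            "x_um": df["x"] * ps,
            "y_um": df["y"] * ps,
        }
    )
    if "cell_id" in df.columns:
        out["cell_id"] = df["cell_id"]
    if "intensity" in df.columns:
        out["intensity"] = df["intensity"]
    return TrackSet(out)


def write_tracks_csv(tracks: TrackSet, path: str | Path) -> None:
    df = tracks.data.rename(columns={"t_s": "t", "x_um": "x", "y_um": "y"})
    df.to_csv(path, index=False)


def filter_tracks_by_intensity(tracks: TrackSet, min_intensity: float) -> TrackSet:
    """Optional refinement: drop tracks whose median intensity is below a
    floor (removes dim noise particles drifting through focus)."""
    if "intensity" not in tracks.data.columns:
        raise ValueError("track table has no intensity column")
    med = tracks.data.groupby("track_id")["intensity"].median()
    keep = med[med >= min_intensity].index
    return TrackSet(tracks.data[tracks.data["track_id"].isin(keep)].copy())


def normalize_tracks(tracks: TrackSet, dt_target_s: float) -> TrackSet:
    """Resample each track onto the grid t0, t0+dt, ... by nearest-sample
    selection within dt/2; gaps are left absent (never interpolated).
    Tracks reduced below two grid samples are dropped with a log record.
    """
    if not (dt_target_s > 0):
        raise ValueError("dt_target_s must be > 0")
    pieces = []
    for tid, g in tracks.data.groupby("track_id", sort=False):
        t = g["t_s"].to_numpy()
        t0 = t[0]
        grid = t0 + np.arange(int(np.floor((t[-1] - t0) / dt_target_s)) + 1) * dt_target_s
        # nearest sample to each grid point, accepted within dt/2
        idx = np.searchsorted(t, grid)
        idx = np.clip(idx, 1, len(t) - 1)
        left_closer = (grid - t[idx - 1]) <= (t[idx] - grid)
        nearest = np.where(left_closer, idx - 1, idx)
        ok = np.abs(t[nearest] - grid) <= dt_target_s / 2 + 1e-9
        nearest = nearest[ok]
        grid_kept = grid[ok]
        # a sample may be nearest to at most one grid point; keep first use
        _, first = np.unique(nearest, return_index=True)
        nearest, grid_kept = nearest[np.sort(first)], grid_kept[np.sort(first)]
        if len(nearest) < 2:
            logger.info("track %s dropped in time normalization (<2 grid samples)", tid)
            continue
        piece = g.iloc[nearest].copy()
        piece["t_s"] = grid_kept
        pieces.append(piece)
    if not pieces:
        empty = pd.DataFrame(
            {"track_id": pd.Series(dtype=int), "t_s": pd.Series(dtype=float),
             "x_um": pd.Series(dtype=float), "y_um": pd.Series(dtype=float),
             "cell_id": pd.Series(dtype=str)}
        )
        return TrackSet(empty)
    return TrackSet(pd.concat(pieces, ignore_index=True))


def classify_displacement(d_um: float, params: AnalysisParameters = DEFAULT_PARAMETERS) -> str:
    """Strict thresholds: below 0.15 µm stationary, above 0.3 µm motile;
    exact threshold values are intermediate."""
    if d_um < params.stationary_max_um:
        return "stationary"
    if d_um > params.motile_min_um:
        return "motile"
    return "intermediate"


def five_second_displacements(
    tracks: TrackSet,
    window_s: float | None = None,
    mode: str = "nonoverlapping",
    params: AnalysisParameters = DEFAULT_PARAMETERS,
) -> pd.DataFrame:
    """Net displacement per 5 s window for every track.

    Windows start at each track's first sample; a window is emitted only
    when samples exist at both endpoints (gaps are skipped, never
    interpolated). ``mode="sliding"`` advances windows by one sample
    instead of one window length.
    """
    if mode not in ("nonoverlapping", "sliding"):
        raise ValueError(f"unknown mode {mode!r}")
    w = params.displacement_window_s if window_s is None else window_s
    if not (w > 0):
        raise ValueError("window_s must be > 0")

    records = []
    for tid, g in tracks.data.groupby("track_id", sort=False):
        t = g["t_s"].to_numpy()
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        cell = g["cell_id"].iloc[0] if "cell_id" in g.columns else "cell_0"
        by_time = {round(ti - t[0], 9): i for i, ti in enumerate(t)}
        if mode == "nonoverlapping":
            starts = np.arange(0.0, (t[-1] - t[0]) - w + 1e-9, w)
        else:
            starts = t - t[0]
        for s in starts:
            i = by_time.get(round(float(s), 9))
            j = by_time.get(round(float(s) + w, 9))
            if i is None or j is None:
                continue
            d = float(np.hypot(x[j] - x[i], y[j] - y[i]))
            records.append(
                {
                    "track_id": tid,
                    "cell_id": cell,
                    "window_start_s": float(t[0] + s),
                    "displacement_um": d,
                    "motility_class": classify_displacement(d, params),
                }
            )
    return pd.DataFrame(
        records,
        columns=["track_id", "cell_id", "window_start_s", "displacement_um", "motility_class"],
    )


def bin_displacements(
    records: pd.DataFrame,
    bin_width_um: float | None = None,
    params: AnalysisParameters = DEFAULT_PARAMETERS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell displacement distribution in 0.05 µm bins.

    Returns ``(per_cell, population)``: per-cell percentages per bin, and
    the population mean ± SEM of those percentages across cells. Cells
    with zero records are excluded (logged).
    """
    bw = params.displacement_bin_um if bin_width_um is None else bin_width_um
    if not (bw > 0):
        raise ValueError("bin_width_um must be > 0")
    if records.empty:
        raise ValueError("no displacement records to bin")
    d = records["displacement_um"].to_numpy()
    n_bins = int(np.floor(d.max() / bw)) + 1
    edges = np.arange(n_bins + 1) * bw

    rows = []
    for cell, g in records.groupby("cell_id"):
        if g.empty:
            logger.info("cell %s has no displacement records; excluded", cell)
            continue
        idx = np.minimum((g["displacement_um"].to_numpy() // bw).astype(int), n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        pct = 100.0 * counts / counts.sum()
        for b in range(n_bins):
            rows.append(
                {
                    "cell_id": cell,
                    "bin_lo_um": edges[b],
                    "bin_hi_um": edges[b + 1],
                    "count": int(counts[b]),
                    "percent": pct[b],
                }
            )
    per_cell = pd.DataFrame(rows)
    population = (
        per_cell.groupby(["bin_lo_um", "bin_hi_um"])["percent"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return per_cell, population


@dataclass
class MotilitySummary:
    """Per-cell stationary / intermediate / motile fractions over windows."""

    per_cell: pd.DataFrame  # cell_id, n_windows, n_tracks, f_stationary, f_intermediate, f_motile
    n_windows: int
    n_tracks: int

    @property
    def overall(self) -> dict[str, float]:
        """Window-weighted fractions pooled over all cells."""
        pc = self.per_cell
        w = pc["n_windows"].to_numpy(dtype=float)
        tot = w.sum()
        return {
            f"f_{k}": float((pc[f"f_{k}"] * w).sum() / tot) if tot else float("nan")
            for k in ("stationary", "intermediate", "motile")
        }


def classify_motility(
    records: pd.DataFrame, params: AnalysisParameters = DEFAULT_PARAMETERS
) -> MotilitySummary:
    """Fractions of 5 s windows per motility class, per cell.

    Each window is one observation; the three fractions sum to 1 exactly.
    An empty record set yields a flagged summary with n=0.
    """
    if records.empty:
        return MotilitySummary(
            per_cell=pd.DataFrame(
                columns=["cell_id", "n_windows", "n_tracks",
                         "f_stationary", "f_intermediate", "f_motile"]
            ),
            n_windows=0,
            n_tracks=0,
        )
    rows = []
    for cell, g in records.groupby("cell_id"):
        n = len(g)
        counts = g["motility_class"].value_counts()
        rows.append(
            {
                "cell_id": cell,
                "n_windows": n,
                "n_tracks": g["track_id"].nunique(),
                "f_stationary": counts.get("stationary", 0) / n,
                "f_intermediate": counts.get("intermediate", 0) / n,
                "f_motile": counts.get("motile", 0) / n,
            }
        )
    per_cell = pd.DataFrame(rows)
    return MotilitySummary(
        per_cell=per_cell,
        n_windows=int(len(records)),
        n_tracks=int(records["track_id"].nunique()),
    )
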