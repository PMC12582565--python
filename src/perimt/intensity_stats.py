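"""Intensity readouts, group statistics, and report generation.

Covers the peripheral tubulin intensity readout (mean intensity in the
outer 2 µm band), depletion folds normalized to marker-negative cells in
the same field of view, the two group comparisons used for
directionality histograms (per-bin unpaired Welch t-tests on per-cell
bin fractions and a two-sample Kolmogorov-Smirnov test on the pooled
per-pixel angle distributions), and a machine-readable report bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .directionality import DirectionalityHistogram
from .images import CellMask, ImageStack
from .preprocess import peripheral_band
from .synthetic.fov import FieldOfView


def peripheral_mean_intensity(
    image: ImageStack | np.ndarray, cell: CellMask, width_um: float = 2.0
) -> float:
    """Mean intensity within the outer ``width_um`` peripheral band."""
    pixels = image.pixels if isinstance(image, ImageStack) else np.asarray(image, dtype=float)
    band = peripheral_band(cell, width_um)
    if not band.any():
        raise ValueError("peripheral band is empty")
    return float(pixels[band].mean())


def depletion_fold(fov: FieldOfView) -> pd.DataFrame:
    """Fold intensity of each marker-positive cell, normalized to the mean
    of marker-negative cells in the same field of view."""
    neg = fov.cells.loc[~fov.cells["positive"], "mean_intensity"]
    if neg.empty:
        raise ValueError("no marker-negative cells to normalize against")
    neg_mean = float(neg.mean())
    if neg_mean <= 0:
        raise ValueError("marker-negative mean intensity is not positive")
    pos = fov.cells[fov.cells["positive"]].copy()
    pos["fold"] = pos["mean_intensity"] / neg_mean
    return pos[["cell_id", "mean_intensity", "fold"]].reset_index(drop=True)


@dataclass
class GroupComparison:
    """Per-bin t-tests plus an overall K-S test between two groups."""

    per_bin: pd.DataFrame | None  # bin_lo_deg, bin_hi_deg, t_stat, p, p_bonferroni
    ks_stat: float
    ks_p: float
    effect_direction_bin0: int  # sign of (mean A - mean B) parallel-bin fraction
    n_cells: tuple[int, int]
    ttest_error: str | None = None


def compare_directionality(
    group_a: list[DirectionalityHistogram],
    group_b: list[DirectionalityHistogram],
    angles_a: np.ndarray,
    angles_b: np.ndarray,
) -> GroupComparison:
    """Compare two cell groups' border-angle distributions.

    Per 10° bin, an unpaired Welch t-test across cells on per-cell bin
    fractions; overall, a two-sample K-S test on the pooled per-pixel
    angles. Groups with fewer than two non-empty cells refuse the t-tests
    (recorded as an error) while the K-S test is still computed. No
    multiple-testing correction is applied to the headline p-values; a
    Bonferroni column is provided alongside, clearly labelled.
    """
    fa = np.array([h.fractions for h in group_a if h.n_pixels > 0])
    fb = np.array([h.fractions for h in group_b if h.n_pixels > 0])
    aa = np.asarray(angles_a, dtype=float)
    ab = np.asarray(angles_b, dtype=float)
    aa = aa[np.isfinite(aa)]
    ab = ab[np.isfinite(ab)]
    if aa.size == 0 or ab.size == 0:
        raise ValueError("pooled angle samples must be non-empty for the K-S test")
    ks = sps.ks_2samp(aa, ab, method="asymp")

    per_bin = None
    ttest_error = None
    if len(fa) < 2 or len(fb) < 2:
        ttest_error = (
            f"per-bin t-tests need >= 2 cells per group (got {len(fa)} and {len(fb)})"
        )
        effect = 0
        if len(fa) and len(fb):
            effect = int(np.sign(fa[:, 0].mean() - fb[:, 0].mean()))
    else:
        edges = group_a[0].bin_edges
        n_bins = len(edges) - 1
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for b in range(n_bins):
                t = sps.ttest_ind(fa[:, b], fb[:, b], equal_var=False)
                rows.append(
                    {
                        "bin_lo_deg": edges[b],
                        "bin_hi_deg": edges[b + 1],
                        "t_stat": float(t.statistic),
                        "p": float(t.pvalue),
                        "p_bonferroni": float(min(t.pvalue * n_bins, 1.0)),
                    }
                )
        per_bin = pd.DataFrame(rows)
        effect = int(np.sign(fa[:, 0].mean() - fb[:, 0].mean()))

    return GroupComparison(
        per_bin=per_bin,
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        effect_direction_bin0=effect,
        n_cells=(len(fa), len(fb)),
        ttest_error=ttest_error,
    )


def ks_on_cell_medians(
    group_a: list[np.ndarray], group_b: list[np.ndarray]
) -> tuple[float, float]:
    """Variant K-S on per-cell median angles instead of pooled pixels."""
    ma = np.array([np.nanmedian(a) for a in group_a])
    mb = np.array([np.nanmedian(b) for b in group_b])
    ks = sps.ks_2samp(ma, mb, method="asymp")
    return float(ks.statistic), float(ks.pvalue)


# ---------------------------------------------------------------------------
# report bundle

_TABLE_NAMES = ("directionality", "motility", "frap", "intensity")


def histograms_to_frame(hists: list[DirectionalityHistogram]) -> pd.DataFrame:
    """Flatten per-cell directionality histograms to a tidy table."""
    rows = []
    for h in hists:
        fr = h.fractions
        for b in range(len(h.counts)):
            rows.append(
                {
                    "cell_id": h.cell_id,
                    "band_lo_um": h.band_um[0],
                    "band_hi_um": h.band_um[1],
                    "bin_lo_deg": h.bin_edges[b],
                    "bin_hi_deg": h.bin_edges[b + 1],
                    "count": int(h.counts[b]),
                    "fraction": float(fr[b]) if np.isfinite(fr[b]) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _summarize(tables: dict[str, pd.DataFrame]) -> dict:
    summary: dict = {}
    if "directionality" in tables:
        t = tables["directionality"]
        pooled = t.groupby(["bin_lo_deg", "bin_hi_deg"], sort=True)["count"].sum()
        total = int(pooled.sum())
        first = pooled.iloc[0] if total else 0
        summary["directionality"] = {
            "n_pixels": total,
            "n_cells": int(t["cell_id"].nunique()),
            "pooled_parallel_fraction": (first / total) if total else None,
        }
    if "motility" in tables:
        t = tables["motility"]
        w = t["n_windows"].to_numpy(dtype=float)
        summary["motility"] = {
            "n_cells": int(len(t)),
            "n_windows": int(w.sum()),
            "f_stationary": float((t["f_stationary"] * w).sum() / w.sum()),
            "f_intermediate": float((t["f_intermediate"] * w).sum() / w.sum()),
            "f_motile": float((t["f_motile"] * w).sum() / w.sum()),
        }
    if "frap" in tables:
        t = tables["frap"]
        i = int(np.argmin(np.abs(t["t_s"].to_numpy() - 300.0)))
        summary["frap"] = {
            "n_frames": int(len(t)),
            "readout_time_s": float(t["t_s"].iloc[i]),
            "readout_area_um2": float(t["area_um2"].iloc[i]),
            "max_area_um2": float(t["area_um2"].max()),
        }
    if "intensity" in tables:
        t = tables["intensity"]
        folds = t["fold"].dropna()
        summary["intensity"] = {
            "n_positive_cells": int(folds.size),
            "mean_fold": float(folds.mean()) if folds.size else None,
            "sem_fold": float(folds.std(ddof=1) / np.sqrt(folds.size)) if folds.size > 1 else None,
        }
    return summary


def rebuild_report_json(outdir: str | Path) -> Path:
    """Recompute report.json from the saved CSV tables alone (idempotent:
    repeated runs produce byte-identical JSON)."""
    outdir = Path(outdir)
    tables = {
        name: pd.read_csv(outdir / f"{name}.csv")
        for name in _TABLE_NAMES
        if (outdir / f"{name}.csv").exists()
    }
    if not tables:
        raise ValueError(f"no report tables found in {outdir} (expected any of {_TABLE_NAMES})")
    payload = json.dumps(_summarize(tables), indent=2, sort_keys=True, allow_nan=False)
    path = outdir / "report.json"
    path.write_text(payload + "\n")
    return path


def _make_figures(outdir: Path, tables: dict[str, pd.DataFrame]) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    if "directionality" in tables:
        t = tables["directionality"]
        pooled = t.groupby("bin_lo_deg", sort=True)["count"].sum()
        frac = pooled / pooled.sum() if pooled.sum() else pooled
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(pooled.index, frac, width=8, align="edge", color="#3366aa")
        ax.set_xlabel("angle to border (deg)")
        ax.set_ylabel("fraction of pixels")
        ax.set_title("MT directionality, outer band")
        fig.tight_layout()
        p = outdir / "directionality_histogram.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    if "frap" in tables:
        t = tables["frap"]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(t["t_s"], t["area_um2"], "-o", ms=3)
        ax.set_xlabel("time after bleach (s)")
        ax.set_ylabel("displaced MT area (µm²)")
        fig.tight_layout()
        p = outdir / "frap_area.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    if "motility" in tables:
        t = tables["motility"]
        fig, ax = plt.subplots(figsize=(4, 3))
        for k, c in (("f_stationary", "#777777"), ("f_intermediate", "#c89b2e"), ("f_motile", "#aa3333")):
            ax.scatter([k.replace("f_", "")] * len(t), t[k], color=c, s=12)
        ax.set_ylabel("fraction of 5 s windows")
        fig.tight_layout()
        p = outdir / "motility_fractions.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    if "intensity" in tables:
        t = tables["intensity"]
        fig, ax = plt.subplots(figsize=(3, 3))
        ax.scatter(np.zeros(len(t)), t["fold"], s=12)
        ax.set_ylabel("fold vs negative cells")
        ax.set_xticks([])
        fig.tight_layout()
        p = outdir / "intensity_fold.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(p)
    return made


def build_report(
    outdir: str | Path,
    directionality: pd.DataFrame | None = None,
    motility: pd.DataFrame | None = None,
    frap: pd.DataFrame | None = None,
    intensity: pd.DataFrame | None = None,
    parameters: dict | None = None,
    make_figures: bool = True,
) -> dict[str, Path]:
    """Write a report bundle: CSV tables, report.json, PNG figures.

    The JSON is derived from the CSVs alone, so every figure and summary
    is regenerable from the saved tables.
    """
    provided = {
        "directionality": directionality,
        "motility": motility,
        "frap": frap,
        "intensity": intensity,
    }
    given = {k: v for k, v in provided.items() if v is not None}
    if not given:
        raise ValueError(
            "no analysis outputs provided; expected at least one of "
            + ", ".join(_TABLE_NAMES)
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in given.items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False)
        paths[name] = p
    if parameters is not None:
        p = outdir / "parameters.json"
        p.write_text(json.dumps(parameters, indent=2, sort_keys=True) + "\n")
        paths["parameters"] = p
    paths["report"] = rebuild_report_json(outdir)
    if make_figures:
        for fig_path in _make_figures(outdir, given):
            paths[fig_path.stem] = fig_path
    return paths
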