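"""Growth metrics: per-position time series, per-track tables, and the
linear/logarithmic raw/optimized fits that yield growth rates.

The specific (exponential) growth rate µ of a quantity y(t) is the slope of
an ordinary least-squares fit of ln y against time in hours.  The *optimized*
variant restricts the fit to the widest contiguous window (>= 3 points) whose
OLS achieves R² > 0.9 — ties broken by higher R², then earlier start — which
trims lag phases and saturation from the estimate.  Tip elongation rates are
the linear-optimized slopes of per-track hypha length in µm·h⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_stack import ImageStack
from .segmentation import BinaryMask
from .skeleton_graph import SkeletonGraph
from .tracking import HyphaTrack

R2_THRESHOLD = 0.9
MIN_WINDOW = 3


@dataclass
class FitResult:
    """An OLS fit of y (or ln y) against time in hours.

    slope is in units of y per hour; for logarithmic fits it is the specific
    rate in h⁻¹.  ``degenerate`` marks zero-variance responses, whose R² is
    reported as 0 by convention.
    """

    transform: str          # linear | logarithmic
    mode: str               # raw | optimized
    slope: float
    intercept: float
    r_squared: float
    t_start_h: float
    t_end_h: float
    n_points: int
    degenerate: bool = False


def _ols(t: np.ndarray, y: np.ndarray):
    """Slope, intercept, R² of an OLS line; zero-variance y gives R² = 0."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tm, ym = t.mean(), y.mean()
    stt = ((t - tm) ** 2).sum()
    syy = ((y - ym) ** 2).sum()
    sty = ((t - tm) * (y - ym)).sum()
    if stt == 0:
        return 0.0, ym, 0.0, True
    slope = sty / stt
    intercept = ym - slope * tm
    if syy == 0:
        return slope, intercept, 0.0, True
    r2 = (sty * sty) / (stt * syy)
    return slope, intercept, r2, False


def _best_window(t: np.ndarray, y: np.ndarray):
    """Widest contiguous window (>= MIN_WINDOW) with R² > R2_THRESHOLD.

    Exhaustive O(n²) search with prefix sums; ties by higher R², then earlier
    start.  Returns (i, j) half-open or None.
    """
    n = len(t)
    one = np.ones(n)
    ct = np.concatenate([[0.0], np.cumsum(t)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    ctt = np.concatenate([[0.0], np.cumsum(t * t)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cty = np.concatenate([[0.0], np.cumsum(t * y)])
    best = None  # (width, r2, start)
    for i in range(n):
        for j in range(i + MIN_WINDOW, n + 1):
            m = j - i
            st = ct[j] - ct[i]
            sy = cy[j] - cy[i]
            stt = (ctt[j] - ctt[i]) - st * st / m
            syy = (cyy[j] - cyy[i]) - sy * sy / m
            sty = (cty[j] - cty[i]) - st * sy / m
            if stt <= 0 or syy <= 0:
                continue
            r2 = (sty * sty) / (stt * syy)
            if r2 > R2_THRESHOLD:
                cand = (m, r2, -i)
                if best is None or cand > best[:3]:
                    best = (m, r2, -i, i, j)
    if best is None:
        return None
    return best[3], best[4]


def fit_series(
    t_hours: Sequence[float],
    y: Sequence[float],
    transform: str = "linear",
    mode: str = "raw",
) -> Optional[FitResult]:
    """OLS fit of y (or ln y) vs time; returns None when under-determined.

    For the logarithmic transform, non-positive values are dropped before
    taking logs (no pseudo-count offset).  Optimized mode selects the widest
    contiguous window of the (filtered) series with R² > 0.9.
    """
    if transform not in ("linear", "logarithmic"):
        raise ValueError(f"unknown transform {transform!r}")
    if mode not in ("raw", "optimized"):
        raise ValueError(f"unknown mode {mode!r}")
    t = np.asarray(t_hours, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    if transform == "logarithmic":
        keep &= y > 0
    t, y = t[keep], y[keep]
    if len(t) < MIN_WINDOW:
        return None
    yy = np.log(y) if transform == "logarithmic" else y

    if mode == "raw":
        i, j = 0, len(t)
    else:
        window = _best_window(t, yy)
        if window is None:
            return None
        i, j = window

    slope, intercept, r2, degenerate = _ols(t[i:j], yy[i:j])
    return FitResult(
        transform=transform,
        mode=mode,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        t_start_h=float(t[i]),
        t_end_h=float(t[j - 1]),
        n_points=j - i,
        degenerate=degenerate,
    )


FIT_KINDS = [("linear", "raw"), ("linear", "optimized"),
             ("logarithmic", "raw"), ("logarithmic", "optimized")]


def _fit_columns(prefix: str, t: np.ndarray, y: np.ndarray) -> dict:
    cols = {}
    for transform, mode in FIT_KINDS:
        fit = fit_series(t, y, transform, mode)
        tag = f"{prefix}_{transform}_{mode}"
        cols[f"{tag}_slope"] = np.nan if fit is None else fit.slope
        cols[f"{tag}_r2"] = np.nan if fit is None else fit.r_squared
    return cols


def position_metrics(
    graphs: Sequence[SkeletonGraph],
    masks: Sequence[BinaryMask],
    stack: ImageStack,
) -> pd.DataFrame:
    """Per-frame position-level metrics: covered area, total mycelium length,
    branching point and tip counts, and the hyphal growth unit."""
    cal2 = stack.calibration ** 2
    rows = []
    crop = stack.crop if stack.crop is not None else (np.nan,) * 4
    h, w = stack.frames.shape[1:]
    for f, (g, m) in enumerate(zip(graphs, masks)):
        mask = m.mask if isinstance(m, BinaryMask) else np.asarray(m, bool)
        tips = len(g.tips)
        total = g.total_length_um()
        rows.append({
            "frame": f,
            "timestamp_s": float(stack.timestamps[f]),
            "timestamp_h": float(stack.timestamps[f]) / 3600.0,
            "image_height_px": h,
            "image_width_px": w,
            "crop_r0": crop[0], "crop_r1": crop[1],
            "crop_c0": crop[2], "crop_c1": crop[3],
            "covered_area_um2": float(mask.sum()) * cal2,
            "total_length_um": total,
            "branching_count": len(g.junctions),
            "tip_count": tips,
            "hyphal_growth_unit_um": total / tips if tips > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def hyphal_track_metrics(
    tracks: Sequence[HyphaTrack],
    timestamps_s: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-track summary rows and per-hypha-and-time rows.

    Relative length is the length minus the track's minimum length.  Each
    track gets all four fit kinds on absolute and relative length; the tip
    elongation rate is the linear-optimized slope on absolute length in
    µm·h⁻¹ (fits are skipped for flagged or excluded tracks).
    """
    timestamps_s = np.asarray(timestamps_s, dtype=float)
    track_rows = []
    point_rows = []
    for tr in tracks:
        frames = np.asarray(tr.frames)
        lengths = tr.lengths_um
        t_s = timestamps_s[frames]
        t_h = t_s / 3600.0
        rel = lengths - lengths.min()
        hops = np.asarray([r.hop_count for r in tr.records])

        row = {
            "track_id": tr.track_id,
            "status": tr.status,
            "flagged_short": tr.flagged_short,
            "flagged_spurious": tr.flagged_spurious,
            "start_time_s": float(t_s[0]),
            "mid_time_s": float(t_s[(len(t_s) - 1) // 2]),
            "end_time_s": float(t_s[-1]),
            "duration_s": float(t_s[-1] - t_s[0]),
            "n_time_points": len(frames),
            "min_length_um": float(lengths.min()),
            "max_length_um": float(lengths.max()),
            "min_hop_count": int(hops.min()),
            "max_hop_count": int(hops.max()),
        }
        if tr.eligible_for_fits():
            row.update(_fit_columns("absolute", t_h, lengths))
            row.update(_fit_columns("relative", t_h, rel))
        else:
            for transform, mode in FIT_KINDS:
                for target in ("absolute", "relative"):
                    row[f"{target}_{transform}_{mode}_slope"] = np.nan
                    row[f"{target}_{transform}_{mode}_r2"] = np.nan
        row["tip_elongation_rate_um_h"] = row["absolute_linear_optimized_slope"]
        track_rows.append(row)

        for rec, length, relative in zip(tr.records, lengths, rel):
            nxt = next(
                (r for r in tr.records if r.frame == rec.frame + 1), None
            )
            point_rows.append({
                "track_id": tr.track_id,
                "frame": rec.frame,
                "timestamp_s": float(timestamps_s[rec.frame]),
                "length_um": float(length),
                "relative_length_um": float(relative),
                "node_ids": ",".join(str(n) for n in rec.path_nodes),
                "hop_count": rec.hop_count,
                "successor_node_ids": (
                    "" if nxt is None else ",".join(str(n) for n in nxt.path_nodes)
                ),
            })
    track_cols = [
        "track_id", "status", "flagged_short", "flagged_spurious",
        "start_time_s", "mid_time_s", "end_time_s", "duration_s",
        "n_time_points", "min_length_um", "max_length_um",
        "min_hop_count", "max_hop_count", "tip_elongation_rate_um_h",
    ] + [
        f"{target}_{transform}_{mode}_{what}"
        for target in ("absolute", "relative")
        for transform, mode in FIT_KINDS
        for what in ("slope", "r2")
    ]
    track_df = pd.DataFrame(track_rows, columns=track_cols if track_rows else None)
    if not track_rows:
        track_df = pd.DataFrame(columns=track_cols)
    point_cols = ["track_id", "frame", "timestamp_s", "length_um",
                  "relative_length_um", "node_ids", "hop_count",
                  "successor_node_ids"]
    point_df = pd.DataFrame(point_rows, columns=point_cols)
    return track_df, point_df


@dataclass
class DerivedSummary:
    """Headline outputs of one position."""

    mycelium_growth_rate_h: Optional[float]
    germination_delay_h: Optional[float]
    first_nonzero_length_h: Optional[float]
    tip_rate_mean_um_h: Optional[float]
    tip_rate_sd_um_h: Optional[float]
    n_tracks: int
    n_tracks_fitted: int

    def to_dict(self) -> dict:
        return {
            "mycelium_growth_rate_h": self.mycelium_growth_rate_h,
            "germination_delay_h": self.germination_delay_h,
            "first_nonzero_length_h": self.first_nonzero_length_h,
            "tip_rate_mean_um_h": self.tip_rate_mean_um_h,
            "tip_rate_sd_um_h": self.tip_rate_sd_um_h,
            "n_tracks": self.n_tracks,
            "n_tracks_fitted": self.n_tracks_fitted,
        }


def derive_summary(
    series: pd.DataFrame,
    tracks: Sequence[HyphaTrack],
) -> DerivedSummary:
    """Mycelium growth rate µ, germination delay, and tip elongation rates.

    µ is the logarithmic-optimized slope of total mycelium length over time.
    Germination delay is the timestamp of the first frame of the
    earliest-starting hypha track (spurious speck tracks excluded); the first
    frame with nonzero mycelium length is emitted as a secondary estimate.
    Tip rates are summarised as mean ± sample standard deviation over the
    tracks eligible for fitting.
    """
    mu = None
    first_nonzero = None
    if len(series):
        fit = fit_series(series["timestamp_h"], series["total_length_um"],
                         "logarithmic", "optimized")
        mu = None if fit is None else fit.slope
        nz = series.loc[series["total_length_um"] > 0, "timestamp_h"]
        first_nonzero = float(nz.iloc[0]) if len(nz) else None

    real = [t for t in tracks if not t.flagged_spurious]
    delay = None
    if real:
        starts = [t.records[0].frame for t in real]
        f0 = min(starts)
        delay = float(series.loc[series["frame"] == f0, "timestamp_h"].iloc[0])

    rates = []
    for t in real:
        if not t.eligible_for_fits():
            continue
        frames = np.asarray(t.frames)
        t_h = series.set_index("frame").loc[frames, "timestamp_h"].to_numpy()
        fit = fit_series(t_h, t.lengths_um, "linear", "optimized")
        if fit is not None:
            rates.append(fit.slope)
    mean = float(np.mean(rates)) if rates else None
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else None
    return DerivedSummary(
        mycelium_growth_rate_h=mu,
        germination_delay_h=delay,
        first_nonzero_length_h=first_nonzero,
        tip_rate_mean_um_h=mean,
        tip_rate_sd_um_h=sd,
        n_tracks=len(tracks),
        n_tracks_fitted=len(rates),
    )
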