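"""Synthetic mycelium growth with ground truth, and phase-contrast-like rendering.

The generator emulates the features of the real imaging problem that the
pipeline must cope with: dark filamentous foreground on a bright noisy
background, a germination delay, per-tip elongation at rates drawn from a
truncated normal, stochastic lateral branching along existing hyphae, slow
stage drift, and (optionally) hyphae that grow into each other and merge.

Growth model.  A spore germinates after ``germination_delay_h``; each active
tip advances by rate·Δt per frame along a direction with small angular
diffusion.  Branch events follow a Poisson process per unit mycelium length
(lateral branching, the dominant mode in mycelial bacteria); daughters emerge
at ± ``branch_angle_deg`` from the local axis with fresh rates.  Total length
then follows dL/dt = v·N, dN/dt = β·L, i.e. L ∝ sinh(µ_mech·τ) with
µ_mech = √(v̄·β).  Because a fit of ln L over a finite window sees the early
transient, the user-facing rate parameter ``specific_rate_h`` is defined as
the *observable* specific growth rate: the slope the standard
optimized-window logarithmic fit returns on the noise-free mean curve over
the configured frame grid.  The mechanistic β is derived from it by
deterministic inversion at construction time, so the generator's ground
truth and the pipeline's estimator speak the same language.

Tips never intersect by default: a tip about to run into another hypha (or
the field border) halts.  ``allow_overlap=True`` disables avoidance so that
merging hyphae — and the track-exclusion logic downstream — can be tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.stats import truncnorm
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_footprint

from .io_stack import ImageStack
from .metrics import fit_series


@dataclass
class GrowthParams:
    """Conditions of a synthetic growth experiment.

    Rates and intervals must be positive; the seed fixes the realization.
    """

    seed: int = 0
    germination_delay_h: float = 12.0
    elongation_rate_mean_um_h: float = 16.33
    elongation_rate_sd_um_h: float = 6.91
    specific_rate_h: float = 0.45            # observable µ of total length
    branch_rate_per_um_h: Optional[float] = None  # mechanistic override
    branch_angle_deg: float = 75.0
    branch_angle_sd_deg: float = 10.0
    direction_jitter_deg: float = 3.0
    frame_interval_s: float = 1200.0
    n_frames: int = 60
    field_px: int = 512
    calibration_um_per_px: float = 0.65
    hyphal_width_um: float = 1.0
    spore_radius_um: float = 0.8
    background_level: float = 100.0
    contrast: float = 40.0
    noise_sd: float = 8.0
    gradient_amplitude: float = 5.0
    drift_step_px: int = 1
    drift_schedule: Optional[np.ndarray] = None  # (n_frames, 2) cumulative px
    n_spores: int = 1
    spore_gap_um: float = 60.0      # separation of spores when n_spores == 2
    spore_offset_um: float = 0.4    # lateral aiming offset of opposing spores
    allow_overlap: bool = False

    def __post_init__(self):
        if not (self.germination_delay_h >= 0 and self.frame_interval_s > 0
                and self.n_frames >= 1 and self.elongation_rate_mean_um_h > 0
                and self.specific_rate_h >= 0):
            raise ValueError("invalid growth parameters")

    @property
    def field_um(self) -> float:
        return self.field_px * self.calibration_um_per_px

    @property
    def frame_times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s / 3600.0

    def mean_elongation_rate(self) -> float:
        """Mean of the truncated-at-zero elongation-rate distribution."""
        m, s = self.elongation_rate_mean_um_h, self.elongation_rate_sd_um_h
        if s <= 0:
            return m
        return float(truncnorm.mean((0 - m) / s, np.inf, loc=m, scale=s))


def calibrated_branch_rate(params: GrowthParams) -> float:
    """Mechanistic lateral branch rate β (µm⁻¹·h⁻¹) for the target rate.

    Inverts the deterministic mean curve L(τ) ∝ sinh(√(v̄β)·τ) sampled on the
    configured frame grid so that the optimized-window logarithmic fit
    recovers ``specific_rate_h``.
    """
    if params.branch_rate_per_um_h is not None:
        return params.branch_rate_per_um_h
    mu_target = params.specific_rate_h
    if mu_target == 0:
        return 0.0
    vbar = params.mean_elongation_rate()
    t = params.frame_times_h
    tau = t - params.germination_delay_h
    grid = t[tau > 0]
    tau = tau[tau > 0]
    if len(tau) < 3:
        return mu_target ** 2 / vbar

    def observed(mu_mech: float) -> float:
        y = np.sinh(mu_mech * tau)
        fit = fit_series(grid, y, "logarithmic", "optimized")
        return np.nan if fit is None else fit.slope

    def f(mu_mech):
        return observed(mu_mech) - mu_target

    lo, hi = 1e-4, 10.0
    try:
        flo, fhi = f(lo), f(hi)
        if not (np.isfinite(flo) and np.isfinite(fhi)) or flo * fhi > 0:
            return mu_target ** 2 / vbar
        mu_mech = brentq(f, lo, hi, xtol=1e-8)
    except ValueError:
        return mu_target ** 2 / vbar
    return mu_mech ** 2 / vbar


@dataclass
class TrueSegment:
    """One hypha of the ground truth: an elongating polyline."""

    seg_id: int
    parent: Optional[int]
    spore_index: int
    birth_h: float
    rate_um_h: float
    vertices: list          # [(x_um, y_um)] appended per frame
    vertex_times_h: list    # time each vertex was reached
    active: bool = True

    def length_at(self, t_h: float) -> float:
        v = np.asarray(self.vertices)
        times = np.asarray(self.vertex_times_h)
        sel = times <= t_h + 1e-9
        if sel.sum() < 2:
            return 0.0
        pts = v[sel]
        return float(np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum())

    def polyline_at(self, t_h: float) -> np.ndarray:
        v = np.asarray(self.vertices)
        times = np.asarray(self.vertex_times_h)
        return v[times <= t_h + 1e-9]

    def tip_at(self, t_h: float) -> Optional[np.ndarray]:
        pts = self.polyline_at(t_h)
        return pts[-1] if len(pts) else None


@dataclass
class SyntheticGroundTruth:
    """Ground truth of one realization: segments, per-frame aggregates."""

    params: GrowthParams
    branch_rate_per_um_h: float
    segments: list
    total_length_um: np.ndarray     # per frame
    tip_count: np.ndarray           # per frame (= number of born segments)
    branch_count: np.ndarray        # per frame (= number of branch events)
    drift_px: Optional[np.ndarray] = None   # set by render()
    overlap_frame: Optional[int] = None     # set by render() for n_spores > 1

    @property
    def frame_times_h(self) -> np.ndarray:
        return self.params.frame_times_h

    def tip_positions(self, frame: int) -> dict[int, np.ndarray]:
        t = self.frame_times_h[frame]
        out = {}
        for s in self.segments:
            tip = s.tip_at(t)
            if tip is not None:
                out[s.seg_id] = tip
        return out

    def tip_rates(self) -> dict[int, float]:
        return {s.seg_id: s.rate_um_h for s in self.segments}


def _densify(p0: np.ndarray, p1: np.ndarray, spacing: float) -> np.ndarray:
    n = max(int(np.ceil(np.linalg.norm(p1 - p0) / spacing)), 1)
    f = np.linspace(0.0, 1.0, n + 1)[1:]
    return p0[None, :] + f[:, None] * (p1 - p0)[None, :]


def grow(params: GrowthParams) -> SyntheticGroundTruth:
    """Run the growth model; fully deterministic given ``params.seed``."""
    rng = np.random.default_rng([params.seed, 0])
    beta = calibrated_branch_rate(params)
    times = params.frame_times_h
    field = params.field_um
    margin = 2.0
    collide_um = params.hyphal_width_um

    def draw_rate():
        if params.elongation_rate_sd_um_h <= 0:
            return params.elongation_rate_mean_um_h
        while True:
            v = rng.normal(params.elongation_rate_mean_um_h,
                           params.elongation_rate_sd_um_h)
            if v > 0:
                return v

    # spore positions and germ-tube directions
    if params.n_spores == 1:
        spores = [np.array([field / 2, field / 2])]
        directions = [rng.uniform(0, 2 * np.pi)]
    elif params.n_spores == 2:
        gap = params.spore_gap_um
        off = params.spore_offset_um
        spores = [
            np.array([field / 2 - gap / 2, field / 2]),
            np.array([field / 2 + gap / 2, field / 2 + off]),
        ]
        # aimed at each other, small per-seed perturbation
        directions = [rng.normal(0.0, 0.01), np.pi + rng.normal(0.0, 0.01)]
    else:
        raise ValueError("n_spores must be 1 or 2")

    segments: list[TrueSegment] = []
    seg_dirs: dict[int, float] = {}
    germinated = [False] * params.n_spores

    # occupancy samples for collision checks: (points, seg ids)
    occ_pts: list[np.ndarray] = []
    occ_seg: list[int] = []

    def occupied_tree():
        if not occ_pts:
            return None, None, None
        pts = np.concatenate(occ_pts)
        return cKDTree(pts), pts, np.asarray(occ_seg)

    def register_step(seg_id, p0, p1):
        dense = _densify(p0, p1, 0.5 * collide_um)
        occ_pts.append(dense)
        occ_seg.extend([seg_id] * len(dense))

    total_length = np.zeros(params.n_frames)
    tip_count = np.zeros(params.n_frames, dtype=int)
    branch_count = np.zeros(params.n_frames, dtype=int)
    n_branches = 0
    warned = False

    for i, t in enumerate(times):
        dt = times[i] - times[i - 1] if i > 0 else 0.0
        if t > params.germination_delay_h:
            for si in range(params.n_spores):
                if not germinated[si]:
                    seg = TrueSegment(
                        seg_id=len(segments), parent=None, spore_index=si,
                        birth_h=params.germination_delay_h,
                        rate_um_h=draw_rate(),
                        vertices=[spores[si].copy()],
                        vertex_times_h=[params.germination_delay_h],
                    )
                    segments.append(seg)
                    seg_dirs[seg.seg_id] = directions[si]
                    germinated[si] = True
            if params.allow_overlap:
                tree, tree_pts, seg_of = None, None, None
            else:
                tree, tree_pts, seg_of = occupied_tree()
            # elongation
            for seg in segments:
                if not seg.active:
                    continue
                step_dt = min(dt, t - seg.birth_h)
                if step_dt <= 0:
                    continue
                theta = seg_dirs[seg.seg_id] + np.deg2rad(
                    rng.normal(0.0, params.direction_jitter_deg)
                )
                seg_dirs[seg.seg_id] = theta
                p0 = np.asarray(seg.vertices[-1], dtype=float)
                p1 = p0 + seg.rate_um_h * step_dt * np.array(
                    [np.cos(theta), np.sin(theta)]
                )
                if np.any(p1 < margin) or np.any(p1 > field - margin):
                    seg.active = False
                    if not warned:
                        warnings.warn("growth reached the field border; halting tip")
                        warned = True
                    continue
                if not params.allow_overlap and tree is not None:
                    probes = _densify(p0, p1, 0.5 * collide_um)
                    hit = False
                    for pr in probes:
                        idx = tree.query_ball_point(pr, collide_um)
                        for k in idx:
                            sid = seg_of[k]
                            if sid == seg.seg_id:
                                continue
                            if (seg.parent is not None and sid == seg.parent
                                    and np.linalg.norm(
                                        tree_pts[k] - np.asarray(seg.vertices[0])
                                    ) < 2.5):
                                continue
                            hit = True
                            break
                        if hit:
                            break
                    if hit:
                        seg.active = False
                        continue
                seg.vertices.append(p1)
                seg.vertex_times_h.append(t)
                register_step(seg.seg_id, p0, p1)
            # lateral branching
            lengths = np.array([s.length_at(t) for s in segments])
            total = lengths.sum()
            if beta > 0 and total > 0:
                n_candidates = len(lengths)
                probs = lengths / total
                for _ in range(rng.poisson(beta * total * dt)):
                    parent = segments[rng.choice(n_candidates, p=probs)]
                    pts = parent.polyline_at(t)
                    if len(pts) < 2:
                        continue
                    steps = np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1))
                    arc = np.concatenate([[0.0], np.cumsum(steps)])
                    u = rng.uniform(0, arc[-1])
                    j = int(np.searchsorted(arc, u, side="right") - 1)
                    j = min(j, len(steps) - 1)
                    frac = (u - arc[j]) / steps[j] if steps[j] > 0 else 0.0
                    origin = pts[j] + frac * (pts[j + 1] - pts[j])
                    tangent = np.arctan2(*(pts[j + 1] - pts[j])[::-1])
                    sign = rng.choice([-1.0, 1.0])
                    angle = tangent + sign * np.deg2rad(
                        rng.normal(params.branch_angle_deg,
                                   params.branch_angle_sd_deg)
                    )
                    child = TrueSegment(
                        seg_id=len(segments), parent=parent.seg_id,
                        spore_index=parent.spore_index, birth_h=t,
                        rate_um_h=draw_rate(),
                        vertices=[origin.copy()], vertex_times_h=[t],
                    )
                    segments.append(child)
                    seg_dirs[child.seg_id] = angle
                    n_branches += 1
        total_length[i] = sum(s.length_at(t) for s in segments)
        tip_count[i] = sum(1 for s in segments if len(s.vertices) >= 2)
        branch_count[i] = n_branches

    return SyntheticGroundTruth(
        params=params,
        branch_rate_per_um_h=beta,
        segments=segments,
        total_length_um=total_length,
        tip_count=tip_count,
        branch_count=branch_count,
    )


def _raster_polyline(mask: np.ndarray, pts_um: np.ndarray, cal: float) -> None:
    px = np.round(pts_um[:, ::-1] / cal).astype(int)  # (row, col) = (y, x)/cal
    h, w = mask.shape
    for k in range(len(px) - 1):
        rr, cc = draw_line(px[k, 0], px[k, 1], px[k + 1, 0], px[k + 1, 1])
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        mask[rr[keep], cc[keep]] = True


def _frame_mask(truth: SyntheticGroundTruth, frame: int,
                spore_index: Optional[int] = None) -> np.ndarray:
    p = truth.params
    cal = p.calibration_um_per_px
    mask = np.zeros((p.field_px, p.field_px), dtype=bool)
    t = truth.frame_times_h[frame]
    for s in truth.segments:
        if spore_index is not None and s.spore_index != spore_index:
            continue
        pts = s.polyline_at(t)
        if len(pts) >= 2:
            _raster_polyline(mask, pts, cal)
    width_px = p.hyphal_width_um / cal
    if width_px >= 2.5:
        mask = ndi.binary_dilation(mask, disk_footprint(int(round(width_px / 2))))
    elif width_px >= 1.5:
        # ~2 px stroke: what a thin filament covers after optical blur
        mask = ndi.binary_dilation(mask, np.ones((2, 2), dtype=bool))
    # spores are visible from the start
    field = p.field_um
    if spore_index is None:
        indices = range(p.n_spores)
    else:
        indices = [spore_index]
    for si in indices:
        if p.n_spores == 1:
            centre = np.array([field / 2, field / 2])
        else:
            gap, off = p.spore_gap_um, p.spore_offset_um
            centre = (np.array([field / 2 - gap / 2, field / 2]) if si == 0
                      else np.array([field / 2 + gap / 2, field / 2 + off]))
        r = max(p.spore_radius_um / cal, 1.0)
        rr, cc = draw_disk((centre[1] / cal, centre[0] / cal), r, shape=mask.shape)
        mask[rr, cc] = True
    return mask


def render(truth: SyntheticGroundTruth) -> tuple[ImageStack, list[np.ndarray]]:
    """Render the ground truth into a drifting, noisy phase-contrast-like stack.

    Returns the stack and the per-frame true foreground masks in undrifted
    (truth) coordinates.  Fills ``truth.drift_px`` and, for two-spore runs,
    ``truth.overlap_frame`` (first frame where the lineages' rasters touch).
    """
    p = truth.params
    rng = np.random.default_rng([p.seed, 1])
    n = p.n_frames
    size = p.field_px

    if p.drift_schedule is not None:
        drift = np.asarray(p.drift_schedule, dtype=int)
        if drift.shape != (n, 2):
            raise ValueError("drift_schedule must have shape (n_frames, 2)")
    else:
        steps = rng.integers(-p.drift_step_px, p.drift_step_px + 1, size=(n, 2))
        steps[0] = 0
        drift = np.cumsum(steps, axis=0)
    truth.drift_px = drift

    yy, xx = np.mgrid[0:size, 0:size]
    gradient = p.gradient_amplitude * (
        0.5 * xx / size + 0.3 * yy / size
        + 0.2 * np.sin(2 * np.pi * xx / size) * np.cos(2 * np.pi * yy / size)
    )

    frames = np.empty((n, size, size), dtype=np.float32)
    true_masks: list[np.ndarray] = []
    overlap_frame = None
    for f in range(n):
        mask = _frame_mask(truth, f)
        true_masks.append(mask)
        if p.n_spores == 2 and overlap_frame is None:
            a = _frame_mask(truth, f, spore_index=0)
            b = _frame_mask(truth, f, spore_index=1)
            # lineages closer than ~3 px are unresolvable for any segmentation
            # that bridges single-pixel gaps, so count that as overlapping
            if np.any(ndi.binary_dilation(a, np.ones((7, 7), bool)) & b):
                overlap_frame = f
        img = np.full((size, size), p.background_level, dtype=np.float64)
        img += gradient
        img[mask] -= p.contrast
        if np.any(drift[f] != 0):
            img = ndi.shift(img, drift[f], order=0, mode="constant",
                            cval=p.background_level)
        # sensor noise is fixed to the camera, not the drifting sample
        if p.noise_sd > 0:
            img += rng.normal(0.0, p.noise_sd, img.shape)
        frames[f] = img
    truth.overlap_frame = overlap_frame

    stack = ImageStack(
        frames=frames,
        timestamps=np.arange(n) * p.frame_interval_s,
        calibration=p.calibration_um_per_px,
        position_id=f"sim-{p.seed}",
    )
    return stack, true_masks


def simulate(params: GrowthParams) -> tuple[SyntheticGroundTruth, ImageStack, list[np.ndarray]]:
    """Convenience: grow and render in one call."""
    truth = grow(params)
    stack, masks = render(truth)
    return truth, stack, masks


def two_spore_overlap_params(seed: int, **overrides) -> GrowthParams:
    """Scenario for merge/shortcut testing: two germ tubes growing into each
    other with a sub-width lateral offset; avoidance disabled."""
    base = dict(
        seed=seed,
        n_spores=2,
        allow_overlap=True,
        germination_delay_h=2.0,
        n_frames=30,
        frame_interval_s=1200.0,
        field_px=256,
        specific_rate_h=0.0,
        branch_rate_per_um_h=0.0,
        elongation_rate_mean_um_h=16.33,
        elongation_rate_sd_um_h=3.0,
        direction_jitter_deg=0.5,
        spore_gap_um=60.0,
        spore_offset_um=0.4,
        drift_step_px=0,
    )
    base.update(overrides)
    return GrowthParams(**base)
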