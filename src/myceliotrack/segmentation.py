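"""Binarization of background-corrected frames and speckle cleaning.

Phase-contrast mycelium appears as dark filaments on a bright background.
The default method is an adapted Niblack threshold: the classical local
criterion (pixel < local mean + k·local std, k < 0) combined with an absolute
contrast floor that suppresses responses in texture-free noisy regions, where
plain Niblack fires on a fixed fraction of pixels regardless of content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing as _closing
from skimage.morphology import remove_small_holes, remove_small_objects

METHODS = ("niblack-adapted", "mean-local", "otsu-global")


@dataclass
class BinaryMask:
    """Boolean foreground mask plus the provenance of its computation."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.mask.shape


def robust_noise_sigma(frame: np.ndarray) -> float:
    """Noise σ estimate from the median absolute deviation (Gaussian scaling)."""
    frame = np.asarray(frame, dtype=np.float64)
    mad = np.median(np.abs(frame - np.median(frame)))
    return 1.4826 * float(mad)


def _local_stats(frame: np.ndarray, window_px: int):
    """Local mean and std over a square window (reflected borders)."""
    f = np.asarray(frame, dtype=np.float64)
    mean = ndi.uniform_filter(f, window_px, mode="reflect")
    sq = ndi.uniform_filter(f * f, window_px, mode="reflect")
    var = np.clip(sq - mean * mean, 0.0, None)
    return mean, np.sqrt(var)


def binarize(
    frame: np.ndarray,
    calibration: float,
    method: str = "niblack-adapted",
    window_um: float = 15.0,
    k: float = -0.6,
    abs_contrast: Optional[float] = None,
    invert: bool = False,
) -> BinaryMask:
    """Binarize a background-corrected frame; dark filaments map to True.

    niblack-adapted : foreground iff  x < mean + k·std  AND  x < mean − c_abs,
                      with c_abs = ``abs_contrast`` or 3× robust noise σ.
    mean-local      : foreground iff  x < mean − c_abs.
    otsu-global     : global Otsu threshold on the corrected intensities.

    ``window_um`` is converted through the calibration; a window below 3 px is
    rejected as a configuration error.
    """
    if method not in METHODS:
        raise ValueError(f"unknown binarization method {method!r}; one of {METHODS}")
    frame = np.asarray(frame, dtype=np.float64)
    if invert:
        frame = -frame

    window_px = int(round(window_um / calibration))
    if method != "otsu-global" and window_px < 3:
        raise ValueError(
            f"binarization window {window_um} µm is {window_px} px at "
            f"{calibration} µm/px; must be at least 3 px"
        )
    if window_px % 2 == 0:
        window_px += 1

    if abs_contrast is None:
        abs_contrast = 3.0 * robust_noise_sigma(frame)

    if method == "otsu-global":
        if np.ptp(frame) == 0:
            mask = np.zeros(frame.shape, dtype=bool)
        else:
            mask = frame < threshold_otsu(frame)
    else:
        mean, std = _local_stats(frame, window_px)
        floor = frame < mean - abs_contrast
        if method == "niblack-adapted":
            mask = (frame < mean + k * std) & floor
        else:  # mean-local
            mask = floor

    return BinaryMask(
        mask=mask,
        provenance={
            "method": method,
            "window_um": window_um,
            "window_px": window_px,
            "k": k,
            "abs_contrast": float(abs_contrast),
            "invert": bool(invert),
        },
    )


def clean_mask(
    mask: BinaryMask | np.ndarray,
    calibration: float,
    min_object_um2: float = 1.0,
    max_hole_um2: float = 0.5,
    closing_um: float = 0.7,
) -> BinaryMask:
    """Clean speckle artifacts from a binary mask.

    A morphological closing of about one hyphal width (``closing_um``) bridges
    single-pixel detection gaps along thin filaments, then foreground
    components below ``min_object_um2`` are removed and enclosed background
    holes below ``max_hole_um2`` are filled (areas converted via calibration²).
    """
    if min_object_um2 < 0 or max_hole_um2 < 0:
        raise ValueError("area thresholds must be >= 0")
    provenance = {}
    if isinstance(mask, BinaryMask):
        provenance = dict(mask.provenance)
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    px_area = calibration * calibration
    min_px = int(np.ceil(min_object_um2 / px_area))
    hole_px = int(np.ceil(max_hole_um2 / px_area))
    out = mask.copy()
    closing_px = int(round(closing_um / calibration)) if closing_um > 0 else 0
    if min_px > 1:
        # speckles are removed before closing so that closing cannot weld
        # isolated noise pixels into objects above the size threshold;
        # 8-connectivity for foreground, matching the skeleton convention
        out = remove_small_objects(out, max_size=min_px - 1, connectivity=2)
    if closing_px >= 1 and out.any():
        # square footprint so diagonal single-pixel gaps get bridged too
        out = _closing(out, np.ones((2 * closing_px + 1,) * 2, dtype=bool))
        if min_px > 1:
            out = remove_small_objects(out, max_size=min_px - 1, connectivity=2)
    if hole_px > 1:
        out = remove_small_holes(out, max_size=hole_px - 1)
    provenance.update(
        cleaning={"min_object_um2": min_object_um2, "max_hole_um2": max_hole_um2,
                  "min_object_px": min_px, "max_hole_px": hole_px,
                  "closing_px": closing_px}
    )
    return BinaryMask(mask=out, provenance=provenance)
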