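"""Calibrated time-lapse stack input, drift compensation and background correction.

Stacks are multi-page TIFF or OME-TIFF, one stack per imaged position.  The
pixel size (µm/px, isotropic) and per-frame timestamps come from the OME-XML
metadata when present and can be overridden (they must be, for plain TIFF
without metadata).  Stage drift is compensated by translation-only,
integer-pixel registration; shading and uneven illumination are removed by
subtracting a heavily blurred version of each frame.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi
import tifffile
from skimage.registration import phase_cross_correlation


class StackInputError(ValueError):
    """The input file is missing, unreadable, or not a TIFF stack."""


class StackConfigError(ValueError):
    """Required acquisition metadata is missing and no override was given."""


@dataclass
class ImageStack:
    """A calibrated time-lapse image stack for one position.

    frames        : (T, H, W) float array, acquisition order
    timestamps    : seconds since acquisition start, strictly increasing
    calibration   : µm per pixel (isotropic, > 0)
    position_id   : label of the imaged position
    crop          : optional (r0, r1, c0, c1), half-open pixel intervals
    drift_offsets : per-frame (dr, dc) integer translation applied during
                    registration (frame 0 is the reference, offset (0, 0))
    """

    frames: np.ndarray
    timestamps: np.ndarray
    calibration: float
    position_id: str = "pos0"
    crop: Optional[tuple[int, int, int, int]] = None
    drift_offsets: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.frames) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (self.calibration > 0):
            raise ValueError("calibration must be > 0 µm/px")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def hours(self) -> np.ndarray:
        return self.timestamps / 3600.0

    def cropped(self, rect: tuple[int, int, int, int]) -> "ImageStack":
        r0, r1, c0, c1 = rect
        return ImageStack(
            frames=self.frames[:, r0:r1, c0:c1].copy(),
            timestamps=self.timestamps,
            calibration=self.calibration,
            position_id=self.position_id,
            crop=rect,
            drift_offsets=self.drift_offsets,
        )


_OME = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"


def _parse_ome(xml: str) -> tuple[Optional[float], Optional[list[float]], Optional[float]]:
    """Extract (pixel size µm, per-plane DeltaT seconds, TimeIncrement seconds)."""
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None, None, None
    pixels = root.find(f".//{_OME}Pixels")
    if pixels is None:
        # tolerate other namespace versions
        pixels = next((e for e in root.iter() if e.tag.endswith("Pixels")), None)
    if pixels is None:
        return None, None, None
    size = pixels.get("PhysicalSizeX")
    calibration = float(size) if size is not None else None
    increment = pixels.get("TimeIncrement")
    time_increment = float(increment) if increment is not None else None
    deltas = []
    for plane in (e for e in pixels.iter() if e.tag.endswith("Plane")):
        dt = plane.get("DeltaT")
        if dt is None:
            deltas = []
            break
        deltas.append(float(dt))
    return calibration, (deltas or None), time_increment


def read_stack(
    path,
    calibration_override: Optional[float] = None,
    interval_override: Optional[float] = None,
    position_id: Optional[str] = None,
) -> ImageStack:
    """Read a multi-page TIFF / OME-TIFF time-lapse stack.

    Calibration and timestamps come from OME metadata when present; explicit
    overrides always win.  A plain TIFF without metadata requires both
    overrides, otherwise a :class:`StackConfigError` names the missing field.
    """
    path = Path(path)
    if not path.exists():
        raise StackInputError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            ome_xml = tif.ome_metadata if tif.is_ome else None
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise StackInputError(f"unreadable TIFF stack {path}: {exc}") from exc
    if frames is None or np.size(frames) == 0:
        raise StackInputError(f"{path}: no image data (truncated or empty file)")
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise StackInputError(
            f"{path}: expected a (T, H, W) stack, got shape {frames.shape}"
        )
    frames = frames.astype(np.float32)

    meta_cal = meta_deltas = meta_increment = None
    if ome_xml:
        meta_cal, meta_deltas, meta_increment = _parse_ome(ome_xml)

    calibration = calibration_override if calibration_override is not None else meta_cal
    if calibration is None:
        raise StackConfigError(
            f"{path}: no pixel calibration in metadata; pass calibration_um_per_px"
        )

    n = len(frames)
    if interval_override is not None:
        timestamps = np.arange(n) * float(interval_override)
    elif meta_deltas is not None and len(meta_deltas) == n:
        timestamps = np.asarray(meta_deltas, dtype=float)
    elif meta_increment is not None:
        timestamps = np.arange(n) * meta_increment
    else:
        raise StackConfigError(
            f"{path}: no frame timing in metadata; pass interval_s"
        )

    return ImageStack(
        frames=frames,
        timestamps=timestamps,
        calibration=float(calibration),
        position_id=position_id or path.stem,
    )


def write_stack(stack: ImageStack, path) -> None:
    """Write an OME-TIFF with calibration and per-plane timestamps."""
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        ome=True,
        metadata={
            "axes": "TYX",
            "PhysicalSizeX": stack.calibration,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.calibration,
            "PhysicalSizeYUnit": "µm",
            "Plane": {"DeltaT": [float(t) for t in stack.timestamps]},
        },
    )


def _shift_frame(frame: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Integer translation; border pixels filled with the frame median."""
    fill = float(np.median(frame))
    return ndi.shift(frame, offset, order=0, mode="constant", cval=fill)


def _structure_image(frame: np.ndarray, calibration: float,
                     blur_um: float = 7.5, clip_sigma: float = 4.0) -> np.ndarray:
    """Noise-suppressed dark-structure image used for registration.

    Background-corrects the frame and keeps only excursions darker than
    ``clip_sigma`` robust noise σ — phase correlation then locks onto the
    mycelium instead of the (non-drifting) sensor noise.
    """
    corrected = background_correct(frame, blur_um, calibration)
    mad = np.median(np.abs(corrected - np.median(corrected)))
    sigma = 1.4826 * float(mad)
    return np.clip(-corrected - clip_sigma * sigma, 0.0, None)


# frames with fewer registerable structure pixels keep the previous offset
MIN_STRUCTURE_PX = 30


def register_stack(stack: ImageStack) -> ImageStack:
    """Compensate stage drift by translation-only, integer-pixel registration.

    Each frame is aligned to the previous *registered* frame by FFT
    cross-correlation of noise-suppressed structure images, so offsets
    accumulate relative to frame 0.  Frames without registerable structure
    (e.g. before germination) inherit the previous offset; implausibly large
    estimates (beyond a quarter of the frame) are rejected the same way.  The
    offsets recorded are the translations applied (a frame drifted by
    (+3, −2) px gets offset (−3, +2)).
    """
    if len(stack) < 2:
        raise ValueError("registration needs at least 2 frames")
    registered = np.empty_like(stack.frames)
    registered[0] = stack.frames[0]
    offsets = np.zeros((len(stack), 2), dtype=int)
    h, w = stack.frames.shape[1:]
    prev_struct = _structure_image(stack.frames[0], stack.calibration)
    for i in range(1, len(stack)):
        cur_struct = _structure_image(stack.frames[i], stack.calibration)
        # the reference is already registered, so the estimated translation is
        # the absolute offset of frame i
        dr, dc = offsets[i - 1]
        if (prev_struct > 0).sum() >= MIN_STRUCTURE_PX and \
                (cur_struct > 0).sum() >= MIN_STRUCTURE_PX:
            shift, _, _ = phase_cross_correlation(
                prev_struct, cur_struct, upsample_factor=1, normalization=None
            )
            est_r = int(round(float(shift[0])))
            est_c = int(round(float(shift[1])))
            step_r = est_r - int(offsets[i - 1][0])
            step_c = est_c - int(offsets[i - 1][1])
            if abs(step_r) <= h // 4 and abs(step_c) <= w // 4:
                dr, dc = est_r, est_c
        offsets[i] = (dr, dc)
        registered[i] = _shift_frame(stack.frames[i], (int(dr), int(dc)))
        prev_struct = _shift_frame(cur_struct, (int(dr), int(dc)))
    return ImageStack(
        frames=registered,
        timestamps=stack.timestamps,
        calibration=stack.calibration,
        position_id=stack.position_id,
        crop=stack.crop,
        drift_offsets=offsets,
    )


def background_correct(
    frame: np.ndarray, blur_um: float, calibration: float
) -> np.ndarray:
    """Subtract a blurred background estimate (σ = blur_um / calibration).

    The background is a Gaussian blur of a median-prefiltered copy of the
    frame (median window ≈ blur_um/2, odd): the median removes the thin dark
    filaments themselves, so the estimate tracks only the illumination field
    and the correction is idempotent up to noise.  The output is signed with
    mean ≈ 0 for structure-free images; dark filaments become negative
    excursions on a flat baseline.
    """
    if not blur_um > 0:
        raise ValueError("blur_um must be > 0")
    img = np.asarray(frame, dtype=np.float64)
    sigma_px = blur_um / calibration
    median_px = int(round(blur_um / 2.0 / calibration)) | 1
    if median_px <= 1:
        background = ndi.gaussian_filter(img, sigma_px, mode="nearest")
    elif median_px >= 5 and min(img.shape) >= 128:
        # the illumination field is smooth: estimate it at half resolution
        small = img[::2, ::2]
        base = ndi.median_filter(small, size=max(median_px // 2, 5) | 1,
                                 mode="nearest")
        base = ndi.gaussian_filter(base, sigma_px / 2.0, mode="nearest")
        background = ndi.zoom(base, (img.shape[0] / base.shape[0],
                                     img.shape[1] / base.shape[1]), order=1)
    else:
        base = ndi.median_filter(img, size=median_px, mode="nearest")
        background = ndi.gaussian_filter(base, sigma_px, mode="nearest")
    return img - background
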