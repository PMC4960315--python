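"""Lateral drift correction and per-frame cell detection.

Drift is estimated at integer-pixel resolution from the cross-correlation of
each frame with frame 0 (mean-subtracted, zero-padded); detection is a median
filter, a manual intensity threshold, and 8-connected component extraction
with binary centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import DimensionError, ValidationError
from .io_formats import AnalysisParameters, MovieStack

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class DriftTable:
    """Per-frame (dx, dy) offset of each frame relative to frame 0.

    ``offsets[t] = (dx, dy)`` means the content of frame ``t`` appears shifted
    by ``dx`` columns and ``dy`` rows with respect to frame 0.  Offsets are
    integer-valued unless the estimator's subpixel refinement was requested.
    """

    offsets: np.ndarray  # (T, 2), columns (dx, dy)

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 2 or self.offsets.shape[1] != 2:
            raise DimensionError("drift table must have shape (T, 2)")
        if self.offsets.shape[0] < 1 or tuple(self.offsets[0]) != (0.0, 0.0):
            raise ValidationError("drift table entry 0 must be (0, 0)")

    @property
    def n_frames(self) -> int:
        return self.offsets.shape[0]

    def rounded(self) -> np.ndarray:
        """(T, 2) integer offsets (nearest pixel)."""
        return np.round(self.offsets).astype(int)

    def residual(self) -> np.ndarray:
        """(T, 2) fractional remainder after integer translation."""
        return self.offsets - self.rounded()


@dataclass
class Detection:
    """One candidate cell object in one frame."""

    frame_index: int
    x_px: float
    y_px: float
    area_px: int
    mean_intensity: float


def _parabolic_offset(left: float, centre: float, right: float) -> float:
    """Vertex offset in [-0.5, 0.5] of a parabola through three equispaced samples."""
    denom = left - 2.0 * centre + right
    if denom >= 0:  # not a strict local maximum; keep the integer peak
        return 0.0
    return float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))


def _best_shift(
    reference: np.ndarray, frame: np.ndarray, subpixel: bool = False
) -> tuple[float, float]:
    """Shift maximising the zero-padded cross-correlation with the reference.

    Both images are mean-subtracted first.  Ties in the correlation peak are
    broken by the smallest |dx| + |dy|, then lexicographically on (dx, dy), so
    the result is deterministic.  With ``subpixel`` the integer peak is refined
    by a separable parabolic fit through its neighbours (offset within half a
    pixel, so integer shifts of clean images remain exact).
    """
    ref = reference.astype(np.float64)
    frm = frame.astype(np.float64)
    ref = ref - ref.mean()
    frm = frm - frm.mean()
    if not ref.any() or not frm.any():
        warnings.warn("zero-variance frame in drift estimation; assuming offset (0, 0)")
        return (0.0, 0.0)
    # full linear cross-correlation: corr[dy + H - 1, dx + W - 1] matches shift (dx, dy)
    corr = signal.fftconvolve(frm, ref[::-1, ::-1], mode="full")
    peak = corr.max()
    # guard against FFT round-off when several shifts are equally good
    candidates = np.argwhere(corr >= peak - 1e-9 * max(1.0, abs(peak)))
    shifts = candidates - np.array([ref.shape[0] - 1, ref.shape[1] - 1])
    dys, dxs = shifts[:, 0], shifts[:, 1]
    order = np.lexsort((dys, dxs, np.abs(dxs) + np.abs(dys)))
    best = order[0]
    dx, dy = float(dxs[best]), float(dys[best])
    if subpixel:
        iy, ix = candidates[best]
        if 0 < ix < corr.shape[1] - 1:
            dx += _parabolic_offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
        if 0 < iy < corr.shape[0] - 1:
            dy += _parabolic_offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    return dx, dy


def estimate_drift(movie: MovieStack, subpixel: bool = False) -> DriftTable:
    """Estimate the lateral (xy) drift of every frame relative to frame 0.

    The default resolution is one pixel (exact for integer shifts of
    noiseless images).  ``subpixel=True`` additionally refines each offset by
    parabolic interpolation of the correlation peak; frame translation is
    still performed at integer resolution, but the fractional remainder can
    then be subtracted from detected centroid positions downstream.
    """
    reference = movie.frames[0]
    offsets = np.zeros((movie.n_frames, 2), dtype=float)
    for t in range(1, movie.n_frames):
        offsets[t] = _best_shift(reference, movie.frames[t], subpixel=subpixel)
    return DriftTable(offsets)


def _translate(frame: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate a frame by (dx, dy) pixels, filling vacated pixels with 0."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = frame[src_y, src_x]
    return out


def correct_drift(movie: MovieStack, drift: DriftTable) -> MovieStack:
    """Translate each frame by minus its (nearest-integer) drift offset.

    Vacated pixels are zero-filled; any fractional part of the offsets is left
    for the caller to subtract from detected positions.
    """
    if drift.n_frames != movie.n_frames:
        raise DimensionError(
            f"drift table has {drift.n_frames} entries for a {movie.n_frames}-frame movie"
        )
    corrected = np.stack(
        [
            _translate(movie.frames[t], -int(dx), -int(dy))
            for t, (dx, dy) in enumerate(drift.rounded())
        ]
    )
    return MovieStack(
        frames=corrected,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
        channel_name=movie.channel_name,
    )


def detect_cells(
    frame: np.ndarray, params: AnalysisParameters, frame_index: int = 0
) -> list[Detection]:
    """Detect candidate cells in one frame.

    The frame is median filtered (window ``median_window_px``), thresholded at
    ``intensity_threshold`` (strictly above), and 8-connected components with
    at least ``min_object_area_px`` pixels become detections.  The centroid is
    the unweighted mean of the component's pixel coordinates by default; an
    intensity-weighted variant is available as a configuration switch.
    """
    if params.intensity_threshold is None:
        raise ValidationError("intensity_threshold must be set before detection")
    frame = np.asarray(frame, dtype=np.float64)
    filtered = ndimage.median_filter(frame, size=params.median_window_px)
    mask = filtered > params.intensity_threshold
    labels, n_objects = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    detections: list[Detection] = []
    if n_objects == 0:
        return detections
    index = np.arange(1, n_objects + 1)
    areas = ndimage.sum_labels(mask, labels, index).astype(int)
    means = ndimage.mean(filtered, labels, index)
    if params.intensity_weighted_centroid:
        centroids = ndimage.center_of_mass(filtered, labels, index)
    else:
        centroids = ndimage.center_of_mass(mask, labels, index)
    for area, mean_int, (cy, cx) in zip(areas, means, centroids):
        if area >= params.min_object_area_px:
            detections.append(
                Detection(
                    frame_index=frame_index,
                    x_px=float(cx),
                    y_px=float(cy),
                    area_px=int(area),
                    mean_intensity=float(mean_int),
                )
            )
    return detections


def detect_movie(movie: MovieStack, params: AnalysisParameters) -> list[list[Detection]]:
    """Run :func:`detect_cells` on every frame, returning detections grouped by frame."""
    return [detect_cells(movie.frames[t], params, frame_index=t) for t in range(movie.n_frames)]
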