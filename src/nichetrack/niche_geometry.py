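"""Distance fields around annotated niche regions and contact/proximal/distal zones.

The minimum Euclidean distance from every pixel to the vascular and to the
endosteal region is precomputed as a distance transform (0 inside the
region), scaled to micrometres.  Track centroids, which are real-valued, are
sampled from those fields bilinearly, so the sampling error is bounded by one
pixel.  Distances partition into three zones: *contact* within
``contact_cutoff_um`` (boundary included), *proximal* up to
``proximal_cutoff_um`` (boundary included), *distal* beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import RegionUndefinedError, ValidationError
from .io_formats import AnalysisParameters, RegionMap
from .tracking import Track

CONTACT = "contact"
PROXIMAL = "proximal"
DISTAL = "distal"


@dataclass
class DistanceField:
    """Euclidean distance (μm) to the nearest pixel of one niche region."""

    values_um: np.ndarray  # (H, W)
    region_label: str  # "vascular" | "endosteal"
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values_um.shape


def distance_field(
    mask: np.ndarray, pixel_size_um: float, region_label: str = ""
) -> DistanceField:
    """Exact Euclidean distance transform of the mask complement, in μm.

    Raises :class:`RegionUndefinedError` for an all-empty mask: distances to a
    region that was never annotated are undefined, not infinite.
    """
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise RegionUndefinedError(
            f"region {region_label or 'mask'} is undefined (empty annotation)"
        )
    values = ndimage.distance_transform_edt(~mask) * float(pixel_size_um)
    return DistanceField(values_um=values, region_label=region_label,
                         pixel_size_um=float(pixel_size_um))


def region_distance_fields(region_map: RegionMap) -> tuple[DistanceField, DistanceField]:
    """Distance fields for both regions of a :class:`RegionMap`."""
    return (
        distance_field(region_map.vascular_mask, region_map.pixel_size_um, "vascular"),
        distance_field(region_map.endosteal_mask, region_map.pixel_size_um, "endosteal"),
    )


def sample_field(field: DistanceField, x_px: np.ndarray, y_px: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the field at real-valued (x, y) pixel positions.

    Positions outside the grid are clamped to the border.
    """
    h, w = field.shape
    x = np.clip(np.asarray(x_px, dtype=float), 0.0, w - 1.0)
    y = np.clip(np.asarray(y_px, dtype=float), 0.0, h - 1.0)
    return ndimage.map_coordinates(field.values_um, [y, x], order=1, mode="nearest")


def sample_distances(
    track: Track,
    vascular_field: DistanceField,
    endosteal_field: DistanceField,
    params: AnalysisParameters,
) -> pd.DataFrame:
    """Per-frame distances of one track to both regions.

    Returns a frame-indexed table with columns
    ``track_id, frame, t_s, d_v_um, d_e_um`` (the label/zone columns are
    filled in by the interaction classifier).
    """
    if vascular_field.shape != endosteal_field.shape:
        raise ValidationError("vascular and endosteal fields must share one grid")
    frames = track.frames
    pos = track.positions
    d_v = sample_field(vascular_field, pos[:, 0], pos[:, 1])
    d_e = sample_field(endosteal_field, pos[:, 0], pos[:, 1])
    return pd.DataFrame(
        {
            "track_id": track.track_id,
            "frame": frames,
            "t_s": frames * params.frame_interval_s,
            "d_v_um": d_v,
            "d_e_um": d_e,
        }
    )


def classify_zone(d_um, params: AnalysisParameters):
    """Map distance(s) in μm to a zone name.

    ``d <= contact_cutoff_um`` is contact, ``d <= proximal_cutoff_um`` is
    proximal, anything farther is distal (both boundaries closed above).
    Accepts a scalar or an array; negative distances are rejected.
    """
    d = np.asarray(d_um, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    zones = np.where(
        d <= params.contact_cutoff_um,
        CONTACT,
        np.where(d <= params.proximal_cutoff_um, PROXIMAL, DISTAL),
    )
    if np.isscalar(d_um) or np.ndim(d_um) == 0:
        return str(zones[()])
    return zones
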