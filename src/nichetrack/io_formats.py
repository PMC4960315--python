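"""Readers, writers and on-disk schemas for movies, masks, tracks, events and parameters.

All distances are handled internally in micrometres and all times in seconds;
positions on disk are pixel coordinates with ``x`` = column, ``y`` = row,
origin at the top-left, 0-based.  Physical calibration (``pixel_size_um``,
``frame_interval_s``) is always user-supplied configuration rather than being
read from TIFF tags, so that a run is reproducible bit-exactly regardless of
which software wrote the image files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import DimensionError, FormatError, SchemaError, ValidationError

TRACK_COLUMNS = ["track_id", "frame", "x_px", "y_px", "interpolated"]
EVENT_COLUMNS = [
    "track_id",
    "label",
    "zone",
    "start_s",
    "end_s",
    "duration_s",
    "duration_class",
]
ZONE_COLUMNS = ["track_id", "frame", "t_s", "d_v_um", "d_e_um", "label", "zone"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MovieStack:
    """A time-ordered stack of 2D intensity frames with physical calibration.

    Parameters
    ----------
    frames
        ``(T, H, W)`` non-negative intensity array, acquisition order.
    pixel_size_um
        Isotropic pixel size in micrometres per pixel.
    frame_interval_s
        Time between consecutive frames in seconds.
    channel_name
        Free-text channel description.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError(
                f"movie must be a T x H x W stack with T >= 1, got shape {self.frames.shape}"
            )
        if np.any(self.frames < 0):
            raise FormatError("movie intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise FormatError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not self.frame_interval_s > 0:
            raise FormatError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) shape of every frame."""
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class RegionMap:
    """Binary vascular and endosteal domain masks on the movie's pixel grid."""

    vascular_mask: np.ndarray
    endosteal_mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.vascular_mask = np.asarray(self.vascular_mask) != 0
        self.endosteal_mask = np.asarray(self.endosteal_mask) != 0
        if self.vascular_mask.ndim != 2 or self.endosteal_mask.ndim != 2:
            raise DimensionError("region masks must be 2D")
        if self.vascular_mask.shape != self.endosteal_mask.shape:
            raise DimensionError(
                f"vascular mask {self.vascular_mask.shape} and endosteal mask "
                f"{self.endosteal_mask.shape} must share one grid"
            )
        if not self.pixel_size_um > 0:
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vascular_mask.shape

    @property
    def vascular_empty(self) -> bool:
        return not self.vascular_mask.any()

    @property
    def endosteal_empty(self) -> bool:
        return not self.endosteal_mask.any()

    def check_grid(self, shape: tuple[int, int]) -> None:
        """Assert that the masks live on the given (H, W) grid."""
        if self.shape != tuple(shape):
            raise DimensionError(
                f"region masks have shape {self.shape} but the movie grid is {tuple(shape)}"
            )


@dataclass
class AnalysisParameters:
    """Every numeric rule of the analysis, with the published defaults.

    Distance cutoffs define the three zones around a niche region: within
    ``contact_cutoff_um`` of the region is *contact*, between the contact and
    ``proximal_cutoff_um`` cutoffs is *proximal*, and beyond that is *distal*.
    ``hysteresis_um`` is the margin a distance must cross beyond a cutoff
    before a zone change is accepted (flicker suppression), and adjacent
    transient interactions shorter than ``merge_window_s`` are merged.
    Interactions shorter than ``long_duration_min`` minutes are classed
    *short*, the rest *long*.
    """

    pixel_size_um: float = 1.0
    frame_interval_s: float = 10.0
    median_window_px: int = 5
    intensity_threshold: float | None = None
    min_object_area_px: int = 4
    max_link_displacement_px: float = 15.0
    gap_memory_frames: int = 1
    min_track_frames: int = 10  # exclusive: keep tracks with MORE than this many frames
    contact_cutoff_um: float = 5.0
    proximal_cutoff_um: float = 25.0
    hysteresis_um: float = 1.0
    merge_window_s: float = 200.0
    long_duration_min: float = 60.0
    intensity_weighted_centroid: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.contact_cutoff_um < self.proximal_cutoff_um:
            raise ValidationError(
                "cutoffs must satisfy 0 < contact_cutoff_um < proximal_cutoff_um, got "
                f"{self.contact_cutoff_um} / {self.proximal_cutoff_um}"
            )
        if not 0 <= self.hysteresis_um < self.contact_cutoff_um:
            raise ValidationError(
                f"hysteresis_um must lie in [0, contact_cutoff_um), got {self.hysteresis_um}"
            )
        if not self.merge_window_s > 0:
            raise ValidationError("merge_window_s must be > 0")
        if not self.long_duration_min > 0:
            raise ValidationError("long_duration_min must be > 0")
        if self.median_window_px < 1 or self.median_window_px % 2 == 0:
            raise ValidationError(
                f"median_window_px must be odd and >= 1, got {self.median_window_px}"
            )
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        if not self.frame_interval_s > 0:
            raise ValidationError("frame_interval_s must be > 0")
        if self.min_object_area_px < 1:
            raise ValidationError("min_object_area_px must be >= 1")
        if not self.max_link_displacement_px > 0:
            raise ValidationError("max_link_displacement_px must be > 0")
        if self.gap_memory_frames < 0:
            raise ValidationError("gap_memory_frames must be >= 0")


# ---------------------------------------------------------------------------
# movies and masks
# ---------------------------------------------------------------------------


def read_movie(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_s: float,
    channel_name: str = "",
) -> MovieStack:
    """Read a multi-page TIFF into a :class:`MovieStack`.

    Intensities are preserved bit-exactly; frames must all share one H x W
    shape or a :class:`FormatError` naming the offending frame is raised.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, ValueError) as exc:  # pragma: no cover - exercised via bad path
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path} contains no frames")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise FormatError(f"{path}: frame {i} is not a single-channel 2D image")
        if page.shape != shape0:
            raise FormatError(
                f"{path}: frame {i} has shape {page.shape}, expected {shape0} (frame 0)"
            )
    return MovieStack(
        frames=np.stack(pages, axis=0),
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        channel_name=channel_name,
    )


def write_movie(movie: MovieStack, path: str | Path) -> None:
    """Write a movie as an uncompressed multi-page TIFF (pixel data bit-exact)."""
    tifffile.imwrite(Path(path), movie.frames)


def read_region_maps(
    vascular_path: str | Path,
    endosteal_path: str | Path,
    pixel_size_um: float,
    expected_shape: tuple[int, int] | None = None,
) -> RegionMap:
    """Read vascular and endosteal annotation masks (any nonzero pixel = inside).

    ``expected_shape`` (the movie grid) is checked when given; empty masks are
    allowed but flagged on the returned object, and distance queries against
    an empty mask are refused downstream.
    """

    def _read_mask(p: str | Path) -> np.ndarray:
        arr = tifffile.imread(Path(p))
        if arr.ndim == 3 and arr.shape[0] == 1:
            arr = arr[0]
        if arr.ndim != 2:
            raise FormatError(f"mask {p} must be a single 2D image, got shape {arr.shape}")
        return arr != 0

    vascular = _read_mask(vascular_path)
    endosteal = _read_mask(endosteal_path)
    region_map = RegionMap(vascular, endosteal, pixel_size_um)
    if expected_shape is not None:
        region_map.check_grid(expected_shape)
    return region_map


def write_region_maps(
    region_map: RegionMap, vascular_path: str | Path, endosteal_path: str | Path
) -> None:
    tifffile.imwrite(Path(vascular_path), region_map.vascular_mask.astype(np.uint8) * 255)
    tifffile.imwrite(Path(endosteal_path), region_map.endosteal_mask.astype(np.uint8) * 255)


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------


def validate_track_table(table: pd.DataFrame) -> pd.DataFrame:
    """Sort a track table by (track_id, frame) and check its invariants."""
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"track table missing columns: {missing}")
    table = table[TRACK_COLUMNS].copy()
    table["track_id"] = table["track_id"].astype(int)
    table["frame"] = table["frame"].astype(int)
    table["x_px"] = table["x_px"].astype(float)
    table["y_px"] = table["y_px"].astype(float)
    table["interpolated"] = table["interpolated"].astype(bool)
    table = table.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    if table.duplicated(["track_id", "frame"]).any():
        dup = table[table.duplicated(["track_id", "frame"])].iloc[0]
        raise SchemaError(
            f"duplicate (track_id, frame) = ({int(dup.track_id)}, {int(dup.frame)})"
        )
    if not np.all(np.isfinite(table[["x_px", "y_px"]].to_numpy())):
        raise SchemaError("track coordinates must be finite")
    return table


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read a track CSV (``track_id,frame,x_px,y_px,interpolated``), sorted in memory."""
    try:
        table = pd.read_csv(path)
    except (OSError, ValueError) as exc:
        raise SchemaError(f"cannot read track CSV {path}: {exc}") from exc
    return validate_track_table(table)


def write_tracks(table: pd.DataFrame, path: str | Path) -> None:
    validate_track_table(table).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------


def read_events(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event table missing columns: {missing}")
    table = table[EVENT_COLUMNS].copy()
    table["track_id"] = table["track_id"].astype(int)
    for col in ("start_s", "end_s", "duration_s"):
        table[col] = table[col].astype(float)
    for col in ("label", "zone", "duration_class"):
        table[col] = table[col].astype(object).where(table[col].notna(), None)
    return table


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    table[EVENT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_PARAM_KEYS = {f.name for f in dataclasses.fields(AnalysisParameters)}


def load_params(config_path: str | Path) -> AnalysisParameters:
    """Load analysis parameters from a YAML (or flat ``key: value``) config file.

    Missing keys fall back to the published defaults on
    :class:`AnalysisParameters`; unknown keys are rejected so that typos never
    silently change a run.
    """
    path = Path(config_path)
    if not path.exists():
        raise FormatError(f"config file {path} does not exist")
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a mapping of parameter names to values")
    return params_from_dict(raw)


def params_from_dict(raw: dict) -> AnalysisParameters:
    unknown = sorted(set(raw) - _PARAM_KEYS)
    if unknown:
        raise ValidationError(f"unknown parameter keys: {unknown}")
    return AnalysisParameters(**raw)


def dump_params(params: AnalysisParameters, path: str | Path) -> None:
    """Write the fully resolved parameter set back out as YAML."""
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(dataclasses.asdict(params), handle, sort_keys=True)
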