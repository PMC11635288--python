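"""Reading, writing and ROI quantification of FRAP image series.

A FRAP series is a single-channel time-lapse stack with one bleach frame.
The stack travels as a multi-frame 16-bit grayscale TIFF plus a JSON sidecar
holding the acquisition metadata (frame period, bleach frame index, bleach
duration).  Measurement regions (the bleached area "a", a distant area "b" of
the same vacuole, and a control area "c" in a neighboring cell) are exchanged
as a small JSON schema of circles and polygons rather than a binary ROI
dialect, so that every region is transparent and testable.

Frame conventions used throughout the package:

* ``Frame -1`` is the last frame before the bleach frame
  (index ``bleach_frame_index - 1``).
* ``Frame 1`` is the first frame after it (index ``bleach_frame_index + 1``).
* The bleach frame itself carries no usable intensity and is never quantified.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import tifffile

__all__ = [
    "FormatError",
    "FrapSeries",
    "CircleRoi",
    "PolygonRoi",
    "RoiSet",
    "IntensityTrace",
    "read_series",
    "write_series",
    "read_rois",
    "write_rois",
    "extract_intensity",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = ("series_id", "region", "n_pixels", "frame", "time_s", "intensity")


class FormatError(ValueError):
    """A file violates the on-disk contract (frame counts, metadata keys)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FrapSeries:
    """A timestamped image stack with bleach-event metadata.

    Attributes
    ----------
    stack : ndarray, shape (T, H, W)
        Intensity grid in arbitrary units; values are non-negative.
    timestamps_s : ndarray, shape (T,)
        Acquisition time of each frame in seconds, strictly increasing.  The
        gap between the bleach frame and the first post-bleach frame includes
        the bleach duration.
    bleach_frame_index : int
        Index of the single bleach frame; pre-bleach frames precede it and at
        least one post-bleach frame follows it.
    """

    stack: np.ndarray
    timestamps_s: np.ndarray
    bleach_frame_index: int
    pixel_size_um: float | None = None
    source_path: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.stack.ndim != 3:
            raise FormatError(f"stack must be T x H x W, got shape {self.stack.shape}")
        t = self.stack.shape[0]
        if self.timestamps_s.shape != (t,):
            raise FormatError(
                f"timestamps length {self.timestamps_s.shape} does not match {t} frames"
            )
        if t < 3:
            raise FormatError(f"a FRAP series needs >= 3 frames, got {t}")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise FormatError("timestamps must be strictly increasing")
        if not 0 < self.bleach_frame_index < t - 1:
            raise FormatError(
                f"bleach_frame_index {self.bleach_frame_index} must lie strictly "
                f"inside the series (T={t})"
            )
        if np.any(self.stack < 0):
            raise FormatError("stack contains negative intensities")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def pre_bleach_indices(self) -> np.ndarray:
        return np.arange(self.bleach_frame_index)

    @property
    def post_bleach_indices(self) -> np.ndarray:
        return np.arange(self.bleach_frame_index + 1, self.n_frames)

    @property
    def frame_minus_1(self) -> int:
        """Index of the last frame before photobleaching."""
        return self.bleach_frame_index - 1

    @property
    def frame_plus_1(self) -> int:
        """Index of the first frame after photobleaching."""
        return self.bleach_frame_index + 1


@dataclass(frozen=True)
class CircleRoi:
    """Circle in pixel coordinates; center is (row, col), origin top-left."""

    center: tuple[float, float]
    radius: float

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        # pixel centers at integer coordinates; boundary included
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2

    def to_json(self, name: str) -> dict:
        return {
            "name": name,
            "shape": "circle",
            "center": [float(self.center[0]), float(self.center[1])],
            "radius": float(self.radius),
        }


@dataclass(frozen=True)
class PolygonRoi:
    """Simple polygon; vertices are (row, col) pairs in pixel coordinates."""

    vertices: tuple[tuple[float, float], ...]

    def __init__(self, vertices: Sequence[Sequence[float]]):
        object.__setattr__(
            self, "vertices", tuple((float(r), float(c)) for r, c in vertices)
        )
        if len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 vertices")

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        # shapely covers() includes the boundary and is independent of vertex
        # order and winding, which keeps rasterization deterministic.
        from shapely import covers, points
        from shapely.geometry import Polygon

        poly = Polygon(self.vertices)
        rmin = max(int(np.floor(min(r for r, _ in self.vertices))), 0)
        rmax = min(int(np.ceil(max(r for r, _ in self.vertices))), shape[0] - 1)
        cmin = max(int(np.floor(min(c for _, c in self.vertices))), 0)
        cmax = min(int(np.ceil(max(c for _, c in self.vertices))), shape[1] - 1)
        mask = np.zeros(shape, dtype=bool)
        if rmin > rmax or cmin > cmax:
            return mask
        rr, cc = np.mgrid[rmin : rmax + 1, cmin : cmax + 1]
        pts = points(np.column_stack([rr.ravel(), cc.ravel()]))
        inside = covers(poly, pts).reshape(rr.shape)
        mask[rmin : rmax + 1, cmin : cmax + 1] = inside
        return mask

    def to_json(self, name: str) -> dict:
        return {
            "name": name,
            "shape": "polygon",
            "vertices": [[float(r), float(c)] for r, c in self.vertices],
        }


Roi = Union[CircleRoi, PolygonRoi]


@dataclass
class RoiSet:
    """Named measurement regions for a FRAP series.

    Conventional names: ``a`` (bleached vacuole area), ``b`` (distant area of
    the same vacuole), ``c`` (vacuole area in a neighboring cell); optional
    ``vacuole_total`` and ``bleach_point``.
    """

    rois: dict[str, Roi]

    def __getitem__(self, name: str) -> Roi:
        return self.rois[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    def names(self) -> list[str]:
        return list(self.rois)


@dataclass
class IntensityTrace:
    """Mean pixel intensity inside one region, one value per frame."""

    values: np.ndarray
    region_name: str
    n_pixels: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


# ---------------------------------------------------------------------------
# series I/O
# ---------------------------------------------------------------------------


def write_series(
    series: FrapSeries, tiff_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write a series as a multi-frame 16-bit TIFF plus JSON sidecar.

    Float stacks are rounded and clipped into the unsigned 16-bit range; a
    warning is emitted when clipping occurs.  uint16 stacks round-trip
    bit-exactly.
    """
    stack = series.stack
    if stack.dtype != np.uint16:
        n_clipped = int(np.count_nonzero((stack < 0) | (stack > 65535)))
        if n_clipped:
            warnings.warn(
                f"{n_clipped} pixel values clipped into the 16-bit range",
                stacklevel=2,
            )
        stack = np.clip(np.rint(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(tiff_path), stack, photometric="minisblack")

    times = series.timestamps_s
    period = float(times[1] - times[0])
    b = series.bleach_frame_index
    bleach_duration = float(times[b + 1] - times[b] - period)
    sidecar = {
        "frame_period_s": period,
        "bleach_frame_index": int(b),
        "bleach_duration_s": max(bleach_duration, 0.0),
        "pixel_size_um": series.pixel_size_um,
    }
    sidecar.update(
        {k: v for k, v in series.metadata.items() if _json_safe(v)}
    )
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def _json_safe(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False


def default_timestamps(
    n_frames: int,
    bleach_frame_index: int,
    frame_period_s: float,
    bleach_duration_s: float = 0.0,
) -> np.ndarray:
    """Timestamps at a fixed frame period with the bleach gap widened by the
    bleach duration."""
    t = np.arange(n_frames, dtype=float) * frame_period_s
    t[bleach_frame_index + 1 :] += bleach_duration_s
    return t


def read_series(tiff_path: str | Path, sidecar_path: str | Path) -> FrapSeries:
    """Load a TIFF stack and its sidecar into a :class:`FrapSeries`."""
    stack = tifffile.imread(str(tiff_path))
    if stack.ndim == 2:
        raise FormatError("TIFF holds a single frame; a FRAP series needs >= 3")
    if stack.ndim != 3:
        raise FormatError(
            f"expected a single-channel T x H x W TIFF, got shape {stack.shape}"
        )
    if stack.shape[0] < 3:
        raise FormatError(f"a FRAP series needs >= 3 frames, got {stack.shape[0]}")

    meta = json.loads(Path(sidecar_path).read_text())
    for key in ("frame_period_s", "bleach_frame_index"):
        if key not in meta:
            raise FormatError(f"sidecar is missing required key {key!r}")
    b = int(meta["bleach_frame_index"])
    if not 0 < b < stack.shape[0] - 1:
        raise FormatError(
            f"sidecar bleach_frame_index {b} inconsistent with {stack.shape[0]} frames"
        )
    times = default_timestamps(
        stack.shape[0],
        b,
        float(meta["frame_period_s"]),
        float(meta.get("bleach_duration_s", 0.0)),
    )
    extra = {
        k: v
        for k, v in meta.items()
        if k
        not in ("frame_period_s", "bleach_frame_index", "bleach_duration_s", "pixel_size_um")
    }
    return FrapSeries(
        stack=stack,
        timestamps_s=times,
        bleach_frame_index=b,
        pixel_size_um=meta.get("pixel_size_um"),
        source_path=str(tiff_path),
        metadata=extra,
    )


# ---------------------------------------------------------------------------
# ROI I/O
# ---------------------------------------------------------------------------


def write_rois(rois: RoiSet, path: str | Path) -> None:
    payload = {"rois": [roi.to_json(name) for name, roi in rois.rois.items()]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path: str | Path) -> RoiSet:
    payload = json.loads(Path(path).read_text())
    out: dict[str, Roi] = {}
    for entry in payload["rois"]:
        name = entry["name"]
        if entry["shape"] == "circle":
            out[name] = CircleRoi(center=tuple(entry["center"]), radius=entry["radius"])
        elif entry["shape"] == "polygon":
            out[name] = PolygonRoi(entry["vertices"])
        else:
            raise FormatError(f"unknown ROI shape {entry['shape']!r}")
    return RoiSet(out)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------


def extract_intensity(
    series: FrapSeries, roi: Roi, region_name: str = "roi"
) -> IntensityTrace:
    """Mean pixel intensity inside ``roi`` at every frame.

    A pixel belongs to the region iff its center lies inside (boundary
    included), with pixel centers at integer (row, col) coordinates and the
    origin at the top-left corner of the image.
    """
    mask = roi.rasterize(series.stack.shape[1:])
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"region {region_name!r} rasterizes to zero pixels inside the image"
        )
    values = series.stack[:, mask].mean(axis=1)
    return IntensityTrace(values=values, region_name=region_name, n_pixels=n)


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return f"{value:.6g}"
    return str(value)


def write_results(records: Iterable[Mapping], path: str | Path) -> None:
    """Write per-frame intensity records as CSV with a fixed column order.

    Floats are serialized at 6 significant digits; row order is preserved from
    the input so repeated runs are byte-identical.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for rec in records:
            writer.writerow([_fmt(rec[col]) for col in RESULT_COLUMNS])


def read_results(path: str | Path):
    import pandas as pd

    return pd.read_csv(path)


def trace_records(
    series_id: str, trace: IntensityTrace, timestamps_s: np.ndarray
) -> list[dict]:
    """Flatten a trace into result rows (one per frame)."""
    return [
        {
            "series_id": series_id,
            "region": trace.region_name,
            "n_pixels": trace.n_pixels,
            "frame": i,
            "time_s": float(timestamps_s[i]),
            "intensity": float(trace.values[i]),
        }
        for i in range(len(trace.values))
    ]
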