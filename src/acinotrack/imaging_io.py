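"""Segmentation, outline extraction, the emphasize-track filter, and file I/O.

Frames move through the pipeline as plain numpy arrays bundled with their
calibration in a :class:`FrameStack`.  Object boundaries are closed polygons
in half-pixel (marching-squares) coordinates so that polygon area tracks
pixel count.  All on-disk formats are plain: multi-page TIFF for movies,
JSON-lines for outlines, CSV for feature tables.  Readers validate and
reject malformed or truncated files instead of returning partial data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import relabel_sequential


class FormatError(ValueError):
    """A file failed validation; the message points at the offending record."""


@dataclass
class FrameStack:
    """A movie plus acquisition metadata.

    ``frames`` is ``(T, H, W)``; grayscale float or integer labels.
    """

    frames: np.ndarray
    dt: float = 1.0
    pixel_size: float = 1.0
    experiment: str = ""
    condition: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("dt and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class Outline:
    """Closed boundary polygon of one object in one frame.

    Vertices are ``(x, y)`` pixel coordinates on the marching-squares
    half-pixel grid; first vertex equals last.
    """

    frame: int
    object_id: int
    vertices: np.ndarray  # (N, 2) float, closed
    centroid: tuple[float, float] = field(default=(np.nan, np.nan))

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (N, 2)")
        if not np.allclose(self.vertices[0], self.vertices[-1]):
            raise FormatError(
                f"outline for object {self.object_id} frame {self.frame} is not closed"
            )

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        """Enclosed area in px²; ≈ pixel count for convex objects."""
        return self.polygon.area


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_frame(
    gray_frame: np.ndarray, min_area: int = 64, objects_dark: bool = True
) -> np.ndarray:
    """Threshold one grayscale frame into a label mask.

    Otsu's global threshold on the object-polarity image, 8-connected
    components, components smaller than ``min_area`` pixels removed, labels
    renumbered 1..K.  A constant frame yields zero objects.
    """
    g = np.asarray(gray_frame, dtype=float)
    if g.ndim != 2:
        raise ValueError("gray_frame must be 2D")
    if not np.all(np.isfinite(g)):
        raise ValueError("gray_frame contains non-finite values")
    work = -g if objects_dark else g
    if np.ptp(work) == 0:
        return np.zeros(g.shape, dtype=np.int32)
    thresh = threshold_otsu(work)
    labels = measure.label(work > thresh, connectivity=2)
    if min_area > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        labels[np.isin(labels, small)] = 0
    return relabel_sequential(labels)[0].astype(np.int32)


def extract_outlines(label_mask: np.ndarray, frame: int = 0) -> list[Outline]:
    """Outer boundary polygon and centroid of every label in one frame.

    Contours follow the marching-squares 0.5-level convention (the mask is
    padded so boundary objects still close); for convex objects the polygon
    area agrees with the pixel count to within a few percent.
    """
    label_mask = np.asarray(label_mask)
    if label_mask.dtype == bool:
        label_mask = label_mask.astype(np.uint8)
    outlines: list[Outline] = []
    for prop in measure.regionprops(label_mask):
        r0, c0, r1, c1 = prop.bbox
        sub = np.pad(prop.image, 1).astype(float)
        contours = measure.find_contours(sub, 0.5)
        contour = max(contours, key=len)  # outer boundary only
        # (row, col) on padded subimage -> (x, y) on full frame
        verts = np.column_stack(
            [contour[:, 1] - 1 + c0, contour[:, 0] - 1 + r0]
        )
        if not np.allclose(verts[0], verts[-1]):
            verts = np.vstack([verts, verts[0]])
        cy, cx = prop.centroid
        outlines.append(
            Outline(frame=frame, object_id=int(prop.label), vertices=verts,
                    centroid=(cx, cy))
        )
    return outlines


def outline_centroids(outlines: Sequence[Outline], pixel_size: float = 1.0) -> pd.DataFrame:
    """Centroid table (frame, object_id, x_um, y_um) from outlines."""
    return pd.DataFrame(
        {
            "frame": [o.frame for o in outlines],
            "object_id": [o.object_id for o in outlines],
            "x_um": [o.centroid[0] * pixel_size for o in outlines],
            "y_um": [o.centroid[1] * pixel_size for o in outlines],
        }
    )


# ---------------------------------------------------------------------------
# Emphasize-track enhancement
# ---------------------------------------------------------------------------

_SHADOW_KERNELS = {
    "north": np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float),
    "south": np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float),
    "east": np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float),
    "west": np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=float),
}


def remove_outliers(
    gray_frame: np.ndarray, radius: int = 25, threshold: float = 2.0
) -> np.ndarray:
    """Replace pixels deviating from their disk-neighborhood median.

    Symmetric (bright and dark) variant: any pixel with
    ``|value - median| > threshold`` becomes the median of its disk
    neighborhood of the given radius.  Idempotent on images whose outliers
    are isolated pixels.
    """
    g = np.asarray(gray_frame, dtype=float)
    if g.ndim != 2:
        raise ValueError("frame must be 2D")
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if 2 * radius + 1 > min(g.shape):
        raise ValueError("radius larger than the frame")
    med = ndimage.median_filter(g, footprint=disk(radius), mode="reflect")
    return np.where(np.abs(g - med) > threshold, med, g)


def emphasize_track(
    gray_frame: np.ndarray,
    radius: int = 25,
    threshold: float = 2.0,
    shadow_direction: str = "north",
    shadow_strength: float = 0.25,
) -> np.ndarray:
    """Enhance ECM tunnels in a phase-contrast frame.

    Pipeline: (1) median-deviation outlier removal (disk neighborhood of
    ``radius``, symmetric ``threshold``), (2) intensity inversion
    (max+min-value), (3) non-finite values replaced by the local median,
    (4) shadow emphasis — subtraction of a directional emboss-gradient
    response that sharpens tunnel edges.  Stage 4 is presentational; no
    quantitative output depends on it.
    """
    g = np.asarray(gray_frame, dtype=float)
    if g.ndim != 2:
        raise ValueError("frame must be 2D")
    bad = ~np.isfinite(g)
    if bad.any():
        finite_med = float(np.nanmedian(np.where(bad, np.nan, g)))
        g = np.where(bad, finite_med, g)
    out = remove_outliers(g, radius=radius, threshold=threshold)
    out = out.max() + out.min() - out  # invert
    if bad.any():
        local_med = ndimage.median_filter(out, footprint=disk(radius), mode="reflect")
        out = np.where(bad, local_med, out)
    if shadow_strength:
        try:
            kernel = _SHADOW_KERNELS[shadow_direction]
        except KeyError:
            raise ValueError(f"unknown shadow direction {shadow_direction!r}") from None
        out = out - shadow_strength * ndimage.convolve(out, kernel, mode="reflect")
    return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def write_movie(stack: FrameStack, path) -> None:
    """Write a movie as multi-page TIFF with metadata in the description tag."""
    meta = {
        "dt": stack.dt,
        "pixel_size": stack.pixel_size,
        "experiment": stack.experiment,
        "condition": stack.condition,
        "well": stack.well,
    }
    tifffile.imwrite(
        path, stack.frames, description=json.dumps(meta), photometric="minisblack"
    )


def read_movie(path) -> FrameStack:
    """Read a multi-page TIFF written by :func:`write_movie` (lossless)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            desc = tf.pages[0].description
    except Exception as exc:  # truncated / not a TIFF
        raise FormatError(f"{path} is not a readable TIFF: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    return FrameStack(
        frames=frames,
        dt=float(meta.get("dt", 1.0)),
        pixel_size=float(meta.get("pixel_size", 1.0)),
        experiment=meta.get("experiment", ""),
        condition=meta.get("condition", ""),
        well=meta.get("well", ""),
    )


def write_outlines(outlines: Sequence[Outline], path) -> None:
    """Write outlines as JSON-lines: one object per line."""
    with open(path, "w") as fh:
        for o in outlines:
            fh.write(
                json.dumps(
                    {
                        "frame": int(o.frame),
                        "object_id": int(o.object_id),
                        "centroid": [float(o.centroid[0]), float(o.centroid[1])],
                        "vertices": o.vertices.tolist(),
                    }
                )
                + "\n"
            )


def read_outlines(path) -> list[Outline]:
    """Read JSON-lines outlines; malformed or non-closed records raise."""
    outlines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.endswith("\n") and lineno > 1:
                pass  # last line may lack newline; json still validates
            try:
                rec = json.loads(line)
                outlines.append(
                    Outline(
                        frame=int(rec["frame"]),
                        object_id=int(rec["object_id"]),
                        vertices=np.asarray(rec["vertices"], dtype=float),
                        centroid=tuple(rec.get("centroid", (np.nan, np.nan))),
                    )
                )
            except FormatError:
                raise
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
    return outlines


def write_features(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV (full float precision, round-trip safe)."""
    table.to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    """Read a feature CSV; empty or truncated files raise :class:`FormatError`."""
    try:
        table = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return table
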