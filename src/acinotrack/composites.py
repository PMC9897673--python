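"""Time-window outline composites.

The central trick of the pipeline: a movie is cut into fixed windows of
consecutive frames (12 hourly frames by default) and each window is
collapsed into *composite objects* — connected components of the pixelwise
union of all object masks inside the window.  Motion becomes static shape:
a stationary acinus composites to its own outline, a locally protruding one
to a roughened star, a translocating (tunnel-forming) one to an elongated
sweep.  Downstream morphometrics and classification operate on these
composites as if they were single objects.

No tracking happens here; objects are associated purely by spatial overlap
of their masks across the window, exactly as overlaid drawn outlines merge
when the composite image is re-segmented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from skimage.morphology import binary_dilation, disk

from .imaging_io import Outline, extract_outlines

DEFAULT_WINDOW = 12  # frames; 12 consecutive hourly frames per interval


@dataclass
class CompositeObject:
    """One connected component of a window's mask union."""

    composite_id: str
    window_index: int
    frame_range: tuple[int, int]  # [start, end)
    union_mask: np.ndarray  # bool, full-frame
    member_outlines: list[tuple[int, Outline]] = field(default_factory=list)
    experiment: str = ""
    condition: str = ""
    well: str = ""
    touches_border: bool = False

    @property
    def area_px(self) -> int:
        return int(self.union_mask.sum())

    @property
    def n_member_frames(self) -> int:
        return len({f for f, _ in self.member_outlines})


def window_partition(
    n_frames: int, window: int = DEFAULT_WINDOW, stride: int | None = None
) -> list[tuple[int, int]]:
    """Cut ``n_frames`` into ``[start, end)`` ranges of length ``window``.

    With ``stride == window`` (default) the ranges tile the movie without
    overlap; a trailing partial window is dropped so every composite sees
    the same exposure.  ``window > n_frames`` yields an empty list with a
    warning.
    """
    if window < 1 or (stride is not None and stride < 1):
        raise ValueError("window and stride must be >= 1")
    stride = window if stride is None else stride
    if window > n_frames:
        warnings.warn(
            f"window ({window}) exceeds movie length ({n_frames}); no windows",
            stacklevel=2,
        )
        return []
    return [(s, s + window) for s in range(0, n_frames - window + 1, stride)]


def build_composites(
    masks: np.ndarray,
    window_index: int = 0,
    frame_start: int = 0,
    dilation: int = 0,
    experiment: str = "",
    condition: str = "",
    well: str = "",
) -> list[CompositeObject]:
    """Collapse one window of label masks into composite objects.

    ``masks`` is ``(T, H, W)`` integer labels (or booleans) for the frames
    of one window.  Composites are the 8-connected components of the union
    ``any(masks > 0)``; each carries the outlines of every per-frame object
    that overlaps it, tagged by absolute frame index.  ``dilation`` (pixels,
    default 0) optionally bridges objects that jump with zero overlap
    between consecutive frames; the stored union mask is never dilated.
    """
    masks = np.asarray(masks)
    if masks.ndim != 3 or masks.shape[0] == 0:
        raise ValueError("masks must be a non-empty (T, H, W) array")
    union = (masks > 0).any(axis=0)
    link = binary_dilation(union, disk(dilation)) if dilation > 0 else union
    comp_labels = measure.label(link, connectivity=2)

    composites: list[CompositeObject] = []
    by_label: dict[int, int] = {}
    h, w = union.shape
    for prop in measure.regionprops(comp_labels):
        comp_mask = (comp_labels == prop.label) & union
        r0, c0, r1, c1 = prop.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        comp = CompositeObject(
            composite_id=f"{well or 'well'}_t{window_index}_c{prop.label}",
            window_index=window_index,
            frame_range=(frame_start, frame_start + masks.shape[0]),
            union_mask=comp_mask,
            experiment=experiment,
            condition=condition,
            well=well,
            touches_border=touches,
        )
        by_label[int(prop.label)] = len(composites)
        composites.append(comp)

    # attach member outlines by overlap with each component
    for t in range(masks.shape[0]):
        frame = frame_start + t
        for o in extract_outlines(masks[t], frame=frame):
            obj_mask = masks[t] == o.object_id
            overlap = comp_labels[obj_mask]
            overlap = overlap[overlap > 0]
            if overlap.size == 0:
                continue
            lab = int(np.bincount(overlap).argmax())
            composites[by_label[lab]].member_outlines.append((frame, o))
    return composites


def composites_for_movie(
    masks: np.ndarray,
    window: int = DEFAULT_WINDOW,
    stride: int | None = None,
    dilation: int = 0,
    experiment: str = "",
    condition: str = "",
    well: str = "",
) -> list[list[CompositeObject]]:
    """Window a whole movie and build composites per window."""
    out = []
    for wi, (s, e) in enumerate(window_partition(masks.shape[0], window, stride)):
        out.append(
            build_composites(
                masks[s:e],
                window_index=wi,
                frame_start=s,
                dilation=dilation,
                experiment=experiment,
                condition=condition,
                well=well,
            )
        )
    return out


def render_rainbow(
    composite: CompositeObject, colormap: str = "rainbow"
) -> np.ndarray:
    """Draw member outlines time-coded earliest→latest on an RGB canvas.

    Frame ``k`` of a ``W``-frame window is drawn in ``colormap(k/(W-1))``;
    later frames are drawn on top.  Returns an (H, W, 3) float image.
    """
    import matplotlib.pyplot as plt
    from skimage.draw import polygon_perimeter

    cmap = plt.get_cmap(colormap)
    h, w = composite.union_mask.shape
    img = np.ones((h, w, 3), dtype=float)
    start, end = composite.frame_range
    span = max(end - start - 1, 1)
    for frame, outline in sorted(composite.member_outlines, key=lambda fo: fo[0]):
        color = np.asarray(cmap((frame - start) / span)[:3])
        rr, cc = polygon_perimeter(
            outline.vertices[:, 1], outline.vertices[:, 0], shape=(h, w), clip=True
        )
        img[rr, cc] = color
    return img
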