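"""Synthetic time-lapse movies of 3D acini with known behavior labels.

Clonal acini grown in ECM gel fall into three dynamic phenotypes when imaged
hourly over several days: *round* (stationary, compact), *local-spreading*
(protrusive shape change about a fixed centroid) and *tunnel-forming*
(the whole object translocates back and forth along a conduit it carves in
the gel).  This module emulates those archetypes as rasterized label movies
with exact per-frame ground truth, so that segmentation, compositing,
classification, tracking and statistics can all be tested without any
real microscopy data.

Geometry is minimal by design: a disk (round), a disk with oscillating
capsule-shaped protrusions (spread), and a disk translating back and forth
along a linear path (tunnel).  These reproduce the property the composite
trick exploits — unions over a time window stay compact for round objects,
roughen for spreading ones and elongate for tunnel-formers.

Coordinates are pixel-centered with origin at the top-left, row-major.
All lengths are stored in micrometres and converted through ``pixel_size``
only at rasterization.  One root seed yields per-well child seeds through
``numpy.random.SeedSequence.spawn`` so wells are independent and every
output is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

BEHAVIORS = ("round", "spread", "tunnel")

#: Default per-behavior parameters.  Acinus radius ~40 µm and protrusion /
#: path scales of tens of µm are typical of single-cell-derived cysts after
#: a few days of 3D culture; they are this package's defaults, configurable
#: throughout.
DEFAULT_BEHAVIOR_PARAMS: Mapping[str, "BehaviorParams"]

#: Default camera calibration (µm per pixel) for a 10x wide-field objective.
DEFAULT_PIXEL_SIZE = 1.24

#: Hourly acquisition over 4 days.
DEFAULT_N_FRAMES = 96
DEFAULT_DT = 1.0


class PlacementError(RuntimeError):
    """Raised when acini cannot be placed without overlap."""


@dataclass(frozen=True)
class BehaviorParams:
    """Motion/shape parameters of one simulated acinus.

    Parameters
    ----------
    behavior:
        One of ``"round"``, ``"spread"``, ``"tunnel"``.
    radius:
        Initial disk radius, µm.
    jitter_sd:
        Per-frame centroid jitter (i.i.d. positional noise, per-axis sd), µm.
    n_protrusions, protrusion_len:
        Spread only: number of radial protrusions and their maximum length
        beyond the disk edge, µm.
    speed:
        Tunnel only: translation speed, µm/h.
    path_len:
        Tunnel only: conduit length; direction reverses at the ends, µm.
    growth_rate:
        Fractional radius growth per frame.
    """

    behavior: str
    radius: float
    jitter_sd: float = 0.0
    n_protrusions: int = 0
    protrusion_len: float = 0.0
    speed: float = 0.0
    path_len: float = 0.0
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.jitter_sd < 0 or self.speed < 0 or self.path_len < 0:
            raise ValueError("jitter_sd, speed and path_len must be >= 0")
        if self.n_protrusions < 0 or self.protrusion_len < 0:
            raise ValueError("protrusion parameters must be >= 0")
        if self.behavior == "round" and (self.speed != 0 or self.n_protrusions != 0):
            raise ValueError("round acini have speed=0 and n_protrusions=0")
        if self.behavior == "tunnel" and self.speed > 0 and self.path_len == 0:
            raise ValueError("moving tunnel acini need path_len > 0")


DEFAULT_BEHAVIOR_PARAMS = {
    "round": BehaviorParams("round", radius=40.0, jitter_sd=2.0, growth_rate=0.004),
    "spread": BehaviorParams(
        "spread",
        radius=40.0,
        jitter_sd=2.0,
        n_protrusions=4,
        protrusion_len=35.0,
        growth_rate=0.004,
    ),
    "tunnel": BehaviorParams(
        "tunnel",
        radius=40.0,
        jitter_sd=2.0,
        speed=20.0,
        path_len=120.0,
        growth_rate=0.004,
    ),
}


@dataclass(frozen=True)
class PlateLayout:
    """Plate geometry and acquisition settings for :func:`simulate_plate`."""

    experiments: Sequence[str]
    conditions: Mapping[str, Mapping[str, float]]
    wells_per_condition: int
    acini_per_well: int
    n_frames: int = DEFAULT_N_FRAMES
    dt: float = DEFAULT_DT
    pixel_size: float = DEFAULT_PIXEL_SIZE
    frame_shape: tuple[int, int] = (512, 512)
    seed: int = 0
    size_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.dt <= 0 or self.pixel_size <= 0:
            raise ValueError("dt and pixel_size must be positive")
        for cond, mix in self.conditions.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture for {cond!r} sums to {total}, not 1")
            for b in mix:
                if b not in BEHAVIORS:
                    raise ValueError(f"unknown behavior {b!r} in condition {cond!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateLayout":
        d = dict(d)
        if "frame_shape" in d:
            d["frame_shape"] = tuple(d["frame_shape"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["experiments"] = list(self.experiments)
        d["conditions"] = {c: dict(m) for c, m in self.conditions.items()}
        d["frame_shape"] = list(self.frame_shape)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class SimulatedMovie:
    """Label-mask movie of one well plus exact ground truth."""

    frames: np.ndarray  # (T, H, W) integer labels, 0 = background
    truth: pd.DataFrame  # object_id, frame, x_um, y_um, behavior, speed_um_h
    experiment: str
    condition: str
    well: str
    dt: float
    pixel_size: float
    layout: PlateLayout | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


class _AcinusGeometry:
    """Pre-drawn per-frame geometric state of one acinus.

    All randomness is drawn up front, in a fixed order, so rasterization is
    deterministic and the same geometry can be placed on any canvas.
    """

    def __init__(
        self,
        params: BehaviorParams,
        n_frames: int,
        dt: float,
        rng: np.random.Generator,
        center_um: tuple[float, float] = (0.0, 0.0),
    ):
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        self.params = params
        self.n_frames = n_frames
        t = np.arange(n_frames)
        self.radii = params.radius * (1.0 + params.growth_rate) ** t

        jitter = rng.normal(0.0, params.jitter_sd, size=(n_frames, 2))
        base = np.asarray(center_um, dtype=float)

        if params.behavior == "tunnel" and params.speed > 0:
            angle = rng.uniform(0.0, 2.0 * np.pi)
            u_vec = np.array([np.cos(angle), np.sin(angle)])
            step = params.speed * dt
            # Direction flips *before* any step that would leave [0, L] so
            # every frame-to-frame displacement is exactly speed*dt.
            u = np.empty(n_frames)
            u[0], d = 0.0, 1.0
            for k in range(1, n_frames):
                nxt = u[k - 1] + d * step
                if nxt > params.path_len or nxt < 0.0:
                    d = -d
                    nxt = u[k - 1] + d * step
                u[k] = nxt
            centers = base + np.outer(u - u.mean(), u_vec)
            self.path = (
                base - u.mean() * u_vec,
                base + (params.path_len - u.mean()) * u_vec,
            )
        else:
            centers = np.broadcast_to(base, (n_frames, 2)).copy()
            self.path = None

        self.centers = centers + jitter

        if params.behavior == "spread" and params.n_protrusions > 0:
            k = params.n_protrusions
            ang0 = rng.uniform(0.0, 2.0 * np.pi)
            self.prot_angles = ang0 + np.arange(k) * (2.0 * np.pi / k)
            self.prot_phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
            period = 24.0  # frames; one extend/retract cycle per day at dt=1 h
            osc = 0.5 * (1.0 + np.sin(2.0 * np.pi * t[:, None] / period + self.prot_phases))
            self.prot_lengths = params.protrusion_len * osc  # (T, k)
            self.prot_width = 0.35 * params.radius
        else:
            self.prot_angles = np.empty(0)
            self.prot_lengths = np.zeros((n_frames, 0))
            self.prot_width = 0.0

    def extent_um(self) -> float:
        """Radius of a disc guaranteed to contain the acinus in all frames."""
        p = self.params
        r = float(self.radii.max())
        reach = r + (self.prot_lengths.max() if self.prot_lengths.size else 0.0)
        half_path = p.path_len / 2.0 if p.behavior == "tunnel" else 0.0
        return reach + half_path + 5.0 * p.jitter_sd

    def rasterize(self, frame: int, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Boolean mask of the acinus at `frame` on the given µm coordinate grid."""
        cx, cy = self.centers[frame]
        r = self.radii[frame]
        dx = x_um - cx
        dy = y_um - cy
        mask = dx * dx + dy * dy <= r * r
        for j, ang in enumerate(self.prot_angles):
            length = r + self.prot_lengths[frame, j]
            ux, uy = np.cos(ang), np.sin(ang)
            # capsule: distance to the segment centroid -> centroid + L*u
            proj = np.clip(dx * ux + dy * uy, 0.0, length)
            qx = dx - proj * ux
            qy = dy - proj * uy
            mask |= qx * qx + qy * qy <= self.prot_width**2
        return mask


def _grid_um(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    y = np.arange(h, dtype=float)[:, None] * pixel_size
    x = np.arange(w, dtype=float)[None, :] * pixel_size
    return x, y


# ---------------------------------------------------------------------------
# Single acinus
# ---------------------------------------------------------------------------


def simulate_acinus(
    params: BehaviorParams,
    n_frames: int,
    dt: float = DEFAULT_DT,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int = 0,
    frame_shape: tuple[int, int] | None = None,
    center_um: tuple[float, float] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate one acinus on its own canvas.

    Returns
    -------
    masks:
        Boolean array of shape ``(n_frames, H, W)``.
    truth:
        One row per frame: ``frame, x_um, y_um, behavior, speed_um_h`` where
        the centroid is the exact (pre-rasterization) model position.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    geom = _AcinusGeometry(params, n_frames, dt, rng, center_um=(0.0, 0.0))
    if frame_shape is None:
        half = geom.extent_um() + 10.0
        n = int(np.ceil(2 * half / pixel_size)) + 1
        frame_shape = (n, n)
    if center_um is None:
        center_um = (
            (frame_shape[1] - 1) / 2.0 * pixel_size,
            (frame_shape[0] - 1) / 2.0 * pixel_size,
        )
    geom.centers = geom.centers + np.asarray(center_um)
    if geom.path is not None:
        geom.path = (geom.path[0] + np.asarray(center_um), geom.path[1] + np.asarray(center_um))

    x, y = _grid_um(frame_shape, pixel_size)
    masks = np.empty((n_frames,) + tuple(frame_shape), dtype=bool)
    for f in range(n_frames):
        masks[f] = geom.rasterize(f, x, y)
    truth = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "x_um": geom.centers[:, 0],
            "y_um": geom.centers[:, 1],
            "behavior": params.behavior,
            "speed_um_h": params.speed if params.behavior == "tunnel" else 0.0,
        }
    )
    return masks, truth


def sample_params(
    behavior: str,
    rng: np.random.Generator,
    base: BehaviorParams | None = None,
    size_cv: float = 0.15,
) -> BehaviorParams:
    """Draw per-acinus parameters around the class defaults.

    Radius, protrusion length and speed are scattered log-normally
    (``size_cv`` = sd of log scale) to emulate acinus-to-acinus heterogeneity.
    """
    if base is None:
        base = DEFAULT_BEHAVIOR_PARAMS[behavior]
    scale = rng.lognormal(0.0, size_cv, size=3)
    return dataclasses.replace(
        base,
        radius=base.radius * scale[0],
        protrusion_len=base.protrusion_len * scale[1],
        speed=base.speed * scale[2],
    )


def assign_behaviors(
    mixture: Mapping[str, float], n: int, rng: np.random.Generator
) -> list[str]:
    """Randomly assign `n` acini to behaviors following mixture fractions."""
    names = sorted(mixture)
    probs = np.array([mixture[b] for b in names], dtype=float)
    probs = probs / probs.sum()
    return [names[i] for i in rng.choice(len(names), size=n, p=probs)]


# ---------------------------------------------------------------------------
# Whole plates
# ---------------------------------------------------------------------------


def _place_acini(
    geoms: Sequence[_AcinusGeometry],
    frame_shape: tuple[int, int],
    pixel_size: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[np.ndarray]:
    """Rejection-sample non-overlapping base positions (µm) for each acinus."""
    h_um = (frame_shape[0] - 1) * pixel_size
    w_um = (frame_shape[1] - 1) * pixel_size
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for geom in geoms:
        ext = geom.extent_um()
        r0_self = float(geom.radii[0])
        if 2 * ext > min(h_um, w_um):
            raise PlacementError(
                f"acinus extent {ext:.0f} µm does not fit the "
                f"{h_um:.0f}x{w_um:.0f} µm field"
            )
        for _ in range(max_tries):
            c = np.array(
                [rng.uniform(ext, w_um - ext), rng.uniform(ext, h_um - ext)]
            )
            # only *initial* disks must not overlap; later contacts are
            # resolved first-come at rasterization
            if all(
                np.hypot(*(c - c0)) > r0_self + r0 + 5.0
                for c0, r0 in zip(centers, radii)
            ):
                centers.append(c)
                radii.append(r0_self)
                break
        else:
            raise PlacementError(
                f"could not place acinus {len(centers)} after {max_tries} tries; "
                "reduce density or enlarge the field"
            )
    return centers


def _simulate_well(
    layout: PlateLayout,
    experiment: str,
    condition: str,
    well: str,
    seed_seq: np.random.SeedSequence,
) -> SimulatedMovie:
    rng = np.random.default_rng(seed_seq)
    behaviors = assign_behaviors(
        layout.conditions[condition], layout.acini_per_well, rng
    )
    geoms = []
    for b in behaviors:
        p = sample_params(b, rng, size_cv=layout.size_cv)
        geoms.append(_AcinusGeometry(p, layout.n_frames, layout.dt, rng))
    centers = _place_acini(geoms, layout.frame_shape, layout.pixel_size, rng)
    for geom, c in zip(geoms, centers):
        geom.centers = geom.centers + c
        if geom.path is not None:
            geom.path = (geom.path[0] + c, geom.path[1] + c)

    h, w = layout.frame_shape
    ps = layout.pixel_size
    frames = np.zeros((layout.n_frames, h, w), dtype=np.uint16)
    rows = []
    for oid, (geom, b) in enumerate(zip(geoms, behaviors), start=1):
        for f in range(layout.n_frames):
            # rasterize only within the acinus bounding box
            cx, cy = geom.centers[f]
            ext = geom.extent_um()
            c0 = max(int((cx - ext) / ps) - 1, 0)
            c1 = min(int((cx + ext) / ps) + 2, w)
            r0 = max(int((cy - ext) / ps) - 1, 0)
            r1 = min(int((cy + ext) / ps) + 2, h)
            x = np.arange(c0, c1, dtype=float)[None, :] * ps
            y = np.arange(r0, r1, dtype=float)[:, None] * ps
            sub = geom.rasterize(f, x, y)
            view = frames[f, r0:r1, c0:c1]
            view[sub & (view == 0)] = oid  # first-come on (rare) overlaps
            rows.append(
                (
                    oid,
                    f,
                    geom.centers[f, 0],
                    geom.centers[f, 1],
                    b,
                    geom.params.speed if b == "tunnel" else 0.0,
                )
            )
    truth = pd.DataFrame(
        rows, columns=["object_id", "frame", "x_um", "y_um", "behavior", "speed_um_h"]
    )
    return SimulatedMovie(
        frames=frames,
        truth=truth,
        experiment=experiment,
        condition=condition,
        well=well,
        dt=layout.dt,
        pixel_size=layout.pixel_size,
        layout=layout,
    )


def simulate_plate(layout: PlateLayout) -> Iterator[SimulatedMovie]:
    """Yield one :class:`SimulatedMovie` per (experiment, condition, well).

    Wells draw independent child seeds from ``layout.seed`` via
    ``SeedSequence.spawn`` in (experiment, condition, well) order, so any
    single well is reproducible and the whole plate is deterministic.
    """
    n_wells = (
        len(layout.experiments) * len(layout.conditions) * layout.wells_per_condition
    )
    children = np.random.SeedSequence(layout.seed).spawn(n_wells)
    i = 0
    for exp in layout.experiments:
        for cond in layout.conditions:
            for wi in range(layout.wells_per_condition):
                yield _simulate_well(layout, exp, cond, f"{cond}_w{wi}", children[i])
                i += 1


def plate_truth(movies: Sequence[SimulatedMovie]) -> pd.DataFrame:
    """Concatenate per-well truth tables with well metadata columns."""
    parts = []
    for m in movies:
        t = m.truth.copy()
        t.insert(0, "well", m.well)
        t.insert(0, "condition", m.condition)
        t.insert(0, "experiment", m.experiment)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Phase-contrast-like rendering
# ---------------------------------------------------------------------------


def render_phase(
    mask_frame: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 0.75,
    object_level: float = 0.35,
    tunnel_paths: Sequence[tuple[np.ndarray, np.ndarray, float]] = (),
    tunnel_level: float = 0.55,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Render a label mask as a phase-contrast-like grayscale frame.

    Objects are darker than the background; an optional darker linear strip
    is drawn under each tunnel path (``(p0_um, p1_um, width_um)`` triples)
    emulating the conduit carved in the ECM.  Additive Gaussian noise with
    sd ``noise_sd`` is applied and the result clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    mask_frame = np.asarray(mask_frame)
    img = np.full(mask_frame.shape, background, dtype=float)
    if tunnel_paths:
        x, y = _grid_um(mask_frame.shape, pixel_size)
        for p0, p1, width in tunnel_paths:
            p0 = np.asarray(p0, float)
            d = np.asarray(p1, float) - p0
            denom = float(d @ d) or 1.0
            proj = np.clip(((x - p0[0]) * d[0] + (y - p0[1]) * d[1]) / denom, 0, 1)
            qx = x - p0[0] - proj * d[0]
            qy = y - p0[1] - proj * d[1]
            img[qx * qx + qy * qy <= (width / 2.0) ** 2] = tunnel_level
    img[mask_frame > 0] = object_level
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)
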