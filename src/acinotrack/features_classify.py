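"""Composite morphometrics and the gentle-boosting behavior classifier.

Each composite object is reduced to a fixed vector of standard shape
measurements (area, perimeter, form factor, eccentricity, solidity, extent,
axis lengths, max Feret diameter, aspect ratio) calibrated to micrometres.
A multiclass gentle-boosting ensemble of single-feature threshold stumps is
then trained on labeled composites to call round / local-spreading /
tunnel-forming behavior.

Gentle boosting fits, per round, one shared (feature, threshold) split with
per-class regression votes by weighted least squares to ±1 class targets,
then reweights examples multiplicatively with the exponential rule.  Votes
are weighted class-conditional means and hence bounded in [-1, 1], which
guarantees the exponential loss of the additive model never increases.
Predictions depend only on the ordering of feature values (splits are at
midpoints), so any strictly monotone per-feature transform applied
consistently to training and test data leaves the classifier unchanged.
Training is a pure function of the input rows, labels and hyperparameters;
ties in the weighted error are broken toward the lower feature index, then
the lower threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure
from sklearn.model_selection import StratifiedKFold

from . import synthetic_data
from .composites import CompositeObject, build_composites

CLASSES = ("round", "spread", "tunnel")

# Elongation descriptors lead, then compactness, then raw size: ties in the
# boosting search break toward the lower feature index, and the motility
# signature (elongation of the composite sweep) should win such ties over
# magnification- and growth-dependent size measures.
FEATURE_NAMES = (
    "eccentricity",
    "aspect_ratio",
    "major_axis_um",
    "max_feret_um",
    "minor_axis_um",
    "form_factor",
    "solidity",
    "extent",
    "area_um2",
    "perimeter_um",
)

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Morphometric features
# ---------------------------------------------------------------------------


def compute_features(
    composite: CompositeObject | np.ndarray, pixel_size: float = 1.0
) -> pd.Series:
    """Morphometrics of one composite's union mask, calibrated by pixel size.

    ``form_factor`` is the isoperimetric ratio 4πA/P² (1 for a circle;
    rasterization may push it slightly above 1).  ``aspect_ratio`` is
    major/minor ellipse axis length.
    """
    mask = composite.union_mask if isinstance(composite, CompositeObject) else composite
    mask = np.asarray(mask).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("empty union mask")
    rp = measure.regionprops(mask)[0]
    ps = float(pixel_size)
    # Crofton estimate: unbiased on rasterized smooth shapes (plain pixel
    # counting overestimates a disk's perimeter by ~5%)
    perimeter = max(rp.perimeter_crofton, 1e-12)
    minor = max(rp.axis_minor_length, 1.0)  # guard 1-px-thin shapes
    values = {
        "eccentricity": rp.eccentricity,
        "aspect_ratio": rp.axis_major_length / minor,
        "major_axis_um": rp.axis_major_length * ps,
        "max_feret_um": rp.feret_diameter_max * ps,
        "minor_axis_um": minor * ps,
        "form_factor": 4.0 * np.pi * rp.area / perimeter**2,
        "solidity": rp.solidity,
        "extent": rp.extent,
        "area_um2": rp.area * ps**2,
        "perimeter_um": perimeter * ps,
    }
    name = composite.composite_id if isinstance(composite, CompositeObject) else None
    return pd.Series(values, index=list(FEATURE_NAMES), name=name)


def features_table(
    composites: Sequence[CompositeObject], pixel_size: float = 1.0
) -> pd.DataFrame:
    """Feature matrix for a batch of composites, indexed by composite id."""
    rows = [compute_features(c, pixel_size) for c in composites]
    table = pd.DataFrame(rows)
    table.index.name = "composite_id"
    return table


# ---------------------------------------------------------------------------
# Gentle boosting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stump:
    """One boosting round: a shared split with per-class votes.

    For class ``c`` the stump contributes ``a[c]`` when
    ``x[feature_index] > threshold`` and ``b[c]`` otherwise.
    """

    feature_index: int
    threshold: float
    a: np.ndarray  # (C,) votes for feature > threshold
    b: np.ndarray  # (C,) votes for feature <= threshold

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("stump votes must be finite")


@dataclass
class BoostModel:
    """An ordered gentle-boosting stump ensemble."""

    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    stumps: list[Stump] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def n_rounds(self) -> int:
        return len(self.stumps)

    # -- inference ---------------------------------------------------------

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"missing feature(s): {', '.join(missing)}")
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if X.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} features, got {X.shape[1]}"
                )
        return X

    def decision_scores(self, X) -> np.ndarray:
        """Additive per-class scores, shape (n, C)."""
        X = self._matrix(X)
        F = np.zeros((X.shape[0], len(self.classes)))
        for s in self.stumps:
            hi = X[:, s.feature_index] > s.threshold
            F += np.where(hi[:, None], s.a, s.b)
        return F

    def predict(self, X) -> np.ndarray:
        """Class labels; ties resolve to the earlier class in ``classes``."""
        scores = self.decision_scores(X)
        return np.asarray(self.classes, dtype=object)[scores.argmax(axis=1)]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "classes": list(self.classes),
            "feature_names": list(self.feature_names),
            "n_rounds": self.n_rounds,
            "stumps": [
                {
                    "feature_index": int(s.feature_index),
                    "threshold": float(s.threshold),
                    "a": s.a.tolist(),
                    "b": s.b.tolist(),
                }
                for s in self.stumps
            ],
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {d.get('format_version')!r}")
        return cls(
            classes=tuple(d["classes"]),
            feature_names=tuple(d["feature_names"]),
            stumps=[
                Stump(s["feature_index"], s["threshold"], s["a"], s["b"])
                for s in d["stumps"]
            ],
            metadata=d.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "BoostModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def candidate_thresholds(x: np.ndarray, max_thresholds: int = 256) -> np.ndarray:
    """Midpoints of sorted unique values, quantile-subsampled to a budget."""
    u = np.unique(x)
    if u.size < 2:
        return np.empty(0)
    mids = (u[:-1] + u[1:]) / 2.0
    if mids.size > max_thresholds:
        idx = np.unique(
            np.round(np.linspace(0, mids.size - 1, max_thresholds)).astype(int)
        )
        mids = mids[idx]
    return mids


def _best_stump_for_feature(
    x: np.ndarray, W: np.ndarray, WY: np.ndarray, thresholds: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray] | None:
    """Best (gain, threshold, a, b) for one feature; None if unsplittable.

    With per-class weights summing to ``tot_c``, the weighted squared error
    of the least-squares votes is ``sum_c tot_c - gain`` with
    ``gain = sum_c a_c^2 * Sw_hi + b_c^2 * Sw_lo``; maximizing the gain
    minimizes the error, so only the gain needs scanning.
    """
    if thresholds.size == 0:
        return None
    order = np.argsort(x, kind="stable")
    xs = x[order]
    cumW = np.cumsum(W[order], axis=0)  # (n, C)
    cumWY = np.cumsum(WY[order], axis=0)
    totW = cumW[-1]
    totWY = cumWY[-1]
    k = np.searchsorted(xs, thresholds, side="right")  # points <= threshold
    k = np.clip(k, 1, len(xs) - 1)
    Sw_lo = cumW[k - 1]  # (m, C)
    Swy_lo = cumWY[k - 1]
    Sw_hi = totW - Sw_lo
    Swy_hi = totWY - Swy_lo
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(Sw_hi > 0, Swy_hi / Sw_hi, 0.0)
        b = np.where(Sw_lo > 0, Swy_lo / Sw_lo, 0.0)
    gain = (a * a * Sw_hi + b * b * Sw_lo).sum(axis=1)
    best = int(np.argmax(gain))  # ties -> lowest threshold
    return float(gain[best]), float(thresholds[best]), a[best], b[best]


def train_gentle_boost(
    X,
    y,
    n_rounds: int = 30,
    thresholds_per_feature: int = 256,
    classes: Sequence[str] | None = None,
    feature_names: Sequence[str] | None = None,
    metadata: dict | None = None,
) -> BoostModel:
    """Train a one-vs-all gentle-boosting stump ensemble.

    Per class ``c`` the targets are ``y_c ∈ {+1, −1}`` with per-class weights
    initialized uniform.  Each round scans candidate (feature, threshold)
    pairs — thresholds are midpoints of sorted unique values, subsampled to
    ``thresholds_per_feature`` — fits the weighted-least-squares votes
    ``a = Σ w·y·[x>θ] / Σ w·[x>θ]`` and ``b`` likewise on the complement,
    selects the pair minimizing the total weighted squared error
    ``Σ_c Σ_i w_ci (y_ci − f_c(x_i))²``, appends the stump and updates
    ``w_ci ← w_ci·exp(−y_ci f_c(x_i))`` before renormalizing per class.

    The model records the exponential loss of the additive ensemble after
    every round in ``metadata["train_loss"]`` (non-increasing).
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    y = np.asarray(y, dtype=object)
    if classes is None:
        present = set(y)
        classes = tuple(c for c in CLASSES if c in present) or tuple(
            sorted(present, key=str)
        )
    classes = tuple(classes)
    if len(set(y)) < 2:
        raise ValueError("training needs at least 2 classes")
    unknown = set(y) - set(classes)
    if unknown:
        raise ValueError(f"labels not in classes: {sorted(map(str, unknown))}")
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(X.shape[1]))

    n, d = X.shape
    C = len(classes)
    Y = np.where(
        y[:, None] == np.asarray(classes, dtype=object)[None, :], 1.0, -1.0
    )  # (n, C)
    W = np.full((n, C), 1.0 / n)
    F = np.zeros((n, C))
    thresholds = [candidate_thresholds(X[:, j], thresholds_per_feature) for j in range(d)]

    stumps: list[Stump] = []
    train_loss: list[float] = []
    for _ in range(n_rounds):
        best = None
        for j in range(d):  # ascending feature index -> tie-break
            res = _best_stump_for_feature(X[:, j], W, W * Y, thresholds[j])
            if res is None:
                continue
            if best is None or res[0] > best[0][0]:
                best = (res, j)
        if best is None:
            break  # all features constant
        (gain, theta, a, b), j = best
        stump = Stump(feature_index=j, threshold=theta, a=a, b=b)
        stumps.append(stump)
        f = np.where((X[:, j] > theta)[:, None], a, b)  # (n, C)
        F += f
        W = W * np.exp(-Y * f)
        W = W / W.sum(axis=0, keepdims=True)
        train_loss.append(float(np.exp(-Y * F).sum() / n))

    meta = dict(metadata or {})
    meta.setdefault("n_rounds_requested", n_rounds)
    meta["train_loss"] = train_loss
    return BoostModel(
        classes=classes,
        feature_names=tuple(feature_names),
        stumps=stumps,
        metadata=meta,
    )


def predict(model: BoostModel, X):
    """Scores and labels for feature rows (see :meth:`BoostModel.predict`)."""
    return model.decision_scores(X), model.predict(X)


def cross_validate(
    X,
    y,
    k_folds: int = 5,
    seed: int = 0,
    n_rounds: int = 30,
    thresholds_per_feature: int = 256,
    classes: Sequence[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Stratified k-fold cross-validation of the gentle-boost classifier.

    Returns mean held-out accuracy and the pooled confusion matrix
    (rows true, columns predicted).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = np.asarray(y, dtype=object)
    labels, counts = np.unique(y.astype(str), return_counts=True)
    if counts.min() < k_folds:
        raise ValueError(
            f"class {labels[counts.argmin()]!r} has {counts.min()} members, "
            f"fewer than k_folds={k_folds}"
        )
    if isinstance(X, pd.DataFrame):
        Xmat = X.to_numpy(dtype=float)
        feature_names = tuple(X.columns)
    else:
        Xmat = np.asarray(X, dtype=float)
        feature_names = None
    if classes is None:
        present = set(y)
        classes = tuple(c for c in CLASSES if c in present) or tuple(
            sorted(present, key=str)
        )
    cm = pd.DataFrame(0, index=list(classes), columns=list(classes))
    accs = []
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(Xmat, y.astype(str)):
        model = train_gentle_boost(
            Xmat[train_idx],
            y[train_idx],
            n_rounds=n_rounds,
            thresholds_per_feature=thresholds_per_feature,
            classes=classes,
            feature_names=feature_names,
        )
        pred = model.predict(Xmat[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
        for t, p in zip(y[test_idx], pred):
            cm.loc[t, p] += 1
    return float(np.mean(accs)), cm


# ---------------------------------------------------------------------------
# Default labeled training set from the simulator
# ---------------------------------------------------------------------------


def make_labeled_composite_dataset(
    n_per_class: int = 300,
    seed: int = 1,
    window: int = 12,
    dt: float = synthetic_data.DEFAULT_DT,
    pixel_size: float = synthetic_data.DEFAULT_PIXEL_SIZE,
    size_cv: float = 0.15,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate labeled composites for classifier training/validation.

    Each acinus is simulated for one window of frames with per-acinus
    parameters drawn around the class defaults, collapsed into its composite
    and measured.  Returns the feature table and the matching ground-truth
    labels.
    """
    rng = np.random.default_rng(seed)
    rows, labels, index = [], [], []
    for behavior in CLASSES:
        for i in range(n_per_class):
            params = synthetic_data.sample_params(behavior, rng, size_cv=size_cv)
            acinus_seed = int(rng.integers(0, 2**31 - 1))
            masks, _ = synthetic_data.simulate_acinus(
                params, n_frames=window, dt=dt, pixel_size=pixel_size,
                seed=acinus_seed,
            )
            comps = build_composites(masks, well=f"{behavior}{i}")
            comp = max(comps, key=lambda c: c.area_px)
            rows.append(compute_features(comp, pixel_size))
            labels.append(behavior)
            index.append(f"{behavior}_{i}")
    X = pd.DataFrame(rows)
    X.index = pd.Index(index, name="composite_id")
    y = pd.Series(labels, index=X.index, name="label")
    return X, y
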