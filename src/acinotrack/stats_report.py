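"""Proportion tables, control normalization, stratified tests, small-table
statistics and heatmap export.

Phenotype calls from many wells, conditions and independent experiments are
aggregated into per-interval class proportions.  Values are normalized to
the control condition within each experiment and interval, z-scored within
(experiment, class) groups and averaged across experiments — the scale the
heatmaps display.  Association of each class with each condition versus
control is tested with the Cochran–Mantel–Haenszel statistic stratified by
experiment (no continuity correction), Bonferroni-adjusted over the family
of classes × intervals.  Small printed-table utilities (Pearson chi-square
with Fisher's exact companion, weighted IHC histoscore, Pearson r,
Student/Welch t) round out the reporting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("round", "spread", "tunnel")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows group 1/2, columns outcome +/−."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def _as_table(t) -> np.ndarray:
    if isinstance(t, ContingencyTable2x2):
        return t.to_array()
    arr = np.asarray(t, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if arr.min() < 0 or arr.sum() == 0:
        raise ValueError("counts must be non-negative with positive total")
    return arr


# ---------------------------------------------------------------------------
# Proportions and normalization
# ---------------------------------------------------------------------------


def proportions(
    calls: pd.DataFrame,
    classes: Sequence[str] = CLASSES,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Per (experiment, condition, well, interval) class counts and fractions.

    ``calls`` needs columns ``experiment, condition, well, interval, label``
    and optionally ``area_um2`` (averaged per row) and ``touches_border``
    (border-flagged composites excluded by default).
    """
    calls = calls.copy()
    unknown = set(calls["label"]) - set(classes)
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(map(str, unknown))}")
    if exclude_border and "touches_border" in calls.columns:
        calls = calls[~calls["touches_border"].astype(bool)]
    keys = ["experiment", "condition", "well", "interval"]
    rows = []
    for key, g in calls.groupby(keys, sort=True):
        counts = {c: int((g["label"] == c).sum()) for c in classes}
        n = sum(counts.values())
        row = dict(zip(keys, key))
        row["n"] = n
        for c in classes:
            row[f"count_{c}"] = counts[c]
            row[f"frac_{c}"] = counts[c] / n if n else np.nan
        row["mean_area_um2"] = (
            float(g["area_um2"].mean()) if "area_um2" in g.columns else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_and_zscore(
    table: pd.DataFrame,
    control_condition: str,
    classes: Sequence[str] = CLASSES,
) -> pd.DataFrame:
    """Control-normalize class fractions and z-score within experiments.

    Per (experiment, interval, class) every well fraction is divided by the
    mean control-condition fraction (zero control mean flags the value
    missing).  Z-scores are taken per (experiment, class) across all
    condition × well × interval normalized values; the cross-experiment
    summary is the mean of per-experiment z-scores per
    (condition, class, interval).  Degenerate groups (sd = 0) flag z as
    missing rather than ±inf.

    Returns a long DataFrame with columns ``experiment, condition, well,
    interval, class, fraction, normalized, z`` plus a ``summary`` attribute
    is *not* used — call :func:`summarize_conditions` for the pooled view.
    """
    for exp, g in table.groupby("experiment"):
        if control_condition not in set(g["condition"]):
            raise ValueError(
                f"control condition {control_condition!r} absent from "
                f"experiment {exp!r}"
            )
    long = table.melt(
        id_vars=["experiment", "condition", "well", "interval"],
        value_vars=[f"frac_{c}" for c in classes],
        var_name="class",
        value_name="fraction",
    )
    long["class"] = long["class"].str.removeprefix("frac_")

    ctrl_means = (
        long[long["condition"] == control_condition]
        .groupby(["experiment", "interval", "class"], sort=False)["fraction"]
        .mean()
        .rename("ctrl_mean")
        .reset_index()
    )
    long = long.merge(ctrl_means, on=["experiment", "interval", "class"], how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        long["normalized"] = np.where(
            long["ctrl_mean"] > 0, long["fraction"] / long["ctrl_mean"], np.nan
        )
    long = long.drop(columns="ctrl_mean")

    grp = long.groupby(["experiment", "class"], sort=False)["normalized"]
    mu = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    long["z"] = np.where(sd > 0, (long["normalized"] - mu) / sd, np.nan)
    return long


def summarize_conditions(normalized_long: pd.DataFrame) -> pd.DataFrame:
    """Cross-experiment summary: mean per-experiment z per (condition, class, interval)."""
    per_exp = (
        normalized_long.groupby(
            ["experiment", "condition", "class", "interval"], sort=True
        )["z"]
        .mean()
        .reset_index()
    )
    return (
        per_exp.groupby(["condition", "class", "interval"], sort=True)["z"]
        .agg(z="mean", n_experiments="count")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Stratified and small-table tests
# ---------------------------------------------------------------------------


def cmh_test(strata: Sequence) -> tuple[float, float]:
    """Cochran–Mantel–Haenszel test over stratified 2x2 tables.

    Statistic ``(Σ_k (a_k − E_k))² / Σ_k V_k`` with the hypergeometric mean
    ``E_k = r1·c1/N`` and variance ``V_k = r1·r2·c1·c2 / (N²(N−1))`` of the
    top-left cell; no continuity correction; p from the upper tail of
    χ²(1 df).  Strata with a zero margin carry no information and are
    skipped with a warning.
    """
    if len(strata) == 0:
        raise ValueError("need at least one stratum")
    num = 0.0
    var = 0.0
    used = 0
    for k, t in enumerate(strata):
        arr = _as_table(t)
        a = arr[0, 0]
        r1, r2 = arr.sum(axis=1)
        c1, c2 = arr.sum(axis=0)
        n = arr.sum()
        if min(r1, r2, c1, c2) == 0 or n < 2:
            warnings.warn(f"stratum {k} is degenerate; skipped", stacklevel=2)
            continue
        num += a - r1 * c1 / n
        var += r1 * r2 * c1 * c2 / (n * n * (n - 1))
        used += 1
    if used == 0:
        raise ValueError("all strata are degenerate")
    if var == 0:
        return 0.0, 1.0
    stat = num * num / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def cmh_by_class(
    table: pd.DataFrame,
    control_condition: str,
    classes: Sequence[str] = CLASSES,
    adjust: bool = True,
) -> pd.DataFrame:
    """One CMH test per (condition, class, interval) versus control.

    Strata are experiments; each stratum is the 2x2 of composite counts
    condition-vs-control × class-vs-rest.  The Bonferroni family is
    classes × intervals per condition comparison.
    """
    intervals = sorted(table["interval"].unique())
    conditions = [c for c in table["condition"].unique() if c != control_condition]
    m = len(classes) * len(intervals)
    rows = []
    for cond in conditions:
        for cls in classes:
            for interval in intervals:
                strata = []
                for _, g in table[table["interval"] == interval].groupby("experiment"):
                    cond_g = g[g["condition"] == cond]
                    ctrl_g = g[g["condition"] == control_condition]
                    a = cond_g[f"count_{cls}"].sum()
                    b = cond_g["n"].sum() - a
                    c = ctrl_g[f"count_{cls}"].sum()
                    d = ctrl_g["n"].sum() - c
                    strata.append([[a, b], [c, d]])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        stat, p = cmh_test(strata)
                    except ValueError:
                        stat, p = np.nan, np.nan
                rows.append((cond, cls, interval, stat, p))
    out = pd.DataFrame(
        rows, columns=["condition", "class", "interval", "cmh_stat", "p"]
    )
    if adjust:
        out["p_adj"] = [
            np.nan if not np.isfinite(p) else min(1.0, p * m) for p in out["p"]
        ]
    return out


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``p → min(1, p·m)``, ``m`` ≥ number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def chi_square_2x2(table) -> tuple[float, float, float]:
    """Pearson chi-square (no continuity correction) plus Fisher's exact.

    Returns ``(chi2, p, fisher_p)`` with ``chi2 = N(ad−bc)²/(r1·r2·c1·c2)``
    and p from the χ²(1 df) upper tail; ``fisher_p`` is the two-sided
    Fisher exact p for the same table.
    """
    arr = _as_table(table)
    if min(*arr.sum(axis=0), *arr.sum(axis=1)) == 0:
        raise ValueError("both margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    fisher_p = stats.fisher_exact(arr, alternative="two-sided")[1]
    return float(chi2), float(p), float(fisher_p)


def weighted_histoscore(
    pct_weak: float, pct_moderate: float, pct_strong: float
) -> float:
    """Weighted IHC histoscore: 1·weak% + 2·moderate% + 3·strong%, in [0, 300]."""
    pcts = (pct_weak, pct_moderate, pct_strong)
    if min(pcts) < 0:
        raise ValueError("area percentages must be >= 0")
    if sum(pcts) > 100 + 1e-9:
        raise ValueError("area percentages must sum to at most 100")
    return 1.0 * pct_weak + 2.0 * pct_moderate + 3.0 * pct_strong


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-distribution p (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def area_t_test(
    areas: pd.DataFrame,
    control_condition: str,
    value: str = "mean_area_um2",
    welch: bool = False,
) -> pd.DataFrame:
    """Unpaired two-tailed t-test of each condition vs control, per interval.

    Equal-variance Student's t by default; Welch's correction behind the
    ``welch`` flag.  Groups with fewer than 2 values flag p as missing.
    """
    intervals = sorted(areas["interval"].unique())
    conditions = [c for c in areas["condition"].unique() if c != control_condition]
    rows = []
    for cond in conditions:
        for interval in intervals:
            sel = areas["interval"] == interval
            x = areas.loc[sel & (areas["condition"] == cond), value].dropna()
            y = areas.loc[sel & (areas["condition"] == control_condition), value].dropna()
            if len(x) < 2 or len(y) < 2:
                rows.append((cond, interval, np.nan, np.nan))
                continue
            t, p = stats.ttest_ind(x, y, equal_var=not welch)
            rows.append((cond, interval, float(t), float(p)))
    return pd.DataFrame(rows, columns=["condition", "interval", "t", "p"])


# ---------------------------------------------------------------------------
# Heatmap export
# ---------------------------------------------------------------------------


def export_heatmaps(
    summary: pd.DataFrame,
    pvalues: pd.DataFrame,
    out_dir,
    classes: Sequence[str] = CLASSES,
) -> dict[str, dict[str, Path]]:
    """Write per-class condition × interval matrices as CSV + PNG.

    ``summary`` comes from :func:`summarize_conditions` (z column);
    ``pvalues`` from :func:`cmh_by_class` (p_adj column).  Z matrices are
    rendered blue-to-red, adjusted-p matrices in grayscale.  CSV re-import
    reproduces the matrices exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for cls in classes:
        z = summary[summary["class"] == cls].pivot(
            index="condition", columns="interval", values="z"
        )
        pv = pvalues[pvalues["class"] == cls].pivot(
            index="condition", columns="interval", values="p_adj"
        )
        paths = {}
        for name, mat, cmap, vmin, vmax in (
            ("z", z, "coolwarm", None, None),
            ("p", pv, "gray", 0.0, 1.0),
        ):
            csv_path = out_dir / f"{cls}_{name}.csv"
            mat.to_csv(csv_path)
            fig, ax = plt.subplots(figsize=(1 + 0.6 * mat.shape[1], 1 + 0.4 * mat.shape[0]))
            im = ax.imshow(mat.to_numpy(dtype=float), cmap=cmap, vmin=vmin, vmax=vmax,
                           aspect="auto")
            ax.set_xticks(range(mat.shape[1]), mat.columns)
            ax.set_yticks(range(mat.shape[0]), mat.index)
            ax.set_title(f"{cls} ({name})")
            fig.colorbar(im, ax=ax)
            png_path = out_dir / f"{cls}_{name}.png"
            fig.savefig(png_path, dpi=100, bbox_inches="tight")
            plt.close(fig)
            paths[f"{name}_csv"] = csv_path
            paths[f"{name}_png"] = png_path
        written[cls] = paths
    return written
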