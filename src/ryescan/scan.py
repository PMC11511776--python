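"""Differentiation outlier scans and the landscape correlation panel.

A window is an outlier when its statistic is *strictly above* the 0.95
linear-interpolation quantile of defined windows — genome-wide on Z(FST),
or within each recombination class on raw FST for the stratified scan.
Because the Z-transform is strictly monotone, genome-wide flags are
identical whether computed on FST or Z(FST) for a fixed window set.

Undefined windows (no usable SNVs) are excluded from both the quantile
and the outlier denominator and reported separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .recombination import LOW

__all__ = [
    "OutlierScanResult",
    "CorrelationPanel",
    "percentile_threshold",
    "scan_genome_wide",
    "scan_stratified",
    "landscape_correlations",
    "write_outliers_bed",
]


def percentile_threshold(values, q: float = 0.95) -> float:
    """Linear-interpolation quantile of the defined (non-NaN) values."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no defined values for percentile threshold")
    return float(np.quantile(x, q))


@dataclass
class OutlierScanResult:
    mode: str  # "genome_wide" | "stratified"
    outlier: np.ndarray  # bool per window
    threshold: float | None = None  # genome-wide threshold (Z scale)
    class_thresholds: dict[str, float] = field(default_factory=dict)
    class_counts: dict[str, dict] = field(default_factory=dict)
    n_defined: int = 0
    n_outliers: int = 0
    n_outliers_low_rec: int | None = None

    @property
    def outlier_fraction(self) -> float:
        return self.n_outliers / self.n_defined if self.n_defined else np.nan


def scan_genome_wide(
    stats_table: pd.DataFrame, q: float = 0.95, classes: np.ndarray | None = None
) -> OutlierScanResult:
    """Flag windows with Z(FST) strictly above the genome-wide q-quantile.

    With a recombination classification supplied, also reports how many
    outliers fall in the low-recombining class.
    """
    z = stats_table["z_fst"].to_numpy(dtype=float)
    defined = ~np.isnan(z)
    if defined.sum() < 20:
        raise ValueError("need >= 20 defined Z(FST) windows for a genome-wide scan")
    thr = percentile_threshold(z, q)
    flags = np.zeros(len(z), dtype=bool)
    flags[defined] = z[defined] > thr
    n_low = None
    if classes is not None:
        n_low = int((flags & (np.asarray(classes) == LOW)).sum())
    return OutlierScanResult(
        mode="genome_wide",
        outlier=flags,
        threshold=thr,
        n_defined=int(defined.sum()),
        n_outliers=int(flags.sum()),
        n_outliers_low_rec=n_low,
    )


def scan_stratified(
    stats_table: pd.DataFrame, classes: np.ndarray, q: float = 0.95, min_windows: int = 5
) -> OutlierScanResult:
    """Independent outlier scans within each recombination class.

    Thresholds are q-quantiles of raw FST within the class; a class with
    fewer than ``min_windows`` defined windows is skipped with a warning.
    Per-class counts report both the fraction of that class's windows and
    the fraction of all outliers.
    """
    fst = stats_table["fst"].to_numpy(dtype=float)
    classes = np.asarray(classes)
    flags = np.zeros(len(fst), dtype=bool)
    thresholds: dict[str, float] = {}
    counts: dict[str, dict] = {}
    for cls in ("low", "intermediate", "high"):
        in_cls = classes == cls
        vals = fst[in_cls]
        defined = ~np.isnan(vals)
        if defined.sum() < min_windows:
            warnings.warn(f"recombination class {cls!r} has < {min_windows} defined windows; skipped", stacklevel=2)
            continue
        thr = percentile_threshold(vals, q)
        cls_flags = np.zeros(len(fst), dtype=bool)
        cls_flags[in_cls] = np.where(np.isnan(fst[in_cls]), False, fst[in_cls] > thr)
        flags |= cls_flags
        thresholds[cls] = thr
        counts[cls] = {
            "threshold": thr,
            "n_windows": int(defined.sum()),
            "n_outliers": int(cls_flags.sum()),
            "fraction_of_class": float(cls_flags.sum() / defined.sum()),
        }
    total = int(flags.sum())
    for cls in counts:
        counts[cls]["fraction_of_outliers"] = (
            counts[cls]["n_outliers"] / total if total else np.nan
        )
    return OutlierScanResult(
        mode="stratified",
        outlier=flags,
        class_thresholds=thresholds,
        class_counts=counts,
        n_defined=int((~np.isnan(fst)).sum()),
        n_outliers=total,
    )


# ---------------------------------------------------------------------------
# correlation panel

_PAIRS = [
    ("fst", "rho"),
    ("dxy", "rho"),
    ("dxy", "fst"),
    ("fst", "pi_avg"),
    ("pi_avg", "dxy"),
]


@dataclass
class CorrelationPanel:
    """Pearson correlations of the windowed landscape statistics.

    ``panel``: one row per statistic pair (r, two-sided p, n windows);
    ``per_chromosome``: FST-dxy correlation per chromosome. p-values come
    from the t-distribution transform of r, uncorrected.
    """

    panel: pd.DataFrame
    per_chromosome: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {
                "panel": self.panel.to_dict(orient="records"),
                "per_chromosome": self.per_chromosome.to_dict(orient="records"),
            },
            indent=2,
            default=float,
        )


def _pearson(df: pd.DataFrame, a: str, b: str) -> tuple[float, float, int]:
    sub = df[[a, b]].dropna()
    n = len(sub)
    if n < 3:
        return np.nan, np.nan, n
    x, y = sub[a].to_numpy(), sub[b].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan, n
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def landscape_correlations(stats_table: pd.DataFrame) -> CorrelationPanel:
    rows = []
    for a, b in _PAIRS:
        if a not in stats_table.columns or b not in stats_table.columns:
            continue
        r, p, n = _pearson(stats_table, a, b)
        rows.append({"x": a, "y": b, "r": r, "p": p, "n": n})
    per_chrom = []
    if {"fst", "dxy"} <= set(stats_table.columns):
        for chrom, sub in stats_table.groupby("chrom", sort=False):
            r, p, n = _pearson(sub, "fst", "dxy")
            per_chrom.append({"chrom": chrom, "x": "fst", "y": "dxy", "r": r, "p": p, "n": n})
    return CorrelationPanel(panel=pd.DataFrame(rows), per_chromosome=pd.DataFrame(per_chrom))


def write_outliers_bed(stats_table: pd.DataFrame, result: OutlierScanResult, path) -> None:
    """Outlier windows as BED (0-based half-open) with the statistic."""
    sub = stats_table.loc[result.outlier, ["chrom", "start", "end", "fst"]]
    sub.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
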