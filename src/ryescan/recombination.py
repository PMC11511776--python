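"""Recombination-rate tracks and window classification.

The population recombination rate rho = 4*Ne*r is consumed as a per-window
input track (e.g. averaged from LD-based interval estimates); this module
averages interval estimates into analysis windows, splits windows into
low / intermediate / high classes by genome-wide rho quantiles, and
relates rho to a meiotic genetic map (cM/Mb).

Low-recombining windows are those at or below the 0.25 rho percentile
(linear-interpolation quantile over defined windows, genome-wide); high
windows are strictly above the 0.75 percentile; ties at a threshold go
to the lower class. The classification is rank-based, hence invariant
under any strictly monotone transform of rho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .window_stats import GenomicWindow

__all__ = [
    "RecombinationClassification",
    "average_rho_in_windows",
    "classify_windows",
    "correlate_with_genetic_map",
    "read_rho_track",
    "write_rho_track",
]

LOW, INTERMEDIATE, HIGH, UNDEFINED = "low", "intermediate", "high", "undefined"


@dataclass
class RecombinationClassification:
    classes: np.ndarray  # per-window label
    low_threshold: float
    high_threshold: float

    @property
    def counts(self) -> dict[str, int]:
        labels, n = np.unique(self.classes, return_counts=True)
        return dict(zip(labels.tolist(), n.tolist()))


def average_rho_in_windows(point_estimates: pd.DataFrame, windows: list[GenomicWindow]) -> pd.DataFrame:
    """Overlap-length-weighted mean of interval rho estimates per window.

    ``point_estimates`` columns: chrom, start, end (0-based half-open),
    rho. Windows with no overlapping estimate get NaN.
    """
    rho = np.full(len(windows), np.nan)
    est_chrom = point_estimates["chrom"].to_numpy()
    est_start = point_estimates["start"].to_numpy(dtype=float)
    est_end = point_estimates["end"].to_numpy(dtype=float)
    est_rho = point_estimates["rho"].to_numpy(dtype=float)
    for i, w in enumerate(windows):
        on = est_chrom == w.chrom
        if not on.any():
            continue
        ov = np.minimum(est_end[on], w.end) - np.maximum(est_start[on], w.start)
        pos = ov > 0
        if pos.any():
            rho[i] = np.average(est_rho[on][pos], weights=ov[pos])
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "rho": rho,
        }
    )


def classify_windows(
    rho: np.ndarray | pd.Series, low_q: float = 0.25, high_q: float = 0.75
) -> RecombinationClassification:
    """Split windows into low/intermediate/high recombination classes.

    Quantiles are computed genome-wide over defined (non-NaN) windows;
    all-equal rho degenerates to everything intermediate, with a warning.
    """
    if isinstance(rho, pd.DataFrame):
        rho = rho["rho"]
    x = np.asarray(rho, dtype=float)
    defined = x[~np.isnan(x)]
    if defined.size < 4:
        raise ValueError("need >= 4 defined rho values to classify")
    lo = float(np.quantile(defined, low_q))
    hi = float(np.quantile(defined, high_q))
    classes = np.full(x.shape, INTERMEDIATE, dtype=object)
    if np.all(defined == defined[0]):
        warnings.warn("all rho values equal; every window classified intermediate", stacklevel=2)
    else:
        classes[x <= lo] = LOW
        classes[x > hi] = HIGH
    classes[np.isnan(x)] = UNDEFINED
    return RecombinationClassification(classes=classes, low_threshold=lo, high_threshold=hi)


def correlate_with_genetic_map(track: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r (and two-sided p) of rho vs cM/Mb over complete windows."""
    sub = track[["rho", "cm_per_mb"]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError("need >= 3 windows with both rho and cM/Mb defined")
    rho = sub["rho"].to_numpy()
    cm = sub["cm_per_mb"].to_numpy()
    if rho.std() == 0 or cm.std() == 0:
        return np.nan, np.nan, n
    r, p = sps.pearsonr(rho, cm)
    return float(r), float(p), n


def read_rho_track(path) -> pd.DataFrame:
    """Read a per-window rho TSV (chrom, start, end, rho[, cm_per_mb]).

    Tolerant of loosely named headers: the first four columns
    are interpreted positionally if the canonical names are absent.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "rho" not in cols:
        rename = dict(zip(df.columns[:4], ["chrom", "start", "end", "rho"]))
        df = df.rename(columns=rename)
    else:
        df = df.rename(columns={cols.get("chrom", df.columns[0]): "chrom"})
    for c in ("start", "end"):
        df[c] = df[c].astype(int)
    df["rho"] = df["rho"].astype(float)
    return df


def write_rho_track(track: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end", "rho"] + (
        ["cm_per_mb"] if "cm_per_mb" in track.columns else []
    )
    track.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.10g")
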