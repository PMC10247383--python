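"""Multidiversity and multifunctionality aggregation.

Indicator panels (plot × indicator, all oriented so that higher = better)
are standardized to unit scale, and multidiversity / multifunctionality is
the number of indicators in a plot that exceed a threshold expressed as a
percentage of the landscape-level maximum of each indicator.  To damp the
influence of extreme values the "maximum" is the mean of the three highest
observed values.  An averaging alternative and a correlation-cluster
pre-selection of redundant indicators are also provided.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform



class DegenerateScaleError(ValueError):
    """Raised when an indicator is constant and cannot be min-max scaled."""


def unit_scale(m: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each indicator column to [0, 1]; missing values kept."""
    out = m.astype(float).copy()
    for col in out.columns:
        x = out[col]
        lo, hi = x.min(skipna=True), x.max(skipna=True)
        if not np.isfinite(hi - lo) or hi == lo:
            raise DegenerateScaleError(f"indicator {col!r} is constant or empty")
        out[col] = (x - lo) / (hi - lo)
    return out


def observed_maximum(column: pd.Series, top: int = 3) -> float:
    """Mean of the ``top`` highest non-missing values of one indicator."""
    vals = pd.Series(column).dropna().to_numpy(dtype=float)
    if vals.size < top:
        raise ValueError(f"need >= {top} values, got {vals.size}")
    return float(np.sort(vals)[-top:].mean())


def multimetric_threshold(
    m: pd.DataFrame, thresholds: range | list[int] = range(1, 100)
) -> pd.DataFrame:
    """Number of indicators per plot crossing each threshold.

    ``m`` must be unit-scaled.  For threshold t (percent), an indicator
    passes in a plot when its value >= (t/100) × its observed maximum (mean
    of top three values across plots).  Missing values never pass.

    Returns a plot × threshold table of counts.
    """
    maxima = m.apply(observed_maximum, axis=0).to_numpy(dtype=float)
    values = m.to_numpy(dtype=float)
    counts = {}
    for t in thresholds:
        cut = (t / 100.0) * maxima
        passing = values >= cut[np.newaxis, :]
        passing &= ~np.isnan(values)
        counts[int(t)] = passing.sum(axis=1)
    out = pd.DataFrame(counts, index=m.index)
    out.columns.name = "threshold_pct"
    return out


def multimetric_average(m: pd.DataFrame) -> pd.Series:
    """Per-plot mean over non-missing unit-scaled indicators."""
    return m.mean(axis=1, skipna=True)


def preselect_indicators(
    m: pd.DataFrame,
    corr_cutoff: float = 0.7,
    force_drop: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Drop redundant indicators by correlation clustering.

    Hierarchical clustering (average linkage) on distance 1 − |Spearman r|,
    cut at height 1 − corr_cutoff.  Within each resulting cluster one
    indicator is retained — the one least correlated (mean |r|) with the
    rest of the panel — and the others are dropped.  ``force_drop`` names
    indicators to drop a priori (before clustering), mirroring an expert
    pre-selection.

    Returns (retained, dropped) column-name lists, in panel order.
    """
    cols = [c for c in m.columns]
    dropped = []
    if force_drop:
        unknown = set(force_drop) - set(cols)
        if unknown:
            raise KeyError(f"force_drop names not in panel: {sorted(unknown)}")
        dropped.extend([c for c in cols if c in set(force_drop)])
        cols = [c for c in cols if c not in set(force_drop)]
    if len(cols) < 2:
        return cols, dropped

    sub = m[cols].astype(float)
    rho = sub.corr(method="spearman").to_numpy()
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - np.abs(rho)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=1.0 - corr_cutoff, criterion="distance")

    mean_abs_r = np.nanmean(np.abs(rho) - np.eye(len(cols)), axis=1)
    retained = set()
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        keep = members[np.argmin(mean_abs_r[members])]
        retained.add(cols[keep])
        dropped.extend(cols[i] for i in members if cols[i] not in retained)
    kept = [c for c in cols if c in retained]
    dropped_ordered = [c for c in m.columns if c in set(dropped)]
    return kept, dropped_ordered
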