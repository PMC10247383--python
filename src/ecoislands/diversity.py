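"""Hill-number diversity with rarefaction standardization.

Diversity of order q is the effective number of equally abundant species:
q=0 is species richness, q=1 is exp(Shannon entropy) and q=2 is the inverse
Simpson concentration.  Rarefaction standardizes unequally sampled
communities to a common number of individuals m; for q=0 the expectation
under sampling without replacement has a closed hypergeometric form, while
for q=1,2 the expectation is estimated by seeded resampling.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd


class UndefinedDiversityError(ValueError):
    """Raised for an all-zero abundance vector."""


def _as_counts(v) -> np.ndarray:
    counts = np.asarray(v, dtype=float)
    if counts.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if (counts < 0).any():
        raise ValueError("abundances must be non-negative")
    if counts.sum() <= 0:
        raise UndefinedDiversityError("diversity undefined for an empty sample")
    return counts


def hill_number(counts, q: int) -> float:
    """Hill number of order q in {0, 1, 2} for one abundance vector."""
    counts = _as_counts(counts)
    p = counts[counts > 0] / counts.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 2:
        return float(1.0 / np.sum(p**2))
    raise ValueError("order q must be 0, 1 or 2")


def rarefied_richness(counts, m: int) -> float:
    """Expected richness of a without-replacement subsample of m individuals.

    Closed form: sum_i [1 - C(n - n_i, m) / C(n, m)].  Requires m <= n.
    """
    counts = _as_counts(counts)
    n = int(round(counts.sum()))
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n:
        raise ValueError("cannot rarefy beyond the sample size")
    log_cnm = math.lgamma(n + 1) - math.lgamma(m + 1) - math.lgamma(n - m + 1)
    total = 0.0
    for ni in counts[counts > 0]:
        ni = int(round(ni))
        if n - ni < m:
            total += 1.0  # species cannot be missed
            continue
        log_c = (
            math.lgamma(n - ni + 1)
            - math.lgamma(m + 1)
            - math.lgamma(n - ni - m + 1)
        )
        total += 1.0 - math.exp(log_c - log_cnm)
    return total


def rarefy_hill(
    counts,
    m: int,
    q: int,
    n_resamples: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Hill number standardized to m individuals by rarefaction.

    q=0 uses the exact hypergeometric expectation; q=1,2 average the Hill
    number over ``n_resamples`` without-replacement subsamples of size m.
    If m exceeds the sample size the observed (unstandardized) value is
    returned with a warning — extrapolation is out of scope.
    """
    counts = _as_counts(counts)
    if m < 1:
        raise ValueError("m must be >= 1")
    n = int(round(counts.sum()))
    if m > n:
        warnings.warn(
            f"sample of {n} individuals cannot be rarefied to {m}; "
            "returning the observed value",
            stacklevel=2,
        )
        return hill_number(counts, q)
    if q == 0:
        return rarefied_richness(counts, m)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pool = np.repeat(np.arange(counts.size), counts.astype(int))
    k = counts.size
    acc = 0.0
    for _ in range(n_resamples):
        draw = rng.choice(pool, size=m, replace=False)
        sub = np.bincount(draw, minlength=k)
        acc += hill_number(sub, q)
    return acc / n_resamples


def plotwise_diversity(
    tables: dict[str, pd.DataFrame],
    rarefy_spec: dict[str, int] | None = None,
    orders: tuple[int, ...] = (0, 1, 2),
    n_resamples: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-plot Hill numbers for a panel of taxa.

    Parameters
    ----------
    tables
        Mapping taxon name -> plot × species count matrix (plots as index).
    rarefy_spec
        Mapping taxon -> target number of individuals m; taxa not listed are
        left unstandardized.  In this study only trees are rarefied (m=24,
        the median number of tree individuals per plot).

    Returns
    -------
    DataFrame indexed by plot with columns ``<taxon>_q<q>``.  Plots with an
    empty sample for a taxon get missing values (never zero).
    """
    rarefy_spec = rarefy_spec or {}
    rng = np.random.default_rng(seed)
    out: dict[str, pd.Series] = {}
    for taxon, table in tables.items():
        m = rarefy_spec.get(taxon)
        for q in orders:
            vals = {}
            for plot_id, row in table.iterrows():
                counts = row.to_numpy(dtype=float)
                if counts.sum() <= 0:
                    vals[plot_id] = np.nan
                    continue
                if m is None:
                    vals[plot_id] = hill_number(counts, q)
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        vals[plot_id] = rarefy_hill(
                            counts, m, q, n_resamples=n_resamples, seed=rng
                        )
            out[f"{taxon}_q{q}"] = pd.Series(vals)
    return pd.DataFrame(out)


def abundance_long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Long (plot_id, species, count) records -> plot × species matrix."""
    wide = df.pivot_table(
        index="plot_id", columns="species", values="count", aggfunc="sum", fill_value=0
    )
    wide.columns.name = None
    wide.index.name = "plot_id"
    return wide
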