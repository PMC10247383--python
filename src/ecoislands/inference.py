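"""Treatment-effect models for the indicator panel and palm yields.

The headline model is a linear mixed-effect model on the long
plot × indicator table: tree island (vs control), log island edge length,
log(planted diversity + 1) and the indicator enter as fixed effects
together with their treatment × indicator interactions, and plot is a
random intercept.  Term-wise F-tests use containment denominator degrees of
freedom: terms that are constant within plots are tested against
between-plot variation, indicator-level terms against the within-plot
residual.  A Kruskal–Wallis panel and a mixed-model Tukey comparison of
palm position classes complement it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .design import PlotSpec
from .yields import PalmYieldRecord

#: Fixed-effect structure of the treatment model.
TREATMENT_FORMULA = (
    "value ~ island + log_edge + log_div1 + C(indicator)"
    " + island:C(indicator) + log_edge:C(indicator) + log_div1:C(indicator)"
    " + log_edge:log_div1 + log_edge:log_div1:C(indicator)"
)

#: Edge length (m) assigned to control plots and their planted diversity.
CONTROL_EDGE_M = 10.0


def make_long_table(
    indicator_matrix: pd.DataFrame, plots: list[PlotSpec]
) -> pd.DataFrame:
    """Assemble the long response table for the treatment model.

    Indicator values must already be unit-scaled and oriented.  Controls
    enter with a 10 m edge length and zero planted diversity.
    """
    meta = {
        p.plot_id: (
            1.0 if p.is_island else 0.0,
            np.log(p.edge_length if p.is_island else CONTROL_EDGE_M),
            np.log1p(p.planted_diversity),
        )
        for p in plots
    }
    rows = []
    for plot_id, row in indicator_matrix.iterrows():
        island, log_edge, log_div1 = meta[str(plot_id)]
        for indicator, value in row.items():
            if pd.isna(value):
                continue
            rows.append(
                {
                    "plot_id": plot_id,
                    "indicator": indicator,
                    "value": float(value),
                    "island": island,
                    "log_edge": log_edge,
                    "log_div1": log_div1,
                }
            )
    return pd.DataFrame(rows)


def _term_is_between(exog_col: np.ndarray, groups: np.ndarray) -> bool:
    """True when a design column is constant within every plot."""
    frame = pd.DataFrame({"g": groups, "x": exog_col})
    return bool((frame.groupby("g")["x"].nunique() <= 1).all())


def fit_treatment_lmm(long_table: pd.DataFrame) -> pd.DataFrame:
    """Term-wise F-tests of the treatment mixed model.

    Returns a table (term, F, df_num, df_den, p) with a plot random
    intercept.  Singular fits are reported via a ``converged`` column, not
    silently absorbed.
    """
    if long_table["indicator"].nunique() < 2:
        raise ValueError("need at least two indicators")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            TREATMENT_FORMULA, groups="plot_id", data=long_table
        )
        result = model.fit(reml=True)
    design_info = model.data.design_info
    exog = model.exog
    groups = long_table["plot_id"].to_numpy()
    n_obs = exog.shape[0]
    n_groups = long_table["plot_id"].nunique()

    between_col = np.array(
        [_term_is_between(exog[:, j], groups) for j in range(exog.shape[1])]
    )
    p_between = int(between_col.sum())
    p_within = exog.shape[1] - p_between
    ddf_between = max(n_groups - p_between, 1)
    ddf_within = max(n_obs - n_groups - p_within, 1)

    cov = np.asarray(result.cov_params())[: exog.shape[1], : exog.shape[1]]
    beta = np.asarray(result.fe_params)
    rows = []
    for term, sl in design_info.term_name_slices.items():
        idx = np.arange(exog.shape[1])[sl]
        if term == "Intercept":
            continue
        v = cov[np.ix_(idx, idx)]
        b = beta[idx]
        try:
            w = float(b @ np.linalg.solve(v, b))
        except np.linalg.LinAlgError:
            w = np.nan
        q = len(idx)
        is_between = bool(between_col[idx].all())
        ddf = ddf_between if is_between else ddf_within
        f = w / q
        p = float(stats.f.sf(f, q, ddf)) if np.isfinite(f) else np.nan
        rows.append(
            {
                "term": term,
                "F": f,
                "df_num": q,
                "df_den": ddf,
                "p": p,
                "stratum": "between-plot" if is_between else "within-plot",
                "converged": bool(result.converged),
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis_panel(
    indicator_matrix: pd.DataFrame, is_island: pd.Series
) -> pd.DataFrame:
    """Kruskal–Wallis island-vs-control test per indicator.

    Constant indicators yield missing results.  Returns (indicator, H, p).
    """
    flags = is_island.reindex(indicator_matrix.index).astype(bool)
    rows = []
    for col in indicator_matrix.columns:
        x = indicator_matrix[col]
        a = x[flags].dropna().to_numpy()
        b = x[~flags].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            raise ValueError(f"indicator {col!r}: a group is empty")
        if np.unique(np.concatenate([a, b])).size < 2:
            rows.append({"indicator": col, "H": np.nan, "p": np.nan})
            continue
        h, p = stats.kruskal(a, b)
        rows.append({"indicator": col, "H": float(h), "p": float(p)})
    return pd.DataFrame(rows)


def tukey_position_test(
    records: list[PalmYieldRecord], min_class_size: int = 2
) -> pd.DataFrame:
    """Tukey-adjusted pairwise comparisons of palm position classes.

    A mixed model (yield ~ position, plot random intercept; reference palms
    are singleton groups) supplies the class means and their covariance;
    pairwise differences are referred to the studentized range
    distribution.  Classes with fewer than ``min_class_size`` palms are
    dropped with a warning.
    """
    frame = pd.DataFrame(
        {
            "y": [r.annual_yield for r in records],
            "position": [r.position for r in records],
            "group": [
                r.plot_id if r.plot_id is not None else f"ref_{r.palm_id}"
                for r in records
            ],
        }
    )
    sizes = frame["position"].value_counts()
    small = sizes[sizes < min_class_size].index.tolist()
    if small:
        warnings.warn(f"dropping position classes with < {min_class_size} palms: {small}")
        frame = frame[~frame["position"].isin(small)]
    classes = sorted(frame["position"].unique())
    k = len(classes)
    if k < 2:
        raise ValueError("need at least two position classes")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "y ~ 0 + C(position)", groups="group", data=frame
        )
        result = model.fit(reml=True)
    beta = np.asarray(result.fe_params)
    cov = np.asarray(result.cov_params())[:k, :k]
    df_resid = max(len(frame) - k - (frame["group"].nunique() - 1), 2)

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = beta[i] - beta[j]
            se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
            t = diff / se
            p_raw = 2.0 * stats.t.sf(abs(t), df_resid)
            q = abs(t) * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, k, df_resid))
            rows.append(
                {
                    "group1": classes[i],
                    "group2": classes[j],
                    "estimate": float(diff),
                    "se": se,
                    "p_raw": float(p_raw),
                    "p_adj": min(1.0, p_adj),
                }
            )
    return pd.DataFrame(rows)
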