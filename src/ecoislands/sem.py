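"""Piecewise structural equation modelling with d-separation.

A path model is assembled from separately fitted linear component models:

    outcome ~ log_area + log_div   (direct treatment effects)
    pc1     ~ log_div              (planted diversity → structural complexity)
    pc2     ~ log_area             (island area → tree dominance)

Candidate mediation paths (pc1 → outcome, pc2 → outcome) are added when
they improve the fit (modification test, P < 0.05, smallest P first).
Global fit is assessed by the test of directed separation: every
independence claim of the basis set is tested by regression, and Fisher's
C = −2 Σ ln(p_i) is compared to a χ² distribution with 2k degrees of
freedom.  Effects are reported as standardized coefficients
(β · sd(x)/sd(y)) and mediated (indirect) effects as products of
standardized path coefficients along each mediation chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: Default causal skeleton: (cause, effect) edges.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("log_area", "pc2"),
    ("log_div", "pc1"),
    ("log_area", "outcome"),
    ("log_div", "outcome"),
)

#: Mediator → outcome paths screened by modification tests.
CANDIDATE_PATHS: tuple[tuple[str, str], ...] = (
    ("pc1", "outcome"),
    ("pc2", "outcome"),
)


@dataclass
class SemFit:
    """A fitted piecewise path model."""

    edges: tuple[tuple[str, str], ...]
    paths: pd.DataFrame  # from, to, beta, beta_std, p, type
    basis_set: list[tuple[str, float]]  # claim description, p-value
    fisher_c: float
    df: int
    p_value: float
    aic: float
    aicc: float
    bic: float
    pseudo_r2: dict[str, float]
    n: int
    transformed: dict[str, bool] = field(default_factory=dict)

    @property
    def indirect_effects(self) -> pd.DataFrame:
        return self.paths[self.paths["type"] == "indirect"]


def ordered_quantile_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal (ordered quantile) normalizing transform."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def _parents(edges, node) -> list[str]:
    return [u for (u, v) in edges if v == node]


def _nodes(edges) -> list[str]:
    """Nodes in a topological order (exogenous first)."""
    nodes: list[str] = []
    for u, v in edges:
        for w in (u, v):
            if w not in nodes:
                nodes.append(w)
    # Kahn ordering
    remaining = set(nodes)
    order = []
    while remaining:
        free = [w for w in nodes if w in remaining and not (set(_parents(edges, w)) & remaining)]
        if not free:
            raise ValueError("graph has a cycle")
        for w in free:
            order.append(w)
            remaining.discard(w)
    return order


def basis_set(edges) -> list[tuple[str, str, tuple[str, ...]]]:
    """Union basis set of independence claims for a DAG.

    For each non-adjacent pair (u, v), the claim is
    u ⊥ v | pa(u) ∪ pa(v).  Pairs of exogenous variables are skipped: their
    correlations are treated as free, as is conventional for d-separation
    tests of path models with correlated inputs.

    Returns (u, v, conditioning) with v the downstream variable of the pair.
    """
    order = _nodes(edges)
    adjacent = {frozenset(e) for e in edges}
    claims = []
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            if frozenset((u, v)) in adjacent:
                continue
            if not _parents(edges, u) and not _parents(edges, v):
                continue  # exogenous pair
            cond = tuple(
                sorted((set(_parents(edges, u)) | set(_parents(edges, v))) - {u, v})
            )
            claims.append((u, v, cond))
    return claims


def _claim_pvalue(
    data: pd.DataFrame,
    u: str,
    v: str,
    cond: tuple[str, ...],
    normality_gate: bool = False,
) -> float:
    """p-value of u in the regression v ~ u + conditioning set.

    With ``normality_gate`` the claim regression applies the same
    Shapiro–Wilk / ordered-quantile treatment as the component models, so
    the d-separation test judges the model on the scale it was fitted on.
    """
    rhs = [u] + [c for c in cond if c not in (u, v)]
    x = sm.add_constant(data[rhs].to_numpy())
    y = data[v].to_numpy(dtype=float)
    fit = sm.OLS(y, x).fit()
    if normality_gate and len(y) >= 3:
        sw_p = stats.shapiro(fit.resid).pvalue
        if np.isfinite(sw_p) and sw_p < 0.05:
            fit = sm.OLS(ordered_quantile_transform(y), x).fit()
    return float(fit.pvalues[1])


def d_separation_test(
    data: pd.DataFrame, edges=DEFAULT_EDGES, normality_gate: bool = False
) -> tuple[float, int, float, list[tuple[str, float]]]:
    """Fisher's C over the DAG's basis set: (C, df, p, tested claims)."""
    claims = basis_set(edges)
    tested = []
    for u, v, cond in claims:
        p = _claim_pvalue(data, u, v, cond, normality_gate=normality_gate)
        tested.append((f"{u} _||_ {v} | {{{', '.join(cond) or ''}}}", p))
    c = fisher_c([p for _, p in tested])
    df = 2 * len(tested)
    p_global = float(stats.chi2.sf(c, df)) if df > 0 else 1.0
    return c, df, p_global, tested


def fisher_c(pvalues) -> float:
    """Fisher's C = −2 Σ ln(p_i) (order-invariant, ≥ 0)."""
    p = np.asarray(list(pvalues), dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return float(-2.0 * np.log(p).sum())


def _fit_component(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    normality_gate: bool,
    alpha: float = 0.05,
):
    """OLS fit with a Shapiro–Wilk residual-normality gate.

    When residuals fail the gate the response is ordered-quantile
    transformed and the model refitted.
    """
    y = data[response].to_numpy(dtype=float)
    x = sm.add_constant(data[predictors].to_numpy())
    fit = sm.OLS(y, x).fit()
    transformed = False
    if normality_gate and len(y) >= 3:
        try:
            sw_p = stats.shapiro(fit.resid).pvalue
        except Exception:
            sw_p = np.nan
        if np.isfinite(sw_p) and sw_p < alpha:
            try:
                y_t = ordered_quantile_transform(y)
                fit = sm.OLS(y_t, x).fit()
                y = y_t
                transformed = True
            except Exception:  # pragma: no cover - transform failure
                warnings.warn("normalizing transform failed; keeping raw fit")
    return fit, y, transformed


def fit_piecewise_sem(
    data: pd.DataFrame,
    outcome: str = "outcome",
    add_paths: str | list[tuple[str, str]] = "auto",
    normality_gate: bool = True,
    mod_alpha: float = 0.05,
) -> SemFit:
    """Fit the three-component path model for one restoration outcome.

    Parameters
    ----------
    data
        One row per island with columns ``log_area``, ``log_div``, ``pc1``,
        ``pc2`` and the outcome.
    add_paths
        ``"auto"`` screens the candidate mediator → outcome paths by
        modification tests (added one at a time, smallest P < ``mod_alpha``
        first, then re-tested); a list fixes the added paths; ``[]`` fits
        the base model as hypothesized.
    """
    df = data.rename(columns={outcome: "outcome"}).copy()
    for col in ("log_area", "log_div", "pc1", "pc2", "outcome"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        if df[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant; model unidentifiable")

    if add_paths == "auto":
        included: list[tuple[str, str]] = []
        remaining = list(CANDIDATE_PATHS)
        while remaining:
            pvals = []
            for cand in remaining:
                preds = ["log_area", "log_div"] + [m for m, _ in included] + [cand[0]]
                fit, _, _ = _fit_component(df, "outcome", preds, normality_gate)
                pvals.append(float(fit.pvalues[len(preds)]))
            best = int(np.argmin(pvals))
            if pvals[best] < mod_alpha:
                included.append(remaining.pop(best))
            else:
                break
        added = included
    else:
        added = list(add_paths)

    edges = DEFAULT_EDGES + tuple(added)

    # component model fits
    specs = {
        "outcome": ["log_area", "log_div"] + [m for m, _ in added],
        "pc1": ["log_div"],
        "pc2": ["log_area"],
    }
    fits: dict[str, sm.regression.linear_model.RegressionResultsWrapper] = {}
    transformed: dict[str, bool] = {}
    y_used: dict[str, np.ndarray] = {}
    for resp, preds in specs.items():
        fit, y, was_t = _fit_component(df, resp, preds, normality_gate)
        fits[resp], transformed[resp], y_used[resp] = fit, was_t, y

    rows = []
    for resp, preds in specs.items():
        fit = fits[resp]
        sd_y = float(np.std(y_used[resp], ddof=1))
        for j, pred in enumerate(preds, start=1):
            beta = float(fit.params[j])
            sd_x = float(df[pred].std(ddof=1))
            rows.append(
                {
                    "from": pred,
                    "to": resp,
                    "beta": beta,
                    "beta_std": beta * sd_x / sd_y,
                    "p": float(fit.pvalues[j]),
                    "type": "direct",
                }
            )
    paths = pd.DataFrame(rows)

    # indirect effects: exogenous → mediator → outcome chains
    for exo, med in (("log_div", "pc1"), ("log_area", "pc2")):
        if (med, "outcome") not in added:
            continue
        b1 = paths.query("`from` == @exo and to == @med")["beta_std"]
        b2 = paths.query("`from` == @med and to == 'outcome'")["beta_std"]
        if len(b1) and len(b2):
            paths = pd.concat(
                [
                    paths,
                    pd.DataFrame(
                        [
                            {
                                "from": exo,
                                "to": "outcome",
                                "beta": np.nan,
                                "beta_std": float(b1.iloc[0]) * float(b2.iloc[0]),
                                "p": np.nan,
                                "type": "indirect",
                            }
                        ]
                    ),
                ],
                ignore_index=True,
            )

    c, dof, p_global, claims = d_separation_test(
        df, edges, normality_gate=normality_gate
    )
    n = len(df)
    k_params = sum(len(p) + 1 for p in specs.values())  # slopes + intercepts
    aic = c + 2.0 * k_params
    aicc = (
        c + 2.0 * k_params * n / (n - k_params - 1.0)
        if n - k_params - 1 > 0
        else np.nan
    )
    bic = c + k_params * np.log(n)
    return SemFit(
        edges=edges,
        paths=paths,
        basis_set=claims,
        fisher_c=c,
        df=dof,
        p_value=p_global,
        aic=aic,
        aicc=float(aicc),
        bic=bic,
        pseudo_r2={resp: float(f.rsquared) for resp, f in fits.items()},
        n=n,
        transformed=transformed,
    )
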