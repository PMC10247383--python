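"""Piecewise SEM: Fisher's C, basis sets, mediation and standardization."""

import numpy as np
import pandas as pd
import pytest

from ecoislands.sem import (
    DEFAULT_EDGES,
    basis_set,
    d_separation_test,
    fisher_c,
    fit_piecewise_sem,
    ordered_quantile_transform,
)


def sem_data(rng, n=52, b_div_pc1=0.6, b_area_pc2=0.6, b_pc1_out=0.5,
             b_pc2_out=0.4, b_area_out=0.0, b_div_out=0.0, noise=0.5):
    """Linear-Gaussian data from the mediation DAG with standardized paths."""
    log_area = np.log(np.sqrt(rng.choice([25, 100, 400, 1600], size=n)))
    log_div = np.log1p(rng.choice([0, 1, 2, 3, 6], size=n))
    z_a = (log_area - log_area.mean()) / log_area.std()
    z_d = (log_div - log_div.mean()) / log_div.std()
    pc1 = b_div_pc1 * z_d + np.sqrt(1 - b_div_pc1**2) * rng.standard_normal(n)
    pc2 = b_area_pc2 * z_a + np.sqrt(1 - b_area_pc2**2) * rng.standard_normal(n)
    out = (
        b_pc1_out * pc1 + b_pc2_out * pc2 + b_area_out * z_a + b_div_out * z_d
        + noise * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {"log_area": log_area, "log_div": log_div, "pc1": pc1, "pc2": pc2,
         "outcome": out}
    )


@pytest.mark.parametrize("k", [1, 3, 5, 8])
def test_fisher_c_closed_form(k):
    assert fisher_c([0.5] * k) == pytest.approx(1.3863 * k, abs=1e-3 * k)


def test_fisher_c_order_invariant(rng):
    p = rng.uniform(0.01, 0.99, size=7)
    assert fisher_c(p) == pytest.approx(fisher_c(p[::-1]))
    assert fisher_c(p) >= 0


def test_fisher_c_rejects_invalid():
    with pytest.raises(ValueError):
        fisher_c([0.0, 0.5])


def test_basis_set_of_default_dag():
    claims = basis_set(DEFAULT_EDGES)
    pairs = {frozenset((u, v)) for u, v, _ in claims}
    assert pairs == {
        frozenset(("log_area", "pc1")),
        frozenset(("log_div", "pc2")),
        frozenset(("pc1", "pc2")),
        frozenset(("pc1", "outcome")),
        frozenset(("pc2", "outcome")),
    }
    # df = 2k
    _, df, _, tested = d_separation_test(
        sem_data(np.random.default_rng(0)), DEFAULT_EDGES
    )
    assert df == 2 * len(claims) == 2 * len(tested)


def test_basis_set_shrinks_with_added_paths():
    edges = DEFAULT_EDGES + (("pc1", "outcome"),)
    assert len(basis_set(edges)) == len(basis_set(DEFAULT_EDGES)) - 1


def test_cycle_detection():
    with pytest.raises(ValueError, match="cycle"):
        basis_set((("a", "b"), ("b", "a")))


def test_perfect_fit_standardized_unity(rng):
    d = sem_data(rng)
    d["outcome"] = d["pc1"]
    fit = fit_piecewise_sem(d, add_paths=[("pc1", "outcome")], normality_gate=False)
    path = fit.paths.query("`from` == 'pc1' and to == 'outcome'").iloc[0]
    assert path["beta_std"] == pytest.approx(1.0, abs=1e-9)
    assert fit.pseudo_r2["outcome"] == pytest.approx(1.0, abs=1e-9)


def test_standardized_equals_correlation_simple_regression(rng):
    """For one predictor the standardized slope equals Pearson's r."""
    d = sem_data(rng)
    fit = fit_piecewise_sem(d, add_paths=[], normality_gate=False)
    b = fit.paths.query("`from` == 'log_div' and to == 'pc1'")["beta_std"].iloc[0]
    r = np.corrcoef(d["log_div"], d["pc1"])[0, 1]
    assert b == pytest.approx(r, abs=1e-9)


def test_modification_indices_add_true_paths(rng):
    d = sem_data(rng, b_pc1_out=0.6, b_pc2_out=0.5, noise=0.4)
    fit = fit_piecewise_sem(d)
    added = set(fit.edges) - set(DEFAULT_EDGES)
    assert ("pc1", "outcome") in added and ("pc2", "outcome") in added


def test_indirect_effects_are_path_products(rng):
    d = sem_data(rng)
    fit = fit_piecewise_sem(d, add_paths=list((("pc1", "outcome"), ("pc2", "outcome"))),
                            normality_gate=False)
    p = fit.paths
    for exo, med in (("log_div", "pc1"), ("log_area", "pc2")):
        ind = p.query("`from` == @exo and to == 'outcome' and type == 'indirect'")
        b1 = p.query("`from` == @exo and to == @med")["beta_std"].iloc[0]
        b2 = p.query("`from` == @med and to == 'outcome' and type == 'direct'")[
            "beta_std"
        ].iloc[0]
        assert ind["beta_std"].iloc[0] == pytest.approx(b1 * b2, abs=1e-12)


def test_total_effect_decomposition_noiseless(rng):
    """Without outcome noise, total = direct + indirect (simple regression)."""
    d = sem_data(rng, b_pc1_out=0.5, b_pc2_out=0.0, b_div_out=0.2, noise=0.0)
    fit = fit_piecewise_sem(
        d, add_paths=[("pc1", "outcome")], normality_gate=False
    )
    p = fit.paths
    direct = p.query("`from` == 'log_div' and to == 'outcome' and type == 'direct'")[
        "beta_std"
    ].iloc[0]
    indirect = p.query("`from` == 'log_div' and to == 'outcome' and type == 'indirect'")[
        "beta_std"
    ].iloc[0]
    # total standardized effect from the bivariate regression outcome ~ z(div)
    z_d = (d["log_div"] - d["log_div"].mean()) / d["log_div"].std()
    total = np.corrcoef(z_d, d["outcome"])[0, 1]
    # pc2 is independent of div; the div-total decomposes along div's chains
    assert direct + indirect == pytest.approx(total, abs=0.02)


def test_constant_covariate_rejected(rng):
    d = sem_data(rng)
    d["log_div"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        fit_piecewise_sem(d)


def test_ordered_quantile_transform_normalizes(rng):
    skewed = np.exp(rng.standard_normal(200) * 1.5)
    from scipy import stats

    transformed = ordered_quantile_transform(skewed)
    assert stats.shapiro(transformed).pvalue > 0.2
    # monotone: preserves order
    assert (np.argsort(transformed) == np.argsort(skewed)).all()


def test_mediation_recovery_single_seed(rng):
    """One large-n dataset recovers the generating paths closely."""
    d = sem_data(rng, n=5000, noise=0.5)
    fit = fit_piecewise_sem(d, normality_gate=False)
    p = fit.paths
    assert p.query("`from` == 'log_div' and to == 'pc1'")["beta_std"].iloc[0] == pytest.approx(
        0.6, abs=0.05
    )
    ind = p.query("`from` == 'log_div' and to == 'outcome' and type == 'indirect'")
    assert ind["beta_std"].iloc[0] == pytest.approx(0.6 * 0.5 / np.sqrt(0.5**2 * 1 + 0.4**2 + 0.25), abs=0.06)
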