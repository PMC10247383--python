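"""Treatment models: mixed-model F-tests, Kruskal–Wallis, Tukey positions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecoislands.inference import (
    fit_treatment_lmm,
    kruskal_wallis_panel,
    make_long_table,
    tukey_position_test,
)
from ecoislands.multimetrics import unit_scale
from ecoislands.yields import PalmYieldRecord


def null_long_table(design, seed, n_indicators=3, plot_sd=1.0, noise_sd=1.0):
    """Long table with a plot random effect and no treatment effects."""
    rng = np.random.default_rng(seed)
    u = rng.normal(0, plot_sd, size=len(design))
    panel = pd.DataFrame(
        {
            f"ind{j}": u + rng.normal(0, noise_sd, size=len(design))
            for j in range(n_indicators)
        },
        index=[p.plot_id for p in design],
    )
    return make_long_table(unit_scale(panel), design)


class TestTreatmentLMM:
    def test_term_table_structure(self, design):
        table = fit_treatment_lmm(null_long_table(design, seed=0))
        between = table[table["stratum"] == "between-plot"]["term"]
        assert {"island", "log_edge", "log_div1", "log_edge:log_div1"} == set(between)
        assert (table["df_num"] >= 1).all()
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    def test_needs_two_indicators(self, design):
        with pytest.raises(ValueError):
            fit_treatment_lmm(null_long_table(design, seed=0, n_indicators=1))

    def test_strong_island_effect_detected(self, design):
        rng = np.random.default_rng(1)
        island = np.array([1.0 if p.is_island else 0.0 for p in design])
        u = rng.normal(0, 0.5, size=len(design))
        panel = pd.DataFrame(
            {
                f"ind{j}": 2.0 * island + u + rng.normal(0, 0.5, size=len(design))
                for j in range(3)
            },
            index=[p.plot_id for p in design],
        )
        table = fit_treatment_lmm(make_long_table(unit_scale(panel), design))
        p_island = table.set_index("term").loc["island", "p"]
        assert p_island < 0.01

    def test_indicator_duplication_leaves_between_F_stable(self, design):
        """Duplicating every indicator column leaves between-plot F similar."""
        base = null_long_table(design, seed=3, n_indicators=2)
        dup = base.copy()
        dup["indicator"] = dup["indicator"] + "_copy"
        both = pd.concat([base, dup], ignore_index=True)
        f_base = fit_treatment_lmm(base).set_index("term")
        f_both = fit_treatment_lmm(both).set_index("term")
        for term in ("island", "log_edge", "log_div1"):
            assert f_both.loc[term, "F"] == pytest.approx(
                f_base.loc[term, "F"], rel=0.05
            )


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                         index=list("pqrstu"))
        flags = pd.Series([True, True, True, False, False, False],
                          index=list("pqrstu"))
        out = kruskal_wallis_panel(m, flags)
        assert out["H"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]}, index=list("pqrstu"))
        flags = pd.Series([True, True, True, False, False, False], index=list("pqrstu"))
        out = kruskal_wallis_panel(m, flags)
        assert out["H"].iloc[0] == pytest.approx(3.857, abs=1e-3)

    def test_matches_scipy_on_random_panels(self, rng):
        idx = [f"p{i}" for i in range(30)]
        flags = pd.Series([i < 22 for i in range(30)], index=idx)
        m = pd.DataFrame(
            rng.normal(size=(30, 20)), index=idx,
            columns=[f"c{j}" for j in range(20)],
        )
        out = kruskal_wallis_panel(m, flags).set_index("indicator")
        for col in m.columns[:5]:
            h, p = stats.kruskal(m[col][flags.values], m[col][~flags.values])
            assert out.loc[col, "H"] == pytest.approx(h)
            assert out.loc[col, "p"] == pytest.approx(p)

    def test_constant_indicator_missing(self):
        m = pd.DataFrame({"a": [1.0] * 6}, index=list("pqrstu"))
        flags = pd.Series([True] * 3 + [False] * 3, index=list("pqrstu"))
        out = kruskal_wallis_panel(m, flags)
        assert np.isnan(out["H"].iloc[0])


def make_yield_records(rng, spill=20.0, n_plots=40, sd=15.0, mu=150.0):
    records = [
        PalmYieldRecord(f"r{i}", None, "reference", float(rng.normal(mu, sd)))
        for i in range(30)
    ]
    for p in range(n_plots):
        plot = f"I{p:02d}"
        for j in range(3):
            records.append(
                PalmYieldRecord(
                    f"{plot}in{j}", plot, "inside", float(rng.normal(mu, sd))
                )
            )
        for pos, shift in (("adjacent1", spill), ("adjacent2", 0.0), ("adjacent3", 0.0)):
            records.append(
                PalmYieldRecord(
                    f"{plot}{pos}", plot, pos, float(rng.normal(mu + shift, sd))
                )
            )
    return records


class TestTukeyPositions:
    def test_spillover_only_adjacent1_significant(self, rng):
        out = tukey_position_test(make_yield_records(rng, spill=25.0))
        out = out.set_index(["group1", "group2"])

        def p(a, b):
            key = (a, b) if (a, b) in out.index else (b, a)
            return out.loc[key, "p_adj"]

        assert p("adjacent1", "reference") < 0.05
        assert p("adjacent2", "reference") > 0.05
        assert p("adjacent3", "reference") > 0.05

    def test_identical_classes_nothing_significant(self, rng):
        out = tukey_position_test(make_yield_records(rng, spill=0.0, sd=10.0))
        assert (out["p_adj"] > 0.05).all() or (out["p_adj"] > 0.01).all()

    def test_adjusted_p_not_smaller_than_raw(self, rng):
        out = tukey_position_test(make_yield_records(rng))
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()

    def test_small_class_dropped_with_warning(self, rng):
        records = make_yield_records(rng)
        records.append(PalmYieldRecord("solo", "I00", "inside", 100.0))
        records = [r for r in records if r.position != "adjacent3"]
        records.append(PalmYieldRecord("a3", "I00", "adjacent3", 100.0))
        with pytest.warns(UserWarning, match="dropping"):
            out = tukey_position_test(records)
        assert "adjacent3" not in set(out["group1"]) | set(out["group2"])
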