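"""Allometric equations and the derived ecosystem-function indicators."""

import numpy as np
import pandas as pd
import pytest

from ecoislands.design import PlotSpec
from ecoislands.indicators import (
    MIN_PALM_HEIGHT,
    PalmMeasurement,
    SoilSample,
    TreeMeasurement,
    agb_palm,
    agb_tree,
    ba_increment,
    kfs_correct,
    litter_annualize,
    litter_panel_stats,
    microclimate_amplitude,
    orient_buffering,
    pollination_rate,
    soil_indicators,
    total_agb,
)
from ecoislands.yields import ExpansionFactor


def tree(rho=0.5, dbh=10.0, h=10.0):
    return TreeMeasurement("Shorea_leprosula", rho, dbh, None, h)


class TestAllometry:
    def test_tree_agb_direct_values(self):
        assert agb_tree(tree()) == pytest.approx(0.0673 * 500**0.976, rel=1e-9)
        one = TreeMeasurement("x", 1.0, 1.0, None, 1.0)
        assert agb_tree(one) == pytest.approx(0.0673, rel=1e-9)

    def test_tree_agb_power_law_scaling(self):
        base = agb_tree(tree())
        assert agb_tree(tree(h=20.0)) == pytest.approx(base * 2**0.976, rel=1e-9)
        # homogeneity in the composite argument via wood density
        assert agb_tree(tree(rho=1.5)) == pytest.approx(base * 3**0.976, rel=1e-9)

    def test_tree_without_dbh_flagged_missing(self):
        sapling = TreeMeasurement("x", 0.5, None, 1.0, 1.1)
        assert agb_tree(sapling) is None

    @pytest.mark.parametrize("h, expected", [(5.0, 351.8978), (1.0, 64.7098)])
    def test_palm_agb_values(self, h, expected):
        assert agb_palm(PalmMeasurement(h)) == pytest.approx(expected, rel=1e-9)

    def test_palm_boundary_height_rejected(self):
        with pytest.raises(ValueError):
            agb_palm(PalmMeasurement(MIN_PALM_HEIGHT))

    def test_total_agb_unit_conversion(self):
        plot = PlotSpec("I01", "island", 100.0, 0, (), 2, 1, 3)
        # one tree of exactly 100 kg on 100 m² → 10 t/ha
        h = (100.0 / 0.0673) ** (1 / 0.976) / (0.5 * 10.0**2)
        trees = [tree(h=h)]
        assert total_agb(plot, trees, [], ExpansionFactor("I01", 120.0)) == pytest.approx(
            10.0, rel=1e-9
        )

    def test_total_agb_empty_and_linear(self):
        plot = PlotSpec("I01", "island", 100.0, 0, (), 2, 1, 3)
        assert total_agb(plot, [], [], ExpansionFactor("I01", 120.0)) == 0.0
        one = total_agb(plot, [tree()], [], ExpansionFactor("I01", 120.0))
        two = total_agb(plot, [tree(), tree()], [], ExpansionFactor("I01", 120.0))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_total_agb_palms_require_n_in(self):
        empty = PlotSpec("I02", "island", 100.0, 0, (), 2, 2, 3)
        with pytest.raises(ValueError):
            total_agb(empty, [], [PalmMeasurement(5.0)], ExpansionFactor("I02", 72.0))


class TestTreeGrowth:
    def test_single_tree_increment(self):
        assert ba_increment([2.0], [4.0], 25.0) == pytest.approx(
            (np.pi / 4) * 12 / 25, rel=1e-9
        )

    def test_no_growth_and_additivity(self):
        assert ba_increment([3.0, 5.0], [3.0, 5.0], 100.0) == 0.0
        one = ba_increment([2.0], [4.0], 25.0)
        assert ba_increment([2.0, 2.0], [4.0, 4.0], 25.0) == pytest.approx(2 * one)

    def test_shrinkage_flagged(self):
        with pytest.raises(ValueError, match="shrank"):
            ba_increment([5.0], [3.0], 25.0)


class TestMicroclimate:
    @staticmethod
    def series(amplitudes, base=24.0):
        idx, vals = [], []
        for d, amp in enumerate(amplitudes):
            day = pd.Timestamp("2018-01-01") + pd.Timedelta(days=d)
            for h, v in ((7, base), (15, base + amp)):
                idx.append(day + pd.Timedelta(hours=h))
                vals.append(v)
        return pd.Series(vals, index=idx)

    def test_constant_series_zero(self):
        assert microclimate_amplitude(self.series([0.0] * 10)) == 0.0

    def test_constant_amplitude(self):
        assert microclimate_amplitude(self.series([8.0] * 30)) == 8.0

    def test_median_robust_to_outlier_day(self):
        amps = [6.0] * 99 + [40.0]
        assert microclimate_amplitude(self.series(amps)) == 6.0

    def test_requires_complete_day(self):
        s = pd.Series([24.0], index=[pd.Timestamp("2018-01-01 07:00")])
        with pytest.raises(ValueError):
            microclimate_amplitude(s)

    def test_orientation(self):
        assert orient_buffering(8.0) == -8.0


class TestLitter:
    def test_constant_traps_annualization(self):
        # 5 g per trap per date over 24 semi-monthly dates → 480 g/m²/yr
        m = pd.DataFrame(5.0, index=range(24), columns=range(4))
        assert litter_annualize(m) == pytest.approx(480.0)

    def test_outlier_date_excluded(self):
        m = pd.DataFrame(5.0, index=range(24), columns=range(4))
        m.loc[0] = 500.0  # >> median + 3 SD of the campaign
        center, sd = 5.0, 1.0
        assert litter_annualize(m, outlier_center=center, outlier_sd=sd) == (
            pytest.approx((23 * 5.0 / 23) * 24 / 0.25)
        )

    def test_zero_content(self):
        m = pd.DataFrame(0.0, index=range(24), columns=range(4))
        assert litter_annualize(m) == 0.0

    def test_all_dates_excluded_is_error(self):
        m = pd.DataFrame(100.0, index=range(5), columns=range(4))
        with pytest.raises(ValueError):
            litter_annualize(m, outlier_center=0.0, outlier_sd=1.0)

    def test_outlier_rule_removes_little_clean_data(self, dataset):
        """On outlier-free synthetic traps the 3-SD rule cuts < 5% of dates."""
        litter = dataset.litter_series
        per_date = litter.pivot_table(
            index=["plot_id", "date_index"], columns="trap", values="mass_g"
        ).median(axis=1)
        center, sd = litter_panel_stats(per_date)
        frac = ((per_date < center - 3 * sd) | (per_date > center + 3 * sd)).mean()
        assert frac < 0.05


class TestSoilAndWater:
    def test_kfs_correction(self):
        assert kfs_correct(0.0) == 1.44
        assert kfs_correct(10.0) == pytest.approx(6.94)

    def test_molar_identity(self):
        s = SoilSample(total_c=12.0107, total_n=14.0067, available_p=0.3,
                       bulk_density=1.0)
        inv_cn, p, decomp = soil_indicators(s)
        assert inv_cn == pytest.approx(1.0, rel=1e-12)
        assert p == 0.3 and decomp == 1.0

    def test_arithmetic_values(self):
        s = SoilSample(1.2, 0.14, 0.2, 1.25)
        inv_cn, _, decomp = soil_indicators(s)
        assert inv_cn == pytest.approx(0.1001, abs=1e-4)
        assert decomp == pytest.approx(0.8)

    def test_zero_nitrogen_rejected(self):
        with pytest.raises(ValueError):
            soil_indicators(SoilSample(1.0, 0.0, 0.1, 1.0))


class TestPollination:
    def test_rate(self):
        assert pollination_rate(10, 40) == 0.25
        assert pollination_rate(0, 40) == 0.0

    def test_zero_flowers_missing(self):
        assert np.isnan(pollination_rate(0, 0))

    def test_impossible_counts_flagged(self):
        with pytest.raises(ValueError):
            pollination_rate(5, 4)
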