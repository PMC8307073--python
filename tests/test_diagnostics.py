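import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iwqi.diagnostics import (
    classify_water_type,
    descriptive_stats,
    gibbs_ratios,
    ion_ratio_panel,
    piper_coordinates,
    to_meq,
    water_types,
)
from iwqi.synthetic import make_exchange_fixture

from .conftest import PARAMS, make_table


def ion_table(rows_meq: list[dict]) -> "SampleTable":  # noqa: F821
    """Table from per-sample meq/L ion specs (converted back to mg/L)."""
    eq = {"Ca": 20.04, "Mg": 12.15, "Na": 22.99, "K": 39.10, "Fe": 18.62,
          "HCO3": 61.02, "SO4": 48.03, "Cl": 35.45, "F": 19.00}
    values = []
    for row in rows_meq:
        r = np.zeros(14)
        r[0] = 7.5
        for ion, meq in row.items():
            r[PARAMS.index(ion)] = meq * eq[ion]
        values.append(r)
    return make_table(np.array(values))


class TestToMeq:
    def test_calcium(self):
        table = ion_table([{"Ca": 2.0}])
        meq = to_meq(table)
        assert meq.data["Ca"].iloc[0] == pytest.approx(2.0)
        # 2 meq/L of Ca is 40.08 mg/L
        assert table.data["Ca"].iloc[0] == pytest.approx(40.08)

    def test_nitrate_from_nitrogen(self):
        values = np.zeros((1, 14))
        values[0, 0] = 7.5
        values[0, PARAMS.index("NO3_N")] = 14.0
        meq = to_meq(make_table(values))
        assert meq.data["NO3_N"].iloc[0] == pytest.approx(1.0)

    def test_zero_stays_zero(self):
        meq = to_meq(ion_table([{"Ca": 1.0}]))
        assert meq.data["Cl"].iloc[0] == 0.0

    def test_linearity_and_group_sums(self):
        base = ion_table([{"Ca": 1.0, "Mg": 2.0, "Cl": 2.5, "HCO3": 0.5}])
        doubled = ion_table([{"Ca": 2.0, "Mg": 4.0, "Cl": 5.0, "HCO3": 1.0}])
        m1, m2 = to_meq(base), to_meq(doubled)
        assert m2.data.to_numpy() == pytest.approx(2 * m1.data.to_numpy())
        assert m1.cation_sum.iloc[0] == pytest.approx(3.0)
        assert m1.anion_sum.iloc[0] == pytest.approx(3.0)


class TestDescriptiveStats:
    def test_moments_and_ses(self, standards):
        values = np.full((4, 14), 1.0)
        values[:, 0] = [7.2, 7.4, 7.6, 7.8]
        values[:, PARAMS.index("TH")] = [400.0, 440.0, 460.0, 500.0]
        stats = descriptive_stats(make_table(values), standards)
        row = stats.loc[("TH", "dry")]
        assert row["min"] == 400.0 and row["max"] == 500.0
        assert row["mean"] == pytest.approx(450.0)
        assert row["sd"] == pytest.approx(np.std([400, 440, 460, 500], ddof=1))
        assert row["pct_ses"] == 50.0  # 2 of 4 exceed 450

    def test_all_below_limit_zero_ses(self, standards):
        values = np.full((3, 14), 0.01)
        values[:, 0] = 7.5
        stats = descriptive_stats(make_table(values), standards)
        assert (stats["pct_ses"].dropna() == 0.0).all()

    def test_ten_of_28_is_35_71(self, standards):
        values = np.full((28, 14), 1.0)
        values[:, 0] = 7.5
        th = np.full(28, 100.0)
        th[:10] = 500.0
        values[:, PARAMS.index("TH")] = th
        stats = descriptive_stats(make_table(values), standards)
        assert stats.loc[("TH", "dry"), "pct_ses"] == 35.71

    def test_single_sample_sd_flagged(self, standards):
        values = np.full((1, 14), 1.0)
        values[0, 0] = 7.5
        stats = descriptive_stats(make_table(values), standards)
        assert (stats["sd"] == 0.0).all()
        assert (stats["sd_flag"] == "single-sample").all()

    def test_seasons_kept_separate(self, dry_table, wet_table):
        import dataclasses

        combined = dataclasses.replace(
            dry_table,
            data=pd.concat([dry_table.data, wet_table.data.set_axis(
                [f"W{i}" for i in range(len(wet_table.data))])]),
            seasons=pd.concat([dry_table.seasons, wet_table.seasons.set_axis(
                [f"W{i}" for i in range(len(wet_table.data))])]),
        )
        stats = descriptive_stats(combined, None)
        assert {"dry", "wet"} == set(stats.index.get_level_values("season"))


class TestPiper:
    def test_single_ion_corners(self):
        coords = piper_coordinates(to_meq(ion_table([{"Ca": 2.0, "HCO3": 2.0}])))
        assert coords.cation_pct.iloc[0].tolist() == pytest.approx([100.0, 0.0, 0.0])
        assert coords.anion_pct.iloc[0].tolist() == pytest.approx([100.0, 0.0, 0.0])

    def test_fifty_fifty(self):
        coords = piper_coordinates(
            to_meq(ion_table([{"Ca": 2.0, "Mg": 2.0, "HCO3": 4.0}]))
        )
        assert coords.cation_pct.iloc[0].tolist() == pytest.approx([50.0, 50.0, 0.0])

    @given(
        ions=st.lists(st.floats(0.01, 50.0), min_size=6, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_fractions_sum_to_100(self, ions):
        ca, mg, na, hco3, so4, cl = ions
        coords = piper_coordinates(to_meq(ion_table([{
            "Ca": ca, "Mg": mg, "Na": na, "HCO3": hco3, "SO4": so4, "Cl": cl,
        }])))
        assert coords.cation_pct.iloc[0].sum() == pytest.approx(100.0, abs=1e-9)
        assert coords.anion_pct.iloc[0].sum() == pytest.approx(100.0, abs=1e-9)
        # hand-computed share for the cation triangle
        assert coords.cation_pct["Ca"].iloc[0] == pytest.approx(
            100 * ca / (ca + mg + na), rel=1e-9
        )

    def test_diamond_coordinates(self):
        coords = piper_coordinates(to_meq(ion_table([{
            "Ca": 1.0, "Na": 3.0, "HCO3": 1.0, "Cl": 1.0,
        }])))
        assert coords.diamond["NaK_pct"].iloc[0] == pytest.approx(75.0)
        assert coords.diamond["SO4Cl_pct"].iloc[0] == pytest.approx(50.0)

    def test_zero_group_flagged(self):
        values = np.zeros((1, 14))
        values[0, 0] = 7.5
        values[0, PARAMS.index("HCO3")] = 61.02
        coords = piper_coordinates(to_meq(make_table(values)))
        assert coords.flagged == ("S01",)


class TestWaterType:
    def test_simple_bicarbonate_calcium(self):
        coords = piper_coordinates(to_meq(ion_table([{"Ca": 2.0, "HCO3": 2.0}])))
        wt = classify_water_type(coords, coords.cation_pct.index[0])
        assert wt.label == "HCO3-Ca"

    def test_mixed_cation(self):
        coords = piper_coordinates(to_meq(ion_table([{
            "Ca": 4.5, "Mg": 4.0, "Na": 1.5, "HCO3": 10.0,
        }])))
        wt = classify_water_type(coords, coords.cation_pct.index[0])
        assert wt.label == "HCO3-Ca-Mg"

    def test_threshold_inclusive(self):
        # Mg at exactly 25% is included
        coords = piper_coordinates(to_meq(ion_table([{
            "Ca": 3.0, "Mg": 1.0, "HCO3": 4.0,
        }])))
        wt = classify_water_type(coords, coords.cation_pct.index[0], threshold=25.0)
        assert wt.label == "HCO3-Ca-Mg"

    def test_dilution_invariance(self):
        a = ion_table([{"Ca": 3.0, "Mg": 1.5, "Na": 0.5, "HCO3": 4.0, "Cl": 1.0}])
        b = ion_table([{"Ca": 0.3, "Mg": 0.15, "Na": 0.05, "HCO3": 0.4, "Cl": 0.1}])
        la = water_types(piper_coordinates(to_meq(a))).iloc[0]
        lb = water_types(piper_coordinates(to_meq(b))).iloc[0]
        assert la == lb


class TestGibbs:
    def test_sodium_only(self):
        table = ion_table([{"Na": 2.0, "Cl": 1.0, "HCO3": 1.0}])
        g = gibbs_ratios(table, to_meq(table)).gibbs
        assert g["na_ratio"].iloc[0] == pytest.approx(1.0)

    def test_equal_chloride_bicarbonate(self):
        table = ion_table([{"Na": 2.0, "Cl": 1.0, "HCO3": 1.0}])
        g = gibbs_ratios(table, to_meq(table)).gibbs
        assert g["cl_ratio"].iloc[0] == pytest.approx(0.5)

    def test_rock_weathering_zone(self):
        values = np.zeros((1, 14))
        values[0, 0] = 7.5
        values[0, PARAMS.index("TDS")] = 500.0
        values[0, PARAMS.index("Na")] = 22.99
        values[0, PARAMS.index("Ca")] = 2 * 20.04
        values[0, PARAMS.index("Cl")] = 0.3 * 35.45
        values[0, PARAMS.index("HCO3")] = 0.7 * 61.02
        table = make_table(values)
        g = gibbs_ratios(table, to_meq(table)).gibbs
        assert g["cl_ratio"].iloc[0] == pytest.approx(0.3)
        assert g["zone"].iloc[0] == "rock-weathering"

    def test_ratios_in_unit_interval(self, dry_table):
        g = gibbs_ratios(dry_table, to_meq(dry_table)).gibbs
        assert ((g["na_ratio"] >= 0) & (g["na_ratio"] <= 1)).all()
        assert ((g["cl_ratio"] >= 0) & (g["cl_ratio"] <= 1)).all()


class TestIonRatioPanel:
    def test_pure_exchange_slope_minus_one(self):
        table = make_exchange_fixture(n=50, seed=1, noise=0.0)
        panel = ion_ratio_panel(to_meq(table))
        assert panel.exchange_slope == pytest.approx(-1.0, abs=1e-9)

    def test_noisy_exchange_slope_near_minus_one(self):
        table = make_exchange_fixture(n=100, seed=2, noise=0.02)
        panel = ion_ratio_panel(to_meq(table))
        assert panel.exchange_slope == pytest.approx(-1.0, abs=0.05)

    def test_na_equals_cl_on_identity_line(self):
        rows = [{"Na": v, "Cl": v, "Ca": 1.0, "HCO3": 1.0} for v in (1.0, 2.0, 3.0)]
        panel = ion_ratio_panel(to_meq(ion_table(rows)))
        assert panel.above_below["Na_vs_Cl"] == (0.0, 0.0)

    def test_slope_matches_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(40):
            rows.append({
                "Ca": rng.uniform(0.5, 5), "Mg": rng.uniform(0.5, 5),
                "Na": rng.uniform(0.5, 5), "Cl": rng.uniform(0.5, 5),
                "HCO3": rng.uniform(0.5, 5), "SO4": rng.uniform(0.5, 5),
            })
        meq = to_meq(ion_table(rows))
        panel = ion_ratio_panel(meq)
        x = (meq.data["Na"] - meq.data["Cl"]).to_numpy()
        y = (meq.data["Ca"] + meq.data["Mg"]
             - meq.data["HCO3"] - meq.data["SO4"]).to_numpy()
        # hand-coded least squares
        xbar, ybar = x.mean(), y.mean()
        slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
        intercept = ybar - slope * xbar
        assert panel.exchange_slope == pytest.approx(slope, abs=1e-10)
        assert panel.exchange_intercept == pytest.approx(intercept, abs=1e-10)

    def test_all_six_panels_present(self, dry_table):
        panel = ion_ratio_panel(to_meq(dry_table))
        assert set(panel.panels) == {
            "Na_vs_Cl", "CaMg_vs_HCO3SO4", "Ca_vs_HCO3",
            "Ca_vs_SO4", "Ca_vs_Mg", "exchange",
        }

    def test_zero_x_variance_flagged(self):
        rows = [{"Na": 1.0, "Cl": 1.0, "Ca": c, "HCO3": 1.0} for c in (1.0, 2.0)]
        panel = ion_ratio_panel(to_meq(ion_table(rows)))
        assert np.isnan(panel.exchange_slope)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ion_ratio_panel(to_meq(ion_table([{"Ca": 1.0, "HCO3": 1.0}])))
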