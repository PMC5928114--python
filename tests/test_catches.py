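"""Catch normalization, export arithmetic, aggregation and shares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishmerc.catches import (
    HG_MOLAR_MASS,
    aggregate,
    export_mass,
    kmol_to_grams,
    mass_to_kmol,
    normalize_catch,
    percent_share,
    share_report,
    tl_bin,
)
from fishmerc.hgdb import GroupConcentration


def _conc(group="G", hg_w=0.38, mehg_frac=0.58, tl=4.0):
    return GroupConcentration(
        isscaap_group=group,
        hg_w=hg_w,
        sd_w=0.1,
        ci95_w=0.05,
        hg_w_edible=hg_w,
        mehg_fraction_whole=mehg_frac,
        mehg_fraction_edible=0.95,
        trophic_level=tl,
        trophic_level_se=0.1,
        total_n=100,
    )


class TestNormalizeCatch:
    def test_mysticete_individuals(self):
        assert normalize_catch(10, "individuals", "Blue-whales, fin-whales") == 430.0

    def test_pinniped_individuals(self):
        out = normalize_catch(100, "individuals", "Eared seals, hair seals, walruses")
        assert out == pytest.approx(23.1)

    def test_odontocete_individuals(self):
        out = normalize_catch(1000, "individuals", "Sperm-whales, pilot-whales")
        assert out == pytest.approx(1290.0)

    def test_tonnes_identity(self):
        assert normalize_catch(5.0, "tonnes", "Oysters") == 5.0

    def test_missing_equivalence(self):
        with pytest.raises(ValueError, match="equivalence"):
            normalize_catch(1, "individuals", "Oysters")


class TestExportMass:
    def test_unit_algebra(self):
        # 1 µg g⁻¹ is numerically 1 g per tonne
        assert export_mass(1_000_000, _conc(hg_w=0.38)) == pytest.approx(3.8e5)

    def test_zero_concentration(self):
        assert export_mass(1e6, _conc(hg_w=0.0)) == 0.0

    def test_mehg_is_fraction_of_thg(self):
        c = _conc()
        assert export_mass(100.0, c, "MeHg") == pytest.approx(0.58 * export_mass(100.0, c))


class TestKmol:
    def test_zero(self):
        assert mass_to_kmol(0.0) == 0.0

    def test_molar_mass_definition(self):
        assert mass_to_kmol(200_590.0) == pytest.approx(1.0)

    def test_known_global_export_in_tonnes(self):
        # 66.3 kmol of Hg is just over 13 metric tonnes
        tonnes = kmol_to_grams(66.3) / 1e6
        assert tonnes == pytest.approx(13.3, abs=0.05)
        assert tonnes > 13

    @given(st.floats(min_value=0, max_value=1e12))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, grams):
        assert kmol_to_grams(mass_to_kmol(grams)) == pytest.approx(grams, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mass_to_kmol(-1.0)


class TestTlBin:
    @pytest.mark.parametrize("tl,expected", [(4.3, 4), (2.1, 2), (3.5, 4), (2.49, 2), (4.6, 4)])
    def test_round_half_up_with_top_merge(self, tl, expected):
        assert tl_bin(tl) == expected

    def test_unmerged_top_bin(self):
        assert tl_bin(4.6, merge_top=False) == 5


class TestAggregate:
    def test_partition_sums_match_global(self, catches_df, conc_table):
        total = aggregate(catches_df, conc_table, by=("year",))
        by_mfa = aggregate(catches_df, conc_table, by=("year", "mfa"))
        by_country = aggregate(catches_df, conc_table, by=("year", "country"))
        by_zone = aggregate(catches_df, conc_table, by=("year", "zone"))
        for part in (by_mfa, by_country, by_zone):
            merged = part.groupby("year")[["catch_tonnes", "thg_g", "mehg_g"]].sum()
            np.testing.assert_allclose(
                merged["thg_g"].to_numpy(),
                total.set_index("year")["thg_g"].to_numpy(),
                rtol=1e-9,
            )
            np.testing.assert_allclose(
                merged["catch_tonnes"].to_numpy(),
                total.set_index("year")["catch_tonnes"].to_numpy(),
                rtol=1e-9,
            )

    def test_linearity_in_catch(self, catches_df, conc_table):
        doubled = catches_df.assign(quantity=catches_df["quantity"] * 2)
        a = aggregate(catches_df, conc_table, by=("year",))
        b = aggregate(doubled, conc_table, by=("year",))
        np.testing.assert_allclose(b["thg_g"], 2 * a["thg_g"], rtol=1e-12)

    def test_linearity_in_concentration(self, catches_df, conc_table):
        target = "Tunas, bonitos, billfishes"
        bumped = conc_table.copy()
        bumped.loc[bumped["isscaap_group"] == target, "hg_w"] *= 2
        a = aggregate(catches_df, conc_table, by=("year", "group"))
        b = aggregate(catches_df, bumped, by=("year", "group"))
        sel = a["group"] == target
        np.testing.assert_allclose(
            b.loc[sel, "thg_g"], 2 * a.loc[sel, "thg_g"], rtol=1e-12
        )
        other = ~sel
        np.testing.assert_allclose(b.loc[other, "thg_g"], a.loc[other, "thg_g"], rtol=1e-12)

    def test_mehg_never_exceeds_thg(self, catches_df, conc_table):
        for by in (("year",), ("year", "mfa"), ("year", "tl_bin")):
            table = aggregate(catches_df, conc_table, by=by)
            assert (table["mehg_g"] <= table["thg_g"] + 1e-9).all()

    def test_matches_naive_per_record_loop(self, catches_df, conc_table):
        sample = catches_df.sample(100, random_state=0)
        conc = conc_table.set_index("isscaap_group")
        from fishmerc.catches import DEFAULT_MASS_EQUIVALENCE

        expected = {}
        for row in sample.itertuples():
            t = row.quantity * (
                DEFAULT_MASS_EQUIVALENCE[row.isscaap_group]
                if row.unit == "individuals"
                else 1.0
            )
            g = t * conc.at[row.isscaap_group, "hg_w"]
            expected[row.year] = expected.get(row.year, 0.0) + g
        table = aggregate(sample, conc_table, by=("year",)).set_index("year")
        for year, g in expected.items():
            assert table.at[year, "thg_g"] == pytest.approx(g, rel=1e-9)

    def test_high_tl_export_share_exceeds_catch_share(self):
        """TL-4 groups with most of the catch and higher concentration dominate export."""
        catches = pd.DataFrame(
            {
                "year": [2000] * 2,
                "mfa": [61] * 2,
                "country": ["A"] * 2,
                "isscaap_group": ["tl4", "tl2"],
                "quantity": [63.0, 37.0],
                "unit": ["tonnes"] * 2,
            }
        )
        conc = pd.DataFrame(
            {
                "isscaap_group": ["tl4", "tl2"],
                "hg_w": [0.25, 0.05],  # 5x concentration ratio
                "mehg_fraction_whole": [0.58, 0.46],
                "trophic_level": [4.2, 2.1],
                "habitat": ["oceanic", "coastal"],
            }
        )
        table = aggregate(catches, conc, by=("tl_bin",))
        shares = share_report(table.rename(columns={"tl_bin": "bin"}), "bin").set_index("bin")
        assert shares.at[4, "thg_pct"] > shares.at[4, "catch_pct"]
        assert shares.at[4, "thg_pct"] > 85

    def test_unknown_grouping_key(self, catches_df, conc_table):
        with pytest.raises(ValueError, match="grouping"):
            aggregate(catches_df, conc_table, by=("continent",))

    def test_missing_group_contributes_zero(self, conc_table, caplog):
        catches = pd.DataFrame(
            {
                "year": [2000],
                "mfa": [61],
                "country": ["A"],
                "isscaap_group": ["Unmapped group"],
                "quantity": [100.0],
                "unit": ["tonnes"],
            }
        )
        table = aggregate(catches, conc_table, by=("year",))
        assert table["thg_g"].sum() == 0.0
        assert table["catch_tonnes"].sum() == 100.0


class TestShares:
    def test_full_share(self):
        table = pd.DataFrame(
            {"key": ["a"], "catch_tonnes": [10.0], "thg_g": [5.0], "mehg_g": [2.0]}
        )
        out = share_report(table, "key").set_index("key")
        assert out.at["a", "catch_pct"] == 100
        assert out.at["a", "thg_pct"] == 100

    def test_printed_country_shares(self):
        # top three exporters against the global total
        assert percent_share(11.3 + 7.1 + 3.6, 66.3) == 33

    def test_printed_mfa_shares(self):
        assert percent_share(16.5 + 15.3 + 7.8, 66.3) == 60

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            percent_share(1.0, 0.0)
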