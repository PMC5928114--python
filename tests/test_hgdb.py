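"""Tissue conversions, whale whole-body combination and record pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishmerc.hgdb import (
    DEFAULT_TISSUE_PROFILES,
    HgRecord,
    TaxonClass,
    Tissue,
    TissueProfile,
    mehg_fraction,
    muscle_to_whole_body,
    pool_group,
    pool_table,
    whale_whole_body,
    whole_body_to_muscle,
)


def _rec(group="G", cls="fish", tissue="whole_body", n=1, mean=1.0, sd=None, form="THg"):
    return HgRecord("tax", group, cls, tissue, n, mean, sd, form, "src")


class TestMuscleConversion:
    def test_unit_muscle_concentration(self):
        # 10^(-0.2545/1.0623)
        assert muscle_to_whole_body(1.0) == pytest.approx(0.5758, abs=5e-4)

    def test_fixed_point(self):
        fp = 10 ** (-0.2545 / 0.0623)
        assert muscle_to_whole_body(fp) == pytest.approx(fp, rel=1e-9)

    def test_monotone(self):
        assert muscle_to_whole_body(0.5) < muscle_to_whole_body(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            muscle_to_whole_body(0.0)
        with pytest.raises(ValueError):
            muscle_to_whole_body(-1.0)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_whole_body_below_muscle_above_fixed_point(self, conc):
        # muscle is enriched relative to the body for realistic concentrations
        assert muscle_to_whole_body(conc) < conc

    @given(st.floats(min_value=1e-4, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_inverse(self, conc):
        assert whole_body_to_muscle(muscle_to_whole_body(conc)) == pytest.approx(
            conc, rel=1e-9
        )


class TestWhaleWholeBody:
    def test_constant_tissues(self):
        profile = DEFAULT_TISSUE_PROFILES[TaxonClass.odontocete]
        concs = {t: 0.4 for t in profile.tissues}
        assert whale_whole_body(concs, profile) == pytest.approx(0.4)

    def test_hand_weighted_sum(self):
        profile = TissueProfile(
            TaxonClass.odontocete,
            ((Tissue.muscle, 0.5), (Tissue.bone, 0.25), (Tissue.viscera, 0.25)),
        )
        out = whale_whole_body({"muscle": 1.0, "bone": 0.0, "viscera": 0.0}, profile)
        assert out == pytest.approx(0.5)

    def test_single_tissue_normalizes(self):
        profile = TissueProfile(TaxonClass.mysticete, ((Tissue.muscle, 0.4),))
        assert whale_whole_body({"muscle": 0.7}, profile) == pytest.approx(0.7)

    def test_missing_tissue_named(self):
        profile = DEFAULT_TISSUE_PROFILES[TaxonClass.odontocete]
        with pytest.raises(ValueError, match="viscera"):
            whale_whole_body({"muscle": 1.0, "bone": 0.5}, profile)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            TissueProfile(TaxonClass.odontocete, ())

    @given(
        st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_tissue_extremes(self, concs):
        profile = DEFAULT_TISSUE_PROFILES[TaxonClass.odontocete]
        mapping = dict(zip(profile.tissues, concs))
        out = whale_whole_body(mapping, profile)
        assert min(concs) - 1e-12 <= out <= max(concs) + 1e-12


class TestMehgFraction:
    @pytest.mark.parametrize(
        "cls,expected",
        [
            ("fish", 0.58),
            ("invertebrate", 0.46),
            ("turtle", 0.39),
            ("odontocete", 0.19),
            ("mysticete", 0.19),
            ("pinniped", 0.19),
        ],
    )
    def test_whole_body_fractions(self, cls, expected):
        assert mehg_fraction(cls) == expected

    def test_edible_fraction(self):
        assert mehg_fraction("fish", "muscle") == 0.95

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            mehg_fraction("plankton")


class TestPoolGroup:
    def test_two_record_weighted_mean(self):
        recs = [_rec(n=2, mean=1.0), _rec(n=8, mean=2.0)]
        gc = pool_group(recs, "G")
        assert gc.hg_w == pytest.approx(1.8)
        assert gc.total_n == 10

    def test_single_record(self):
        gc = pool_group([_rec(n=9, mean=0.5, sd=0.3)], "G")
        assert gc.hg_w == pytest.approx(0.5)
        assert gc.ci95_w == pytest.approx(1.96 * gc.sd_w / math.sqrt(9))

    def test_fish_muscle_converted_before_pooling(self):
        gc = pool_group([_rec(tissue="muscle", mean=1.0)], "G")
        assert gc.hg_w == pytest.approx(muscle_to_whole_body(1.0))
        # edible pool keeps the unconverted muscle value
        assert gc.hg_w_edible == pytest.approx(1.0)

    def test_invertebrate_records_taken_as_whole_body(self):
        gc = pool_group([_rec(cls="invertebrate", tissue="other", mean=0.02)], "G")
        assert gc.hg_w == pytest.approx(0.02)
        assert gc.mehg_fraction_whole == 0.46

    def test_mehg_form_records_excluded_from_thg_pool(self):
        recs = [_rec(n=5, mean=1.0), _rec(n=100, mean=9.0, form="MeHg")]
        gc = pool_group(recs, "G")
        assert gc.hg_w == pytest.approx(1.0)
        assert gc.total_n == 5

    def test_no_data_returns_none(self, caplog):
        assert pool_group([], "Empty") is None

    def test_low_tl_group_well_below_high_tl_group(self):
        # oysters-like vs tunas-like whole-body levels
        oysters = pool_group([_rec(cls="invertebrate", mean=0.015, n=50)], "G")
        tunas = pool_group([_rec(tissue="muscle", mean=whole_body_to_muscle(0.38), n=50)], "G")
        assert oysters.hg_w < 0.2 * tunas.hg_w

    def test_order_invariance(self):
        recs = [_rec(n=3, mean=0.5, sd=0.1), _rec(n=7, mean=1.5, sd=0.2), _rec(n=2, mean=0.9)]
        a = pool_group(recs, "G")
        b = pool_group(recs[::-1], "G")
        assert a.hg_w == pytest.approx(b.hg_w)
        assert a.sd_w == pytest.approx(b.sd_w)

    @given(
        st.integers(min_value=2, max_value=40),
        st.integers(min_value=1, max_value=39),
        st.floats(min_value=0.001, max_value=5.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_split_invariance(self, n, n1_raw, mean, sd):
        """Splitting (n, mean) into two same-mean records leaves the pool unchanged."""
        n1 = min(n1_raw, n - 1)
        whole = [_rec(n=n, mean=mean, sd=sd), _rec(n=5, mean=2 * mean + 0.1, sd=0.0)]
        split = [
            _rec(n=n1, mean=mean, sd=sd),
            _rec(n=n - n1, mean=mean, sd=sd),
            _rec(n=5, mean=2 * mean + 0.1, sd=0.0),
        ]
        a, b = pool_group(whole, "G"), pool_group(split, "G")
        assert a.hg_w == pytest.approx(b.hg_w, rel=1e-12)
        assert a.sd_w == pytest.approx(b.sd_w, rel=1e-9, abs=1e-12)
        assert a.total_n == b.total_n

    def test_pool_matches_pseudo_observation_expansion(self):
        """hg_w equals the plain mean over n_i copies of each study mean."""
        rng = np.random.default_rng(42)
        recs = [
            _rec(n=int(n), mean=float(m))
            for n, m in zip(rng.integers(1, 30, 20), rng.uniform(0.01, 2.0, 20))
        ]
        expanded = np.concatenate([[r.mean_conc] * r.n for r in recs])
        gc = pool_group(recs, "G")
        assert gc.hg_w == pytest.approx(expanded.mean(), rel=1e-12)

    def test_whale_tissue_records_collapsed(self):
        recs = [
            _rec(cls="odontocete", tissue="muscle", mean=1.0, n=10),
            _rec(cls="odontocete", tissue="bone", mean=0.2, n=8),
            _rec(cls="odontocete", tissue="viscera", mean=0.5, n=12),
        ]
        gc = pool_group(recs, "G")
        profile = DEFAULT_TISSUE_PROFILES[TaxonClass.odontocete]
        expected = whale_whole_body({"muscle": 1.0, "bone": 0.2, "viscera": 0.5}, profile)
        assert gc.hg_w == pytest.approx(expected)
        assert gc.total_n == 8  # min tissue n

    def test_pinniped_whole_body_used_directly(self):
        gc = pool_group([_rec(cls="pinniped", tissue="whole_body", mean=0.25, n=15)], "G")
        assert gc.hg_w == pytest.approx(0.25)


class TestRecordValidation:
    def test_invalid_sample_size(self):
        with pytest.raises(ValueError):
            _rec(n=0)

    def test_negative_concentration(self):
        with pytest.raises(ValueError):
            _rec(mean=-0.1)


def test_pool_table_joins_trophic_levels(hg_records, group_attrs, conc_table):
    assert set(conc_table["isscaap_group"]) <= set(group_attrs["isscaap_group"])
    tunas = conc_table.set_index("isscaap_group").loc["Tunas, bonitos, billfishes"]
    assert tunas["trophic_level"] == pytest.approx(4.3)
    assert tunas["mehg_fraction_whole"] == 0.58
    # pooled value sits within the span of simulated study means
    assert 0.1 < tunas["hg_w"] < 1.5
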