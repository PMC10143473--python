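import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilcr import (
    BackgroundTable,
    RegionRecord,
    assess_regions,
    classify_e,
    classify_igeo,
    ecological_risk,
    igeo,
    summarize_by_type,
)

positive = st.floats(min_value=1e-6, max_value=1e9, allow_nan=False)


class TestIgeo:
    @pytest.mark.parametrize(
        "cn,bn,expected",
        [
            (91.5, 61.0, 0.0),  # cn = 1.5*bn
            (61.0, 61.0, math.log2(2 / 3)),  # -0.585
            (2500.0, 61.0, math.log2(2500 / 91.5)),  # 4.772
        ],
    )
    def test_closed_form(self, cn, bn, expected):
        assert igeo(cn, bn) == pytest.approx(expected, abs=1e-12)

    def test_three_dp_values(self):
        assert round(igeo(61, 61), 3) == -0.585
        assert round(igeo(2500, 61), 3) == 4.772

    @pytest.mark.parametrize("cn,bn", [(0, 61), (-1, 61), (61, 0)])
    def test_domain_errors(self, cn, bn):
        with pytest.raises(ValueError):
            igeo(cn, bn)

    @given(positive, positive)
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_cn(self, cn, bn):
        assert igeo(2 * cn, bn) > igeo(cn, bn)

    def test_agrees_with_arbitrary_precision_oracle(self):
        """log2 ratio matches sympy's arbitrary-precision log within 1e-12."""
        import sympy

        rng = np.random.default_rng(42)
        cns = 10 ** rng.uniform(-1, 5, size=1000)
        bns = 10 ** rng.uniform(0.5, 2.5, size=1000)
        for cn, bn in zip(cns, bns):
            exact = float(
                sympy.log(sympy.Float(cn, 30) / (sympy.Rational(3, 2) * sympy.Float(bn, 30)), 2)
            )
            got = igeo(float(cn), float(bn))
            assert abs(got - exact) <= 1e-12 * max(1.0, abs(exact))


class TestEcologicalRisk:
    @pytest.mark.parametrize(
        "cn,bn,tn,expected",
        [(61, 61, 2, 2.0), (30.5, 61, 2, 1.0), (2500, 61, 2, 81.967)],
    )
    def test_values(self, cn, bn, tn, expected):
        assert ecological_risk(cn, bn, tn) == pytest.approx(expected, abs=5e-4)

    def test_linear_in_cn(self):
        assert ecological_risk(200, 61, 2) == pytest.approx(
            2 * ecological_risk(100, 61, 2)
        )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            ecological_risk(100, 61, 0)


class TestClassification:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (-0.73, 0),  # mildly below background: unpolluted class
            (0.0, 0),  # boundary convention: class 0 is upper-closed at 0
            (0.5, 1),
            (1.0, 1),
            (1.0000001, 2),
            (5.0, 5),
            (5.1, 6),  # beyond 5: extremely polluted
            (12.0, 6),
        ],
    )
    def test_igeo_classes(self, value, expected):
        assert classify_igeo(value) == expected

    def test_igeo_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_igeo(float("nan"))

    @pytest.mark.parametrize(
        "value,expected",
        [
            (24.27, "low"),
            (39.999, "low"),
            (40.0, "moderate"),
            (80.0, "considerable"),
            (160.0, "high"),
            (292.73, "high"),
            (320.0, "significant high"),
            (1000.0, "significant high"),
        ],
    )
    def test_e_classes(self, value, expected):
        assert classify_e(value) == expected

    def test_e_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_e(-1.0)

    @given(st.floats(min_value=-50, max_value=50, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_igeo_classification_total_and_monotone(self, v):
        c = classify_igeo(v)
        assert 0 <= c <= 6
        assert classify_igeo(v + 0.5) >= c


class TestAssessRegions:
    def test_composition_of_closed_forms(self, national_bg):
        rec = RegionRecord("r", "Hunan", "M", 91.5)
        res = assess_regions([rec], national_bg, tn=2.0)[0]
        assert res.igeo == pytest.approx(0.0, abs=1e-12)
        assert res.e_value == pytest.approx(3.0)
        assert res.bn_used == 61.0

    def test_order_preserved(self, small_records, national_bg):
        res = assess_regions(small_records, national_bg)
        assert [r.region_id for r in res] == [r.region_id for r in small_records]

    @given(positive, positive, st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=500, deadline=None)
    def test_igeo_e_identity(self, cn, bn, tn):
        """I_geo = log2(E / (1.5*Tn)) exactly links the two indices."""
        e = ecological_risk(cn, bn, tn)
        assert igeo(cn, bn) == pytest.approx(math.log2(e / (1.5 * tn)), abs=1e-9)

    def test_identity_on_assessed_regions(self, paperlike_table, national_bg):
        tn = 2.0
        for res in assess_regions(paperlike_table[:200], national_bg, tn):
            assert res.igeo == pytest.approx(
                math.log2(res.e_value / (1.5 * tn)), abs=1e-12
            )


class TestSummarizeByType:
    def test_hand_case_two_regions(self, national_bg):
        recs = [
            RegionRecord("a", "Hunan", "M", 91.5 / 2),  # igeo = -1
            RegionRecord("b", "Hunan", "M", 91.5 * 2),  # igeo = +1
        ]
        res = assess_regions(recs, national_bg)
        with pytest.warns(UserWarning):
            s = summarize_by_type(res, recs)
        assert s["M"]["mean_igeo"] == pytest.approx(0.0, abs=1e-12)
        assert s["M"]["igeo_class_fractions"][0] == 0.5
        assert s["M"]["igeo_class_fractions"][1] == 0.5

    def test_crsalt_class6_fraction(self, national_bg):
        # 26 Cr-salt regions of which 11 have I_geo > 5 (cn > 91.5*2^5)
        high = [RegionRecord(f"h{i}", "Hunan", "C", 3000.0) for i in range(11)]
        low = [RegionRecord(f"l{i}", "Hunan", "C", 100.0) for i in range(15)]
        recs = high + low
        res = assess_regions(recs, national_bg)
        with pytest.warns(UserWarning):
            s = summarize_by_type(res, recs)
        assert round(100 * s["C"]["igeo_class_fractions"][6], 2) == 42.31

    def test_tanning_significant_high_fraction(self, national_bg):
        # 17 tanning regions of which 5 have E >= 320 (cn >= 160*61)
        high = [RegionRecord(f"h{i}", "Hunan", "T", 160 * 61.0) for i in range(5)]
        low = [RegionRecord(f"l{i}", "Hunan", "T", 61.0) for i in range(12)]
        recs = high + low
        res = assess_regions(recs, national_bg)
        with pytest.warns(UserWarning):
            s = summarize_by_type(res, recs)
        assert round(
            100 * s["T"]["e_class_fractions"]["significant high"], 2
        ) == 29.41

    def test_fractions_sum_to_one(self, paperlike_table, national_bg):
        res = assess_regions(paperlike_table, national_bg)
        s = summarize_by_type(res, paperlike_table)
        for entry in s.values():
            assert sum(entry["igeo_class_fractions"].values()) == pytest.approx(1.0)
            assert sum(entry["e_class_fractions"].values()) == pytest.approx(1.0)
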