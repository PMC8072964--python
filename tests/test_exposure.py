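"""Censoring substitution, per-cigarette aggregation, exposure and RCR."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from flavorisk.core import ContentRecord, Part, RiskRow, Status
from flavorisk.exposure import (
    ExposureParams,
    build_risk_table,
    content_stat,
    derive_exposure_params,
    exposure_concentration,
    format_exposure,
    format_rcr,
    per_cigarette_total,
    risk_characterization,
    risk_rows_from_content_stats,
    round_sig,
    substitute_censored,
)


def _content(cig, part, compound="Menthol", content=1.0, status=Status.QUANTIFIED,
             capsule_index=None, has_capsule=None):
    part = Part(part)
    if has_capsule is None:
        has_capsule = part is Part.CAPSULE
    return ContentRecord(
        cigarette_id=cig,
        has_capsule=has_capsule,
        part=part,
        compound=compound,
        concentration_ng_per_g=content * 4000,
        content_ug_per_cigarette=content if status is Status.QUANTIFIED else 0.0,
        status=status,
        capsule_index=capsule_index,
    )


class TestDeriveParams:
    def test_study_defaults(self):
        p = derive_exposure_params(82.7, 13.2, 13.2, 14.25, 365.0)
        assert p.exposure_duration_years == pytest.approx(69.5)
        assert p.averaging_time_days == pytest.approx(25_367.5)
        assert p == ExposureParams()

    def test_onset_at_life_expectancy_rejected(self):
        with pytest.raises(ValueError):
            derive_exposure_params(80.0, 80.0)

    @settings(max_examples=100, derandomize=True)
    @given(life=st.floats(min_value=40, max_value=120),
           onset=st.floats(min_value=5, max_value=39))
    def test_at_per_ed_is_always_365(self, life, onset):
        p = derive_exposure_params(life, onset)
        assert p.averaging_time_days / p.exposure_duration_years == pytest.approx(365.0)

    def test_inconsistent_at_rejected(self):
        with pytest.raises(ValueError, match="AT"):
            ExposureParams(averaging_time_days=1000.0)


class TestSubstitution:
    def test_below_loq_gets_loq_equivalent_content(self, simple_table):
        rec = _content("A", Part.FILTER_TIP, status=Status.BELOW_LOQ)
        res = substitute_censored([rec], simple_table)
        # LOQ 0.41 ng/mL in 25 mL → 0.01025 µg
        assert res.records[0].content_ug_per_cigarette == pytest.approx(0.41 * 25 / 1000)
        assert res.records[0].status is Status.BELOW_LOQ

    def test_quantified_unchanged_and_nd_zero(self, simple_table):
        recs = [
            _content("A", Part.TOBACCO, content=2.0),
            _content("A", Part.FILTER_TIP, status=Status.NOT_DETECTED),
        ]
        res = substitute_censored(recs, simple_table)
        assert res.records[0] == recs[0]
        assert res.records[1].content_ug_per_cigarette == 0.0
        assert res.excluded_compounds == frozenset()

    def test_never_detected_compound_excluded(self, compounds):
        recs = [
            _content("A", Part.TOBACCO, "Coumarin", status=Status.NOT_DETECTED),
            _content("B", Part.TOBACCO, "Coumarin", status=Status.NOT_DETECTED),
            _content("A", Part.TOBACCO, "Menthol", content=1.0),
        ]
        res = substitute_censored(recs, compounds)
        assert res.excluded_compounds == frozenset({"Coumarin"})

    @settings(max_examples=500, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=10**6))
    def test_substitution_never_decreases_totals(self, seed, simple_table):
        """LOQ substitution is monotone: totals, means and maxima can only grow."""
        rng = random.Random(seed)
        recs = []
        for i in range(rng.randint(2, 12)):
            part = rng.choice([Part.TOBACCO, Part.FILTER_TIP])
            status = rng.choice(list(Status))
            recs.append(
                _content(f"K{i % 4}", part, content=rng.random() * 10,
                         status=status)
            )
        # de-duplicate (cigarette, part) pairs
        seen, unique = set(), []
        for r in recs:
            key = (r.cigarette_id, r.part)
            if key not in seen:
                seen.add(key)
                unique.append(r)
        before = per_cigarette_total(unique, "Menthol")
        after = per_cigarette_total(
            substitute_censored(unique, simple_table).records, "Menthol"
        )
        for cig in before:
            assert after[cig] >= before[cig]
        if any(v > 0 for v in after.values()):
            assert max(after.values()) >= max(before.values())


class TestPerCigaretteTotal:
    def test_sums_all_parts_and_capsules(self):
        recs = [
            _content("A", Part.TOBACCO, content=1.0),
            _content("A", Part.FILTER_TIP, content=2.0),
            _content("A", Part.CAPSULE, content=3.0, capsule_index=1),
            _content("A", Part.CAPSULE, content=3.0, capsule_index=2),
        ]
        assert per_cigarette_total(recs, "Menthol") == {"A": 9.0}

    def test_duplicate_rows_rejected(self):
        recs = [_content("A", Part.TOBACCO), _content("A", Part.TOBACCO)]
        with pytest.raises(ValueError, match="duplicate"):
            per_cigarette_total(recs, "Menthol")

    def test_all_nd_cigarette_counts_zero(self):
        recs = [_content("A", Part.TOBACCO, status=Status.NOT_DETECTED)]
        assert per_cigarette_total(recs, "Menthol") == {"A": 0.0}

    def test_two_capsule_max_total_exceeds_sum_of_part_maxima(self):
        """A two-capsule cigarette can push the per-cigarette maximum above
        the sum of single-part maxima across the study."""
        recs = [
            # cigarette A holds the part-wise maxima for tobacco and filter
            _content("A", Part.TOBACCO, content=5.0),
            _content("A", Part.FILTER_TIP, content=6.0),
            _content("A", Part.CAPSULE, content=4.0, capsule_index=1),
            # cigarette B has two capsules at the capsule maximum
            _content("B", Part.TOBACCO, content=4.9),
            _content("B", Part.FILTER_TIP, content=5.9),
            _content("B", Part.CAPSULE, content=7.0, capsule_index=1),
            _content("B", Part.CAPSULE, content=7.0, capsule_index=2),
        ]
        totals = per_cigarette_total(recs, "Menthol")
        part_maxima = 5.0 + 6.0 + 7.0
        assert max(totals.values()) == pytest.approx(24.8)
        assert max(totals.values()) > part_maxima


class TestContentStat:
    def test_average_and_maximum(self):
        totals = {"a": 1.0, "b": 3.0}
        assert content_stat(totals, "average") == 2.0
        assert content_stat(totals, "maximum") == 3.0

    def test_single_cigarette_average_equals_maximum(self):
        totals = {"a": 4.2}
        assert content_stat(totals, "average") == content_stat(totals, "maximum")

    def test_denominator_switch_is_exact_count_ratio(self):
        totals = {"a": 2.0, "b": 4.0, "c": 0.0, "d": 0.0}
        detected = content_stat(totals, "average", "detected_cigarettes")
        all_ = content_stat(totals, "average", "all_cigarettes")
        assert all_ == pytest.approx(detected * 2 / 4)


class TestExposureConcentration:
    def test_published_anchor_values(self, default_params):
        assert exposure_concentration(1565.01, default_params) == pytest.approx(
            1.44969, abs=5e-6
        )
        assert exposure_concentration(7870.83, default_params) == pytest.approx(
            7.29087, abs=5e-6
        )
        assert exposure_concentration(0.0, default_params) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(content=st.floats(min_value=0, max_value=1e5),
           a=st.floats(min_value=0.01, max_value=100))
    def test_linearity(self, content, a, default_params):
        ec = exposure_concentration(content, default_params)
        assert exposure_concentration(a * content, default_params) == pytest.approx(
            a * ec, rel=1e-9
        )

    def test_default_simplification_to_n_over_ir(self, default_params):
        """With AT = ED × 365 and EF = 365, EC(µg/m³) = C × N / IR exactly."""
        c = 123.456
        ec_ug = exposure_concentration(c, default_params) * 1000
        assert ec_ug == pytest.approx(c * 13.2 / 14.25, rel=1e-12)

    def test_negative_content_rejected(self, default_params):
        with pytest.raises(ValueError):
            exposure_concentration(-1.0, default_params)


class TestRiskCharacterization:
    def test_ratio_and_flags(self):
        assert risk_characterization(1.44969, 8.17) == pytest.approx(0.17744, abs=1e-5)
        assert risk_characterization(2.0, 2.0) == 1.0
        row = RiskRow("x", "maximum", 1.0, 0.27962, 0.7, 0.27962 / 0.7)
        assert row.attention and not row.exceeds

    def test_nonpositive_dnel_rejected(self):
        with pytest.raises(ValueError):
            risk_characterization(1.0, 0.0)

    def test_formatting(self):
        assert format_rcr(0.177441) == "1.8 × 10^-1"
        assert format_rcr(0.39946) == "4.0 × 10^-1"
        assert format_rcr(0.0999) == "1.0 × 10^-1"
        assert format_exposure(1.4496934) == "1.44969"
        assert round_sig(0.087715) == pytest.approx(0.088)


class TestBuildRiskTable:
    def test_compound_without_dnel_absent(self, compounds, default_params):
        recs = [
            _content("A", Part.TOBACCO, "Coumarin", content=1.0),
            _content("A", Part.TOBACCO, "Menthol", content=1.0),
        ]
        rows = build_risk_table(recs, default_params, compounds)
        assert {r.compound for r in rows} == {"Menthol"}
        assert {r.stat for r in rows} == {"average", "maximum"}

    def test_empty_records_give_empty_table(self, compounds, default_params):
        assert build_risk_table([], default_params, compounds) == []

    def test_bypass_entry_point(self, compounds, default_params):
        rows = risk_rows_from_content_stats(
            [("Menthol", "average", 1565.01), ("Coumarin", "average", 1.0)],
            default_params, compounds,
        )
        assert len(rows) == 1
        assert rows[0].rcr == pytest.approx(0.17744, abs=1e-5)
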