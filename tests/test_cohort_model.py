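"""Clinical derivation layer: index formulas, cut-offs, outcomes,
exclusions and quartile binning."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irnet import cohort_model as cm


class TestIndices:
    @pytest.mark.parametrize("insulin,fbg,expected", [
        (8.1, 100.0, 2.0),          # 8.1 * 100 / 405 cancels exactly
        (10.0, 81.0, 2.0),
        (5.0, 405.0, 5.0),
    ])
    def test_homa_ir(self, insulin, fbg, expected):
        out = cm.compute_indices([insulin], [fbg], [100.0], [50.0])
        assert out["homa_ir"].iloc[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("tg,fbg,expected", [
        (2.0, 1.0, 0.0),                       # ln(1)
        (150.0, 100.0, math.log(7500.0)),      # ~8.9227
    ])
    def test_tyg(self, tg, fbg, expected):
        out = cm.compute_indices([5.0], [fbg], [tg], [50.0])
        assert out["tyg"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_tg_hdl_ratio(self):
        out = cm.compute_indices([5.0], [100.0], [100.0], [50.0])
        assert out["tg_hdl"].iloc[0] == 2.0

    @pytest.mark.parametrize("field", ["fbg", "tg", "hdl"])
    def test_nonpositive_inputs_name_the_field(self, field):
        kwargs = {"insulin": [5.0], "fbg": [100.0], "tg": [100.0], "hdl": [50.0]}
        kwargs[field] = [0.0]
        with pytest.raises(cm.DomainError, match=field):
            cm.compute_indices(**kwargs)

    def test_missing_insulin_gives_missing_homa_not_zero(self):
        out = cm.compute_indices([np.nan], [100.0], [100.0], [50.0])
        assert np.isnan(out["homa_ir"].iloc[0])
        assert out["tyg"].notna().all() and out["tg_hdl"].notna().all()

    @settings(max_examples=50, derandomize=True)
    @given(
        insulin=st.floats(0.5, 60), fbg=st.floats(60, 300),
        tg=st.floats(30, 600), hdl=st.floats(20, 120),
        bump=st.floats(0.1, 50),
    )
    def test_monotonicity(self, insulin, fbg, tg, hdl, bump):
        base = cm.compute_indices([insulin], [fbg], [tg], [hdl]).iloc[0]
        up_tg = cm.compute_indices([insulin], [fbg], [tg + bump], [hdl]).iloc[0]
        up_ins = cm.compute_indices([insulin + bump], [fbg], [tg], [hdl]).iloc[0]
        up_fbg = cm.compute_indices([insulin], [fbg + bump], [tg], [hdl]).iloc[0]
        up_hdl = cm.compute_indices([insulin], [fbg], [tg], [hdl + bump]).iloc[0]
        assert up_tg["tyg"] > base["tyg"] and up_tg["tg_hdl"] > base["tg_hdl"]
        assert up_ins["homa_ir"] > base["homa_ir"]
        assert up_fbg["tyg"] > base["tyg"] and up_fbg["homa_ir"] > base["homa_ir"]
        assert up_hdl["tg_hdl"] < base["tg_hdl"]


class TestFriedewald:
    @pytest.mark.parametrize("tchol,hdl,tg,expected", [
        (200.0, 50.0, 150.0, 120.0),
        (100.0, 100.0, 0.0, 0.0),
        (186.0, 46.0, 150.0, 110.0),
    ])
    def test_values(self, tchol, hdl, tg, expected):
        assert cm.friedewald_ldl(tchol, hdl, tg) == pytest.approx(expected)

    def test_negative_estimate_is_returned_not_rejected(self):
        assert cm.friedewald_ldl(150.0, 40.0, 600.0) == pytest.approx(-10.0)

    def test_domain_violation_raises(self):
        with pytest.raises(cm.DomainError):
            cm.friedewald_ldl(40.0, 50.0, 100.0)


class TestCategorize:
    @pytest.mark.parametrize("col,value,expected", [
        ("sbp", 119, "Normal"), ("sbp", 120, "Caution"), ("sbp", 140, "Danger"),
        ("dbp", 79, "Normal"), ("dbp", 80, "Caution"), ("dbp", 90, "Danger"),
        ("fbg", 99, "Normal"), ("fbg", 100, "Caution"),
        ("fbg", 125, "Caution"), ("fbg", 126, "Danger"),
        ("hba1c", 5.6, "Normal"), ("hba1c", 5.7, "Caution"), ("hba1c", 6.4, "Danger"),
        ("hdl", 39, "Danger"), ("hdl", 40, "Normal"),
        ("tg", 149, "Normal"), ("tg", 150, "Caution"), ("tg", 200, "Danger"),
        ("tchol", 199, "Normal"), ("tchol", 200, "Caution"), ("tchol", 240, "Danger"),
        ("ldl", 129, "Normal"), ("ldl", 130, "Caution"), ("ldl", 190, "Danger"),
    ])
    def test_threshold_boundaries(self, col, value, expected):
        out = cm.categorize_clinical(pd.DataFrame({col: [value]}))
        assert str(out[f"{col}_cat"].iloc[0]) == expected

    def test_behaviour_recodes(self):
        df = pd.DataFrame({
            "sleep_hours": [5.9, 6.0],
            "drink_freq": [0.5, 1.0],
            "smoked_ge5packs": ["no", "yes"],
            "current_smoker": ["no", "no"],
        })
        out = cm.categorize_clinical(df)
        assert list(out["sleep"].astype(str)) == ["<6h", ">=6h"]
        assert list(out["drinking"].astype(str)) == ["<1/mo", ">=1/mo"]
        assert list(out["smoking"].astype(str)) == ["no", "yes"]

    def test_guard_range_lists_record_ids(self):
        df = pd.DataFrame({"fbg": [100.0, 1e5]}, index=["a", "b"])
        with pytest.raises(cm.ValidationError, match="b"):
            cm.categorize_clinical(df)

    def test_idempotent_on_recategorization(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"fbg": rng.uniform(70, 200, 50),
                           "tg": rng.uniform(50, 400, 50)})
        once = cm.categorize_clinical(df)
        twice = cm.categorize_clinical(once)
        pd.testing.assert_frame_equal(once, twice)


def _outcome_oracle(rec):
    """Plain per-record re-statement of each outcome's criterion list."""
    def yes(col):
        return rec.get(col) == "yes"

    def ge(col, t):
        v = rec.get(col)
        return v is not None and not (isinstance(v, float) and math.isnan(v)) and v >= t

    def le(col, t):
        v = rec.get(col)
        return v is not None and not (isinstance(v, float) and math.isnan(v)) and v <= t

    dia = yes("dx_diabetes") or yes("med_diabetes") or ge("fbg", 126) or ge("hba1c", 6.5)
    dys = (yes("dx_dyslipidemia") or yes("med_dyslipidemia") or ge("tchol", 240)
           or ge("ldl", 160) or le("hdl", 40) or ge("tg", 200))
    htn = (yes("dx_hypertension") or yes("med_hypertension") or ge("sbp", 140)
           or ge("dbp", 90))
    ob = ge("bmi", 25)
    obwc = ge("wc", 90) if rec.get("sex") == "M" else ge("wc", 85)
    whtr = rec.get("wc", math.nan) / rec.get("height", math.nan)
    obwh = not math.isnan(whtr) and whtr >= 0.5
    return dia, dys, htn, ob, obwc, obwh


class TestOutcomes:
    def test_single_criterion_examples(self):
        base = {"fbg": 90.0, "hba1c": 5.4, "tchol": 180.0, "ldl": 100.0,
                "hdl": 55.0, "tg": 120.0, "sbp": 115.0, "dbp": 70.0,
                "bmi": 22.0, "wc": 80.0, "height": 170.0, "sex": "M",
                "dx_diabetes": "no", "med_diabetes": "no",
                "dx_dyslipidemia": "no", "med_dyslipidemia": "no",
                "dx_hypertension": "no", "med_hypertension": "no"}
        rows = [dict(base), dict(base, fbg=130.0), dict(base, tg=210.0)]
        out, _ = cm.define_outcomes(pd.DataFrame(rows))
        assert list(out["diabetes"].astype(str)) == ["no", "yes", "no"]
        assert list(out["dyslipidemia"].astype(str)) == ["no", "no", "yes"]
        assert (out.loc[0].astype(str) == "no").all()

    def test_matches_bruteforce_or_oracle_on_random_records(self):
        rng = np.random.default_rng(42)
        n = 10_000
        df = pd.DataFrame({
            "fbg": rng.uniform(70, 200, n), "hba1c": rng.uniform(4.5, 9, n),
            "tchol": rng.uniform(120, 320, n), "ldl": rng.uniform(40, 220, n),
            "hdl": rng.uniform(25, 90, n), "tg": rng.uniform(40, 400, n),
            "sbp": rng.uniform(95, 175, n), "dbp": rng.uniform(55, 110, n),
            "bmi": rng.uniform(17, 35, n), "wc": rng.uniform(60, 110, n),
            "height": rng.uniform(145, 195, n),
            "sex": rng.choice(["M", "F"], n),
            "dx_diabetes": rng.choice(["yes", "no"], n, p=[0.05, 0.95]),
            "med_dyslipidemia": rng.choice(["yes", "no"], n, p=[0.05, 0.95]),
            "dx_hypertension": rng.choice(["yes", "no"], n, p=[0.05, 0.95]),
        })
        out, _ = cm.define_outcomes(df)
        expected = np.array([_outcome_oracle(rec) for rec in df.to_dict("records")])
        got = np.column_stack([
            (out[c] == "yes").to_numpy()
            for c in ("diabetes", "dyslipidemia", "hypertension",
                      "obesity_bmi", "obesity_wc", "obesity_whtr")])
        assert (got == expected).all()

    def test_missing_components(self):
        df = pd.DataFrame({
            "fbg": [np.nan, np.nan, 130.0],
            "hba1c": [np.nan, 5.0, np.nan],
        })
        out, log = cm.define_outcomes(df)
        # every diabetes component missing -> missing outcome, logged
        assert pd.isna(out["diabetes"].iloc[0])
        assert str(out["diabetes"].iloc[1]) == "no"
        # a satisfied criterion wins even with other components missing
        assert str(out["diabetes"].iloc[2]) == "yes"
        assert log["diabetes"]["missing"] == 1


class TestExclusions:
    def _cohort(self):
        return pd.DataFrame({
            "age": [39, 55, 70, 50, 60],
            "hx_cvd": ["no", "no", "no", "yes", "no"],
            "hx_cancer": ["no"] * 5,
            "hx_kidney": ["no"] * 5,
            "fbg": [100.0, 110.0, 120.0, 100.0, np.nan],
        })

    def test_cascade_order_and_attribution(self):
        kept, log = cm.apply_exclusions(self._cohort())
        by = {e["criterion"]: e["removed"] for e in log}
        assert by["incomplete_survey_or_examination"] == 1   # the NaN record
        assert by["age_outside_40_69"] == 2                  # 39 and 70
        assert by["cvd_cancer_or_kidney_history"] == 1
        assert list(kept["age"]) == [55]

    def test_retained_record(self):
        kept, _ = cm.apply_exclusions(self._cohort())
        assert 55 in list(kept["age"])

    def test_empty_cohort_raises(self):
        df = pd.DataFrame({"age": [20, 25]})
        with pytest.raises(cm.EmptyCohortError):
            cm.apply_exclusions(df)

    def test_configurable_upper_bound(self):
        kept, _ = cm.apply_exclusions(self._cohort(), age_max=70)
        assert set(kept["age"]) == {55, 70}


class TestQuartiles:
    def test_rank_interpolation_cuts(self):
        g = cm.quartile_bin(list(range(1, 9)))
        assert g.cuts == pytest.approx((2.75, 4.5, 6.25))
        assert str(g.assign([5.0])[0]) == "Q3"

    def test_boundary_value_falls_low(self):
        g = cm.quartile_bin(list(range(1, 9)))
        assert str(g.assign([g.cuts[0]])[0]) == "Q1"
        assert str(g.assign([g.cuts[1]])[0]) == "Q2"

    def test_degenerate_raises(self):
        with pytest.raises(cm.DegenerateQuartileError):
            cm.quartile_bin([3.0, 3.0, 3.0, 3.0])
        with pytest.raises(cm.DegenerateQuartileError):
            cm.quartile_bin([1.0, 2.0])

    def test_groups_partition_with_balanced_sizes(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=1000)
        g = cm.quartile_bin(vals)
        counts = pd.Series(g.labels).value_counts()
        assert counts.sum() == 1000
        assert counts.max() - counts.min() <= 1  # continuous draws: no ties
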