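"""Synthetic cohort generation, aggregation, and contingency statistics."""

import numpy as np
import pandas as pd
import pytest

from annl36.cohort import (
    AGE_GROUPS,
    DISEASES,
    GENDERS,
    REGIONS,
    StratumParams,
    TwoByTwo,
    aggregate_prevalence,
    default_params,
    generate_cohort,
    load_composition,
    odds_ratio,
    round_half_up,
    two_proportion_test,
)


class TestComposition:
    def test_totals_add_up(self):
        comp = load_composition()
        assert comp["years"][2013] + comp["years"][2019] == comp["total"] == 27801
        assert sum(comp["regions"].values()) == 27801
        assert sum(comp["age_groups"].values()) == 27801
        assert sum(comp["gender"].values()) == 27801

    @pytest.mark.parametrize(
        "group, key, share",
        [
            ("years", 2013, 52.6),
            ("regions", "Belgrade", 24.3),
            ("regions", "Vojvodina", 21.3),
            ("age_groups", "55-64", 18.9),
            ("gender", "female", 52.6),
        ],
    )
    def test_published_shares(self, group, key, share):
        comp = load_composition()
        pct = 100.0 * comp[group][key] / comp["total"]
        assert round_half_up(pct, 1) == share

    def test_cell_counts_sum_to_year_totals(self):
        params = default_params()
        assert params.year_total(2013) == 14623
        assert params.year_total(2019) == 13178

    def test_cell_grid_is_complete(self):
        params = default_params()
        assert len(params.cells) == 2 * len(REGIONS) * len(AGE_GROUPS) * len(GENDERS)


class TestGenerate:
    def test_year_counts_exact(self):
        params = default_params(years=(2013,))
        cohort = generate_cohort(params, seed=3)
        assert len(cohort) == 14623
        assert (cohort["year"] == 2013).all()

    def test_same_seed_identical(self):
        params = default_params(years=(2013,))
        a = generate_cohort(params, seed=11)
        b = generate_cohort(params, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_probability_stratum_has_no_cases(self):
        cells = pd.DataFrame(
            [(2013, "Belgrade", "15-24", "male", 500)],
            columns=["year", "region", "age_group", "gender", "count"],
        )
        params = StratumParams(cells=cells, disease_probs={"Asthma": {2013: 0.0}})
        cohort = generate_cohort(params, seed=5)
        assert cohort["Asthma"].sum() == 0

    def test_invalid_probability_rejected(self):
        cells = pd.DataFrame(
            [(2013, "Belgrade", "15-24", "male", 10)],
            columns=["year", "region", "age_group", "gender", "count"],
        )
        with pytest.raises(ValueError):
            StratumParams(cells=cells, disease_probs={"Asthma": {2013: 1.5}})

    def test_parameter_recovery_across_seeds(self):
        """Sample prevalence stays within 4 binomial SEs of the planted
        probability in at least 99% of seeds (reduced stratum size)."""
        n, p = 600, 0.34
        cells = pd.DataFrame(
            [(2013, "Belgrade", "15-24", "male", n)],
            columns=["year", "region", "age_group", "gender", "count"],
        )
        params = StratumParams(cells=cells, disease_probs={"Hypertension": {2013: p}})
        se = np.sqrt(p * (1 - p) / n)
        hits = 0
        for seed in range(100):
            cohort = generate_cohort(params, seed=seed)
            phat = cohort["Hypertension"].mean()
            hits += abs(phat - p) <= 4 * se
        assert hits >= 99


class TestAggregate:
    def test_quarter_prevalence(self):
        rec = pd.DataFrame(
            {
                "year": [2013] * 4,
                "region": ["Belgrade"] * 4,
                "age_group": ["15-24"] * 4,
                "gender": ["male"] * 4,
                "Asthma": [1, 0, 0, 0],
            }
        )
        out = aggregate_prevalence(rec, by=["year"])
        assert out.loc[0, "prevalence_pct"] == 25.0
        assert out.loc[0, "n"] == 4

    def test_totals_conserved_across_strata(self):
        params = default_params(years=(2013,))
        cohort = generate_cohort(params, seed=2)
        by_region = aggregate_prevalence(cohort, by=["year", "region"])
        pooled = aggregate_prevalence(cohort, by=["year"])
        for disease in ("Hypertension", "Asthma"):
            sub = by_region[by_region["disease"] == disease]
            positives = (sub["prevalence_pct"] / 100 * sub["n"]).sum()
            pooled_row = pooled[pooled["disease"] == disease].iloc[0]
            assert positives == pytest.approx(pooled_row["prevalence_pct"] / 100 * pooled_row["n"])

    def test_planted_hypertension_recovered_at_cohort_scale(self):
        params = default_params(years=(2013,))
        cohort = generate_cohort(params, seed=1)
        out = aggregate_prevalence(cohort, by=["year"])
        phat = out[out["disease"] == "Hypertension"]["prevalence_pct"].iloc[0]
        se_pct = 100 * np.sqrt(0.34 * 0.66 / 14623)
        assert abs(phat - 34.0) <= 4 * se_pct

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            aggregate_prevalence(pd.DataFrame())


class TestOddsRatio:
    def test_null_table(self):
        or_, lo, hi, p = odds_ratio(TwoByTwo(10, 10, 10, 10))
        assert or_ == 1.0
        assert lo < 1.0 < hi
        assert p == pytest.approx(1.0)

    def test_cross_product_example(self):
        or_, lo, hi, p = odds_ratio(TwoByTwo(20, 10, 10, 20))
        assert or_ == pytest.approx(4.0)
        # Woolf CI: exp(ln 4 ± 1.95996·sqrt(0.3)); oracle-frozen endpoints
        assert lo == pytest.approx(1.3672, abs=5e-4)
        assert hi == pytest.approx(11.7026, abs=5e-4)
        assert p < 0.05

    def test_reciprocal_under_exposure_swap(self):
        a = odds_ratio(TwoByTwo(20, 10, 5, 30))[0]
        b = odds_ratio(TwoByTwo(5, 30, 20, 10))[0]
        assert a == pytest.approx(1 / b)

    def test_invariant_under_simultaneous_row_and_column_swap(self):
        a = odds_ratio(TwoByTwo(20, 10, 5, 30))
        b = odds_ratio(TwoByTwo(30, 5, 10, 20))
        assert a[0] == pytest.approx(b[0])

    def test_zero_cell_raises_with_guidance(self):
        with pytest.raises(ZeroDivisionError, match="continuity"):
            odds_ratio(TwoByTwo(0, 10, 10, 20))
        corrected = TwoByTwo(0, 10, 10, 20).corrected()
        or_, *_ = odds_ratio(corrected)
        assert or_ > 0


class TestTwoProportion:
    def test_identical_proportions(self):
        z, p = two_proportion_test(50, 100, 50, 100)
        assert z == 0.0 and p == 1.0

    def test_pooled_z_oracle_value(self):
        # frozen from direct evaluation of the pooled formula (and
        # statsmodels proportions_ztest agrees to 5 decimals)
        z, p = two_proportion_test(340, 1000, 300, 1000)
        assert z == pytest.approx(1.91741, abs=1e-5)
        assert p == pytest.approx(0.05519, abs=1e-5)

    def test_statsmodels_agreement(self):
        from statsmodels.stats.proportion import proportions_ztest

        z, p = two_proportion_test(123, 841, 170, 911)
        zo, po = proportions_ztest([123, 170], [841, 911])
        assert z == pytest.approx(float(zo))
        assert p == pytest.approx(float(po))

    def test_degenerate_pooled_proportion_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(0, 10, 0, 10)


def test_disease_list_has_seventeen_flags():
    assert len(DISEASES) == 17
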