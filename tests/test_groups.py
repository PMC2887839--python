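"""ANCOVA adjusted means, chi-square count-table tests, sample size."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agscore import (
    ancova_adjusted_means,
    chisq_count_table,
    sample_size_two_means,
    table2_fixture,
)
from agscore.scoring import CountDistribution


def _balanced_cohort_frame(offsets, n_per_group=30, noise_sd=5.0, seed=0,
                           sex_effect=0.0, age_effect=0.0):
    """Groups with identical sex/age composition, so covariate adjustment
    cannot move the group means unless the covariates carry real effects."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, off in offsets.items():
        for i in range(n_per_group):
            sex = "male" if i % 2 == 0 else "female"
            age = 50 + (i % 10) * 3
            ags = (
                60 + off
                + sex_effect * (sex == "male")
                + age_effect * (age - 64)
                + rng.normal(0, noise_sd)
            )
            rows.append({"dose_group": g, "sex": sex, "age": age, "ags": ags})
    return pd.DataFrame(rows)


def test_adjusted_means_equal_raw_means_when_covariates_balanced():
    """With identical covariate composition in every group the adjusted
    means reduce to the raw group means exactly."""
    df = _balanced_cohort_frame({"low": -10, "medium": 0, "high": 10}, seed=3)
    res = ancova_adjusted_means(df)
    raw = df.groupby("dose_group")["ags"].mean()
    for g in res.groups:
        assert res.means[g] == pytest.approx(raw[g], abs=1e-9)


def test_ancova_recovers_known_group_offset():
    """Parameter recovery: +20 AGS in high vs low with additive sex/age
    effects; the contrast estimate lands within 2 SE of truth."""
    df = _balanced_cohort_frame(
        {"low": 0, "high": 20}, n_per_group=50, seed=11, sex_effect=4.0, age_effect=0.3
    )
    res = ancova_adjusted_means(df)
    c = res.contrasts[("low", "high")]
    assert abs(c["estimate"] - 20.0) < 2 * c["se"]
    assert c["p_bonferroni"] == pytest.approx(min(1.0, 1 * c["p_unadjusted"]))


def test_bonferroni_multiplies_by_number_of_pairs():
    df = _balanced_cohort_frame({"low": 0, "medium": 0, "high": 0}, seed=7)
    res = ancova_adjusted_means(df)
    assert len(res.contrasts) == 3
    for c in res.contrasts.values():
        assert c["p_bonferroni"] == pytest.approx(min(1.0, 3 * c["p_unadjusted"]))
        assert c["p_bonferroni"] >= c["p_unadjusted"]


def test_adjusted_means_invariant_to_affine_covariate_rescaling():
    df = _balanced_cohort_frame({"low": -5, "high": 5}, seed=19, age_effect=0.4)
    res1 = ancova_adjusted_means(df)
    df2 = df.assign(age=(df["age"] - 64.0) / 10.0)
    res2 = ancova_adjusted_means(df2)
    for g in res1.groups:
        assert res1.means[g] == pytest.approx(res2.means[g], abs=1e-8)


def test_singular_design_is_named():
    df = _balanced_cohort_frame({"low": 0, "high": 10}, seed=5)
    df["age"] = df["dose_group"].map({"low": 50.0, "high": 70.0})  # confounded
    with pytest.raises(ValueError, match="singular"):
        ancova_adjusted_means(df)


def test_ancova_needs_two_groups():
    df = _balanced_cohort_frame({"low": 0}, seed=5)
    with pytest.raises(ValueError, match="two dose groups"):
        ancova_adjusted_means(df)


# ---------------------------------------------------------------- chi-square


def _random_dist(rng, rows=6, cols=3, lam=8.0):
    counts = rng.poisson(lam, size=(rows, cols))
    counts[0, :] += 1  # keep at least one non-zero row
    return CountDistribution(category="normal", groups=("low", "medium", "high")[:cols],
                             counts=counts)


@pytest.mark.parametrize("seed", range(8))
def test_pearson_statistic_matches_direct_formula(seed):
    """Brute-force oracle: sum (O-E)^2 / E over the retained table."""
    rng = np.random.default_rng(seed)
    dist = _random_dist(rng)
    res = chisq_count_table(dist)
    table = dist.counts[dist.counts.sum(axis=1) > 0].astype(float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    direct = ((table - expected) ** 2 / expected).sum()
    assert res.statistic == pytest.approx(direct, abs=1e-10)
    assert res.df == (table.shape[0] - 1) * (table.shape[1] - 1)
    assert res.p_value == pytest.approx(stats.chi2.sf(direct, res.df), abs=1e-12)


def test_proportional_columns_give_zero_statistic():
    base = np.array([4, 8, 2, 6, 0, 1])
    dist = CountDistribution(
        category="slow",
        groups=("low", "medium", "high"),
        counts=np.column_stack([base, 2 * base, 5 * base]),
    )
    res = chisq_count_table(dist)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chisq_symmetric_under_group_permutation(rng):
    dist = _random_dist(rng)
    permuted = CountDistribution(
        category=dist.category,
        groups=(dist.groups[2], dist.groups[0], dist.groups[1]),
        counts=dist.counts[:, [2, 0, 1]],
    )
    assert chisq_count_table(dist).statistic == pytest.approx(
        chisq_count_table(permuted).statistic
    )


def test_all_zero_rows_dropped_and_flagged():
    counts = np.array([[20, 30, 10], [5, 8, 3], [0, 0, 0], [0, 0, 0], [0, 0, 0], [0, 0, 0]])
    dist = CountDistribution(category="very_slow", groups=("low", "medium", "high"), counts=counts)
    res = chisq_count_table(dist)
    assert res.n_rows_used == 2
    assert res.df == 2
    assert res.n_expected_below_5 >= 1


def test_trend_test_detects_ordered_association():
    """A monotone shift across groups: the 1-df trend test fires while
    being insensitive to sparse outer cells."""
    counts = np.array([[20, 10, 2], [10, 10, 4], [5, 10, 6], [2, 10, 8], [1, 5, 8], [0, 2, 6]])
    dist = CountDistribution(category="normal", groups=("low", "medium", "high"), counts=counts)
    res = chisq_count_table(dist, method="trend")
    assert res.df == 1
    assert res.p_value < 1e-6


def test_published_count_tables_significance_pattern():
    """On the packaged tables the ordinal trend test separates the
    very-slow and normal categories from the slow one, matching the
    published pattern of significance."""
    dists, _ = table2_fixture()
    p_trend = {c: chisq_count_table(d, "trend").p_value for c, d in dists.items()}
    assert p_trend["very_slow"] < 0.05
    assert p_trend["normal"] < 0.05
    assert p_trend["slow"] > 0.05


# ---------------------------------------------------------------- sample size


def test_sample_size_unit_effect():
    """Closed form: d = 1, two-sided alpha 0.05, power 0.80 -> n = 16."""
    res = sample_size_two_means(10, 11, 1, 1, alpha=0.05, power=0.80, sided=2)
    assert res.n_per_group == 16
    assert res.n_unrounded == pytest.approx(2 * (1.959964 + 0.841621) ** 2, rel=1e-5)


def test_doubling_effect_quarters_n():
    a = sample_size_two_means(0, 1, 2, 2, power=0.9)
    b = sample_size_two_means(0, 2, 2, 2, power=0.9)
    assert a.n_unrounded == pytest.approx(4 * b.n_unrounded)


def test_zero_effect_is_error():
    with pytest.raises(ValueError, match="infinite"):
        sample_size_two_means(5, 5, 1, 1)


def test_published_scenario_variants():
    """Group means 84.1/62.2 with SDs rebuilt from SEMs (3.4*sqrt(18),
    4.8*sqrt(34)), power 95%: the default two-sided pooled-SD form gives 27
    per group; the one-sided averaged-SD variant gives 21."""
    sd_high, sd_low = 3.4 * math.sqrt(18), 4.8 * math.sqrt(34)
    default = sample_size_two_means(84.1, 62.2, sd_high, sd_low, power=0.95)
    assert default.n_per_group == 27
    variant = sample_size_two_means(
        84.1, 62.2, sd_high, sd_low, power=0.95, sided=1, sd_method="averaged"
    )
    assert variant.n_per_group == 21
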