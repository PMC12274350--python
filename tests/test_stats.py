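"""Statistical routines against independent numerical oracles."""
import math

import numpy as np
import pytest
from scipy import integrate
from scipy import stats as sps

from dlbtext.stats import (chi_squared_test, cohort_frame,
                           counts_from_percentage, derived_percentage,
                           pooled_percentage, table_one, table_two,
                           welch_t_test)


# --- independent oracles ----------------------------------------------------

def t_tail_by_quadrature(stat: float, df: float) -> float:
    """Two-sided t p-value via direct integration of the density."""
    log_c = (math.lgamma((df + 1) / 2) - math.lgamma(df / 2)
             - 0.5 * math.log(df * math.pi))

    def pdf(x):
        return math.exp(log_c - (df + 1) / 2 * math.log1p(x * x / df))

    tail, _ = integrate.quad(pdf, abs(stat), np.inf)
    return 2 * tail


def chi2_tail_by_quadrature(stat: float, df: float) -> float:
    log_c = -(df / 2) * math.log(2) - math.lgamma(df / 2)

    def pdf(x):
        return math.exp(log_c + (df / 2 - 1) * math.log(x) - x / 2)

    tail, _ = integrate.quad(pdf, stat, np.inf)
    return tail


def permutation_midp(table) -> float:
    """Exact permutation null of the Pearson statistic for a 2x2 table.

    Enumerates the hypergeometric distribution of the (1,1) cell under
    label permutation; ties at the observed statistic counted with
    weight 1/2 (mid-p), the standard convention when comparing a
    discrete permutation distribution with a continuous reference.
    """
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    total = r1 + r2

    def stat(x):
        t = np.array([[x, r1 - x], [c1 - x, r2 - c1 + x]], dtype=float)
        expected = np.outer(t.sum(1), t.sum(0)) / total
        return ((t - expected) ** 2 / expected).sum()

    xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = sps.hypergeom.pmf(xs, total, r1, c1)
    values = np.array([stat(x) for x in xs])
    observed = stat(a)
    return float(pmf[values > observed + 1e-9].sum()
                 + 0.5 * pmf[np.isclose(values, observed)].sum())


# --- Welch t ----------------------------------------------------------------

def test_welch_null_case():
    res = welch_t_test(10.0, 2.0, 50, 10.0, 2.0, 50)
    assert res.statistic == 0 and res.p_value == pytest.approx(1.0)


def test_welch_on_referral_age_summaries_is_highly_significant():
    res = welch_t_test(76.9, 10.2, 617, 80.6, 8.5, 13712)
    assert res.p_value < 0.001
    assert res.statistic < 0  # DLB younger


@pytest.mark.parametrize("args", [
    (76.9, 10.2, 617, 80.6, 8.5, 13712),
    (2.3, 0.5, 2563, 2.8, 0.7, 513),
    (5.0, 1.0, 10, 5.5, 2.0, 12),
    (0.0, 1.0, 3, 0.2, 0.5, 4),
])
def test_welch_p_matches_quadrature_oracle(args):
    res = welch_t_test(*args)
    assert res.p_value == pytest.approx(
        t_tail_by_quadrature(res.statistic, res.df), abs=1e-8)


def test_welch_undefined_inputs_flagged():
    assert welch_t_test(1.0, 1.0, 1, 2.0, 1.0, 10).undefined
    assert welch_t_test(3.0, 0.0, 10, 3.0, 0.0, 10).undefined
    with pytest.raises(ValueError):
        welch_t_test(1.0, -0.5, 10, 2.0, 1.0, 10)


# --- chi-squared ------------------------------------------------------------

def test_chi2_independent_table():
    res = chi_squared_test([[10, 10], [10, 10]])
    assert res.statistic == 0 and res.p_value == pytest.approx(1.0)


def test_chi2_on_reconstructed_vh_counts():
    res = chi_squared_test([[513, 104], [2290, 11422]])
    assert res.p_value < 0.001


def test_chi2_zero_margin_names_offender():
    with pytest.raises(ValueError, match="column 1"):
        chi_squared_test([[5, 0], [7, 0]])
    with pytest.raises(ValueError, match="row 0"):
        chi_squared_test([[0, 0], [7, 3]])


@pytest.mark.parametrize("table", [
    [[10, 5], [5, 10]], [[8, 2], [3, 7]], [[12, 8], [7, 13]],
])
def test_chi2_statistic_reduces_to_closed_form_on_2x2(table):
    (a, b), (c, d) = table
    n = a + b + c + d
    closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    res = chi_squared_test(table)
    assert res.statistic == pytest.approx(closed, rel=1e-12)
    assert res.df == 1


@pytest.mark.parametrize("table", [
    [[513, 104], [2290, 11422]],
    [[10, 5], [5, 10]],
    [[30, 70], [45, 55]],
])
def test_chi2_p_matches_quadrature_oracle(table):
    res = chi_squared_test(table)
    assert res.p_value == pytest.approx(
        chi2_tail_by_quadrature(res.statistic, res.df), abs=1e-8)


def test_chi2_p_matches_permutation_null_in_asymptotic_regime():
    """Exact permutation mid-p agrees once cell counts are moderate."""
    for table in ([[55, 45], [45, 55]], [[30, 70], [45, 55]]):
        res = chi_squared_test(table)
        assert res.p_value == pytest.approx(permutation_midp(table), abs=0.01)


# --- percentage arithmetic --------------------------------------------------

@pytest.mark.parametrize("num,den,expected", [
    (617, 14329, 4.3),
    (13712, 14329, 95.7),
    (4546, 13712, 33.2),
    (2563, 13712, 18.7),
    (0, 100, 0.0),
    (1, 16, 6.3),  # 6.25 rounds half-up
])
def test_derived_percentage(num, den, expected):
    assert derived_percentage(num, den) == expected


def test_derived_percentage_errors():
    with pytest.raises(ValueError):
        derived_percentage(1, 0)
    with pytest.raises(ValueError):
        derived_percentage(5, 4)


def test_counts_from_percentage_round_trip():
    assert counts_from_percentage(83.1, 617) == 513
    assert counts_from_percentage(16.7, 13712) == 2290


# --- tables -----------------------------------------------------------------

def _frame(corpus):
    from conftest import patients_frame
    from dlbtext.aggregate import build_profiles
    from dlbtext.extract import extract_corpus

    mentions = extract_corpus(corpus.documents)
    profiles = build_profiles(mentions, patients_frame(corpus))
    return cohort_frame(patients_frame(corpus), profiles)


def test_full_cohort_percentage_is_pooled_group_percentage(small_corpus):
    df = _frame(small_corpus)
    dlb, ad = df[df["diagnosis"] == "DLB"], df[df["diagnosis"] == "AD"]
    for var in ("female", "vh", "fluct", "parkinsonism", "rbd"):
        pooled = pooled_percentage(
            [100 * dlb[var].mean(), 100 * ad[var].mean()],
            [len(dlb), len(ad)])
        assert pooled == derived_percentage(int(df[var].sum()), len(df))


def test_symptom_count_rows_sum_to_one(small_corpus):
    df = _frame(small_corpus)
    table, _ = table_one(df)
    for col in table.columns[:3]:
        rows = [float(table.loc[name, col].rstrip("%"))
                for name in ("No core symptom", "1 core symptom",
                             "2 core symptoms", "3 core symptoms",
                             "4 core symptoms")]
        assert sum(rows) == pytest.approx(100.0, abs=0.2)


def test_table_two_strata_partition(small_corpus):
    df = _frame(small_corpus)
    table, stats = table_two(df)
    ns = [int(col.split("n = ")[1].rstrip(")"))
          for col in table.columns[:3]]
    dlb_two_plus = ((df["diagnosis"] == "DLB") & (df["core_count"] >= 2)).sum()
    assert sum(ns) == (df["diagnosis"] == "AD").sum() + dlb_two_plus
    assert "core_count" in stats


def test_empty_group_flagged_not_crashing():
    from dlbtext.stats import summarize_groups
    df = _frame_small_all_ad()
    groups = [("AD", df), ("DLB", df.iloc[0:0])]
    summaries, comparisons = summarize_groups(df, groups, [("AD", "DLB")])
    assert summaries[1].n == 0
    assert all(res.undefined for res in
               (comparisons["age_referral"]["AD vs DLB"],
                comparisons["vh"]["AD vs DLB"]))


def _frame_small_all_ad():
    from dlbtext.config import CorpusConfig
    from dlbtext.corpus import generate_corpus

    corpus = generate_corpus(CorpusConfig(n_ad=12, n_dlb=0), seed=3)
    return _frame(corpus)


def test_every_core_symptom_significant_at_study_scale_over_seeds():
    """Group contrasts planted at published prevalences stay below p=0.001."""
    from dlbtext.aggregate import profiles_from_truth
    from dlbtext.config import PrevalenceConfig
    from dlbtext.corpus import generate_cohort

    params = PrevalenceConfig.default()
    for seed in range(20):
        cohort = generate_cohort(13712, 617, params, seed=seed)
        profiles = profiles_from_truth(cohort)
        dlb = profiles[profiles["diagnosis"] == "DLB"]
        ad = profiles[profiles["diagnosis"] == "AD"]
        for var in ("vh", "fluct", "parkinsonism", "rbd"):
            res = chi_squared_test(
                [[int(dlb[var].sum()), len(dlb) - int(dlb[var].sum())],
                 [int(ad[var].sum()), len(ad) - int(ad[var].sum())]])
            assert res.p_value < 0.001, (seed, var)
        ages_dlb = [rec.age_referral for rec, _ in cohort if
                    rec.diagnosis.value == "DLB"]
        ages_ad = [rec.age_referral for rec, _ in cohort if
                   rec.diagnosis.value == "AD"]
        res = welch_t_test(float(np.mean(ages_dlb)),
                           float(np.std(ages_dlb, ddof=1)), len(ages_dlb),
                           float(np.mean(ages_ad)),
                           float(np.std(ages_ad, ddof=1)), len(ages_ad))
        assert res.p_value < 0.001, seed
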