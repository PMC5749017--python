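"""Rates, rate ratios with Katz CIs, standardized differences, Cohen's
kappa (cross-checked against scikit-learn), and the assembled tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

import babyfeed as bf
from babyfeed.errors import BabyfeedError
from babyfeed.extract import round_half_away
from babyfeed.stats import rate_table_frame


# ----------------------------------------------------------------- rate


def test_rate_printed_flow_fractions():
    assert round_half_away(bf.rate(1044, 8815), 1) == 11.8
    assert round_half_away(bf.rate(7051, 8815), 1) == 80.0
    assert round_half_away(bf.rate(4955, 7051), 1) == 70.3


def test_rate_bounds():
    assert bf.rate(0, 10) == 0.0
    assert bf.rate(10, 10) == 100.0
    with pytest.raises(BabyfeedError):
        bf.rate(1, 0)


# ------------------------------------------------------------ rate ratio


def test_rate_ratio_urban_six_months():
    rr, lo, hi = bf.rate_ratio(0.267, 5464, 0.198, 1719)
    assert round_half_away(rr, 2) == 1.35
    assert abs(lo - 1.22) < 0.02 and abs(hi - 1.50) < 0.02


def test_rate_ratio_oldest_vs_youngest_six_months():
    rr, lo, hi = bf.rate_ratio(0.313, 252, 0.128, 195)
    assert round_half_away(rr, 2) == 2.45
    assert abs(lo - 1.62) < 0.02 and abs(hi - 3.68) < 0.02


@given(
    p=st.floats(0.05, 0.95),
    n=st.integers(20, 5000),
)
def test_rate_ratio_identity_and_ci_covers_one(p, n):
    rr, lo, hi = bf.rate_ratio(p, n, p, n)
    assert rr == 1.0
    assert lo <= 1.0 <= hi


def test_zero_numerator_flags_ci_non_computable():
    rr, lo, hi = bf.rate_ratio(0.0, 100, 0.2, 100)
    assert rr == 0.0
    assert np.isnan(lo) and np.isnan(hi)
    with pytest.raises(BabyfeedError):
        bf.rate_ratio(0.1, 100, 0.0, 100)


# -------------------------------------------------- standardized difference


def test_std_diff_rural_residence():
    assert round_half_away(bf.standardized_difference(0.105, 0.244), 1) == -0.4


def test_std_diff_maternal_age_continuous():
    d = bf.standardized_difference((29.9, 5.5), (30.2, 5.3))
    assert abs(d - (-0.0555)) < 0.001


def test_std_diff_identical_summaries_zero():
    assert bf.standardized_difference(0.3, 0.3) == 0.0
    assert bf.standardized_difference((10.0, 2.0), (10.0, 2.0)) == 0.0


def test_std_diff_zero_variance_unequal_means_errors():
    with pytest.raises(BabyfeedError):
        bf.standardized_difference((1.0, 0.0), (2.0, 0.0))


# ----------------------------------------------------------------- kappa


def test_kappa_identical_vectors():
    assert bf.cohens_kappa(["a", "b", "a"], ["a", "b", "a"]) == 1.0


def test_kappa_symmetric_two_by_two_table():
    a = ["x"] * 50 + ["y"] * 50
    b = ["x"] * 40 + ["y"] * 10 + ["x"] * 10 + ["y"] * 40
    assert bf.cohens_kappa(a, b) == pytest.approx(0.6)


def test_kappa_chance_level_is_zero():
    a = ["x", "x", "y", "y"]
    b = ["x", "y", "x", "y"]
    assert bf.cohens_kappa(a, b) == pytest.approx(0.0)


def test_kappa_degenerate_agreement_errors():
    with pytest.raises(BabyfeedError):
        bf.cohens_kappa(["a", "a"], ["a", "a"])
    with pytest.raises(BabyfeedError):
        bf.cohens_kappa([], [])


@given(
    labels=st.lists(
        st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
        min_size=5,
        max_size=60,
    )
)
def test_kappa_bounded_and_matches_sklearn(labels):
    a = [x for x, _ in labels]
    b = [y for _, y in labels]
    try:
        k = bf.cohens_kappa(a, b)
    except BabyfeedError:
        return  # degenerate marginals
    assert -1.0 - 1e-12 <= k <= 1.0 + 1e-12
    assert k == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


# ------------------------------------------------------- stratified tables


def test_stratified_table_partitions_denominator(study_run):
    st_df = bf.statuses_frame(study_run.statuses)
    reg_df = bf.registry_frame(study_run.cohort.records)
    rows = bf.stratified_rr_table(st_df, reg_df, "income_quintile", 182)
    total = sum(r.n for r in rows)
    overall = bf.ebf_rates(study_run.statuses)[182][1]
    assert total == overall
    (ref,) = [r for r in rows if r.is_referent]
    assert ref.rr == 1.0
    for r in rows:
        if np.isfinite(r.rr) and np.isfinite(r.ci_low):
            assert r.ci_low <= r.rr <= r.ci_high or r.is_referent


def test_two_level_covariate_rr_is_ratio_of_rates(study_run):
    st_df = bf.statuses_frame(study_run.statuses)
    reg_df = bf.registry_frame(study_run.cohort.records)
    rows = {r.stratum_label: r for r in
            bf.stratified_rr_table(st_df, reg_df, "urban", 182)}
    assert rows["Yes"].rr == pytest.approx(rows["Yes"].rate / rows["No"].rate)


def test_lowest_referent_convention_makes_all_rr_at_least_one(study_run):
    st_df = bf.statuses_frame(study_run.statuses)
    reg_df = bf.registry_frame(study_run.cohort.records)
    rows = bf.stratified_rr_table(
        st_df, reg_df, "maternal_age_band", 182, referent="lowest"
    )
    for r in rows:
        if r.stratum_label != "Unknown" and np.isfinite(r.rr):
            assert r.rr >= 1.0 - 1e-9


def test_urban_gradient_matches_generator_design(study_run):
    """Urban residents breastfeed exclusively for longer in the generator's
    covariate model, so the urban stratum should show RR > 1 vs rural."""
    st_df = bf.statuses_frame(study_run.statuses)
    reg_df = bf.registry_frame(study_run.cohort.records)
    rows = {r.stratum_label: r for r in
            bf.stratified_rr_table(st_df, reg_df, "urban", 182)}
    assert rows["Yes"].rr > 1.0


def test_rate_table_frame_rounding(study_run):
    st_df = bf.statuses_frame(study_run.statuses)
    reg_df = bf.registry_frame(study_run.cohort.records)
    df = rate_table_frame(bf.stratified_rr_table(st_df, reg_df, "urban", 60))
    assert list(df.columns) == [
        "stratum", "n", "rate_pct", "rr", "ci_low", "ci_high", "is_referent",
    ]
    assert df["rr"].dropna().apply(lambda x: x == round(x, 2)).all()


# ----------------------------------------------------------- balance table


def test_balance_identical_registries_all_zero(study_run):
    reg_df = bf.registry_frame(study_run.cohort.records)
    rows = bf.balance_table(reg_df, reg_df)
    assert rows
    assert all(r.std_diff == 0.0 for r in rows)


def test_balance_detects_urbanicity_shift():
    a = bf.registry_frame(
        bf.generate_birth_registry(bf.SimConfig(n_infants=3000, seed=1, urban_prob=0.895))
    )
    b = bf.registry_frame(
        bf.generate_birth_registry(bf.SimConfig(n_infants=3000, seed=2, urban_prob=0.756))
    )
    rows = {r.characteristic: r for r in bf.balance_table(a, b)}
    # rural share 10.5% vs 24.4% gives a standardized difference near -0.4
    assert rows["Rural residence"].std_diff < -0.25


def test_balance_schema_mismatch_errors(study_run):
    reg_df = bf.registry_frame(study_run.cohort.records)
    with pytest.raises(BabyfeedError):
        bf.balance_table(reg_df, reg_df.drop(columns=["urban"]))
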