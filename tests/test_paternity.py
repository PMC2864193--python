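"""Paternity statistics: P2, the angular transform, filters, ANOVA and
baseline comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cspmap import paternity as pat
from cspmap import synthetic as syn


# ---------------------------------------------------------------------------
# P2 and the angular transform
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("wt, eb, expected", [(30, 10, 0.75), (0, 25, 0.0),
                                              (25, 0, 1.0)])
def test_compute_p2(wt, eb, expected):
    assert pat.compute_p2(wt, eb) == pytest.approx(expected)


def test_compute_p2_undefined_without_progeny():
    with pytest.raises(pat.UndefinedP2Error):
        pat.compute_p2(0, 0)


@pytest.mark.parametrize("p, expected", [(0.0, 0.0), (0.5, math.pi / 4),
                                         (1.0, math.pi / 2)])
def test_angular_transform_fixed_points(p, expected):
    assert pat.angular_transform(p) == pytest.approx(expected, abs=1e-12)


@given(st.floats(0, 1), st.floats(0, 1))
def test_angular_transform_monotone_and_bounded(p, q):
    tp, tq = pat.angular_transform(p), pat.angular_transform(q)
    assert 0.0 <= tp <= math.pi / 2
    if p < q:
        assert tp < tq


def test_angular_transform_rejects_outside_unit_interval():
    for bad in (-0.1, 1.1):
        with pytest.raises(ValueError):
            pat.angular_transform(bad)


# ---------------------------------------------------------------------------
# Trial filters
# ---------------------------------------------------------------------------

def test_filter_full_drops_failed_matings(trial_frame):
    kept = pat.filter_trials(trial_frame, "full")
    assert set(kept["female_id"]) == {"F1", "F4", "F5", "F6"}


def test_filter_restricted_applies_fecundity_and_line_thresholds(trial_frame):
    kept = pat.filter_trials(trial_frame, "restricted", min_males_per_line=2)
    # F5 (fecundity 19) is dropped; line A retains only F1 -> dropped whole
    assert set(kept["female_id"]) == {"F4", "F6"}


def test_filter_restricted_is_subset_of_full():
    trials, _ = syn.gen_mating_trials(syn.MatingSimConfig(
        n_lines=8, females_per_line=15, n_baseline_lines=2, seed=7))
    full = pat.filter_trials(trials, "full")
    restricted = pat.filter_trials(trials, "restricted")
    assert set(restricted["female_id"]) <= set(full["female_id"])


def test_filter_unknown_policy(trial_frame):
    with pytest.raises(ValueError):
        pat.filter_trials(trial_frame, "everything")


# ---------------------------------------------------------------------------
# ANOVA against an explicit projection-matrix oracle
# ---------------------------------------------------------------------------

def _projection(X):
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def anova_oracle(df, response="tp2", covariate="fecundity",
                 factors=("line_id", "block"), interaction=True):
    """Sequential sums of squares by explicit hat-matrix differences."""
    y = df[response].to_numpy(float)
    n = len(df)
    blocks = pat._term_blocks(df, covariate, list(factors), interaction)
    X = np.ones((n, 1))
    out = {}
    P_prev = _projection(X)
    for name, cols in blocks:
        X = np.hstack([X, cols])
        P = _projection(X)
        out[name] = {"ss": float(y @ (P - P_prev) @ y),
                     "df": int(round(np.trace(P - P_prev)))}
        P_prev = P
    out["residual"] = {"ss": float(y @ (np.eye(n) - P_prev) @ y),
                       "df": int(round(np.trace(np.eye(n) - P_prev)))}
    return out


def random_design(rng, n_lines=3, n_blocks=2, n_rows=24):
    df = pd.DataFrame({
        "line_id": rng.choice([f"L{i}" for i in range(n_lines)], n_rows),
        "block": rng.choice([f"B{i}" for i in range(n_blocks)], n_rows),
        "fecundity": rng.normal(40, 8, n_rows),
        "tp2": rng.normal(0.8, 0.3, n_rows),
    })
    # guarantee at least two lines present
    df.loc[0, "line_id"], df.loc[1, "line_id"] = "L0", "L1"
    return df


def test_ancova_matches_projection_oracle(rng):
    for _ in range(10):
        df = random_design(rng, n_rows=int(rng.integers(15, 30)))
        table = pat.fit_ancova(df)
        oracle = anova_oracle(df)
        for term, expected in oracle.items():
            assert table.table.loc[term, "ss"] == pytest.approx(
                expected["ss"], abs=1e-8)
            assert table.table.loc[term, "df"] == expected["df"]


def test_ancova_sequential_ss_conserve_total(rng):
    df = random_design(rng)
    table = pat.fit_ancova(df)
    assert table.table["ss"].sum() == pytest.approx(table.total_ss, rel=1e-10)


def test_ancova_constant_response_flagged(rng):
    df = random_design(rng)
    df["tp2"] = 1.0
    table = pat.fit_ancova(df)
    assert np.allclose(table.table["ss"].drop("residual"), 0.0, atol=1e-16)
    assert np.isnan(table.f_stat("line_id"))


def test_ancova_detects_planted_line_effect(rng):
    df = random_design(rng, n_rows=60)
    df.loc[df["line_id"] == "L0", "tp2"] += 2.0
    assert pat.fit_ancova(df).p_value("line_id") < 1e-3


def test_one_way_anova_textbook_example():
    # three groups, hand-computed decomposition
    values = [4, 5, 6, 7, 8, 9, 10, 11, 12]
    groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    table = pat.one_way_anova(values, groups)
    assert table["g"]["ss"] == pytest.approx(54.0)
    assert table["residual"]["ss"] == pytest.approx(6.0)
    assert table["g"]["df"] == 2 and table["residual"]["df"] == 6
    assert table.f_stat("g") == pytest.approx(27.0)


def test_one_way_anova_zero_between_groups_variation():
    table = pat.one_way_anova([1.0, 2.0, 1.0, 2.0], ["a", "a", "b", "b"])
    assert table.f_stat("g") == pytest.approx(0.0, abs=1e-12)


def test_one_way_anova_single_group_rejected():
    with pytest.raises(ValueError):
        pat.one_way_anova([1, 2, 3], ["a", "a", "a"])


# ---------------------------------------------------------------------------
# Correlation and baseline tests
# ---------------------------------------------------------------------------

def test_pearson_perfect_and_sign(rng):
    x = rng.normal(size=50)
    assert pat.pearson_correlation(x, x).r == pytest.approx(1.0)
    noisy = -x + rng.normal(0, 0.2, 50)
    assert pat.pearson_correlation(x, noisy).r < 0


def test_pearson_null_is_uniform(rng):
    pvals = [pat.pearson_correlation(rng.normal(size=40),
                                     rng.normal(size=40)).p_value
             for _ in range(200)]
    assert stats.kstest(pvals, "uniform").pvalue > 1e-3


def test_pearson_zero_variance_rejected(rng):
    with pytest.raises(ValueError):
        pat.pearson_correlation([1.0] * 10, list(rng.normal(size=10)))


def test_baseline_identical_samples_flagged():
    sample = [0.1, 0.2, 0.15, 0.12]
    res = pat.baseline_comparison(sample, sample)
    assert res.breakdown_flag


def test_baseline_strong_line_not_flagged(rng):
    line = rng.normal(0.8, 0.1, 30)
    base = rng.normal(0.05, 0.1, 30)
    res = pat.baseline_comparison(line, base)
    assert not res.breakdown_flag
    # independent Welch-t computation
    se = math.sqrt(line.var(ddof=1) / 30 + base.var(ddof=1) / 30)
    assert res.t_stat == pytest.approx((line.mean() - base.mean()) / se)


def test_baseline_ci_upper_bound(rng):
    base = rng.normal(0.05, 0.1, 30)
    res = pat.baseline_comparison(rng.normal(0.5, 0.1, 20), base)
    tcrit = stats.t.ppf(0.975, 29)
    expected = base.mean() + tcrit * base.std(ddof=1) / math.sqrt(30)
    assert res.baseline_ci_upper == pytest.approx(expected)


def test_pipeline_recovery_of_planted_baseline_lines():
    """Baseline-equal lines are flagged with high sensitivity on generated
    trials at the default design."""
    config = syn.MatingSimConfig(seed=11)
    trials, truth = syn.gen_mating_trials(config)
    records = pat.filter_trials(pat.add_paternity_records(trials), "full")
    base = records[records["line_id"] == truth["baseline_sample_id"]]
    lines = records[records["line_id"] != truth["baseline_sample_id"]]
    flags = pat.flag_breakdown_lines(lines, base)
    flagged = set(flags.loc[flags["breakdown_flag"], "line_id"])
    planted = set(truth["baseline_line_ids"])
    sensitivity = len(flagged & planted) / len(planted)
    assert sensitivity >= 0.95
    # conspecific-like lines are almost never flagged
    assert len(flagged - planted) <= 2
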