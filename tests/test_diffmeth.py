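"""Differential methylation statistics and descriptive methylome profiles.

The Welch test, BH adjustment and the full per-probe pipeline are checked
against independent direct-formula oracles, then the descriptive profiles
against planted simulator structure.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metx.diffmeth import (
    bh_adjust,
    bin_census,
    context_stratify,
    diff_methylation,
    distribution_summary,
    dm_probes,
    region_mean_profile,
    welch_t_test,
    welch_t_test_rows,
)


def welch_oracle(a, b):
    """Textbook Welch statistic with Welch-Satterthwaite df, written
    independently of the implementation path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def bh_oracle(p):
    """Hand application of the step-up rule: sort ascending,
    adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1, in input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def test_welch_matches_direct_formula():
    a, b = [1.1, 2.0, 2.9], [4.8, 6.1, 7.0]
    t, p = welch_t_test(a, b)
    t0, p0 = welch_oracle(a, b)
    assert t == pytest.approx(t0, abs=1e-9)
    assert p == pytest.approx(p0, abs=1e-9)


def test_welch_random_instances_match_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        a = rng.normal(size=rng.integers(2, 9))
        b = rng.normal(1.0, 2.0, size=rng.integers(2, 9))
        t, p = welch_t_test(a, b)
        t0, p0 = welch_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-9)
        assert p == pytest.approx(p0, abs=1e-9)


def test_welch_identical_groups():
    assert welch_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)


def test_welch_degenerate_zero_variance():
    assert welch_t_test([0, 0, 0], [0, 0, 0]) == (0.0, 1.0)
    t, p = welch_t_test([0, 0, 0], [5, 5, 5])
    assert np.isinf(t) and t < 0 and p == 0.0


def test_welch_too_small_group_rejected():
    with pytest.raises(ValueError):
        welch_t_test([1.0], [1, 2, 3])


def test_vectorized_welch_agrees_with_scalar():
    rng = np.random.default_rng(4)
    A = rng.normal(size=(20, 4))
    B = rng.normal(size=(20, 5))
    t, p = welch_t_test_rows(A, B)
    for i in range(20):
        ti, pi = welch_t_test(A[i], B[i])
        assert t[i] == pytest.approx(ti, abs=1e-12)
        assert p[i] == pytest.approx(pi, abs=1e-12)


def test_bh_hand_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_identity_cases():
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert bh_adjust([0.3]).tolist() == [0.3]


def test_bh_random_instances_match_step_up_oracle():
    rng = np.random.default_rng(5)
    for _ in range(30):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
@settings(derandomize=True, max_examples=60)
def test_bh_dominates_input_and_caps_at_one(pvals):
    adj = bh_adjust(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-15)
    assert np.all(adj <= 1.0)
    # order-preserving on the sorted sequence
    order = np.argsort(pvals)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_diff_methylation_detects_planted_shift():
    rng = np.random.default_rng(6)
    n = 400
    base = rng.uniform(0.3, 0.6, n)
    shifted = np.zeros(n, bool)
    shifted[:40] = True
    mean_b = np.where(shifted, base + 0.3, base)
    reps = 6  # per-probe q<0.05 detection needs more than triplicates
    A = rng.beta(base[:, None] * 100, (1 - base[:, None]) * 100, (n, reps))
    B = rng.beta(mean_b[:, None] * 100, (1 - mean_b[:, None]) * 100, (n, reps))
    a_cols = [f"a{i}" for i in range(reps)]
    b_cols = [f"b{i}" for i in range(reps)]
    betas = pd.DataFrame(np.hstack([A, B]),
                         index=[f"cg{i}" for i in range(n)],
                         columns=a_cols + b_cols)
    res = diff_methylation(betas, a_cols, b_cols)
    hits = set(dm_probes(res, 0.05, 0.2))
    true = {f"cg{i}" for i in range(40)}
    assert len(hits & true) / 40 >= 0.9
    assert res.loc["cg0", "delta_beta"] == pytest.approx(
        res.loc["cg0", "mean_b"] - res.loc["cg0", "mean_a"])
    assert (res["q"] >= res["p"] - 1e-15).all()


def test_diff_methylation_overlapping_groups_rejected(small_dataset):
    betas = small_dataset["betas"]
    with pytest.raises(ValueError, match="overlap"):
        diff_methylation(betas, betas.columns[:3], betas.columns[2:5])


def test_region_mean_profile_trivial_cases():
    manifest = pd.DataFrame({
        "probe_id": ["cg1", "cg2", "cg3"], "chromosome": ["1"] * 3,
        "position": [1, 2, 3], "gene": ["G"] * 3,
        "region_class": ["Body", "Body", "TSS200"],
        "island_relation": ["Island"] * 3,
    })
    betas = pd.DataFrame({"s1": [0.2, 0.4, 0.9]}, index=["cg1", "cg2", "cg3"])
    prof = region_mean_profile(betas, manifest, ["cg1", "cg2", "cg3"], {"g": ["s1"]})
    assert prof.loc["g", "Body"] == pytest.approx(0.3)
    assert prof.loc["g", "TSS200"] == pytest.approx(0.9)
    assert np.isnan(prof.loc["g", "5UTR"])  # empty region reported missing


def test_region_profile_recovers_planted_body_shift():
    rng = np.random.default_rng(7)
    n = 200
    manifest = pd.DataFrame({
        "probe_id": [f"cg{i}" for i in range(n)], "chromosome": ["1"] * n,
        "position": range(1, n + 1), "gene": ["G"] * n,
        "region_class": ["Body"] * (n // 2) + ["TSS200"] * (n // 2),
        "island_relation": ["Island"] * n,
    })
    base = 0.3
    w0 = rng.beta(base * 200, (1 - base) * 200, (n, 3))
    shift = np.array([0.3] * (n // 2) + [0.0] * (n // 2))
    m6 = base + shift
    w6 = rng.beta(m6[:, None] * 200, (1 - m6[:, None]) * 200, (n, 3))
    betas = pd.DataFrame(np.hstack([w0, w6]), index=manifest["probe_id"],
                         columns=["a1", "a2", "a3", "b1", "b2", "b3"])
    prof = region_mean_profile(betas, manifest, betas.index,
                               {"week0": ["a1", "a2", "a3"], "week6": ["b1", "b2", "b3"]})
    assert prof.loc["week6", "Body"] - prof.loc["week0", "Body"] == pytest.approx(0.3, abs=0.02)
    assert prof.loc["week6", "TSS200"] - prof.loc["week0", "TSS200"] == pytest.approx(0.0, abs=0.02)


def test_context_stratify_excludes_shores_and_reports_empty_strata():
    manifest = pd.DataFrame({
        "probe_id": ["cg1", "cg2"], "chromosome": ["1", "1"],
        "position": [1, 2], "gene": ["G", "G"],
        "region_class": ["Body", "Body"],
        "island_relation": ["Island", "Shore"],
    })
    betas = pd.DataFrame({"s1": [0.7, 0.2]}, index=["cg1", "cg2"])
    out = context_stratify(betas, manifest, ["cg1", "cg2"], {"g": ["s1"]})
    assert out.loc[("Island", "g"), "Body"] == pytest.approx(0.7)  # shore excluded
    assert np.isnan(out.loc[("OpenSea", "g"), "Body"])


def test_bin_census_boundary_convention():
    manifest = pd.DataFrame({
        "probe_id": ["cg1", "cg2", "cg3", "cg4"], "chromosome": ["1"] * 4,
        "position": [1, 2, 3, 4], "gene": ["G"] * 4,
        "region_class": ["Body"] * 4, "island_relation": ["Island"] * 4,
    })
    betas = pd.DataFrame({"s1": [0.40, 0.41, 0.80, 0.81]},
                         index=["cg1", "cg2", "cg3", "cg4"])
    census = bin_census(betas, manifest, ["s1"])
    assert census.loc["1"].tolist() == [1, 2, 1]


def test_bin_census_conserves_probe_counts(small_dataset):
    d = small_dataset
    census = bin_census(d["betas"], d["manifest"], d["sheet"]["sample_id"])
    per_chrom = d["manifest"].drop_duplicates("probe_id")["chromosome"].value_counts()
    for chrom, row in census.iterrows():
        assert row.sum() == per_chrom[chrom]


def test_distribution_summary_constant_and_uniform():
    betas = pd.DataFrame({"s1": [0.7] * 10, "s2": np.linspace(0, 1, 10)},
                         index=[f"cg{i}" for i in range(10)])
    summ = distribution_summary(betas, betas.index)
    assert summ.loc["s1", "q50"] == pytest.approx(0.7)
    assert summ.loc["s1", "mode"] == pytest.approx(0.7)
    assert summ.loc["s2", "q50"] == pytest.approx(0.5, abs=0.06)


def test_distribution_summary_finds_planted_bimodal_mode():
    rng = np.random.default_rng(8)
    vals = np.concatenate([rng.beta(0.2 * 80, 0.8 * 80, 300),
                           rng.beta(0.8 * 80, 0.2 * 80, 200)])
    betas = pd.DataFrame({"s1": vals}, index=[f"cg{i}" for i in range(500)])
    mode = distribution_summary(betas, betas.index).loc["s1", "mode"]
    assert min(abs(mode - 0.2), abs(mode - 0.8)) < 0.05
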