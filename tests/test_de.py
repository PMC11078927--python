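"""Differential-expression stage: size factors, dispersions, Wald test, BH."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrgrn.de import (
    DeThresholds,
    bh_adjust,
    classify_degs,
    estimate_dispersions,
    estimate_size_factors,
    nb_wald_test,
    run_de,
)
from mrgrn.io import CountMatrix

from conftest import nb_count_matrix


def _cm(counts: dict, conditions: list[str]) -> CountMatrix:
    df = pd.DataFrame(counts)
    meta = pd.DataFrame(
        {
            "sample_id": df.columns,
            "tissue": "colon",
            "condition": conditions,
            "batch": "B1",
        }
    ).set_index("sample_id")
    return CountMatrix(df, meta)


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------


def test_size_factors_identical_columns_are_one():
    cm = _cm({"a": [5, 9, 2], "b": [5, 9, 2]}, ["control", "case"])
    sf = estimate_size_factors(cm)
    assert np.allclose(sf.to_numpy(), 1.0)


def test_size_factors_median_of_ratios_worked_example():
    cm = _cm({"s1": [2, 8], "s2": [4, 16]}, ["control", "case"])
    sf = estimate_size_factors(cm)
    assert sf["s1"] == pytest.approx(0.7071, abs=5e-5)
    assert sf["s2"] == pytest.approx(1.4142, abs=5e-5)


def test_size_factors_equivariant_under_sample_permutation():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 500, size=(20, 4))
    cm = _cm(
        {f"s{j}": counts[:, j] for j in range(4)},
        ["control", "control", "case", "case"],
    )
    sf = estimate_size_factors(cm)
    perm = ["s2", "s0", "s3", "s1"]
    cm_perm = CountMatrix(cm.counts[perm], cm.sample_meta.loc[perm])
    sf_perm = estimate_size_factors(cm_perm)
    assert np.allclose(sf_perm.to_numpy(), sf.loc[perm].to_numpy())


def test_size_factors_require_a_reference_gene():
    cm = _cm({"s1": [0, 5], "s2": [5, 0]}, ["control", "case"])
    with pytest.raises(ValueError, match="pseudo-reference"):
        estimate_size_factors(cm)


# ---------------------------------------------------------------------------
# dispersions
# ---------------------------------------------------------------------------


def test_dispersion_floor_for_poisson_like_and_constant_genes():
    cm = _cm(
        {"s1": [10, 7], "s2": [11, 7], "s3": [9, 7], "s4": [10, 7]},
        ["control", "control", "case", "case"],
    )
    sf = pd.Series(1.0, index=cm.sample_ids)
    disp = estimate_dispersions(cm, sf)
    assert disp.iloc[1] == pytest.approx(1e-8)  # constant gene at the floor
    assert disp.iloc[0] <= 0.01  # variance ~ mean stays near the floor


def test_dispersion_mom_recovery_at_n50():
    cm = nb_count_matrix(300, 50, seed=11, mu=200.0, alpha=0.1)
    sf = estimate_size_factors(cm)
    disp = estimate_dispersions(cm, sf)
    assert 0.05 <= float(np.median(disp)) <= 0.2


def test_dispersion_requires_two_samples_per_condition():
    cm = _cm({"s1": [5], "s2": [5], "s3": [5]}, ["control", "control", "case"])
    sf = pd.Series(1.0, index=cm.sample_ids)
    with pytest.raises(ValueError, match="fewer than 2"):
        estimate_dispersions(cm, sf)


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------


def test_wald_log2fc_consistency_low_dispersion():
    shift = np.zeros(200)
    shift[:5] = 2.0  # 100 -> 400 for a sparse subset of genes
    cm = nb_count_matrix(200, 60, seed=5, mu=100.0, alpha=0.01, case_log2fc=shift)
    sf = estimate_size_factors(cm)
    disp = estimate_dispersions(cm, sf)
    det = nb_wald_test(cm, sf, disp)
    assert np.all(np.abs(det["log2fc"].to_numpy()[:5] - 2.0) < 0.1)


def test_wald_null_pvalues_uniform_at_large_n():
    cm = nb_count_matrix(2000, 50, seed=42, mu=200.0, alpha=0.1)
    sf = estimate_size_factors(cm)
    disp = estimate_dispersions(cm, sf)
    det = nb_wald_test(cm, sf, disp)
    ks = stats.kstest(det["p"].to_numpy(), "uniform")
    assert ks.pvalue > 0.01


def test_all_zero_gene_is_untested(small_counts):
    sf = estimate_size_factors(small_counts)
    disp = estimate_dispersions(small_counts, sf)
    det = nb_wald_test(small_counts, sf, disp)
    assert det.loc["gZero", "status"] == "untested"
    assert np.isnan(det.loc["gZero", "p"])


def test_wald_requires_control_and_case(small_counts):
    sf = estimate_size_factors(small_counts)
    disp = estimate_dispersions(small_counts, sf)
    groups = {s: "case" for s in small_counts.sample_ids}
    with pytest.raises(ValueError, match="control"):
        nb_wald_test(small_counts, sf, disp, groups)


def test_scale_invariance_of_log2fc():
    """Multiplying one sample's counts by an integer is absorbed by the
    size factors: log2fc moves by < 0.05."""
    cm = nb_count_matrix(300, 4, seed=9, mu=200.0, alpha=0.1)
    det1, _ = run_de(cm)
    counts2 = cm.counts.copy()
    counts2["case_0"] = counts2["case_0"] * 3
    det2, _ = run_de(CountMatrix(counts2, cm.sample_meta))
    assert np.nanmax(np.abs(det1["log2fc"] - det2["log2fc"])) < 0.05


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


def _bh_bruteforce(p):
    """Independent step-up oracle, straight from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def test_bh_worked_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_value_identity():
    assert bh_adjust([0.5])[0] == pytest.approx(0.5)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_bh_nan_excluded_from_m():
    out = bh_adjust([0.05, np.nan])
    assert out[0] == pytest.approx(0.05)  # m=1, not 2
    assert np.isnan(out[1])


def test_bh_matches_bruteforce_oracle_on_random_vectors():
    rng = np.random.default_rng(123)
    for _ in range(100):
        p = rng.random(rng.integers(1, 40)).tolist()
        got = bh_adjust(p)
        expect = _bh_bruteforce(p)
        assert np.allclose(got, expect, atol=1e-12)
        assert np.all(got >= np.asarray(p) - 1e-15)  # adjusted >= raw


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    p = rng.random(200)
    _, expected, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(bh_adjust(p), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "padj, log2fc, fc_threshold, expected",
    [
        (0.04, 3.0, 0.0, "up"),
        (0.2, 3.0, 0.0, "ns"),
        (0.01, -2.5, 2.0, "down"),
        (0.01, 1.5, 2.0, "ns"),
    ],
)
def test_classify_degs_rules(padj, log2fc, fc_threshold, expected):
    det = pd.DataFrame(
        {
            "base_mean": [10.0],
            "log2fc": [log2fc],
            "dispersion": [0.1],
            "p": [padj / 2],
            "padj": [padj],
            "status": ["ns"],
        },
        index=["g1"],
    )
    out, summary = classify_degs(det, DeThresholds(alpha=0.05, fc_threshold=fc_threshold))
    assert out.loc["g1", "status"] == expected
    assert summary["n_up"] == (1 if expected == "up" else 0)
    assert summary["n_down"] == (1 if expected == "down" else 0)
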