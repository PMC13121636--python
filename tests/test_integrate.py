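"""Expression integration: TPM, W statistic, stratification, PCA, APA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

from glori_dilution.errors import InputError
from glori_dilution.integrate import (
    aggregate_methylation,
    apa_association,
    benjamini_hochberg,
    cumulative_abundance,
    filter_expressed,
    naive_log2fc,
    pca_separation,
    stratified_expression_shift,
    tpm_from_counts,
    weighted_global_methylation,
)


# ------------------------------------------------------------------ TPM
def test_tpm_hand_computation():
    counts = pd.DataFrame({"s": [10, 10]}, index=["t1", "t2"])
    lengths = pd.Series([1000, 2000], index=["t1", "t2"])
    tpm = tpm_from_counts(counts, lengths)
    assert tpm.loc["t1", "s"] == pytest.approx(666666.6667, rel=1e-6)
    assert tpm.loc["t2", "s"] == pytest.approx(333333.3333, rel=1e-6)


def test_tpm_degenerate_cases():
    single = tpm_from_counts(
        pd.DataFrame({"s": [7]}, index=["t"]), pd.Series([500], index=["t"])
    )
    assert single.loc["t", "s"] == pytest.approx(1e6)
    uniform = tpm_from_counts(
        pd.DataFrame({"s": [5, 5, 5]}, index=list("abc")),
        pd.Series([100, 100, 100], index=list("abc")),
    )
    assert uniform["s"].tolist() == pytest.approx([1e6 / 3] * 3)
    with pytest.raises(InputError):
        tpm_from_counts(
            pd.DataFrame({"s": [0]}, index=["t"]), pd.Series([100], index=["t"])
        )


def test_tpm_always_sums_to_one_million(rng):
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(30, 4)) + 1,
        index=[f"t{i}" for i in range(30)],
        columns=list("wxyz"),
    )
    lengths = pd.Series(
        rng.integers(200, 5000, 30), index=counts.index
    )
    tpm = tpm_from_counts(counts, lengths)
    assert tpm.sum(axis=0).tolist() == pytest.approx([1e6] * 4, abs=1e-3)


def test_filter_expressed_requires_more_than_ten_everywhere():
    counts = pd.DataFrame(
        {"s1": [11, 10, 50], "s2": [12, 50, 9]}, index=["a", "b", "c"]
    )
    assert list(filter_expressed(counts)) == ["a"]


# ----------------------------------------------------------- aggregation
@pytest.mark.parametrize(
    "levels,expected_agg,expected_class",
    [
        ((0.5, 0.9, 0.8), 2.2, "high"),
        ((0.3,), 0.3, "low"),
        ((), 0.0, "unmethylated"),
    ],
)
def test_aggregate_methylation_rules(levels, expected_agg, expected_class):
    sites = pd.DataFrame(
        {"transcript_id": ["t"] * len(levels), "level": list(levels)}
    )
    out = aggregate_methylation(sites, transcript_ids=["t"]).set_index(
        "transcript_id"
    )
    assert out.loc["t", "aggregate"] == pytest.approx(expected_agg)
    assert out.loc["t", "meth_class"] == expected_class


# ------------------------------------------------------------------- W
def _w_of(aggregates, tpms):
    meth = pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(len(aggregates))],
            "aggregate": aggregates,
        }
    )
    tpm = pd.DataFrame(
        {"s": tpms}, index=[f"t{i}" for i in range(len(tpms))]
    )
    per_sample, _ = weighted_global_methylation(meth, tpm, {"s": "A"})
    return per_sample["W"].iloc[0]


def test_weighted_methylation_examples():
    assert _w_of([1.0, 0.0], [5e5, 5e5]) == pytest.approx(0.5)
    assert _w_of([0.0, 0.0], [5e5, 5e5]) == 0.0


def test_weighted_methylation_no_overlap_errors():
    meth = pd.DataFrame({"transcript_id": ["x"], "aggregate": [1.0]})
    tpm = pd.DataFrame({"s": [1e6]}, index=["y"])
    with pytest.raises(InputError):
        weighted_global_methylation(meth, tpm, {"s": "A"})


def test_w_invariants():
    """Order invariance and linear scaling in the aggregates."""
    aggs, tpms = [0.5, 2.0, 0.0], [2e5, 3e5, 5e5]
    w = _w_of(aggs, tpms)
    for perm in itertools.permutations(range(3)):
        assert _w_of(
            [aggs[i] for i in perm], [tpms[i] for i in perm]
        ) == pytest.approx(w)
    assert _w_of([3 * a for a in aggs], tpms) == pytest.approx(3 * w)


def test_dilution_lowers_w_algebraically():
    """Moving expression mass to an unmethylated transcript decreases W."""
    aggs = [1.0, 0.5, 0.0]
    base = [3e5, 3e5, 4e5]
    w0 = _w_of(aggs, base)
    # double the unmethylated transcript's expression, renormalize to 1e6
    shifted = np.array([3e5, 3e5, 8e5])
    shifted = shifted / shifted.sum() * 1e6
    w1 = _w_of(aggs, list(shifted))
    assert w1 < w0


# ------------------------------------------------------------------ k50
def test_k50_examples():
    curve, k50 = cumulative_abundance(
        pd.Series([5e5, 3e5, 2e5], index=list("abc"))
    )
    assert k50 == 1  # top share is exactly 0.5, inclusive
    _, k50u = cumulative_abundance(
        pd.Series([1e5] * 10, index=[f"t{i}" for i in range(10)])
    )
    assert k50u == 5
    with pytest.raises(InputError):
        cumulative_abundance(pd.Series([0.0, 0.0]))


def test_k50_small_for_skewed_abundance(rng):
    tpm = pd.Series(
        rng.lognormal(0, 2.0, 500), index=[f"t{i}" for i in range(500)]
    )
    _, k50 = cumulative_abundance(tpm)
    assert k50 < 250 / 2  # far fewer than half the transcripts


# ---------------------------------------------------------- stratified FC
def test_stratified_shift_recovers_planted_fold_changes():
    ids = [f"t{i}" for i in range(6)]
    log2fc = pd.Series([1, 1, -1, -1, 0, 0], index=ids, dtype=float)
    classes = pd.Series(
        ["unmethylated", "unmethylated", "high", "high", "low", "low"],
        index=ids,
    )
    abundance = pd.Series([10, 9, 8, 7, 6, 5], index=ids, dtype=float)
    out = stratified_expression_shift(log2fc, classes, abundance, top_k=4)
    pivot = out.set_index(["subset", "meth_class"])["median_log2fc"]
    assert pivot[("all", "unmethylated")] == 1.0
    assert pivot[("all", "high")] == -1.0
    # top-4 excludes the 'low' class entirely; no error, just absent
    assert ("top_abundant", "low") not in pivot.index


def test_naive_log2fc_uses_pseudocount():
    tpm = pd.DataFrame({"a": [0.0], "b": [3.0]}, index=["t"])
    fc = naive_log2fc(tpm, {"a": "A", "b": "B"})
    assert fc["t"] == pytest.approx(2.0)  # log2((3+1)/(0+1))


# ------------------------------------------------------------------ PCA
def test_pca_rank_one_structure_separates_groups():
    levels = pd.DataFrame(
        {
            "a1": [0.2, 0.5], "a2": [0.2, 0.5],
            "b1": [0.8, 0.5], "b2": [0.8, 0.5],
        }
    )
    groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    coords, sil = pca_separation(levels, groups)
    assert sil == pytest.approx(1.0)
    pc1 = coords.set_index("sample")["PC1"]
    assert pc1["a1"] == pytest.approx(pc1["a2"])
    assert np.sign(pc1["a1"]) != np.sign(pc1["b1"])


def test_pca_zero_variance_is_defined():
    levels = pd.DataFrame({s: [0.4, 0.4] for s in ("x", "y", "z")})
    coords, sil = pca_separation(levels, {"x": "A", "y": "A", "z": "B"})
    assert sil == 0.0
    assert np.allclose(coords[["PC1", "PC2"]].to_numpy(), 0.0)


def test_pca_requires_three_samples():
    levels = pd.DataFrame({"x": [0.1], "y": [0.9]})
    with pytest.raises(InputError):
        pca_separation(levels, {"x": "A", "y": "B"})


# ------------------------------------------------------------------ APA
def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + 1e-12):
            total += pk
    return min(total, 1.0)


def test_fisher_matches_enumeration_oracle(rng):
    tables = [[[10, 20], [30, 5]]] + [
        rng.integers(0, 40, size=(2, 2)).tolist() for _ in range(25)
    ]
    for table in tables:
        if sum(map(sum, table)) == 0:
            continue
        _, p = stats.fisher_exact(table, alternative="two-sided")
        assert p == pytest.approx(
            fisher_enumeration_oracle(table), abs=1e-10
        )


def test_bh_matches_reference_step_up(rng):
    def reference_bh(p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    for _ in range(10):
        p = rng.uniform(0, 1, size=rng.integers(1, 40))
        np.testing.assert_allclose(
            benjamini_hochberg(p), reference_bh(p), atol=1e-12
        )


def test_apa_classification_rules(rng):
    ids = [f"t{i}" for i in range(40)]
    base = rng.uniform(0.4, 0.8, 40)
    data = {}
    for s in ("a1", "a2", "a3"):
        data[s] = base + rng.normal(0, 0.005, 40)
    shift = np.zeros(40)
    shift[:10] = -0.15  # clearly shortened
    shift[10:12] = -0.05  # too small to classify
    for s in ("b1", "b2", "b3"):
        data[s] = base + shift + rng.normal(0, 0.005, 40)
    pdui = pd.DataFrame(data, index=ids).clip(0, 1)
    groups = {s: ("A" if s.startswith("a") else "B") for s in pdui.columns}
    m6a = pd.Series([True] * 10 + [False] * 30, index=ids)
    records, summary = apa_association(pdui, groups, m6a)
    rec = records.set_index("transcript_id")
    assert (rec.loc[[f"t{i}" for i in range(10)], "apa_class"] == "shortened").all()
    assert (rec.loc[["t10", "t11"], "apa_class"] == "none").all()
    assert summary["n_shortened"] == 10
    assert 0 <= summary["fisher_p"] <= 1


def test_apa_requires_two_samples_per_group():
    pdui = pd.DataFrame({"a1": [0.5], "b1": [0.3]}, index=["t"])
    with pytest.raises(InputError):
        apa_association(
            pdui, {"a1": "A", "b1": "B"}, pd.Series([True], index=["t"])
        )
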