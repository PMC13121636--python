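"""Beta-binomial differential methylation: oracles and classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glori_dilution.annotation import Annotation, TranscriptModel
from glori_dilution.diffmeth import (
    DiffThresholds,
    _bb_loglik,
    beta_binomial_test,
    build_test_universe,
    classify_differential,
    classify_transcripts,
    sd_threshold_report,
)
from glori_dilution.diffmeth import test_differential as run_differential_tests
from glori_dilution.errors import InputError, PipelineError
from glori_dilution.simulate import simulate_betabinomial_sites


def binomial_lrt_oracle(a_a, n_a, a_b, n_b):
    """Pure binomial LRT on pooled group counts (the phi -> 0 limit)."""
    a_a, n_a, a_b, n_b = map(np.asarray, (a_a, n_a, a_b, n_b))

    def ll(a, n, p):
        p = min(max(p, 1e-12), 1 - 1e-12)
        return float((a * np.log(p) + (n - a) * np.log1p(-p)).sum())

    p1 = a_a.sum() / n_a.sum()
    p2 = a_b.sum() / n_b.sum()
    pp = (a_a.sum() + a_b.sum()) / (n_a.sum() + n_b.sum())
    lr = 2 * (
        ll(a_a, n_a, p1)
        + ll(a_b, n_b, p2)
        - ll(np.r_[a_a, a_b], np.r_[n_a, n_b], pp)
    )
    return stats.chi2.sf(max(lr, 0.0), 1)


def test_loglik_matches_scipy_betabinom():
    """Our gammaln-based likelihood equals scipy's betabinom logpmf."""
    a = np.array([3, 10, 0, 25])
    n = np.array([30, 40, 15, 50])
    for pi, theta in [(0.3, 5.0), (0.7, 120.0), (0.05, 1.0)]:
        alpha, beta = pi * theta, (1 - pi) * theta
        expected = stats.betabinom.logpmf(a, n, alpha, beta).sum()
        assert _bb_loglik(a, n, pi, theta) == pytest.approx(expected, abs=1e-9)


def test_identical_counts_give_null_result():
    a = np.array([5, 6, 7])
    n = np.array([50, 50, 50])
    res = beta_binomial_test(a, n, a, n)
    assert res.delta == 0.0
    assert res.p_value == pytest.approx(1.0, abs=1e-4)


def test_agrees_with_binomial_lrt_when_dispersion_vanishes(rng):
    """Without overdispersion the p-value equals the binomial LRT to 1e-6."""
    for _ in range(20):
        n_a = rng.integers(20, 80, size=5)
        n_b = rng.integers(20, 80, size=5)
        p_a, p_b = rng.uniform(0.1, 0.9, 2)
        a_a = rng.binomial(n_a, p_a)
        a_b = rng.binomial(n_b, p_b)
        res = beta_binomial_test(a_a, n_a, a_b, n_b)
        if res.dispersion == 0.0:
            oracle = binomial_lrt_oracle(a_a, n_a, a_b, n_b)
            assert res.p_value == pytest.approx(oracle, abs=1e-6)


def test_group_swap_symmetry_is_exact(rng):
    for _ in range(10):
        n = rng.integers(15, 60, size=9)
        a_a = rng.binomial(n, 0.3)
        a_b = rng.binomial(n, 0.45)
        r1 = beta_binomial_test(a_a, n, a_b, n)
        r2 = beta_binomial_test(a_b, n, a_a, n)
        assert r1.p_value == r2.p_value
        assert r1.delta == -r2.delta
        assert r1.level_a == r2.level_b


def test_detects_overdispersion():
    """Beta-binomial data with strong dispersion should not look binomial."""
    rng = np.random.default_rng(5)
    a_a, n_a, a_b, n_b = simulate_betabinomial_sites(
        0.4, 0.4, 0.15, 100, 9, 30, rng
    )
    phis = [
        beta_binomial_test(a_a[i], n_a[i], a_b[i], n_b[i]).dispersion
        for i in range(30)
    ]
    assert np.median(phis) > 0.01


def test_zero_coverage_group_raises():
    with pytest.raises(InputError):
        beta_binomial_test(
            np.array([0, 0]), np.array([0, 0]), np.array([5]), np.array([20])
        )


def test_direction_correct_at_high_coverage():
    """At near-infinite coverage a planted gain is never called a loss."""
    cov = 200_000
    a_a = np.full(9, int(0.30 * cov))
    a_b = np.full(9, int(0.50 * cov))
    n = np.full(9, cov)
    res = beta_binomial_test(a_a, n, a_b, n)
    classified = classify_differential(
        pd.DataFrame(
            [dict(delta=res.delta, p_value=res.p_value)]
        )
    )
    assert classified["direction"].iloc[0] == "hyper"


# ------------------------------------------------------------ thresholds
@pytest.mark.parametrize(
    "delta,p,expected",
    [
        (0.12, 0.01, "hyper"),
        (0.12, 0.2, "none"),
        (-0.09, 0.001, "none"),  # |delta| below the 10% cutoff
        (-0.15, 0.01, "hypo"),
        (0.10, 0.049, "hyper"),  # inclusive delta boundary
    ],
)
def test_classify_differential_rules(delta, p, expected):
    out = classify_differential(
        pd.DataFrame([dict(delta=delta, p_value=p)]), DiffThresholds()
    )
    assert out["direction"].iloc[0] == expected


def test_classify_transcripts():
    diff = pd.DataFrame(
        dict(
            transcript_id=["t1", "t1", "t2", "t2", "t3"],
            direction=["hyper", "hyper", "hyper", "hypo", "none"],
        )
    )
    out = classify_transcripts(diff).set_index("transcript_id")
    assert out.loc["t1", "class"] == "hyper"
    assert out.loc["t2", "class"] == "both"
    assert out.loc["t3", "class"] == "unchanged"


# --------------------------------------------------------------- universe
def _toy_universe_inputs():
    model = TranscriptModel("t", "chr", "+", 0, 100, 300, 200)
    annotation = Annotation([model])
    # GGACT centered at genomic 202 (CDS); non-DRAC A at 302
    seq = list("G" * 600)
    seq[200:205] = "GGACT"
    seq[300:305] = "GGATT"
    reference = {"chr": "".join(seq)}

    def counts(cov_202, cov_302):
        return pd.DataFrame(
            {
                "contig": ["chr", "chr"],
                "pos0": [202, 302],
                "strand": ["+", "+"],
                "a_count": [0, 0],
                "g_count": [cov_202, cov_302],
            }
        )

    return annotation, reference, counts


def test_universe_includes_unmethylated_drac_and_excludes_others():
    annotation, reference, counts = _toy_universe_inputs()
    by_sample = {"s1": counts(20, 20), "s2": counts(25, 25)}
    universe = build_test_universe(by_sample, annotation, reference)
    # the unmethylated DRAC position stays; the non-DRAC one is excluded
    assert universe["pos0"].tolist() == [202]
    assert (universe[["a_s1", "a_s2"]].to_numpy() == 0).all()


def test_universe_coverage_filter_applies_to_every_sample():
    annotation, reference, counts = _toy_universe_inputs()
    by_sample = {"s1": counts(20, 20), "s2": counts(10, 25)}
    with pytest.raises(PipelineError):
        build_test_universe(by_sample, annotation, reference)


# -------------------------------------------------------------- SD report
def test_sd_report_hand_values():
    universe = pd.DataFrame(
        {
            "contig": ["c"],
            "pos0": [1],
            "strand": ["+"],
            "a_s1": [40], "n_s1": [100],
            "a_s2": [60], "n_s2": [100],
            "a_s3": [50], "n_s3": [100],
            "a_s4": [50], "n_s4": [100],
        }
    )
    groups = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
    table, summary = sd_threshold_report(universe, groups)
    # levels (0.4, 0.6): SD = sqrt(2 * 0.01) ~ 0.1414
    assert table["sd_A"].iloc[0] == pytest.approx(np.sqrt(0.02), abs=1e-12)
    assert table["sd_B"].iloc[0] == 0.0
    assert summary["mean_sd_A"] == pytest.approx(np.sqrt(0.02))


def test_sd_report_requires_two_samples_per_group():
    universe = pd.DataFrame(
        {
            "contig": ["c"], "pos0": [1], "strand": ["+"],
            "a_s1": [40], "n_s1": [100], "a_s2": [60], "n_s2": [100],
        }
    )
    with pytest.raises(InputError):
        sd_threshold_report(universe, {"s1": "A", "s2": "B"})


def test_sd_small_under_tight_simulation(rng):
    """Deep coverage + tight levels give within-group SD well below 10%."""
    a_a, n_a, a_b, n_b = simulate_betabinomial_sites(
        0.5, 0.5, 1e-4, 10_000, 5, 200, rng
    )
    cols = {}
    groups = {}
    for j in range(5):
        cols[f"a_sA{j}"], cols[f"n_sA{j}"] = a_a[:, j], n_a[:, j]
        cols[f"a_sB{j}"], cols[f"n_sB{j}"] = a_b[:, j], n_b[:, j]
        groups[f"sA{j}"], groups[f"sB{j}"] = "A", "B"
    universe = pd.DataFrame(
        dict(contig="c", pos0=np.arange(200), strand="+", **cols)
    )
    _, summary = sd_threshold_report(universe, groups)
    assert summary["mean_sd_A"] < 0.02
    assert summary["p90_sd_B"] < 0.05


def test_per_site_testing_runs_on_simulated_universe(small_dataset):
    reference, annotation, truth, data = small_dataset
    universe = build_test_universe(
        data.counts, annotation, reference
    )
    universe = universe[universe["contig"] != "spikein"].head(40)
    diff = run_differential_tests(universe, data.sample_groups)
    assert len(diff) == len(universe)
    assert ((diff["p_value"] > 0) & (diff["p_value"] <= 1)).all()
    assert (diff["delta"].abs() <= 1).all()
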