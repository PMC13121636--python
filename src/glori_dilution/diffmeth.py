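"""Two-group per-site differential methylation with a beta-binomial model.

Per site, unconverted-A counts are modeled as

    a_i ~ BetaBinomial(n_i, pi_g, phi)

with a group methylation proportion pi_g and a common per-site dispersion
phi (the intra-class correlation of the Beta: sample-level methylation
probabilities are Beta with mean pi and concentration theta = (1-phi)/phi).
pi_A, pi_B and phi are fit by maximum likelihood; the null constrains
pi_A = pi_B; the p-value comes from the likelihood-ratio statistic against
chi-square(1).  No windowing or smoothing — the test is per single site —
and no multiple-testing correction by default (a Benjamini-Hochberg column
is available but classification uses raw p).

The group difference delta is reported on the model estimates
(pi_hat_B - pi_hat_A), i.e. coverage-weighted, consistent with the
likelihood; users wanting the unweighted mean of per-sample levels can
compute it from the universe table.

Numerics: the likelihood is optimized on logit/log scales; when the fitted
concentration indicates no overdispersion, the statistic is recomputed with
the closed-form binomial MLEs, so the phi -> 0 limit reproduces the pure
binomial likelihood-ratio test exactly.  Group-label symmetry is exact: the
two groups are internally put in a canonical, label-independent order before
fitting, so swapping labels negates delta and leaves p unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln, logit

from .calling import extract_pentamer
from .errors import InputError, PipelineError
from .motifs import classify_motif, DRAC_CLASSES

logger = logging.getLogger(__name__)

_THETA_MIN, _THETA_MAX = 1e-2, 1e8
_ETA_BOUND = 12.0  # |logit pi| bound
_P_FLOOR = np.finfo(float).eps


@dataclass(frozen=True)
class DiffThresholds:
    min_delta: float = 0.10
    alpha: float = 0.05
    min_coverage_per_sample: int = 15

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class BetaBinomialResult:
    level_a: float
    level_b: float
    delta: float
    dispersion: float
    lr_stat: float
    p_value: float


# ----------------------------------------------------------- likelihoods
def _bb_loglik(a: np.ndarray, n: np.ndarray, pi: float, theta: float) -> float:
    alpha = pi * theta
    beta = (1.0 - pi) * theta
    ll = (
        gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
        + gammaln(a + alpha) + gammaln(n - a + beta) - gammaln(n + theta)
        + gammaln(theta) - gammaln(alpha) - gammaln(beta)
    )
    return float(ll.sum())


def _binom_loglik(a: np.ndarray, n: np.ndarray, pi: float) -> float:
    pi = min(max(pi, 1e-12), 1.0 - 1e-12)
    ll = (
        gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
        + a * np.log(pi) + (n - a) * np.log1p(-pi)
    )
    return float(ll.sum())


def _fit_bb_null(a: np.ndarray, n: np.ndarray) -> Tuple[float, float, float]:
    """MLE of (pi, theta) with one proportion; returns (ll, pi, theta)."""
    eta0 = float(logit(np.clip((a.sum() + 0.5) / (n.sum() + 1.0), 1e-6, 1 - 1e-6)))

    def nll(x: np.ndarray) -> float:
        return -_bb_loglik(a, n, expit(x[0]), np.exp(x[1]))

    best = None
    for theta0 in (50.0, 1e5):
        res = optimize.minimize(
            nll,
            x0=np.array([eta0, np.log(theta0)]),
            method="L-BFGS-B",
            bounds=[(-_ETA_BOUND, _ETA_BOUND),
                    (np.log(_THETA_MIN), np.log(_THETA_MAX))],
        )
        if best is None or res.fun < best.fun:
            best = res
    return -best.fun, float(expit(best.x[0])), float(np.exp(best.x[1]))


def _fit_bb_alt(
    a1: np.ndarray, n1: np.ndarray, a2: np.ndarray, n2: np.ndarray
) -> Tuple[float, float, float, float]:
    """MLE of (pi1, pi2, common theta); returns (ll, pi1, pi2, theta)."""
    eta1 = float(logit(np.clip((a1.sum() + 0.5) / (n1.sum() + 1.0), 1e-6, 1 - 1e-6)))
    eta2 = float(logit(np.clip((a2.sum() + 0.5) / (n2.sum() + 1.0), 1e-6, 1 - 1e-6)))

    def nll(x: np.ndarray) -> float:
        theta = np.exp(x[2])
        return -(
            _bb_loglik(a1, n1, expit(x[0]), theta)
            + _bb_loglik(a2, n2, expit(x[1]), theta)
        )

    best = None
    for theta0 in (50.0, 1e5):
        res = optimize.minimize(
            nll,
            x0=np.array([eta1, eta2, np.log(theta0)]),
            method="L-BFGS-B",
            bounds=[(-_ETA_BOUND, _ETA_BOUND),
                    (-_ETA_BOUND, _ETA_BOUND),
                    (np.log(_THETA_MIN), np.log(_THETA_MAX))],
        )
        if best is None or res.fun < best.fun:
            best = res
    return (
        -best.fun,
        float(expit(best.x[0])),
        float(expit(best.x[1])),
        float(np.exp(best.x[2])),
    )


def _canonical_order(
    a_a: np.ndarray, n_a: np.ndarray, a_b: np.ndarray, n_b: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, bool]:
    """Sort observations within groups and order the groups by a
    label-independent key; returns (a1, n1, a2, n2, swapped)."""

    def prep(a: np.ndarray, n: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        order = np.lexsort((a, n))
        return a[order], n[order]

    a_a, n_a = prep(np.asarray(a_a, dtype=np.int64), np.asarray(n_a, dtype=np.int64))
    a_b, n_b = prep(np.asarray(a_b, dtype=np.int64), np.asarray(n_b, dtype=np.int64))
    key_a = (tuple(n_a), tuple(a_a))
    key_b = (tuple(n_b), tuple(a_b))
    if key_b < key_a:
        return a_b, n_b, a_a, n_a, True
    return a_a, n_a, a_b, n_b, False


def beta_binomial_test(
    a_a: np.ndarray, n_a: np.ndarray, a_b: np.ndarray, n_b: np.ndarray
) -> BetaBinomialResult:
    """Likelihood-ratio test of pi_A = pi_B at one site.

    Each array holds one entry per sample (unconverted-A count and
    coverage).  Raises ``InputError`` when a group has no coverage at all.
    """
    a1, n1, a2, n2, swapped = _canonical_order(a_a, n_a, a_b, n_b)
    if n1.sum() == 0 or n2.sum() == 0:
        raise InputError("a group has zero total coverage at this site")
    if (a1 > n1).any() or (a2 > n2).any() or (a1 < 0).any() or (a2 < 0).any():
        raise InputError("counts must satisfy 0 <= a <= coverage")

    ll_alt_bb, pi1_bb, pi2_bb, theta_alt = _fit_bb_alt(a1, n1, a2, n2)
    a_all = np.concatenate([a1, a2])
    n_all = np.concatenate([n1, n2])
    ll_null_bb, _, _ = _fit_bb_null(a_all, n_all)

    # closed-form binomial MLEs (the phi -> 0 limit)
    pi1_bin = a1.sum() / n1.sum()
    pi2_bin = a2.sum() / n2.sum()
    pi_pool = a_all.sum() / n_all.sum()
    ll_alt_bin = _binom_loglik(a1, n1, pi1_bin) + _binom_loglik(a2, n2, pi2_bin)
    ll_null_bin = _binom_loglik(a_all, n_all, pi_pool)

    if ll_alt_bb - ll_alt_bin < 1e-4:
        # overdispersion adds nothing: use the exact binomial pair
        lr = 2.0 * (ll_alt_bin - ll_null_bin)
        pi1, pi2, phi = pi1_bin, pi2_bin, 0.0
    else:
        lr = 2.0 * (ll_alt_bb - ll_null_bb)
        pi1, pi2 = pi1_bb, pi2_bb
        phi = 1.0 / (1.0 + theta_alt)
    lr = max(lr, 0.0)
    p = max(float(stats.chi2.sf(lr, df=1)), _P_FLOOR)

    if swapped:
        pi1, pi2 = pi2, pi1
    return BetaBinomialResult(
        level_a=pi1,
        level_b=pi2,
        delta=pi2 - pi1,
        dispersion=max(phi, 0.0),
        lr_stat=lr,
        p_value=p,
    )


# -------------------------------------------------------------- universe
def build_test_universe(
    counts_by_sample: Dict[str, pd.DataFrame],
    annotation,
    reference: Dict[str, str],
    min_coverage_per_sample: int = 15,
) -> pd.DataFrame:
    """All annotated DRAC center-A positions covered in every sample.

    Unmethylated positions (level 0) are retained: the universe is defined
    by coverage and motif context, not by methylation.  Returns a frame with
    the site key, transcript/region/pentamer annotation, and per-sample
    ``a_<sample>`` / ``n_<sample>`` columns.
    """
    samples = list(counts_by_sample)
    if not samples:
        raise PipelineError("test universe: no samples provided")
    frames = []
    for sample, df in counts_by_sample.items():
        f = df[["contig", "pos0", "strand", "a_count", "g_count"]].copy()
        f["coverage"] = f["a_count"] + f["g_count"]
        f = f.set_index(["contig", "pos0", "strand"])
        frames.append(
            f[["a_count", "coverage"]].rename(
                columns={"a_count": f"a_{sample}", "coverage": f"n_{sample}"}
            )
        )
    joined = pd.concat(frames, axis=1, join="inner")
    cov_cols = [f"n_{s}" for s in samples]
    joined = joined[(joined[cov_cols] >= min_coverage_per_sample).all(axis=1)]

    records = []
    for (contig, pos0, strand), row in joined.iterrows():
        model = annotation.locate(contig, pos0, strand)
        if model is None:
            continue
        try:
            pentamer = extract_pentamer(reference, contig, pos0, strand)
        except InputError:
            continue
        if classify_motif(pentamer) not in DRAC_CLASSES:
            continue
        rec = dict(
            contig=contig,
            pos0=pos0,
            strand=strand,
            transcript_id=model.transcript_id,
            region=model.region(model.to_transcript_pos(pos0)),
            pentamer=pentamer,
        )
        rec.update(row.to_dict())
        records.append(rec)
    if not records:
        raise PipelineError(
            "test universe is empty: no DRAC position is covered at "
            f">={min_coverage_per_sample} reads in every sample"
        )
    universe = pd.DataFrame.from_records(records)
    int_cols = [c for c in universe.columns if c.startswith(("a_", "n_"))]
    universe[int_cols] = universe[int_cols].astype(np.int64)
    return universe.sort_values(
        ["contig", "pos0", "strand"], kind="mergesort"
    ).reset_index(drop=True)


def _group_columns(
    universe: pd.DataFrame, sample_groups: Dict[str, str]
) -> Tuple[List[str], List[str]]:
    groups = sorted(set(sample_groups.values()))
    if len(groups) != 2:
        raise InputError("differential testing needs exactly two groups")
    in_table = [s for s in sample_groups if f"a_{s}" in universe.columns]
    a_samples = [s for s in in_table if sample_groups[s] == groups[0]]
    b_samples = [s for s in in_table if sample_groups[s] == groups[1]]
    if not a_samples or not b_samples:
        raise InputError("each group needs at least one sample in the table")
    return a_samples, b_samples


# ------------------------------------------------------- per-site testing
def test_differential(
    universe: pd.DataFrame, sample_groups: Dict[str, str]
) -> pd.DataFrame:
    """Run the beta-binomial LRT at every universe site."""
    a_samples, b_samples = _group_columns(universe, sample_groups)
    a_cols_a = [f"a_{s}" for s in a_samples]
    n_cols_a = [f"n_{s}" for s in a_samples]
    a_cols_b = [f"a_{s}" for s in b_samples]
    n_cols_b = [f"n_{s}" for s in b_samples]

    aa = universe[a_cols_a].to_numpy()
    na = universe[n_cols_a].to_numpy()
    ab = universe[a_cols_b].to_numpy()
    nb = universe[n_cols_b].to_numpy()

    rows = []
    for i in range(len(universe)):
        try:
            res = beta_binomial_test(aa[i], na[i], ab[i], nb[i])
        except InputError as exc:
            logger.info(
                "skipping site %s:%s:%s: %s",
                universe["contig"].iat[i],
                universe["pos0"].iat[i],
                universe["strand"].iat[i],
                exc,
            )
            continue
        rows.append(
            dict(
                contig=universe["contig"].iat[i],
                pos0=universe["pos0"].iat[i],
                strand=universe["strand"].iat[i],
                transcript_id=universe["transcript_id"].iat[i],
                region=universe["region"].iat[i],
                pentamer=universe["pentamer"].iat[i],
                level_a=res.level_a,
                level_b=res.level_b,
                delta=res.delta,
                dispersion=res.dispersion,
                lr_stat=res.lr_stat,
                p_value=res.p_value,
            )
        )
    return pd.DataFrame(rows)


def classify_differential(
    diff: pd.DataFrame, thresholds: DiffThresholds = DiffThresholds()
) -> pd.DataFrame:
    """Attach hyper/hypo/none direction labels (raw p, no FDR)."""
    out = diff.copy()
    significant = out["p_value"] < thresholds.alpha
    out["direction"] = np.select(
        [
            significant & (out["delta"] >= thresholds.min_delta),
            significant & (out["delta"] <= -thresholds.min_delta),
        ],
        ["hyper", "hypo"],
        default="none",
    )
    return out


def classify_transcripts(diff_classified: pd.DataFrame) -> pd.DataFrame:
    """Transcript-level hyper/hypo/both/unchanged from site directions."""
    per_tx = (
        diff_classified.groupby("transcript_id")["direction"]
        .agg(
            n_hyper_sites=lambda d: int((d == "hyper").sum()),
            n_hypo_sites=lambda d: int((d == "hypo").sum()),
        )
        .reset_index()
    )
    per_tx["class"] = np.select(
        [
            (per_tx["n_hyper_sites"] >= 1) & (per_tx["n_hypo_sites"] >= 1),
            per_tx["n_hyper_sites"] >= 1,
            per_tx["n_hypo_sites"] >= 1,
        ],
        ["both", "hyper", "hypo"],
        default="unchanged",
    )
    return per_tx


# --------------------------------------------------------------- SD report
def sd_threshold_report(
    universe: pd.DataFrame, sample_groups: Dict[str, str]
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Within-group per-site sample SD of observed levels, with summaries.

    Justifies the 10% effect-size cutoff: the summary reports mean SD and
    the 90th percentile per group, computed with the n-1 denominator.
    """
    a_samples, b_samples = _group_columns(universe, sample_groups)
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise InputError("SD requires at least two samples per group")
    groups = sorted(set(sample_groups.values()))
    out = universe[["contig", "pos0", "strand"]].copy()
    summary: Dict[str, float] = {}
    for g, members in zip(groups, (a_samples, b_samples)):
        levels = np.column_stack(
            [
                universe[f"a_{s}"] / universe[f"n_{s}"].replace(0, np.nan)
                for s in members
            ]
        )
        sd = np.nanstd(levels, axis=1, ddof=1)
        out[f"sd_{g}"] = sd
        summary[f"mean_sd_{g}"] = float(np.nanmean(sd))
        summary[f"p90_sd_{g}"] = float(np.nanquantile(sd, 0.9))
    return out, summary
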