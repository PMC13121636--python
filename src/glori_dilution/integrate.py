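"""Expression integration: TPM, transcript methylation aggregation, the
expression-weighted global methylation ("dilution") statistic, abundance
stratification, PCA separation, and alternative-polyadenylation association.

The central statistic is the weighted global methylation level of a sample,

    W = sum_t aggregate(t) * TPM(t) / 1e6,

the TPM-weighted mean of per-transcript aggregate methylation (the sum of
methylation levels over a transcript's called sites, which can exceed 1).
Dividing by 1e6 makes W an expression-weighted mean; it differs from the raw
weighted sum only by this constant and leaves group comparisons unchanged.
Shifting expression mass toward unmethylated transcripts lowers W — the
dilution mechanism.
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .errors import InputError

MIN_READ_COUNT = 10  # transcripts need count > 10 in every sample


# ------------------------------------------------------------------ TPM
def tpm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Standard TPM: per-length read rate rescaled to sum to 1e6 per sample.

    ``counts`` is transcripts x samples (index = transcript_id); ``lengths``
    gives effective lengths in nt on the same index.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise InputError("length missing for some transcripts")
    if (lengths <= 0).any():
        raise InputError("transcript lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise InputError(f"zero total read rate in sample(s) {bad}")
    return rate.div(totals, axis=1) * 1e6


def filter_expressed(counts: pd.DataFrame) -> pd.Index:
    """Transcripts with read count > 10 in every sample."""
    return counts.index[(counts > MIN_READ_COUNT).all(axis=1)]


# ------------------------------------------- transcript-level methylation
def aggregate_methylation(sites: pd.DataFrame,
                          transcript_ids: Optional[Iterable[str]] = None,
                          high_threshold: float = 2.0) -> pd.DataFrame:
    """Sum site levels per transcript and classify.

    ``high`` means aggregate methylation above ``high_threshold`` (default 2,
    only reachable because the aggregate is a sum, not a mean);
    ``unmethylated`` means no called site on the transcript.
    """
    per_tx = (
        sites[sites["transcript_id"] != ""]
        .groupby("transcript_id")["level"]
        .agg(n_sites="size", aggregate="sum")
    )
    if transcript_ids is not None:
        per_tx = per_tx.reindex(list(transcript_ids))
        per_tx["n_sites"] = per_tx["n_sites"].fillna(0).astype(int)
        per_tx["aggregate"] = per_tx["aggregate"].fillna(0.0)
    out = per_tx.reset_index()
    out["meth_class"] = np.select(
        [out["n_sites"] == 0, out["aggregate"] > high_threshold],
        ["unmethylated", "high"],
        default="low",
    )
    return out


def weighted_global_methylation(
    transcript_meth: pd.DataFrame,
    tpm: pd.DataFrame,
    sample_groups: Dict[str, str],
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-sample W plus a two-sided two-group t-test.

    ``transcript_meth`` must carry transcript_id and aggregate columns;
    ``tpm`` is transcript_id-indexed with one column per sample.
    """
    agg = transcript_meth.set_index("transcript_id")["aggregate"]
    common = agg.index.intersection(tpm.index)
    if len(common) == 0:
        raise InputError("no overlap between methylation and TPM tables")
    agg = agg.loc[common]
    rows = []
    for sample in tpm.columns:
        weights = tpm.loc[common, sample] / 1e6
        rows.append(
            dict(
                sample=sample,
                group=sample_groups[sample],
                W=float((agg * weights).sum()),
            )
        )
    per_sample = pd.DataFrame(rows)
    groups = sorted(per_sample["group"].unique())
    summary: Dict[str, float] = {}
    for g in groups:
        summary[f"mean_W_{g}"] = float(
            per_sample.loc[per_sample["group"] == g, "W"].mean()
        )
    if len(groups) == 2:
        wa = per_sample.loc[per_sample["group"] == groups[0], "W"]
        wb = per_sample.loc[per_sample["group"] == groups[1], "W"]
        t_res = stats.ttest_ind(wa, wb)
        summary["t_statistic"] = float(t_res.statistic)
        summary["p_value"] = float(t_res.pvalue)
    return per_sample, summary


# --------------------------------------------------------- abundance curve
def cumulative_abundance(tpm: pd.Series) -> Tuple[pd.DataFrame, int]:
    """Descending cumulative TPM share and k50.

    k50 is the smallest number of transcripts whose cumulative share reaches
    (>=) 50% of the total.
    """
    tpm = tpm[tpm >= 0]
    total = tpm.sum()
    if total <= 0:
        raise InputError("cumulative abundance undefined for all-zero TPM")
    ordered = tpm.sort_values(ascending=False)
    share = ordered.cumsum() / total
    curve = pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "transcript_id": ordered.index,
            "tpm": ordered.to_numpy(),
            "cumulative_share": share.to_numpy(),
        }
    )
    k50 = int(np.searchsorted(share.to_numpy(), 0.5) + 1)
    return curve, k50


# ------------------------------------------------------ expression shifts
def naive_log2fc(
    tpm: pd.DataFrame,
    sample_groups: Dict[str, str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2 of mean TPM(B)/mean TPM(A) with a pseudocount of 1 TPM."""
    groups = sorted(set(sample_groups.values()))
    if len(groups) != 2:
        raise InputError("naive_log2fc needs exactly two groups")
    a_cols = [s for s in tpm.columns if sample_groups[s] == groups[0]]
    b_cols = [s for s in tpm.columns if sample_groups[s] == groups[1]]
    mean_a = tpm[a_cols].mean(axis=1)
    mean_b = tpm[b_cols].mean(axis=1)
    return np.log2((mean_b + pseudocount) / (mean_a + pseudocount))


def stratified_expression_shift(
    log2fc: pd.Series,
    meth_class: pd.Series,
    tpm_rank_source: pd.Series,
    top_k: int = 500,
) -> pd.DataFrame:
    """Per-methylation-class log2FC summaries, overall and among the top-K
    most abundant transcripts (abundance ranked on ``tpm_rank_source``)."""
    df = pd.DataFrame(
        {
            "log2fc": log2fc,
            "meth_class": meth_class.reindex(log2fc.index),
            "abundance": tpm_rank_source.reindex(log2fc.index),
        }
    ).dropna(subset=["meth_class"])
    top_ids = df["abundance"].nlargest(min(top_k, len(df))).index
    out_rows = []
    for subset_name, subset in (
        ("all", df),
        ("top_abundant", df.loc[top_ids]),
    ):
        for cls, grp in subset.groupby("meth_class"):
            if grp.empty:
                continue
            out_rows.append(
                dict(
                    subset=subset_name,
                    meth_class=cls,
                    n=len(grp),
                    median_log2fc=float(grp["log2fc"].median()),
                    q25=float(grp["log2fc"].quantile(0.25)),
                    q75=float(grp["log2fc"].quantile(0.75)),
                )
            )
    return pd.DataFrame(out_rows)


# ------------------------------------------------------------------- PCA
def pca_separation(
    level_matrix: pd.DataFrame, sample_groups: Dict[str, str]
) -> Tuple[pd.DataFrame, float]:
    """Sample coordinates from an SVD of the site-centered level matrix and
    the silhouette of the group labels on the first two components.

    ``level_matrix`` is sites x samples.  A zero-variance matrix yields
    all-zero coordinates and silhouette 0.
    """
    if level_matrix.shape[1] < 3:
        raise InputError("PCA separation needs at least 3 samples")
    X = level_matrix.to_numpy(dtype=float).T  # samples x sites
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = u * s  # principal-component scores
    n_pc = min(2, coords.shape[1])
    pc = np.zeros((coords.shape[0], 2))
    pc[:, :n_pc] = coords[:, :n_pc]
    labels = [sample_groups[s_] for s_ in level_matrix.columns]
    if np.allclose(pc, 0) or len(set(labels)) < 2:
        silhouette = 0.0
    else:
        silhouette = float(silhouette_score(pc, labels))
    out = pd.DataFrame(
        {
            "sample": level_matrix.columns,
            "group": labels,
            "PC1": pc[:, 0],
            "PC2": pc[:, 1],
        }
    )
    return out, silhouette


# ------------------------------------------------------------------- APA
def apa_association(
    pdui: pd.DataFrame,
    sample_groups: Dict[str, str],
    m6a_status: pd.Series,
    delta_threshold: float = 0.1,
    fdr_threshold: float = 0.05,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Classify transcripts as 3'-UTR shortened/lengthened and test the
    association between APA class and m6A status.

    delta_pdui = mean PDUI(group B) - mean PDUI(group A); negative values
    mean shortening in group B.  Per-transcript two-sided t-tests are
    BH-corrected across transcripts; a transcript is classified only when
    |delta| exceeds ``delta_threshold`` and FDR < ``fdr_threshold``.  The
    association is a two-sided Fisher exact test on the 2x2 table
    {shortened, lengthened} x {m6A, non-m6A}.
    """
    groups = sorted(set(sample_groups.values()))
    if len(groups) != 2:
        raise InputError("APA association needs exactly two groups")
    a_cols = [s for s in pdui.columns if sample_groups[s] == groups[0]]
    b_cols = [s for s in pdui.columns if sample_groups[s] == groups[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise InputError("per-transcript PDUI test needs >=2 samples per group")

    mean_a = pdui[a_cols].mean(axis=1)
    mean_b = pdui[b_cols].mean(axis=1)
    delta = mean_b - mean_a
    with warnings.catch_warnings():
        # near-identical PDUI vectors trip scipy's precision-loss warning;
        # those transcripts end up with p ~ 1, which is the right answer
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_ind(pdui[b_cols], pdui[a_cols], axis=1)
    pvals = np.nan_to_num(t_res.pvalue, nan=1.0)
    fdr = benjamini_hochberg(pvals)
    significant = (np.abs(delta) > delta_threshold) & (fdr < fdr_threshold)
    apa_class = np.select(
        [significant & (delta < 0), significant & (delta > 0)],
        ["shortened", "lengthened"],
        default="none",
    )
    records = pd.DataFrame(
        {
            "transcript_id": pdui.index,
            "mean_pdui_a": mean_a.to_numpy(),
            "mean_pdui_b": mean_b.to_numpy(),
            "delta_pdui": delta.to_numpy(),
            "p_value": pvals,
            "fdr": fdr,
            "apa_class": apa_class,
            "m6a_status": m6a_status.reindex(pdui.index)
            .fillna(False)
            .to_numpy(dtype=bool),
        }
    )
    short = records["apa_class"] == "shortened"
    lng = records["apa_class"] == "lengthened"
    m6a = records["m6a_status"]
    table = np.array(
        [
            [int((short & m6a).sum()), int((short & ~m6a).sum())],
            [int((lng & m6a).sum()), int((lng & ~m6a).sum())],
        ]
    )
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    summary = {
        "n_shortened": int(short.sum()),
        "n_lengthened": int(lng.sum()),
        "fisher_odds_ratio": float(odds),
        "fisher_p": float(p),
        "contingency": table.tolist(),
    }
    return records, summary


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    return multipletests(pvals, method="fdr_bh")[1]
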