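"""m6A site calling from GLORI deamination count tables.

A position is called as an m6A site when it survives three filters jointly:
coverage (A+G reads) >= 15, unconverted A reads >= 5, and methylation level
(A / (A+G), the non-conversion rate) >= 0.10.  All three boundaries are
inclusive.  Conversion QC estimates the sample's deamination efficiency as
the median A-to-G conversion ratio over spike-in (known unmethylated)
positions and compares it against a 0.99 threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import Annotation, INTERGENIC, reverse_complement
from .errors import InputError, QCError
from .motifs import classify_motif

SiteKey = Tuple[str, int, str]


@dataclass(frozen=True)
class CallThresholds:
    """Site-calling filters; defaults follow the GLORI selection parameters."""

    min_coverage: int = 15
    min_a_reads: int = 5
    min_level: float = 0.10

    def __post_init__(self) -> None:
        if self.min_coverage < 0 or self.min_a_reads < 0 or self.min_level < 0:
            raise InputError("call thresholds must be nonnegative")


@dataclass(frozen=True)
class ConversionQC:
    sample_id: str
    median_conversion: float
    n_spikein_sites: int
    threshold: float

    @property
    def passed(self) -> bool:
        return self.median_conversion >= self.threshold

    def to_dict(self) -> Dict[str, object]:
        return {
            "sample_id": self.sample_id,
            "median_conversion": self.median_conversion,
            "n_spikein_sites": self.n_spikein_sites,
            "threshold": self.threshold,
            "pass": self.passed,
        }


def conversion_qc(
    counts: pd.DataFrame,
    spikein_sites: Iterable[SiteKey],
    threshold: float = 0.99,
    sample_id: str = "",
) -> ConversionQC:
    """Median A-to-G conversion ratio over covered spike-in positions."""
    keys = set(spikein_sites)
    if not keys:
        raise QCError("no spike-in sites provided")
    mask = [
        (c, p, s) in keys
        for c, p, s in zip(counts["contig"], counts["pos0"], counts["strand"])
    ]
    sub = counts.loc[mask]
    cov = sub["a_count"] + sub["g_count"]
    sub = sub.loc[cov > 0]
    if sub.empty:
        raise QCError("spike-in sites have no coverage; conversion undefined")
    conv = sub["g_count"] / (sub["a_count"] + sub["g_count"])
    return ConversionQC(
        sample_id=sample_id,
        median_conversion=float(conv.median()),
        n_spikein_sites=int(len(sub)),
        threshold=threshold,
    )


def call_sites(
    counts: pd.DataFrame, thresholds: CallThresholds = CallThresholds()
) -> pd.DataFrame:
    """Apply the three calling filters and return sorted site records."""
    if (counts["a_count"] < 0).any() or (counts["g_count"] < 0).any():
        raise InputError("negative counts in input table")
    df = counts.copy()
    df["coverage"] = df["a_count"] + df["g_count"]
    with np.errstate(invalid="ignore", divide="ignore"):
        df["level"] = np.where(
            df["coverage"] > 0, df["a_count"] / df["coverage"], 0.0
        )
    keep = (
        (df["coverage"] >= thresholds.min_coverage)
        & (df["a_count"] >= thresholds.min_a_reads)
        & (df["level"] >= thresholds.min_level)
    )
    out = df.loc[keep].sort_values(
        ["contig", "pos0", "strand"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def shared_sites(
    calls_by_sample: Dict[str, pd.DataFrame]
) -> Tuple[Set[SiteKey], pd.DataFrame]:
    """Intersection of per-sample call sets and detection-count strata.

    A site is keyed by (contig, pos0, strand); it is "shared" when called in
    every sample of the group, whatever the reason it failed elsewhere.  The
    strata table reports, for each detection count k, the number of sites and
    the median (over sites) of the mean per-sample coverage and level.
    """
    if not calls_by_sample:
        raise InputError("shared_sites requires at least one sample")
    n_samples = len(calls_by_sample)
    frames = []
    for sample, calls in calls_by_sample.items():
        f = calls[["contig", "pos0", "strand", "coverage", "level"]].copy()
        f["sample"] = sample
        frames.append(f)
    pooled = pd.concat(frames, ignore_index=True)
    grouped = pooled.groupby(["contig", "pos0", "strand"]).agg(
        k=("sample", "nunique"),
        mean_coverage=("coverage", "mean"),
        mean_level=("level", "mean"),
    )
    shared = {key for key, k in grouped["k"].items() if k == n_samples}
    strata = (
        grouped.groupby("k")
        .agg(
            n_sites=("k", "size"),
            median_coverage=("mean_coverage", "median"),
            median_level=("mean_level", "median"),
        )
        .reset_index()
        .sort_values("k")
        .reset_index(drop=True)
    )
    return shared, strata


def extract_pentamer(
    reference: Dict[str, str], contig: str, pos: int, strand: str
) -> str:
    """Strand-aware pentamer centered on a genomic position.

    Returns the 5-mer in transcript orientation (reverse complement for the
    minus strand).  Raises if the window runs off the contig.
    """
    seq = reference[contig]
    if pos - 2 < 0 or pos + 3 > len(seq):
        raise InputError(f"site {contig}:{pos} within 2 nt of contig edge")
    window = seq[pos - 2 : pos + 3]
    return reverse_complement(window) if strand == "-" else window


def annotate_sites(
    sites: pd.DataFrame, annotation: Annotation, reference: Dict[str, str]
) -> pd.DataFrame:
    """Attach pentamer, motif class, transcript and region to called sites.

    Sites within 2 nt of a contig edge (pentamer undefined) are dropped with
    a warning; sites outside any annotated transcript are labeled intergenic.
    """
    records = []
    n_dropped = 0
    for row in sites.itertuples(index=False):
        if row.contig not in reference:
            raise InputError(f"contig {row.contig} missing from reference")
        try:
            pentamer = extract_pentamer(
                reference, row.contig, row.pos0, row.strand
            )
        except InputError:
            n_dropped += 1
            continue
        model = annotation.locate(row.contig, row.pos0, row.strand)
        if model is None:
            transcript_id, region = "", INTERGENIC
        else:
            transcript_id = model.transcript_id
            region = model.region(model.to_transcript_pos(row.pos0))
        rec = row._asdict()
        rec.update(
            pentamer=pentamer,
            motif_class=classify_motif(pentamer),
            transcript_id=transcript_id,
            region=region,
        )
        records.append(rec)
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} site(s) within 2 nt of a contig edge",
            stacklevel=2,
        )
    if not records:
        return pd.DataFrame(
            columns=list(sites.columns)
            + ["pentamer", "motif_class", "transcript_id", "region"]
        )
    return pd.DataFrame.from_records(records)
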