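"""Synthetic GLORI study generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes, at the
count level (read alignment is upstream of the pipeline's contract):

* single-exon transcripts with UTR5/CDS/UTR3 segments on synthetic contigs,
  both strands represented, plus one unmethylated spike-in transcript;
* every planted m6A site carries a DRACH pentamer in transcript orientation;
* site positions concentrate around the stop codon (a mixture of a
  stop-proximal window and region-weighted uniform placement), reproducing
  the characteristic metagene peak;
* per-site methylation levels follow a two-component Beta mixture with modes
  near 20% and 95%;
* a configurable fraction of 3'-UTR sites inside a stop-codon window gain
  ``+hyper_delta`` in group B (focal hypermethylation); a fraction elsewhere
  lose the same amount (hypomethylation).  Gaining sites draw their baseline
  from the low-methylation component and losing sites from the high one, so
  the planted effect is realized instead of being destroyed by clipping to
  [0, 1] (clipping is still applied);
* observed counts: coverage ~ NegBin(mean proportional to TPM), unconverted
  A reads ~ Binomial(coverage, m + (1-m)(1-conversion_rate));
* group-B expression is shifted (unmethylated transcripts up, highly
  methylated transcripts down), producing the global methylation dilution;
* methylated transcripts shift their poly(A) site usage (PDUI) in group B.

Everything is driven by a single integer seed; identical configurations and
seeds reproduce byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .annotation import Annotation, TranscriptModel, reverse_complement, write_fasta
from .errors import ConfigurationError
from .integrate import tpm_from_counts
from . import tables

DRACH_PENTAMERS = [
    d + r + "A" + "C" + h for d in "AGT" for r in "AG" for h in "ACT"
]

GROUP_A = "A"
GROUP_B = "B"
SPIKEIN_ID = "spikein"


@dataclass(frozen=True)
class MethMixture:
    """Two-component Beta mixture for baseline site methylation levels."""

    weight_low: float = 0.6
    mean_low: float = 0.20
    mean_high: float = 0.95
    conc_low: float = 15.0
    conc_high: float = 30.0


@dataclass(frozen=True)
class DilutionScheme:
    """Group-B expression fold changes by transcript methylation class."""

    unmethylated_fc: float = 2.0
    high_fc: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    n_transcripts: int = 200
    utr5_len: int = 200
    cds_len: int = 900
    utr3_len: int = 600
    sites_per_transcript_mean: float = 4.0
    frac_unmethylated: float = 0.3
    background_sites_per_transcript: int = 8
    meth_mixture: MethMixture = field(default_factory=MethMixture)
    conversion_rate: float = 0.992
    coverage_mean_per_tpm: float = 0.02
    coverage_dispersion: float = 0.1
    n_samples_per_group: int = 9
    hyper_fraction_3utr: float = 0.6
    hyper_window_nt: int = 200
    hyper_delta: float = 0.20
    hypo_fraction: float = 0.05
    dilution_scheme: DilutionScheme = field(default_factory=DilutionScheme)
    pdui_effect: float = -0.2
    pdui_lengthen_fraction: float = 0.25
    pdui_noise_sd: float = 0.03
    tpm_lognorm_sigma: float = 1.5
    expr_count_per_tpm_nt: float = 5e-4
    expr_dispersion: float = 0.05
    stop_weight: float = 0.35
    stop_window_nt: int = 150
    region_weights: Tuple[float, float, float] = (0.08, 0.50, 0.42)
    spikein_utr5: int = 50
    spikein_cds: int = 150
    spikein_utr3: int = 100
    spikein_coverage_mean: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0:
            raise ConfigurationError("n_transcripts must be nonnegative")
        if min(self.utr5_len, self.cds_len, self.utr3_len) <= 0:
            raise ConfigurationError("segment lengths must be positive")
        if self.cds_len % 3 != 0:
            raise ConfigurationError("cds_len must be divisible by 3")
        for name in (
            "frac_unmethylated",
            "hyper_fraction_3utr",
            "hyper_delta",
            "hypo_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if not 0.9 < self.conversion_rate <= 1.0:
            raise ConfigurationError("conversion_rate must be in (0.9, 1]")
        if self.n_samples_per_group < 1:
            raise ConfigurationError("need at least one sample per group")

    @property
    def transcript_length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len


@dataclass
class SimTruth:
    """Planted ground truth: per-site levels/classes, per-transcript state."""

    sites: pd.DataFrame
    transcripts: pd.DataFrame

    def spikein_site_keys(self) -> List[Tuple[str, int, str]]:
        sub = self.sites[self.sites["is_spikein"]]
        return list(zip(sub["contig"], sub["pos0"], sub["strand"]))

    def to_json(self, path: str) -> None:
        obj = {
            "sites": self.sites.to_dict(orient="list"),
            "transcripts": self.transcripts.to_dict(orient="list"),
        }
        tables.write_json(obj, path)

    @classmethod
    def from_json(cls, path: str) -> "SimTruth":
        obj = tables.read_json(path)
        return cls(
            sites=pd.DataFrame(obj["sites"]),
            transcripts=pd.DataFrame(obj["transcripts"]),
        )


@dataclass
class SimData:
    """Simulated observables: count, expression, and PDUI tables."""

    counts: Dict[str, pd.DataFrame]
    expression_counts: pd.DataFrame
    tpm: pd.DataFrame
    pdui: pd.DataFrame
    sample_groups: Dict[str, str]

    @property
    def samples(self) -> List[str]:
        return list(self.counts)


# --------------------------------------------------------------------------
# stage 1: annotation + reference
# --------------------------------------------------------------------------
def _draw_site_positions(
    config: SimConfig, n_sites: int, rng: np.random.Generator
) -> List[int]:
    """Stop-codon-enriched site positions with >=5 nt spacing."""
    length = config.transcript_length
    stop = config.utr5_len + config.cds_len  # transcript pos of first UTR3 base
    starts = (0, config.utr5_len, stop)
    lens = (config.utr5_len, config.cds_len, config.utr3_len)
    weights = np.asarray(config.region_weights, dtype=float)
    weights = weights / weights.sum()
    chosen: List[int] = []
    attempts = 0
    while len(chosen) < n_sites and attempts < 200 * max(n_sites, 1):
        attempts += 1
        if rng.random() < config.stop_weight:
            # triangular offset peaked at the junction: the metagene density
            # crests right at the stop codon
            pos = stop + int(
                round(
                    rng.triangular(
                        -config.stop_window_nt, 0.0, config.stop_window_nt
                    )
                )
            )
        else:
            region = rng.choice(3, p=weights)
            pos = starts[region] + int(rng.integers(0, lens[region]))
        if not 2 <= pos <= length - 3:
            continue
        if all(abs(pos - other) >= 5 for other in chosen):
            chosen.append(pos)
    return sorted(chosen)


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(np.array(list("ACGT")), size=length)


def generate_annotation(
    config: SimConfig,
) -> Tuple[Dict[str, str], Annotation, pd.DataFrame]:
    """Build reference contigs, transcript models, and planted site positions.

    Returns ``(reference, annotation, planted)`` where ``planted`` lists one
    row per emitted site position (methylated candidates with a DRACH
    pentamer written into the reference, unmethylated background positions,
    and the spike-in positions).
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    reference: Dict[str, str] = {}
    models: List[TranscriptModel] = []
    rows: List[dict] = []

    for i in range(config.n_transcripts):
        tid = f"tx{i:04d}"
        contig = f"chr_{tid}"
        strand = "+" if i % 2 == 0 else "-"
        length = config.transcript_length
        tx_seq = _random_sequence(length, rng)

        methylated = rng.random() >= config.frac_unmethylated
        n_sites = (
            int(rng.poisson(config.sites_per_transcript_mean)) if methylated else 0
        )
        site_positions = _draw_site_positions(config, n_sites, rng)
        for tpos in site_positions:
            pentamer = DRACH_PENTAMERS[int(rng.integers(len(DRACH_PENTAMERS)))]
            tx_seq[tpos - 2 : tpos + 3] = list(pentamer)

        # unmethylated background adenosines emitted in the count tables
        candidates = [
            t
            for t in range(2, length - 2)
            if tx_seq[t] == "A"
            and all(abs(t - s) >= 3 for s in site_positions)
        ]
        n_bg = min(config.background_sites_per_transcript, len(candidates))
        background = sorted(
            int(t) for t in rng.choice(candidates, size=n_bg, replace=False)
        ) if n_bg else []

        model = TranscriptModel(
            transcript_id=tid,
            contig=contig,
            strand=strand,
            tx_start=0,
            utr5_len=config.utr5_len,
            cds_len=config.cds_len,
            utr3_len=config.utr3_len,
        )
        tx_str = "".join(tx_seq)
        reference[contig] = tx_str if strand == "+" else reverse_complement(tx_str)
        models.append(model)
        for tpos in site_positions:
            rows.append(
                dict(
                    transcript_id=tid,
                    contig=contig,
                    pos0=model.to_genomic_pos(tpos),
                    strand=strand,
                    tpos=tpos,
                    region=model.region(tpos),
                    is_spikein=False,
                    is_background=False,
                )
            )
        for tpos in background:
            rows.append(
                dict(
                    transcript_id=tid,
                    contig=contig,
                    pos0=model.to_genomic_pos(tpos),
                    strand=strand,
                    tpos=tpos,
                    region=model.region(tpos),
                    is_spikein=False,
                    is_background=True,
                )
            )

    # spike-in: an unmethylated transcript; every interior adenosine reports
    # the deamination efficiency
    spike_len = config.spikein_utr5 + config.spikein_cds + config.spikein_utr3
    spike_seq = _random_sequence(spike_len, rng)
    spike_model = TranscriptModel(
        transcript_id=SPIKEIN_ID,
        contig=SPIKEIN_ID,
        strand="+",
        tx_start=0,
        utr5_len=config.spikein_utr5,
        cds_len=config.spikein_cds,
        utr3_len=config.spikein_utr3,
    )
    reference[SPIKEIN_ID] = "".join(spike_seq)
    models.append(spike_model)
    for tpos in range(2, spike_len - 2):
        if spike_seq[tpos] == "A":
            rows.append(
                dict(
                    transcript_id=SPIKEIN_ID,
                    contig=SPIKEIN_ID,
                    pos0=tpos,
                    strand="+",
                    tpos=tpos,
                    region=spike_model.region(tpos),
                    is_spikein=True,
                    is_background=False,
                )
            )

    planted = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "contig", "pos0", "strand", "tpos",
            "region", "is_spikein", "is_background",
        ],
    )
    planted.insert(0, "site_id", [f"site{i:06d}" for i in range(len(planted))])
    return reference, Annotation(models), planted


# --------------------------------------------------------------------------
# stage 2: ground truth levels, classes, expression, PDUI
# --------------------------------------------------------------------------
def _beta_draw(
    mean: float, conc: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.beta(mean * conc, (1.0 - mean) * conc, size=size)


def plant_truth(
    annotation: Annotation, planted: pd.DataFrame, config: SimConfig
) -> SimTruth:
    """Assign true methylation levels, group effects, expression and PDUI."""
    rng = np.random.default_rng([config.rng_seed, 2])
    mix = config.meth_mixture
    sites = planted.copy()
    n = len(sites)

    meth_candidate = (~sites["is_spikein"] & ~sites["is_background"]).to_numpy()
    high_component = rng.random(n) >= mix.weight_low
    level_a = np.where(
        high_component,
        _beta_draw(mix.mean_high, mix.conc_high, n, rng),
        _beta_draw(mix.mean_low, mix.conc_low, n, rng),
    )
    level_a[~meth_candidate] = 0.0

    stop_offsets = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    for idx, row in enumerate(sites.itertuples(index=False)):
        model = annotation.transcripts[row.transcript_id]
        stop_offsets[idx] = model.stop_offset(row.tpos)

    in_window = (
        meth_candidate
        & (sites["region"].to_numpy() == "UTR3")
        & (stop_offsets >= 0)
        & (stop_offsets < config.hyper_window_nt)
    )
    is_hyper = in_window & (rng.random(n) < config.hyper_fraction_3utr)
    is_hypo = (
        meth_candidate
        & ~is_hyper
        & (rng.random(n) < config.hypo_fraction)
    )
    # hyper sites start low, hypo sites start high, so the planted shift
    # survives the clip to [0, 1]
    n_hyper = int(is_hyper.sum())
    n_hypo = int(is_hypo.sum())
    if n_hyper:
        level_a[is_hyper] = _beta_draw(mix.mean_low, mix.conc_low, n_hyper, rng)
    if n_hypo:
        level_a[is_hypo] = _beta_draw(mix.mean_high, mix.conc_high, n_hypo, rng)

    level_b = level_a.copy()
    level_b[is_hyper] = np.clip(level_b[is_hyper] + config.hyper_delta, 0.0, 1.0)
    level_b[is_hypo] = np.clip(level_b[is_hypo] - config.hyper_delta, 0.0, 1.0)

    sites["level_a"] = level_a
    sites["level_b"] = level_b
    sites["planted_class"] = np.select(
        [is_hyper, is_hypo], ["hyper", "hypo"], default="unchanged"
    )

    # ---------------------------------------------------- transcript truth
    tx_rows = []
    meth_sites = sites[meth_candidate]
    agg = meth_sites.groupby("transcript_id")["level_a"].agg(["sum", "size"])
    for model in sorted(annotation, key=lambda m: m.transcript_id):
        tid = model.transcript_id
        if tid == SPIKEIN_ID:
            continue
        aggregate = float(agg["sum"].get(tid, 0.0))
        n_meth = int(agg["size"].get(tid, 0))
        if n_meth == 0:
            meth_class = "unmethylated"
        elif aggregate > 2.0:
            meth_class = "high"
        else:
            meth_class = "low"
        tx_rows.append(
            dict(
                transcript_id=tid,
                contig=model.contig,
                strand=model.strand,
                length=model.length,
                n_meth_sites=n_meth,
                aggregate_a=aggregate,
                meth_class=meth_class,
            )
        )
    transcripts = pd.DataFrame(tx_rows)

    if len(transcripts):
        base_weight = rng.lognormal(
            mean=0.0, sigma=config.tpm_lognorm_sigma, size=len(transcripts)
        )
        tpm_a = base_weight / base_weight.sum() * 1e6
        fc = np.select(
            [
                transcripts["meth_class"] == "unmethylated",
                transcripts["meth_class"] == "high",
            ],
            [
                config.dilution_scheme.unmethylated_fc,
                config.dilution_scheme.high_fc,
            ],
            default=1.0,
        )
        weight_b = base_weight * fc
        tpm_b = weight_b / weight_b.sum() * 1e6
        pdui_a = rng.uniform(0.4, 0.9, size=len(transcripts))
        methylated = (transcripts["meth_class"] != "unmethylated").to_numpy()
        lengthen = ~methylated & (
            rng.random(len(transcripts)) < config.pdui_lengthen_fraction
        )
        pdui_shift = np.where(
            methylated, config.pdui_effect, 0.0
        ) + np.where(lengthen, -config.pdui_effect, 0.0)
        pdui_b = np.clip(pdui_a + pdui_shift, 0.0, 1.0)
        transcripts["tpm_a"] = tpm_a
        transcripts["tpm_b"] = tpm_b
        transcripts["pdui_a"] = pdui_a
        transcripts["pdui_b"] = pdui_b
    else:
        for col in ("tpm_a", "tpm_b", "pdui_a", "pdui_b"):
            transcripts[col] = pd.Series(dtype=float)

    return SimTruth(sites=sites, transcripts=transcripts)


# --------------------------------------------------------------------------
# stage 3: observed counts
# --------------------------------------------------------------------------
def _negbin(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB draws parametrized by mean and dispersion (var = mu + phi mu^2)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    positive = mean > 0
    if dispersion <= 0:
        out[positive] = rng.poisson(mean[positive])
        return out
    size = 1.0 / dispersion
    p = size / (size + mean[positive])
    out[positive] = rng.negative_binomial(size, p)
    return out


def simulate_counts(truth: SimTruth, config: SimConfig) -> SimData:
    """Draw per-sample count, expression, and PDUI tables from the truth."""
    rng = np.random.default_rng([config.rng_seed, 3])
    n_per_group = config.n_samples_per_group
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    sample_groups = {
        s: (GROUP_A if s.startswith("A") else GROUP_B) for s in samples
    }

    sites = truth.sites
    tx = truth.transcripts.set_index("transcript_id")
    tpm_by_group = {GROUP_A: tx["tpm_a"], GROUP_B: tx["tpm_b"]}
    level_by_group = {
        GROUP_A: sites["level_a"].to_numpy(),
        GROUP_B: sites["level_b"].to_numpy(),
    }
    is_spike = sites["is_spikein"].to_numpy()
    site_tx = sites["transcript_id"].to_numpy()
    failure = 1.0 - config.conversion_rate

    counts: Dict[str, pd.DataFrame] = {}
    for sample in samples:
        group = sample_groups[sample]
        tpm = tpm_by_group[group]
        cov_mean = np.where(
            is_spike,
            config.spikein_coverage_mean,
            config.coverage_mean_per_tpm
            * np.array([tpm.get(t, 0.0) for t in site_tx]),
        )
        coverage = _negbin(cov_mean, config.coverage_dispersion, rng)
        m = level_by_group[group]
        p_obs = m + (1.0 - m) * failure
        a_count = rng.binomial(coverage, p_obs)
        counts[sample] = pd.DataFrame(
            {
                "contig": sites["contig"],
                "pos0": sites["pos0"],
                "strand": sites["strand"],
                "a_count": a_count,
                "g_count": coverage - a_count,
            }
        )

    expr = pd.DataFrame({"transcript_id": tx.index})
    pdui = pd.DataFrame({"transcript_id": tx.index})
    lengths = tx["length"].to_numpy(dtype=float)
    for sample in samples:
        group = sample_groups[sample]
        tpm = tpm_by_group[group].to_numpy()
        expr[sample] = _negbin(
            config.expr_count_per_tpm_nt * tpm * lengths,
            config.expr_dispersion,
            rng,
        )
        true_pdui = (
            tx["pdui_a"] if group == GROUP_A else tx["pdui_b"]
        ).to_numpy()
        pdui[sample] = np.clip(
            true_pdui + rng.normal(0.0, config.pdui_noise_sd, size=len(tx)),
            0.0,
            1.0,
        )

    tpm_table = tpm_from_counts(
        expr.set_index("transcript_id"), tx["length"]
    ).reset_index()
    return SimData(
        counts=counts,
        expression_counts=expr,
        tpm=tpm_table,
        pdui=pdui,
        sample_groups=sample_groups,
    )


def simulate_dataset(
    config: SimConfig,
) -> Tuple[Dict[str, str], Annotation, SimTruth, SimData]:
    """Run all three generator stages for one configuration."""
    reference, annotation, planted = generate_annotation(config)
    truth = plant_truth(annotation, planted, config)
    data = simulate_counts(truth, config)
    return reference, annotation, truth, data


def write_dataset(
    outdir: str,
    reference: Dict[str, str],
    annotation: Annotation,
    truth: SimTruth,
    data: SimData,
) -> None:
    """Serialize a simulated study to a directory of plain-text files."""
    os.makedirs(outdir, exist_ok=True)
    write_fasta(reference, os.path.join(outdir, "reference.fa"))
    annotation.to_gtf(os.path.join(outdir, "annotation.gtf"))
    annotation.to_bed12(os.path.join(outdir, "annotation.bed12"))
    for sample, df in data.counts.items():
        tables.write_counts(df, os.path.join(outdir, f"counts_{sample}.tsv"))
    tables.write_table(
        data.expression_counts, os.path.join(outdir, "expression.tsv")
    )
    tables.write_table(data.tpm, os.path.join(outdir, "tpm.tsv"))
    tables.write_table(data.pdui, os.path.join(outdir, "pdui.tsv"))
    truth.to_json(os.path.join(outdir, "truth.json"))
    tables.write_json(
        {"sample_groups": data.sample_groups},
        os.path.join(outdir, "samples.json"),
    )


# --------------------------------------------------------------------------
# direct beta-binomial site sampler (test-bench for the differential model)
# --------------------------------------------------------------------------
def simulate_betabinomial_sites(
    pi_a: float,
    pi_b: float,
    phi: float,
    coverage: int,
    n_per_group: int,
    n_sites: int,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site beta-binomial counts for two groups.

    ``phi`` is the intra-class correlation; sample-level methylation
    probabilities are Beta with mean pi and concentration (1-phi)/phi, and
    counts are Binomial(coverage, p).  Returns (a_A, n_A, a_B, n_B) arrays of
    shape (n_sites, n_per_group).
    """
    shape = (n_sites, n_per_group)

    def draw(pi: float) -> np.ndarray:
        if phi <= 0:
            p = np.full(shape, pi)
        else:
            theta = (1.0 - phi) / phi
            p = rng.beta(pi * theta, (1.0 - pi) * theta, size=shape)
        return rng.binomial(coverage, p)

    a_a = draw(pi_a)
    a_b = draw(pi_b)
    n = np.full(shape, coverage, dtype=np.int64)
    return a_a, n.copy(), a_b, n.copy()
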