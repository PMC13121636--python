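"""End-to-end orchestration: simulate/load -> QC -> call -> motif -> diff ->
integrate -> positional, with a deterministic report bundle.

Identical configuration + seed reproduce byte-identical outputs: all
randomness flows from the single seed, tables serialize with a fixed float
format, and JSON is written with sorted keys.  Every threshold actually
applied is logged and recorded in the report for audit parity.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import calling, diffmeth, integrate, motifs, positional, tables
from . import simulate as sim_mod
from .annotation import Annotation, read_fasta
from .errors import ConfigurationError, PipelineError, QCError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "glori_run"
    seed: int = 0
    log_level: str = "INFO"
    simulate: Optional[sim_mod.SimConfig] = field(
        default_factory=sim_mod.SimConfig
    )
    inputs: Optional[Dict[str, Any]] = None  # file mode: paths + groups
    spikein_contig: str = sim_mod.SPIKEIN_ID
    # thresholds (defaults reproduce the published procedure)
    min_coverage: int = 15
    min_a_reads: int = 5
    min_level: float = 0.10
    qc_conversion: float = 0.99
    min_delta: float = 0.10
    alpha: float = 0.05
    min_coverage_per_sample: int = 15
    top_k: int = 500
    high_aggregate: float = 2.0
    apa_delta: float = 0.1
    apa_fdr: float = 0.05
    metagene_bins: int = 90
    stop_window: int = 400
    stop_bin: int = 20

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulate", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulate"})
        if sim_raw is None and cfg.inputs is None:
            raise ConfigurationError(
                "config must define either 'simulate' or 'inputs'"
            )
        if sim_raw is not None:
            mixture = sim_mod.MethMixture(**sim_raw.pop("meth_mixture", {}))
            scheme = sim_mod.DilutionScheme(**sim_raw.pop("dilution_scheme", {}))
            cfg.simulate = sim_mod.SimConfig(
                meth_mixture=mixture, dilution_scheme=scheme, **sim_raw
            )
        else:
            cfg.simulate = None
        return cfg

    def validate(self) -> None:
        if self.inputs is not None:
            groups = self.inputs.get("groups")
            counts = self.inputs.get("counts")
            if not counts:
                raise ConfigurationError("inputs mode requires 'counts' paths")
            if not groups:
                raise ConfigurationError("inputs mode requires 'groups'")
            for sample in counts:
                if sample not in groups:
                    raise ConfigurationError(
                        f"sample {sample!r} has no group label"
                    )
            for sample, g in groups.items():
                if g not in ("A", "B"):
                    raise ConfigurationError(
                        f"group of {sample!r} must be 'A' or 'B', got {g!r}"
                    )
        elif self.simulate is None:
            raise ConfigurationError("neither simulation nor inputs configured")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Execute all stages; write the output bundle; return the report."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    os.makedirs(config.outdir, exist_ok=True)
    report: Dict[str, Any] = {
        "seed": config.seed,
        "thresholds": {
            "min_coverage": config.min_coverage,
            "min_a_reads": config.min_a_reads,
            "min_level": config.min_level,
            "qc_conversion": config.qc_conversion,
            "min_delta": config.min_delta,
            "alpha": config.alpha,
            "min_coverage_per_sample": config.min_coverage_per_sample,
            "high_aggregate": config.high_aggregate,
            "top_k": config.top_k,
            "apa_delta": config.apa_delta,
            "apa_fdr": config.apa_fdr,
        },
    }
    logger.info("thresholds applied: %s", report["thresholds"])

    # ------------------------------------------------------------ inputs
    with _stage("simulate/load"):
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, rng_seed=config.seed)
            reference, annotation, truth, data = sim_mod.simulate_dataset(sim_cfg)
            simdir = os.path.join(config.outdir, "sim")
            sim_mod.write_dataset(simdir, reference, annotation, truth, data)
            counts_by_sample = data.counts
            sample_groups = data.sample_groups
            expression = data.expression_counts.set_index("transcript_id")
            tpm = data.tpm.set_index("transcript_id")
            pdui = data.pdui.set_index("transcript_id")
            spikein_keys = truth.spikein_site_keys()
        else:
            paths = config.inputs
            reference = read_fasta(paths["reference"])
            annot_path = paths["annotation"]
            annotation = (
                Annotation.from_bed12(annot_path)
                if annot_path.endswith((".bed", ".bed12"))
                else Annotation.from_gtf(annot_path)
            )
            counts_by_sample = {
                s: tables.read_counts(p) for s, p in paths["counts"].items()
            }
            sample_groups = dict(paths["groups"])
            expression = tables.read_table(paths["expression"]).set_index(
                "transcript_id"
            )
            tpm = tables.read_table(paths["tpm"]).set_index("transcript_id")
            pdui = (
                tables.read_table(paths["pdui"]).set_index("transcript_id")
                if paths.get("pdui")
                else None
            )
            any_counts = next(iter(counts_by_sample.values()))
            spike = any_counts[any_counts["contig"] == config.spikein_contig]
            spikein_keys = list(
                zip(spike["contig"], spike["pos0"], spike["strand"])
            )

    samples = sorted(counts_by_sample)
    group_of = {g: [s for s in samples if sample_groups[s] == g] for g in "AB"}

    # ---------------------------------------------------------------- QC
    with _stage("conversion_qc"):
        qc_results = {}
        for sample in samples:
            try:
                qc = calling.conversion_qc(
                    counts_by_sample[sample],
                    spikein_keys,
                    threshold=config.qc_conversion,
                    sample_id=sample,
                )
                qc_results[sample] = qc.to_dict()
            except QCError as exc:
                qc_results[sample] = {"sample_id": sample, "error": str(exc)}
        tables.write_json(qc_results, os.path.join(config.outdir, "qc.json"))
        report["qc"] = qc_results

    # ------------------------------------------------------- site calling
    with _stage("call_sites"):
        thresholds = calling.CallThresholds(
            config.min_coverage, config.min_a_reads, config.min_level
        )
        annotated_calls: Dict[str, pd.DataFrame] = {}
        for sample in samples:
            called = calling.call_sites(counts_by_sample[sample], thresholds)
            called = called[called["contig"] != config.spikein_contig]
            annotated_calls[sample] = calling.annotate_sites(
                called, annotation, reference
            )
            tables.write_table(
                annotated_calls[sample],
                os.path.join(config.outdir, f"sites_{sample}.tsv"),
            )
        report["n_called_sites"] = {
            s: int(len(df)) for s, df in annotated_calls.items()
        }

    with _stage("shared_sites"):
        shared_info = {}
        for g in "AB":
            shared, strata = calling.shared_sites(
                {s: annotated_calls[s] for s in group_of[g]}
            )
            tables.write_table(
                strata, os.path.join(config.outdir, f"strata_{g}.tsv")
            )
            shared_info[g] = {"n_shared": len(shared)}
        report["shared_sites"] = shared_info

    # ---------------------------------------------------- motif analysis
    with _stage("motif_analysis"):
        pooled = pd.concat(annotated_calls.values(), ignore_index=True)
        pooled_unique = (
            pooled.groupby(["contig", "pos0", "strand"])
            .agg(
                level=("level", "mean"),
                pentamer=("pentamer", "first"),
                motif_class=("motif_class", "first"),
                transcript_id=("transcript_id", "first"),
                region=("region", "first"),
            )
            .reset_index()
        )
        freq, class_levels, top = motifs.motif_summary(pooled_unique)
        tables.write_table(
            freq, os.path.join(config.outdir, "motif_summary.tsv")
        )
        tables.write_table(
            motifs.position_frequency_matrix(pooled_unique).reset_index(
                names="base"
            ),
            os.path.join(config.outdir, "position_frequency_matrix.tsv"),
        )
        class_counts = (
            pooled_unique["motif_class"].value_counts().to_dict()
        )
        tables.write_json(
            {k: int(v) for k, v in sorted(class_counts.items())},
            os.path.join(config.outdir, "class_counts.json"),
        )
        n_total = max(len(pooled_unique), 1)
        report["motif"] = {
            "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
            "drac_fraction": float(
                pooled_unique["motif_class"].isin(motifs.DRAC_CLASSES).sum()
                / n_total
            ),
        }

    # ------------------------------------------- differential methylation
    with _stage("differential_methylation"):
        universe = diffmeth.build_test_universe(
            counts_by_sample,
            annotation,
            reference,
            min_coverage_per_sample=config.min_coverage_per_sample,
        )
        universe = universe[universe["contig"] != config.spikein_contig]
        sd_table, sd_summary = diffmeth.sd_threshold_report(
            universe, sample_groups
        ) if min(len(group_of["A"]), len(group_of["B"])) >= 2 else (None, {})
        if sd_table is not None:
            tables.write_json(
                sd_summary, os.path.join(config.outdir, "sd_report.json")
            )
        diff = diffmeth.test_differential(universe, sample_groups)
        diff = diffmeth.classify_differential(
            diff,
            diffmeth.DiffThresholds(
                config.min_delta, config.alpha, config.min_coverage_per_sample
            ),
        )
        tables.write_table(
            diff, os.path.join(config.outdir, "diff_sites.tsv")
        )
        tx_classes = diffmeth.classify_transcripts(diff)
        tables.write_table(
            tx_classes, os.path.join(config.outdir, "transcript_classes.tsv")
        )
        report["differential"] = {
            "n_universe": int(len(universe)),
            "n_hyper_sites": int((diff["direction"] == "hyper").sum()),
            "n_hypo_sites": int((diff["direction"] == "hypo").sum()),
            "transcript_classes": {
                k: int(v)
                for k, v in sorted(
                    tx_classes["class"].value_counts().to_dict().items()
                )
            },
            "sd_summary": sd_summary,
        }

    # -------------------------------------------------------- integration
    with _stage("integration"):
        expressed = integrate.filter_expressed(expression)
        tpm_expressed = tpm.loc[tpm.index.intersection(expressed)]

        # per-sample transcript aggregates from that sample's DRAC calls
        w_rows = []
        control_aggs = []
        for sample in samples:
            drac_calls = motifs.restrict_to_drac(annotated_calls[sample])
            agg = integrate.aggregate_methylation(
                drac_calls, high_threshold=config.high_aggregate
            )
            if sample_groups[sample] == "A":
                control_aggs.append(
                    agg.set_index("transcript_id")["aggregate"]
                )
            w_rows.append((sample, agg))
        w_records = []
        for sample, agg in w_rows:
            per_sample, _ = integrate.weighted_global_methylation(
                agg, tpm[[sample]], sample_groups
            )
            w_records.append(per_sample.iloc[0])
        w_table = pd.DataFrame(w_records).reset_index(drop=True)
        from scipy import stats as _stats

        wa = w_table.loc[w_table["group"] == "A", "W"]
        wb = w_table.loc[w_table["group"] == "B", "W"]
        t_res = _stats.ttest_ind(wa, wb)
        tables.write_table(
            w_table, os.path.join(config.outdir, "weighted_methylation.tsv")
        )
        report["weighted_methylation"] = {
            "mean_W_A": float(wa.mean()),
            "mean_W_B": float(wb.mean()),
            "t_p_value": float(t_res.pvalue),
        }

        # control-side transcript classification for stratification and APA
        mean_control_agg = (
            pd.concat(control_aggs, axis=1).fillna(0.0).mean(axis=1)
            if control_aggs
            else pd.Series(dtype=float)
        )
        known = mean_control_agg.reindex(tpm.index).fillna(0.0)
        meth_class = pd.Series(
            np.select(
                [known > config.high_aggregate, known > 0],
                ["high", "low"],
                default="unmethylated",
            ),
            index=tpm.index,
            name="meth_class",
        )

        k50s = {}
        for g in "AB":
            mean_tpm = tpm[group_of[g]].mean(axis=1)
            curve, k50 = integrate.cumulative_abundance(mean_tpm)
            k50s[g] = k50
        report["k50"] = k50s

        log2fc = integrate.naive_log2fc(tpm_expressed, sample_groups)
        strat = integrate.stratified_expression_shift(
            log2fc,
            meth_class,
            tpm_expressed.mean(axis=1),
            top_k=config.top_k,
        )
        tables.write_table(
            strat, os.path.join(config.outdir, "stratified_fc.tsv")
        )
        report["stratified_fc"] = {
            f"{r.subset}/{r.meth_class}": float(r.median_log2fc)
            for r in strat.itertuples(index=False)
        }

        # PCA on the universe level matrix and on differential sites
        level_matrix = pd.DataFrame(
            {
                s: universe[f"a_{s}"] / universe[f"n_{s}"]
                for s in samples
            }
        )
        pca_all, sil_all = integrate.pca_separation(level_matrix, sample_groups)
        diff_dir_keys = set(
            zip(*(diff.loc[diff["direction"] != "none", c]
                  for c in ("contig", "pos0", "strand")))
        ) if (diff["direction"] != "none").any() else set()
        diff_mask = [
            key in diff_dir_keys
            for key in zip(universe["contig"], universe["pos0"], universe["strand"])
        ]
        if any(diff_mask):
            _, sil_diff = integrate.pca_separation(
                level_matrix.loc[diff_mask], sample_groups
            )
        else:
            sil_diff = sil_all
        tables.write_table(pca_all, os.path.join(config.outdir, "pca.tsv"))
        report["pca"] = {
            "silhouette_all_sites": sil_all,
            "silhouette_diff_sites": sil_diff,
        }

        if pdui is not None:
            m6a_status = meth_class.reindex(pdui.index) != "unmethylated"
            apa_records, apa_summary = integrate.apa_association(
                pdui,
                sample_groups,
                m6a_status,
                delta_threshold=config.apa_delta,
                fdr_threshold=config.apa_fdr,
            )
            tables.write_table(
                apa_records, os.path.join(config.outdir, "apa.tsv")
            )
            report["apa"] = apa_summary

    # --------------------------------------------------------- positional
    with _stage("positional"):
        drac_pooled = motifs.restrict_to_drac(pooled_unique)
        on_tx = drac_pooled[drac_pooled["transcript_id"] != ""]
        x = positional.metagene_coordinate(on_tx, annotation)
        density = positional.metagene_density(x, n_bins=config.metagene_bins)
        tables.write_table(
            density, os.path.join(config.outdir, "metagene.tsv")
        )
        modal = density.loc[density["density"].idxmax()]
        report["metagene_modal_x"] = float(modal["x_mid"])

        diff_dir = diff[diff["direction"] != "none"]
        profile = positional.stop_codon_profile(
            diff_dir, annotation, window=config.stop_window,
            bin_width=config.stop_bin,
        )
        tables.write_table(
            profile, os.path.join(config.outdir, "stop_profile.tsv")
        )

    tables.write_json(report, os.path.join(config.outdir, "report.json"))
    return report
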