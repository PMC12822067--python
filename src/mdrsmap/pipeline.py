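"""End-to-end orchestration: data -> preprocessing -> inference -> analyses.

``run_pipeline`` executes the stages in order, writes every intermediate
artifact plus a machine-readable manifest and a plain-text summary into the
output directory, and is bit-for-bit reproducible under a fixed config and
seed.  Stage failures abort with the failing stage named and leave a FAILED
marker next to any partial outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import context as ctx
from . import metrics as met
from .config import PipelineConfig, stage_seed
from .io import (
    align_temperature,
    read_abundance_table,
    read_temperature,
    write_abundance_table,
    write_temperature,
)
from .model import MDRSMap
from .preprocess import bin_auxiliary, bin_series, filter_common_taxa, select_bin_width
from .simulate import observe, simulate_community

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _fmt(x) -> str:
    return "NA" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:.4f}"


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stage = "setup"
    try:
        # ---- stage: data ------------------------------------------------
        stage = "data"
        if config.synthetic is not None:
            syn = config.synthetic
            params = syn.community_params(stage_seed(config.seed, "synthetic"))
            ds = simulate_community(params, syn.n_steps, burn_in=syn.burn_in)
            table = observe(
                ds,
                sample_interval=syn.sample_interval,
                missing_fraction=syn.missing_fraction,
                seed=stage_seed(config.seed, "observe"),
                relative=syn.relative,
            )
            dates = ds.dates()
            temperature = pd.Series(ds.temperature, index=dates, name="temp_C")
        else:
            table = read_abundance_table(config.abundance_path)
            temperature = read_temperature(config.temperature_path)
        write_abundance_table(table, outdir / "abundance.tsv")
        write_temperature(temperature, outdir / "temperature.csv")
        logger.info("data stage: %d taxa, %d samples", *table.shape)

        # ---- stage: preprocess ------------------------------------------
        stage = "preprocess"
        prep = config.preprocessing
        filtered = filter_common_taxa(
            table,
            detection=prep.detection,
            occupancy=prep.occupancy,
            detection_mode=prep.detection_mode,
        )
        width = select_bin_width(filtered.columns, prep.bin_candidates)
        binned = bin_series(filtered, width, aggregator=prep.aggregator)
        daily_temp = align_temperature(temperature, filtered.columns)
        temp_binned = bin_auxiliary(daily_temp, binned)
        binned.values.to_csv(outdir / "binned.tsv", sep="\t")
        logger.info(
            "preprocess stage: %d taxa retained, %d bins of %d days",
            len(filtered), binned.values.shape[1], width,
        )

        # ---- stage: infer -----------------------------------------------
        stage = "infer"
        model = MDRSMap(
            binned,
            temperature=temp_binned.to_numpy(),
            config=config.mdr.replace(seed=stage_seed(config.seed, "infer")),
        )
        res = model.fit()
        tensor = res.interactions
        tensor.save(outdir / "interactions.tsv.gz", outdir / "diagnostics.tsv")
        logger.info("infer stage: %d targets failed", int(tensor.diagnostics["failed"].sum()))

        # ---- stage: metrics ---------------------------------------------
        stage = "metrics"
        mcfg = config.metrics
        thresholds = res.thresholds(mcfg.strength_threshold, mcfg.occurrence_threshold)
        classification = met.classify_pairs(tensor, thresholds)
        mean_relabund = table.loc[binned.taxon_ids].mean(axis=1)
        tmetrics = met.taxon_metrics(
            classification, tensor.taxon_ids,
            orientation=mcfg.orientation, mean_relabund=mean_relabund,
        )
        tmetrics = met.select_keystones(tmetrics, fraction=mcfg.keystone_fraction)
        classification.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        tmetrics.to_csv(outdir / "taxon_metrics.tsv", sep="\t")
        (outdir / "thresholds.json").write_text(
            json.dumps({"strength": thresholds[0], "occurrence": thresholds[1]}, indent=2)
        )
        sign_frac = (
            100.0
            * classification["sign"].value_counts(normalize=True)
            .reindex(["positive", "negative", "neutral"]).fillna(0.0)
        )
        try:
            pooled = tensor.valid_taxa_values()
            off = ~np.eye(tensor.n_taxa, dtype=bool)
            nz = pooled[:, off]
            dist = met.distribution_stats(nz[nz != 0])
        except ValueError:
            dist = None

        # ---- stage: context ---------------------------------------------
        stage = "context"
        valid_temp = temp_binned.to_numpy()[tensor.valid_time_indices]
        labels = ctx.bin_temperature(valid_temp)
        summary_bins = ctx.per_bin_metrics(tensor, classification, labels)
        gk = list(tmetrics.index[tmetrics["keystone"]])
        turnover = ctx.per_bin_keystones(
            summary_bins, fraction=mcfg.keystone_fraction, global_keystones=gk
        )
        summary_bins.interactiveness_mean.to_csv(outdir / "bin_interactiveness_mean.tsv", sep="\t")
        summary_bins.interactiveness_se.to_csv(outdir / "bin_interactiveness_se.tsv", sep="\t")
        summary_bins.facilitation_mean.to_csv(outdir / "bin_facilitation_mean.tsv", sep="\t")
        summary_bins.facilitation_se.to_csv(outdir / "bin_facilitation_se.tsv", sep="\t")
        turnover.membership.to_csv(outdir / "bin_keystones.tsv", sep="\t")
        dists = {
            b: v for b, v in summary_bins.community_distribution("interactiveness").items()
            if len(v) >= 5
        }
        ks_letters = None
        if len(dists) >= 2:
            comp = ctx.compare_distributions(dists, alpha=config.context.alpha)
            comp.pairs.to_csv(outdir / "bin_ks_tests.tsv", sep="\t", index=False)
            pd.Series(comp.letters, name="letter").to_csv(outdir / "bin_letters.tsv", sep="\t")
            ks_letters = comp.letters
        medians = {
            int(b): float(np.median(v)) for b, v in
            summary_bins.community_distribution("interactiveness").items() if len(v)
        }
        decline = None
        if len(medians) >= 2:
            cold, warm = min(medians), max(medians)
            if medians[cold] != 0:
                decline = ctx.percent_change(medians[cold], medians[warm])
        if config.context.run_ordination and gk:
            ordi = ctx.interaction_profile_ordination(
                tensor, gk,
                stress_cutoff=config.context.stress_cutoff,
                seed=stage_seed(config.seed, "context"),
                max_points=500,
            )
            ordi.coords.to_csv(outdir / "ordination.tsv", sep="\t", index=False)

        # ---- report -------------------------------------------------------
        stage = "report"
        lines = [
            "mdrsmap pipeline summary",
            "=" * 40,
            f"taxa in input:           {table.shape[0]}",
            f"taxa retained:           {len(binned.taxon_ids)}",
            f"bin width (days):        {width}",
            f"bins:                    {binned.values.shape[1]}",
            f"strength threshold:      {thresholds[0]:.6g}",
            f"occurrence threshold:    {thresholds[1]:.6g}",
            "pair signs (% of ordered pairs): "
            f"positive {sign_frac['positive']:.1f} / negative {sign_frac['negative']:.1f}"
            f" / neutral {sign_frac['neutral']:.1f}",
            f"keystones: {', '.join(tmetrics.index[tmetrics['keystone']])}",
        ]
        if dist is not None:
            lines.append(
                f"nonzero coefficient distribution: skewness {_fmt(dist.skewness)}, "
                f"kurtosis {_fmt(dist.kurtosis)}, JB p {_fmt(dist.jb_pvalue)}"
            )
        lines.append(
            "per-bin interactiveness medians: "
            + "; ".join(f"{b}C={m:.4f}" for b, m in sorted(medians.items()))
        )
        if decline is not None:
            lines.append(f"cold-to-warm interactiveness change: {decline:.1f}%")
        if ks_letters is not None:
            lines.append(
                "KS letters: " + "; ".join(f"{b}C={l}" for b, l in sorted(ks_letters.items()))
            )
        (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "config": config.to_canonical_yaml(),
            "package": "mdrsmap 0.1.0",
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return outdir
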