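"""End-to-end runner: simulation -> quantification -> phenotype ->
heritability filter -> linkage (per-sample and aggregate) -> consolidation
-> pleiotropy, with a manifest and, on simulated input, a
truth-vs-detection scorecard.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import sim, barcodes, phenotype, heritability, linkage, consolidate, pleiotropy
from .io import write_tsv, write_truth

log = logging.getLogger("persistqtl")


@dataclass
class PipelineConfig:
    """Configuration for a simulated end-to-end run.

    Simulation defaults mirror the study design (822 segregants, 86
    triplicated, 16 chromosomes, full 5x2x2x3x3 organ factorial); scan
    parameters default to the published procedure (1,000 permutations, 5th
    percentile, 2-unit drop CIs, Bonferroni alpha 0.05).
    """

    n_segregants: int = 822
    n_triplicated: int = 86
    n_markers: int = 512
    expected_crossovers: float = 3.0
    n_general: int = 10
    n_antagonistic: int = 8
    effect_scale: float = 0.25
    sequencing_depth: int = 1_000_000
    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 1000
    per_sample_n_perm: int | None = None
    quantile: float = 0.05
    drop: float = 2.0
    max_stages: int = 20
    min_organ_replicates: int = 2
    exclude_samples: tuple = ()
    general_enriched: int = 7
    general_depleted: int = 3
    brain_enriched: int = 6
    brain_depleted: int = 3
    auto_tune_thresholds: bool = False
    run_per_sample_scans: bool = True
    n_boot: int = 1000
    match_window_bp: int = 150_000
    outdir: str = "persistqtl_out"

    def __post_init__(self):
        for name in ("alpha", "quantile"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "exclude_samples" in data:
            data["exclude_samples"] = tuple(data["exclude_samples"])
        return cls(**data)


def score_detections(truth_loci: pd.DataFrame, detections: pd.DataFrame,
                     locus_classes: pd.DataFrame | None = None,
                     consolidated: pd.DataFrame | None = None,
                     match_window_bp: int = 150_000) -> pd.DataFrame:
    """Score aggregate-scan detections against the planted loci.

    A planted locus is *recovered* when a detection on its chromosome has a
    peak within ``match_window_bp`` of it or a CI containing it.
    ``ci_covered`` reports whether the matched detection's CI contains the
    planted position, ``class_concordant`` whether the consolidated locus
    covering it was classified (general vs antagonistic) as planted.
    """
    rows = []
    for _, locus in truth_loci.iterrows():
        cand = detections[detections["chromosome"] == locus["chromosome"]]
        rec = {"marker_id": locus["marker_id"], "chromosome": locus["chromosome"],
               "position": locus["position"], "locus_class": locus["locus_class"],
               "recovered": False, "ci_covered": False,
               "peak_distance_bp": np.nan, "class_concordant": np.nan}
        if len(cand):
            dist = (cand["peak_position"] - locus["position"]).abs()
            inside = ((cand["ci_start_position"] <= locus["position"])
                      & (locus["position"] <= cand["ci_end_position"]))
            hit = (dist <= match_window_bp) | inside
            if hit.any():
                best = dist[hit].idxmin()
                rec["recovered"] = True
                rec["peak_distance_bp"] = float(dist.loc[best])
                rec["ci_covered"] = bool(inside.loc[best])
        if rec["recovered"] and locus_classes is not None and consolidated is not None:
            cover = consolidated[
                (consolidated["chromosome"] == locus["chromosome"])
                & (consolidated["union_start"] - match_window_bp <= locus["position"])
                & (locus["position"] <= consolidated["union_end"] + match_window_bp)
            ]
            if len(cover):
                lid = cover.iloc[0]["locus_id"]
                cls = locus_classes.loc[locus_classes["locus_id"] == lid, "locus_class"]
                if len(cls):
                    rec["class_concordant"] = bool(cls.iloc[0] == locus["locus_class"])
        rows.append(rec)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute every stage on simulated data and write all stage outputs.

    Returns a result bundle (dict of DataFrames and summary scalars); all
    tables are also written as TSV under ``outdir``.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    if config.n_perm < 1000 or (config.per_sample_n_perm or config.n_perm) < 1000:
        log.warning("n_perm below the recommended 1,000 permutations; "
                    "thresholds will be noisier")

    # --- simulation -------------------------------------------------------
    marker_map = sim.make_marker_map(config.n_markers, seed=config.seed + 1)
    genotypes = sim.simulate_cross(marker_map, config.n_segregants,
                                   config.expected_crossovers, seed=config.seed + 2)
    effect_model = sim.simulate_effect_model(
        marker_map, config.n_general, config.n_antagonistic,
        config.effect_scale, seed=config.seed + 3)
    assignment = sim.make_barcode_assignment(
        genotypes.index, n_triplicated=config.n_triplicated, seed=config.seed + 4)
    design = sim.ExperimentDesign(sequencing_depth=config.sequencing_depth)
    counts, meta, truth = sim.simulate_experiment(
        genotypes, assignment, effect_model, design, seed=config.seed + 5)
    write_tsv(marker_map, out / "marker_map.tsv", index=False)
    write_tsv(genotypes, out / "genotypes.tsv")
    write_tsv(assignment, out / "barcode_assignment.tsv", index=False)
    write_tsv(counts, out / "counts.tsv")
    write_tsv(meta, out / "sample_meta.tsv")
    write_truth(truth, out)
    log.info("simulate: %d segregants, %d markers, %d samples",
             len(genotypes), len(marker_map), len(counts))

    # --- quantification ---------------------------------------------------
    freq, unusable = barcodes.normalize(counts)
    log.info("quantify: %d samples normalised, %d unusable", len(freq), len(unusable))

    # --- phenotypes -------------------------------------------------------
    meta_used = meta.drop(index=unusable, errors="ignore")
    freq = freq.drop(index=unusable, errors="ignore")
    persist_bc = phenotype.persistence_matrix(freq, meta_used, time_correct=False)
    persist_bc_tc = phenotype.persistence_matrix(freq, meta_used, time_correct=True)
    write_tsv(persist_bc, out / "persistence_barcode.tsv")
    log.info("phenotype: %d organ samples x %d barcodes", *persist_bc.shape)

    # --- heritability & sample filter ------------------------------------
    filt = heritability.significance_filter(
        persist_bc, assignment, alpha=config.alpha,
        exclude=tuple(config.exclude_samples))
    filt = heritability.apply_organ_replicate_rule(
        filt, meta_used, min_replicates=config.min_organ_replicates)
    write_tsv(filt, out / "sample_filter.tsv")
    kept = filt.index[filt["kept"]]
    organs_kept = meta_used.loc[kept, "organ"]
    brain_samples = list(kept[organs_kept.isin(sim.BRAIN_ORGANS)])
    nonbrain_samples = list(kept[organs_kept.isin(sim.NONBRAIN_ORGANS)])
    log.info("heritability filter: kept %d/%d samples (%d brain, %d nonbrain)",
             len(kept), len(filt), len(brain_samples), len(nonbrain_samples))
    if not brain_samples or not nonbrain_samples:
        raise RuntimeError("significance filter left no brain or no nonbrain samples")

    persist_seg = phenotype.to_segregant_level(persist_bc, assignment)
    persist_seg_tc = phenotype.to_segregant_level(persist_bc_tc, assignment)
    write_tsv(persist_seg, out / "persistence_segregant.tsv")

    h2_across = heritability.across_sample_h2(persist_seg.loc[kept])
    h2_brain = heritability.across_sample_h2(persist_seg_tc.loc[brain_samples])
    h2_nonbrain = heritability.across_sample_h2(persist_seg_tc.loc[nonbrain_samples])
    # H2 of the differential phenotype: brain-sample values minus each
    # segregant's nonbrain aggregate, decomposed across brain samples.
    nonbrain_mean = persist_seg_tc.loc[nonbrain_samples].mean(axis=0)
    diff_matrix = persist_seg_tc.loc[brain_samples].sub(nonbrain_mean, axis=1)
    h2_difference = heritability.across_sample_h2(diff_matrix)

    # --- aggregation ------------------------------------------------------
    aggregates = phenotype.aggregate(persist_seg_tc, brain_samples, nonbrain_samples)
    write_tsv(aggregates, out / "aggregates.tsv")

    # --- aggregate linkage scans -----------------------------------------
    agg_detections = []
    for i, scan_name in enumerate(("brain", "nonbrain", "difference")):
        y = aggregates[scan_name].reindex(genotypes.index).to_numpy()
        det = linkage.forward_scan(
            y, genotypes.to_numpy(), marker_map, n_perm=config.n_perm,
            quantile=config.quantile, drop=config.drop,
            seed=config.seed + 101 + i, max_stages=config.max_stages,
            scan_id=scan_name)
        agg_detections.append(det)
        log.info("scan %s: %d detections", scan_name, len(det))
    agg_detections = pd.concat(agg_detections, ignore_index=True)
    write_tsv(agg_detections, out / "detections_aggregate.tsv", index=False)

    # --- per-sample scans (optional) --------------------------------------
    sample_detections = pd.DataFrame()
    sample_loci = pd.DataFrame()
    if config.run_per_sample_scans:
        n_perm_ps = config.per_sample_n_perm or config.n_perm
        dets = []
        for i, s in enumerate(sorted(kept)):
            y = persist_seg.loc[s].to_numpy()
            dets.append(linkage.forward_scan(
                y, genotypes.to_numpy(), marker_map, n_perm=n_perm_ps,
                quantile=config.quantile, drop=config.drop,
                seed=config.seed + 1000 + i, max_stages=config.max_stages,
                scan_id=s))
        nonempty = [d for d in dets if len(d)]
        sample_detections = (pd.concat(nonempty, ignore_index=True)
                             if nonempty else dets[0])
        sample_loci = consolidate.consolidate(sample_detections)
        write_tsv(sample_detections, out / "detections_per_sample.tsv", index=False)
        write_tsv(sample_loci, out / "consolidated_per_sample.tsv", index=False)
        log.info("per-sample scans: %d detections -> %d consolidated loci",
                 len(sample_detections), len(sample_loci))

    # --- consolidation & effects of aggregate loci ------------------------
    agg_loci = consolidate.consolidate(agg_detections)
    effects = consolidate.locus_effect_table(
        agg_loci, aggregates, genotypes, n_boot=config.n_boot,
        seed=config.seed + 7)
    write_tsv(agg_loci, out / "consolidated_aggregate.tsv", index=False)
    write_tsv(effects, out / "locus_effects.tsv", index=False)

    # --- pleiotropy -------------------------------------------------------
    classes = pleiotropy.classify_table(effects) if len(effects) else pd.DataFrame()
    doses = pleiotropy.allele_dose(
        genotypes, classes, config.general_enriched, config.general_depleted,
        config.brain_enriched, config.brain_depleted,
        auto_tune=config.auto_tune_thresholds) if len(classes) else pd.DataFrame()
    summary_rows = []
    contingency = {}
    if len(doses):
        for ctx, count_col in (("brain", "n_general_beneficial"),
                               ("nonbrain", "n_general_beneficial"),
                               ("brain", "n_brain_favoring"),
                               ("nonbrain", "n_brain_favoring")):
            try:
                r2, p, slope = pleiotropy.dose_regression(
                    aggregates[ctx].reindex(doses.index), doses[count_col])
                summary_rows.append({"context": ctx, "count": count_col,
                                     "r_squared": r2, "p_value": p, "slope": slope})
            except ValueError as err:
                log.warning("dose regression %s/%s skipped: %s", ctx, count_col, err)
        for ctx, group in (("brain", brain_samples), ("nonbrain", nonbrain_samples)):
            slopes = pleiotropy.time_slopes(persist_seg.loc[group], meta_used)
            try:
                chi2, p, table = pleiotropy.enrichment_contingency(doses, slopes)
                contingency[ctx] = {"chi2": chi2, "p_value": p,
                                    "table": table.tolist()}
            except ValueError as err:
                log.warning("contingency %s skipped: %s", ctx, err)
    dose_summary = pd.DataFrame(summary_rows)
    if len(classes):
        write_tsv(classes, out / "locus_classes.tsv", index=False)
        write_tsv(doses, out / "allele_doses.tsv")
        write_tsv(dose_summary, out / "dose_regressions.tsv", index=False)
    timecourse = {}
    if len(doses):
        for ctx, group in (("brain", brain_samples), ("nonbrain", nonbrain_samples)):
            tc = pleiotropy.timecourse_summary(
                persist_seg.loc[group], meta_used, doses,
                n_boot=config.n_boot, seed=config.seed + 8)
            timecourse[ctx] = tc
            write_tsv(tc, out / f"timecourse_{ctx}.tsv", index=False)

    # --- variance explained ----------------------------------------------
    var_explained = {}
    for scan_name, h2 in (("brain", h2_brain), ("nonbrain", h2_nonbrain),
                          ("difference", h2_difference)):
        peaks = agg_detections.loc[agg_detections["scan_id"] == scan_name,
                                   "peak_marker"]
        y = aggregates[scan_name].reindex(genotypes.index).to_numpy()
        var_explained[scan_name] = linkage.variance_explained(
            y, genotypes[list(peaks)].to_numpy(), h2.h2)

    # --- scorecard ---------------------------------------------------------
    scorecard = score_detections(
        truth["loci"], agg_detections, locus_classes=classes if len(classes) else None,
        consolidated=agg_loci, match_window_bp=config.match_window_bp)
    write_tsv(scorecard, out / "scorecard.tsv", index=False)
    n_rec = int(scorecard["recovered"].sum())
    conc = scorecard["class_concordant"].dropna()
    summary = {
        "n_samples_kept": int(len(kept)),
        "median_within_sample_h2": float(filt.loc[kept, "h2"].median()),
        "across_sample_h2": h2_across.h2,
        "across_sample_h2_brain": h2_brain.h2,
        "across_sample_h2_nonbrain": h2_nonbrain.h2,
        "n_aggregate_detections": int(len(agg_detections)),
        "n_aggregate_loci": int(len(agg_loci)),
        "n_per_sample_detections": int(len(sample_detections)),
        "n_per_sample_loci": int(len(sample_loci)),
        "recall": float(n_rec / len(scorecard)) if len(scorecard) else np.nan,
        "sign_concordance": float(conc.mean()) if len(conc) else np.nan,
        "ci_coverage": (float(scorecard.loc[scorecard["recovered"], "ci_covered"].mean())
                        if n_rec else np.nan),
        "mean_peak_distance_bp": (float(scorecard["peak_distance_bp"].dropna().mean())
                                  if n_rec else np.nan),
        "variance_explained_pct": var_explained,
        "contingency": contingency,
    }

    manifest = {
        "package": "persistqtl",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "record_counts": {
            "markers": len(marker_map), "segregants": len(genotypes),
            "barcodes": len(assignment), "samples": len(counts),
            "samples_kept": len(kept),
            "aggregate_detections": len(agg_detections),
            "aggregate_loci": len(agg_loci),
            "per_sample_detections": len(sample_detections),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline finished in %.1f s", time.perf_counter() - t_start)

    return {
        "marker_map": marker_map, "genotypes": genotypes,
        "assignment": assignment, "counts": counts, "meta": meta,
        "truth": truth, "persistence_barcode": persist_bc,
        "persistence_segregant": persist_seg,
        "persistence_segregant_timecorrected": persist_seg_tc,
        "sample_filter": filt, "aggregates": aggregates,
        "aggregate_detections": agg_detections,
        "aggregate_loci": agg_loci, "locus_effects": effects,
        "locus_classes": classes, "allele_doses": doses,
        "dose_regressions": dose_summary, "timecourse": timecourse,
        "per_sample_detections": sample_detections,
        "per_sample_loci": sample_loci,
        "scorecard": scorecard, "summary": summary,
        "brain_samples": brain_samples, "nonbrain_samples": nonbrain_samples,
    }
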