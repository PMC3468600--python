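"""End-to-end orchestration: simulate -> detect -> classify -> characterize
-> cluster -> enrich, with per-stage reports and a markdown summary.

Every stage writes flat TSVs when an output directory is given, so any stage
can be re-run or audited standalone; the summary only restates numbers the
stages computed.  Given a fixed seed the whole bundle is reproducible
byte-for-byte (stage wall-times are kept in memory, never written).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, enrichment, expression, genesets, genome, io, rhythm
from .config import PipelineConfig
from .genesets import GeneSetPartition
from .rhythm import RhythmCall, TimeCourseMatrix
from .simulate import SyntheticDataset, generate_dataset
from .utils import format_pvalue

__all__ = ["StageReport", "PipelineResult", "run_pipeline", "evaluate_against_truth"]

logger = logging.getLogger("circaparam")


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    parameters: dict
    warnings: list[str] = field(default_factory=list)
    wall_time: float = 0.0


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    jtk_calls: list[RhythmCall]
    mm_calls: list[RhythmCall]
    combined_calls: list[RhythmCall]
    representative: dict[str, RhythmCall]
    ambiguous: set[str]
    cutoff: float
    partition: GeneSetPartition
    fpr_negative: float | None
    fpr_positive: float | None
    genome_tables: dict
    expression_tables: dict
    clusters: list[clustering.ConsensusCluster]
    enrichment_results: list[enrichment.EnrichmentResult]
    reports: list[StageReport]
    summary_md: str


def _locus_matrix(probe_matrix: TimeCourseMatrix, probe_map: dict[str, str]) -> TimeCourseMatrix:
    """Average the probe rows of each locus (expression-level statistics)."""
    by_locus: dict[str, list[int]] = {}
    for i, pid in enumerate(probe_matrix.row_ids):
        by_locus.setdefault(probe_map[pid], []).append(i)
    ids = sorted(by_locus)
    values = np.vstack([probe_matrix.values[by_locus[l]].mean(axis=0) for l in ids])
    return TimeCourseMatrix(ids, probe_matrix.times, values)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    reports: list[StageReport] = []

    def _stage(name: str, n_in: int, n_out: int, t0: float, **params) -> None:
        reports.append(StageReport(name, n_in, n_out, params, wall_time=time.time() - t0))
        logger.info("stage %s: %d in -> %d out", name, n_in, n_out)

    # ---- synthesize -------------------------------------------------------
    t0 = time.time()
    dataset = generate_dataset(config.simulation)
    truth_by_id = dataset.truth_by_id
    _stage("synthesize", 0, len(dataset.annotation.loci), t0, seed=config.simulation.seed)
    if out is not None:
        io.write_timecourse(dataset.timecourse, out / "expression_probes.tsv")
        io.write_probe_map(dataset.probe_map, out / "probe_map.tsv")
        io.write_gff3(dataset.annotation, out / "annotation.gff3")
        io.write_tissue_matrix(dataset.tissue, out / "tissue_expression.tsv")
        io.write_truth(dataset.truth, out / "truth.tsv")
        io.write_gene_list(sorted(dataset.general_circadian_list), out / "general_circadian.txt")

    # ---- detect -----------------------------------------------------------
    t0 = time.time()
    jtk_calls = rhythm.jtk_scan(dataset.timecourse, periods=config.periods)
    mm_calls = rhythm.model_match_scan(dataset.timecourse, periods=config.periods)
    combined = rhythm.combine_rhythm_calls(jtk_calls, mm_calls, config.q_threshold)
    _stage("detect", len(dataset.timecourse.row_ids), len(combined), t0,
           q_threshold=config.q_threshold, periods=list(config.periods))
    if out is not None:
        io.write_calls(combined, out / "rhythm_calls.tsv")

    # ---- classify ---------------------------------------------------------
    t0 = time.time()
    per_locus: dict[str, list[RhythmCall]] = {}
    for call in combined:
        per_locus.setdefault(dataset.probe_map[call.row_id], []).append(call)
    representative: dict[str, RhythmCall] = {}
    ambiguous: set[str] = set()
    for locus_id, calls in per_locus.items():
        sel = genesets.select_representative_probe(calls)
        if sel.excluded:
            ambiguous.add(locus_id)
        else:
            representative[locus_id] = sel.call
    locus_expr = _locus_matrix(dataset.timecourse, dataset.probe_map)
    if config.expression_cutoff is not None:
        cutoff = config.expression_cutoff
    else:
        try:
            cutoff = genesets.estimate_expression_cutoff(locus_expr.values.ravel())
        except ValueError as exc:
            warnings.warn(f"cutoff estimation failed ({exc}); using {genesets.DEFAULT_CUTOFF}")
            cutoff = genesets.DEFAULT_CUTOFF
    partition = genesets.partition_gene_sets(
        representative, locus_expr, dataset.general_circadian_list, cutoff, ambiguous
    )
    fpr_neg = (
        genesets.estimate_false_positive_rate(partition.lcg, dataset.negative_controls)
        if dataset.negative_controls else None
    )
    fpr_pos = (
        genesets.estimate_false_positive_rate(partition.lncg, dataset.positive_controls)
        if dataset.positive_controls else None
    )
    _stage("classify", len(per_locus), len(partition.lcg), t0, cutoff=round(cutoff, 4))
    if out is not None:
        with open(out / "partition.tsv", "w") as fh:
            fh.write("locus_id\tlabel\n")
            for locus_id in sorted(partition.labels):
                fh.write(f"{locus_id}\t{partition.labels[locus_id]}\n")

    groups = {
        "LCG": partition.lcg,
        "NLCG": partition.nlcg,
        "LNCG": partition.lncg,
        "AL": partition.al,
    }

    # ---- genome parameters ------------------------------------------------
    t0 = time.time()
    ann = dataset.annotation
    index = genome.LocusIndex(ann.loci)
    genome_tables: dict = {}
    stats = genome.chromosome_stats(
        ann.loci, ann.chrom_lengths, ann.chrom_gc,
        {"LCG": partition.lcg, "LNCG": partition.lncg},
    )
    genome_tables["chromosome_stats"] = stats
    corr = {}
    if len(stats) >= 3:
        try:
            corr["density_vs_gc"] = genome.correlate_group_gc(stats.gc_percent, stats.density)
            if partition.lcg:
                corr["lcg_pct_vs_gc"] = genome.correlate_group_gc(stats.gc_percent, stats.pct_LCG)
            if partition.lncg:
                corr["lncg_pct_vs_gc"] = genome.correlate_group_gc(stats.gc_percent, stats.pct_LNCG)
        except ValueError as exc:
            warnings.warn(f"GC correlation skipped: {exc}")
    genome_tables["gc_correlations"] = corr
    neighbor_windows = (60_000, 150_000)
    genome_tables["neighbor_means"] = pd.DataFrame(
        {
            name: genome.neighbor_profile(index, members, neighbor_windows)
            for name, members in groups.items() if members
        }
    )
    genome_tables["length_medians"] = pd.DataFrame(
        {
            name: genome.length_statistics([ann.locus(l) for l in members])
            for name, members in groups.items() if members
        }
    )
    phases_ct = {
        l: clustering.normalize_phase(c.phase, c.period) for l, c in representative.items()
    }
    genome_tables["divergent_pairs"] = genome.find_divergent_pairs(ann.loci, phases_ct)
    retained_sites, site_table = genome.annotate_sites_to_tss(
        dataset.aux.binding_sites, index, groups={"LCG": partition.lcg, "LNCG": partition.lncg}
    )
    genome_tables["binding_site_table"] = site_table
    _, meth_vectors = genome.annotate_methylation_probes(
        dataset.aux.methylation_probes, index,
        groups={"LCG": partition.lcg, "LNCG": partition.lncg},
    )
    meth_p = {}
    for cls in ("strong", "weak", "poor"):
        a, b = meth_vectors.get(("LCG", cls)), meth_vectors.get(("LNCG", cls))
        if a is not None and b is not None and a.size and b.size:
            meth_p[cls] = expression.ranksum_onesided(a, b, "less")
    genome_tables["methylation_p"] = meth_p
    _stage("genome", len(ann.loci), len(retained_sites), t0)

    # ---- expression features ----------------------------------------------
    t0 = time.time()
    expr_tables: dict = {}
    idx = {l: i for i, l in enumerate(locus_expr.row_ids)}
    rep_series = {
        l: dataset.timecourse.values[dataset.timecourse.row_ids.index(c.row_id)]
        for l, c in representative.items()
    }
    amp = {}
    for name, members in groups.items():
        vals = []
        for m in sorted(members):
            series = rep_series.get(m)
            if series is None:
                series = locus_expr.values[idx[m]]
            vals.append(expression.amplitude(series))
        amp[name] = np.asarray(vals)
    expr_tables["amplitude"] = {k: float(v.mean()) if v.size else float("nan") for k, v in amp.items()}
    if amp["LCG"].size and amp["LNCG"].size:
        expr_tables["amplitude_p_lncg_less"] = expression.ranksum_onesided(
            amp["LNCG"], amp["LCG"], "less"
        )
        expr_tables["lncg_amp_below_2_pct"] = float(100.0 * (amp["LNCG"] < 2.0).mean())

    mean_expr = dict(zip(locus_expr.row_ids, locus_expr.values.mean(axis=1)))
    expressed_mean = {l: v for l, v in mean_expr.items() if l in partition.al}
    if expressed_mean:
        bins = expression.expression_bins(expressed_mean, bin_size=config.expression_bin_size)
        expr_tables["bins"] = expression.bin_group_percentages(
            bins, {"LCG": partition.lcg, "LNCG": partition.lncg}
        )

    stats_time = expression.temporal_stats(locus_expr.values, locus_expr.row_ids)
    tissue_idx = {g: i for i, g in enumerate(dataset.tissue.gene_ids)}
    stats_tissue = expression.temporal_stats(dataset.tissue.values, dataset.tissue.gene_ids)
    summary_rows = {}
    for name, members in groups.items():
        if not members:
            continue
        members = sorted(members)
        summary_rows[name] = {
            "mean_time": float(stats_time.loc[members, "mean"].mean()),
            "std_time": float(stats_time.loc[members, "std"].mean()),
            "mean_tissue": float(stats_tissue.loc[members, "mean"].mean()),
            "std_tissue": float(stats_tissue.loc[members, "std"].mean()),
        }
    expr_tables["mean_std"] = pd.DataFrame.from_dict(summary_rows, orient="index")
    if partition.lcg and partition.lncg:
        expr_tables["std_time_p"] = expression.ranksum_onesided(
            stats_time.loc[sorted(partition.lncg), "std"],
            stats_time.loc[sorted(partition.lcg), "std"],
            "less",
        )

    breadth = expression.expression_breadth(dataset.tissue, cutoff)
    expr_tables["breadth_hist"] = expression.breadth_histogram(
        breadth, dataset.tissue.n_tissues,
        {k: v for k, v in groups.items() if v},
    )
    expr_tables["ubiquitous_pct"] = {
        name: float(100.0 * (breadth.loc[sorted(m)] == dataset.tissue.n_tissues).mean())
        for name, m in groups.items() if m
    }

    kept = expression.filter_halflife(dataset.aux.halflife_records)
    hl = {r.gene_id: r.halflife_es for r in kept}
    hl_means = {}
    hl_vectors = {}
    for name, members in groups.items():
        vals = np.array([hl[m] for m in sorted(members) if m in hl])
        hl_vectors[name] = vals
        if vals.size:
            hl_means[name] = float(vals.mean())
    expr_tables["halflife_mean"] = hl_means
    if hl_vectors["LCG"].size and hl_vectors["LNCG"].size:
        expr_tables["halflife_p_lcg_less"] = expression.ranksum_onesided(
            hl_vectors["LCG"], hl_vectors["LNCG"], "less"
        )
    _stage("expression", len(locus_expr.row_ids), len(expr_tables), t0)

    # ---- temporal clustering ----------------------------------------------
    t0 = time.time()
    clusters: list[clustering.ConsensusCluster] = []
    if len(partition.lcg) >= 2 * config.min_cluster_size:
        lcg_sorted = sorted(partition.lcg)
        profiles = np.vstack([rep_series.get(l, locus_expr.values[idx[l]]) for l in lcg_sorted])
        nonneg = clustering.prepare_nonnegative(profiles)
        consensus = clustering.consensus_matrix(
            nonneg, lcg_sorted, k=config.nmf_rank, n_runs=config.nmf_runs,
            master_seed=config.simulation.seed,
        )
        clusters = clustering.select_coexpression_clusters(
            consensus, threshold=config.consensus_threshold,
            min_size=config.min_cluster_size, phases=phases_ct, profiles=nonneg,
        )
    else:
        warnings.warn("too few circadian genes for co-expression clustering; skipped")
    hist = clustering.phase_histogram([phases_ct[l] for l in partition.lcg if l in phases_ct])
    _stage("cluster", len(partition.lcg), len(clusters), t0,
           k=config.nmf_rank, runs=config.nmf_runs)
    if out is not None:
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("gene_id\tcluster\twindow\n")
            for i, cl in enumerate(clusters):
                for g in cl.member_gene_ids:
                    fh.write(f"{g}\t{i}\t{cl.window}\n")
        pd.Series(hist, name="count").to_csv(out / "phase_histogram.tsv", sep="\t")

    # ---- enrichment --------------------------------------------------------
    t0 = time.time()
    enrich_results: list[enrichment.EnrichmentResult] = []
    if len(clusters) >= 2 and partition.lncg:
        enrich_results = enrichment.phase_specific_terms(
            clusters, partition.lncg, dataset.aux.gene_terms, mode="go"
        )
    flagged = [r for r in enrich_results if r.flagged]
    _stage("enrich", len(clusters), len(flagged), t0)

    summary = _summarize(
        config, dataset, partition, cutoff, fpr_neg, fpr_pos,
        genome_tables, expr_tables, clusters, flagged,
    )
    if out is not None:
        (out / "summary.md").write_text(summary)

    return PipelineResult(
        config=config,
        dataset=dataset,
        jtk_calls=jtk_calls,
        mm_calls=mm_calls,
        combined_calls=combined,
        representative=representative,
        ambiguous=ambiguous,
        cutoff=cutoff,
        partition=partition,
        fpr_negative=fpr_neg,
        fpr_positive=fpr_pos,
        genome_tables=genome_tables,
        expression_tables=expr_tables,
        clusters=clusters,
        enrichment_results=enrich_results,
        reports=reports,
        summary_md=summary,
    )


def _summarize(config, dataset, partition, cutoff, fpr_neg, fpr_pos,
               genome_tables, expr_tables, clusters, flagged) -> str:
    lines = ["# Circadian characterization summary", ""]
    n_planted = sum(t.is_rhythmic for t in dataset.truth)
    lines += [
        f"- loci: {len(dataset.annotation.loci)}; planted rhythmic: {n_planted}",
        f"- expression cutoff (log10): {cutoff:.3f}",
        f"- LCG: {len(partition.lcg)}; LNLCG: {len(partition.lnlcg)}; "
        f"LNCG: {len(partition.lncg)}; expressed (AL): {len(partition.al)}",
    ]
    if fpr_neg is not None:
        lines.append(f"- false positive rate vs negative controls: {fpr_neg}%")
    if fpr_pos is not None:
        lines.append(f"- false positive rate vs literature circadian controls: {fpr_pos}%")
    lines.append("")
    lines.append("## Genomic parameters")
    lines.append(genome_tables["neighbor_means"].to_markdown())
    lines.append("")
    lines.append(genome_tables["length_medians"].round(1).to_markdown())
    lines.append("")
    for name, (r, p) in genome_tables["gc_correlations"].items():
        lines.append(f"- {name}: R = {r:.2f}, P = {format_pvalue(p)}")
    lines.append(f"- divergent rhythmic pairs: {len(genome_tables['divergent_pairs'])}")
    lines.append("")
    lines.append("## Expression features")
    for name, v in expr_tables["amplitude"].items():
        lines.append(f"- mean amplitude {name}: {v:.2f}")
    if "amplitude_p_lncg_less" in expr_tables:
        lines.append(
            f"- amplitude LNCG < LCG one-sided P: "
            f"{format_pvalue(expr_tables['amplitude_p_lncg_less'])}; "
            f"LNCG amplitude < 2: {expr_tables['lncg_amp_below_2_pct']:.1f}%"
        )
    lines.append("")
    lines.append(expr_tables["mean_std"].round(3).to_markdown())
    if "std_time_p" in expr_tables:
        lines.append(
            f"- temporal STD LNCG < LCG one-sided P: {format_pvalue(expr_tables['std_time_p'])}"
        )
    if expr_tables.get("halflife_mean"):
        means = ", ".join(f"{k}: {v:.2f} h" for k, v in expr_tables["halflife_mean"].items())
        lines.append(f"- mean mRNA half-life: {means}")
    ubi = ", ".join(f"{k}: {v:.1f}%" for k, v in expr_tables["ubiquitous_pct"].items())
    lines.append(f"- expressed in all tissues: {ubi}")
    lines.append("")
    lines.append("## Temporal clusters")
    for i, cl in enumerate(clusters):
        lines.append(
            f"- cluster {i}: {cl.size} genes, window {cl.window}, "
            f"mean phase CT{cl.mean_phase:.1f}"
        )
    if flagged:
        lines.append("")
        lines.append("## Phase-specific terms")
        for r in flagged:
            lines.append(f"- {r.term} in {r.cluster} ({r.passes}/4 comparisons pass)")
    lines.append("")
    return "\n".join(lines)


def evaluate_against_truth(result: PipelineResult) -> dict[str, float]:
    """Score the recovered partition against the planted truth."""
    truth = result.dataset.truth_by_id
    planted_rhythmic = {l for l, t in truth.items() if t.is_rhythmic}
    called = set(result.partition.lcg)
    tp = len(called & planted_rhythmic)
    precision = tp / len(called) if called else 0.0
    recall = tp / len(planted_rhythmic) if planted_rhythmic else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    planted_lncg = {
        l for l, t in truth.items()
        if not t.is_rhythmic and t.expressed and not t.in_general_list
    }
    lncg = set(result.partition.lncg)
    inter = len(lncg & planted_lncg)
    lncg_f1 = (
        2 * inter / (len(lncg) + len(planted_lncg)) if lncg or planted_lncg else 0.0
    )
    return {
        "lcg_precision": precision,
        "lcg_recall": recall,
        "lcg_f1": f1,
        "lncg_f1": lncg_f1,
        "n_lcg": float(len(called)),
        "n_planted": float(len(planted_rhythmic)),
    }
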