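"""End-to-end driver tying the stages together in analysis order:
quantile normalization (IP and input separately) → input subtraction →
broad-peak calling per condition → union/cluster → signal matrix →
k-means → gain/loss/common labelling → promoter & repeat association →
Obs/Exp enrichment.

The driver is deliberately thin: every stage is a library call, and the
summary JSON doubles as a regression fixture (identical config + inputs +
seed give identical outputs).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    GenomeModel,
    PromoterConfig,
    Region,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_repeat_bed,
    extract_promoters,
    write_bed,
)
from .differential import (
    ClusterConfig,
    MatrixConfig,
    classify_clusters,
    cluster_condition_means,
    extract_signal_matrix,
    kmeans_cluster,
)
from .enrichment import (
    EnrichmentConfig,
    EnrichmentResult,
    obs_exp_enrichment,
    percent_associated,
)
from .peaks import PeakCallConfig, UnionConfig, call_broad_peaks, region_size_stats, union_regions
from .signal import Sample, TrackSet, quantile_normalize, subtract_input

logger = logging.getLogger("k9diff")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed (stays < 2^31)."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    genome_path: str
    sample_sheet: list[dict]            # sample_id, role, condition, bedgraph
    repeat_bed: str | None = None
    repeat_dialect: str = "columns"
    gene_bed: str | None = None
    bin_width: int = 200
    peak: PeakCallConfig = field(default_factory=lambda: PeakCallConfig(1000, 500))
    union: UnionConfig = field(default_factory=UnionConfig)
    matrix: MatrixConfig = field(default_factory=MatrixConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    promoter: PromoterConfig = field(default_factory=PromoterConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    out_dir: str = "k9diff_out"
    seed: int = 0

    def validate(self) -> None:
        conditions = {s["condition"] for s in self.sample_sheet}
        for cond in conditions:
            roles = {s["role"] for s in self.sample_sheet if s["condition"] == cond}
            if "IP" not in roles:
                raise ValueError(f"condition {cond!r} has no IP sample")
            if "input" not in roles:
                raise ValueError(f"condition {cond!r} has no input sample")


@dataclass
class PipelineResult:
    union: list[Region]
    assignment: np.ndarray
    cluster_labels: dict[int, str]
    region_labels: list[str]
    enrichment: list[EnrichmentResult]
    summary: dict
    out_dir: Path


def _load_tracks(config: PipelineConfig, genome: GenomeModel, base: Path) -> TrackSet:
    samples = []
    for row in config.sample_sheet:
        path = Path(row["bedgraph"])
        if not path.is_absolute():
            path = base / path
        track = read_bedgraph(path, genome, config.bin_width)
        samples.append(Sample(row["sample_id"], row["role"], row["condition"], track))
    return TrackSet(samples)


def run_pipeline(config: PipelineConfig, tracks: TrackSet | None = None,
                 base_dir: str | Path = ".") -> PipelineResult:
    """Run the full differential-domain analysis; see module docstring."""
    config.validate()
    base = Path(base_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genome = read_chrom_sizes(
        config.genome_path if Path(config.genome_path).is_absolute()
        else base / config.genome_path)
    if tracks is None:
        tracks = _load_tracks(config, genome, base)
    logger.info("loaded %d samples on %d chromosomes", len(tracks), len(genome))

    # normalization: IP and input groups separately
    ips = tracks.by_role("IP")
    inputs = tracks.by_role("input")
    ip_norm = quantile_normalize([s.track for s in ips]) if len(ips) > 1 else [s.track for s in ips]
    in_norm = quantile_normalize([s.track for s in inputs]) if len(inputs) > 1 else [s.track for s in inputs]
    logger.info("quantile normalized %d IP and %d input tracks", len(ip_norm), len(in_norm))

    # noise reduction per condition: mean IP - mean input of that condition
    conditions = tracks.conditions()
    reduced: dict[str, "object"] = {}
    for cond in conditions:
        ip_tracks = [t for s, t in zip(ips, ip_norm) if s.condition == cond]
        in_tracks = [t for s, t in zip(inputs, in_norm) if s.condition == cond]
        ip_mean = _mean_tracks(ip_tracks)
        in_mean = _mean_tracks(in_tracks)
        reduced[cond] = subtract_input(ip_mean, in_mean)
    logger.info("noise-reduced tracks for conditions: %s", ", ".join(conditions))

    # broad peaks per condition, then union
    peak_sets = {}
    for cond in conditions:
        peak_sets[cond] = call_broad_peaks(reduced[cond], config.peak)
        write_bed(peak_sets[cond], out_dir / f"peaks_{cond}.bed")
        logger.info("condition %s: %d broad peaks", cond, len(peak_sets[cond]))
    union = union_regions(list(peak_sets.values()), config.union, genome=genome)
    write_bed(union, out_dir / "union.bed")
    logger.info("union: %d clustered regions", len(union))

    summary: dict = {
        "n_samples": len(tracks),
        "conditions": conditions,
        "peaks_per_condition": {c: len(peak_sets[c]) for c in conditions},
        "n_union": len(union),
    }
    if union:
        summary["union_size_stats"] = region_size_stats(union)

    # signal matrix + k-means + labelling
    assignment = np.array([], dtype=int)
    cluster_labels: dict[int, str] = {}
    region_labels: list[str] = []
    if len(union) >= config.cluster.k:
        matrix = extract_signal_matrix(reduced, union, config.matrix)
        matrix.to_frame().to_csv(out_dir / "matrix.tsv", sep="\t")
        assignment = kmeans_cluster(matrix, config.cluster)
        pair = (conditions[0], conditions[-1])
        means = cluster_condition_means(matrix, assignment, pair)
        cluster_labels = classify_clusters(means, config.cluster.fold_threshold)
        region_labels = [cluster_labels[int(c)] for c in assignment]
        labelled = [Region(r.chrom, r.start, r.end, name=f"{lab}_{r.name}")
                    for r, lab in zip(union, region_labels)]
        write_bed(labelled, out_dir / "clusters.bed")
        summary["cluster_sizes"] = {str(c): int((assignment == c).sum())
                                    for c in np.unique(assignment)}
        summary["cluster_labels"] = {str(c): l for c, l in cluster_labels.items()}
        summary["regions_per_label"] = {
            lab: region_labels.count(lab) for lab in ("common", "gain", "loss")}
        for lab in ("common", "gain", "loss"):
            sub = [r for r, l in zip(union, region_labels) if l == lab]
            if sub:
                summary[f"{lab}_size_stats"] = region_size_stats(sub)
        logger.info("k-means: %s", summary["cluster_sizes"])

    # annotation association + enrichment
    repeats = None
    if config.repeat_bed is not None:
        rp = Path(config.repeat_bed)
        repeats = read_repeat_bed(rp if rp.is_absolute() else base / rp,
                                  genome, config.repeat_dialect)
    if config.gene_bed is not None:
        gp = Path(config.gene_bed)
        genes = read_bed(gp if gp.is_absolute() else base / gp, genome)
        promoters = extract_promoters(genes, config.promoter, genome)
        write_bed(promoters, out_dir / "promoters.bed")
        if union:
            summary["pct_promoter"] = {
                lab: percent_associated(sub, promoters)
                for lab in ("common", "gain", "loss")
                if (sub := [r for r, l in zip(union, region_labels) if l == lab])}
    enrichment_results: list[EnrichmentResult] = []
    if repeats is not None and union:
        summary["pct_repeat"] = {
            lab: percent_associated(sub, repeats)
            for lab in ("common", "gain", "loss")
            if (sub := [r for r, l in zip(union, region_labels) if l == lab])}
        differential = [r for r, l in zip(union, region_labels) if l in ("gain", "loss")]
        if differential:
            enr_cfg = EnrichmentConfig(
                n_shuffles=config.enrichment.n_shuffles,
                seed=derive_seed(config.seed, "enrichment"),
                grouping=config.enrichment.grouping,
                mu0=config.enrichment.mu0,
                count_events=config.enrichment.count_events)
            enrichment_results = obs_exp_enrichment(differential, repeats, enr_cfg, genome=genome)
            _write_enrichment_tsv(enrichment_results, out_dir / "enrichment.tsv")
            summary["enrichment"] = [
                {"group": r.group, "observed": r.observed, "mean_ratio": _json_num(r.mean_ratio),
                 "sd": _json_num(r.sd_ratio), "t": r.t_stat, "p": r.p_one_sided, "flag": r.flag}
                for r in enrichment_results]
            logger.info("enrichment tested %d groups", len(enrichment_results))

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return PipelineResult(union, assignment, cluster_labels, region_labels,
                          enrichment_results, summary, out_dir)


def _json_num(x: float):
    return None if x != x else x  # NaN -> null


def _mean_tracks(tracks):
    if len(tracks) == 1:
        return tracks[0]
    from .core_io import BinnedTrack
    out = BinnedTrack(tracks[0].genome, tracks[0].bin_width)
    for chrom in out.genome.names:
        out.values[chrom] = np.mean([t.values[chrom] for t in tracks], axis=0)
    return out


def _write_enrichment_tsv(results: list[EnrichmentResult], path: Path) -> None:
    with open(path, "w") as fh:
        if not results:
            fh.write("group\tobserved\n")
            return
        n = len(results[0].expected)
        head = (["group", "observed"] + [f"expected_{i+1}" for i in range(n)]
                + [f"ratio_{i+1}" for i in range(n)] + ["mean", "sd", "t", "p", "flag"])
        fh.write("\t".join(head) + "\n")
        for r in results:
            ratios = r.ratios if r.ratios else [float("nan")] * n
            row = ([r.group, str(r.observed)] + [str(e) for e in r.expected]
                   + [f"{x:.6g}" for x in ratios]
                   + [f"{r.mean_ratio:.6g}", f"{r.sd_ratio:.6g}",
                      f"{r.t_stat:.6g}" if r.t_stat is not None else "NA",
                      f"{r.p_one_sided:.6g}" if r.p_one_sided is not None else "NA",
                      r.flag or "."])
            fh.write("\t".join(row) + "\n")
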