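"""Self-contained benchmarks on synthetic data: planted-domain recovery,
cluster-label agreement, planted-enrichment detection and null-test
calibration.

These drive both the test suite and the reproduction script.  The planted
benchmark runs the full pipeline (normalize → subtract → call → union →
matrix → k-means → classify → enrich) on a generated dataset and scores
it against the generator's truth table; the calibration benchmark places
unplanted regions uniformly and measures how often the one-sided Obs/Exp
t-test rejects at a given level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .core_io import GenomeModel, Region
from .differential import (
    ClusterConfig,
    MatrixConfig,
    classify_clusters,
    cluster_condition_means,
    extract_signal_matrix,
    kmeans_cluster,
)
from .enrichment import EnrichmentConfig, obs_exp_enrichment, overlap_annotate, shuffle_intervals
from .peaks import PeakCallConfig, UnionConfig, call_broad_peaks, union_regions
from .signal import quantile_normalize, subtract_input
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["PlantedScore", "run_planted_benchmark", "null_calibration"]


@dataclass
class PlantedScore:
    """Scores of one full-pipeline run against the generator's truth."""

    seed: int
    n_planted: int
    n_union: int
    recovery: float          # fraction of planted domains hit by a union region
    ari: float               # cluster assignment vs truth label, matched domains
    target_mean_ratio: float
    target_significant: bool
    neutral_significant: bool
    neutral_tested: bool

    @property
    def enrichment_ok(self) -> bool:
        return self.target_significant and not self.neutral_significant


def run_planted_benchmark(seed: int, config: SimulationConfig | None = None,
                          peak_cutoff: float | None = None,
                          link_cutoff: float | None = None,
                          k: int = 8) -> PlantedScore:
    """Generate a planted dataset, run the full analysis, score vs truth.

    Default cutoffs are half the planted domain amplitude (peak) and a
    quarter of it (link), on the noise-reduced scale where background is
    approximately zero.  Peaks must span at least two bins: planted
    domains are 600 bp and larger, while quantile normalization can lift
    isolated background bins of the condition with the smaller domain
    footprint above the cutoff.  k defaults to the three planted classes
    plus one, which gives the spurious/low-amplitude regions a cluster of
    their own; the adjusted Rand index compares the gain/loss/common
    label partition against the truth table on recovered domains.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    else:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    if peak_cutoff is None:
        peak_cutoff = config.signal.domain_fold / 2
    if link_cutoff is None:
        link_cutoff = config.signal.domain_fold / 4

    repeats, truth, tracks = simulate_dataset(config)
    genome = config.genome_model()

    ips = tracks.by_role("IP")
    inputs = tracks.by_role("input")
    ip_norm = quantile_normalize([s.track for s in ips]) if len(ips) > 1 else [s.track for s in ips]
    in_norm = (quantile_normalize([s.track for s in inputs])
               if len(inputs) > 1 else [s.track for s in inputs])
    conditions = list(config.conditions)
    reduced = {}
    for cond in conditions:
        ip = [t for s, t in zip(ips, ip_norm) if s.condition == cond]
        inp = [t for s, t in zip(inputs, in_norm) if s.condition == cond]
        reduced[cond] = subtract_input(_mean(ip), _mean(inp))

    pk_cfg = PeakCallConfig(peak_cutoff, link_cutoff,
                            min_peak_length=2 * config.bin_width)
    peak_sets = [call_broad_peaks(reduced[c], pk_cfg) for c in conditions]
    union = union_regions(peak_sets, UnionConfig(), genome=genome)

    # recovery: planted domains hit by >=1 union region
    hits = overlap_annotate(truth.domains, union)
    recovered = [i for i, (_, _, assoc) in enumerate(hits) if assoc]
    recovery = len(recovered) / len(truth.domains)

    # clustering on the union regions
    matrix = extract_signal_matrix(reduced, union, MatrixConfig())
    assignment = kmeans_cluster(matrix, ClusterConfig(k=k, seed=seed))
    means = cluster_condition_means(matrix, assignment, (conditions[0], conditions[-1]))
    labels = classify_clusters(means)
    region_labels = [labels[int(c)] for c in assignment]

    # match each recovered planted domain to its best-overlapping union
    # region and compare the gain/loss/common partitions
    true_labels, recovered_labels = [], []
    for i in recovered:
        d = truth.domains[i]
        best, best_bp = None, 0
        for j, u in enumerate(union):
            if u.chrom != d.chrom:
                continue
            bp = min(u.end, d.end) - max(u.start, d.start)
            if bp > best_bp:
                best, best_bp = j, bp
        if best is not None:
            true_labels.append(truth.labels[i])
            recovered_labels.append(region_labels[best])
    ari = float(adjusted_rand_score(true_labels, recovered_labels)) if true_labels else 0.0

    # planted enrichment on the differential regions
    differential = [r for r, l in zip(union, region_labels) if l in ("gain", "loss")]
    target_ratio, target_sig, neutral_sig, neutral_tested = float("nan"), False, False, False
    if differential:
        results = obs_exp_enrichment(
            differential, repeats,
            EnrichmentConfig(seed=seed + 1_000_003), genome=genome)
        for r in results:
            if r.group == config.target_class:
                target_ratio = r.mean_ratio
                target_sig = r.significant
            if r.group == "NEUTRAL":
                neutral_tested = r.flag is None
                neutral_sig = r.significant
    return PlantedScore(seed, len(truth.domains), len(union), recovery, ari,
                        target_ratio, target_sig, neutral_sig, neutral_tested)


def null_calibration(n_replicates: int = 1000, n_regions: int = 40, seed: int = 0,
                     alpha: float = 0.05,
                     config: SimulationConfig | None = None) -> dict:
    """Type-I error of the Obs/Exp t-test on unplanted region sets.

    Regions with the planted-domain length distribution are placed
    uniformly (the shuffle null itself), so every group's true enrichment
    is 1.  Returns the pooled rejection rate over all testable
    (group, replicate) pairs and the grand mean Obs/Exp ratio.
    """
    if config is None:
        config = SimulationConfig(seed=seed)
    rng = np.random.default_rng(seed)
    genome = config.genome_model()
    from .simulate import simulate_repeats
    repeats = simulate_repeats(config, rng)
    dom = config.domains

    rejections = 0
    tested = 0
    ratios: list[float] = []
    for rep in range(n_replicates):
        lengths = rng.integers(dom.min_len, dom.max_len + 1, size=n_regions)
        templates = [Region("chr1", 0, int(l)) for l in lengths]
        regions = shuffle_intervals(templates, genome, rng)
        results = obs_exp_enrichment(
            regions, repeats,
            EnrichmentConfig(seed=int(rng.integers(2**31 - 1))), genome=genome)
        for r in results:
            if r.flag is None:
                tested += 1
                ratios.append(r.mean_ratio)
                if r.p_one_sided <= alpha:
                    rejections += 1
    return {
        "n_replicates": n_replicates,
        "n_tested": tested,
        "rejection_rate": rejections / tested if tested else float("nan"),
        "mean_ratio": float(np.mean(ratios)) if ratios else float("nan"),
        "sem_ratio": float(np.std(ratios, ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else float("nan"),
    }


def _mean(tracks):
    if len(tracks) == 1:
        return tracks[0]
    from .core_io import BinnedTrack
    out = BinnedTrack(tracks[0].genome, tracks[0].bin_width)
    for chrom in out.genome.names:
        out.values[chrom] = np.mean([t.values[chrom] for t in tracks], axis=0)
    return out
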