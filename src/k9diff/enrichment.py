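"""Annotation overlap, length-preserving genome shuffling, and the
observed/expected repeat-enrichment statistic.

The null model redistributes each query region, keeping its length, to a
uniformly random position on the genome (chromosome drawn with probability
proportional to its number of valid start positions).  For every repeat
class or subfamily the number of query regions touching at least one
element (*observed*) is compared against the same count for each of
``n_shuffles`` shuffled region sets (*expected*), giving one Obs/Exp ratio
per shuffle.  A one-sample t-test asks whether the mean ratio exceeds 1
(one-sided); groups where any shuffle yields zero expected overlaps, or
where the ratios have zero spread, are flagged instead of producing
infinities — with the default three shuffles both cases are reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core_io import BinnedTrack, GenomeModel, Region, RepeatElement

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "overlap_annotate",
    "percent_associated",
    "shuffle_intervals",
    "obs_exp_enrichment",
    "obs_exp_ttest",
    "repeat_composition",
    "filter_repeats_with_signal",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    n_shuffles: int = 3
    seed: int = 0
    grouping: Literal["class", "subfamily"] = "class"
    mu0: float = 1.0
    count_events: bool = False  # count overlap events instead of regions

    def __post_init__(self):
        if self.n_shuffles < 2:
            raise ValueError("n_shuffles must be >= 2 (t-test needs df >= 1)")


@dataclass
class EnrichmentResult:
    """Per-group Obs/Exp summary with its one-sided one-sample t-test."""

    group: str
    observed: int
    expected: list[int]
    ratios: list[float]
    mean_ratio: float
    sd_ratio: float
    t_stat: float | None
    p_one_sided: float | None
    df: int
    flag: str | None = None  # 'expected-zero' or 'sd-zero' when untestable

    @property
    def significant(self) -> bool:
        return self.flag is None and self.p_one_sided is not None and self.p_one_sided <= 0.05


# ---------------------------------------------------------------------------
# overlap machinery


def _merged_starts_ends(annotation: Sequence[Region]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union of annotation intervals per chromosome as sorted arrays."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for a in annotation:
        per_chrom.setdefault(a.chrom, []).append((a.start, a.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in per_chrom.items():
        ivs.sort()
        ms, me = [], []
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                ms.append(cs); me.append(ce)
                cs, ce = s, e
        ms.append(cs); me.append(ce)
        merged[chrom] = (np.array(ms), np.array(me))
    return merged


def overlap_annotate(regions: Sequence[Region], annotation: Sequence[Region]
                     ) -> list[tuple[int, float, bool]]:
    """Per region: (overlap_bp with the union of the annotation,
    overlap fraction of the region, associated = any overlap)."""
    merged = _merged_starts_ends(annotation)
    out: list[tuple[int, float, bool]] = []
    for r in regions:
        if r.chrom not in merged:
            out.append((0, 0.0, False))
            continue
        ms, me = merged[r.chrom]
        # merged intervals possibly overlapping r
        lo = int(np.searchsorted(me, r.start, side="right"))
        hi = int(np.searchsorted(ms, r.end, side="left"))
        bp = 0
        for i in range(lo, hi):
            bp += min(me[i], r.end) - max(ms[i], r.start)
        out.append((int(bp), bp / (r.end - r.start), bp > 0))
    return out


def _count_associated(regions: Sequence[Region], annotation: Sequence[Region]) -> int:
    return sum(1 for _, _, assoc in overlap_annotate(regions, annotation) if assoc)


def percent_associated(regions: Sequence[Region], annotation: Sequence[Region]) -> float:
    """Percentage of regions touching at least one annotation interval."""
    if not regions:
        raise ValueError("percent_associated: empty region set")
    return 100.0 * _count_associated(regions, annotation) / len(regions)


# ---------------------------------------------------------------------------
# shuffle null


def shuffle_intervals(regions: Sequence[Region], genome: GenomeModel,
                      rng: np.random.Generator) -> list[Region]:
    """Redistribute each region, length preserved, uniformly over the genome.

    A chromosome is drawn with probability proportional to its number of
    valid start positions (L - len + 1); the start is uniform among them.
    Overlaps among shuffled intervals are permitted.
    """
    chroms = list(genome)
    out: list[Region] = []
    for r in regions:
        size = r.end - r.start
        slots = np.array([max(0, L - size + 1) for _, L in chroms], dtype=float)
        total = slots.sum()
        if total <= 0:
            raise ValueError(f"region of length {size} exceeds every chromosome")
        ci = rng.choice(len(chroms), p=slots / total)
        start = int(rng.integers(0, int(slots[ci])))
        out.append(Region(chroms[ci][0], start, start + size))
    return out


# ---------------------------------------------------------------------------
# Obs/Exp statistic


def _group_elements(repeat_annotation: Sequence[RepeatElement],
                    grouping: str) -> dict[str, list[RepeatElement]]:
    groups: dict[str, list[RepeatElement]] = {}
    for e in repeat_annotation:
        key = e.repeat_class if grouping == "class" else e.repeat_subfamily
        groups.setdefault(key, []).append(e)
    return groups


def obs_exp_enrichment(regions: Sequence[Region],
                       repeat_annotation: Sequence[RepeatElement],
                       config: EnrichmentConfig = EnrichmentConfig(),
                       genome: GenomeModel | None = None,
                       ) -> list[EnrichmentResult]:
    """Obs/Exp enrichment of regions in repeat classes or subfamilies.

    Shuffles the region set ``n_shuffles`` times, keeps only groups with at
    least one overlap in the real or any shuffled set, and tests per group
    whether the mean of the per-shuffle Obs/Exp ratios exceeds ``mu0``
    (one-sided one-sample t-test, df = n_shuffles - 1).
    """
    if not regions:
        raise ValueError("obs_exp_enrichment: empty region set")
    if genome is None:
        raise ValueError("obs_exp_enrichment requires the genome for shuffling")
    rng = np.random.default_rng(config.seed)
    shuffled_sets = [shuffle_intervals(regions, genome, rng)
                     for _ in range(config.n_shuffles)]

    groups = _group_elements(repeat_annotation, config.grouping)
    results: list[EnrichmentResult] = []
    for group in sorted(groups):
        elements = groups[group]
        if config.count_events:
            observed = _count_events(regions, elements)
            expected = [_count_events(s, elements) for s in shuffled_sets]
        else:
            observed = _count_associated(regions, elements)
            expected = [_count_associated(s, elements) for s in shuffled_sets]
        if observed == 0 and all(e == 0 for e in expected):
            continue  # no overlap in any of the files
        results.append(obs_exp_ttest(group, observed, expected, config.mu0))
    return results


def obs_exp_ttest(group: str, observed: int, expected: Sequence[int],
                  mu0: float = 1.0) -> EnrichmentResult:
    """Obs/Exp ratios from per-shuffle expected counts, with the one-sided
    one-sample t-test of mean ratio > ``mu0`` (df = n_shuffles - 1).

    Zero expected counts and zero ratio spread are flagged rather than
    producing infinite ratios or t statistics.
    """
    n = len(expected)
    df = n - 1
    if any(e == 0 for e in expected):
        return EnrichmentResult(group, observed, list(expected), [],
                                float("nan"), float("nan"), None, None, df,
                                flag="expected-zero")
    ratios = [observed / e for e in expected]
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1))
    if sd == 0.0:
        return EnrichmentResult(group, observed, list(expected), ratios,
                                mean, sd, None, None, df, flag="sd-zero")
    t = float((mean - mu0) / (sd / np.sqrt(n)))
    p = float(stats.t.sf(t, df=df))
    return EnrichmentResult(group, observed, list(expected), ratios,
                            mean, sd, t, p, df)


def _count_events(regions: Sequence[Region], elements: Sequence[RepeatElement]) -> int:
    """Total region-element overlap pairs (the alternative counting mode)."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for e in elements:
        per_chrom.setdefault(e.chrom, []).append((e.start, e.end))
    for ivs in per_chrom.values():
        ivs.sort()
    n = 0
    for r in regions:
        ivs = per_chrom.get(r.chrom)
        if not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        n += int(np.sum((starts < r.end) & (ends > r.start)))
    return n


# ---------------------------------------------------------------------------
# catalogue utilities


def repeat_composition(repeat_annotation: Sequence[RepeatElement],
                       class_name: str) -> dict[str, float]:
    """Percentage of a class's elements in each of its subfamilies."""
    members = [e for e in repeat_annotation if e.repeat_class == class_name]
    if not members:
        raise ValueError(f"no elements of class {class_name!r}")
    counts: dict[str, int] = {}
    for e in members:
        counts[e.repeat_subfamily] = counts.get(e.repeat_subfamily, 0) + 1
    return {sub: 100.0 * c / len(members) for sub, c in sorted(counts.items())}


def filter_repeats_with_signal(elements: Sequence[RepeatElement],
                               track: BinnedTrack) -> list[RepeatElement]:
    """Keep elements whose overlapping track bins sum to positive signal."""
    w = track.bin_width
    kept: list[RepeatElement] = []
    for e in elements:
        v = track.values[e.chrom]
        b0, b1 = e.start // w, -(-(e.end) // w)
        if float(v[b0:b1].sum()) > 0:
            kept.append(e)
    return kept
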