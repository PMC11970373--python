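"""Binned-signal arithmetic: coverage binning, quantile normalization and
input subtraction.

Quantile normalization forces every sample onto a common empirical
distribution: the value at genome-wide rank *r* in each sample is replaced
by the mean, across samples, of their rank-*r* values.  Ties share the mean
of the reference distribution over the tied rank span, so the procedure is
well-defined on count data with many equal bins.  IP and input samples are
normalized in separate groups; "noise reduction" is then the bin-wise
difference IP − input, with negative values retained (the broad-peak
cutoffs make them irrelevant for calling, and clamping would distort the
matrices fed to clustering).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .core_io import BinnedTrack, GenomeModel, Region

__all__ = ["TrackSet", "Sample", "bin_coverage", "quantile_normalize", "subtract_input"]


@dataclass
class Sample:
    sample_id: str
    role: Literal["IP", "input"]
    condition: str
    track: BinnedTrack


class TrackSet:
    """Ordered collection of IP/input tracks sharing one genome and bin grid."""

    def __init__(self, samples: Iterable[Sample]):
        self.samples = list(samples)
        if not self.samples:
            raise ValueError("TrackSet needs at least one sample")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in TrackSet")
        ref = self.samples[0].track
        for s in self.samples[1:]:
            if not s.track.same_shape(ref):
                raise ValueError(f"sample {s.sample_id}: genome/bin_width mismatch")
        self.genome = ref.genome
        self.bin_width = ref.bin_width

    def by_role(self, role: str) -> list[Sample]:
        return [s for s in self.samples if s.role == role]

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.condition not in seen:
                seen.append(s.condition)
        return seen

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)


def bin_coverage(intervals: Sequence[Region], genome: GenomeModel,
                 bin_width: int = 200) -> BinnedTrack:
    """Per-bin base-pair coverage of a set of intervals (weight 1 per base).

    The value of bin *b* is the total number of interval base pairs falling
    inside *b*; overlapping intervals stack.  Total signal equals total
    interval length (mass conservation).
    """
    track = BinnedTrack(genome, bin_width)
    w = bin_width
    for iv in intervals:
        iv.validate(genome)
        v = track.values[iv.chrom]
        b0, b1 = iv.start // w, (iv.end - 1) // w
        if b0 == b1:
            v[b0] += iv.end - iv.start
            continue
        v[b0] += (b0 + 1) * w - iv.start
        v[b1] += iv.end - b1 * w
        if b1 > b0 + 1:
            v[b0 + 1:b1] += w
    return track


def quantile_normalize(tracks: Sequence[BinnedTrack]) -> list[BinnedTrack]:
    """Cross-sample quantile normalization over all genome-wide bins.

    Returns new tracks whose sorted value vectors are identical across
    samples (the rank-wise mean of the inputs); per-track bin order is
    preserved and tied values within a track receive the mean reference
    value over their tied rank span.
    """
    if len(tracks) < 2:
        raise ValueError("quantile normalization needs at least 2 tracks")
    ref_track = tracks[0]
    for t in tracks[1:]:
        if not t.same_shape(ref_track):
            raise ValueError("all tracks must share genome and bin_width")

    flat = np.stack([t.flatten() for t in tracks])  # samples x N
    n_samples, n_bins = flat.shape
    reference = np.sort(flat, axis=1).mean(axis=0)  # rank-r means

    out: list[BinnedTrack] = []
    for s in range(n_samples):
        v = flat[s]
        order = np.argsort(v, kind="stable")
        sorted_v = v[order]
        normalized_sorted = reference.copy()
        # average the reference over each run of tied input values
        boundaries = np.nonzero(np.diff(sorted_v))[0] + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_bins]))
        csum = np.concatenate(([0.0], np.cumsum(reference)))
        for b0, b1 in zip(starts, ends):
            if b1 - b0 > 1:
                normalized_sorted[b0:b1] = (csum[b1] - csum[b0]) / (b1 - b0)
        new_flat = np.empty(n_bins)
        new_flat[order] = normalized_sorted
        out.append(BinnedTrack.from_flat(ref_track.genome, ref_track.bin_width, new_flat))
    return out


def subtract_input(ip: BinnedTrack, input_track: BinnedTrack) -> BinnedTrack:
    """Noise reduction: bin-wise IP − input (negatives retained)."""
    if not ip.same_shape(input_track):
        raise ValueError("IP and input tracks must share genome and bin_width")
    out = BinnedTrack(ip.genome, ip.bin_width)
    for chrom in ip.genome.names:
        out.values[chrom] = ip.values[chrom] - input_track.values[chrom]
    return out
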