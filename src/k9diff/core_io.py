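"""Domain types and text I/O for the genomic formats the pipeline consumes.

All coordinates are 0-based half-open, the native convention of BED and
bedGraph.  A :class:`GenomeModel` fixes the chromosome universe and its
order; every region, repeat element and signal track is validated against
it.  Signal lives in :class:`BinnedTrack` objects on a fixed-width bin grid
(200 bp by default), which is the resolution the whole analysis operates at.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "GenomeModel",
    "Region",
    "RepeatElement",
    "BinnedTrack",
    "PromoterConfig",
    "read_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_bed",
    "write_bed",
    "read_repeat_bed",
    "write_repeat_bed",
    "extract_promoters",
]


class GenomeModel:
    """Ordered set of chromosomes with lengths.

    The order given at construction is preserved and defines output order
    in every writer and every sorted region list.
    """

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = list(chromosomes)
        if not chroms:
            raise ValueError("genome must contain at least one chromosome")
        names = [c[0] for c in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome name in genome")
        for name, length in chroms:
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValueError(f"chromosome {name!r}: length must be a positive integer, got {length!r}")
        self._names: list[str] = names
        self._lengths: dict[str, int] = {n: int(l) for n, l in chroms}

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self):
        return ((n, self._lengths[n]) for n in self._names)

    def __len__(self) -> int:
        return len(self._names)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenomeModel):
            return NotImplemented
        return self._names == other._names and self._lengths == other._lengths

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}:{self._lengths[n]}" for n in self._names)
        return f"GenomeModel({inner})"

    def total_length(self) -> int:
        return sum(self._lengths.values())

    def chrom_index(self, chrom: str) -> int:
        return self._names.index(chrom)


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)")
        if self.strand is not None and self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, genome: GenomeModel) -> "Region":
        if self.chrom not in genome:
            raise ValueError(f"region on unknown chromosome {self.chrom!r}")
        if self.end > genome.length(self.chrom):
            raise ValueError(
                f"region {self.chrom}:{self.start}-{self.end} extends beyond chromosome end "
                f"({genome.length(self.chrom)})"
            )
        return self


@dataclass(frozen=True)
class RepeatElement(Region):
    """A repeat-annotation interval carrying name, class and subfamily.

    ``repeat_subfamily`` defaults to ``repeat_class`` when the annotation
    gives no finer grouping (RepeatMasker strings without a '/').
    """

    repeat_name: str = ""
    repeat_class: str = ""
    repeat_subfamily: str = ""

    def __post_init__(self):
        super().__post_init__()
        if not self.repeat_class:
            raise ValueError("repeat_class must be non-empty")
        if not self.repeat_subfamily:
            object.__setattr__(self, "repeat_subfamily", self.repeat_class)


@dataclass(frozen=True)
class PromoterConfig:
    """Promoter = the window ``flank`` bp either side of the TSS (default 1 kb)."""

    flank: int = 1000

    def __post_init__(self):
        if self.flank <= 0:
            raise ValueError("flank must be positive")


class BinnedTrack:
    """Fixed-width binned signal over a genome.

    Bin ``i`` of a chromosome of length ``L`` covers
    ``[i*w, min((i+1)*w, L))``; there are ``ceil(L/w)`` bins.
    """

    def __init__(self, genome: GenomeModel, bin_width: int = 200,
                 values: dict[str, np.ndarray] | None = None):
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.genome = genome
        self.bin_width = int(bin_width)
        self.values: dict[str, np.ndarray] = {}
        for chrom, length in genome:
            n = -(-length // bin_width)  # ceil division
            if values is not None and chrom in values:
                v = np.asarray(values[chrom], dtype=float)
                if v.shape != (n,):
                    raise ValueError(f"{chrom}: expected {n} bins, got {v.shape}")
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"{chrom}: non-finite values in track")
                self.values[chrom] = v.copy()
            else:
                self.values[chrom] = np.zeros(n, dtype=float)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def total_bins(self) -> int:
        return sum(len(v) for v in self.values.values())

    def flatten(self) -> np.ndarray:
        """All bin values concatenated in genome chromosome order."""
        return np.concatenate([self.values[c] for c in self.genome.names])

    @classmethod
    def from_flat(cls, genome: GenomeModel, bin_width: int, flat: np.ndarray) -> "BinnedTrack":
        track = cls(genome, bin_width)
        offset = 0
        for chrom in genome.names:
            n = track.n_bins(chrom)
            track.values[chrom] = np.asarray(flat[offset:offset + n], dtype=float).copy()
            offset += n
        if offset != len(flat):
            raise ValueError("flat vector length does not match genome bin count")
        return track

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.genome, self.bin_width, self.values)

    def same_shape(self, other: "BinnedTrack") -> bool:
        return self.genome == other.genome and self.bin_width == other.bin_width

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinnedTrack):
            return NotImplemented
        return (self.same_shape(other)
                and all(np.array_equal(self.values[c], other.values[c]) for c in self.genome.names))


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path: str | Path) -> GenomeModel:
    """Read a two-column ``chrom.sizes`` TSV into a :class:`GenomeModel`."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            name, raw_len = parts[0], parts[1]
            try:
                length = int(raw_len)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer length {raw_len!r}") from None
            chroms.append((name, length))
    if not chroms:
        raise ValueError(f"{path}: empty chrom.sizes file")
    return GenomeModel(chroms)


def read_bedgraph(path: str | Path, genome: GenomeModel, bin_width: int = 200) -> BinnedTrack:
    """Read a bedGraph whose intervals lie on the ``bin_width`` grid.

    Intervals spanning several bins are expanded; uncovered bins are 0.
    The last bin of a chromosome may be truncated by the chromosome end, so
    an interval ending exactly at the chromosome end is on-grid.
    """
    track = BinnedTrack(genome, bin_width)
    w = bin_width
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            start, end, value = int(s), int(e), float(v)
            L = genome.length(chrom)
            if end > L:
                raise ValueError(f"{path}:{lineno}: interval beyond chromosome end")
            if start % w != 0 or (end % w != 0 and end != L):
                raise ValueError(f"{path}:{lineno}: interval {start}-{end} off the {w}-bp bin grid")
            track.values[chrom][start // w: -(-end // w)] = value
    return track


def write_bedgraph(track: BinnedTrack, path: str | Path, merge_equal: bool = True) -> None:
    """Write a track as bedGraph; with ``merge_equal`` runs of equal bins
    become one line (round-trips through :func:`read_bedgraph`)."""
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom, length in track.genome:
            v = track.values[chrom]
            if merge_equal:
                # run-length encode adjacent equal values
                change = np.nonzero(np.diff(v))[0] + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(v)]))
                for b0, b1 in zip(starts, ends):
                    fh.write(f"{chrom}\t{b0 * w}\t{min(b1 * w, length)}\t{_fmt(v[b0])}\n")
            else:
                for i, val in enumerate(v):
                    fh.write(f"{chrom}\t{i * w}\t{min((i + 1) * w, length)}\t{_fmt(val)}\n")


def _fmt(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() and abs(x) < 1e15 else repr(float(x))


def read_bed(path: str | Path, genome: GenomeModel) -> list[Region]:
    """Read BED3+ into validated :class:`Region` objects."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] != "." else None
            try:
                region = Region(chrom, start, end, name=name, score=score, strand=strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            regions.append(region.validate(genome))
    return regions


def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    """Write regions as BED, keeping optional columns that are present."""
    with open(path, "w") as fh:
        for r in regions:
            cols = [r.chrom, str(r.start), str(r.end)]
            if r.name is not None or r.score is not None or r.strand is not None:
                cols.append(r.name if r.name is not None else ".")
            if r.score is not None or r.strand is not None:
                cols.append(_fmt(r.score) if r.score is not None else ".")
            if r.strand is not None:
                cols.append(r.strand)
            fh.write("\t".join(cols) + "\n")


def read_repeat_bed(path: str | Path, genome: GenomeModel,
                    dialect: Literal["columns", "slash"] = "columns") -> list[RepeatElement]:
    """Read a RepeatMasker-style BED.

    ``columns`` dialect: class and subfamily in two extra columns after the
    standard BED6 fields.  ``slash`` dialect: one extra column holding
    ``class/subfamily`` which is split on the first '/'; a bare class (no
    '/') yields subfamily = class.  Class strings containing '?' are kept
    verbatim.
    """
    elements: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            rname = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else None
            if dialect == "slash":
                if len(parts) < 7:
                    raise ValueError(f"{path}:{lineno}: missing class/subfamily column")
                cls, _, sub = parts[6].partition("/")
            elif dialect == "columns":
                if len(parts) < 8:
                    raise ValueError(f"{path}:{lineno}: missing class and subfamily columns")
                cls, sub = parts[6], parts[7]
            else:
                raise ValueError(f"unknown repeat BED dialect {dialect!r}")
            if not cls:
                raise ValueError(f"{path}:{lineno}: empty repeat class")
            elem = RepeatElement(chrom, start, end, name=rname, score=score, strand=strand,
                                 repeat_name=rname, repeat_class=cls, repeat_subfamily=sub or cls)
            elem.validate(genome)
            elements.append(elem)
    return elements


def write_repeat_bed(elements: Sequence[RepeatElement], path: str | Path) -> None:
    """Write repeat elements in the ``columns`` dialect (BED6 + class + subfamily)."""
    with open(path, "w") as fh:
        for e in elements:
            fh.write("\t".join([
                e.chrom, str(e.start), str(e.end), e.repeat_name or ".",
                _fmt(e.score) if e.score is not None else ".",
                e.strand or ".", e.repeat_class, e.repeat_subfamily,
            ]) + "\n")


def extract_promoters(genes: Sequence[Region], config: PromoterConfig,
                      genome: GenomeModel) -> list[Region]:
    """Derive promoters as the ``flank`` bp either side of each TSS.

    The TSS of a '+' gene is its start, of a '-' gene its end.  Promoters
    are clipped to chromosome bounds, exact-duplicate intervals are removed,
    and the result is sorted by (genome chromosome order, start, end).
    """
    seen: set[tuple[str, int, int]] = set()
    promoters: list[Region] = []
    for gene in genes:
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene.chrom}:{gene.start}-{gene.end} has no strand")
        tss = gene.start if gene.strand == "+" else gene.end
        L = genome.length(gene.chrom)
        start = max(0, tss - config.flank)
        end = min(L, tss + config.flank)
        if start >= end:
            continue
        key = (gene.chrom, start, end)
        if key in seen:
            continue
        seen.add(key)
        promoters.append(Region(gene.chrom, start, end, name=gene.name))
    order = {name: i for i, name in enumerate(genome.names)}
    promoters.sort(key=lambda r: (order[r.chrom], r.start, r.end))
    return promoters
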