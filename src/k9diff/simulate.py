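"""Synthetic genomes, repeat catalogues and IP/input tracks with planted
heterochromatin domains.

The generator emulates the structure the differential analysis assumes:
a small genome (two 2-Mb chromosomes by default) carrying a repeat
catalogue with LTR (ERV1, ERVL, ERVL-MalR), SINE (Alu, MIR), Satellite and
a neutral class; broad elevated-signal domains that are shared between two
conditions (*common*) or specific to one (*gain*: condition B only,
*loss*: condition A only); and Poisson-distributed 200-bp bin counts for
IP and input samples.  Differential domains are, with probability
``p_enrich``, centred on a randomly chosen element of a target repeat
class, planting the repeat enrichment the Obs/Exp statistic measures.
Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    BinnedTrack,
    GenomeModel,
    Region,
    RepeatElement,
    write_bed,
    write_bedgraph,
    write_repeat_bed,
)
from .signal import Sample, TrackSet

__all__ = [
    "RepeatSpec",
    "DomainSpec",
    "SignalSpec",
    "SimulationConfig",
    "TruthTable",
    "simulate_repeats",
    "simulate_domains",
    "simulate_tracks",
    "simulate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class RepeatSpec:
    """One (class, subfamily) stratum: element count and length range."""

    repeat_class: str
    repeat_subfamily: str
    count: int
    min_len: int
    max_len: int


# Element counts approximate human-genome repeat densities on a 4-Mb
# genome: SINE ~13% of bp (Alu:MIR roughly 2:1 by count), LTR ~9% with
# subfamily shares near ERV1 24% / ERVL 22% / ERVL-MalR 47%, a few large
# satellites, plus a neutral control class carrying no planted enrichment.
DEFAULT_REPEATS: tuple[RepeatSpec, ...] = (
    RepeatSpec("SINE", "Alu", 1200, 250, 350),
    RepeatSpec("SINE", "MIR", 500, 100, 250),
    RepeatSpec("LTR", "ERV1", 150, 300, 800),
    RepeatSpec("LTR", "ERVL", 140, 300, 800),
    RepeatSpec("LTR", "ERVL-MalR", 290, 300, 800),
    RepeatSpec("Satellite", "Satellite", 15, 2000, 8000),
    RepeatSpec("NEUTRAL", "NEUTRAL", 500, 200, 500),
)


@dataclass(frozen=True)
class DomainSpec:
    """Counts of planted domains and their length range."""

    n_common: int = 30
    n_gain: int = 20
    n_loss: int = 20
    min_len: int = 600
    max_len: int = 3000


@dataclass(frozen=True)
class SignalSpec:
    """Poisson means per 200-bp bin.

    ``background_mean`` is the IP level outside domains, ``domain_fold``
    the signal added inside an active domain, ``input_mean`` the input
    level everywhere; defaults put domain bins far above the calling
    cutoffs used on the synthetic data, so decision-boundary behaviour is
    exercised by dedicated small-track tests instead.
    """

    background_mean: float = 20.0
    domain_fold: float = 60.0
    input_mean: float = 20.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 2_000_000), ("chr2", 2_000_000))
    bin_width: int = 200
    repeats: tuple[RepeatSpec, ...] = DEFAULT_REPEATS
    domains: DomainSpec = field(default_factory=DomainSpec)
    target_class: str = "LTR"       # repeat class differential domains anchor to
    p_enrich: float = 0.8           # probability a differential domain is anchored
    signal: SignalSpec = field(default_factory=SignalSpec)
    conditions: tuple[str, ...] = ("A", "B")
    replicates: int = 1

    def __post_init__(self):
        if not 0 <= self.p_enrich <= 1:
            raise ValueError("p_enrich must be in [0, 1]")
        if self.signal.background_mean <= 0 or self.signal.input_mean <= 0:
            raise ValueError("Poisson means must be positive")

    def genome_model(self) -> GenomeModel:
        return GenomeModel(self.genome)


@dataclass
class TruthTable:
    """Planted domains with their labels and anchoring."""

    domains: list[Region]            # name column carries the label
    labels: list[str]                # common / gain / loss, parallel to domains
    anchored_class: list[str | None]  # target class if anchored, else None
    p_enrich: float

    def by_label(self, label: str) -> list[Region]:
        return [d for d, l in zip(self.domains, self.labels) if l == label]


def _uniform_region(length: int, genome: GenomeModel, rng: np.random.Generator) -> Region:
    chroms = list(genome)
    slots = np.array([max(0, L - length + 1) for _, L in chroms], dtype=float)
    total = slots.sum()
    if total <= 0:
        raise ValueError(f"length {length} exceeds every chromosome")
    ci = rng.choice(len(chroms), p=slots / total)
    start = int(rng.integers(0, int(slots[ci])))
    return Region(chroms[ci][0], start, start + length)


def simulate_repeats(config: SimulationConfig, rng: np.random.Generator) -> list[RepeatElement]:
    """Draw the repeat catalogue: per stratum, ``count`` elements with
    uniform lengths and uniform placement (overlaps permitted)."""
    genome = config.genome_model()
    elements: list[RepeatElement] = []
    for spec in config.repeats:
        for i in range(spec.count):
            length = int(rng.integers(spec.min_len, spec.max_len + 1))
            r = _uniform_region(length, genome, rng)
            elements.append(RepeatElement(
                r.chrom, r.start, r.end,
                name=f"{spec.repeat_subfamily}_{i}",
                repeat_name=f"{spec.repeat_subfamily}_{i}",
                repeat_class=spec.repeat_class,
                repeat_subfamily=spec.repeat_subfamily))
    return elements


def simulate_domains(config: SimulationConfig, repeats: Sequence[RepeatElement],
                     rng: np.random.Generator) -> TruthTable:
    """Place common domains uniformly; anchor each differential domain on a
    random element of the target class with probability ``p_enrich``.

    Planted domains are kept mutually disjoint and separated by a 6-kb
    margin (anchor elements drawn without replacement, uniform placements
    rejection-sampled): overlapping gain and loss domains would plant a
    region whose real signal is *common*, and domains closer than the
    10-kb profile window would bleed into each other's signal rows,
    leaving the truth table ill-defined either way.
    """
    genome = config.genome_model()
    targets = [e for e in repeats if e.repeat_class == config.target_class]
    spec = config.domains
    needs_anchor = (spec.n_gain + spec.n_loss) > 0 and config.p_enrich > 0
    if needs_anchor and not targets:
        raise ValueError(f"no elements of target class {config.target_class!r} to anchor on")
    anchor_pool = list(range(len(targets)))

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}

    def clear(region: Region, margin: int = 6000) -> bool:
        return all(region.end + margin <= s or e + margin <= region.start
                   for s, e in placed[region.chrom])

    domains: list[Region] = []
    labels: list[str] = []
    anchored: list[str | None] = []
    plan = [("common", spec.n_common), ("gain", spec.n_gain), ("loss", spec.n_loss)]
    for label, count in plan:
        for i in range(count):
            length = int(rng.integers(spec.min_len, spec.max_len + 1))
            region: Region | None = None
            anchor: str | None = None
            if label != "common" and rng.random() < config.p_enrich:
                for _ in range(1000):
                    if not anchor_pool:
                        raise ValueError("anchor elements exhausted; reduce domain counts")
                    j = int(rng.integers(0, len(anchor_pool)))
                    elem = targets[anchor_pool[j]]
                    centre = (elem.start + elem.end) // 2
                    L = genome.length(elem.chrom)
                    start = max(0, min(centre - length // 2, L - length))
                    candidate = Region(elem.chrom, start, start + length)
                    if clear(candidate):
                        anchor_pool.pop(j)
                        region, anchor = candidate, config.target_class
                        break
                    anchor_pool.pop(j)
                if region is None:
                    raise ValueError("could not place anchored domain without overlap")
            else:
                for _ in range(1000):
                    candidate = _uniform_region(length, genome, rng)
                    if clear(candidate):
                        region = candidate
                        break
                if region is None:
                    raise ValueError("could not place domain without overlap; genome too crowded")
            placed[region.chrom].append((region.start, region.end))
            domains.append(Region(region.chrom, region.start, region.end, name=label))
            labels.append(label)
            anchored.append(anchor)
    return TruthTable(domains, labels, anchored, config.p_enrich)


def simulate_tracks(config: SimulationConfig, truth: TruthTable,
                    rng: np.random.Generator) -> TrackSet:
    """Poisson bin counts: input ~ Poisson(input_mean) everywhere; IP ~
    Poisson(background + fold · [bin in an active domain]).  Common domains
    are active in every condition, gain domains only in the last condition,
    loss domains only in the first."""
    genome = config.genome_model()
    w = config.bin_width
    sig = config.signal
    cond_first, cond_last = config.conditions[0], config.conditions[-1]

    # per-condition indicator of active-domain bins
    active: dict[str, dict[str, np.ndarray]] = {
        c: {chrom: np.zeros(-(-L // w), dtype=bool) for chrom, L in genome}
        for c in config.conditions
    }
    for d, label in zip(truth.domains, truth.labels):
        if label == "common":
            conds = list(config.conditions)
        elif label == "gain":
            conds = [cond_last]
        else:
            conds = [cond_first]
        b0, b1 = d.start // w, -(-d.end // w)
        for c in conds:
            active[c][d.chrom][b0:b1] = True

    samples: list[Sample] = []
    for cond in config.conditions:
        for rep in range(1, config.replicates + 1):
            ip = BinnedTrack(genome, w)
            inp = BinnedTrack(genome, w)
            for chrom, L in genome:
                lam = sig.background_mean + sig.domain_fold * active[cond][chrom]
                ip.values[chrom] = rng.poisson(lam).astype(float)
                inp.values[chrom] = rng.poisson(sig.input_mean, size=len(lam)).astype(float)
            samples.append(Sample(f"{cond}_rep{rep}_IP", "IP", cond, ip))
            samples.append(Sample(f"{cond}_rep{rep}_input", "input", cond, inp))
    return TrackSet(samples)


def simulate_dataset(config: SimulationConfig):
    """Convenience wrapper: repeats, truth table and tracks from one seed."""
    rng = np.random.default_rng(config.seed)
    repeats = simulate_repeats(config, rng)
    truth = simulate_domains(config, repeats, rng)
    tracks = simulate_tracks(config, truth, rng)
    return repeats, truth, tracks


def write_dataset(genome: GenomeModel, repeats: Sequence[RepeatElement],
                  truth: TruthTable, tracks: TrackSet, out_dir: str | Path) -> dict[str, Path]:
    """Write chrom.sizes, repeat BED (columns dialect), per-sample
    bedGraphs and a truth TSV; re-reading reproduces the objects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    sizes = out / "genome.chrom.sizes"
    with open(sizes, "w") as fh:
        for chrom, L in genome:
            fh.write(f"{chrom}\t{L}\n")
    paths["chrom_sizes"] = sizes

    rep_path = out / "repeats.bed"
    write_repeat_bed(list(repeats), rep_path)
    paths["repeats"] = rep_path

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\tanchored_class\n")
        for d, label, anchor in zip(truth.domains, truth.labels, truth.anchored_class):
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{label}\t{anchor or '.'}\n")
    paths["truth"] = truth_path

    sheet = out / "samples.tsv"
    with open(sheet, "w") as fh:
        fh.write("sample_id\trole\tcondition\tbedgraph\n")
        for s in tracks:
            bg = out / f"{s.sample_id}.bedgraph"
            write_bedgraph(s.track, bg)
            paths[s.sample_id] = bg
            fh.write(f"{s.sample_id}\t{s.role}\t{s.condition}\t{bg.name}\n")
    paths["sample_sheet"] = sheet
    return paths
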