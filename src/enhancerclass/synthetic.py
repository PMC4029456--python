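"""Synthetic genomes, motifs, enhancers and chromatin tracks.

The generator emulates the statistical structure the analysis assumes:
a random background genome, a panel of position weight matrices of
which a few "drivers" have instances planted inside enhancers, and
per-mark windowed signal tracks in which informative marks are elevated
over enhancers against Gaussian noise.  Everything is deterministic
under a fixed seed, and the generated files are loadable by
:mod:`enhancerclass.io`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    Genome,
    GenomicRegion,
    PWM,
    SignalTrack,
    overlaps,
    reverse_complement,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_jaspar_pfm,
)

__all__ = [
    "MARK_NAMES",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_genome",
    "generate_pwms",
    "place_enhancers",
    "simulate_tracks",
    "generate_dataset",
]

#: Canonical mark panel: six histone modifications plus PolII occupancy
#: and Mef2 binding, the signals typically profiled around enhancers.
MARK_NAMES = (
    "H3K4me1",
    "H3K4me3",
    "H3K27Ac",
    "H3K27me3",
    "H3K36me3",
    "H3K79me3",
    "Mef2",
    "PolII",
)

BASES = "ACGT"


def _default_informative_marks() -> dict[str, float]:
    # enhancer-associated mark, transcription-coupled mark, and the
    # tissue-specific TF track, with decreasing effect sizes
    return {"H3K4me1": 4.0, "H3K36me3": 3.0, "Mef2": 2.0}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the real positive set at reduced scale: 500
    enhancers with Gaussian lengths (mean 270.47 bp, sd 112 bp), an
    8-mark panel of which 3 are informative, and a 20-motif panel of
    which 2 are drivers planted inside enhancers.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    chrom_prefix: str = "chr"
    gc_content: float = 0.43
    n_positives: int = 500
    pos_length_mean: float = 270.47
    pos_length_sd: float = 112.0
    n_motifs: int = 20
    n_driver_motifs: int = 2
    motif_length_range: tuple[int, int] = (8, 12)
    plants_per_enhancer: float = 3.0
    n_marks: int = 8
    informative_marks: dict[str, float] = field(default_factory=_default_informative_marks)
    noise_sd: float = 1.0
    window_width: int = 50
    nonadditive_pair: tuple[str, str] | None = None
    repeat_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must lie in [0, 1]")
        if self.n_driver_motifs > self.n_motifs:
            raise ValueError("driver motifs must be a subset of motifs")
        if self.n_marks > len(MARK_NAMES):
            raise ValueError(f"at most {len(MARK_NAMES)} marks available")
        if min(self.n_chroms, self.n_positives, self.n_motifs) < 0:
            raise ValueError("counts must be >= 0")
        unknown = set(self.informative_marks) - set(self.mark_names)
        if unknown:
            raise ValueError(f"informative marks {sorted(unknown)} not in mark panel")
        if self.nonadditive_pair is not None:
            pair = tuple(self.nonadditive_pair)
            if len(pair) != 2 or any(m not in self.mark_names for m in pair):
                raise ValueError("nonadditive_pair must name two marks in the panel")
            self.nonadditive_pair = pair
        lo, hi = self.motif_length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid motif_length_range")

    @property
    def mark_names(self) -> tuple[str, ...]:
        return MARK_NAMES[: self.n_marks]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    genome: Genome
    positives: list[GenomicRegion]
    repeat_tracts: list[GenomicRegion]
    pwms: list[PWM]
    tracks: list[SignalTrack]
    truth: dict
    config: SyntheticConfig


# ---------------------------------------------------------------------------


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[Genome, list[GenomicRegion]]:
    """I.i.d. background genome plus optional low-complexity tracts.

    Bases are drawn independently with P(G) = P(C) = gc/2.  Repeat
    tracts are non-overlapping runs of a repeated 2-mer covering about
    ``repeat_fraction`` of the genome, returned as annotated regions.
    """
    if config.chrom_length < 10 * config.pos_length_mean:
        raise ValueError(
            "infeasible config: chrom_length must be >= 10 x pos_length_mean"
        )
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs: dict[str, str] = {}
    for i in range(config.n_chroms):
        draws = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=config.chrom_length, p=probs)
        seqs[f"{config.chrom_prefix}{i + 1}"] = draws.tobytes().decode("ascii")
    genome = Genome(seqs)

    tracts: list[GenomicRegion] = []
    if config.repeat_fraction > 0:
        total = config.n_chroms * config.chrom_length
        target = config.repeat_fraction * total
        covered = 0
        attempts = 0
        while covered < target and attempts < 10_000:
            attempts += 1
            chrom = f"{config.chrom_prefix}{rng.integers(config.n_chroms) + 1}"
            length = int(rng.integers(200, 801))
            start = int(rng.integers(0, config.chrom_length - length))
            cand = GenomicRegion(chrom, start, start + length)
            if any(overlaps(cand, t) for t in tracts):
                continue
            unit = "".join(rng.choice(list(BASES), size=2, replace=False))
            tract_seq = (unit * (length // 2 + 1))[:length]
            genome._set_slice(chrom, start, tract_seq)
            tracts.append(cand)
            covered += length
    return genome, tracts


def _longest_shared_run(a: str, b: str) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while i + k < len(a) and j + k < len(b) and a[i + k] == b[j + k]:
                k += 1
            best = max(best, k)
    return best


def generate_pwms(config: SyntheticConfig, rng: np.random.Generator) -> list[PWM]:
    """Random probability PWMs with one dominant base per position.

    The dominant-base probability is drawn in [0.85, 0.95] so planted
    instances are detectable against background, and panel members are
    redrawn until their consensus words (either strand) share at most
    a 5-mer — a non-redundant panel, in the spirit of curated motif
    collections, so that planted drivers do not bleed signal into
    unrelated motifs.  The first ``n_driver_motifs`` ids are drivers.
    """
    lo, hi = config.motif_length_range
    pwms: list[PWM] = []
    consensi: list[str] = []
    for i in range(config.n_motifs):
        for _attempt in range(100):
            m = int(rng.integers(lo, hi + 1))
            mat = np.empty((m, 4))
            for j in range(m):
                dom = int(rng.integers(4))
                p_dom = rng.uniform(0.85, 0.95)
                rest = (1.0 - p_dom) / 3.0
                mat[j] = rest
                mat[j, dom] = p_dom
            pwm = PWM(id=f"TF{i + 1:03d}", matrix=mat)
            cons = pwm.consensus()
            rc = reverse_complement(cons)
            if all(
                max(_longest_shared_run(cons, c), _longest_shared_run(rc, c)) <= 5
                for c in consensi
            ):
                break
        pwms.append(pwm)
        consensi.append(cons)
    return pwms


def _sample_length(
    rng: np.random.Generator, mean: float, sd: float, minimum: int
) -> int:
    for _ in range(10_000):
        length = int(round(rng.normal(mean, sd)))
        if length >= minimum:
            return length
    raise RuntimeError("length distribution places almost no mass above the minimum")


def place_enhancers(
    config: SyntheticConfig,
    genome: Genome,
    rng: np.random.Generator,
    pwms: list[PWM] | None = None,
) -> list[GenomicRegion]:
    """Place non-overlapping enhancers and plant driver-motif instances.

    Lengths follow Normal(pos_length_mean, pos_length_sd) rounded,
    redrawn while shorter than twice the longest motif.  Each enhancer
    receives Poisson(plants_per_enhancer) driver instances, sampled
    base-by-base from the PWM, on a random strand, at uniform
    non-overlapping offsets; instances never straddle the enhancer
    boundary.  The genome sequence is overwritten in place.
    """
    if pwms is None:
        pwms = generate_pwms(config, rng)
    drivers = pwms[: config.n_driver_motifs]
    max_m = max((p.length for p in pwms), default=1)
    min_len = max(2 * max_m, 20)
    sizes = genome.sizes()
    chrom_names = list(sizes)
    chrom_weights = np.array([sizes[c] for c in chrom_names], dtype=float)
    chrom_weights /= chrom_weights.sum()

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    positives: list[GenomicRegion] = []
    budget = 1000 * max(config.n_positives, 1)
    attempts = 0
    for i in range(config.n_positives):
        while True:
            attempts += 1
            if attempts > budget:
                raise RuntimeError(
                    f"could not place {config.n_positives} non-overlapping "
                    f"enhancers within {budget} attempts"
                )
            length = _sample_length(rng, config.pos_length_mean, config.pos_length_sd, min_len)
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
            if length >= sizes[chrom]:
                continue
            start = int(rng.integers(0, sizes[chrom] - length + 1))
            end = start + length
            if any(s < end and start < e for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            region = GenomicRegion(chrom, start, end, label="positive", id=f"pos{i + 1:05d}")
            positives.append(region)
            break

        if drivers and config.plants_per_enhancer > 0:
            n_plants = rng.poisson(config.plants_per_enhancer)
            enh = bytearray(genome.fetch(region), "ascii")
            occupied: list[tuple[int, int]] = []
            for _ in range(n_plants):
                pwm = drivers[rng.integers(len(drivers))]
                m = pwm.length
                site = "".join(
                    BASES[rng.choice(4, p=pwm.matrix[j] / pwm.matrix[j].sum())]
                    for j in range(m)
                )
                if rng.random() < 0.5:
                    site = reverse_complement(site)
                for _try in range(50):
                    off = int(rng.integers(0, length - m + 1))
                    if all(off + m <= s or off >= e for s, e in occupied):
                        enh[off : off + m] = site.encode("ascii")
                        occupied.append((off, off + m))
                        break
            genome._set_slice(chrom, start, enh.decode("ascii"))
    return positives


def simulate_tracks(
    config: SyntheticConfig,
    genome: Genome,
    positives: list[GenomicRegion],
    rng: np.random.Generator,
) -> list[SignalTrack]:
    """Windowed mark signal: delta over enhancers plus Gaussian noise.

    Window value = delta_m * 1[window overlaps an enhancer] +
    Normal(0, noise_sd), with delta_m = 0 for uninformative marks.
    When ``nonadditive_pair`` is set, a fair coin per enhancer routes
    the whole effect to exactly one of the paired marks, so each mark
    alone is weakly informative but jointly they separate the classes.
    """
    w = config.window_width
    sizes = genome.sizes()
    # indicator masks per mark: a window overlapping any (routed) enhancer
    # gets the effect once, even where two enhancers share a window
    masks: dict[str, dict[str, np.ndarray]] = {
        mark: {c: np.zeros(math.ceil(s / w), dtype=bool) for c, s in sizes.items()}
        for mark in config.informative_marks
    }
    pair = config.nonadditive_pair
    for region in positives:
        i0 = region.start // w
        i1 = (region.end - 1) // w
        if pair is not None:
            routed = pair[int(rng.random() < 0.5)]
        for mark in config.informative_marks:
            if pair is not None and mark in pair and mark != routed:
                continue
            masks[mark][region.chrom][i0 : i1 + 1] = True

    tracks: list[SignalTrack] = []
    for mark in config.mark_names:
        values = {}
        for chrom, size in sizes.items():
            vec = rng.normal(0.0, config.noise_sd, size=math.ceil(size / w))
            if mark in masks:
                vec += config.informative_marks[mark] * masks[mark][chrom]
            values[chrom] = vec
        tracks.append(SignalTrack(mark=mark, width=w, values=values))
    return tracks


def generate_dataset(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Compose genome, motifs, enhancers and tracks from one seed.

    When ``outdir`` is given, writes genome.fa, positives.bed, one
    bedGraph per mark, motifs.pfm, truth.json and config.json — all
    loadable by :mod:`enhancerclass.io`.
    """
    rng = np.random.default_rng(config.seed)
    genome, tracts = generate_genome(config, rng)
    pwms = generate_pwms(config, rng)
    positives = place_enhancers(config, genome, rng, pwms=pwms)
    tracks = simulate_tracks(config, genome, positives, rng)
    truth = {
        "driver_motifs": [p.id for p in pwms[: config.n_driver_motifs]],
        "informative_marks": dict(config.informative_marks),
        "nonadditive_pair": list(config.nonadditive_pair) if config.nonadditive_pair else None,
        "seed": config.seed,
    }
    ds = SyntheticDataset(
        genome=genome,
        positives=positives,
        repeat_tracts=tracts,
        pwms=pwms,
        tracks=tracks,
        truth=truth,
        config=config,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fa")
        write_bed(positives, outdir / "positives.bed")
        if tracts:
            write_bed(tracts, outdir / "repeats.bed")
        write_jaspar_pfm(pwms, outdir / "motifs.pfm")
        for track in tracks:
            write_bedgraph(track, outdir / f"{track.mark}.bedgraph")
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
        (outdir / "config.json").write_text(config.to_json())
    return ds
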