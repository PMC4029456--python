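"""Negative-set sampling: random background regions length-matched to
the positive enhancer set, with exclusion and repeat-avoidance filters.

Lengths are drawn from a Gaussian fitted to the positive set (sample
mean / sample sd), chromosomes are chosen proportionally to their
length, and candidates overlapping any exclusion set are rejected and
redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import Genome, GenomicRegion, overlaps

__all__ = [
    "SamplerSpec",
    "fit_length_distribution",
    "sample_negatives",
    "remove_overlapping",
]

#: Gaussian length draws below this are redrawn; the fitted Gaussian
#: has positive mass below 1 bp.
MIN_NEGATIVE_LENGTH = 20

#: Candidates with more than this fraction of N bases are rejected.
MAX_N_FRACTION = 0.5


@dataclass
class SamplerSpec:
    n: int
    length_mean: float
    length_sd: float
    exclusions: dict[str, Sequence[GenomicRegion]] = field(default_factory=dict)
    mutual_exclusion: bool = True
    max_attempts_factor: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.length_mean <= 0:
            raise ValueError("length_mean must be > 0")
        if self.length_sd < 0:
            raise ValueError("length_sd must be >= 0")


def fit_length_distribution(positives: Sequence[GenomicRegion]) -> tuple[float, float]:
    """Sample mean and sample sd (n-1 denominator) of region lengths."""
    if len(positives) < 2:
        raise ValueError("need at least 2 regions to fit a length distribution")
    lengths = np.array([r.length for r in positives], dtype=float)
    return float(lengths.mean()), float(lengths.std(ddof=1))


def _trees(regions: Sequence[GenomicRegion]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    return trees


def sample_negatives(
    genome_sizes: Mapping[str, int],
    spec: SamplerSpec,
    rng: np.random.Generator | None = None,
    genome: Genome | None = None,
) -> list[GenomicRegion]:
    """Draw exactly ``spec.n`` negative regions from the background.

    Each length ~ Normal(mean, sd) rounded, redrawn while below
    ``MIN_NEGATIVE_LENGTH``; chromosome chosen with probability
    proportional to length, start uniform.  Candidates overlapping any
    exclusion set (or, with ``mutual_exclusion``, any prior draw) are
    rejected.  If a ``genome`` is supplied, candidates with >50% N
    bases are also rejected.  Errors when the attempt budget is
    exhausted, naming the exclusion set that rejected most candidates.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    chroms = list(genome_sizes)
    if not chroms:
        raise ValueError("empty genome")
    weights = np.array([genome_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    excl_trees = {name: _trees(regs) for name, regs in spec.exclusions.items()}
    drawn_tree: dict[str, IntervalTree] = {}
    rejections: dict[str, int] = {name: 0 for name in spec.exclusions}
    rejections["<mutual>"] = 0
    rejections["<N-content>"] = 0

    negatives: list[GenomicRegion] = []
    budget = spec.n * spec.max_attempts_factor
    # mutual exclusion can wedge itself in tight free space (early draws
    # blocking the only feasible layout); a stall discards them and retries
    stall_limit = max(200, 10 * spec.n)
    attempts = 0
    stalled = 0
    while len(negatives) < spec.n:
        attempts += 1
        if spec.mutual_exclusion and negatives and stalled > stall_limit:
            negatives.clear()
            drawn_tree.clear()
            stalled = 0
        if attempts > budget:
            tightest = max(rejections, key=rejections.get)
            raise RuntimeError(
                f"exhausted {budget} attempts after drawing "
                f"{len(negatives)}/{spec.n} negatives; tightest exclusion: "
                f"{tightest} ({rejections[tightest]} rejections)"
            )
        length = int(round(rng.normal(spec.length_mean, spec.length_sd)))
        if length < MIN_NEGATIVE_LENGTH:
            continue
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        if length >= genome_sizes[chrom]:
            continue
        start = int(rng.integers(0, genome_sizes[chrom] - length + 1))
        end = start + length

        hit = None
        for name, trees in excl_trees.items():
            if chrom in trees and trees[chrom].overlaps(start, end):
                hit = name
                break
        if hit is None and spec.mutual_exclusion:
            if chrom in drawn_tree and drawn_tree[chrom].overlaps(start, end):
                hit = "<mutual>"
        if hit is None and genome is not None:
            seq = genome[chrom][start:end]
            if seq.count("N") > MAX_N_FRACTION * length:
                hit = "<N-content>"
        if hit is not None:
            rejections[hit] += 1
            stalled += 1
            continue

        stalled = 0
        negatives.append(
            GenomicRegion(chrom, start, end, label="negative", id=f"neg{len(negatives) + 1:05d}")
        )
        if spec.mutual_exclusion:
            drawn_tree.setdefault(chrom, IntervalTree()).addi(start, end)
    return negatives


def remove_overlapping(
    candidates: Sequence[GenomicRegion], reference: Sequence[GenomicRegion]
) -> list[GenomicRegion]:
    """Keep candidates with no overlap against any reference region.

    Used to purge external validation sets of regions overlapping the
    training set, which would otherwise bias validation metrics.
    Order is preserved.
    """
    trees = _trees(reference)
    kept = []
    for c in candidates:
        if c.chrom in trees and trees[c.chrom].overlaps(c.start, c.end):
            continue
        kept.append(c)
    return kept
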