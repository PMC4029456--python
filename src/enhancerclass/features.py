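"""Region features: thermodynamic motif affinities and mark averages.

Motif (MOT) features use the TRAP occupancy model: a position weight
matrix assigns each length-m window a mismatch energy

    E_i = (1/lambda) * sum_j ln( p(j, b*_j) / p(j, b_ij) )

relative to the best-binding (consensus) word, and the expected number
of bound molecules over a sequence is the sum of per-site occupancies

    A = sum_i R0 * exp(-E_i) / (1 + R0 * exp(-E_i))

over both strands, with R0 = exp(0.584 * m - 5.66) by default and
lambda = 0.7.  Windows containing N contribute zero occupancy.

Chromatin (EPI) features are the unweighted mean of every fixed-width
signal window a region overlaps, partial overlaps counting fully.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    EPI_PREFIX,
    MOT_PREFIX,
    Genome,
    GenomicRegion,
    LabeledFeatureMatrix,
    PWM,
    SignalTrack,
    reverse_complement,
)

__all__ = [
    "TrapParams",
    "pwm_probabilities",
    "mismatch_energy",
    "default_r0",
    "trap_affinity",
    "epi_feature",
    "build_feature_matrix",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class TrapParams:
    """TRAP model parameters.

    lam scales mismatch energies (dimensionless; 0.7 is the calibrated
    default for natural-log energies).  R0 sets overall binding
    strength and grows exponentially with motif length unless
    overridden.  The pseudocount regularizes count PFMs before
    log-ratios are taken.
    """

    lam: float = 0.7
    r0_slope: float = 0.584
    r0_intercept: float = -5.66
    r0_override: float | None = None
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.r0_override is not None and self.r0_override <= 0:
            raise ValueError("R0 must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def pwm_probabilities(pwm: PWM, pseudocount: float = 1.0) -> np.ndarray:
    """Normalize a count/probability matrix to per-position probabilities.

    p(j,b) = (count(j,b) + pc) / (sum_b count(j,b) + 4*pc).  A
    probability matrix passed with pseudocount 0 is returned unchanged.
    """
    mat = pwm.matrix
    row_sums = mat.sum(axis=1)
    if pseudocount == 0 and np.any(row_sums == 0):
        raise ValueError(f"PWM {pwm.id!r}: all-zero position with pseudocount 0")
    return (mat + pseudocount) / (row_sums + 4 * pseudocount)[:, None]


def mismatch_energy(pwm_probs: np.ndarray, subseq: str, lam: float = 0.7) -> float:
    """Lambda-scaled log-likelihood deficit of an m-mer vs the consensus.

    Zero iff ``subseq`` is a consensus word; additive over positions;
    infinite where the matrix assigns probability zero.
    """
    m = pwm_probs.shape[0]
    if len(subseq) != m:
        raise ValueError(f"subsequence length {len(subseq)} != motif length {m}")
    energy = 0.0
    best = pwm_probs.max(axis=1)
    for j, base in enumerate(subseq.upper()):
        idx = _BASE_INDEX.get(base)
        if idx is None or idx == 4:
            raise ValueError(f"illegal base {base!r} in subsequence")
        p = pwm_probs[j, idx]
        energy += math.inf if p == 0 else math.log(best[j] / p)
    return energy / lam


def default_r0(m: int, params: TrapParams | None = None) -> float:
    """Length-dependent binding-strength constant R0 = exp(slope*m + intercept)."""
    if params is None:
        params = TrapParams()
    if m < 1:
        raise ValueError("motif length must be >= 1")
    if params.r0_override is not None:
        return params.r0_override
    return math.exp(params.r0_slope * m + params.r0_intercept)


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    if np.any(codes < 0):
        raise ValueError("sequence contains characters outside ACGTN")
    return codes


def _strand_occupancy(codes: np.ndarray, energy_lut: np.ndarray, r0: float) -> float:
    """Sum of per-window occupancies for one strand.

    ``energy_lut`` is (m x 5): per-position lambda-scaled log-ratio
    energies with an infinite column for N, which zeroes the occupancy
    of any window containing N.
    """
    m = energy_lut.shape[0]
    n_windows = codes.size - m + 1
    if n_windows <= 0:
        return 0.0
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    energies = energy_lut[np.arange(m), windows].sum(axis=1)
    with np.errstate(over="ignore"):
        x = r0 * np.exp(-energies)
    return float(np.sum(x / (1.0 + x)))


def trap_affinity(pwm: PWM, sequence: str, params: TrapParams | None = None) -> float:
    """Expected bound-molecule count of a motif over both strands."""
    if params is None:
        params = TrapParams()
    if not sequence:
        raise ValueError("empty sequence")
    probs = pwm_probabilities(pwm, params.pseudocount)
    m = probs.shape[0]
    if len(sequence) < m:
        warnings.warn(
            f"sequence shorter than motif {pwm.id!r} ({len(sequence)} < {m}); affinity 0",
            stacklevel=2,
        )
        return 0.0
    r0 = default_r0(m, params)
    with np.errstate(divide="ignore"):
        lut = np.log(probs.max(axis=1)[:, None] / probs) / params.lam
    lut = np.hstack([lut, np.full((m, 1), np.inf)])  # N column
    fwd = _encode(sequence)
    rev = _encode(reverse_complement(sequence))
    return _strand_occupancy(fwd, lut, r0) + _strand_occupancy(rev, lut, r0)


def epi_feature(track: SignalTrack, region: GenomicRegion) -> float:
    """Unweighted mean over every window the region overlaps.

    Partial overlap counts fully; windows beyond the recorded vector
    are imputed as 0 signal.
    """
    if region.chrom not in track.values:
        raise KeyError(f"track {track.mark!r} has no chromosome {region.chrom!r}")
    w = track.width
    i0 = region.start // w
    i1 = (region.end - 1) // w
    vec = track.values[region.chrom]
    vals = np.zeros(i1 - i0 + 1)
    hi = min(i1 + 1, vec.size)
    if hi > i0:
        vals[: hi - i0] = vec[i0:hi]
    return float(vals.mean())


def build_feature_matrix(
    genome: Genome,
    tracks: Sequence[SignalTrack],
    pwms: Sequence[PWM],
    regions: Sequence[GenomicRegion],
    feature_set: str = "ALL",
    params: TrapParams | None = None,
) -> LabeledFeatureMatrix:
    """Regions x features table for one of the EPI / MOT / ALL sets.

    Column order is stable: chromatin marks first ("EPI:<mark>"), then
    motif affinities ("MOT:<id>"); row order follows the input regions.
    """
    feature_set = feature_set.upper()
    if feature_set not in ("EPI", "MOT", "ALL"):
        raise ValueError(f"unknown feature set {feature_set!r}")
    if params is None:
        params = TrapParams()
    labels = []
    for r in regions:
        if r.label is None:
            raise ValueError(f"unlabeled region {r.name}")
        labels.append(1 if r.label == "positive" else 0)

    columns: dict[str, np.ndarray] = {}
    if feature_set in ("EPI", "ALL"):
        for track in tracks:
            columns[EPI_PREFIX + track.mark] = np.array(
                [epi_feature(track, r) for r in regions]
            )
    if feature_set in ("MOT", "ALL"):
        seqs = [genome.fetch(r) for r in regions]
        for pwm in pwms:
            columns[MOT_PREFIX + pwm.id] = np.array(
                [trap_affinity(pwm, s, params) for s in seqs]
            )
    ids = []
    seen: set[str] = set()
    for r in regions:
        name = r.name
        if name in seen:
            name = f"{name}#{len(ids)}"
        seen.add(name)
        ids.append(name)
    df = pd.DataFrame(columns, index=ids)
    return LabeledFeatureMatrix(features=df, labels=np.array(labels))
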