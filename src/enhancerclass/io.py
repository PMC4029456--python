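"""Genomic domain types and text-format I/O.

Covers the formats every other stage touches: FASTA genomes, BED
intervals, fixed-window bedGraph signal tracks, JASPAR-style position
frequency matrices, and the tab-separated feature tables produced by
feature extraction.

Coordinates are 0-based half-open throughout (BED-native): a region
``(chrom, start, end)`` covers bases ``start .. end-1`` and has length
``end - start``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "GenomicRegion",
    "Genome",
    "PWM",
    "SignalTrack",
    "LabeledFeatureMatrix",
    "overlaps",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_feature_table",
    "write_feature_table",
]

DNA_ALPHABET = frozenset("ACGTN")
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Feature-name prefixes encoding provenance: chromatin-mark features,
#: motif-affinity features, and permuted contrast (shadow) features.
EPI_PREFIX = "EPI:"
MOT_PREFIX = "MOT:"
CONTRAST_PREFIX = "CONTRAST:"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval, the unit of classification."""

    chrom: str
    start: int
    end: int
    label: str | None = None  # "positive" | "negative" | None
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.label is not None and self.label not in ("positive", "negative"):
            raise ValueError(f"label must be 'positive'/'negative', got {self.label!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return self.id if self.id is not None else f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicRegion, b: GenomicRegion) -> bool:
    """True iff the two half-open intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class Genome:
    """Ordered map of chromosome name -> uppercase DNA string over ACGTN."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self._seqs:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            seq = seq.upper()
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"illegal character(s) {sorted(bad)} in chromosome {name!r}"
                )
            self._seqs[name] = seq

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self._seqs == other._seqs

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    def items(self):
        return self._seqs.items()

    def fetch(self, region: GenomicRegion) -> str:
        """Sequence of a region; raises if it runs past the chromosome end."""
        if region.chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {region.chrom!r}")
        seq = self._seqs[region.chrom]
        if region.end > len(seq):
            raise ValueError(
                f"region {region.chrom}:{region.start}-{region.end} exceeds "
                f"chromosome length {len(seq)}"
            )
        return seq[region.start : region.end]

    def _set_slice(self, chrom: str, start: int, subseq: str) -> None:
        # internal mutation hook for the synthetic generator
        seq = self._seqs[chrom]
        if start < 0 or start + len(subseq) > len(seq):
            raise ValueError("slice out of bounds")
        self._seqs[chrom] = seq[:start] + subseq.upper() + seq[start + len(subseq) :]


@dataclass
class PWM:
    """Position frequency/weight matrix: m positions x 4 bases (A,C,G,T).

    ``matrix`` may hold raw counts or probabilities; entries must be
    non-negative.  ``normalized()`` converts to per-position probability
    rows summing to 1.
    """

    id: str
    matrix: np.ndarray
    name: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.id!r}: matrix must be m x 4")
        if self.matrix.shape[0] < 1:
            raise ValueError(f"PWM {self.id!r}: motif length must be >= 1")
        if np.any(self.matrix < 0):
            raise ValueError(f"PWM {self.id!r}: negative entries")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"PWM {self.id!r}: non-finite entries")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[j] for j in np.argmax(self.matrix, axis=1))


@dataclass
class SignalTrack:
    """Fixed-width windowed signal for one chromatin mark.

    Window ``i`` on a chromosome covers bases ``[i*width, (i+1)*width)``.
    Windows absent from the source file are imputed as 0 signal.
    """

    mark: str
    width: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("window width must be >= 1")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for chrom, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite signal on {chrom} ({self.mark})")


@dataclass
class LabeledFeatureMatrix:
    """Regions x features table with binary activity labels.

    Feature provenance is encoded in the column name prefix ("EPI:" for
    chromatin marks, "MOT:" for motif affinities), so feature-set
    selection is a pure name filter.
    """

    features: pd.DataFrame  # index = region ids
    labels: np.ndarray  # 0/1, aligned to rows

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("row count != label count")
        if self.features.columns.duplicated().any():
            dupes = self.features.columns[self.features.columns.duplicated()]
            raise ValueError(f"duplicate feature names: {list(dupes)}")
        if self.features.isna().any().any():
            raise ValueError("missing values in feature matrix")

    @property
    def ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def tag(self) -> str:
        """Feature-set tag by column provenance: EPI, MOT or ALL."""
        has_epi = any(c.startswith(EPI_PREFIX) for c in self.feature_names)
        has_mot = any(c.startswith(MOT_PREFIX) for c in self.feature_names)
        if has_epi and not has_mot:
            return "EPI"
        if has_mot and not has_epi:
            return "MOT"
        return "ALL"

    def select(self, feature_set: str) -> "LabeledFeatureMatrix":
        """Restrict to one of the named feature sets: EPI, MOT or ALL."""
        feature_set = feature_set.upper()
        if feature_set == "EPI":
            cols = [c for c in self.feature_names if c.startswith(EPI_PREFIX)]
        elif feature_set == "MOT":
            cols = [c for c in self.feature_names if c.startswith(MOT_PREFIX)]
        elif feature_set == "ALL":
            cols = [
                c
                for c in self.feature_names
                if c.startswith(EPI_PREFIX) or c.startswith(MOT_PREFIX)
            ]
        else:
            raise ValueError(f"unknown feature set {feature_set!r}")
        if not cols:
            raise ValueError(f"no {feature_set} features present")
        return LabeledFeatureMatrix(self.features[cols].copy(), self.labels.copy())

    def subset_features(self, names: Sequence[str]) -> "LabeledFeatureMatrix":
        missing = [c for c in names if c not in self.features.columns]
        if missing:
            raise ValueError(f"unknown feature names: {missing}")
        if not list(names):
            raise ValueError("empty feature subset")
        return LabeledFeatureMatrix(self.features[list(names)].copy(), self.labels.copy())

    def drop_features(self, names: Sequence[str]) -> "LabeledFeatureMatrix":
        keep = [c for c in self.feature_names if c not in set(names)]
        return self.subset_features(keep)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a Genome (uppercased, ACGTN enforced)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(seqs)


def write_fasta(genome: Genome, path: str | Path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, label: str | None = None) -> list[GenomicRegion]:
    """Read BED3/BED4 regions, optionally attaching one label to all."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rid = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") else None
            regions.append(GenomicRegion(chrom, start, end, label=label, id=rid))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            if r.id is not None:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# bedGraph (fixed-width windows)


def read_bedgraph(path: str | Path, window_width: int = 50, mark: str | None = None) -> SignalTrack:
    """Read a bedGraph whose intervals align to a fixed window grid.

    Every interval must start on a multiple of ``window_width`` and span
    exactly one window (the final interval of a chromosome may be
    shorter).  Unlisted windows are filled with 0.
    """
    per_chrom: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need chrom/start/end/value")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if start % window_width != 0:
                raise ValueError(
                    f"{path}:{lineno}: interval start {start} off the "
                    f"{window_width}-bp window grid"
                )
            span = end - start
            if span <= 0 or span > window_width:
                raise ValueError(
                    f"{path}:{lineno}: interval span {span} incompatible with "
                    f"window width {window_width}"
                )
            idx = start // window_width
            windows = per_chrom.setdefault(chrom, {})
            if idx in windows:
                raise ValueError(f"{path}:{lineno}: overlapping interval at window {idx}")
            windows[idx] = value
    values = {}
    for chrom, windows in per_chrom.items():
        vec = np.zeros(max(windows) + 1)
        for idx, v in windows.items():
            vec[idx] = v
        values[chrom] = vec
    if mark is None:
        mark = Path(path).stem
    return SignalTrack(mark=mark, width=window_width, values=values)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    w = track.width
    with open(path, "w") as fh:
        for chrom, vec in track.values.items():
            for i, v in enumerate(vec):
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM


def read_jaspar_pfm(path: str | Path) -> list[PWM]:
    """Read a JASPAR-dialect PFM file (">ID name" then 4 bracketed rows).

    The 4 x m base-major rows are transposed to positions x ACGT.
    """
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise ValueError(f"malformed JASPAR PFM file {path}: {exc}") from exc
    pwms: list[PWM] = []
    seen: set[str] = set()
    for m in parsed:
        if m.length < 1:
            raise ValueError(f"motif {m.matrix_id!r} has no count rows")
        mat = np.array([[m.counts[b][j] for b in BASES] for j in range(m.length)])
        mid = m.matrix_id or m.name
        if mid in seen:
            raise ValueError(f"duplicate motif id {mid!r}")
        seen.add(mid)
        pwms.append(PWM(id=mid, matrix=mat, name=m.name))
    if not pwms:
        raise ValueError(f"no motifs in {path}")
    return pwms


def write_jaspar_pfm(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            header = f">{pwm.id}"
            if pwm.name and pwm.name != pwm.id:
                header += f" {pwm.name}"
            fh.write(header + "\n")
            for b, col in zip(BASES, pwm.matrix.T):
                row = " ".join(f"{v:.6g}" for v in col)
                fh.write(f"{b} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Feature tables


def write_feature_table(matrix: LabeledFeatureMatrix, path: str | Path) -> None:
    """Write a tab-separated feature table (last column = label).

    Values are printed at 12 significant digits, enough for a lossless
    round trip at the precisions the pipeline produces.
    """
    df = matrix.features.copy()
    df["label"] = matrix.labels
    df.index.name = "region_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_feature_table(path: str | Path) -> LabeledFeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: no 'label' column")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing cell(s) in feature table")
    labels = df.pop("label").to_numpy()
    if not np.all(np.isin(labels, [0, 1])):
        raise ValueError(f"{path}: labels must be 0/1")
    df.index = df.index.astype(str)
    df.index.name = None
    return LabeledFeatureMatrix(features=df, labels=labels)
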