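"""Genomic coordinate model and text-format I/O shared by the whole pipeline.

All coordinates are 0-based half-open (BED convention) internally; 1-based
positions appear only in human-readable report text.  Four containers are
defined:

``GenomeIndex``
    named sequences with lengths; holds the genome size *g* used by the
    chance-overlap formulas.
``FragmentSet``
    sequenced fragment intervals (proper read pairs collapsed to intervals).
``CoverageTrack``
    per-base fragment coverage, one dense float array per sequence.
``IntervalSet``
    generic BED3/BED6 interval records (promoters, hotspots, peaks...).

Formats read: BED3/BED6, bedGraph, and samtools-style genome indexes.
Formats written: bedGraph and TSV tables, tab-separated, LF-terminated,
with a single '#' header line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeIndex",
    "FragmentSet",
    "CoverageTrack",
    "IntervalSet",
    "read_genome_index",
    "read_fragments",
    "write_fragments",
    "fragments_to_coverage",
    "classify_atac_fragments",
    "fragment_centers",
    "read_intervals",
    "write_intervals",
    "read_bedgraph",
    "write_bedgraph",
]


class ParseError(ValueError):
    """Raised for malformed interval/fragment records, naming the line."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered map of sequence name -> length (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate sequence names in genome index")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("sequence lengths must be positive")
        if len(self.names) != len(self.lengths):
            raise ValueError("names/lengths length mismatch")

    @property
    def size(self) -> int:
        """Total genome length g in bp."""
        return int(sum(self.lengths))

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown sequence {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeIndex":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))


def read_genome_index(path: str | Path) -> GenomeIndex:
    """Read a samtools-style .fai (name, length, ...) or two-column TSV."""
    names, lengths = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            names.append(parts[0])
            lengths.append(int(parts[1]))
    return GenomeIndex(tuple(names), tuple(lengths))


@dataclass
class FragmentSet:
    """Fragment intervals per sequence: (chrom, start, end), half-open."""

    chroms: np.ndarray  # array of str
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (self.ends > self.starts).all():
            raise ValueError("fragment insert sizes must be positive")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def insert_sizes(self) -> np.ndarray:
        return self.ends - self.starts

    def sorted(self) -> "FragmentSet":
        order = np.lexsort((self.starts, self.chroms.astype(str)))
        return FragmentSet(self.chroms[order], self.starts[order], self.ends[order])

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        return FragmentSet(self.chroms[mask], self.starts[mask], self.ends[mask])


def read_fragments(path: str | Path, genome: GenomeIndex) -> FragmentSet:
    """Read fragments from a BED-like file (first three columns used).

    Records that fall outside the genome bounds are rejected; their count is
    logged as a warning.  Malformed lines raise :class:`ParseError` naming the
    line number; an unknown sequence name is an error.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if end <= start:
                raise ParseError(f"{path}: line {lineno}: end <= start")
            if chrom not in genome:
                raise ParseError(f"{path}: line {lineno}: unknown sequence {chrom!r}")
            if start < 0 or end > genome.length_of(chrom):
                dropped += 1
                continue
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    if dropped:
        logger.warning("%s: dropped %d out-of-bounds fragment(s)", path, dropped)
    return FragmentSet(np.array(chroms, dtype=object), np.array(starts), np.array(ends))


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e in zip(frags.chroms, frags.starts, frags.ends):
            fh.write(f"{c}\t{s}\t{e}\n")


@dataclass
class CoverageTrack:
    """Per-base fragment coverage over a genome, plus sample bookkeeping."""

    genome: GenomeIndex
    values: dict[str, np.ndarray]
    sample: str = ""
    total_fragments: int = 0

    def __post_init__(self) -> None:
        for name, arr in self.values.items():
            if len(arr) != self.genome.length_of(name):
                raise ValueError(f"coverage length mismatch for {name}")
            if (arr < 0).any():
                raise ValueError("coverage values must be non-negative")

    @classmethod
    def zeros(cls, genome: GenomeIndex, sample: str = "") -> "CoverageTrack":
        vals = {n: np.zeros(l, dtype=np.float64) for n, l in zip(genome.names, genome.lengths)}
        return cls(genome, vals, sample=sample, total_fragments=0)

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def fragments_to_coverage(
    frags: FragmentSet, genome: GenomeIndex, sample: str = ""
) -> CoverageTrack:
    """Per-base coverage: value at base b = number of fragments spanning b.

    Implemented with a difference array per sequence (add 1 at start,
    subtract 1 at end, cumulative sum), so runtime is O(fragments + genome).
    """
    track = CoverageTrack.zeros(genome, sample=sample)
    for name in genome.names:
        mask = frags.chroms == name
        if not mask.any():
            continue
        n = genome.length_of(name)
        diff = np.zeros(n + 1, dtype=np.float64)
        np.add.at(diff, frags.starts[mask], 1.0)
        np.add.at(diff, frags.ends[mask], -1.0)
        track.values[name] = np.cumsum(diff[:-1])
    track.total_fragments = int(len(frags))
    return track


# ATAC fragment-size classes: inter-nucleosome and mono-nucleosome inserts.
INTER_NUCLEOSOME_RANGE = (51, 100)
MONO_NUCLEOSOME_RANGE = (180, 247)


def classify_atac_fragments(frags: FragmentSet) -> tuple[FragmentSet, FragmentSet]:
    """Split fragments by insert size into (inter-nucleosome, mono-nucleosome).

    Inter-nucleosome inserts are 51-100 bp, mono-nucleosome 180-247 bp
    (inclusive); fragments outside both ranges are dropped.
    """
    sizes = frags.insert_sizes
    inter = frags.subset((sizes >= INTER_NUCLEOSOME_RANGE[0]) & (sizes <= INTER_NUCLEOSOME_RANGE[1]))
    mono = frags.subset((sizes >= MONO_NUCLEOSOME_RANGE[0]) & (sizes <= MONO_NUCLEOSOME_RANGE[1]))
    return inter, mono


def fragment_centers(frags: FragmentSet) -> np.ndarray:
    """Central base of each fragment; even inserts take the left of the two
    central bases: center = floor((start + end - 1) / 2)."""
    return (frags.starts + frags.ends - 1) // 2


@dataclass
class IntervalSet:
    """BED-style records; strand defaults to '.', score to 0."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    strands: np.ndarray = field(default=None)  # type: ignore[assignment]
    scores: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.strands is None:
            self.strands = np.full(len(self.starts), ".", dtype=object)
        else:
            self.strands = np.asarray(self.strands, dtype=object)
        if self.scores is None:
            self.scores = np.zeros(len(self.starts), dtype=np.float64)
        else:
            self.scores = np.asarray(self.scores, dtype=np.float64)
        if not (self.ends > self.starts).all():
            raise ValueError("intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        return IntervalSet(
            self.chroms[mask], self.starts[mask], self.ends[mask],
            self.strands[mask], self.scores[mask],
        )

    def iter_records(self) -> Iterator[tuple[str, int, int, str, float]]:
        yield from zip(self.chroms, self.starts, self.ends, self.strands, self.scores)


def read_intervals(path: str | Path, genome: GenomeIndex | None = None) -> IntervalSet:
    """Read BED3/BED6.  With a genome, bounds are validated (hard error)."""
    chroms, starts, ends, strands, scores = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            if end <= start:
                raise ParseError(f"{path}: line {lineno}: end <= start")
            if genome is not None:
                if parts[0] not in genome:
                    raise ParseError(f"{path}: line {lineno}: unknown sequence {parts[0]!r}")
                if start < 0 or end > genome.length_of(parts[0]):
                    raise ParseError(f"{path}: line {lineno}: interval out of bounds")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            scores.append(float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0)
            strands.append(parts[5] if len(parts) > 5 else ".")
    return IntervalSet(
        np.array(chroms, dtype=object), np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64), np.array(strands, dtype=object),
        np.array(scores, dtype=np.float64),
    )


def write_intervals(ivals: IntervalSet, path: str | Path, bed6: bool = False) -> None:
    with open(path, "w") as fh:
        for i, (c, s, e, st, sc) in enumerate(ivals.iter_records()):
            if bed6:
                fh.write(f"{c}\t{s}\t{e}\tiv{i}\t{sc:g}\t{st}\n")
            else:
                fh.write(f"{c}\t{s}\t{e}\n")


def read_bedgraph(path: str | Path, genome: GenomeIndex, sample: str = "") -> CoverageTrack:
    """Read bedGraph into a dense per-base track (unlisted bases are 0)."""
    track = CoverageTrack.zeros(genome, sample=sample)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in genome:
                raise ParseError(f"{path}: line {lineno}: unknown sequence {chrom!r}")
            track.values[chrom][start:end] = value
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write run-length-compressed bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        fh.write(f"# bedGraph sample={track.sample} total_fragments={track.total_fragments}\n")
        for name in track.genome.names:
            vals = track.values[name]
            if len(vals) == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{name}\t{s}\t{e}\t{v:g}\n")
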