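"""Core data model for quadripartite plastid genomes.

Plastomes are circular molecules partitioned into a large single-copy (LSC)
region, a small single-copy (SSC) region, and two inverted repeats (IRb, IRa)
that are reverse complements of one another.  All coordinates in this package
are 1-based inclusive (the GenBank convention); an interval whose ``end`` is
smaller than its ``start`` wraps the numeric origin of the circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PARTITION_NAMES = ("LSC", "IRb", "SSC", "IRa")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PartitionError(ValueError):
    """Raised when a quadripartite partition map is absent or inconsistent."""


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval on a circle; wraps the origin iff end < start."""

    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 1 or self.end < 1:
            raise ValueError(f"coordinates must be >= 1, got [{self.start}, {self.end}]")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, circle: int) -> int:
        if self.wraps:
            return circle - self.start + 1 + self.end
        return self.end - self.start + 1

    def runs(self, circle: int) -> list[tuple[int, int]]:
        """Materialize as one or two non-wrapping (start, end) runs."""
        if self.wraps:
            return [(self.start, circle), (1, self.end)]
        return [(self.start, self.end)]

    def positions(self, circle: int) -> np.ndarray:
        """All 1-based positions covered, in 5'->3' order along the circle."""
        parts = [np.arange(s, e + 1) for s, e in self.runs(circle)]
        return np.concatenate(parts)

    def contains(self, pos: int, circle: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class PartitionMap:
    """The four named intervals LSC, IRb, SSC, IRa covering the circle exactly once."""

    LSC: Interval
    IRb: Interval
    SSC: Interval
    IRa: Interval

    def __getitem__(self, name: str) -> Interval:
        if name not in PARTITION_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self):
        return [(name, self[name]) for name in PARTITION_NAMES]

    def validate(self, circle: int) -> None:
        cover = np.zeros(circle, dtype=np.int8)
        for name in PARTITION_NAMES:
            iv = self[name]
            if iv.length(circle) < 1:
                raise PartitionError(f"partition {name} has zero length")
            for s, e in iv.runs(circle):
                if e > circle:
                    raise PartitionError(
                        f"partition {name} extends past genome end ({e} > {circle})")
                cover[s - 1:e] += 1
        if (cover > 1).any():
            pos = int(np.argmax(cover > 1)) + 1
            raise PartitionError(f"partitions overlap (first overlap at position {pos})")
        if (cover == 0).any():
            pos = int(np.argmax(cover == 0)) + 1
            raise PartitionError(f"partitions leave position {pos} uncovered")

    def partition_of(self, pos: int, circle: int) -> str:
        for name in PARTITION_NAMES:
            if self[name].contains(pos, circle):
                return name
        raise PartitionError(f"position {pos} not covered")


@dataclass(frozen=True)
class GeneFeature:
    """A gene annotation: possibly multi-interval (exons), strand-aware."""

    name: str
    strand: str  # '+' or '-'
    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.intervals:
            raise ValueError(f"gene {self.name} has no intervals")


@dataclass
class PlastomeRecord:
    """One plastid genome: sequence, quadripartite partition map, gene annotations."""

    sample_id: str
    sequence: str
    partition_map: PartitionMap
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("empty sequence")
        bad = set(self.sequence.upper()) - IUPAC_CODES
        if bad:
            pos = next(i for i, c in enumerate(self.sequence.upper(), 1) if c in bad)
            raise ValueError(f"non-IUPAC character {self.sequence[pos-1]!r} at position {pos}")
        self.partition_map.validate(len(self.sequence))
        L = len(self.sequence)
        for g in self.genes:
            for iv in g.intervals:
                if iv.start > L or iv.end > L:
                    raise ValueError(
                        f"gene {g.name} interval [{iv.start},{iv.end}] outside [1,{L}]")

    def __len__(self) -> int:
        return len(self.sequence)

    def extract(self, interval: Interval) -> str:
        """Sequence of an interval, honouring origin wrap."""
        return "".join(self.sequence[s - 1:e] for s, e in interval.runs(len(self)))

    def gene_mask(self) -> np.ndarray:
        """Boolean per-position mask of the union of gene intervals (introns included)."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for g in self.genes:
            for iv in g.intervals:
                for s, e in iv.runs(len(self.sequence)):
                    mask[s - 1:e] = True
        return mask


MISSING = "missing"


@dataclass(frozen=True)
class SampleMetadata:
    """Harmonized per-sample sequencing/assembly metadata.

    ``platform`` and ``software`` are controlled-vocabulary labels or the
    explicit sentinel :data:`MISSING`; ``avg_read_length`` is in bp, or None
    for missing.
    """

    sample_id: str
    platform: str = MISSING
    software: str = MISSING
    avg_read_length: float | None = None

    def __post_init__(self) -> None:
        if self.avg_read_length is not None and not self.avg_read_length > 0:
            raise ValueError(
                f"avg_read_length must be positive, got {self.avg_read_length}")
        if self.platform == "" or self.software == "":
            raise ValueError("empty string labels are not allowed; use MISSING")


@dataclass
class CoverageProfile:
    """Per-base read depth along one plastome (index 1..L)."""

    sample_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1 or len(self.depths) == 0:
            raise ValueError("depths must be a non-empty 1-D array")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depths)
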