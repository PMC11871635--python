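"""Core domain types shared by every pipeline stage.

All genomic coordinates are 0-based half-open (BED convention). GTF input is
converted on read; nothing downstream ever sees 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

STRANDS = ("+", "-", ".")
ALPHABET = "ACGT"


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Peak:
    """A called peak (one narrowPeak record).

    ``signal_value`` is narrowPeak column 7; optional columns are carried
    through unchanged so that read → write round-trips.
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    summit: int = -1

    def __post_init__(self) -> None:
        if self.signal_value < 0:
            raise ValueError(f"signal_value must be >= 0, got {self.signal_value}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its transcription start site.

    The TSS is the 5' end of the gene body: ``start`` on the + strand,
    ``end - 1`` on the − strand.
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class SignalTrack:
    """Per-chromosome step function from a bedGraph (non-overlapping steps).

    Steps are stored as sorted numpy arrays so that interval sums are
    vectorised searchsorted lookups.
    """

    def __init__(self, steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping steps on {chrom}")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"non-finite signal values on {chrom}")
            self._steps[chrom] = (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        steps = {}
        for chrom, rows in by_chrom.items():
            arr = np.array(rows, dtype=float)
            steps[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return cls(steps)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._steps)

    def steps_for(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._steps:
            z = np.zeros(0)
            return z.astype(np.int64), z.astype(np.int64), z
        return self._steps[chrom]

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of value × covered-bp over [start, end); uncovered bp add 0."""
        starts, ends, values = self.steps_for(chrom)
        if len(starts) == 0:
            return 0.0
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i1 <= i0:
            return 0.0
        ov = np.minimum(ends[i0:i1], end) - np.maximum(starts[i0:i1], start)
        return float(np.sum(values[i0:i1] * np.clip(ov, 0, None)))

    def total_mass(self) -> float:
        """Σ value × step length over all chromosomes."""
        total = 0.0
        for starts, ends, values in self._steps.values():
            total += float(np.sum(values * (ends - starts)))
        return total

    def iter_records(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in sorted(self._steps):
            starts, ends, values = self._steps[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


@dataclass
class PWMRecord:
    """A letter-probability matrix over A,C,G,T for one TF motif."""

    motif_id: str
    tf_symbol: str
    probs: np.ndarray  # width × 4, rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a width × 4 matrix")
        if self.width < 4:
            raise ValueError(f"motif width must be >= 4, got {self.width}")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        row_sums = self.probs.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-6):
            raise ValueError("each probability row must sum to 1 within 1e-6")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in np.argmax(self.probs, axis=1))
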