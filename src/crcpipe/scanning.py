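"""FIMO-style PWM scanning with exact p-values.

Windows on both strands are scored as log2 odds against a 0-order background.
P-values are exact tail probabilities of the window score under the
background, computed by position-wise dynamic-programming convolution of the
discretized per-position score distributions (the standard exact-p-value
construction). Hit calling and the p-value lookup both operate on the same
discretized integer scores, so calling is internally consistent; the
real-valued bit score is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .types import GenomicInterval, PWMRecord

__all__ = [
    "ScanParams",
    "MotifHit",
    "extend_region",
    "log_odds_matrix",
    "score_distribution",
    "ScoreDistribution",
    "MotifScanner",
    "scan_region",
    "count_hits",
    "estimate_background",
]

UNIFORM_BG = np.full(4, 0.25)

_ENCODE = np.full(256, 4, dtype=np.int8)  # everything unknown scores as N
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to codes A=0 C=1 G=2 T=3, anything else (N)=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ScanParams:
    """Scanning parameters (FIMO-conventional defaults)."""

    extension: int = 500
    pseudocount: float = 0.1
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    pvalue_threshold: float = 1e-4
    score_discretization_bins: int = 1000

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        if not 0 < self.pvalue_threshold < 1:
            raise ValueError("pvalue_threshold must be in (0, 1)")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")
        if self.score_discretization_bins < 100:
            raise ValueError("need at least 100 discretization bins")


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in a scanned region sequence."""

    motif_id: str
    region_id: str
    offset: int  # 0-based start within the region sequence
    strand: str  # '+' or '-'
    score: float  # log2 odds, bits
    pvalue: float


def extend_region(
    interval: GenomicInterval, extension: int, chrom_length: int
) -> GenomicInterval:
    """Extend both sides by ``extension`` bp, clipped to [0, chrom_length)."""
    if extension < 0:
        raise ValueError("extension must be >= 0")
    return GenomicInterval(
        interval.chrom,
        max(0, interval.start - extension),
        min(chrom_length, interval.end + extension),
        interval.strand,
    )


def log_odds_matrix(
    pwm: PWMRecord,
    background: Sequence[float] | np.ndarray = UNIFORM_BG,
    pseudocount: float = 0.1,
) -> np.ndarray:
    """width × 4 log2-odds matrix with background-proportional pseudocount.

    entry(j, b) = log2( (p(j,b) + pc·bg(b)) / (1 + pc) / bg(b) ).
    """
    bg = np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be positive")
    adjusted = (pwm.probs + pseudocount * bg) / (1.0 + pseudocount)
    with np.errstate(divide="ignore"):
        return np.log2(adjusted / bg)


class ScoreDistribution:
    """Exact distribution of discretized window scores under the background.

    Log-odds entries are scaled so that the achievable score range spans
    ``bins`` integer units, rounded to integers, and convolved position by
    position. The tail array answers P(int score >= v) in O(1).
    """

    def __init__(
        self,
        log_odds: np.ndarray,
        background: Sequence[float] | np.ndarray = UNIFORM_BG,
        bins: int = 1000,
    ):
        if bins < 100:
            raise ValueError("need at least 100 bins")
        bg = np.asarray(background, dtype=float)
        lom = np.asarray(log_odds, dtype=float)
        lo = float(lom.min(axis=1).sum())
        hi = float(lom.max(axis=1).sum())
        span = hi - lo
        self.scale = bins / span if span > 0 else 1.0
        self.int_matrix = np.rint(lom * self.scale).astype(np.int64)
        self.min_score = int(self.int_matrix.min(axis=1).sum())
        self.max_score = int(self.int_matrix.max(axis=1).sum())

        pmf = np.zeros(self.max_score - self.min_score + 1)
        pmf[0] = 1.0
        offset = 0  # current pmf[0] corresponds to int score (row mins so far)
        width = 1
        for j in range(lom.shape[0]):
            row = self.int_matrix[j]
            row_min = int(row.min())
            new_width = width + int(row.max()) - row_min
            new = np.zeros(new_width)
            for b in range(4):
                d = int(row[b]) - row_min
                new[d : d + width] += pmf[:width] * bg[b]
            pmf[:new_width] = new
            pmf[new_width:] = 0.0
            width = new_width
            offset += row_min
        # offset == self.min_score by construction
        tail = np.cumsum(pmf[::-1])[::-1]
        self.tail = np.clip(tail, 0.0, 1.0)
        if abs(float(pmf[:width].sum()) - 1.0) > 1e-9:
            raise AssertionError("score distribution mass drifted from 1")

    def pvalue_int(self, scores: np.ndarray | int) -> np.ndarray:
        """P(window int score >= v) under the background, elementwise."""
        v = np.atleast_1d(np.asarray(scores, dtype=np.int64))
        idx = np.clip(v - self.min_score, 0, len(self.tail) - 1)
        p = self.tail[idx]
        p = np.where(v < self.min_score, 1.0, p)
        p = np.where(v > self.max_score, 0.0, p)
        return p

    def pvalue(self, score: float) -> float:
        """P(window score >= score) for a real-valued bit-score threshold."""
        v = int(np.rint(score * self.scale))
        return float(self.pvalue_int(v)[0])


def score_distribution(
    score_matrix: np.ndarray,
    background: Sequence[float] | np.ndarray = UNIFORM_BG,
    bins: int = 1000,
) -> ScoreDistribution:
    """Exact discretized distribution of window scores under the background."""
    return ScoreDistribution(score_matrix, background, bins)


def _with_n_column(matrix: np.ndarray) -> np.ndarray:
    """Append an N column contributing 0 (background substitution)."""
    out = np.zeros((matrix.shape[0], 5), dtype=matrix.dtype)
    out[:, :4] = matrix
    return out


class MotifScanner:
    """Reusable scanner for one PWM: precomputes matrices and the exact DP."""

    def __init__(self, pwm: PWMRecord, params: ScanParams | None = None):
        self.pwm = pwm
        self.params = params or ScanParams()
        self.lom = log_odds_matrix(
            pwm, self.params.background, self.params.pseudocount
        )
        self.dist = ScoreDistribution(
            self.lom, self.params.background, self.params.score_discretization_bins
        )
        w = pwm.width
        int_fwd = self.dist.int_matrix
        int_rc = int_fwd[::-1, ::-1].copy()  # reverse-complement orientation
        real_rc = self.lom[::-1, ::-1].copy()
        self._int_f = _with_n_column(int_fwd)
        self._int_r = _with_n_column(int_rc)
        self._real_f = _with_n_column(self.lom)
        self._real_r = _with_n_column(real_rc)
        self.width = w

    def _window_scores(self, codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
        n_win = len(codes) - self.width + 1
        scores = np.zeros(n_win, dtype=matrix.dtype)
        for j in range(self.width):
            scores += matrix[j, codes[j : j + n_win]]
        return scores

    def scan(self, sequence: str, region_id: str = "region") -> list[MotifHit]:
        """All hits with pvalue <= threshold, both strands, overlaps kept.

        Hits are ordered by offset, '+' strand before '-'.
        """
        codes = encode_sequence(sequence)
        if len(codes) < self.width:
            return []
        hits: list[MotifHit] = []
        int_f = self._window_scores(codes, self._int_f)
        int_r = self._window_scores(codes, self._int_r)
        p_f = self.dist.pvalue_int(int_f)
        p_r = self.dist.pvalue_int(int_r)
        thresh = self.params.pvalue_threshold
        keep_f = p_f <= thresh
        keep_r = p_r <= thresh
        real_f = real_r = None
        if keep_f.any():
            real_f = self._window_scores(codes, self._real_f)
        if keep_r.any():
            real_r = self._window_scores(codes, self._real_r)
        for i in range(len(int_f)):
            if keep_f[i]:
                hits.append(
                    MotifHit(
                        self.pwm.motif_id,
                        region_id,
                        int(i),
                        "+",
                        float(real_f[i]),  # type: ignore[index]
                        float(p_f[i]),
                    )
                )
            if keep_r[i]:
                hits.append(
                    MotifHit(
                        self.pwm.motif_id,
                        region_id,
                        int(i),
                        "-",
                        float(real_r[i]),  # type: ignore[index]
                        float(p_r[i]),
                    )
                )
        return hits


def scan_region(
    sequence: str,
    pwm: PWMRecord,
    params: ScanParams | None = None,
    region_id: str = "region",
) -> list[MotifHit]:
    """Scan one region sequence with one PWM (see MotifScanner.scan)."""
    return MotifScanner(pwm, params).scan(sequence, region_id)


def count_hits(
    pwm: PWMRecord,
    sequences: Iterable[str],
    params: ScanParams | None = None,
) -> int:
    """Total motif occurrences across the given (extended SE) sequences."""
    scanner = MotifScanner(pwm, params)
    return sum(len(scanner.scan(seq)) for seq in sequences)


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order A,C,G,T frequencies over the scanned sequences (N ignored)."""
    counts = np.zeros(4)
    for seq in sequences:
        codes = encode_sequence(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    total = counts.sum()
    if total == 0:
        return UNIFORM_BG.copy()
    return counts / total
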