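"""Super-enhancer calling: ranked-signal cutoff and SE-to-gene assignment.

Stitched regions are ranked by signal; the hockey-stick (inflection) cutoff
is the ROSE tangent criterion: with overall slope m = (max − min)/n, pick the
rank x whose slope-m line through (x, s_x) leaves the fewest points on or
below it. Regions with signal strictly above the cutoff are super-enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SE_TABLE_COLUMNS
from .stitching import StitchedRegion
from .types import GeneModel

__all__ = [
    "RankedEnhancerTable",
    "SEAssignment",
    "hockey_stick_cutoff",
    "call_superenhancers",
    "assign_genes",
]


def hockey_stick_cutoff(signals: Sequence[float]) -> tuple[int, float]:
    """Find the inflection cutoff of an ascending ranked-signal curve.

    Returns (cutoff_index x*, cutoff y*), x* 1-based into the ascending sort.
    For each candidate rank x, consider the line of slope m = (range)/n
    through (x, s_x); x* minimises the number of points on or below that
    line, ties going to the largest x (fewest, strongest SEs). A point j
    counts as on or below the line iff its rank-adjusted signal
    t_j = s_j − m·j is at most t_x; evaluating both sides in t-space keeps
    knife-edge comparisons consistent across candidate lines, and minimising
    the count is then equivalent to minimising t_x, which is how it is
    computed.

    All-equal input degenerates to x* = n, y* = max, hence zero SEs.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 signals to locate a cutoff")
    m = (s[-1] - s[0]) / n
    x = np.arange(1, n + 1)
    t = s - m * x
    # argmin with ties to the largest index
    best = n - 1 - int(np.argmin(t[::-1]))
    return best + 1, float(s[best])


@dataclass
class RankedEnhancerTable:
    """Regions sorted by ascending signal with the SE cutoff applied."""

    regions: list[StitchedRegion]
    cutoff_index: int
    cutoff: float
    is_super: np.ndarray  # bool per region, aligned with .regions

    @property
    def signals(self) -> np.ndarray:
        return np.asarray([r.signal for r in self.regions], dtype=float)

    @property
    def superenhancers(self) -> list[StitchedRegion]:
        return [r for r, f in zip(self.regions, self.is_super) if f]

    @property
    def n_super(self) -> int:
        return int(self.is_super.sum())

    def to_frame(
        self, assignments: "dict[str, SEAssignment] | None" = None
    ) -> pd.DataFrame:
        assignments = assignments or {}
        rows = []
        for rank, (region, flag) in enumerate(
            zip(self.regions, self.is_super), start=1
        ):
            asn = assignments.get(region.id)
            genes = ",".join(asn.genes) if asn else ""
            rows.append(
                {
                    "se_id": region.id,
                    "chrom": region.interval.chrom,
                    "start": region.interval.start,
                    "end": region.interval.end,
                    "n_constituents": region.n_constituents,
                    "signal": region.signal,
                    "rank": rank,
                    "is_super": bool(flag),
                    "assigned_genes": genes,
                }
            )
        return pd.DataFrame(rows, columns=SE_TABLE_COLUMNS)


def call_superenhancers(regions: Sequence[StitchedRegion]) -> RankedEnhancerTable:
    """Rank quantified regions and flag those above the hockey-stick cutoff.

    A single region cannot define a curve and is flagged typical. The sort
    (signal, then coordinates) makes the output invariant to input order.
    """
    if not regions:
        raise ValueError("no regions to rank")
    if any(r.signal is None for r in regions):
        raise ValueError("regions must be quantified before SE calling")
    ordered = sorted(
        regions,
        key=lambda r: (
            r.signal,
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            r.id,
        ),
    )
    if len(ordered) == 1:
        return RankedEnhancerTable(
            regions=ordered,
            cutoff_index=1,
            cutoff=float(ordered[0].signal),  # type: ignore[arg-type]
            is_super=np.array([False]),
        )
    signals = np.asarray([r.signal for r in ordered], dtype=float)
    x_star, y_star = hockey_stick_cutoff(signals)
    return RankedEnhancerTable(
        regions=ordered,
        cutoff_index=x_star,
        cutoff=y_star,
        is_super=signals > y_star,
    )


@dataclass
class SEAssignment:
    """Genes assigned to one super-enhancer by TSS proximity."""

    se_id: str
    genes: list[str] = field(default_factory=list)
    distances: dict[str, int] = field(default_factory=dict)
    primary_gene: str | None = None


def _tss_distance(tss: int, start: int, end: int) -> int:
    """0 if the TSS lies inside [start, end), else bp to the nearest boundary."""
    if start <= tss < end:
        return 0
    return start - tss if tss < start else tss - (end - 1)


def assign_genes(
    table: RankedEnhancerTable,
    genes: Sequence[GeneModel],
    window: int = 50000,
    restrict_to: Sequence[str] | None = None,
) -> dict[str, SEAssignment]:
    """Assign genes to super-enhancers by TSS-within-window proximity.

    A gene is assigned to an SE iff its TSS lies inside the SE or within
    ``window`` bp of an SE boundary. ``restrict_to`` limits assignable
    symbols (e.g. to a TF list). Genes may hit several SEs and vice versa;
    the primary gene of an SE is the one with the smallest TSS distance
    (ties: lexicographic symbol).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    allowed = set(restrict_to) if restrict_to is not None else None
    assignments: dict[str, SEAssignment] = {}
    for region in table.superenhancers:
        asn = SEAssignment(se_id=region.id)
        hits: list[tuple[int, str]] = []
        for g in genes:
            if g.chrom != region.interval.chrom:
                continue
            if allowed is not None and g.symbol not in allowed:
                continue
            d = _tss_distance(g.tss, region.interval.start, region.interval.end)
            if d <= window:
                hits.append((d, g.symbol))
        for d, symbol in sorted(hits, key=lambda t: (t[1], t[0])):
            if symbol not in asn.distances or d < asn.distances[symbol]:
                asn.distances[symbol] = d
        asn.genes = sorted(asn.distances)
        if asn.distances:
            asn.primary_gene = min(asn.distances, key=lambda s: (asn.distances[s], s))
        assignments[region.id] = asn
    return assignments


def se_associated_tfs(assignments: dict[str, SEAssignment]) -> dict[str, list[str]]:
    """Map each assigned TF symbol to the SE ids it is associated with."""
    out: dict[str, list[str]] = {}
    for se_id in sorted(assignments):
        for symbol in assignments[se_id].genes:
            out.setdefault(symbol, []).append(se_id)
    return out
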