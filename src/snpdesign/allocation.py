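"""Distribute the SNP budget across chromosomes and chromosome segments.

Under the design model the number of selected SNPs per chromosome is
multinomial with probabilities proportional to map length; the expected
count is used directly.  Map lengths are discounted for *gaps* —
adjacent-candidate intervals more than twice the reference mean spacing
— since gaps cannot harbor selected SNPs.  Expected (real-valued)
counts are realized as integers by floor-then-largest-remainder
rounding, which conserves the total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class AllocationError(ValueError):
    pass


@dataclass(frozen=True)
class ChromosomeGaps:
    """Gaps on one chromosome: disjoint sorted (start, end) intervals."""

    intervals: tuple[tuple[float, float], ...]
    fraction: float  # g_k = total gap length / L_k

    def __post_init__(self):
        for (a, b), (c, d) in zip(self.intervals, self.intervals[1:]):
            if c < b:
                raise AllocationError("gap intervals must be disjoint and sorted")
        if not (0.0 <= self.fraction < 1.0 + 1e-12):
            raise AllocationError(f"gap fraction out of [0,1): {self.fraction}")

    @property
    def total_length(self) -> float:
        return sum(b - a for a, b in self.intervals)


EMPTY_GAPS = ChromosomeGaps((), 0.0)


@dataclass
class GapSet:
    """Per-chromosome gap annotation for a genome."""

    per_chromosome: dict[int, ChromosomeGaps] = field(default_factory=dict)

    def fraction(self, chrom: int) -> float:
        return self.per_chromosome.get(chrom, EMPTY_GAPS).fraction

    def intervals(self, chrom: int) -> tuple[tuple[float, float], ...]:
        return self.per_chromosome.get(chrom, EMPTY_GAPS).intervals


@dataclass
class AllocationPlan:
    """Integer SNP counts per chromosome (and optionally per segment)."""

    per_chromosome: dict[int, int]
    total: int
    per_segment: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self):
        if sum(self.per_chromosome.values()) != self.total:
            raise AllocationError("per-chromosome counts do not sum to total")


def reference_mean_spacing(chrom_length: float, n_k: int) -> float:
    """Mean distance between neighboring selected SNPs: L_k / (n_k - 1)."""
    if n_k < 2:
        raise AllocationError(f"mean spacing undefined for n_k={n_k} (< 2)")
    return chrom_length / (n_k - 1)


def detect_gaps(positions: Sequence[float], reference_spacing: float,
                chrom_length: float | None = None) -> ChromosomeGaps:
    """Find adjacent-candidate intervals longer than 2x the reference spacing.

    ``chrom_length`` defaults to the span of the positions; the gap
    fraction g is total gap length over that length.
    """
    pos = np.asarray(positions, dtype=float)
    if len(pos) < 2:
        raise AllocationError("need at least 2 positions to detect gaps")
    if np.any(np.diff(pos) < 0):
        raise AllocationError("positions must be sorted ascending")
    length = float(chrom_length) if chrom_length is not None else float(pos[-1] - pos[0])
    diffs = np.diff(pos)
    idx = np.nonzero(diffs > 2.0 * reference_spacing)[0]
    intervals = tuple((float(pos[i]), float(pos[i + 1])) for i in idx)
    total = sum(b - a for a, b in intervals)
    fraction = total / length if length > 0 else 0.0
    return ChromosomeGaps(intervals, min(fraction, 1.0))


def largest_remainder(weights: Sequence[float], total: int,
                      minima: Sequence[int] | None = None,
                      maxima: Sequence[int] | None = None) -> list[int]:
    """Round ``total * weights/sum(weights)`` to integers conserving the sum.

    Floors first, then hands leftover units to the largest fractional
    remainders (ties -> lower index).  ``minima`` forces per-cell lower
    bounds (e.g. obligatory counts) and ``maxima`` per-cell capacities
    (e.g. available candidates); violations are pinned at the bound and
    the remaining budget re-apportioned over unconstrained cells.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise AllocationError("negative weights")
    n = len(w)
    minima = [0] * n if minima is None else list(minima)
    maxima = [None] * n if maxima is None else list(maxima)
    if len(minima) != n or len(maxima) != n:
        raise AllocationError("minima/maxima length mismatch")
    for lo, hi in zip(minima, maxima):
        if hi is not None and lo > hi:
            raise AllocationError(f"minimum {lo} exceeds capacity {hi}")
    if sum(minima) > total:
        raise AllocationError(
            f"minima sum {sum(minima)} exceeds total {total}"
        )
    cap_total = sum(h for h in maxima if h is not None)
    if all(h is not None for h in maxima) and cap_total < total:
        raise AllocationError(
            f"capacities sum {cap_total} below total {total}"
        )
    fixed: dict[int, int] = {}
    while True:
        free = [i for i in range(n) if i not in fixed]
        budget = total - sum(fixed.values())
        if budget > 0 and not free:
            raise AllocationError("no capacity left for remaining budget")
        wf = w[free]
        if len(free) and wf.sum() <= 0:
            wf = np.ones(len(free))  # degenerate: spread evenly
        counts = _lr_round(wf, budget) if free else []
        # freeze minima violations first; capacity violations only once no
        # minimum is violated (keeps the frozen sum within the total)
        low = [i for i, c in zip(free, counts) if c < minima[i]]
        if low:
            for i in low:
                fixed[i] = minima[i]
            continue
        high = [
            i for i, c in zip(free, counts)
            if maxima[i] is not None and c > maxima[i]
        ]
        if high:
            for i in high:
                fixed[i] = maxima[i]
            continue
        out = [0] * n
        for i, c in zip(free, counts):
            out[i] = c
        for i, c in fixed.items():
            out[i] = c
        return out


def _lr_round(weights: np.ndarray, total: int) -> list[int]:
    if total == 0:
        return [0] * len(weights)
    quotas = total * weights / weights.sum()
    base = np.floor(quotas).astype(int)
    leftover = total - int(base.sum())
    remainders = quotas - base
    order = np.lexsort((np.arange(len(weights)), -remainders))
    for j in order[:leftover]:
        base[j] += 1
    return base.tolist()


def allocate_across_chromosomes(
    N: int,
    chrom_lengths: Mapping[int, float],
    gaps: GapSet | None = None,
    obligatory_counts: Mapping[int, int] | None = None,
) -> AllocationPlan:
    """Allocate N SNPs over chromosomes proportionally to non-gap length.

    n_k is the largest-remainder realization of N * p_k with
    p_k = (1-g_k) L_k / sum_i (1-g_i) L_i, then raised where needed to
    the chromosome's obligatory count.
    """
    gaps = gaps or GapSet()
    obligatory_counts = obligatory_counts or {}
    chroms = sorted(chrom_lengths)
    if not chroms:
        raise AllocationError("no chromosomes")
    if any(chrom_lengths[k] <= 0 for k in chroms):
        raise AllocationError("all chromosome lengths must be positive")
    oblig_total = sum(obligatory_counts.get(k, 0) for k in chroms)
    if N < oblig_total:
        raise AllocationError(
            f"budget N={N} below obligatory total {oblig_total}"
        )
    weights = [(1.0 - gaps.fraction(k)) * chrom_lengths[k] for k in chroms]
    if sum(weights) <= 0:
        raise AllocationError("all-gap genome: no non-gap map length")
    minima = [obligatory_counts.get(k, 0) for k in chroms]
    counts = largest_remainder(weights, N, minima)
    return AllocationPlan({k: c for k, c in zip(chroms, counts)}, N)


def allocate_within_segments(n_k: int, segment_lengths: Sequence[float],
                             minima: Sequence[int] | None = None) -> list[int]:
    """Split a chromosome's count over its gap-free segments by length."""
    if len(segment_lengths) == 0:
        raise AllocationError("no segments")
    return largest_remainder(segment_lengths, n_k, minima)


def segments_from_gaps(start: float, end: float,
                       gap_intervals: Sequence[tuple[float, float]],
                       fixed_positions: Sequence[float] = ()) -> list[tuple[float, float]]:
    """Cut [start, end] into gap-free segments.

    ``fixed_positions`` (e.g. obligatory SNPs) falling strictly inside a
    gap shrink it to the sub-intervals flanking them, so fixed SNPs are
    never stranded inside a gap.
    """
    pieces: list[tuple[float, float]] = []
    for a, b in gap_intervals:
        inside = sorted(p for p in fixed_positions if a < p < b)
        lo = a
        for p in inside:
            pieces.append((lo, p))
            lo = p
        pieces.append((lo, b))
    # pieces are the (possibly shrunk) gap spans; fixed positions split a gap
    # into consecutive gaps with a zero-width non-gap point between them.
    segs: list[tuple[float, float]] = []
    cursor = start
    for a, b in sorted(pieces):
        if a > cursor:
            segs.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < end:
        segs.append((cursor, end))
    if not segs:  # whole interval is gap
        segs.append((start, start))
    return segs
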