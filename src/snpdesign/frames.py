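"""Virtual-frame (VF) SNP placement and local search bins.

VF SNPs are idealized, real-valued target positions guiding where real
SNPs should be selected; snapping to candidates happens at selection
time.  Placement is either uniform (equally spaced, endpoints included)
or terminally enriched: the chromosome is cut into 20 equal segments,
the outer two segments at each end form terminal groups, and fixed
fractions of the frame are assigned to (left, middle, right) groups —
(29%, 42%, 29%) for "more" enrichment, (22%, 56%, 22%) for "less" —
an operational rendering of a smoothed Beta(0.5, 0.5) location density.

Each VF position ``w_j`` owns a search bin ``[w_j - y*D, w_j + y*D]``
where ``D`` is the mean VF spacing and ``y`` (gamma) in [0, 1] tunes
the radius; bins of adjacent VF positions are disjoint for gamma <= 0.5
and start overlapping beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .allocation import largest_remainder

N_SEGMENTS = 20
TERMINAL_SEGMENTS = 2  # per end
ENRICHMENT_QUOTAS = {
    "more": (0.29, 0.42, 0.29),
    "less": (0.22, 0.56, 0.22),
}


class FrameError(ValueError):
    pass


@dataclass
class FrameDesign:
    """VF positions and search bins for one chromosome."""

    vf_positions: np.ndarray
    bins: list[tuple[float, float]]
    gamma: float
    meta_quotas: tuple[float, float, float] | None = None
    segment_index: list[int] = field(default_factory=list)


def place_uniform(start: float, end: float, m: int) -> np.ndarray:
    """m equally spaced VF positions spanning [start, end], endpoints included."""
    if m < 2:
        raise FrameError(f"uniform placement needs m >= 2, got {m}")
    if end < start:
        raise FrameError("segment end before start")
    return np.linspace(start, end, m)


def place_beta(start: float, end: float, m: int, enrichment: str,
               gap_intervals: Sequence[tuple[float, float]] = ()) -> np.ndarray:
    """Terminally enriched VF placement over a (gap-annotated) chromosome.

    The chromosome is divided into 20 equal-length segments; quotas for
    the left-end (segments 1-2), middle (3-18) and right-end (19-20)
    groups follow the enrichment option, realized by largest-remainder
    rounding so counts sum to m.  Within each group, counts spread over
    its segments proportionally to non-gap length, and VF positions are
    placed uniformly inside the non-gap parts of each segment.  A group
    with no non-gap length passes its quota to the middle group.  The
    first and last VF positions are snapped to the chromosome ends so
    boundary SNPs are always representable.
    """
    if m < 4:
        raise FrameError(f"beta placement needs m >= 4, got {m}")
    if enrichment not in ENRICHMENT_QUOTAS:
        raise FrameError(f"unknown enrichment {enrichment!r}")
    quotas = ENRICHMENT_QUOTAS[enrichment]
    length = end - start
    if length <= 0:
        raise FrameError("chromosome length must be positive")
    edges = start + length * np.arange(N_SEGMENTS + 1) / N_SEGMENTS
    seg_bounds = list(zip(edges[:-1], edges[1:]))
    nongap = [_nongap_parts(a, b, gap_intervals) for a, b in seg_bounds]
    nongap_len = [sum(b - a for a, b in parts) for parts in nongap]

    groups = [
        list(range(0, TERMINAL_SEGMENTS)),
        list(range(TERMINAL_SEGMENTS, N_SEGMENTS - TERMINAL_SEGMENTS)),
        list(range(N_SEGMENTS - TERMINAL_SEGMENTS, N_SEGMENTS)),
    ]
    group_len = [sum(nongap_len[i] for i in g) for g in groups]
    weights = list(quotas)
    # all-gap terminal group: its quota is reassigned to the middle group
    for gi in (0, 2):
        if group_len[gi] <= 0:
            weights[1] += weights[gi]
            weights[gi] = 0.0
    if group_len[1] <= 0 and weights[1] > 0:
        raise FrameError("middle group has no non-gap length")
    group_counts = largest_remainder(weights, m)

    positions: list[float] = []
    for g, count in zip(groups, group_counts):
        seg_counts = largest_remainder([nongap_len[i] for i in g], count)
        for i, c in zip(g, seg_counts):
            positions.extend(_spread_in_parts(nongap[i], c))
    pos = np.sort(np.asarray(positions, dtype=float))
    # boundary SNPs always kept: pin the outermost frame positions
    lo = _nongap_parts(start, end, gap_intervals)
    if len(pos):
        pos[0] = lo[0][0] if lo else start
        pos[-1] = lo[-1][1] if lo else end
    return pos


def _nongap_parts(a: float, b: float,
                  gaps: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    parts = [(a, b)]
    for ga, gb in gaps:
        nxt = []
        for pa, pb in parts:
            if gb <= pa or ga >= pb:
                nxt.append((pa, pb))
                continue
            if ga > pa:
                nxt.append((pa, ga))
            if gb < pb:
                nxt.append((gb, pb))
        parts = nxt
    return [(pa, pb) for pa, pb in parts if pb > pa]


def _spread_in_parts(parts: Sequence[tuple[float, float]], count: int) -> list[float]:
    """Place ``count`` positions uniformly inside non-gap sub-intervals."""
    if count == 0 or not parts:
        return []
    lens = [b - a for a, b in parts]
    per_part = largest_remainder(lens, count)
    out = []
    for (a, b), c in zip(parts, per_part):
        if c:
            # mid-cell placement keeps positions strictly inside the part
            out.extend((a + (b - a) * (i + 0.5) / c) for i in range(c))
    return out


def build_bins(vf_positions: Sequence[float], gamma: float,
               bounds: tuple[float, float] | None = None
               ) -> list[tuple[float, float]]:
    """Per-VF search interval [w_j - y*D, w_j + y*D], clipped to bounds.

    D is the mean adjacent VF spacing.  With gamma = 0 every interval
    degenerates to the point w_j (the optimizer then falls back to the
    nearest candidate).
    """
    if not (0.0 <= gamma <= 1.0):
        raise FrameError(f"gamma must be in [0, 1], got {gamma}")
    vf = np.asarray(vf_positions, dtype=float)
    if len(vf) < 2:
        raise FrameError("need at least 2 VF positions")
    mean_spacing = float(np.diff(vf).mean())
    radius = gamma * mean_spacing
    lo_b, hi_b = bounds if bounds is not None else (vf[0], vf[-1])
    return [
        (max(lo_b, w - radius), min(hi_b, w + radius)) for w in vf
    ]
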