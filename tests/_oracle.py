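"""Independent brute-force reference for small design instances.

Re-derives the whole-chip selection by exhaustive enumeration of every
one-candidate-per-bin assignment, scored with the same frame-anchored
adjusted-entropy objective the optimizer defines, but implemented from
scratch (plain floats and itertools, no shared code paths with the
search).  Only valid for single-chromosome, gap-free instances with a
uniform frame.
"""

import itertools
import math


def entropy(p):
    if p in (0.0, 1.0):
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def adjusted(h, positions, c=1.0):
    pos = sorted(positions)
    deltas = [b - a for a, b in zip(pos, pos[1:])]
    dbar = sum(deltas) / len(deltas)
    if dbar <= 0:
        raise ValueError("zero mean spacing")
    factor = 1.0 - sum(abs(d - dbar) for d in deltas) / (len(deltas) * c * dbar)
    return h * max(factor, 0.0)


def exhaustive_design(candidates, n_picks, gamma=0.5, c=1.0):
    """Globally optimal one-per-bin selection, or None if infeasible.

    ``candidates``: list of (snp_id, pos, maf) on one chromosome.
    Returns the list of chosen snp_ids in frame order.  Instances where
    an interior bin holds no candidate, or where the boundary picks
    collide with interior bins, are reported as None (the caller skips
    them).
    """
    cands = sorted(candidates, key=lambda t: t[1])
    first, last = cands[0][1], cands[-1][1]
    m = n_picks
    if m < 3 or last <= first:
        return None
    vf = [first + (last - first) * j / (m - 1) for j in range(m)]
    spacing = (last - first) / (m - 1)
    radius = gamma * spacing

    def nearest(w, excluded):
        pool = [t for t in cands if t[0] not in excluded]
        return min(pool, key=lambda t: (abs(t[1] - w), t[1]))

    left_pick = nearest(vf[0], set())
    right_pick = nearest(vf[-1], {left_pick[0]})
    fixed_ids = {left_pick[0], right_pick[0]}

    pools = []
    for j in range(1, m - 1):
        pool = [t for t in cands
                if vf[j] - radius <= t[1] <= vf[j] + radius
                and t[0] not in fixed_ids]
        if not pool:
            return None
        pools.append(pool)

    def bin_key(j, cand):
        # anchors: fixed neighbours (boundary picks) or VF positions
        la = left_pick[1] if j == 1 else vf[j - 1]
        ra = right_pick[1] if j == m - 2 else vf[j + 1]
        score = adjusted(entropy(cand[2]), [la, cand[1], ra], c)
        return (-score, abs(cand[1] - vf[j]), cand[1], cand[0])

    best = None
    for combo in itertools.product(*pools):
        ids = [t[0] for t in combo]
        if len(set(ids)) < len(ids):
            continue
        key = tuple(bin_key(j + 1, cand) for j, cand in enumerate(combo))
        total = sum(-k[0] for k in key)
        full = (-total, key)
        if best is None or full < best[0]:
            best = (full, ids)
    if best is None:
        return None
    return [left_pick[0]] + best[1] + [right_pick[0]]
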