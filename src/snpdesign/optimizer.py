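"""Conditional, bin-wise local optimization of a SNP array design.

The engine distributes the selectable budget over chromosomes and
gap-free segments, places virtual-frame (VF) positions, and then sweeps
the resulting bins left to right, choosing in each bin the candidate
that maximizes spacing-adjusted Shannon entropy (locus-wise, or
haplotype-wise over multi-bin windows).  Selection is conditional:
obligatory SNPs consume bins before any optimization, boundary SNPs
(first/last candidate of every gap-free segment) are always kept, and
reserved slots only shrink the selectable budget.

Bin scoring is frame-anchored: the anchors of a bin are the flanking
*fixed* positions — a boundary SNP, an obligatory SNP, or the
neighbouring VF position — never another optimizer pick.  This makes
the per-bin scores separable, so the left-to-right sweep attains the
global arg-max of the summed objective over all one-candidate-per-bin
selections, and it reproduces the boundary-anchored single-bin worked
example exactly.

Tie-breaking everywhere: higher adjusted entropy, then nearer the VF
position, then lower bp position, then lexicographic id.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import allocation as alloc
from . import entropy as ent
from . import frames
from .maps import CandidateMap, HaplotypePanel

logger = logging.getLogger(__name__)

COMBINATION_CAP = 10 ** 6


class OptimizationError(ValueError):
    pass


@dataclass
class SelectionResult:
    """Final chosen SNPs with provenance and objective diagnostics.

    ``chosen`` columns: snp_id, chrom, pos, maf, provenance, bin_index.
    Provenance is one of obligatory, obligatory_unmapped, boundary,
    optimized, gap_fill.  ``shortfall`` counts slots that could not be
    filled because candidates were exhausted.
    """

    chosen: pd.DataFrame
    objective: float
    settings: dict = field(default_factory=dict)
    shortfall: int = 0
    reserved: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.chosen["snp_id"])

    @property
    def per_bin(self) -> dict[int, str]:
        placed = self.chosen[self.chosen["bin_index"] >= 0]
        return dict(zip(placed["bin_index"], placed["snp_id"]))


# ---------------------------------------------------------------------------
# slot machinery
# ---------------------------------------------------------------------------

@dataclass
class _Slot:
    vf: float
    lo: float
    hi: float
    boundary: bool = False
    taken_id: str | None = None
    taken_pos: float | None = None
    provenance: str | None = None

    @property
    def consumed(self) -> bool:
        return self.taken_id is not None


def _rank_key(score: float, vf: float, pos: float, snp_id: str):
    return (-score, abs(pos - vf), pos, snp_id)


def select_map_oriented(cands: pd.DataFrame, vf_positions) -> list[str]:
    """Map-only baseline: nearest not-yet-taken candidate per VF position.

    Ties go to the lower position.  Returns chosen snp_ids in VF order.
    """
    taken: set[str] = set()
    chosen = []
    pos = cands["pos"].to_numpy(dtype=float)
    ids = cands["snp_id"].to_list()
    for w in vf_positions:
        best = None
        for p, sid in zip(pos, ids):
            if sid in taken:
                continue
            key = (abs(p - w), p)
            if best is None or key < best[0]:
                best = (key, sid)
        if best is None:
            break
        taken.add(best[1])
        chosen.append(best[1])
    return chosen


def select_lase_bin(cands: pd.DataFrame, left_anchor: float, right_anchor: float,
                    c: float = 1.0, maf_threshold: float | None = None,
                    vf: float | None = None) -> tuple[str, float]:
    """Pick the in-bin candidate maximizing anchored adjusted entropy.

    Scores each candidate x by ``adjusted_entropy(H(maf), sorted([left,
    x, right]), c)``.  Returns (snp_id, score).  ``cands`` must already
    be restricted to the bin (and to not-yet-taken SNPs).
    """
    if cands.empty:
        raise OptimizationError("no candidates in bin")
    pool = cands
    if maf_threshold is not None:
        filtered = cands[cands["maf"] > maf_threshold]
        if not filtered.empty:
            pool = filtered
    vf_ref = vf if vf is not None else 0.5 * (left_anchor + right_anchor)
    best = None
    for row in pool.itertuples(index=False):
        score = _anchored_score(row.maf, row.pos, left_anchor, right_anchor, c)
        key = _rank_key(score, vf_ref, row.pos, row.snp_id)
        if best is None or key < best[0]:
            best = (key, row.snp_id, score)
    return best[1], best[2]


def _anchored_score(maf: float, pos: float, la: float, ra: float, c: float) -> float:
    h = ent.locus_entropy(maf)
    positions = sorted([la, pos, ra])
    return ent.adjusted_entropy(h, positions, c)


def select_hase_window(bin_pools: list[pd.DataFrame], left_anchor: float,
                       right_anchor: float, c: float = 1.0,
                       panel: HaplotypePanel | None = None,
                       vf_positions: list[float] | None = None,
                       cap: int = COMBINATION_CAP,
                       truncate: bool = False) -> tuple[list[str], float]:
    """Exhaustively score one-per-bin combinations by adjusted HASE.

    The joint haplotype frequency table comes from ``panel`` (aligned
    column order) or, absent a panel, from the independence product of
    the candidates' allele frequencies.  The uniformity adjustment uses
    the window positions bracketed by the two anchors.  Ties prefer the
    combination with the smallest total |position - VF| and then the
    lexicographically smallest id tuple.
    """
    w = len(bin_pools)
    if any(p.empty for p in bin_pools):
        raise OptimizationError("empty bin in haplotype window")
    sizes = [len(p) for p in bin_pools]
    product = int(np.prod(sizes))
    if product > cap:
        if not truncate:
            raise OptimizationError(
                f"window combination count {product} exceeds cap {cap}"
            )
        bin_pools = _truncate_pools(bin_pools, cap)
    vfs = vf_positions if vf_positions is not None else [
        0.5 * (left_anchor + right_anchor)
    ] * w
    col_of = None
    if panel is not None:
        col_of = {s: i for i, s in enumerate(panel.snp_ids)}
    best = None
    rows_per_bin = [list(p.itertuples(index=False)) for p in bin_pools]
    for combo in itertools.product(*rows_per_bin):
        ids = [r.snp_id for r in combo]
        if len(set(ids)) < w:
            continue
        positions = [r.pos for r in combo]
        if panel is not None:
            table = ent.haplotype_frequencies(panel, [col_of[i] for i in ids])
        else:
            table = ent.independent_haplotype_frequencies([r.maf for r in combo])
        h = ent.hase(table, w, normalization="per_snp")
        score = h * ent.uniformity_factor(
            sorted([left_anchor, *positions, right_anchor]), c
        )
        dist = sum(abs(p - v) for p, v in zip(positions, vfs))
        key = (-score, dist, tuple(ids))
        if best is None or key < best[0]:
            best = (key, ids, score)
    if best is None:
        raise OptimizationError("no feasible combination in haplotype window")
    return best[1], best[2]


def _truncate_pools(pools: list[pd.DataFrame], cap: int) -> list[pd.DataFrame]:
    pools = [p.sort_values(["maf", "pos"], ascending=[False, True]) for p in pools]
    while int(np.prod([len(p) for p in pools])) > cap:
        largest = max(range(len(pools)), key=lambda i: len(pools[i]))
        pools[largest] = pools[largest].iloc[:-1]
    return pools


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

def optimize_chip(cmap: CandidateMap, panel_size: int,
                  obligatory_ids=None, reserved: int = 0,
                  criterion: str = "lase", gamma: float = 0.5, c: float = 1.0,
                  enrichment: str = "uniform", window: int = 3,
                  maf_threshold: float | None = None,
                  haplotypes: HaplotypePanel | None = None) -> SelectionResult:
    """Design a panel of ``panel_size`` SNPs from the candidate map.

    Pipeline: reserve slots (manufacturing bins, unmapped obligatory
    SNPs), allocate the remainder over chromosomes and segments with
    gap adjustment and obligatory minima, place VF positions (uniform
    or terminally enriched), consume bins holding obligatory SNPs, fill
    the remaining bins by locus- or haplotype-entropy local search, and
    finally fill oversized gaps with any leftover budget.
    """
    if criterion not in {"lase", "hase"}:
        raise OptimizationError(f"unknown criterion {criterion!r}")
    if not (0.0 <= gamma <= 1.0):
        raise OptimizationError(f"gamma must be in [0, 1], got {gamma}")
    if gamma > 0.5:
        logger.warning("gamma=%.2f > 0.5: neighbouring search bins overlap", gamma)
    if window not in (1, 3, 5):
        raise OptimizationError(f"window must be 1, 3 or 5, got {window}")
    if enrichment not in {"uniform", "more", "less"}:
        raise OptimizationError(f"unknown enrichment {enrichment!r}")

    work = cmap.with_obligatory(obligatory_ids) if obligatory_ids else cmap
    panel = haplotypes.align(list(work.mapped["snp_id"])) if haplotypes else None

    unmapped_oblig = work.unmapped[work.unmapped["obligatory"]]
    selectable = panel_size - reserved - len(unmapped_oblig)
    mapped_oblig = work.mapped[work.mapped["obligatory"]]
    if selectable < len(mapped_oblig):
        raise OptimizationError(
            f"selectable budget {selectable} below mapped obligatory count "
            f"{len(mapped_oblig)}"
        )

    settings = {
        "panel_size": panel_size, "reserved": reserved, "criterion": criterion,
        "gamma": gamma, "c": c, "enrichment": enrichment, "window": window,
        "maf_threshold": maf_threshold,
    }

    overflow = max(0, selectable - len(work.mapped))
    if overflow:
        logger.warning("budget exceeds candidate pool by %d; recording shortfall",
                       overflow)
    plan, gapset = _allocate_with_gaps(work, selectable - overflow)

    chosen_rows: list[dict] = []
    bin_counter = 0
    shortfall = overflow
    for chrom in work.chromosomes:
        rows, bin_counter, short = _optimize_chromosome(
            work, chrom, plan.per_chromosome[chrom], gapset, criterion,
            gamma, c, enrichment, window, maf_threshold, panel, bin_counter,
        )
        chosen_rows.extend(rows)
        shortfall += short

    for row in unmapped_oblig.itertuples(index=False):
        chosen_rows.append(dict(
            snp_id=row.snp_id, chrom=None, pos=None, maf=row.maf,
            provenance="obligatory_unmapped", bin_index=-1,
        ))

    chosen = pd.DataFrame(
        chosen_rows,
        columns=["snp_id", "chrom", "pos", "maf", "provenance", "bin_index"],
    )
    result = SelectionResult(chosen, 0.0, settings, shortfall, reserved)
    if shortfall:
        result = fill_gaps(result, work, shortfall, c)
        result.shortfall = shortfall - (len(result.chosen) - len(chosen))
        if result.shortfall:
            logger.warning("%d slots unfilled: candidates exhausted",
                           result.shortfall)
    _finalize_objective(result, c)
    return result


def _allocate_with_gaps(cmap: CandidateMap, selectable: int):
    """Two-pass allocation: gap-free first, then with detected gaps."""
    lengths = cmap.chrom_lengths
    chroms = sorted(lengths)
    oblig = {
        k: int(cmap.chromosome(k)["obligatory"].sum()) for k in chroms
    }
    capacity = {k: len(cmap.chromosome(k)) for k in chroms}
    counts = alloc.largest_remainder(
        [lengths[k] for k in chroms], selectable,
        minima=[oblig[k] for k in chroms],
        maxima=[capacity[k] for k in chroms],
    )
    plan0 = {k: c for k, c in zip(chroms, counts)}
    per_chrom_gaps = {}
    for k in chroms:
        if plan0[k] >= 2 and len(cmap.positions(k)) >= 2:
            ref = alloc.reference_mean_spacing(lengths[k], plan0[k])
            per_chrom_gaps[k] = _shrunk_gaps(cmap, k, ref, lengths[k])
    gapset = alloc.GapSet(per_chrom_gaps)
    weights = [(1.0 - gapset.fraction(k)) * lengths[k] for k in chroms]
    counts = alloc.largest_remainder(
        weights, selectable,
        minima=[oblig[k] for k in chroms],
        maxima=[capacity[k] for k in chroms],
    )
    plan = alloc.AllocationPlan({k: c for k, c in zip(chroms, counts)}, selectable)
    return plan, gapset


def _shrunk_gaps(cmap: CandidateMap, chrom: int, ref: float,
                 length: float) -> alloc.ChromosomeGaps:
    """Detected gaps, shrunk around obligatory SNPs sitting inside them."""
    raw = alloc.detect_gaps(cmap.positions(chrom), ref, length)
    oblig_pos = cmap.chromosome(chrom).loc[lambda d: d["obligatory"], "pos"]
    pieces = []
    for a, b in raw.intervals:
        inside = sorted(p for p in oblig_pos if a < p < b)
        lo = a
        for p in inside:
            if p - lo > 2.0 * ref:
                pieces.append((lo, float(p)))
            lo = float(p)
        if b - lo > 2.0 * ref:
            pieces.append((lo, b))
    total = sum(b - a for a, b in pieces)
    return alloc.ChromosomeGaps(tuple(pieces), min(total / length, 1.0))


def _optimize_chromosome(cmap, chrom, n_k, gapset, criterion, gamma, c,
                         enrichment, window, maf_threshold, panel,
                         bin_counter, ):
    df = cmap.chromosome(chrom)
    rows: list[dict] = []
    if n_k <= 0:
        return rows, bin_counter, 0
    if n_k >= len(df):  # saturation: take everything
        for r in df.itertuples(index=False):
            rows.append(dict(
                snp_id=r.snp_id, chrom=chrom, pos=r.pos, maf=r.maf,
                provenance="obligatory" if r.obligatory else "optimized",
                bin_index=-1,
            ))
        return rows, bin_counter, n_k - len(df)

    first, last = float(df["pos"].iloc[0]), float(df["pos"].iloc[-1])
    gaps = gapset.intervals(chrom)
    oblig_pos = set(df.loc[df["obligatory"], "pos"].astype(float))

    # obligatory SNPs stranded inside residual gaps are taken directly
    segs = alloc.segments_from_gaps(first, last, gaps)
    in_segment = np.zeros(len(df), dtype=bool)
    seg_of = np.full(len(df), -1)
    positions = df["pos"].to_numpy(dtype=float)
    for si, (a, b) in enumerate(segs):
        mask = (positions >= a) & (positions <= b) & ~in_segment
        in_segment |= mask
        seg_of[mask] = si
    direct = df[(~in_segment) & df["obligatory"]]
    for r in direct.itertuples(index=False):
        rows.append(dict(snp_id=r.snp_id, chrom=chrom, pos=r.pos, maf=r.maf,
                         provenance="obligatory", bin_index=-1))
    budget = n_k - len(direct)

    seg_lengths = [b - a for a, b in segs]
    seg_oblig = [
        int(((seg_of == si) & df["obligatory"].to_numpy()).sum())
        for si in range(len(segs))
    ]
    seg_cap = [int((seg_of == si).sum()) for si in range(len(segs))]
    shortfall = 0
    if enrichment == "uniform":
        seg_counts = alloc.largest_remainder(
            seg_lengths, budget, minima=seg_oblig, maxima=seg_cap)
        groups = []
        for (a, b), m_s in zip(segs, seg_counts):
            if m_s <= 0:
                continue
            vf = _segment_frames(a, b, m_s)
            groups.append(((a, b), vf))
    else:
        vf = (frames.place_beta(first, last, budget, enrichment, gaps)
              if budget >= 4 else _segment_frames(first, last, budget))
        groups = [((first, last), vf)]

    taken: set[str] = set()
    for (a, b), vf in groups:
        grp = df[(positions >= a) & (positions <= b)]
        new_rows, bin_counter, short = _sweep_group(
            grp, vf, (a, b), chrom, criterion, gamma, c, window,
            maf_threshold, panel, taken, bin_counter)
        rows.extend(new_rows)
        shortfall += short
    return rows, bin_counter, shortfall


def _segment_frames(a: float, b: float, m: int) -> np.ndarray:
    if m >= 2:
        return frames.place_uniform(a, b, m)
    return np.array([0.5 * (a + b)])


def _sweep_group(grp: pd.DataFrame, vf: np.ndarray, bounds, chrom,
                 criterion, gamma, c, window, maf_threshold, panel,
                 taken: set, bin_counter: int):
    """Fill one slot per VF position within a segment/chromosome group."""
    a, b = bounds
    m = len(vf)
    if m >= 2:
        bins = frames.build_bins(vf, gamma, (a, b))
    else:
        r = gamma * 0.5 * (b - a)
        bins = [(vf[0] - r, vf[0] + r)]
    slots = [
        _Slot(float(w), lo, hi,
              boundary=(m >= 2 and j in (0, m - 1)))
        for j, (w, (lo, hi)) in enumerate(zip(vf, bins))
    ]
    pos = grp["pos"].to_numpy(dtype=float)

    # 1. boundary slots snap to the nearest candidate (the segment ends)
    for slot in slots:
        if slot.boundary:
            _consume_nearest(slot, grp, taken, "boundary")

    # 2. obligatory SNPs consume the nearest unconsumed slots
    oblig = grp[grp["obligatory"] & ~grp["snp_id"].isin(taken)]
    for r in oblig.sort_values("pos").itertuples(index=False):
        free = [s for s in slots if not s.consumed]
        if not free:
            break
        slot = min(free, key=lambda s: (abs(s.vf - r.pos), s.vf))
        _assign(slot, r, taken, "obligatory")

    # leftover obligatory (more obligatory than slots) are appended directly
    extra_oblig = grp[grp["obligatory"] & ~grp["snp_id"].isin(taken)]

    # 3. optimization sweep, left to right
    open_idx = [j for j, s in enumerate(slots) if not s.consumed]
    if criterion == "hase" and window > 1:
        runs = _consecutive_runs(open_idx)
        plan: list[tuple[str, list[int]]] = []
        for run in runs:
            i = 0
            while i + window <= len(run):
                plan.append(("hase", run[i:i + window]))
                i += window
            for j in run[i:]:
                plan.append(("lase", [j]))
    else:
        plan = [("lase", [j]) for j in open_idx]

    shortfall = 0
    for kind, idxs in plan:
        if kind == "lase":
            j = idxs[0]
            slot = slots[j]
            pool = _slot_pool(grp, slot, taken, maf_threshold)
            if pool is None:
                shortfall += 1
                continue
            la, ra = _anchors(slots, j, j, (a, b))
            sid, score = select_lase_bin(pool, la, ra, c, None, slot.vf)
            row = grp[grp["snp_id"] == sid].iloc[0]
            _assign(slot, row, taken, "optimized")
        else:
            pools = []
            ok = True
            for j in idxs:
                pool = _slot_pool(grp, slots[j], taken, maf_threshold)
                if pool is None:
                    ok = False
                    break
                pools.append(pool)
            if not ok:
                # degrade to locus scoring slot by slot
                for j in idxs:
                    slot = slots[j]
                    pool = _slot_pool(grp, slot, taken, maf_threshold)
                    if pool is None:
                        shortfall += 1
                        continue
                    la, ra = _anchors(slots, j, j, (a, b))
                    sid, _ = select_lase_bin(pool, la, ra, c, None, slot.vf)
                    _assign(slots[j], grp[grp["snp_id"] == sid].iloc[0],
                            taken, "optimized")
                continue
            la, ra = _anchors(slots, idxs[0], idxs[-1], (a, b))
            ids, _ = select_hase_window(
                pools, la, ra, c, panel,
                [slots[j].vf for j in idxs], truncate=True)
            for j, sid in zip(idxs, ids):
                _assign(slots[j], grp[grp["snp_id"] == sid].iloc[0],
                        taken, "optimized")

    rows = []
    for j, slot in enumerate(slots):
        if slot.consumed:
            r = grp[grp["snp_id"] == slot.taken_id].iloc[0]
            rows.append(dict(
                snp_id=slot.taken_id, chrom=chrom, pos=r["pos"], maf=r["maf"],
                provenance=slot.provenance, bin_index=bin_counter + j,
            ))
    for r in extra_oblig.itertuples(index=False):
        if r.snp_id not in taken:
            taken.add(r.snp_id)
            rows.append(dict(snp_id=r.snp_id, chrom=chrom, pos=r.pos,
                             maf=r.maf, provenance="obligatory", bin_index=-1))
    return rows, bin_counter + m, shortfall


def _consecutive_runs(indices: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for j in indices:
        if runs and j == runs[-1][-1] + 1:
            runs[-1].append(j)
        else:
            runs.append([j])
    return runs


def _slot_pool(grp: pd.DataFrame, slot: _Slot, taken: set,
               maf_threshold: float | None) -> pd.DataFrame | None:
    """Candidates eligible for a slot, honouring the fallback rules.

    In-bin candidates above the MAF threshold; if none, in-bin ignoring
    the threshold; if the bin is empty, the single nearest remaining
    candidate to the VF position (the gamma = 0 semantics).  Returns
    None when the group is exhausted.
    """
    avail = grp[~grp["snp_id"].isin(taken)]
    if avail.empty:
        return None
    inbin = avail[(avail["pos"] >= slot.lo) & (avail["pos"] <= slot.hi)]
    if not inbin.empty:
        if maf_threshold is not None:
            f = inbin[inbin["maf"] > maf_threshold]
            if not f.empty:
                return f
        return inbin
    order = (avail["pos"] - slot.vf).abs()
    nearest = avail.loc[[order.sort_values(kind="stable").index[0]]]
    return nearest


def _anchors(slots: list[_Slot], j_left: int, j_right: int,
             bounds) -> tuple[float, float]:
    """Fixed flanking positions for slots [j_left..j_right].

    A neighbouring slot anchors at its fixed content (boundary or
    obligatory SNP) if consumed, else at its VF position; segment
    bounds anchor the outermost slots.
    """
    a, b = bounds
    if j_left == 0:
        la = a
    else:
        la = _fixed_position(slots[j_left - 1])
    if j_right == len(slots) - 1:
        ra = b
    else:
        ra = _fixed_position(slots[j_right + 1])
    return float(la), float(ra)


def _fixed_position(slot: _Slot) -> float:
    """A slot anchors at its fixed content, never at an optimizer pick."""
    if slot.provenance in ("boundary", "obligatory"):
        return slot.taken_pos
    return slot.vf


def _consume_nearest(slot: _Slot, grp: pd.DataFrame, taken: set,
                     provenance: str) -> None:
    avail = grp[~grp["snp_id"].isin(taken)]
    if avail.empty:
        return
    order = (avail["pos"] - slot.vf).abs()
    row = avail.loc[order.sort_values(kind="stable").index[0]]
    prov = "obligatory" if row["obligatory"] else provenance
    _assign(slot, row, taken, prov)


def _assign(slot: _Slot, row, taken: set, provenance: str) -> None:
    sid = row.snp_id if hasattr(row, "snp_id") else row["snp_id"]
    pos = row.pos if hasattr(row, "pos") else row["pos"]
    oblig = getattr(row, "obligatory", None)
    if oblig is None:
        oblig = row["obligatory"]
    slot.taken_id = str(sid)
    slot.taken_pos = float(pos)
    slot.provenance = "obligatory" if bool(oblig) else provenance
    taken.add(str(sid))


# ---------------------------------------------------------------------------
# gap filling and layering
# ---------------------------------------------------------------------------

def fill_gaps(selection: SelectionResult, cmap: CandidateMap,
              budget: int, c: float = 1.0) -> SelectionResult:
    """Insert candidates into oversized gaps of the selected panel.

    Repeatedly finds the largest selected-SNP gap exceeding twice the
    chip's per-chromosome mean spacing and inserts the interior
    candidate maximizing anchored adjusted entropy (ties: nearer the
    gap midpoint, then lower position).  Gaps without interior
    candidates remain unfilled.
    """
    chosen = selection.chosen.copy()
    added = []
    while budget > 0:
        gaps = _panel_gaps(chosen)
        pick = None
        for chrom, lo, hi in gaps:  # sorted by length, descending
            taken = set(chosen["snp_id"])
            cands = cmap.chromosome(chrom)
            inside = cands[(cands["pos"] > lo) & (cands["pos"] < hi)
                           & ~cands["snp_id"].isin(taken)]
            if inside.empty:
                continue
            mid = 0.5 * (lo + hi)
            best = None
            for r in inside.itertuples(index=False):
                score = _anchored_score(r.maf, r.pos, lo, hi, c)
                key = (-score, abs(r.pos - mid), r.pos, r.snp_id)
                if best is None or key < best[0]:
                    best = (key, r)
            pick = (chrom, best[1])
            break
        if pick is None:
            break
        chrom, r = pick
        added.append(dict(snp_id=r.snp_id, chrom=chrom, pos=r.pos, maf=r.maf,
                          provenance="gap_fill", bin_index=-1))
        chosen = pd.concat([chosen, pd.DataFrame(added[-1:])], ignore_index=True)
        budget -= 1
    out = SelectionResult(chosen, selection.objective, dict(selection.settings),
                          selection.shortfall, selection.reserved,
                          dict(selection.diagnostics))
    _finalize_objective(out, c)
    return out


def _panel_gaps(chosen: pd.DataFrame) -> list[tuple[int, float, float]]:
    """Oversized inter-SNP intervals of the panel, largest first."""
    out = []
    placed = chosen.dropna(subset=["pos"])
    for chrom, grp in placed.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy(dtype=float))
        if len(pos) < 2:
            continue
        d = np.diff(pos)
        mean = d.mean()
        for i in np.nonzero(d > 2.0 * mean)[0]:
            out.append((chrom, float(pos[i]), float(pos[i + 1])))
    return sorted(out, key=lambda t: t[2] - t[1], reverse=True)


def _finalize_objective(result: SelectionResult, c: float) -> None:
    placed = result.chosen.dropna(subset=["pos"])
    if placed.empty:
        result.objective = 0.0
        return
    panel_lase = ent.lase(placed["maf"].to_numpy(dtype=float))
    adj_parts, weights = [], []
    for chrom, grp in placed.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy(dtype=float))
        h = ent.lase(grp["maf"].to_numpy(dtype=float))
        if len(pos) >= 2 and np.diff(pos).mean() > 0:
            adj_parts.append(ent.adjusted_entropy(h, pos, c))
        else:
            adj_parts.append(h)
        weights.append(len(grp))
    adjusted = float(np.average(adj_parts, weights=weights))
    result.objective = adjusted
    result.diagnostics.update({
        "lase": panel_lase, "adjusted_lase": adjusted,
        "n_chosen": int(len(result.chosen)),
    })


def compose_layered_panel(base_map: CandidateMap,
                          layers: list[dict]) -> SelectionResult:
    """Build a panel in layers, each conditional on all previous picks.

    Each layer dict: ``label``, ``count``, optional ``maf`` (mapping
    snp_id -> frequency overriding the shared map, e.g. breed-specific
    frequencies), optional ``map`` (a CandidateMap subset), and
    ``settings`` forwarded to :func:`optimize_chip`.  Accumulated SNPs
    are treated as obligatory for every later layer; a final gap-fill
    pass runs on the union.
    """
    accumulated: list[str] = []
    cumulative = 0
    result = None
    for layer in layers:
        layer_map = layer.get("map", base_map)
        if "maf" in layer and layer["maf"] is not None:
            layer_map = _override_maf(layer_map, layer["maf"])
        cumulative += int(layer["count"])
        obligatory = accumulated + list(layer_map.obligatory_ids())
        result = optimize_chip(
            layer_map, cumulative, obligatory_ids=obligatory,
            **layer.get("settings", {}),
        )
        accumulated = result.snp_ids
    if result is None:
        raise OptimizationError("no layers given")
    c = result.settings.get("c", 1.0)
    result = fill_gaps(result, base_map, result.shortfall, c)
    return result


def _override_maf(cmap: CandidateMap, maf_table) -> CandidateMap:
    df = cmap.df.copy()
    maf = pd.Series(dict(maf_table))
    missing = set(df["snp_id"]) - set(maf.index)
    if missing:
        raise OptimizationError(
            f"layer frequency table missing SNPs: {sorted(missing)[:10]}"
        )
    df["maf"] = df["snp_id"].map(maf)
    return CandidateMap.from_frame(df, cmap.chrom_lengths)
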