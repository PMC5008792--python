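import itertools

import numpy as np
import pandas as pd
import pytest

import snpdesign as sd
from snpdesign.entropy import adjusted_entropy, locus_entropy, uniformity_factor
from snpdesign.maps import CandidateMap, HaplotypePanel, SnpRecord
from snpdesign.optimizer import (
    OptimizationError,
    fill_gaps,
    optimize_chip,
    select_hase_window,
    select_lase_bin,
    select_map_oriented,
)
from tests._oracle import exhaustive_design
from tests.conftest import make_map


def frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "maf",
                                       "obligatory"])


class TestSelectMapOriented:
    def test_nearest_per_frame_position(self, four_snp_map):
        chosen = select_map_oriented(four_snp_map.chromosome(1), [0, 50, 100])
        assert chosen == ["A", "C", "D"]  # 10, 50, 90

    def test_exact_match_taken(self):
        cands = frame([("A", 1, 25, 0.1, False), ("B", 1, 60, 0.2, False)])
        assert select_map_oriented(cands, [25]) == ["A"]

    def test_equidistant_tie_lower_position(self):
        cands = frame([("A", 1, 40, 0.1, False), ("B", 1, 60, 0.2, False)])
        assert select_map_oriented(cands, [50]) == ["A"]


class TestSelectLaseBin:
    def test_worked_example_prefers_balanced_snp(self, fig_segment):
        # MAF 0.4239 off-center vs 0.2000 centered vs 0.3524 nearly
        # centered: the adjusted criterion picks the 0.3524 SNP at 48
        sid, score = select_lase_bin(fig_segment, 0.0, 100.0, c=1.0, vf=50.0)
        assert sid == "B"
        assert score == pytest.approx(0.96 * locus_entropy(0.3524))
        # frozen per-candidate adjusted values
        scores = {
            r.snp_id: adjusted_entropy(
                locus_entropy(r.maf), sorted([0, r.pos, 100]), 1.0)
            for r in fig_segment.itertuples(index=False)
        }
        assert scores["A"] == pytest.approx(0.60960, abs=1e-4)
        assert scores["C"] == pytest.approx(0.72193, abs=1e-4)
        assert scores["D"] == pytest.approx(0.40891, abs=1e-4)

    def test_large_c_reverts_to_pure_entropy(self, fig_segment):
        sid, _ = select_lase_bin(fig_segment, 0.0, 100.0, c=1e6, vf=50.0)
        assert sid == "A"  # highest MAF wins when location weighting vanishes

    def test_single_candidate_regardless_of_maf(self):
        cands = frame([("only", 1, 93, 0.01, False)])
        sid, _ = select_lase_bin(cands, 0.0, 100.0)
        assert sid == "only"

    def test_maf_threshold_filters(self, fig_segment):
        sid, _ = select_lase_bin(fig_segment, 0.0, 100.0, maf_threshold=0.40,
                                 vf=50.0)
        assert sid == "A"

    def test_empty_bin_errors(self):
        with pytest.raises(OptimizationError):
            select_lase_bin(frame([]), 0.0, 100.0)


class TestSelectHaseWindow:
    def test_single_candidate_bins(self):
        pools = [frame([(f"s{j}", 1, 25 * (j + 1), 0.3, False)])
                 for j in range(3)]
        ids, _ = select_hase_window(pools, 0.0, 100.0)
        assert ids == ["s0", "s1", "s2"]

    def test_centered_equifrequent_set_wins(self):
        pools = [
            frame([(f"c{j}", 1, 25 * (j + 1), 0.4, False),
                   (f"o{j}", 1, 25 * (j + 1) + 9, 0.4, False)])
            for j in range(3)
        ]
        ids, _ = select_hase_window(pools, 0.0, 100.0, c=1.0,
                                    vf_positions=[25, 50, 75])
        assert ids == ["c0", "c1", "c2"]  # equal entropy, better spacing

    def test_matches_brute_force_with_ld(self):
        # 2x2x2 toy with a panel carrying real LD structure
        rng = np.random.default_rng(42)
        mat = rng.integers(0, 2, size=(30, 6))
        mat[:, 3] = mat[:, 0]  # force strong dependence between two bins
        ids = [f"s{i}" for i in range(6)]
        panel = HaplotypePanel(mat, ids)
        freqs = panel.frequencies()
        pools = [
            frame([(ids[2 * j], 1, 30 * j + 20, freqs[2 * j], False),
                   (ids[2 * j + 1], 1, 30 * j + 28, freqs[2 * j + 1], False)])
            for j in range(3)
        ]
        got, got_score = select_hase_window(pools, 0.0, 120.0, c=1.0,
                                            panel=panel,
                                            vf_positions=[25, 55, 85])
        best = None
        for combo in itertools.product(*(p.itertuples(index=False)
                                         for p in pools)):
            cols = [ids.index(r.snp_id) for r in combo]
            codes = mat[:, cols] @ (1 << np.arange(2, -1, -1))
            table = np.bincount(codes, minlength=8) / len(mat)
            h = -(table[table > 0] * np.log2(table[table > 0])).sum() / 3
            score = h * uniformity_factor(
                sorted([0.0, *[r.pos for r in combo], 120.0]), 1.0)
            if best is None or score > best[0] + 1e-12:
                best = (score, [r.snp_id for r in combo])
        assert got_score == pytest.approx(best[0])
        assert got == best[1]

    def test_cap_exceeded_errors(self):
        pool = frame([(f"s{i}", 1, 10 + i, 0.3, False) for i in range(20)])
        with pytest.raises(OptimizationError, match="cap"):
            select_hase_window([pool] * 3, 0.0, 100.0, cap=100)


class TestOptimizeChip:
    def test_saturation_selects_everything(self):
        cmap = make_map(n_candidates=40, n_chromosomes=1, seed=2)
        res = optimize_chip(cmap, len(cmap))
        assert sorted(res.snp_ids) == sorted(cmap.df["snp_id"])
        assert res.diagnostics["lase"] == pytest.approx(
            sd.lase(cmap.df["maf"].to_numpy()))

    def test_gamma_zero_equals_map_oriented_baseline(self):
        cmap = make_map(n_candidates=120, n_chromosomes=1, seed=3)
        res = optimize_chip(cmap, 20, gamma=0.0)
        assert set(res.snp_ids) == sd.baseline_uniform(cmap, 20)

    def test_matches_exhaustive_search_small_instances(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(40):
            n_cand = int(rng.integers(8, 16))
            pos = np.sort(rng.choice(np.arange(1, 2000), n_cand, replace=False))
            maf = rng.uniform(0.02, 0.5, n_cand)
            cands = [(f"s{i:02d}", int(p), float(f))
                     for i, (p, f) in enumerate(zip(pos, maf))]
            expected = exhaustive_design(cands, 5, gamma=0.5, c=1.0)
            if expected is None:
                continue
            cmap = CandidateMap([SnpRecord(s, 1, p, f) for s, p, f in cands])
            res = optimize_chip(cmap, 5, gamma=0.5, c=1.0)
            assert res.snp_ids == expected
            checked += 1
        assert checked >= 15

    def test_obligatory_always_included(self):
        cmap = make_map(n_candidates=200, n_chromosomes=2, seed=8,
                        obligatory_fraction=0.05)
        res = optimize_chip(cmap, 60)
        oblig = set(cmap.obligatory_ids())
        assert oblig <= set(res.snp_ids)

    def test_obligatory_dilution_never_raises_lase(self):
        cmap = make_map(n_candidates=250, n_chromosomes=1, seed=9)
        rng = np.random.default_rng(10)
        ids = cmap.df["snp_id"].to_numpy()
        oblig1 = list(rng.choice(ids, 12, replace=False))
        oblig3 = oblig1 + list(
            rng.choice(np.setdiff1d(ids, oblig1), 24, replace=False))
        lases = []
        for ob in (None, oblig1, oblig3):
            res = optimize_chip(cmap, 50, obligatory_ids=ob)
            lases.append(res.diagnostics["lase"])
        assert lases[0] >= lases[1] >= lases[2]

    def test_reserved_slots_shrink_selection(self):
        cmap = make_map(n_candidates=150, n_chromosomes=1, seed=12)
        res = optimize_chip(cmap, 30, reserved=5)
        assert len(res.chosen) == 25
        assert res.reserved == 5

    def test_unmapped_obligatory_reported(self, tmp_path):
        records = [SnpRecord(f"s{i}", 1, 10 * (i + 1), 0.3) for i in range(20)]
        records.append(SnpRecord("lost", 0, 0, 0.2, obligatory=True,
                                 no_map=True))
        cmap = CandidateMap(records)
        res = optimize_chip(cmap, 8)
        row = res.chosen[res.chosen["snp_id"] == "lost"]
        assert row["provenance"].iloc[0] == "obligatory_unmapped"
        assert len(res.chosen) == 8

    def test_infeasible_budget_errors(self):
        cmap = make_map(n_candidates=50, n_chromosomes=1, seed=13,
                        obligatory_fraction=0.5)
        n_oblig = int(cmap.df["obligatory"].sum())
        with pytest.raises(OptimizationError):
            optimize_chip(cmap, n_oblig - 1)

    def test_deterministic_output(self):
        cmap = make_map(n_candidates=200, n_chromosomes=2, seed=14)
        a = optimize_chip(cmap, 40, gamma=0.5)
        b = optimize_chip(cmap, 40, gamma=0.5)
        assert a.chosen.to_csv() == b.chosen.to_csv()
        assert a.objective == b.objective

    def test_hase_reduces_to_lase_selection_count(self):
        cmap = make_map(n_candidates=200, n_chromosomes=1, seed=15)
        panel = sd.simulate_haplotypes(cmap, 30, 3e4, seed=16)
        res = optimize_chip(cmap, 30, criterion="hase", window=3,
                            haplotypes=panel)
        assert len(res.chosen) == 30
        assert not res.chosen["snp_id"].duplicated().any()


class TestBinGammaMonotonicity:
    def test_bin_score_nondecreasing_in_gamma(self):
        rng = np.random.default_rng(20)
        for _ in range(25):
            pos = np.sort(rng.uniform(0, 100, 12))
            maf = rng.uniform(0.02, 0.5, 12)
            cands = frame([(f"s{i}", 1, p, f, False)
                           for i, (p, f) in enumerate(zip(pos, maf))])
            vf, delta = 50.0, 25.0
            last = -np.inf
            for gamma in (0.1, 0.25, 0.5, 0.75, 1.0):
                pool = cands[(cands["pos"] >= vf - gamma * delta)
                             & (cands["pos"] <= vf + gamma * delta)]
                if pool.empty:
                    continue
                _, score = select_lase_bin(pool, 0.0, 100.0, c=1.0, vf=vf)
                assert score >= last - 1e-12
                last = score


class TestFillGaps:
    def _selection(self, positions, mafs):
        chosen = pd.DataFrame({
            "snp_id": [f"p{i}" for i in range(len(positions))],
            "chrom": 1, "pos": positions, "maf": mafs,
            "provenance": "optimized", "bin_index": -1,
        })
        return sd.SelectionResult(chosen, 0.0)

    def test_no_oversized_gap_unchanged(self):
        cmap = make_map(n_candidates=50, n_chromosomes=1, seed=21)
        sel = self._selection([0, 100, 200, 300], [0.3] * 4)
        out = fill_gaps(sel, cmap, budget=3)
        assert len(out.chosen) == 4

    def test_single_candidate_in_gap_added(self):
        records = [SnpRecord("a", 1, 10, 0.3), SnpRecord("mid", 1, 500, 0.4),
                   SnpRecord("b", 1, 1000, 0.3), SnpRecord("c", 1, 1010, 0.3),
                   SnpRecord("d", 1, 1020, 0.3)]
        cmap = CandidateMap(records)
        sel = self._selection([10, 1000, 1010, 1020], [0.3] * 4)
        out = fill_gaps(sel, cmap, budget=2)
        assert "mid" in set(out.chosen["snp_id"])
        fill = out.chosen[out.chosen["snp_id"] == "mid"]
        assert fill["provenance"].iloc[0] == "gap_fill"

    def test_tie_resolved_by_entropy_then_position(self):
        records = [SnpRecord("a", 1, 10, 0.3),
                   SnpRecord("lo", 1, 480, 0.2), SnpRecord("hi", 1, 520, 0.4),
                   SnpRecord("b", 1, 1000, 0.3), SnpRecord("c", 1, 1005, 0.3),
                   SnpRecord("d", 1, 1010, 0.3)]
        cmap = CandidateMap(records)
        sel = self._selection([10, 1000, 1005, 1010], [0.3] * 4)
        out = fill_gaps(sel, cmap, budget=1)
        added = set(out.chosen["snp_id"]) - set(sel.chosen["snp_id"])
        assert added == {"hi"}  # symmetric offsets: higher entropy wins


class TestLayeredComposition:
    def test_single_layer_equals_direct_call(self):
        cmap = make_map(n_candidates=150, n_chromosomes=1, seed=22)
        direct = optimize_chip(cmap, 30)
        layered = sd.compose_layered_panel(cmap, [
            {"label": "only", "count": 30, "settings": {}}])
        assert set(layered.snp_ids) == set(direct.snp_ids)

    def test_two_layers_no_duplicates_and_conditioning(self):
        cmap = make_map(n_candidates=250, n_chromosomes=1, seed=23)
        layered = sd.compose_layered_panel(cmap, [
            {"label": "base", "count": 20, "settings": {}},
            {"label": "top", "count": 20, "settings": {}},
        ])
        assert len(layered.snp_ids) == len(set(layered.snp_ids)) == 40

    def test_anticorrelated_breed_frequencies_change_layer_two(self):
        cmap = make_map(n_candidates=200, n_chromosomes=1, seed=24)
        flipped = {s: 0.5 - m + 0.001
                   for s, m in zip(cmap.df["snp_id"], cmap.df["maf"])}
        conditional = sd.compose_layered_panel(cmap, [
            {"label": "b1", "count": 25, "settings": {}},
            {"label": "b2", "count": 25, "settings": {}, "maf": flipped},
        ])
        unconditional = optimize_chip(
            sd.optimizer._override_maf(cmap, flipped), 25)
        layer2 = set(conditional.snp_ids)
        assert layer2 != set(unconditional.snp_ids)
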