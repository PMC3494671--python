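"""Pair classification, reliability criteria, error rates and the masking loop."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import aflpmask as am
from aflpmask.masking import MaskingError

from conftest import random_table
from naive_masking import naive_error_rates, naive_fixpoint


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

class TestClassifyPairs:
    def test_worked_example_states(self, worked_example):
        matrix, reps = worked_example
        table = am.classify_pairs(matrix, reps)
        assert table.states(0) == [
            ("0", "0"), ("0", "0"), ("1", "1"), ("1", "1"), ("0", "1"),
            ("0", "1"), ("1", "1"), ("1", "1"), ("0", "0"), ("0", "?"),
        ]

    def test_all_zero_profiles_give_reproducible_absences(self):
        m = am.AFLPMatrix(["a", "b"], [f"x{i}" for i in range(5)],
                          np.zeros((2, 5), dtype=np.int8))
        t = am.classify_pairs(m, am.ReplicateSet(pairs=[("a", "b")]))
        assert t.states(0) == [("0", "0")] * 5

    def test_all_missing_profiles_are_fully_ambiguous(self):
        m = am.AFLPMatrix(["a", "b"], ["x", "y"], np.full((2, 2), -1, dtype=np.int8))
        t = am.classify_pairs(m, am.ReplicateSet(pairs=[("a", "b")]))
        assert t.states(0) == [("?", "?")] * 2

    def test_state_count_invariants(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, 6, 9)
        for x in t.bin_ids:
            assert sum(t.bin_state_counts(x).values()) == t.n_pairs
        for y in t.pair_ids:
            assert sum(t.pair_state_counts(y).values()) == t.n_bins

    def test_unknown_sample_and_zero_pairs_error(self, worked_example):
        matrix, _ = worked_example
        with pytest.raises(am.AFLPError):
            am.classify_pairs(matrix, am.ReplicateSet(pairs=[("IndA_rep1", "ghost")]))
        with pytest.raises(am.AFLPError):
            am.classify_pairs(matrix, am.ReplicateSet(pairs=[]))


# ---------------------------------------------------------------------------
# reliability criteria and error rates
# ---------------------------------------------------------------------------

def _table_from_states(columns):
    """Build a PairStateTable from per-bin lists of (i, j) char states."""
    n_bins = len(columns)
    n_pairs = len(columns[0])
    code = {"0": 0, "1": 1, "?": -1}
    a = np.array([[code[columns[x][y][0]] for x in range(n_bins)] for y in range(n_pairs)], dtype=np.int8)
    b = np.array([[code[columns[x][y][1]] for x in range(n_bins)] for y in range(n_pairs)], dtype=np.int8)
    return am.PairStateTable(
        pair_ids=[(f"p{y}a", f"p{y}b") for y in range(n_pairs)],
        bin_ids=[f"b{x}" for x in range(n_bins)],
        a=a, b=b,
    )


class TestReliability:
    def test_bin_reliability_mixed_states(self):
        t = _table_from_states([[("0", "0"), ("1", "1"), ("0", "1")]])
        assert am.bin_reliability(t, "b0") == pytest.approx(2 / 3)

    def test_bin_reliability_perfect_and_undefined(self):
        t = _table_from_states([[("1", "1"), ("1", "1")], [("0", "?"), ("?", "?")]])
        assert am.bin_reliability(t, "b0") == 1.0
        assert math.isnan(am.bin_reliability(t, "b1"))

    def test_replicate_reliability_worked_example(self, worked_example):
        table = am.classify_pairs(*worked_example)
        assert am.replicate_reliability(table, table.pair_ids[0]) == pytest.approx(7 / 9)

    def test_replicate_reliability_all_ambiguous_is_undefined(self):
        t = _table_from_states([[("?", "?")], [("0", "?")]])
        assert math.isnan(am.replicate_reliability(t, t.pair_ids[0]))

    def test_unknown_bin_or_pair_errors(self, worked_example):
        table = am.classify_pairs(*worked_example)
        with pytest.raises(am.AFLPError):
            am.bin_reliability(table, "nope")
        with pytest.raises(am.AFLPError):
            am.replicate_reliability(table, ("a", "b"))


class TestErrorRates:
    def test_worked_example_rates(self, worked_example):
        table = am.classify_pairs(*worked_example)
        assert am.bonin_error(table) == pytest.approx(2 / 9)
        assert am.jaccard_error(table) == pytest.approx(2 / 6)

    def test_perfectly_reproducible_table_rates_are_zero(self):
        t = _table_from_states([[("0", "0")], [("1", "1")]])
        assert am.bonin_error(t) == 0.0
        assert am.jaccard_error(t) == 0.0

    def test_fully_mismatched_table_rates_are_one(self):
        t = _table_from_states([[("0", "1")], [("0", "1")]])
        assert am.bonin_error(t) == 1.0
        assert am.jaccard_error(t) == 1.0

    def test_empty_denominators_error_distinctly(self):
        ambiguous = _table_from_states([[("?", "?")]])
        with pytest.raises(MaskingError, match="mismatch"):
            am.bonin_error(ambiguous)
        only_absence = _table_from_states([[("0", "0")]])
        with pytest.raises(MaskingError, match="Jaccard"):
            am.jaccard_error(only_absence)

    def test_all_pairs_denominator_switch(self):
        t = _table_from_states([[("0", "1")], [("?", "?")]])
        assert am.bonin_error(t, denominator="unambiguous") == 1.0
        assert am.bonin_error(t, denominator="all") == 0.5

    @given(st.integers(0, 2**31 - 1))
    def test_bonin_never_exceeds_jaccard(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, int(rng.integers(1, 6)), int(rng.integers(1, 12)))
        try:
            rb = am.bonin_error(t)
            rj = am.jaccard_error(t)
        except MaskingError:
            return
        assert rb <= rj + 1e-12


# ---------------------------------------------------------------------------
# bin distance criterion
# ---------------------------------------------------------------------------

class TestBinDistance:
    def test_close_pair_masked(self):
        m = am.AFLPMatrix(["s"], ["b1", "b2", "b3"], np.zeros((1, 3), dtype=np.int8),
                          bin_size=[100.0, 100.1, 102.0])
        assert am.bin_distance_mask(m, m.bin_ids, 0.15) == {"b1", "b2"}

    def test_zero_threshold_distinct_sizes_empty(self):
        m = am.AFLPMatrix(["s"], ["b1", "b2"], np.zeros((1, 2), dtype=np.int8),
                          bin_size=[100.0, 100.5])
        assert am.bin_distance_mask(m, m.bin_ids, 0.0) == set()

    def test_without_sizes_empty(self):
        m = am.AFLPMatrix(["s"], ["b1", "b2"], np.zeros((1, 2), dtype=np.int8))
        assert am.bin_distance_mask(m, m.bin_ids, 0.5) == set()

    def test_invalid_threshold_rejected(self):
        m = am.AFLPMatrix(["s"], ["b1"], np.zeros((1, 1), dtype=np.int8))
        with pytest.raises(am.AFLPError, match="BD"):
            am.bin_distance_mask(m, m.bin_ids, 1.0)

    def test_only_unmasked_bins_considered(self):
        m = am.AFLPMatrix(["s"], ["b1", "b2", "b3"], np.zeros((1, 3), dtype=np.int8),
                          bin_size=[100.0, 100.1, 100.2])
        # with b2 already masked, b1 and b3 are adjacent but 0.2 apart
        assert am.bin_distance_mask(m, ["b1", "b3"], 0.15) == set()


# ---------------------------------------------------------------------------
# fixpoint loop
# ---------------------------------------------------------------------------

def _perfect_table(n_pairs=5, n_bins=8):
    rng = np.random.default_rng(0)
    a = rng.integers(0, 2, size=(n_pairs, n_bins)).astype(np.int8)
    a[0, :] = 1  # every bin has a (1,1)
    a[1, :] = 0  # and a (0,0), so no bin is invariant-present or -absent
    return am.PairStateTable(
        pair_ids=[(f"p{y}a", f"p{y}b") for y in range(n_pairs)],
        bin_ids=[f"b{x}" for x in range(n_bins)],
        a=a, b=a.copy(),
    )


class TestMaskFixpoint:
    def test_nothing_to_mask_on_perfect_table(self):
        t = _perfect_table()
        res = am.mask_fixpoint(None, None, 0.7, 0.5, 0.0, table=t)
        assert res.masked_bins == frozenset() and res.masked_pairs == frozenset()
        assert res.iterations == 1
        assert res.r_bonin == 0.0 and res.r_jaccard == 0.0

    def test_low_reliability_bin_masked_and_rates_recover(self):
        t = _perfect_table(n_pairs=4, n_bins=6)
        # corrupt bin b2: three mismatching pairs, one (1,1) -> BR = 1/4
        t.b[1:4, 2] = 1 - t.a[1:4, 2]
        t.a[0, 2] = t.b[0, 2] = 1
        res = am.mask_fixpoint(None, None, 0.7, 0.0, table=t)
        assert res.masked_bins == frozenset({"b2"})
        assert res.r_bonin == 0.0

    def test_masking_low_rr_pair_first_can_save_a_bin(self):
        # pair p1 is globally unreliable; bin b0's BR is dragged to 1/2 by it.
        # Masking the pair in step 1 lifts b0 to BR 1 before step 2 runs.
        cols = [
            [("1", "1"), ("0", "1")],
            [("1", "1"), ("1", "0")],
            [("1", "1"), ("0", "1")],
        ]
        t = _table_from_states(cols)
        res = am.mask_fixpoint(None, None, 0.7, 0.2, table=t)
        assert res.masked_pairs == frozenset({("p1a", "p1b")})
        assert res.masked_bins == frozenset()
        # order dependence: a bins-first variant would have masked every bin
        for x in range(3):
            col = [cols[x][y] for y in range(2)]
            rep = sum(1 for s in col if s[0] == s[1])
            assert rep / len(col) <= 0.7

    def test_all_pairs_masked_errors(self):
        t = _table_from_states([[("0", "1")], [("1", "0")]])
        with pytest.raises(MaskingError, match="all replicate pairs"):
            am.mask_fixpoint(None, None, 0.7, 0.5, table=t)

    def test_absent_bin_flag(self):
        cols = [
            [("0", "0"), ("0", "0")],          # invariant absent
            [("1", "1"), ("0", "0")],
        ]
        t = _table_from_states(cols)
        strict = am.mask_fixpoint(None, None, 0.7, 0.0, table=t)
        assert strict.masked_bins == frozenset({"b0"})
        lenient = am.mask_fixpoint(None, None, 0.7, 0.0, table=t,
                                   mask_all_absent_bins=False)
        assert lenient.masked_bins == frozenset()

    def test_prelim_masked_bins_stay_excluded(self):
        t = _perfect_table(n_pairs=4, n_bins=6)
        res = am.mask_fixpoint(None, None, 0.7, 0.0, table=t,
                               prelim_masked_bins=["b0", "b5"])
        assert res.n_bins_remaining == 4
        assert "b0" not in res.masked_bins  # pre-masked, not loop-masked


class TestFixpointProperties:
    N_TABLES = 200

    def test_postconditions_and_idempotence_on_random_tables(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(self.N_TABLES):
            n_pairs = int(rng.integers(2, 8))
            n_bins = int(rng.integers(2, 20))
            t = random_table(rng, n_pairs, n_bins, p_missing=float(rng.uniform(0, 0.3)))
            br = float(rng.integers(70, 96)) / 100
            rr = float(rng.integers(0, 10)) / 10
            try:
                res = am.mask_fixpoint(None, None, br, rr, table=t)
            except MaskingError:
                continue
            checked += 1
            pair_keep = np.array([p not in res.masked_pairs for p in t.pair_ids])
            bin_keep = np.array([b not in res.masked_bins for b in t.bin_ids])
            for b, keep in zip(t.bin_ids, bin_keep):
                if not keep:
                    continue
                brx = am.bin_reliability(t, b, pair_keep=pair_keep)
                counts = {
                    s: sum(
                        1
                        for y, k in enumerate(pair_keep)
                        if k and t.state(y, t.bin_ids.index(b)) == s
                    )
                    for s in [("1", "1"), ("0", "0"), ("0", "1"), ("1", "0")]
                }
                assert brx > br
                assert counts[("1", "1")] >= 1
                unamb = sum(counts.values())
                assert counts[("0", "0")] < unamb  # not all-(0,0)
            for p, keep in zip(t.pair_ids, pair_keep):
                if keep:
                    assert am.replicate_reliability(t, p, bin_keep=bin_keep) > rr
            # fixpoint: re-running on the masked table masks nothing further
            sub = am.PairStateTable(
                pair_ids=[p for p, k in zip(t.pair_ids, pair_keep) if k],
                bin_ids=[b for b, k in zip(t.bin_ids, bin_keep) if k],
                a=t.a[np.ix_(pair_keep, bin_keep)],
                b=t.b[np.ix_(pair_keep, bin_keep)],
            )
            res2 = am.mask_fixpoint(None, None, br, rr, table=sub)
            assert res2.masked_bins == frozenset() and res2.masked_pairs == frozenset()
        assert checked > self.N_TABLES // 4

    def test_agrees_with_naive_oracle_on_small_tables(self):
        rng = np.random.default_rng(7)
        agreements = 0
        for _ in range(300):
            n_pairs = int(rng.integers(1, 5))
            n_bins = int(rng.integers(1, 7))
            t = random_table(rng, n_pairs, n_bins, p_missing=float(rng.uniform(0, 0.4)))
            states = [t.states(y) for y in range(n_pairs)]
            br = float(rng.integers(0, 96)) / 100
            rr = float(rng.integers(0, 10)) / 10
            try:
                res = am.mask_fixpoint(None, None, br, rr, table=t)
                got = (
                    sorted(y for y, p in enumerate(t.pair_ids) if p not in res.masked_pairs),
                    sorted(x for x, b in enumerate(t.bin_ids) if b not in res.masked_bins),
                )
            except MaskingError:
                got = None
            expected = naive_fixpoint(states, br, rr)
            assert got == expected, (states, br, rr)
            if got is not None:
                rb, rj = naive_error_rates(states, got[0], got[1])
                assert res.r_bonin == pytest.approx(float(rb))
                if math.isfinite(res.r_jaccard):
                    assert res.r_jaccard == pytest.approx(float(rj))
                agreements += 1
        assert agreements > 50

    def test_exhaustive_two_pair_two_bin_tables(self):
        """Every {0,1,?}^(2x2x2) table, compared against the naive oracle."""
        from itertools import product

        codes = [0, 1, -1]
        cells = list(product(codes, repeat=8))
        for flat in cells:
            a = np.array(flat[:4], dtype=np.int8).reshape(2, 2)
            b = np.array(flat[4:], dtype=np.int8).reshape(2, 2)
            t = am.PairStateTable(
                pair_ids=[("pa0", "pb0"), ("pa1", "pb1")],
                bin_ids=["b0", "b1"], a=a, b=b,
            )
            states = [t.states(0), t.states(1)]
            for br, rr in [(0.7, 0.0), (0.5, 0.5), (0.95, 0.9)]:
                try:
                    res = am.mask_fixpoint(None, None, br, rr, table=t)
                    got = (
                        sorted(y for y, p in enumerate(t.pair_ids) if p not in res.masked_pairs),
                        sorted(x for x, bb in enumerate(t.bin_ids) if bb not in res.masked_bins),
                    )
                except MaskingError:
                    got = None
                assert got == naive_fixpoint(states, br, rr), (states, br, rr)

    def test_bins_remaining_monotone_in_br(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, 8, 40, p_missing=0.1)
        for rr in (0.0, 0.3):
            prev = None
            for brh in range(70, 96):
                try:
                    res = am.mask_fixpoint(None, None, brh / 100, rr, table=t)
                except MaskingError:
                    break
                if prev is not None:
                    assert res.n_bins_remaining <= prev
                prev = res.n_bins_remaining

    def test_determinism(self):
        rng = np.random.default_rng(9)
        t = random_table(rng, 5, 15)
        r1 = am.mask_fixpoint(None, None, 0.8, 0.2, table=t)
        r2 = am.mask_fixpoint(None, None, 0.8, 0.2, table=t)
        assert r1 == r2


# ---------------------------------------------------------------------------
# threshold sweep and mask application
# ---------------------------------------------------------------------------

class TestThresholdSweep:
    def test_default_grid_has_260_cells(self):
        assert am.Thresholds(br_min=0.7).grid_size == 260

    def test_maximal_br_min_gives_10_cells(self):
        assert am.Thresholds(br_min=0.95).grid_size == 10

    def test_grid_values_are_exact_decimals(self):
        th = am.Thresholds(br_min=0.7)
        grid = th.br_grid()
        assert grid[0] == 0.70 and grid[-1] == 0.95
        assert all(round(v * 100) == round(v * 100, 10) for v in grid)

    def test_two_quality_classes_collapse_to_few_groups(self, small_simulation):
        cfg, (matrix, reps, truth) = small_simulation
        sweep = am.threshold_sweep(matrix, reps, am.Thresholds())
        assert len(sweep.cells) == 260
        assert 1 <= len(sweep.emitted_groups) <= 15
        for g in sweep.groups:
            results = set()
            for br, rr in g.cells:
                cell = next(c for c in sweep.cells if c.br == br and c.rr == rr)
                results.add((cell.result.masked_bins, cell.result.masked_pairs))
            assert len(results) == 1

    def test_failed_cells_are_recorded_not_fatal(self):
        # both pairs have RR 1/2 at best, so strict RR cells mask everyone
        t = _table_from_states([[("0", "1"), ("1", "0")], [("1", "1"), ("0", "1")]])
        sweep = am.threshold_sweep(None, None, am.Thresholds(), table=t)
        assert any(c.result is None and c.error for c in sweep.cells)

    def test_sweep_matches_individual_fixpoints(self):
        rng = np.random.default_rng(21)
        t = random_table(rng, 6, 25)
        sweep = am.threshold_sweep(None, None, am.Thresholds(br_min=0.9), table=t)
        for cell in sweep.cells:
            if cell.result is None:
                continue
            solo = am.mask_fixpoint(None, None, cell.br, cell.rr, table=t)
            assert solo == cell.result


class TestApplyMask:
    def test_masked_bins_removed_for_all_samples(self, small_simulation):
        cfg, (matrix, reps, truth) = small_simulation
        res = am.mask_fixpoint(matrix, reps, 0.8, 0.0)
        out = am.apply_mask(matrix, res)
        assert out.n_bins == matrix.n_bins - len(res.masked_bins)
        assert set(out.bin_ids) == set(matrix.bin_ids) - res.masked_bins

    def test_empty_mask_is_identity(self, small_simulation):
        cfg, (matrix, reps, truth) = small_simulation
        res = am.MaskResult(0.7, 0.0, frozenset(), frozenset(), 0.0, 0.0,
                            matrix.n_bins, reps.n_pairs, 1)
        assert am.apply_mask(matrix, res).equals(matrix)

    def test_masked_pair_drops_replicate_profile_only(self, small_simulation):
        cfg, (matrix, reps, truth) = small_simulation
        pair = reps.pairs[0]
        res = am.MaskResult(0.7, 0.9, frozenset(), frozenset({pair}), 0.0, 0.0,
                            matrix.n_bins, reps.n_pairs - 1, 1)
        out = am.apply_mask(matrix, res)
        assert pair[0] in out.sample_ids and pair[1] not in out.sample_ids
        both = am.apply_mask(matrix, res, drop_paired_individuals=True)
        assert pair[0] not in both.sample_ids and pair[1] not in both.sample_ids

    def test_foreign_mask_rejected(self, small_simulation):
        cfg, (matrix, reps, truth) = small_simulation
        res = am.MaskResult(0.7, 0.0, frozenset({"no-such-bin"}), frozenset(),
                            0.0, 0.0, 1, 1, 1)
        with pytest.raises(am.AFLPError):
            am.apply_mask(matrix, res)
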