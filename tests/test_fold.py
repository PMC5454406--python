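"""Folding engine: closed-form pseudo-energies, hand-scored helices,
DP-vs-enumeration oracle equivalence, restraint response, and the
pseudoknot heuristic on planted structures."""

import math
import random

import numpy as np
import pytest

from oracles import enumerate_nested_structures
from tipirt.fold import (
    EnergyModel,
    energy_of,
    enumerate_helices,
    mfe_fold,
    shapeknots_fold,
)
from tipirt.restraints import RestraintParams, shape_pseudo_energy
from tipirt.shape import process_replicates
from tipirt.structure import Structure
from tipirt.synth import gen_structured_sequence, simulate_shape


class TestPseudoEnergy:
    @pytest.mark.parametrize(
        "S, expected",
        [
            (0.0, -0.6),                    # ln 1 = 0 → intercept only
            (math.e - 1.0, 1.8 - 0.6),      # ln e = 1 → slope + intercept
            (None, 0.0),                    # missing → no contribution
            (-1.5, 0.0),                    # negative treated as absent
            (float("nan"), 0.0),
        ],
    )
    def test_closed_form(self, S, expected):
        assert shape_pseudo_energy(S, RestraintParams()) == pytest.approx(expected)

    def test_monotone_in_reactivity(self):
        p = RestraintParams(m=1.8, b=-0.6)
        vals = [shape_pseudo_energy(s, p) for s in np.linspace(0, 4, 50)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            RestraintParams(m=-0.1)


class TestEnergyOf:
    def test_empty_structure_is_zero(self, model):
        assert energy_of(Structure(frozenset(), 10), "ACGUACGUAC", model) == 0.0

    def test_single_helix_hand_sum(self, model):
        # GGGAAAACCC: helix (1,10),(2,9),(3,8), 4-nt hairpin loop
        seq = "GGGAAAACCC"
        st = Structure({(1, 10), (2, 9), (3, 8)}, 10)
        expected = 2 * model.stack_energy("GC", "GC") + model.hairpin_penalty(4)
        assert energy_of(st, seq, model) == pytest.approx(expected)

    def test_zero_shape_shifts_by_b_per_stack_charge(self, model):
        seq = "GGGAAAACCC"
        st = Structure({(1, 10), (2, 9), (3, 8)}, 10)
        base = energy_of(st, seq, model)
        params = RestraintParams(m=1.8, b=-0.6, double_charge=True)
        shaped = energy_of(st, seq, model, np.zeros(10), params)
        # 2 stacks × 4 nucleotides charged each = 8 charges of b
        assert shaped - base == pytest.approx(8 * -0.6)
        single = energy_of(
            st, seq, model, np.zeros(10), RestraintParams(double_charge=False)
        )
        # inner-pair-only convention: 2 stacks × 2 nucleotides
        assert single - base == pytest.approx(4 * -0.6)

    def test_illegal_pair_rejected(self, model):
        with pytest.raises(ValueError, match="illegal pair"):
            energy_of(Structure({(1, 10)}, 10), "AAGAAAACCC", model)


def _best_enumerated(seq, model, shape=None, banned=frozenset()):
    best = math.inf
    for pairs0 in enumerate_nested_structures(seq, model.min_hairpin, banned):
        st = Structure(frozenset((i + 1, j + 1) for i, j in pairs0), len(seq))
        best = min(best, energy_of(st, seq, model, shape))
    return best


class TestMfeFold:
    def test_poly_a_has_no_pairs(self, model):
        assert mfe_fold("A" * 30, model).pairs == frozenset()

    def test_empty_sequence(self, model):
        assert mfe_fold("", model).pairs == frozenset()

    @pytest.mark.parametrize("with_shape", [False, True])
    def test_dp_equals_enumeration(self, model, with_shape):
        """DP MFE energy matches exhaustive enumeration on short sequences."""
        rng = random.Random(20 + with_shape)
        nprng = np.random.default_rng(99)
        for _ in range(60):
            n = rng.randint(6, 16)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            shape = nprng.random(n) * 2 if with_shape else None
            st = mfe_fold(seq, model, shape)
            e_dp = energy_of(st, seq, model, shape)
            assert e_dp == pytest.approx(_best_enumerated(seq, model, shape), abs=1e-4)

    def test_determinism(self, model):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGU") for _ in range(40))
        assert mfe_fold(seq, model).pairs == mfe_fold(seq, model).pairs

    def test_restraints_open_reactive_helix(self, model):
        """High reactivity on one strand of a designed hairpin removes
        pairs the unrestrained fold keeps."""
        seq = "AUAUAUAUACCCCUAUAUAUAU"  # 9-bp A-U stem, 4-nt C loop
        free = mfe_fold(seq, model)
        assert len(free.pairs) >= 8
        shape = np.zeros(len(seq))
        shape[:9] = 2.0  # one helix strand highly reactive
        restrained = mfe_fold(seq, model, shape)
        assert len(restrained.pairs) < len(free.pairs)

    def test_restraint_monotone_pair_count(self, model):
        seq = "AUAUAUAUACCCCUAUAUAUAU"
        helix_positions = set(range(1, 10))
        prev = None
        for level in (0.0, 0.5, 1.0, 2.0, 4.0):
            shape = np.zeros(len(seq))
            shape[:9] = level
            st = mfe_fold(seq, model, shape)
            n_helix = sum(1 for i, j in st.pairs if i in helix_positions)
            if prev is not None:
                assert n_helix <= prev
            prev = n_helix

    def test_banned_positions_never_pair(self, model):
        seq = "GGGGAAAACCCCGGGGAAAACCCC"
        banned = {1, 2, 3, 4}
        st = mfe_fold(seq, model, banned=banned)
        assert all(i not in banned and j not in banned for i, j in st.pairs)


class TestShapeknots:
    def test_no_crossing_candidates_returns_nested(self, model):
        seq = "GGGGAAAACCCC"
        assert shapeknots_fold(seq, None, model).pairs == mfe_fold(seq, model).pairs

    def test_never_worse_than_nested(self, model):
        rng = random.Random(31)
        for _ in range(10):
            seq = "".join(rng.choice("ACGU") for _ in range(45))
            nested_e = energy_of(mfe_fold(seq, model), seq, model)
            pk_e = energy_of(shapeknots_fold(seq, None, model), seq, model)
            assert pk_e <= nested_e + 1e-9

    def test_recovers_planted_pseudoknot_with_shape(self, model):
        truth = gen_structured_sequence(seed=2)
        tables = simulate_shape(truth, noise_sd=0.2, n_replicates=3, seed=2)
        profile, _ = process_replicates(tables)
        st = shapeknots_fold(truth.sequence, profile, model)
        assert truth.pseudoknot_pairs <= st.pairs

    def test_energy_bound_within_heuristic_search_space(self, model):
        """For short sequences, the heuristic's energy is at most the best
        over its own search space — nested structures plus every candidate
        helix combined with every nested fold of the remaining positions —
        enumerated by brute force."""
        rng = random.Random(77)
        for _ in range(6):
            n = rng.randint(12, 17)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            result = shapeknots_fold(seq, None, model, max_candidates=1000)
            e_result = energy_of(result, seq, model)
            best = _best_enumerated(seq, model)
            for _helix_e, helix in enumerate_helices(seq, model):
                banned = {p for pair in helix for p in pair}
                for pairs0 in enumerate_nested_structures(
                    seq, model.min_hairpin, frozenset(banned)
                ):
                    union = Structure(
                        frozenset((i + 1, j + 1) for i, j in pairs0)
                        | frozenset(helix),
                        n,
                    )
                    best = min(best, energy_of(union, seq, model))
            assert e_result <= best + 1e-6


class TestHelixEnumeration:
    def test_planted_stems_are_candidates(self):
        truth = gen_structured_sequence(seed=9)
        helices = [frozenset(h) for _, h in enumerate_helices(truth.sequence)]
        assert any(frozenset(truth.s2_pairs) <= h for h in helices) or any(
            frozenset(truth.s1_pairs) <= h for h in helices
        )

    def test_runs_are_complementary_and_long_enough(self, model):
        rng = random.Random(1)
        seq = "".join(rng.choice("ACGU") for _ in range(60))
        for _, helix in enumerate_helices(seq, model):
            assert len(helix) >= 3
            for (i, j), (k, l) in zip(helix, helix[1:]):
                assert (k, l) == (i + 1, j - 1)
            for i, j in helix:
                assert model.can_pair(seq[i - 1], seq[j - 1])
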