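"""Reactivity processing: subtraction, boxplot normalization, replicate
QC and composite merging, checked against direct-sorting oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import boxplot_normalize_oracle, sample_sd
from tipirt.shape import (
    ReactivityProfile,
    boxplot_normalize,
    composite_merge,
    compute_raw_reactivity,
    filter_by_sd,
    process_replicates,
)
from tipirt.synth import gen_structured_sequence, simulate_shape


class TestRawReactivity:
    def test_treated_equals_control_gives_zero(self):
        x = np.array([3.0, 5.0, 1.0])
        assert np.allclose(compute_raw_reactivity(x, x), 0.0)

    def test_zero_control_passes_treated_through(self):
        t = np.array([4.0, 0.0, 7.5])
        assert np.array_equal(compute_raw_reactivity(t, np.zeros(3)), t)

    def test_direct_subtraction_retains_negatives(self):
        out = compute_raw_reactivity([5, 2, 9], [1, 3, 4])
        assert out.tolist() == [4, -1, 5]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_raw_reactivity([1, 2], [1, 2, 3])


class TestBoxplotNormalize:
    def test_constant_vector_normalizes_to_one(self):
        out, scale = boxplot_normalize(np.full(20, 7.0))
        assert np.allclose(out, 1.0)
        assert scale == pytest.approx(7.0)

    def test_matches_sorting_oracle_on_1_to_100(self):
        vals = list(range(1, 101))
        expected, expected_scale = boxplot_normalize_oracle([float(v) for v in vals])
        out, scale = boxplot_normalize(np.array(vals, dtype=float))
        assert scale == pytest.approx(expected_scale)
        assert np.allclose(out, expected)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_oracle_on_random_profiles(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(1.0, 1.0, size=rng.integers(10, 200))
        expected, expected_scale = boxplot_normalize_oracle(vals.tolist())
        out, scale = boxplot_normalize(vals)
        assert scale == pytest.approx(expected_scale)
        assert np.allclose(out, expected)

    @given(st.floats(1e-6, 1e6), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(1.0, 1.0, size=50)
        base, _ = boxplot_normalize(vals)
        scaled, _ = boxplot_normalize(c * vals)
        assert np.allclose(base, scaled, atol=1e-12, rtol=1e-12)

    def test_top_ten_percent_mean_is_one(self):
        rng = np.random.default_rng(42)
        vals = rng.gamma(1.0, 1.0, size=137)
        out, scale = boxplot_normalize(vals)
        # recompute the selected top set on the normalized scale
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        keep = np.sort(vals[vals <= q3 + 1.5 * (q3 - q1)])
        n_top = int(np.ceil(0.10 * keep.size))
        assert np.mean(keep[-n_top:]) / scale == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(ValueError):
            boxplot_normalize(np.zeros(20))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            boxplot_normalize(np.ones(5))


class TestSdFilter:
    def test_identical_replicates_keep_everything(self):
        prof = np.tile(np.linspace(0, 2, 30), (3, 1))
        assert not filter_by_sd(prof).any()

    def test_threshold_is_strict(self):
        # replicate triples (1−d, 1, 1+d) have sample SD exactly d:
        # column SDs straddle the default threshold, 0.71 out, 0.69 in
        prof = np.array([
            [1 - 0.71, 1 - 0.69],
            [1.0, 1.0],
            [1 + 0.71, 1 + 0.69],
        ])
        sds = [sample_sd(prof[:, c].tolist()) for c in range(2)]
        assert sds[0] == pytest.approx(0.71) and sds[1] == pytest.approx(0.69)
        mask = filter_by_sd(prof)
        assert mask.tolist() == [True, False]

    def test_infinite_threshold_excludes_nothing(self):
        rng = np.random.default_rng(0)
        prof = rng.normal(size=(3, 40))
        assert not filter_by_sd(prof, threshold=np.inf).any()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        prof = rng.normal(scale=0.8, size=(3, 50))
        lo = filter_by_sd(prof, threshold=0.4)
        hi = filter_by_sd(prof, threshold=0.9)
        assert not (hi & ~lo).any()  # raising threshold never adds exclusions

    def test_single_replicate_warns_noop(self):
        with pytest.warns(UserWarning, match="single replicate"):
            mask = filter_by_sd(np.ones((1, 10)))
        assert not mask.any()


class TestCompositeMerge:
    def test_single_profile_identity(self):
        prof = ReactivityProfile(values={1: 0.2, 2: 1.1}, missing={3})
        merged = composite_merge([prof], [1])
        assert merged.values == prof.values
        assert merged.missing == {3}

    def test_overlap_is_unweighted_mean(self):
        a = ReactivityProfile(values={p: 1.0 for p in range(50, 101)})
        b = ReactivityProfile(values={p: 2.0 for p in range(1, 52)})
        merged = composite_merge([a, b], [1, 50])  # b maps 1..51 → 50..100
        for p in range(50, 101):
            assert merged.values[p] == pytest.approx(1.5)

    def test_disjoint_profiles_concatenate_with_gap(self):
        a = ReactivityProfile(values={1: 0.1, 2: 0.2})
        b = ReactivityProfile(values={1: 0.5})
        merged = composite_merge([a, b], [1, 10])
        assert set(merged.values) == {1, 2, 10}
        assert 5 not in merged.values and 5 not in merged.missing

    def test_coverage_conservation(self):
        rng = np.random.default_rng(3)
        profs, offs = [], []
        covered = set()
        for off in (1, 20, 45):
            vals = {int(p): float(rng.random()) for p in range(1, 31)}
            profs.append(ReactivityProfile(values=vals))
            offs.append(off)
            covered |= {p + off - 1 for p in vals}
        merged = composite_merge(profs, offs)
        assert set(merged.values) <= covered


class TestRoundTrip:
    def test_simulated_replicates_roundtrip(self):
        """Normalized profile correlates with the planted unpairedness."""
        truth = gen_structured_sequence(seed=11)
        tables = simulate_shape(truth, noise_sd=0.2, n_replicates=3, seed=11)
        profile, report = process_replicates(tables)
        arr = profile.to_array(len(truth.sequence))
        unpaired = ~truth.paired_mask()
        ok = ~np.isnan(arr)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(arr[ok], unpaired[ok].astype(float))
        assert rho > 0.5
        assert report["n_replicates"] == 3

    def test_zero_noise_replicates_identical(self):
        truth = gen_structured_sequence(seed=4)
        tables = simulate_shape(truth, noise_sd=0.0, n_replicates=3, seed=4)
        assert np.array_equal(tables[0].treated, tables[1].treated)
        profile, _ = process_replicates(tables)
        assert not profile.missing  # SD = 0 everywhere, nothing excluded
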