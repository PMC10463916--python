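import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sidermap.rings import (
    SectionSkipped,
    enumerate_combos,
    fit_ring_model,
    predict_map,
    residual_value,
    ring_counts,
    ring_densities,
    ring_offsets,
    scale_factor,
    compare_ring_models,
)

from conftest import heatmap_from_counts


def brute_ring_mean(counts, valid, i, j, k):
    """Independent neighborhood enumeration for the ring-k mean."""
    if k == 0:
        return counts[i, j] if valid[i, j] else np.nan
    num = den = 0.0
    nr, nc = counts.shape
    for di in range(-k, k + 1):
        for dj in range(-k, k + 1):
            if max(abs(di), abs(dj)) != k:
                continue
            r, c = i + di, j + dj
            if 0 <= r < nr and 0 <= c < nc and valid[r, c]:
                num += counts[r, c]
                den += 1
    return num / den if den else np.nan


class TestRingCounts:
    def test_ring_tallies_are_8_16_24(self):
        assert [len(ring_offsets(k)) for k in (1, 2, 3)] == [8, 16, 24]
        heat = heatmap_from_counts(np.ones((9, 9)))
        _, tallies = ring_counts(heat, 3)
        assert tallies[1, 4, 4] == 8 and tallies[2, 4, 4] == 16 and tallies[3, 4, 4] == 24

    def test_one_hot_map_ring_means(self):
        counts = np.zeros((5, 5))
        counts[2, 2] = 8.0
        heat = heatmap_from_counts(counts)
        means, _ = ring_counts(heat, 1)
        assert means[1, 2, 2] == 0.0  # its own ring-1 excludes the center
        assert means[1, 2, 3] == 1.0  # 8 spread over 8 neighbors
        assert means[0, 2, 2] == 8.0

    def test_random_map_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        counts = rng.poisson(4.0, (20, 20)).astype(float)
        valid = rng.uniform(size=(20, 20)) > 0.2
        heat = heatmap_from_counts(counts, valid)
        means, _ = ring_counts(heat, 3)
        for i in range(20):
            for j in range(20):
                for k in range(4):
                    expect = brute_ring_mean(counts, valid, i, j, k)
                    got = means[k, i, j]
                    if np.isnan(expect):
                        assert np.isnan(got)
                    else:
                        assert got == pytest.approx(expect)

    def test_negative_ring_count_rejected(self):
        with pytest.raises(ValueError):
            ring_counts(heatmap_from_counts(np.ones((3, 3))), -1)


class TestScaleFactor:
    def test_identical_maps_scale_one(self):
        heat = heatmap_from_counts([[2.0, 4.0], [0.0, 1.0]])
        marker = heatmap_from_counts([[2.0, 4.0], [0.0, 1.0]], stain="GFAP")
        assert scale_factor(marker, heat) == pytest.approx(1.0)

    def test_median_of_two_is_midpoint(self):
        iron = heatmap_from_counts([[2.0, 4.0, 0.0]])
        marker = heatmap_from_counts([[3.0, 9.0, 0.0]], stain="GFAP")
        assert scale_factor(marker, iron) == pytest.approx(2.0)

    def test_all_zero_iron_skips_section(self):
        iron = heatmap_from_counts(np.zeros((2, 2)))
        marker = heatmap_from_counts(np.ones((2, 2)), stain="GFAP")
        with pytest.raises(SectionSkipped):
            scale_factor(marker, iron)

    def test_subunit_warped_counts_do_not_enter_the_median(self):
        iron = heatmap_from_counts([[2.0, 4.0]])
        marker = heatmap_from_counts([[0.4, 6.0]], stain="GFAP")  # 0.4 < 1 object
        assert scale_factor(marker, iron) == pytest.approx(6.0 / 3.0)


def brute_partitions(total, parts):
    """Count monotone non-increasing compositions by direct recursion."""

    def rec(remaining, cap, slots):
        if slots == 0:
            return 1 if remaining == 0 else 0
        return sum(
            rec(remaining - v, v, slots - 1)
            for v in range(min(cap, remaining), -1, -1)
            if v * slots >= remaining
        )

    return rec(total, total, parts)


class TestEnumerateCombos:
    def test_zero_rings_is_the_trivial_combo(self):
        assert enumerate_combos(0).tolist() == [[100]]

    def test_one_ring_gives_51_combos(self):
        combos = enumerate_combos(1)
        assert combos.shape == (51, 2)
        assert combos[:, 0].min() == 50 and combos[:, 0].max() == 100

    def test_three_ring_count_matches_partition_enumeration(self):
        combos = enumerate_combos(3)
        assert combos.shape[0] == brute_partitions(100, 4)

    def test_constraint_chain_and_sum_hold_everywhere(self):
        for n in range(4):
            combos = enumerate_combos(n)
            assert (combos.sum(axis=1) == 100).all()
            assert (np.diff(combos, axis=1) <= 0).all()
            assert (combos >= 0).all()

    def test_deterministic_descending_order(self):
        combos = enumerate_combos(2)
        as_tuples = [tuple(r) for r in combos]
        assert as_tuples == sorted(as_tuples, reverse=True)
        assert as_tuples[0] == (100, 0, 0)

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            enumerate_combos(-1)
        with pytest.raises(ValueError):
            enumerate_combos(1, step=0.015)


class TestPredictMap:
    def _rings(self, seed=0, n_rings=3):
        rng = np.random.default_rng(seed)
        iron = heatmap_from_counts(rng.poisson(6.0, (8, 8)))
        marker = heatmap_from_counts(rng.poisson(6.0, (8, 8)), stain="GFAP")
        return ring_densities(iron, marker, n_rings), iron, marker

    def test_fully_local_combo_reproduces_scaled_iron(self):
        rings, iron, marker = self._rings()
        s = scale_factor(marker, iron)
        pred = predict_map(rings, np.array([100, 0, 0, 0]))
        assert np.allclose(pred, rings.d[:, 0])
        # d_pixel is the scaled iron count of the pixel itself
        fit_counts = iron.counts[tuple(rings.pixel_index.T)]
        assert np.allclose(rings.d[:, 0], s * fit_counts)

    def test_uniform_combo_is_the_mean_of_ring_values(self):
        rings, _, _ = self._rings()
        pred = predict_map(rings, np.array([0.25, 0.25, 0.25, 0.25]))
        assert np.allclose(pred, rings.d.mean(axis=1))

    def test_hand_built_weights_match_arithmetic(self):
        rings, _, _ = self._rings(seed=1, n_rings=2)
        combo = np.array([0.5, 0.3, 0.2])
        pred = predict_map(rings, combo)
        assert np.allclose(pred, rings.d @ combo)

    def test_wrong_length_combo_rejected(self):
        rings, _, _ = self._rings()
        with pytest.raises(ValueError, match="weights"):
            predict_map(rings, np.array([1.0, 0.0]))


class TestResidual:
    def test_multiply_and_divide_modes(self):
        marker = heatmap_from_counts([[3.0, 0.0, 5.0]], stain="GFAP")
        assert residual_value(2.0, marker, "multiply") == pytest.approx(8.0)
        assert residual_value(2.0, marker, "divide") == pytest.approx(0.5)

    def test_zero_error_gives_zero_residual(self):
        marker = heatmap_from_counts([[3.0]], stain="GFAP")
        assert residual_value(0.0, marker, "multiply") == 0.0
        assert residual_value(0.0, marker, "divide") == 0.0

    def test_no_marker_pixels_is_undefined(self):
        marker = heatmap_from_counts([[0.0, 0.5]], stain="GFAP")
        with pytest.raises(SectionSkipped):
            residual_value(1.0, marker)

    def test_mode_ordering_agrees_within_a_section(self):
        rng = np.random.default_rng(3)
        iron = heatmap_from_counts(rng.poisson(8.0, (12, 12)))
        marker = heatmap_from_counts(rng.poisson(8.0, (12, 12)), stain="GFAP")
        r_mul, r_div = [], []
        for n in range(4):
            fit_m = fit_ring_model(iron, marker, n, residual_mode="multiply")
            fit_d = fit_ring_model(iron, marker, n, residual_mode="divide")
            r_mul.append(fit_m.residual)
            r_div.append(fit_d.residual)
        assert np.argsort(r_mul).tolist() == np.argsort(r_div).tolist()


class TestFitRingModel:
    def test_exact_generative_marker_recovers_planted_combo(self):
        rng = np.random.default_rng(5)
        iron = heatmap_from_counts(rng.poisson(9.0, (15, 15)))
        marker0 = heatmap_from_counts(rng.poisson(9.0, (15, 15)), stain="GFAP")
        cstar = np.array([55, 25, 15, 5])
        rings = ring_densities(iron, marker0, 3)
        built = predict_map(rings, cstar)
        vals = np.zeros(iron.counts.shape)
        vals[tuple(rings.pixel_index.T)] = built
        marker = heatmap_from_counts(vals, stain="GFAP")
        # the generative construction holds the scale factor fixed
        fit = fit_ring_model(iron, marker, 3, scale=rings.scale)
        assert fit.error < 1e-9
        assert fit.coefficients_hundredths == tuple(cstar)

    def test_marker_equal_to_iron_selects_local_combo(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(7.0, (12, 12)).astype(float)
        iron = heatmap_from_counts(counts)
        marker = heatmap_from_counts(counts.copy(), stain="GFAP")
        fit = fit_ring_model(iron, marker, 3)
        assert fit.coefficients_hundredths == (100, 0, 0, 0)
        assert fit.error < 1e-12

    def test_too_few_pixels_skips_section(self):
        iron = heatmap_from_counts(np.ones((2, 2)))
        marker = heatmap_from_counts(np.ones((2, 2)), stain="GFAP")
        with pytest.raises(SectionSkipped, match="fit pixels"):
            fit_ring_model(iron, marker, 1, min_pixels=10)

    def test_strict_chain_mode_excludes_tied_weights(self):
        rng = np.random.default_rng(7)
        iron = heatmap_from_counts(rng.poisson(6.0, (10, 10)))
        marker = heatmap_from_counts(rng.poisson(6.0, (10, 10)), stain="GFAP")
        fit = fit_ring_model(iron, marker, 2, strict_chain=True)
        c = fit.coefficients_hundredths
        for a, b in zip(c[:-1], c[1:]):
            assert a > b or a == b == 0

    def test_search_equals_bruteforce_reevaluation(self):
        rng = np.random.default_rng(9)
        iron = heatmap_from_counts(rng.poisson(5.0, (10, 10)))
        marker = heatmap_from_counts(rng.poisson(5.0, (10, 10)), stain="GFAP")
        fit = fit_ring_model(iron, marker, 2)
        rings = ring_densities(iron, marker, 2)
        best_err, best_combo = np.inf, None
        for combo in enumerate_combos(2):
            pred = rings.d @ (combo / 100.0)
            err = np.abs(pred - rings.actual).mean()
            if err < best_err:
                best_err, best_combo = err, tuple(combo)
        assert fit.error == pytest.approx(best_err)
        assert fit.coefficients_hundredths == best_combo


class TestCompareRingModels:
    def test_noiseless_local_marker_gives_flat_residuals(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(8.0, (12, 12)).astype(float)
        iron = heatmap_from_counts(counts)
        marker = heatmap_from_counts(2.0 * counts, stain="GFAP")
        table, skipped = compare_ring_models([(iron, marker)], max_rings=3)
        assert not skipped
        assert np.allclose(table["residual"], table["residual"].iloc[0])
        assert (table.loc[table.n_rings == 3, ["c1", "c2", "c3"]].to_numpy() == 0).all()

    def test_error_is_nonincreasing_in_ring_count(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            iron = heatmap_from_counts(rng.poisson(6.0, (12, 12)))
            marker = heatmap_from_counts(rng.poisson(6.0, (12, 12)), stain="GFAP")
            table, _ = compare_ring_models([(iron, marker)], max_rings=3)
            errs = table.sort_values("n_rings")["error"].to_numpy()
            assert np.all(np.diff(errs) <= 1e-12)

    def test_skipped_sections_are_reported(self):
        iron = heatmap_from_counts(np.zeros((6, 6)))
        marker = heatmap_from_counts(np.ones((6, 6)), stain="GFAP")
        table, skipped = compare_ring_models([(iron, marker)], max_rings=1)
        assert len(table) == 0 and len(skipped) == 1
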