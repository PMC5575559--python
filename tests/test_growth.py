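import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carrierscope import (
    CarrierAnalysis,
    DetectedCircle,
    build_growth_profile,
    colonization_histogram,
    convergence_index,
    running_mean,
)


def _analysis(corrected):
    return CarrierAnalysis(
        circle=DetectedCircle(0.0, 0.0, 60.0, 1.0),
        confluence_pct=None,
        cells_visible=corrected // 2,
        cells_corrected=corrected,
    )


class TestRunningMean:
    def test_simple_sequence(self):
        assert np.allclose(running_mean([10, 20, 30]), [10, 15, 20])

    def test_constant_sequence(self):
        assert np.allclose(running_mean([7.0] * 5), [7.0] * 5)

    def test_final_element_is_overall_mean(self, rng):
        counts = rng.integers(0, 60, 40)
        assert running_mean(counts)[-1] == pytest.approx(counts.mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            running_mean([])


def convergence_oracle(means, tol):
    """Direct scan: smallest 1-based k with all later means in band."""
    means = np.asarray(means, float)
    final = means[-1]
    band = abs(final) * tol if final != 0 else tol
    for k in range(1, means.size + 1):
        if np.all(np.abs(means[k - 1:] - final) <= band):
            return k
    return means.size


class TestConvergenceIndex:
    def test_constant_sequence_converges_immediately(self):
        assert convergence_index([5.0, 5.0, 5.0], 0.05) == 1

    def test_cold_start_sequence(self):
        means = running_mean([0, 20] + [10] * 10)
        # direct-scan oracle: the 2-element partial mean already equals
        # the final mean, so k = 2
        assert convergence_oracle(means, 0.05) == 2
        assert convergence_index(means, 0.05) == 2

    def test_never_converging_returns_length(self):
        means = [0.0, 100.0, 0.0, 100.0, 50.0]
        assert convergence_index(means, 0.01) == convergence_oracle(means, 0.01)

    def test_zero_final_mean_uses_absolute_band(self):
        means = [1.0, 0.02, 0.0]
        assert convergence_index(means, 0.05) == convergence_oracle(means, 0.05)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_direct_scan_oracle(self, seed):
        r = np.random.default_rng(seed)
        means = running_mean(r.integers(0, 50, int(r.integers(2, 40))) + 1)
        for tol in (0.02, 0.05, 0.2):
            assert convergence_index(means, tol) == convergence_oracle(means, tol)

    def test_tolerance_monotonicity(self, rng):
        means = running_mean(rng.poisson(30, 60))
        ks = [convergence_index(means, t) for t in (0.02, 0.05, 0.1, 0.3)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_plausible_convergence_for_poisson_counts(self):
        # analogue of needing a few tens of carriers for a stable count
        ks = []
        for rep in range(100):
            counts = np.random.default_rng(5000 + rep).poisson(30, 100)
            ks.append(convergence_index(running_mean(counts), 0.05))
        assert 10 <= np.median(ks) <= 60

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            convergence_index([1.0], 0.05)
        with pytest.raises(ValueError):
            convergence_index([1.0, 2.0], 0.0)


class TestColonizationHistogram:
    def test_identical_counts_single_full_bin(self):
        h = colonization_histogram([12] * 8, bin_width=5)
        assert h.normalized_frequency.max() == 1.0
        assert (h.normalized_frequency == 1.0).sum() == 1

    def test_direct_tally_example(self):
        counts = [0] * 5 + [12] * 10 + [25] * 5
        h = colonization_histogram(counts, bin_width=10)
        assert np.allclose(h.normalized_frequency, [0.5, 1.0, 0.5])
        assert np.allclose(h.bin_edges, [0, 10, 20, 30])

    def test_normalization_bounds(self, rng):
        h = colonization_histogram(rng.integers(0, 80, 200), bin_width=5)
        assert h.normalized_frequency.min() >= 0.0
        assert h.normalized_frequency.max() == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            colonization_histogram([])
        with pytest.raises(ValueError):
            colonization_histogram([1, 2], bin_width=0)


class TestBuildGrowthProfile:
    def test_single_day_mean_and_density(self):
        pts = build_growth_profile({2: [_analysis(10), _analysis(20)]},
                                   carriers_per_ml=1000.0)
        (p,) = pts
        assert p.mean_cells_per_carrier == pytest.approx(15.0)
        assert p.cell_density_per_ml == pytest.approx(1.5e4)
        assert p.n_carriers_analyzed == 2

    def test_days_sorted_ascending(self):
        pts = build_growth_profile({6: [_analysis(8)], 2: [_analysis(4)]})
        assert [p.culture_day for p in pts] == [2, 6]

    def test_missing_concentration_omits_density(self):
        (p,) = build_growth_profile({1: [_analysis(6)]})
        assert p.cell_density_per_ml is None
        assert p.mean_cells_per_carrier == pytest.approx(6.0)

    def test_matches_brute_force_recomputation(self, rng):
        per_day = {
            int(day): [_analysis(int(2 * v))
                       for v in rng.integers(0, 40, 30)]
            for day in (2, 4, 6, 8)
        }
        pts = build_growth_profile(per_day, carriers_per_ml=750.0)
        for p in pts:
            raw = [a.cells_corrected for a in per_day[p.culture_day]]
            assert p.mean_cells_per_carrier == pytest.approx(
                sum(raw) / len(raw))
            assert p.cell_density_per_ml == pytest.approx(
                750.0 * sum(raw) / len(raw))

    def test_empty_days_skipped(self):
        pts = build_growth_profile({2: [_analysis(4)], 4: []})
        assert [p.culture_day for p in pts] == [2]
        with pytest.raises(ValueError):
            build_growth_profile({2: []})
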