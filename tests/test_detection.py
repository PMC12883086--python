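"""Unit and property tests for the per-probe peak detector."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betamodes import DetectionParams, classify_probe, estimate_density
from betamodes.detection import (
    DegenerateInputError,
    DensityCurve,
    Peak,
    TooFewObservationsError,
    assign_candidate_peaks,
    filter_noise_peaks,
    find_stationary_points,
    merge_close_peaks,
    refilter_merged_peaks,
    rule_of_thumb_bandwidth,
)
from betamodes.simulate import ProbeSpec, probe_seed, simulate_probe

from conftest import brute_force_stationary_points, random_bump_curve


def nrd0_reference(x):
    # Independent evaluation of the rule-of-thumb formula.
    sd = np.std(x, ddof=1)
    iqr = np.percentile(x, 75) - np.percentile(x, 25)
    lo = min(sd, iqr / 1.34) or sd
    return 0.9 * lo * len(x) ** (-1 / 5)


def curve_from(density):
    density = np.asarray(density, dtype=float)
    grid = np.linspace(0.0, 1.0, density.size)
    return DensityCurve(grid=grid, density=density, bandwidth=0.05, n_obs=100)


# ---------------------------------------------------------------------------
# bandwidth


class TestBandwidth:
    def test_worked_four_point_example(self):
        bw = rule_of_thumb_bandwidth(np.array([0.2, 0.4, 0.6, 0.8]))
        # 0.9 * min(0.2582, 0.3/1.34) * 4^(-1/5)
        assert bw == pytest.approx(0.1527, abs=5e-4)
        assert bw == pytest.approx(nrd0_reference([0.2, 0.4, 0.6, 0.8]), abs=1e-15)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_closed_form_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.0, 1.0, int(rng.integers(10, 500)))
        assert rule_of_thumb_bandwidth(x) == pytest.approx(nrd0_reference(x), abs=1e-12)

    def test_zero_iqr_falls_back_to_sd(self):
        # 80% of the mass on one value: IQR is 0 but SD is not.
        x = np.array([0.5] * 16 + [0.2, 0.3, 0.7, 0.8])
        sd = np.std(x, ddof=1)
        assert rule_of_thumb_bandwidth(x) == pytest.approx(0.9 * sd * 20 ** (-0.2))


# ---------------------------------------------------------------------------
# density estimation


class TestEstimateDensity:
    def test_constant_input_is_degenerate(self, default_params):
        with pytest.raises(DegenerateInputError):
            estimate_density(np.full(100, 0.5), default_params)

    def test_too_few_observations(self, default_params):
        with pytest.raises(TooFewObservationsError):
            estimate_density(np.linspace(0.1, 0.9, 9), default_params)

    def test_missing_values_dropped_and_counted(self, default_params):
        x = np.linspace(0.1, 0.9, 30)
        x[::3] = np.nan
        curve = estimate_density(x, default_params)
        assert curve.n_obs == 20

    def test_curve_contract(self, default_params):
        rng = np.random.default_rng(3)
        x = rng.beta(2.0, 5.0, 200)
        curve = estimate_density(x, default_params)
        assert curve.grid.size == curve.density.size == default_params.grid_size
        assert np.all(curve.density >= 0.0)
        spacing = np.diff(curve.grid)
        assert np.allclose(spacing, spacing[0])
        assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=0.02)
        assert curve.grid[0] == pytest.approx(x.min() - 3 * curve.bandwidth)
        assert curve.grid[-1] == pytest.approx(x.max() + 3 * curve.bandwidth)

    def test_matches_scipy_gaussian_kde(self, default_params):
        scipy_stats = pytest.importorskip("scipy.stats")
        rng = np.random.default_rng(7)
        x = rng.beta(3.0, 3.0, 150)
        curve = estimate_density(x, default_params)
        kde = scipy_stats.gaussian_kde(
            x, bw_method=curve.bandwidth / np.std(x, ddof=1)
        )
        np.testing.assert_allclose(curve.density, kde(curve.grid), atol=1e-10)

    def test_matches_r_density_reference(self, default_params, tmp_path):
        # The canonical contract: base R's density() with bw="nrd0",
        # n=512, cut=3.  R bins data and convolves by FFT, so the density
        # agrees only to the binning error; bandwidth and grid are exact.
        rng = np.random.default_rng(11)
        x = rng.beta(5.0, 2.0, 60)
        data = tmp_path / "x.txt"
        out = tmp_path / "d.csv"
        np.savetxt(data, x, fmt="%.17g")
        script = (
            f'x <- scan("{data}"); d <- density(x, bw="nrd0", n=512, cut=3); '
            f'write.csv(data.frame(x=d$x, y=d$y, bw=d$bw), "{out}", row.names=FALSE)'
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)
        curve = estimate_density(x, default_params)
        assert curve.bandwidth == pytest.approx(float(ref["bw"][0]), abs=1e-12)
        np.testing.assert_allclose(curve.grid, ref["x"], atol=1e-9)
        np.testing.assert_allclose(
            curve.density, ref["y"], atol=5e-3 * curve.density.max()
        )

    def test_fixed_bandwidth(self):
        params = DetectionParams(bandwidth_rule="fixed", fixed_bandwidth=0.02)
        curve = estimate_density(np.linspace(0.2, 0.8, 50), params)
        assert curve.bandwidth == 0.02


# ---------------------------------------------------------------------------
# stationary points


class TestStationaryPoints:
    @pytest.mark.parametrize(
        "density, exp_max, exp_min",
        [
            ([0, 1, 0], [1], []),
            ([0, 2, 1, 3, 0], [1, 3], [2]),
            ([0, 1, 1, 0], [1], []),  # flat top: first plateau index
            ([1, 0, 1], [], [1]),
            ([0, 1, 0, 2, 0, 1, 0], [1, 3, 5], [2, 4]),
        ],
    )
    def test_switch_rule_examples(self, density, exp_max, exp_min):
        maxima, minima = find_stationary_points(curve_from(density))
        assert maxima.tolist() == exp_max
        assert minima.tolist() == exp_min

    def test_matches_brute_force_oracle_on_random_curves(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            density = random_bump_curve(rng)
            maxima, minima = find_stationary_points(curve_from(density))
            ref_max, ref_min = brute_force_stationary_points(density)
            np.testing.assert_array_equal(maxima, ref_max)
            np.testing.assert_array_equal(minima, ref_min)

    def test_maxima_and_minima_interleave(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            density = random_bump_curve(rng)
            maxima, minima = find_stationary_points(curve_from(density))
            merged = sorted(
                [(m, "max") for m in maxima] + [(m, "min") for m in minima]
            )
            kinds = [k for _, k in merged]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))


# ---------------------------------------------------------------------------
# candidate peaks


class TestCandidatePeaks:
    def test_single_maximum_captures_everything(self, default_params):
        rng = np.random.default_rng(9)
        x = rng.beta(50.0, 50.0, 200)
        curve = estimate_density(x, default_params)
        maxima, minima = find_stationary_points(curve)
        peaks = assign_candidate_peaks(curve, maxima, minima, x)
        if len(peaks) == 1:
            assert peaks[0].proportion == 1.0
            assert peaks[0].left_bound == -np.inf
            assert peaks[0].right_bound == np.inf

    # Smooth two-peak curve on an 11-point grid over [0, 1]: maxima at
    # grid 0.2 and 0.7, the single interior minimum at grid 0.4.
    TWO_PEAK = [0.1, 0.5, 1.0, 0.6, 0.2, 0.4, 0.7, 1.0, 0.6, 0.3, 0.1]

    def test_balanced_split_at_interior_minimum(self):
        # Minimum at 0.4 separates two maxima; betas split 5 below /
        # 5 at-or-above the boundary.
        curve = curve_from(self.TWO_PEAK)
        maxima, minima = find_stationary_points(curve)
        betas = np.array([0.1, 0.15, 0.2, 0.3, 0.39, 0.4, 0.5, 0.6, 0.7, 0.8])
        peaks = assign_candidate_peaks(curve, maxima, minima, betas)
        assert [p.proportion for p in peaks] == [0.5, 0.5]

    def test_boundary_tie_goes_right(self):
        curve = curve_from(self.TWO_PEAK)
        maxima, minima = find_stationary_points(curve)
        betas = np.array([0.4] * 10)  # exactly on the boundary
        peaks = assign_candidate_peaks(curve, maxima, minima, betas)
        assert peaks[0].proportion == 0.0
        assert peaks[1].proportion == 1.0

    def test_conservation_before_filtering(self, fixture_matrix, default_params):
        # Candidate proportions partition the cohort: they sum to one on
        # every fixture probe, exactly.
        for values in fixture_matrix.values[:25]:
            curve = estimate_density(values, default_params)
            maxima, minima = find_stationary_points(curve)
            peaks = assign_candidate_peaks(curve, maxima, minima, values)
            assert sum(p.proportion for p in peaks) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# filtering and merging


def make_peak(apex, prop, left=0.0, right=1.0, left_d=1.0, right_d=1.0, apex_d=1.0):
    return Peak(
        apex_beta=apex,
        apex_density=apex_d,
        left_bound=left,
        right_bound=right,
        proportion=prop,
        variance=0.0,
        left_density=left_d,
        right_density=right_d,
    )


class TestNoiseFilter:
    def setup_method(self):
        self.curve = curve_from(np.ones(16))
        self.params = DetectionParams(zero_density_tol=1e-6)

    def test_small_and_zero_bounded_is_discarded(self):
        p = make_peak(0.5, 0.005, right_d=0.0)
        assert filter_noise_peaks([p], self.curve, self.params) == []

    def test_small_but_well_bounded_is_retained(self):
        p = make_peak(0.5, 0.005, left_d=0.4, right_d=0.4)
        assert filter_noise_peaks([p], self.curve, self.params) == [p]

    def test_large_with_zero_bound_is_retained(self):
        p = make_peak(0.5, 0.02, left_d=0.0)
        assert filter_noise_peaks([p], self.curve, self.params) == [p]

    def test_relative_zero_tolerance_resolves_per_curve(self, default_params):
        curve = curve_from(np.full(16, 8.0))
        assert curve.zero_tolerance(default_params) == pytest.approx(8e-4)


class TestMergeAndRefilter:
    def test_close_apexes_merge(self, default_params):
        betas = np.linspace(0.2, 0.5, 100)
        peaks = [
            make_peak(0.30, 0.5, left=0.0, right=0.33, apex_d=1.0),
            make_peak(0.35, 0.5, left=0.33, right=1.0, apex_d=2.0),
        ]
        merged = merge_close_peaks(peaks, default_params, betas)
        assert len(merged) == 1
        assert merged[0].apex_beta == 0.35  # highest-density member wins
        assert merged[0].merged_from == 2
        assert merged[0].left_bound == 0.0
        assert merged[0].right_bound == 1.0
        assert merged[0].proportion == 1.0

    def test_distant_apexes_do_not_merge(self, default_params):
        peaks = [
            make_peak(0.20, 0.5, right=0.35),
            make_peak(0.50, 0.5, left=0.35),
        ]
        merged = merge_close_peaks(peaks, default_params, np.linspace(0, 1, 50))
        assert merged == peaks

    def test_transitive_chain_merges_into_one(self, default_params):
        peaks = [
            make_peak(0.30, 0.3, left=0.0, right=0.34),
            make_peak(0.38, 0.3, left=0.34, right=0.42),
            make_peak(0.46, 0.3, left=0.42, right=1.0),
        ]
        merged = merge_close_peaks(peaks, default_params, np.linspace(0.2, 0.6, 60))
        assert len(merged) == 1
        assert merged[0].merged_from == 3

    def test_exact_peak_distance_does_not_merge(self, default_params):
        peaks = [
            make_peak(0.30, 0.5, right=0.35),
            make_peak(0.40, 0.5, left=0.35),
        ]
        assert len(merge_close_peaks(peaks, default_params, np.linspace(0, 1, 50))) == 2

    def test_refilter_is_strict(self, default_params):
        peaks = [make_peak(0.3, 0.008), make_peak(0.6, 0.01), make_peak(0.9, 0.5)]
        kept = refilter_merged_peaks(peaks, default_params)
        assert [p.apex_beta for p in kept] == [0.6, 0.9]

    def test_refilter_monotone_in_proportion_sample(self):
        peaks = [make_peak(0.2, 0.005), make_peak(0.5, 0.03), make_peak(0.8, 0.96)]
        survivors = [
            len(refilter_merged_peaks(peaks, DetectionParams(proportion_sample=ps)))
            for ps in (0.001, 0.01, 0.05, 0.5)
        ]
        assert survivors == sorted(survivors, reverse=True)


# ---------------------------------------------------------------------------
# classification


class TestClassifyProbe:
    def test_unimodal_simulation(self, default_params):
        spec = ProbeSpec.unimodal("u", mean=0.5)
        betas = simulate_probe(spec, 1000, seed=101)
        call = classify_probe(betas, default_params)
        assert call.label == "unimodal"
        assert call.n_peaks == 1
        assert abs(call.peaks[0].apex_beta - 0.5) < 0.05

    def test_snp_trimodal_simulation(self, default_params):
        spec = ProbeSpec.snp_trimodal("t", maf=0.3)
        betas = simulate_probe(spec, 1000, seed=202)
        call = classify_probe(betas, default_params)
        assert call.label == "multimodal"
        assert call.n_peaks == 3
        apices = [p.apex_beta for p in call.peaks]
        np.testing.assert_allclose(apices, [0.05, 0.50, 0.95], atol=0.05)
        # HWE expectations for MAF 0.3
        props = np.array([p.proportion for p in call.peaks])
        w = np.array([0.49, 0.42, 0.09])
        se = np.sqrt(w * (1 - w) / 1000)
        assert np.all(np.abs(props - w) <= 3 * se)

    def test_close_modes_merge_to_unimodal(self, default_params):
        # Two tight clusters 0.06 apart: candidate apexes fall within
        # peak_distance and are merged into one mode.
        rng = np.random.default_rng(33)
        betas = np.concatenate(
            [rng.normal(0.42, 0.015, 500), rng.normal(0.48, 0.015, 500)]
        )
        betas = np.clip(betas, 0.0, 1.0)
        call = classify_probe(betas, default_params)
        assert call.label == "unimodal"

    def test_peaks_sorted_with_disjoint_boundaries(self, default_params):
        spec = ProbeSpec.snp_trimodal("t", maf=0.4)
        betas = simulate_probe(spec, 800, seed=5)
        call = classify_probe(betas, default_params)
        apices = [p.apex_beta for p in call.peaks]
        assert apices == sorted(apices)
        for left, right in zip(call.peaks, call.peaks[1:]):
            assert left.right_bound <= right.left_bound
            assert left.left_bound < left.apex_beta < left.right_bound

    def test_deterministic(self, default_params):
        betas = simulate_probe(ProbeSpec.snp_trimodal("t", maf=0.2), 600, seed=8)
        first = classify_probe(betas, default_params)
        second = classify_probe(betas.copy(), default_params)
        assert first == second

    def test_all_filtered_falls_back_to_unimodal(self):
        # An aggressive proportion floor removes every merged peak; the
        # largest candidate is restored and the probe flagged.
        betas = simulate_probe(ProbeSpec.snp_trimodal("t", maf=0.45), 500, seed=3)
        call = classify_probe(betas, DetectionParams(proportion_sample=0.8))
        assert call.label == "unimodal"
        assert call.fallback
        assert call.n_peaks == 1

    def test_error_propagation(self, default_params):
        with pytest.raises(TooFewObservationsError):
            classify_probe(np.array([0.1, 0.2]), default_params)
        with pytest.raises(DegenerateInputError):
            classify_probe(np.full(50, 0.7), default_params)
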