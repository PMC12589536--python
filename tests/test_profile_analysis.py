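import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comsli import (
    AngularStack,
    PeakSet,
    PhantomSpec,
    ProfileParams,
    Region,
    analyze_stack,
    detect_peaks,
    fourier_lowpass,
    generate_phantom,
    orientations_from_pairs,
    pair_peaks,
    single_fiber_spec,
)
from conftest import circular_diff


def make_profile(thetas, n=24, width=15.0, baseline=1.0, amps=None):
    """Noise-free azimuthal profile with lobe pairs perpendicular to thetas."""
    from comsli.phantom import _region_profile

    amps = amps or [1.0] * len(thetas)
    angles = np.arange(n) * 360.0 / n
    return baseline + _region_profile(list(zip(thetas, amps)), angles, width)


class TestFourierLowpass:
    def test_constant_profile_unchanged(self, params):
        p = np.full(24, 3.3)
        np.testing.assert_allclose(fourier_lowpass(p, params), p, atol=1e-12)

    def test_low_harmonic_passes(self, params):
        phi = np.deg2rad(np.arange(24) * 15.0)
        p = np.cos(2 * phi)
        np.testing.assert_allclose(fourier_lowpass(p, params), p, atol=1e-9)

    def test_high_harmonic_suppressed(self, params):
        phi = np.deg2rad(np.arange(24) * 15.0)
        p = np.cos(2 * phi) + 0.5 * np.cos(10 * phi)
        out = fourier_lowpass(p, params)
        # harmonic 10 lies above the roll-off (cutoff 4.8 + half-window 1.35)
        np.testing.assert_allclose(out, np.cos(2 * phi), atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_mean_preserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 10, 24)
        out = fourier_lowpass(p, ProfileParams())
        assert abs(out.mean() - p.mean()) < 1e-9

    def test_noop_when_cutoff_full(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 10, 24)
        out = fourier_lowpass(
            p, ProfileParams(fourier_cutoff_fraction=1.0, fourier_window_width=0.0)
        )
        np.testing.assert_allclose(out, p, atol=1e-9)


class TestDetectPeaks:
    def test_flat_profile_no_peaks(self, params):
        assert len(detect_peaks(np.ones(24), params)) == 0

    def test_single_fiber_peak_pair_positions(self, params):
        p = make_profile([40.0])
        peaks = detect_peaks(p, params)
        assert len(peaks) == 2
        np.testing.assert_allclose(peaks.positions_deg, [130.0, 310.0], atol=0.5)

    def test_prominence_threshold_boundary(self):
        # bump of prominence 0.05 x range: rejected at 0.08, kept at 0.04
        p = make_profile([0.0], baseline=0.0)
        rng_val = p.max() - p.min()
        bump_center = 0.0  # in the flat region between the main lobes at 90/270
        angles = np.arange(24) * 15.0
        d = (angles - bump_center + 180) % 360 - 180
        bump = 0.05 * rng_val * np.exp(-(d**2) / (2 * 8.0**2))
        p2 = p + bump
        n_default = len(detect_peaks(p2, ProfileParams(prominence_fraction=0.08)))
        n_loose = len(detect_peaks(p2, ProfileParams(prominence_fraction=0.04)))
        assert n_loose == n_default + 1

    def test_wraparound_peak_counted_once(self, params):
        p = make_profile([90.0])  # lobes at 0/180: one peak wraps the origin
        peaks = detect_peaks(p, params)
        assert len(peaks) == 2
        np.testing.assert_allclose(np.sort(peaks.positions_deg), [0.0, 180.0], atol=0.5)


def brute_force_pairs(peaks: PeakSet, params: ProfileParams):
    """Exhaustive oracle for the greedy pairing rule.

    Enumerates every set of disjoint admissible pairs (up to
    max_populations) and returns the one whose pair-priority rank tuple
    is lexicographically smallest, longer sets breaking prefix ties.
    """
    pos, prom = peaks.positions_deg, peaks.prominences
    n = len(pos)
    admissible = []
    for i, j in itertools.combinations(range(n), 2):
        sep = (pos[j] - pos[i]) % 360.0
        if abs(sep - 180.0) <= params.pairing_tolerance_deg:
            admissible.append((i, j))
    ranked = sorted(
        range(len(admissible)),
        key=lambda k: (
            -(prom[admissible[k][0]] + prom[admissible[k][1]]),
            min(pos[admissible[k][0]], pos[admissible[k][1]]),
            max(pos[admissible[k][0]], pos[admissible[k][1]]),
        ),
    )
    rank_of = {admissible[k]: r for r, k in enumerate(ranked)}
    best_key, best = (), []
    for size in range(0, min(params.max_populations, n // 2) + 1):
        for combo in itertools.combinations(admissible, size):
            used = [i for p in combo for i in p]
            if len(set(used)) != len(used):
                continue
            key = tuple(sorted(rank_of[p] for p in combo)) + (float("inf"),) * (
                params.max_populations - size
            )
            if not best or key < best_key:
                best_key, best = key, list(combo)
    best.sort(key=lambda p: rank_of[p])
    return [
        (float(pos[i]), float(pos[j]), float(prom[i] + prom[j])) for i, j in best
    ]


class TestPairPeaks:
    def test_exact_pair(self, params):
        peaks = PeakSet(np.array([130.0, 310.0]), np.array([1.0, 1.0]))
        pairs = pair_peaks(peaks, params)
        assert pairs == [(130.0, 310.0, 2.0)]

    def test_three_pairs(self, params):
        pos = np.array([30.0, 90.0, 150.0, 210.0, 270.0, 330.0])
        peaks = PeakSet(pos, np.ones(6))
        pairs = pair_peaks(peaks, params)
        assert sorted((a, b) for a, b, _ in pairs) == [
            (30.0, 210.0),
            (90.0, 270.0),
            (150.0, 330.0),
        ]

    def test_unpaired_peak_discarded(self, params):
        peaks = PeakSet(np.array([10.0, 100.0, 190.0]), np.array([1.0, 0.9, 0.8]))
        pairs = pair_peaks(peaks, params)
        assert [(a, b) for a, b, _ in pairs] == [(10.0, 190.0)]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed, params):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 9))
        pos = np.sort(rng.uniform(0, 360, n))
        prom = rng.uniform(0.1, 1.0, n)
        peaks = PeakSet(pos, prom)
        assert pair_peaks(peaks, params) == brute_force_pairs(peaks, params)

    def test_max_populations_cap(self):
        pos = np.array([10.0, 55.0, 100.0, 145.0, 190.0, 235.0, 280.0, 325.0])
        peaks = PeakSet(pos, np.ones(8))
        pairs = pair_peaks(peaks, ProfileParams(max_populations=3))
        assert len(pairs) <= 3


class TestOrientationsFromPairs:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            ((130.0, 310.0), 40.0),
            ((350.0, 170.0), 80.0),
            ((0.0, 180.0), 90.0),
        ],
    )
    def test_midline(self, pair, expected):
        [theta] = orientations_from_pairs([(pair[0], pair[1], 1.0)])
        assert circular_diff(theta, expected) < 1e-9

    @given(
        st.floats(0, 360, allow_nan=False),
        st.floats(-30, 30, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_in_range_and_perpendicular(self, a, delta):
        b = (a + 180.0 + delta) % 360.0
        [theta] = orientations_from_pairs([(a, b, 1.0)])
        assert 0 <= theta < 180
        # midline sits 90 deg (+/- delta/2) from either peak, mod 180
        assert circular_diff(theta, (a + 90.0 + delta / 2.0) % 180.0) < 1e-9


class TestAnalyzeStack:
    def test_uniform_single_fiber(self, single_fiber_stack):
        stack, truth = single_fiber_stack
        field = analyze_stack(stack)
        assert np.all(field.n_populations == 1)
        errs = circular_diff(field.orientations_deg[:, :, 0], 30.0)
        assert errs.max() <= 7.5  # half the 15-deg azimuthal step

    def test_two_population_pixel(self, crossing_stack):
        stack, truth = crossing_stack
        field = analyze_stack(stack)
        assert np.all(field.n_populations == 2)
        got = np.sort(field.orientations_deg[5, 5, :2]) % 180
        assert circular_diff(got[0], 0.0) < 1.0
        assert circular_diff(got[1], 90.0) < 1.0

    def test_all_zero_stack_fully_masked(self):
        stack = AngularStack(np.zeros((6, 6, 24)), np.arange(24) * 15.0)
        field = analyze_stack(stack)
        assert not field.mask.any()
        assert np.all(field.n_populations == 0)

    def test_rotational_equivariance_on_grid(self):
        """Shifting all fiber angles by a grid step shifts output angles."""
        delta = 15.0
        spec_a = single_fiber_spec(shape=(6, 6), theta=40.0)
        spec_b = single_fiber_spec(shape=(6, 6), theta=40.0 + delta)
        fa = analyze_stack(generate_phantom(spec_a)[0])
        fb = analyze_stack(generate_phantom(spec_b)[0])
        shift = circular_diff(
            fb.orientations_deg[:, :, 0], fa.orientations_deg[:, :, 0]
        )
        np.testing.assert_allclose(shift, delta, atol=1.0)

    def test_azimuth_reversal_mirrors_orientations(self):
        spec = single_fiber_spec(shape=(6, 6), theta=40.0)
        stack, _ = generate_phantom(spec)
        reversed_data = stack.data[:, :, ::-1].copy()
        reversed_data = np.roll(reversed_data, 1, axis=-1)  # keep phi=0 first
        rstack = AngularStack(reversed_data, stack.angles.copy())
        fa = analyze_stack(stack)
        fb = analyze_stack(rstack)
        expected = (180.0 - fa.orientations_deg[:, :, 0]) % 180.0
        assert np.all(circular_diff(fb.orientations_deg[:, :, 0], expected) < 1e-6)

    def test_population_count_matches_truth_multi_region(self):
        rng_mask = np.zeros((9, 9), dtype=bool)
        masks = []
        for i, sl in enumerate([slice(0, 3), slice(3, 6), slice(6, 9)]):
            m = rng_mask.copy()
            m[sl] = True
            masks.append(m)
        spec = PhantomSpec(
            shape=(9, 9),
            regions=[
                Region(masks[0], [(10.0, 1.0)]),
                Region(masks[1], [(10.0, 1.0), (100.0, 0.8)]),
                Region(masks[2], [(10.0, 1.0), (70.0, 0.9), (130.0, 0.8)]),
            ],
        )
        stack, truth = generate_phantom(spec)
        field = analyze_stack(stack)
        np.testing.assert_array_equal(field.n_populations, truth.n_populations)

    def test_background_quantile_masks_dim_pixels(self):
        spec = single_fiber_spec(shape=(8, 8), theta=30.0)
        stack, _ = generate_phantom(spec)
        stack.data[:4] *= 0.01  # dim half the image
        field = analyze_stack(stack, ProfileParams(background_quantile=0.5))
        assert not field.mask[:4].any()
        assert field.mask[4:].all()
        assert np.all(field.n_populations[:4] == 0)
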