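"""The four-part identification criterion and the subtraction engine."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iondecon import (ChromRun, DataValidationError, MatchCriteria,
                      NoiseModel, PeakRegion, PlantedCompound, Scan,
                      SimConfig, Spectrum, TargetCompound, TargetLibrary,
                      UndefinedReductionError, average_spectrum, cosine,
                      deconvolve_peak, deconvolve_run, delta_i, detect_peaks,
                      evaluate_target, q_ratio_deviation, q_value,
                      random_spectrum, reduced_intensities,
                      residual_is_background, select_invariant_scans,
                      simulate_run, ssv, subtract_component)
from iondecon.deconvolution import scan_distance_matrix


def make_target(ratios, main=93):
    """Target with main ion and qualifiers at the given expected ratios."""
    peaks = {main: 1000.0}
    mz = 100
    for r in ratios:
        peaks[mz] = 1000.0 * r
        mz += 10
    return TargetCompound.from_spectrum("t", 1.0, Spectrum(peaks),
                                        n_qualifiers=len(ratios))


class TestReducedIntensities:
    def test_perfect_ratio_gives_one(self):
        t = make_target([0.5, 0.25])
        scan = Scan(1.0, Spectrum({93: 10000.0, 100: 5000.0, 110: 2500.0}))
        assert reduced_intensities(scan, t) == pytest.approx([1.0, 1.0])

    def test_direct_evaluation(self):
        t = make_target([0.5, 0.25])
        scan = Scan(1.0, Spectrum({93: 10000.0, 100: 4000.0, 110: 2500.0}))
        assert reduced_intensities(scan, t) == pytest.approx([0.8, 1.0])

    def test_zero_main_ion_raises(self):
        t = make_target([0.5, 0.25])
        with pytest.raises(UndefinedReductionError):
            reduced_intensities(Scan(1.0, Spectrum({100: 4000.0})), t)


class TestDeltaI:
    @pytest.mark.parametrize("reduced,expected", [
        ((1.0, 1.0, 1.0), 0.0),
        ((1.0, 0.8, 1.2), (0.2 + 0.2 + 0.4) / 3),
        ((0.9, 1.1), 0.2),
    ])
    def test_hand_computed_values(self, reduced, expected):
        assert delta_i(np.array(reduced)) == pytest.approx(expected)

    def test_single_value_rejected(self):
        with pytest.raises(DataValidationError):
            delta_i(np.array([1.0]))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, values, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert delta_i(np.array(shuffled)) == pytest.approx(
            delta_i(np.array(values)))


class TestSSV:
    def test_zero_deviation_gives_zero(self):
        assert ssv(0.0, 12345.0) == 0.0

    def test_log10_weighting(self):
        assert ssv(0.5, 1e4) == pytest.approx(2.0)

    def test_exceeds_ceiling(self):
        assert ssv(2.0, 1e4) == pytest.approx(8.0)
        assert ssv(2.0, 1e4) > MatchCriteria().delta_e_max

    def test_nonpositive_abundance_rejected(self):
        with pytest.raises(DataValidationError):
            ssv(0.5, 0.0)


def scans_with_ratio_factor(t, factor, n=5, a_main=10000.0):
    """n scans whose observed qualifier ratios are factor x expected."""
    scans = []
    for i in range(n):
        peaks = {t.main_ion: a_main}
        for mz, ri in t.qualifiers:
            peaks[mz] = a_main * ri * factor
        scans.append(Scan(0.1 * (i + 1), Spectrum(peaks)))
    return scans


class TestQValue:
    def test_perfect_match_is_100(self):
        t = make_target([0.5, 0.25])
        assert q_value(t, scans_with_ratio_factor(t, 1.0)) == pytest.approx(100.0)

    def test_ten_percent_offset_gives_90(self):
        t = make_target([0.5, 0.25])
        assert q_value(t, scans_with_ratio_factor(t, 1.1)) == pytest.approx(90.0)

    def test_doubled_ratios_clamp_to_zero(self):
        t = make_target([0.5, 0.25])
        assert q_value(t, scans_with_ratio_factor(t, 2.0)) == pytest.approx(0.0)

    def test_no_usable_scan_raises(self):
        t = make_target([0.5, 0.25])
        with pytest.raises(UndefinedReductionError):
            q_value(t, [Scan(0.1, Spectrum({100: 5.0}))])


class TestQRatio:
    def test_perfect_ratios_give_zero(self):
        t = make_target([0.5, 0.25])
        assert q_ratio_deviation(t, scans_with_ratio_factor(t, 1.0)) == \
            pytest.approx(0.0)

    @pytest.mark.parametrize("factor,expected,passes", [
        (1.3, 0.30, False),
        (1.15, 0.15, True),
    ])
    def test_tolerance_boundary(self, factor, expected, passes):
        t = make_target([0.5, 0.25])
        dev = q_ratio_deviation(t, scans_with_ratio_factor(t, factor))
        assert dev == pytest.approx(expected)
        assert (dev <= MatchCriteria().q_ratio_tol) is passes


class TestScalingInvariance:
    """Multiplying all intensities by c leaves ratios alone, shifts dE."""

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_invariants_and_de_shift(self, c):
        t = make_target([0.5, 0.25, 0.1])
        base = scans_with_ratio_factor(t, 1.08, n=6)
        scaled = [Scan(s.time, s.spectrum.scaled(c)) for s in base]
        r0 = reduced_intensities(base[0], t)
        r1 = reduced_intensities(scaled[0], t)
        assert r1 == pytest.approx(r0)
        assert q_value(t, scaled) == pytest.approx(q_value(t, base))
        assert q_ratio_deviation(t, scaled) == pytest.approx(
            q_ratio_deviation(t, base))
        di = delta_i(r0)
        a0 = base[0].spectrum.get(t.main_ion)
        assert ssv(di, c * a0) - ssv(di, a0) == pytest.approx(
            di * np.log10(c))


def brute_force_verdict(run, target, criteria):
    """Straight-line re-implementation of the four-part criterion.

    Enumerates every window of consecutive scans, checks each criterion
    with direct loops, and reports whether any window passes.
    """
    scans = run.scans
    best = None
    for lo in range(len(scans)):
        for hi in range(lo, len(scans)):
            window = scans[lo:hi + 1]
            ok = True
            des = []
            for s in window:
                a_main = s.spectrum.get(target.main_ion)
                if a_main <= 0:
                    ok = False
                    break
                red = [s.spectrum.get(mz) / (ri * a_main)
                       for mz, ri in target.qualifiers]
                if any(abs(r - 1.0) > criteria.max_ion_deviation for r in red):
                    ok = False
                    break
                pair_sum = sum(abs(a - b) for a, b in
                               itertools.combinations(red, 2))
                di = pair_sum / (len(red) * (len(red) - 1) / 2)
                if di > criteria.k + criteria.delta0 / a_main:
                    ok = False
                    break
                des.append(di * np.log10(a_main))
            if not ok or len(window) < criteria.min_consecutive_scans:
                continue
            if min(des) > criteria.delta_e_max:
                continue
            devs = []
            ratios_per_q = [[] for _ in target.qualifiers]
            for s in window:
                a_main = s.spectrum.get(target.main_ion)
                for qi, (mz, ri) in enumerate(target.qualifiers):
                    r = s.spectrum.get(mz) / a_main
                    devs.append(100.0 * abs(ri - r) / ri)
                    ratios_per_q[qi].append(r)
            q = max(0.0, 100.0 - float(np.mean(devs)))
            if q < criteria.q_value_min:
                continue
            qr = max(abs(float(np.mean(rs)) - ri) / ri
                     for rs, (_, ri) in zip(ratios_per_q, target.qualifiers))
            if qr > criteria.q_ratio_tol:
                continue
            best = (lo, hi, q)
    return best is not None


class TestEvaluateTarget:
    def test_clean_peak_passes_with_high_q(self, clean_run, simple_target,
                                           default_criteria):
        run, _, comp = clean_run
        res = evaluate_target(run, simple_target, default_criteria,
                              rt_window=0.1)
        assert res.passed
        assert res.q_value == pytest.approx(100.0, abs=0.5)
        assert np.nanmin(res.delta_i) == pytest.approx(0.0, abs=1e-6)

    def test_coeluter_distorting_a_qualifier_fails(self, simple_spectrum,
                                                   simple_target,
                                                   default_criteria):
        # interference adds 50% extra signal on qualifier 136 throughout
        a = PlantedCompound("a", simple_spectrum, 0.25, 0.01, 5e5)
        b = PlantedCompound("b", Spectrum({136: 999.0, 200: 500.0}),
                            0.25, 0.01, 2.2e5)
        run, _ = simulate_run([a, b], SimConfig(duration=0.5, seed=2))
        res = evaluate_target(run, simple_target, default_criteria,
                              rt_window=0.1)
        assert res.q_ratio_dev > default_criteria.q_ratio_tol
        assert not res.passed

    def test_peak_of_four_scans_fails_consecutive_rule(self, simple_target,
                                                       default_criteria):
        scans = scans_with_ratio_factor(simple_target, 1.0, n=4)
        run = ChromRun(scans=scans)
        res = evaluate_target(run, simple_target, default_criteria,
                              rt_window=10.0)
        assert res.n_consecutive_pass == 4
        assert not res.passed

    def test_rt_outside_run_gives_not_found(self, clean_run, simple_spectrum,
                                            default_criteria):
        run, _, _ = clean_run
        far = TargetCompound.from_spectrum("far", 99.0, simple_spectrum)
        res = evaluate_target(run, far, default_criteria)
        assert not res.passed and res.region is None

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_brute_force_on_toy_runs(self, seed,
                                                 default_criteria):
        """Exhaustive window enumeration cross-checks the fast path."""
        rng = np.random.default_rng(seed)
        t = make_target([0.5, 0.25])
        scans = []
        for i in range(int(rng.integers(5, 9))):
            a_main = float(rng.uniform(100, 10000))
            factor = float(rng.uniform(0.7, 1.3))
            jitter = rng.uniform(0.95, 1.05, size=2)
            peaks = {93: a_main,
                     100: a_main * 0.5 * factor * jitter[0],
                     110: a_main * 0.25 * factor * jitter[1]}
            if rng.random() < 0.2:
                peaks.pop(93)   # drop the main ion sometimes
            scans.append(Scan(0.1 * (i + 1), Spectrum(peaks)))
        run = ChromRun(scans=scans)
        fast = evaluate_target(run, t, default_criteria, rt_window=10.0)
        assert fast.passed == brute_force_verdict(run, t, default_criteria)


class TestDetectPeaks:
    def test_single_gaussian_gives_one_region(self, noisy_run):
        run, _, comp = noisy_run
        noise = NoiseModel.estimate(run)
        regions = detect_peaks(run, noise)
        assert len(regions) == 1
        apex_time = run.times()[regions[0].apex_scan]
        assert apex_time == pytest.approx(comp.rt, abs=0.01)

    def test_flat_noise_only_run_has_no_regions(self):
        run, _ = simulate_run([], SimConfig(duration=0.5, seed=7,
                                            noise_sd=3.0))
        assert detect_peaks(run, NoiseModel.estimate(run)) == []

    def test_five_sigma_separation_splits_at_valley(self):
        a = PlantedCompound("a", random_spectrum(1, 10), 0.20, 0.01, 5e5)
        b = PlantedCompound("b", random_spectrum(2, 10), 0.25, 0.01, 5e5)
        run, _ = simulate_run([a, b], SimConfig(duration=0.5, seed=3,
                                                noise_sd=2.0))
        regions = detect_peaks(run, NoiseModel.estimate(run))
        assert len(regions) == 2
        assert regions[0].end_scan <= regions[1].start_scan

    def test_too_few_scans_rejected(self):
        run = ChromRun(scans=[Scan(0.01 * i, Spectrum({93: 1.0}))
                              for i in range(5)])
        with pytest.raises(DataValidationError):
            detect_peaks(run, NoiseModel(1.0, 0.1))


class TestInvariantScans:
    def test_pure_peak_selects_coherent_window(self, noisy_run):
        run, _, comp = noisy_run
        noise = NoiseModel.estimate(run)
        region = detect_peaks(run, noise)[0]
        window = select_invariant_scans(run, region)
        assert window is not None and 3 <= len(window) <= 5
        specs = [run.scans[i].spectrum for i in window]
        for s1, s2 in itertools.combinations(specs, 2):
            assert cosine(s1, s2) >= 0.999

    def test_two_coeluters_window_sits_where_one_dominates(self):
        a = PlantedCompound("a", random_spectrum(1, 10), 0.25, 0.01, 5e5)
        b = PlantedCompound("b", random_spectrum(2, 10), 0.267, 0.01, 5e5)
        run, truth = simulate_run([a, b], SimConfig(duration=0.5, seed=3,
                                                    noise_sd=2.0))
        noise = NoiseModel.estimate(run)
        region = detect_peaks(run, noise)[0]
        window = select_invariant_scans(run, region, tol=0.02)
        assert window is not None
        avg = average_spectrum(run, window)
        # window belongs overwhelmingly to one of the two compounds
        assert max(cosine(avg, a.spectrum), cosine(avg, b.spectrum)) >= 0.98

    def test_noise_only_region_finds_nothing(self):
        run, _ = simulate_run([], SimConfig(duration=0.2, seed=9,
                                            noise_sd=3.0))
        region = PeakRegion(10, 50, 100)
        assert select_invariant_scans(run, region, tol=0.05) is None

    def test_distance_matrix_diagnostic_is_symmetric(self, noisy_run):
        run, _, _ = noisy_run
        region = PeakRegion(170, 180, 190)
        d = scan_distance_matrix(run, region)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestAverageSpectrum:
    def test_identical_scans_return_that_spectrum(self):
        s = Spectrum({93: 10.0})
        run = ChromRun(scans=[Scan(0.0, s), Scan(0.1, s)])
        assert average_spectrum(run, [0, 1]) == s

    def test_arithmetic_mean_per_mz(self):
        run = ChromRun(scans=[Scan(0.0, Spectrum({100: 10.0})),
                              Scan(0.1, Spectrum({100: 30.0}))])
        assert average_spectrum(run, [0, 1]).peaks == {100: 20.0}

    def test_disjoint_sets_union_with_halved_intensities(self):
        run = ChromRun(scans=[Scan(0.0, Spectrum({100: 10.0})),
                              Scan(0.1, Spectrum({200: 30.0}))])
        assert average_spectrum(run, [0, 1]).peaks == {100: 5.0, 200: 15.0}

    def test_empty_index_list_rejected(self):
        run = ChromRun(scans=[Scan(0.0, Spectrum({100: 1.0}))])
        with pytest.raises(DataValidationError):
            average_spectrum(run, [])


class TestSubtraction:
    def test_true_spectrum_leaves_numerical_zero_residual(self, clean_run):
        run, _, comp = clean_run
        noise = NoiseModel.estimate(run)
        region = detect_peaks(run, noise)[0]
        residual, prof = subtract_component(run, region, comp.spectrum,
                                            comp.main_ion)
        tic = residual.tic()[region.start_scan:region.end_scan + 1]
        assert np.max(tic) <= 1e-6 * run.tic().max()

    def test_reveals_second_coeluter(self):
        a = PlantedCompound("a", random_spectrum(1, 10), 0.25, 0.01, 5e5)
        b = PlantedCompound("b", random_spectrum(2, 10), 0.262, 0.01, 3e5)
        run, _ = simulate_run([a, b], SimConfig(duration=0.5, seed=3))
        noise = NoiseModel.estimate(run)
        region = detect_peaks(run, noise)[0]
        residual, _ = subtract_component(run, region, a.spectrum, a.main_ion)
        apex_b = residual.index_at(b.rt)
        assert cosine(residual.scans[apex_b].spectrum, b.spectrum) >= 0.99

    def test_anchor_missing_from_component_rejected(self, clean_run):
        run, _, comp = clean_run
        with pytest.raises(DataValidationError):
            subtract_component(run, PeakRegion(0, 5, 10), comp.spectrum, 77)

    def test_preclip_mass_balance_is_exact(self, noisy_run):
        run, _, comp = noisy_run
        noise = NoiseModel.estimate(run)
        region = detect_peaks(run, noise)[0]
        _, prof = subtract_component(run, region, comp.spectrum,
                                     comp.main_ion)
        assert prof.balance_error <= 1e-9 * prof.original_sum


class TestResidualIsBackground:
    def test_zero_residual_is_background(self):
        run = ChromRun(scans=[Scan(0.01 * i, Spectrum({}))
                              for i in range(1, 30)])
        assert residual_is_background(run, PeakRegion(0, 10, 28),
                                      NoiseModel(10.0, 1.0))

    def test_unsubtracted_compound_is_not_background(self):
        c = PlantedCompound("c", random_spectrum(5, 10), 0.25, 0.01, 3e5)
        run, _ = simulate_run([c], SimConfig(duration=0.5, seed=5,
                                             noise_sd=3.0))
        noise = NoiseModel.estimate(run)
        region = detect_peaks(run, noise)[0]
        assert not residual_is_background(run, region, noise)

    def test_pure_noise_draws_pass_almost_always(self):
        """Over 100 seeded baseline draws the check accepts >= 99%."""
        accepted = 0
        for seed in range(100):
            run, _ = simulate_run([], SimConfig(duration=0.1, seed=seed,
                                                noise_sd=3.0))
            noise = NoiseModel.estimate(run)
            region = PeakRegion(10, 35, 60)
            accepted += residual_is_background(run, region, noise)
        assert accepted >= 99


class TestDeconvolvePeak:
    def test_single_library_compound_identified(self, noisy_run,
                                                simple_target,
                                                default_criteria):
        run, _, comp = noisy_run
        noise = NoiseModel.estimate(run)
        region = detect_peaks(run, noise)[0]
        lib = TargetLibrary(entries=[simple_target])
        comps, residual = deconvolve_peak(run, region, lib,
                                          default_criteria.with_noise(noise),
                                          noise)
        assert len(comps) == 1
        assert comps[0].target.id == "probe"
        assert not comps[0].is_unknown
        assert residual_is_background(residual, region, noise)

    def test_noise_region_yields_no_components(self):
        run, _ = simulate_run([], SimConfig(duration=0.2, seed=4,
                                            noise_sd=3.0))
        noise = NoiseModel.estimate(run)
        region = PeakRegion(20, 70, 120)
        comps, residual = deconvolve_peak(run, region, TargetLibrary(),
                                          MatchCriteria().with_noise(noise),
                                          noise)
        assert comps == []
        assert residual.approx_equal(run)

    def test_unknown_discovery_without_library(self, noisy_run):
        run, _, comp = noisy_run
        comps = deconvolve_run(run)
        assert len(comps) >= 1
        best = max(comps, key=lambda c: cosine(c.target.ref_spectrum,
                                               comp.spectrum))
        assert best.is_unknown
        assert cosine(best.target.ref_spectrum, comp.spectrum) >= 0.99
        assert best.result.abundance == pytest.approx(comp.main_ion_area(),
                                                      rel=0.05)
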