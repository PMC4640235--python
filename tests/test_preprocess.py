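"""The nine preprocessing operators, SNR, provenance and the pipeline."""

import numpy as np
import pytest

from mrsxml import (
    AcquisitionParams,
    AdditionalInfo,
    AlignmentSpec,
    GridRecord,
    NoiseRegion,
    PeakModel,
    PpmAxis,
    PpmRange,
    PreprocessingRecord,
    Spectrum,
    StepId,
    TimeSignal,
    align,
    apodize,
    apply_steps,
    baseline_correct,
    blank_template,
    change_points_in_range,
    compute_snr,
    gen_fid,
    gen_mv_grid,
    hlsvd_filter,
    interpret_template,
    l2_normalize,
    output_range,
    resolve_steps,
    run_pipeline,
    set_reference,
    set_to_zero,
    to_frequency_domain,
)
from mrsxml.errors import (
    DegenerateNoiseError,
    NumericsError,
    ParameterError,
    ValidationError,
)


def _spectrum(values, first=5.0, step=0.01, params=None):
    values = np.asarray(values, dtype=complex)
    if params is None:
        params = AcquisitionParams(63.86, 1300.0, max(len(values), 2), 4.7)
    return Spectrum(values, PpmAxis.uniform(first, step, len(values)), params)


def _provenance():
    return PreprocessingRecord(additional_info=AdditionalInfo(name="t", place="l"))


class TestSetReference:
    def test_water_maximum_lands_on_475(self, params_small):
        # unsuppressed water generated exactly on the carrier
        fid = gen_fid([PeakModel(ppm=4.7, amplitude=1.0, damping=12.0)], params_small)
        spec = to_frequency_domain(fid)
        out = set_reference(spec, 4.75)
        i = int(np.argmax(np.abs(out.intensities)))
        assert out.axis.values[i] == pytest.approx(4.75, abs=1e-12)

    def test_identity_when_reference_unchanged(self, params_small):
        spec = to_frequency_domain(gen_fid([PeakModel(4.7, 1.0, 12.0)], params_small))
        out = set_reference(spec, params_small.reference_ppm)
        np.testing.assert_array_equal(out.axis.values, spec.axis.values)
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_axis_maximum_is_reference_plus_half_span(self, params_small):
        spec = to_frequency_domain(gen_fid([PeakModel(4.7, 1.0, 12.0)], params_small))
        out = set_reference(spec, 4.75)
        half_span = (params_small.num_points / 2) * params_small.ppm_step
        assert out.axis.values[0] == pytest.approx(4.75 + half_span, rel=1e-12)

    def test_intensities_untouched(self, params_small):
        spec = to_frequency_domain(gen_fid([PeakModel(4.7, 1.0, 12.0)], params_small))
        out = set_reference(spec, 0.0)
        np.testing.assert_array_equal(out.intensities, spec.intensities)


class TestApodize:
    def test_zero_linewidth_is_identity(self, params_small, rng):
        sig = TimeSignal(rng.standard_normal(512) + 0j, params_small)
        for shape in ("Gaussian", "Lorentzian"):
            np.testing.assert_array_equal(apodize(sig, shape, 0.0).samples, sig.samples)

    def test_first_sample_unchanged(self, params_small, rng):
        sig = TimeSignal(rng.standard_normal(512) + 0j, params_small)
        for lw in (1.0, 5.0, 50.0):
            assert apodize(sig, "Lorentzian", lw).samples[0] == sig.samples[0]
            assert apodize(sig, "Gaussian", lw).samples[0] == sig.samples[0]

    def test_negative_linewidth_rejected(self, params_small):
        sig = TimeSignal(np.ones(512, dtype=complex), params_small)
        with pytest.raises(ParameterError):
            apodize(sig, "Lorentzian", -1.0)
        with pytest.raises(ParameterError):
            apodize(sig, "Voigt", 1.0)

    def test_lorentzian_fwhm_adds_linewidths(self):
        # noiseless Lorentzian of FWHM a Hz, broadened by b Hz -> a + b
        a_hz, b_hz = 5.0, 7.0
        params = AcquisitionParams(63.86, 2000.0, 8192, 4.7)
        t = np.arange(8192) / 2000.0
        sig = TimeSignal(np.exp(-np.pi * a_hz * t), params)  # on-carrier line

        def fwhm_hz(spec):
            y = spec.intensities.real
            half = y.max() / 2
            above = np.flatnonzero(y >= half)
            lo, hi = above[0], above[-1]

            def cross(i, j):  # linear interpolation of the half-max crossing
                return i + (half - y[i]) / (y[j] - y[i]) * (j - i)

            width_pts = cross(hi, hi + 1) - cross(lo, lo - 1)
            return width_pts * params.sweep_width / params.num_points

        broadened = apodize(sig, "Lorentzian", b_hz)
        bin_hz = params.sweep_width / params.num_points
        assert fwhm_hz(to_frequency_domain(sig)) == pytest.approx(a_hz, abs=bin_hz)
        assert fwhm_hz(to_frequency_domain(broadened)) == pytest.approx(a_hz + b_hz, abs=bin_hz)


class TestHlsvdFilter:
    def test_removes_known_component(self, params_small):
        fid = gen_fid([PeakModel(4.7, 1.0, 12.0)], params_small)
        out = hlsvd_filter(fid, 1, [PpmRange(upper=5.2, lower=4.2)])
        assert np.sum(np.abs(out.samples) ** 2) < 1e-6 * np.sum(np.abs(fid.samples) ** 2)

    def test_region_without_component_is_identity(self, params_small):
        fid = gen_fid([PeakModel(2.0, 1.0, 12.0)], params_small)
        out = hlsvd_filter(fid, 1, [PpmRange(upper=5.2, lower=4.2)])
        norm = np.linalg.norm(fid.samples)
        assert np.linalg.norm(out.samples - fid.samples) < 1e-8 * norm

    def test_more_than_three_regions_rejected(self, params_small):
        fid = gen_fid([PeakModel(4.7, 1.0, 12.0)], params_small)
        four = [PpmRange(upper=u, lower=u - 0.5) for u in (6.0, 5.0, 4.0, 3.0)]
        with pytest.raises(ParameterError):
            hlsvd_filter(fid, 1, four)
        with pytest.raises(ParameterError):
            hlsvd_filter(fid, 1, [])

    def test_water_removed_metabolites_survive(self, brain_fid):
        fid, truth = brain_fid
        out = hlsvd_filter(fid, 8, [PpmRange(upper=5.2, lower=4.2)])
        spec = to_frequency_domain(out)
        peak_ppm = spec.axis.values[int(np.argmax(np.abs(spec.intensities)))]
        assert not (4.2 <= peak_ppm <= 5.2)  # no longer water
        assert 1.8 <= peak_ppm <= 3.4        # one of the metabolite singlets


class TestBaseline:
    def test_mean_of_per_region_means(self):
        # per-region mean heights 2 and 4 -> every point drops by 3
        vals = np.full(100, 7.0)
        vals[10:20] = 2.0   # region A
        vals[50:70] = 4.0   # region B
        spec = _spectrum(vals)
        ax = spec.axis.values
        regions = [
            PpmRange(upper=ax[10] + 1e-6, lower=ax[19] - 1e-6),
            PpmRange(upper=ax[50] + 1e-6, lower=ax[69] - 1e-6),
        ]
        out = baseline_correct(spec, regions)
        np.testing.assert_allclose(out.intensities.real, vals - 3.0)

    def test_all_zero_unchanged(self):
        spec = _spectrum(np.zeros(50))
        out = baseline_correct(spec, [PpmRange(upper=5.0, lower=4.9)])
        assert not np.any(out.intensities)

    def test_matches_brute_force_single_region(self, rng):
        vals = rng.standard_normal(200) + 1j * rng.standard_normal(200)
        spec = _spectrum(vals)
        region = PpmRange(upper=4.8, lower=4.3)
        mask = (spec.axis.values >= 4.3) & (spec.axis.values <= 4.8)
        expected = vals - vals[mask].mean()
        out = baseline_correct(spec, [region])
        np.testing.assert_allclose(out.intensities, expected, rtol=1e-12)

    def test_bad_region_counts_rejected(self, rng):
        spec = _spectrum(rng.standard_normal(50))
        with pytest.raises(ParameterError):
            baseline_correct(spec, [])
        with pytest.raises(ParameterError):
            baseline_correct(spec, [PpmRange(upper=100.0, lower=99.0)])  # no points


class TestChangePoints:
    def test_interpret_canonical_count(self, params_1h, brain_fid):
        fid, _ = brain_fid
        spec = to_frequency_domain(fid)  # spans ~20 ppm around 4.7
        window = PpmRange(upper=7.1, lower=-2.7)
        out = change_points_in_range(spec, 512, window)
        in_window = out.axis.mask_range(window)
        assert int(in_window.sum()) == 512
        assert out.axis.values[np.flatnonzero(in_window)[0]] == pytest.approx(7.1, abs=1e-12)

    def test_exact_count_is_identity(self):
        spec = _spectrum(np.arange(100, dtype=float))
        ax = spec.axis.values
        rng_ = PpmRange(upper=ax[10] + 0.001, lower=ax[19] - 0.001)  # exactly 10 points
        out = change_points_in_range(spec, 10, rng_)
        np.testing.assert_array_equal(out.intensities, spec.intensities)
        np.testing.assert_array_equal(out.axis.values, spec.axis.values)

    def test_zero_filling_preserves_peak_position(self, params_small):
        # 512-point spectrum, ~50 points in a 2-ppm window, target 200
        fid = gen_fid([PeakModel(4.7, 1.0, 6.0), PeakModel(2.0, 0.5, 6.0)], params_small)
        spec = to_frequency_domain(fid)
        window = PpmRange(upper=5.2, lower=3.2)
        assert int(spec.axis.mask_range(window).sum()) < 200
        out = change_points_in_range(spec, 200, window)
        assert int(out.axis.mask_range(window).sum()) == 200
        new_step = (window.upper - window.lower) / 199
        mask = out.axis.mask_range(window)
        peak_ppm = out.axis.values[mask][int(np.argmax(np.abs(out.intensities[mask])))]
        assert abs(peak_ppm - 4.7) <= new_step

    def test_full_span_retained(self, params_small, brain_fid):
        fid, _ = brain_fid
        spec = to_frequency_domain(fid)
        out = change_points_in_range(spec, 512, PpmRange(upper=7.1, lower=-2.7))
        assert out.axis.values[0] > 7.1
        assert out.axis.values[-1] < -2.7

    def test_range_outside_axis_rejected(self):
        spec = _spectrum(np.ones(50))
        with pytest.raises(ParameterError):
            change_points_in_range(spec, 10, PpmRange(upper=50.0, lower=40.0))


class TestSetToZero:
    def test_whole_axis_zeroed(self, rng):
        spec = _spectrum(rng.standard_normal(80))
        out = set_to_zero(spec, [PpmRange(upper=10.0, lower=0.0)])
        assert not np.any(out.intensities)

    def test_interval_without_points_is_identity(self, rng):
        vals = rng.standard_normal(80)
        out = set_to_zero(_spectrum(vals), [PpmRange(upper=100.0, lower=99.0)])
        np.testing.assert_array_equal(out.intensities.real, vals)

    def test_matches_brute_force_scan(self, params_1h, rng):
        vals = rng.standard_normal(2048) + 1j * rng.standard_normal(2048)
        spec = _spectrum(vals, first=14.9, step=0.01, params=params_1h)
        interval = PpmRange(upper=5.2, lower=4.2)
        out = set_to_zero(spec, [interval])
        in_count = int(np.sum((spec.axis.values >= 4.2) & (spec.axis.values <= 5.2)))
        assert int(np.sum(out.intensities == 0)) == in_count
        outside = ~((spec.axis.values >= 4.2) & (spec.axis.values <= 5.2))
        np.testing.assert_array_equal(out.intensities[outside], vals[outside])

    def test_more_than_two_intervals_rejected(self, rng):
        spec = _spectrum(rng.standard_normal(50))
        with pytest.raises(ParameterError):
            set_to_zero(spec, [PpmRange(upper=u, lower=u - 0.1) for u in (5.0, 4.0, 3.0)])


class TestNormalize:
    def test_three_four_five(self):
        out = l2_normalize(_spectrum([3.0, 4.0]))
        np.testing.assert_allclose(out.intensities.real, [0.6, 0.8], rtol=1e-15)

    def test_idempotent(self, rng):
        vals = rng.standard_normal(128) + 1j * rng.standard_normal(128)
        once = l2_normalize(_spectrum(vals))
        twice = l2_normalize(once)
        np.testing.assert_allclose(twice.intensities, once.intensities, atol=1e-12)

    def test_unit_norm_against_brute_force(self, rng):
        vals = rng.standard_normal(256) + 1j * rng.standard_normal(256)
        out = l2_normalize(_spectrum(vals))
        total = sum(abs(x) ** 2 for x in out.intensities)  # brute-force sum
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(NumericsError):
            l2_normalize(_spectrum(np.zeros(10)))


class TestSnr:
    def test_direct_ratio(self):
        # max amplitude 10, noise std exactly 1 -> SNR 5
        vals = np.zeros(100)
        vals[10] = 10.0
        a = np.sqrt(0.5)
        vals[50], vals[51] = a, -a  # sample std (ddof=1) == 1
        spec = _spectrum(vals)
        ax = spec.axis.values
        noise = NoiseRegion(PpmRange(upper=ax[50] + 1e-6, lower=ax[51] - 1e-6))
        res = compute_snr(spec, noise)
        assert res.max_peak == pytest.approx(10.0)
        assert res.noise_std == pytest.approx(1.0)
        assert res.snr == pytest.approx(5.0)
        assert res.snr == pytest.approx(res.max_peak / (2 * res.noise_std))

    def test_constant_noise_region_is_degenerate(self):
        vals = np.ones(50)
        spec = _spectrum(vals)
        with pytest.raises(DegenerateNoiseError):
            compute_snr(spec, NoiseRegion(PpmRange(upper=5.0, lower=4.8)))

    def test_too_few_noise_points_rejected(self, rng):
        spec = _spectrum(rng.standard_normal(50))
        lone = spec.axis.values[3]
        with pytest.raises(ParameterError):
            compute_snr(spec, NoiseRegion(PpmRange(upper=lone + 1e-6, lower=lone - 1e-6)))

    def test_matches_brute_force(self, rng):
        vals = rng.standard_normal(300) + 1j * rng.standard_normal(300)
        spec = _spectrum(vals)
        noise_rng = PpmRange(upper=4.0, lower=3.0)
        res = compute_snr(spec, NoiseRegion(noise_rng))
        mask = (spec.axis.values >= 3.0) & (spec.axis.values <= 4.0)
        expected_std = np.std(vals[mask].real, ddof=1)
        assert res.max_peak == pytest.approx(np.max(np.abs(vals)), rel=1e-12)
        assert res.snr == pytest.approx(np.max(np.abs(vals)) / (2 * expected_std), rel=1e-12)


def _displaced_brain_spectrum(params, displacement, seed=3):
    fid, _ = __import__("mrsxml").gen_brain_like_sv(params, seed=seed, noise_sd=0.005)
    spec = to_frequency_domain(fid)
    rolled = np.roll(spec.intensities, displacement)
    return Spectrum(rolled, spec.axis, spec.params), spec


class TestAlign:
    NOISE = NoiseRegion(PpmRange(upper=-1.0, lower=-2.6))

    def test_exact_shift_recovered(self, params_1h):
        displaced, original = _displaced_brain_spectrum(params_1h, 3)
        spec = align(displaced, AlignmentSpec(peaks=[4.7], noise=self.NOISE))
        i_t = spec.axis.nearest_index(4.7)
        assert int(np.argmax(np.abs(spec.intensities))) == i_t

    @pytest.mark.parametrize("displacement", range(-20, 21, 5))
    def test_shift_never_exceeds_ten_points(self, params_1h, displacement):
        displaced, _ = _displaced_brain_spectrum(params_1h, displacement)
        before = int(np.argmax(np.abs(displaced.intensities)))
        out = align(displaced, AlignmentSpec(peaks=[4.7], noise=self.NOISE))
        after = int(np.argmax(np.abs(out.intensities)))
        assert abs(after - before) <= 10

    def test_aligned_spectrum_unchanged(self, params_1h):
        displaced, _ = _displaced_brain_spectrum(params_1h, 0)
        out = align(displaced, AlignmentSpec(peaks=[4.7], noise=self.NOISE))
        np.testing.assert_array_equal(out.intensities, displaced.intensities)

    def test_highest_snr_peak_drives_the_shift(self, params_1h):
        # water dominates, so the water theoretical peak wins over NAA
        displaced, _ = _displaced_brain_spectrum(params_1h, 4)
        out = align(displaced, AlignmentSpec(peaks=[2.01, 4.7], noise=self.NOISE))
        i_t = out.axis.nearest_index(4.7)
        assert int(np.argmax(np.abs(out.intensities))) == i_t

    def test_empty_peaks_rejected(self):
        with pytest.raises(ParameterError):
            AlignmentSpec(peaks=[], noise=self.NOISE)


class TestOutputRange:
    def test_full_span_is_identity(self, rng):
        vals = rng.standard_normal(100)
        spec = _spectrum(vals)
        rng_ = PpmRange(upper=spec.axis.values[0] + 0.1, lower=spec.axis.values[-1] - 0.1)
        out = output_range(spec, rng_)
        np.testing.assert_array_equal(out.intensities.real, vals)

    def test_length_equals_brute_force_count(self, rng):
        vals = rng.standard_normal(333)
        spec = _spectrum(vals)
        window = PpmRange(upper=4.5, lower=3.21)
        out = output_range(spec, window)
        expected = int(np.sum((spec.axis.values >= 3.21) & (spec.axis.values <= 4.5)))
        assert len(out) == expected

    def test_empty_range_rejected(self, rng):
        spec = _spectrum(rng.standard_normal(50))
        with pytest.raises(ParameterError):
            output_range(spec, PpmRange(upper=100.0, lower=99.0))

    def test_differing_spans_give_equal_lengths(self):
        # two scanners, same point count, slightly different ppm spans:
        # after fixing the density (Step V) and cropping (Step IX) the
        # output vectors have identical lengths
        window = PpmRange(upper=7.1, lower=-2.7)
        lengths = []
        for sw in (1300.0, 1250.0):
            p = AcquisitionParams(63.86, sw, 2048, 4.7)
            spec = to_frequency_domain(gen_fid([PeakModel(4.7, 1.0, 12.0)], p))
            spec = change_points_in_range(spec, 512, window)
            lengths.append(len(output_range(spec, window)))
        assert lengths[0] == lengths[1] == 512


class TestPipeline:
    def test_disabled_config_is_plain_transform(self, params_small):
        fid = gen_fid([PeakModel(4.7, 1.0, 12.0)], params_small)
        ds = run_pipeline(fid, blank_template().with_identity("t", "l"))
        assert ds.preprocessing.steps == []
        np.testing.assert_array_equal(
            ds.payload.spectrum.intensities, to_frequency_domain(fid).intensities
        )

    def test_interpret_composition(self, brain_fid):
        fid, _ = brain_fid
        cfg = interpret_template().with_identity("t", "l")
        ds = run_pipeline(fid, cfg)
        spec = ds.payload.spectrum
        assert len(spec) == 512
        assert spec.axis.values[0] == pytest.approx(7.1, abs=1e-12)
        # unit l2 norm holds exactly right after the normalization step;
        # the final crop removes a little out-of-window energy
        upto_norm = [s for s in ds.preprocessing.steps if s.step_id <= StepId.Normalization]
        normed = apply_steps(fid, upto_norm)
        assert np.sum(np.abs(normed.intensities) ** 2) == pytest.approx(1.0, abs=1e-12)
        assert np.sum(np.abs(spec.intensities) ** 2) == pytest.approx(1.0, abs=0.05)
        assert ds.payload.snr is not None and ds.payload.snr.snr > 0

    def test_step_records_reproduce_run_bit_for_bit(self, brain_fid):
        fid, _ = brain_fid
        ds = run_pipeline(fid, interpret_template().with_identity("t", "l"))
        replayed = apply_steps(fid, ds.preprocessing.steps)
        np.testing.assert_array_equal(replayed.intensities, ds.payload.spectrum.intensities)
        np.testing.assert_array_equal(replayed.axis.values, ds.payload.spectrum.axis.values)

    def test_records_always_in_execution_order(self):
        steps = resolve_steps(interpret_template())
        ids = [s.step_id for s in steps]
        assert ids == sorted(ids)

    def test_out_of_order_records_rejected(self, params_small):
        fid = gen_fid([PeakModel(4.7, 1.0, 12.0)], params_small)
        steps = resolve_steps(interpret_template())
        with pytest.raises(ValidationError):
            apply_steps(fid, list(reversed(steps)))

    def test_each_operator_appends_one_record(self, params_small, rng):
        fid = gen_fid([PeakModel(4.7, 1.0, 12.0)], params_small, noise_sd=0.01, seed=1)
        rec = _provenance()
        spec = to_frequency_domain(fid)
        spec = set_reference(spec, 4.75, record=rec)
        spec = baseline_correct(spec, [PpmRange(upper=-1.0, lower=-2.0)], record=rec)
        spec = l2_normalize(spec, record=rec)
        assert [s.step_id for s in rec.steps] == [
            StepId.SetReference, StepId.BaselineCorrection, StepId.Normalization,
        ]
        replayed = apply_steps(fid, rec.steps)
        np.testing.assert_array_equal(replayed.intensities, spec.intensities)

    def test_grid_processed_uniformly(self):
        params = AcquisitionParams(63.86, 1300.0, 256, 4.7)
        grid, _ = gen_mv_grid(2, 2, params, seed=5)
        cfg = blank_template().with_identity("t", "l")
        cfg.normalization.enabled = True
        ds = run_pipeline(grid, cfg)
        assert ds.is_grid and ds.payload.rows == 2 and ds.payload.cols == 2
        axes = {tuple(v.spectrum.axis.values) for row in ds.payload.voxels for v in row}
        assert len(axes) == 1
        for row in ds.payload.voxels:
            for v in row:
                assert np.sum(np.abs(v.spectrum.intensities) ** 2) == pytest.approx(1.0, abs=1e-12)

    def test_one_by_one_grid_stays_a_grid(self):
        params = AcquisitionParams(63.86, 1300.0, 256, 4.7)
        grid, _ = gen_mv_grid(1, 1, params, seed=5)
        ds = run_pipeline(grid, blank_template().with_identity("t", "l"))
        assert isinstance(ds.payload, GridRecord)

    def test_voxel_errors_carry_position(self):
        params = AcquisitionParams(63.86, 1300.0, 256, 4.7)
        grid, _ = gen_mv_grid(1, 2, params, seed=5)
        grid.voxels[0][1].spectrum.intensities[:] = 0.0  # normalization must fail here
        cfg = blank_template().with_identity("t", "l")
        cfg.normalization.enabled = True
        with pytest.raises(NumericsError, match=r"row 1, col 2"):
            run_pipeline(grid, cfg)
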