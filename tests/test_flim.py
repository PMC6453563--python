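"""Lifetime fitting, FRET efficiency, engaged-fraction estimation, masking."""

import numpy as np
import pytest

from tensionmap import flim
from tensionmap import synthetic as syn


def _hist_from_counts(counts, bin_width=0.08, window=12.5):
    n = int(window / bin_width + 1e-9)
    centers = (np.arange(n) + 0.5) * bin_width
    full = np.zeros(n)
    full[: len(counts)] = counts
    return flim.PhotonDecayHistogram(
        bin_centers=centers, counts=full, bin_width=bin_width, window=window
    )


class TestMonoExpTail:
    def test_two_point_tail_exact(self):
        # two points one 1 ns apart with ratio 1000/716.53 force
        # tau = 1/ln(1000/716.53) = 3.0 ns exactly
        centers = np.array([1.0, 2.0])
        counts = np.array([1000.0, 716.53])
        h = flim.PhotonDecayHistogram(
            bin_centers=centers, counts=counts, bin_width=1.0, window=2.5
        )
        res = flim.MonoExpTailModel(h, tail_start=0.0).fit()
        assert res.tau == pytest.approx(1.0 / np.log(1000.0 / 716.53), rel=1e-6)
        assert res.tau == pytest.approx(3.0, abs=2e-3)

    def test_unbiased_on_synthetic_truth(self):
        taus, rels = [], []
        for seed in range(60):
            h = syn.gen_decay_histogram(
                syn.DecaySpec(components=((3.0, 1.0),), total_photons=1e6,
                              seed=seed)
            )
            r = flim.fit_monoexponential_tail(h)
            assert r.converged
            taus.append(r.tau)
            rels.append(r.rel_error)
        taus = np.array(taus)
        se = taus.std(ddof=1) / np.sqrt(taus.size)
        assert abs(taus.mean() - 3.0) < 3 * se
        assert np.mean(np.array(rels) < 0.05) > 0.95

    def test_mixture_lifetime_between_components(self):
        h = syn.gen_decay_histogram(
            syn.DecaySpec(components=((3.0, 0.5), (1.5, 0.5)),
                          total_photons=1e6, seed=11)
        )
        r = flim.fit_monoexponential_tail(h)
        assert 1.5 < r.tau < 3.0

    def test_empty_tail_flagged(self):
        h = _hist_from_counts([1000.0, 700.0, 500.0])
        res = flim.MonoExpTailModel(h, tail_start=5.0).fit()
        assert not res.converged
        assert np.isnan(res.tau)

    def test_background_fit_recovers_floor(self):
        h = syn.gen_decay_histogram(
            syn.DecaySpec(components=((2.5, 1.0),), total_photons=1e6,
                          background_rate=30.0, seed=4)
        )
        res = flim.MonoExpTailModel(h, fit_background=True).fit()
        assert res.background == pytest.approx(30.0, rel=0.2)
        assert res.tau == pytest.approx(2.5, rel=0.02)


class TestFretEfficiency:
    @pytest.mark.parametrize(
        "tau_da, tau_d, expected",
        [(3.0, 3.0, 0.0), (2.4, 3.0, 0.2), (1e-9, 3.0, 1.0)],
    )
    def test_values(self, tau_da, tau_d, expected):
        assert flim.fret_efficiency(tau_da, tau_d).efficiency == pytest.approx(
            expected, abs=1e-6
        )

    def test_invalid_lifetimes(self):
        with pytest.raises(ValueError):
            flim.fret_efficiency(2.0, 0.0)


class TestQcFilter:
    def _fit(self, rel, converged=True):
        return flim.LifetimeFitResults(
            tau=3.0, amplitude=1.0, background=0.0, rel_error=rel,
            tail_start=1.0, converged=converged,
        )

    def test_five_and_ten_percent_cutoffs(self):
        fits = [self._fit(0.04), self._fit(0.06)]
        assert flim.qc_filter(fits, 0.05) == [fits[0]]
        assert flim.qc_filter(fits, 0.10) == fits

    def test_nonconverged_always_dropped(self):
        assert flim.qc_filter([self._fit(0.01, converged=False)], 0.05) == []

    def test_empty_ok(self):
        assert flim.qc_filter([], 0.05) == []


class TestBiexpFixed:
    def test_photon_to_molecule_algebra(self):
        # equal photon fractions with tau 3.0/1.5 -> FRET molecule fraction 2/3
        # construct amplitudes giving p1 = p2 = 0.5: A1*3 = A2*1.5
        n = 156
        centers = (np.arange(n) + 0.5) * 0.08
        a1, a2 = 1000.0, 2000.0
        counts = a1 * np.exp(-centers / 3.0) + a2 * np.exp(-centers / 1.5)
        h = flim.PhotonDecayHistogram(
            bin_centers=centers, counts=np.round(counts), bin_width=0.08,
            window=12.5,
        )
        res = flim.fit_biexponential_fixed(h, 3.0, 1.5, tail_start=0.0)
        assert res.photon_fraction_noFRET == pytest.approx(0.5, abs=0.01)
        fret_molecule_fraction = 1 - res.molecule_fraction_noFRET
        assert fret_molecule_fraction == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_pure_nofret_gives_unity(self):
        h = syn.gen_decay_histogram(
            syn.DecaySpec(components=((3.0, 1.0),), total_photons=1e6, seed=2)
        )
        res = flim.fit_biexponential_fixed(h, 3.0, 1.5)
        assert res.molecule_fraction_noFRET == pytest.approx(1.0, abs=0.01)

    def test_recovers_simulated_open_fraction(self):
        f_raws = []
        for seed in range(40):
            h = syn.gen_decay_histogram(
                syn.sensor_decay_spec(0.132, 0.0, 1e6, seed=seed)
            )
            f_raws.append(
                flim.fit_biexponential_fixed(h, 3.0, 1.5).molecule_fraction_noFRET
            )
        assert abs(np.mean(f_raws) - 0.132) < 0.01

    def test_photon_molecule_duality(self):
        h = syn.gen_decay_histogram(
            syn.sensor_decay_spec(0.3, 0.0, 1e5, seed=8)
        )
        res = flim.fit_biexponential_fixed(h, 3.0, 1.5)
        a1, a2 = res.amplitudes
        # molecule fraction from photon fractions equals the amplitude ratio
        p = res.photon_fraction_noFRET
        from_photons = (p / 3.0) / (p / 3.0 + (1 - p) / 1.5)
        assert from_photons == pytest.approx(a1 / (a1 + a2), rel=1e-12)


class TestCalibration:
    def test_recovers_reference_lifetimes(self):
        donors = [
            syn.gen_decay_histogram(
                syn.DecaySpec(components=((3.0, 1.0),), total_photons=1e6,
                              seed=s)
            )
            for s in range(5)
        ]
        controls = [
            syn.gen_decay_histogram(
                syn.DecaySpec(components=((3.0, 0.3), (1.5, 0.7)),
                              total_photons=1e6, seed=100 + s)
            )
            for s in range(5)
        ]
        tau_nofret, tau_fret = flim.calibrate_reference_lifetimes(
            donors, controls
        )
        assert tau_nofret == pytest.approx(3.0, abs=0.02)
        assert tau_fret == pytest.approx(1.5, abs=0.03)

    def test_degenerate_control_raises(self):
        donors = [
            syn.gen_decay_histogram(
                syn.DecaySpec(components=((3.0, 1.0),), total_photons=1e6,
                              seed=1)
            )
        ]
        # control without any FRET species: tau_FRET unidentifiable
        controls = [
            syn.gen_decay_histogram(
                syn.DecaySpec(components=((3.0, 1.0),), total_photons=1e6,
                              seed=2)
            )
        ]
        with pytest.raises(flim.CalibrationError):
            flim.calibrate_reference_lifetimes(donors, controls)

    def test_empty_lists_rejected(self):
        with pytest.raises(flim.CalibrationError):
            flim.calibrate_reference_lifetimes([], [])


class TestEngagedFraction:
    def _biexp(self, f_raw):
        return flim.BiexpFitResults(
            tau_noFRET=3.0, tau_FRET=1.5, photon_fraction_noFRET=f_raw,
            molecule_fraction_noFRET=f_raw, rel_error=0.01,
            amplitudes=(f_raw, 1 - f_raw), converged=True,
        )

    @pytest.mark.parametrize(
        "f_ts, f_c, expected",
        [(0.40, 0.25, 0.20), (0.25, 0.25, 0.0), (0.132, 0.0, 0.132)],
    )
    def test_normalisation(self, f_ts, f_c, expected):
        res = flim.engaged_fraction(self._biexp(f_ts), self._biexp(f_c))
        assert res.f_engaged == pytest.approx(expected, abs=1e-12)

    def test_control_at_unity_rejected(self):
        with pytest.raises(ValueError):
            flim.engaged_fraction(self._biexp(0.5), self._biexp(1.0))

    def test_negative_value_warns(self):
        with pytest.warns(UserWarning):
            res = flim.engaged_fraction(self._biexp(0.2), self._biexp(0.3))
        assert res.f_engaged < 0


class TestIntermolecularControl:
    def test_offset_recovery(self, rng):
        homo = rng.normal(0.0, 0.01, 30)
        het = rng.normal(0.02, 0.01, 30)
        off = flim.intermolecular_fret_control(het, homo)
        assert off == pytest.approx(0.02, abs=0.01)

    def test_identical_distributions_zero(self):
        vals = [0.01, 0.02, 0.03]
        assert flim.intermolecular_fret_control(vals, vals) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            flim.intermolecular_fret_control([], [0.1])


class TestBuildMask:
    def test_three_class_image_high_jaccard(self, rng):
        img = np.full((80, 80), 10.0)
        img[20:60, :] = 100.0
        true_bright = np.zeros((80, 80), dtype=bool)
        true_bright[35:45, :] = True
        img[true_bright] = 1000.0
        noisy = rng.poisson(img)
        mask = flim.build_mask(noisy)
        inter = (mask.mask & true_bright).sum()
        union = (mask.mask | true_bright).sum()
        assert inter / union >= 0.95

    def test_uniform_image_raises(self):
        with pytest.raises(flim.DegenerateThresholdError):
            flim.build_mask(np.full((30, 30), 7.0))

    def test_hole_filled(self, rng):
        img = rng.poisson(10.0, (60, 60)).astype(float)
        img[10:50, 10:50] = rng.poisson(100.0, (40, 40))  # mid class
        img[20:40, 20:40] = rng.poisson(1000.0, (20, 20))  # bright class
        img[28:32, 28:32] = rng.poisson(100.0, (4, 4))  # hole in bright
        mask = flim.build_mask(img)
        assert mask.mask[29, 29]
        assert mask.mask[22, 22]
        assert not mask.mask[5, 5]

    def test_constant_roi_raises(self, rng):
        img = rng.poisson(10.0, (60, 60)).astype(float)
        img[:, 30:] += 500.0
        img[:, :30] = 7.0  # constant inside the ROI
        roi = [(0, 0), (0, 29), (59, 29), (59, 0)]  # left half only
        with pytest.raises(flim.DegenerateThresholdError):
            flim.build_mask(img, roi)

    def test_mask_confined_to_roi(self, rng):
        img = rng.poisson(10.0, (60, 60)).astype(float)
        img[10:50, 5:55] += 90.0
        img[25:35, 5:55] += 900.0
        roi = [(0, 0), (0, 29), (59, 29), (59, 0)]  # left half only
        mask = flim.build_mask(img, roi)
        assert mask.n_pixels > 0
        assert not mask.mask[:, 30:].any()

    def test_remasking_never_leaks_outside_mask(self, band_image):
        # re-thresholding an already masked image can only shrink the mask
        mask1 = flim.build_mask(band_image)
        masked = band_image.counts * mask1.mask
        mask2 = flim.build_mask(masked)
        assert not (mask2.mask & ~mask1.mask).any()
        assert mask2.n_pixels > 0
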