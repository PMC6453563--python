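"""Generator correctness: forward models, Poisson statistics, determinism."""

import numpy as np
import pytest
from scipy.integrate import quad

from tensionmap import synthetic as syn
from tensionmap.fcs import acf_model


class TestDecayGenerator:
    def test_total_counts_and_mean_arrival(self, single_exp_hist):
        h = single_exp_hist
        assert h.bin_centers.size == 156
        # Poisson total: within 5 sigma of 1e6
        assert abs(h.n_photons - 1e6) < 5 * np.sqrt(1e6)
        # empirical mean arrival vs truncated-exponential expectation,
        # computed here by numerical quadrature as an independent oracle
        tau, span = 3.0, 156 * 0.08
        norm = quad(lambda t: np.exp(-t / tau), 0, span)[0]
        expected_mean = quad(lambda t: t * np.exp(-t / tau), 0, span)[0] / norm
        emp_mean = float((h.bin_centers * h.counts).sum() / h.counts.sum())
        assert emp_mean == pytest.approx(expected_mean, rel=0.01)

    def test_photon_share_weights_lifetime(self):
        spec = syn.DecaySpec(
            components=((3.0, 0.5), (1.5, 0.5)), total_photons=1e5
        )
        # photon yield proportional to n_i * tau_i
        assert spec.photon_shares[0] == pytest.approx(2.0 / 3.0)

    def test_determinism(self):
        spec = syn.DecaySpec(components=((2.5, 1.0),), total_photons=1e5, seed=9)
        h1 = syn.gen_decay_histogram(spec)
        h2 = syn.gen_decay_histogram(spec)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_background_adds_uniform_floor(self):
        spec = syn.DecaySpec(
            components=((3.0, 1.0),), total_photons=1e4,
            background_rate=50.0, seed=1,
        )
        h = syn.gen_decay_histogram(spec)
        # late bins (decayed to ~nothing) sit at the background level
        late = h.counts[-10:]
        assert abs(late.mean() - 50.0) < 5 * np.sqrt(50.0 / 10)

    @pytest.mark.parametrize(
        "kw",
        [
            {"components": ((-1.0, 1.0),), "total_photons": 1e4},
            {"components": ((3.0, 0.6), (1.5, 0.6)), "total_photons": 1e4},
            {"components": ((3.0, 1.0),), "total_photons": -5},
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        with pytest.raises(ValueError):
            syn.DecaySpec(**kw)


class TestFcsGenerator:
    def test_zero_noise_equals_model(self):
        spec = syn.FcsSpec(
            n_particles=10.0, diffusion_times=((1e-3, 1.0),),
            dark_states=((0.2, 1e-5),), noise_rel=0.0,
        )
        curve = syn.gen_fcs_curve(spec)
        expected = acf_model(
            "T-3D",
            {"n": 10.0, "components": [(1e-3, 1.0)], "dark": [(0.2, 1e-5)],
             "s": 5.0},
            spec.lag_grid,
        )
        np.testing.assert_allclose(curve.G, expected)

    def test_g0_is_inverse_n_without_dark_states(self):
        spec = syn.FcsSpec(
            n_particles=10.0, diffusion_times=((1e-3, 1.0),),
            lag_grid=np.geomspace(1e-8, 1, 100), noise_rel=0.0,
        )
        curve = syn.gen_fcs_curve(spec)
        assert curve.G[0] == pytest.approx(0.1, rel=1e-4)

    def test_noise_model_scale(self):
        # per-lag sample SD of 100 replicates within 20% of 0.02*G
        spec0 = syn.FcsSpec(
            n_particles=10.0, diffusion_times=((1e-3, 1.0),),
            dark_states=((0.1, 1e-5),), noise_rel=0.0,
        )
        g_true = syn.gen_fcs_curve(spec0).G
        reps = np.array([
            syn.gen_fcs_curve(
                syn.FcsSpec(
                    n_particles=10.0, diffusion_times=((1e-3, 1.0),),
                    dark_states=((0.1, 1e-5),), noise_rel=0.02, seed=s,
                )
            ).G
            for s in range(100)
        ])
        sd = reps.std(axis=0)
        ratio = sd / (0.02 * g_true)
        assert np.all(np.abs(ratio - 1) < 0.35)
        assert abs(np.median(ratio) - 1) < 0.2

    def test_empty_lag_grid_rejected(self):
        with pytest.raises(ValueError):
            syn.FcsSpec(
                n_particles=5, diffusion_times=((1e-3, 1.0),),
                lag_grid=np.array([]),
            )


class TestImageGenerator:
    def test_forward_model_mean(self):
        # 5 uM, CPP=1400 Hz, PT=50 us, V_eff=0.32 fL -> 67.4 counts/pixel
        spec = syn.ImageSpec(
            shape=(64, 64), concentration_field=5.0, cpp=1400.0,
            pixel_dwell=50e-6, v_eff=0.32e-15, seed=3,
        )
        assert spec.expected_counts[0, 0] == pytest.approx(67.4, abs=0.2)
        img = syn.gen_attachment_image(spec)
        n = img.counts.size
        assert img.counts.mean() == pytest.approx(
            67.4, abs=5 * np.sqrt(67.4 / n)
        )

    def test_zero_concentration_all_zero(self):
        img = syn.gen_attachment_image(
            syn.ImageSpec(shape=(16, 16), concentration_field=0.0)
        )
        assert img.counts.sum() == 0

    def test_band_interior_ratio(self):
        field = syn.band_concentration_field((60, 60), band_uM=30.0,
                                             interior_uM=3.0)
        img = syn.gen_attachment_image(
            syn.ImageSpec(shape=(60, 60), concentration_field=field,
                          cpp=200.0, seed=2)
        )
        band = field == 30.0
        interior = field == 3.0
        ratio = img.counts[band].mean() / img.counts[interior].mean()
        assert ratio == pytest.approx(10.0, rel=0.1)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            syn.ImageSpec(shape=(8, 8), concentration_field=-1.0)

    def test_saturation_cap_enforced(self):
        with pytest.raises(ValueError, match="2 MHz"):
            syn.gen_attachment_image(
                syn.ImageSpec(shape=(8, 8), concentration_field=50.0,
                              cpp=1400.0)
            )

    def test_dilution_series(self):
        concs = [1e-2, 1e-1, 1, 10, 100]
        spec = syn.ImageSpec(shape=(64, 64), concentration_field=1.0,
                             cpp=100.0, seed=5)
        imgs = syn.gen_dilution_series(concs, spec)
        assert len(imgs) == 5
        means = [im.counts.mean() for im in imgs]
        # spans 4 decades
        assert np.log10(means[-1] / means[0]) == pytest.approx(4.0, abs=0.2)
        with pytest.raises(ValueError):
            syn.gen_dilution_series([], spec)


class TestFrapGenerator:
    def test_instant_full_recovery_limit(self):
        curve = syn.gen_frap_series(1.0, k=100.0, dt=5.0, noise_rel=0.0)
        post = curve.times >= 0
        # at the second post-bleach frame recovery is complete
        assert curve.bleach_trace[post][1] == pytest.approx(
            curve.pre_bleach_mean, rel=1e-3
        )

    def test_half_recovery_at_half_time(self):
        k = np.log(2) / 5.0  # t1/2 = 5 s
        curve = syn.gen_frap_series(0.6, k, pre_bleach=1000, post_bleach=400,
                                    dt=5.0, noise_rel=0.0)
        idx = np.where(curve.times == 5.0)[0][0]
        assert curve.bleach_trace[idx] == pytest.approx(
            400 + 0.3 * 600, rel=1e-6
        )

    def test_shared_drift_cancels_in_ratio(self):
        c = syn.gen_frap_series(0.5, 0.1, drift=0.01, noise_rel=0.0)
        c0 = syn.gen_frap_series(0.5, 0.1, drift=0.0, noise_rel=0.0)
        # control decays ~1%/s
        decay = c.control_trace[-1] / c.control_trace[0]
        t_span = c.times[-1] - c.times[0]
        assert decay == pytest.approx(np.exp(-0.01 * t_span), rel=1e-6)
        np.testing.assert_allclose(
            c.bleach_trace / c.control_trace,
            c0.bleach_trace / c0.control_trace, rtol=1e-9,
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            syn.gen_frap_series(0.5, 0.1, dt=-1)
        with pytest.raises(ValueError):
            syn.gen_frap_series(0.5, 0.1, pre_bleach=100, post_bleach=200)


class TestKymographGenerator:
    def test_static_edge(self):
        k = syn.gen_kymograph(0.0, noise=0.0, seed=1)
        np.testing.assert_allclose(k.image[0], k.image[-1])

    def test_edge_advances_v_dt_per_frame(self):
        k = syn.gen_kymograph(5.0, dt=0.3, px_size=0.5, n_frames=10, noise=0.0)
        pos = k.truth["positions_um"]
        steps = np.diff(pos)
        assert steps[0] == pytest.approx(1.5)  # 3 px/frame

    def test_determinism(self):
        k1 = syn.gen_kymograph(2.0, seed=5)
        k2 = syn.gen_kymograph(2.0, seed=5)
        np.testing.assert_array_equal(k1.image, k2.image)

    def test_edge_leaving_fov_warns(self):
        with pytest.warns(UserWarning, match="field of view"):
            k = syn.gen_kymograph(20.0, n_frames=60)
        assert k.truth["valid_frames"] < 60
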