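"""Synthetic-data generators with attached ground truth.

Every input the analysis pipeline consumes can be generated here with known
generating parameters, so each downstream stage is testable as a parameter
recovery problem:

* TCSPC photon decay histograms (mono- or multi-exponential, Poisson
  counting statistics, 12.5 ns window at 0.08 ns binning),
* FCS autocorrelation curves (3D diffusion + dark states, multiplicative
  per-lag noise),
* photon-counting attachment-site images from a concentration field via
  the forward model ``counts = c * N_A * V_eff * CPP * PT`` with Poisson
  noise,
* FRAP bleach/control trace pairs with shared acquisition-bleaching drift,
* kymographs with a recoiling edge.

All generators are deterministic under a fixed seed, and attach their
generating parameters on the returned object's ``truth`` attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .concentration import AVOGADRO, SATURATION_RATE_HZ, CountImage
from .dynamics import FrapCurve, Kymograph
from .fcs import AutocorrelationCurve, _dark_term, _diffusion_term
from .flim import PhotonDecayHistogram

__all__ = [
    "DecaySpec",
    "FcsSpec",
    "ImageSpec",
    "gen_decay_histogram",
    "gen_fcs_curve",
    "gen_attachment_image",
    "gen_dilution_series",
    "gen_frap_series",
    "gen_kymograph",
    "sensor_decay_spec",
    "band_concentration_field",
]


# ---------------------------------------------------------------------------
# TCSPC decay histograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecaySpec:
    """Specification of a synthetic photon decay.

    ``components`` lists (lifetime_ns, molecule_fraction) pairs; molecule
    fractions must sum to 1. ``total_photons`` is the expected photon
    count; photons distribute over species proportional to
    molecule_fraction * lifetime (photon yield is proportional to
    lifetime). The default 12.5 ns window at 0.08 ns binning gives 156
    bins, the standard 80 MHz TCSPC configuration.

    ``irf_sigma`` optionally blurs the decay with a Gaussian instrument
    response (ns); the default 0 (delta IRF) reflects tail fitting, which
    skips the rise region entirely.
    """

    components: tuple[tuple[float, float], ...]
    total_photons: float
    window: float = 12.5
    bin_width: float = 0.08
    background_rate: float = 0.0
    irf_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        comps = tuple((float(t), float(f)) for t, f in self.components)
        if not comps:
            raise ValueError("need at least one decay component")
        if any(t <= 0 for t, _ in comps):
            raise ValueError("lifetimes must be positive")
        if any(f < 0 for _, f in comps):
            raise ValueError("molecule fractions must be non-negative")
        if abs(sum(f for _, f in comps) - 1.0) > 1e-9:
            raise ValueError("molecule fractions must sum to 1")
        if self.total_photons <= 0:
            raise ValueError("total_photons must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if self.window < self.bin_width:
            raise ValueError("window must hold at least one bin")
        object.__setattr__(self, "components", comps)

    @property
    def n_bins(self) -> int:
        # whole bins tiling the laser period (12.5 ns / 0.08 ns -> 156 bins;
        # the 0.02 ns remainder is not recorded by the TCSPC electronics)
        return int(self.window / self.bin_width + 1e-9)

    @property
    def span(self) -> float:
        """Time covered by whole bins (ns); the decay is truncated here."""
        return self.n_bins * self.bin_width

    @property
    def photon_shares(self) -> np.ndarray:
        """Per-species share of detected photons, proportional to n_i*tau_i."""
        w = np.array([f * t for t, f in self.components])
        return w / w.sum()


def _truncated_exp_bin_probs(tau: float, edges: np.ndarray, window: float):
    """Bin probabilities of an exponential truncated to [0, window)."""
    cdf = -np.expm1(-edges / tau)  # 1 - exp(-t/tau)
    norm = -np.expm1(-window / tau)
    return np.diff(cdf) / norm


def truncated_exp_mean(tau: float, window: float) -> float:
    """Mean arrival time of an exponential truncated to [0, window)."""
    z = window / tau
    return tau - window * np.exp(-z) / (-np.expm1(-z))


def gen_decay_histogram(spec: DecaySpec) -> PhotonDecayHistogram:
    """Generate a Poisson-sampled photon decay histogram.

    Expected bin counts follow the mixture of truncated exponentials with
    photons allocated to species in proportion to molecule_fraction *
    lifetime; a constant background (counts/bin) may be added. Counts are
    Poisson-distributed and reproducible under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    edges = np.arange(spec.n_bins + 1) * spec.bin_width
    centers = edges[:-1] + spec.bin_width / 2.0
    expected = np.zeros(spec.n_bins)
    for (tau, _), share in zip(spec.components, spec.photon_shares):
        expected += spec.total_photons * share * _truncated_exp_bin_probs(
            tau, edges, spec.span
        )
    if spec.irf_sigma > 0:
        # periodic blur: the laser period wraps late photons into early bins
        expected = gaussian_filter1d(
            expected, spec.irf_sigma / spec.bin_width, mode="wrap"
        )
    expected += spec.background_rate
    counts = rng.poisson(expected)
    truth = {
        "components": [list(c) for c in spec.components],
        "total_photons": spec.total_photons,
        "photon_shares": spec.photon_shares.tolist(),
        "background_rate": spec.background_rate,
        "irf_sigma": spec.irf_sigma,
        "seed": spec.seed,
    }
    return PhotonDecayHistogram(
        bin_centers=centers, counts=counts, bin_width=spec.bin_width,
        window=spec.window, truth=truth,
    )


def sensor_decay_spec(
    engaged_fraction: float,
    dark_acceptor_fraction: float,
    total_photons: float,
    tau_nofret: float = 3.0,
    tau_fret: float = 1.5,
    seed: int = 0,
    **kw,
) -> DecaySpec:
    """Decay spec of a tension-sensor sample.

    The no-FRET molecule fraction combines mechanically open sensors
    (``engaged_fraction`` of the fluorescent-acceptor population) and
    sensors with a non-fluorescent acceptor: ``f_noFRET = d + (1 - d) * f``.
    A zero-force control is the special case ``engaged_fraction = 0``.
    """
    if not 0 <= engaged_fraction <= 1:
        raise ValueError("engaged_fraction must be in [0, 1]")
    if not 0 <= dark_acceptor_fraction < 1:
        raise ValueError("dark_acceptor_fraction must be in [0, 1)")
    d = dark_acceptor_fraction
    f_nofret = d + (1.0 - d) * engaged_fraction
    return DecaySpec(
        components=((tau_nofret, f_nofret), (tau_fret, 1.0 - f_nofret)),
        total_photons=total_photons, seed=seed, **kw,
    )


# ---------------------------------------------------------------------------
# FCS curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FcsSpec:
    """Specification of a synthetic autocorrelation curve.

    ``diffusion_times`` lists (tau_diff_s, fraction) pairs (fractions sum
    to 1); ``dark_states`` lists (T, tau_trip_s) pairs with total T < 1.
    ``noise_rel`` is the relative standard deviation of multiplicative
    Gaussian noise per lag (scalar or per-lag array); the default 0.02
    reflects a typical in-vivo 40 s recording. ``cpp`` (Hz per molecule),
    when given, sets the attached mean intensity to ``cpp * n_particles``
    for brightness round trips.
    """

    n_particles: float
    diffusion_times: tuple[tuple[float, float], ...]
    dark_states: tuple[tuple[float, float], ...] = ()
    s: float = 5.0
    lag_grid: np.ndarray | None = None
    noise_rel: float | np.ndarray = 0.02
    cpp: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        comps = tuple((float(t), float(f)) for t, f in self.diffusion_times)
        if not comps or any(t <= 0 for t, _ in comps):
            raise ValueError("diffusion times must be positive and non-empty")
        if abs(sum(f for _, f in comps) - 1.0) > 1e-9:
            raise ValueError("diffusion fractions must sum to 1")
        dark = tuple((float(t), float(tt)) for t, tt in self.dark_states)
        if any(not 0 <= t < 1 for t, _ in dark) or sum(t for t, _ in dark) >= 1:
            raise ValueError("dark fractions must satisfy 0 <= T < 1, sum < 1")
        if any(tt <= 0 for _, tt in dark):
            raise ValueError("dark residence times must be positive")
        lags = (
            np.geomspace(1e-6, 1.0, 150)
            if self.lag_grid is None
            else np.asarray(self.lag_grid, dtype=float)
        )
        if lags.size == 0:
            raise ValueError("lag grid must be non-empty")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        object.__setattr__(self, "diffusion_times", comps)
        object.__setattr__(self, "dark_states", dark)
        object.__setattr__(self, "lag_grid", lags)

    @property
    def model_id(self) -> str | None:
        """Matching fit-model id, when one exists."""
        key = (len(self.diffusion_times), len(self.dark_states))
        return {(1, 1): "T-3D", (2, 1): "T-3D-3D", (2, 2): "T+T+3D+3D"}.get(key)


def gen_fcs_curve(spec: FcsSpec) -> AutocorrelationCurve:
    """Generate a noisy autocorrelation curve from the diffusion model.

    The noiseless curve equals the analytical model G(tau); multiplicative
    Gaussian noise of relative sigma ``noise_rel`` is applied per lag.
    """
    lags = spec.lag_grid
    g = (
        (1.0 / spec.n_particles)
        * _diffusion_term(lags, list(spec.diffusion_times), spec.s)
        * (_dark_term(lags, list(spec.dark_states)) if spec.dark_states else 1.0)
    )
    rng = np.random.default_rng(spec.seed)
    sigma = np.broadcast_to(np.asarray(spec.noise_rel, float), lags.shape)
    noisy = g * (1.0 + sigma * rng.standard_normal(lags.shape))
    intensity = spec.cpp * spec.n_particles if spec.cpp is not None else None
    truth = {
        "n_particles": spec.n_particles,
        "diffusion_times": [list(c) for c in spec.diffusion_times],
        "dark_states": [list(d) for d in spec.dark_states],
        "s": spec.s,
        "noise_rel": float(np.mean(sigma)),
        "cpp": spec.cpp,
        "model_id": spec.model_id,
        "seed": spec.seed,
    }
    return AutocorrelationCurve(
        lags=lags, G=noisy, intensity_mean=intensity, truth=truth
    )


# ---------------------------------------------------------------------------
# photon-count images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSpec:
    """Specification of a synthetic photon-counting image.

    The expected count per pixel follows the forward model
    ``counts = c * N_A * V_eff * CPP * PT`` (c in mol/L). The generator
    refuses concentration fields whose Poisson-mean count rate reaches the
    2 MHz detector cap unless ``allow_saturation`` is set.
    """

    shape: tuple[int, int]
    concentration_field: np.ndarray | float  # uM
    cpp: float = 1400.0  # Hz per molecule
    pixel_dwell: float = 50e-6  # s
    v_eff: float = 0.32e-15  # L
    allow_saturation: bool = False
    seed: int = 0

    def __post_init__(self):
        c = np.broadcast_to(
            np.asarray(self.concentration_field, dtype=float), self.shape
        ).copy()
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        if self.cpp <= 0 or self.pixel_dwell <= 0 or self.v_eff <= 0:
            raise ValueError("cpp, pixel_dwell and v_eff must be positive")
        object.__setattr__(self, "concentration_field", c)

    @property
    def expected_counts(self) -> np.ndarray:
        c_molar = self.concentration_field * 1e-6
        return c_molar * AVOGADRO * self.v_eff * self.cpp * self.pixel_dwell


def gen_attachment_image(spec: ImageSpec) -> CountImage:
    """Generate a Poisson photon-count image from a concentration field."""
    expected = spec.expected_counts
    max_rate = expected.max() / spec.pixel_dwell
    if max_rate >= SATURATION_RATE_HZ and not spec.allow_saturation:
        raise ValueError(
            f"expected count rate {max_rate / 1e6:.2f} MHz reaches the "
            "2 MHz detector cap; lower the concentration/CPP or set "
            "allow_saturation=True"
        )
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(expected)
    truth = {
        "concentration_field_uM": spec.concentration_field,
        "cpp": spec.cpp,
        "pixel_dwell": spec.pixel_dwell,
        "v_eff": spec.v_eff,
        "expected_counts": expected,
        "seed": spec.seed,
    }
    return CountImage(
        counts=counts, pixel_dwell=spec.pixel_dwell, metadata={"synthetic": True},
        truth=truth,
    )


def band_concentration_field(
    shape: tuple[int, int],
    band_uM: float,
    interior_uM: float,
    background_uM: float = 0.0,
    band_rows: tuple[int, int] | None = None,
    interior_rows: tuple[int, int] | None = None,
) -> np.ndarray:
    """Attachment-site-like field: bright band, dim interior, background.

    Emulates a muscle-tendon attachment: a band of high sensor
    concentration (the attachment) on one side of a dimmer muscle
    interior, on zero background. Row ranges default to the middle fifth
    (band) and the lower half (interior).
    """
    rows, _ = shape
    field_ = np.full(shape, float(background_uM))
    if band_rows is None:
        band_rows = (2 * rows // 5, 3 * rows // 5)
    if interior_rows is None:
        interior_rows = (3 * rows // 5, rows)
    field_[interior_rows[0]:interior_rows[1], :] = interior_uM
    field_[band_rows[0]:band_rows[1], :] = band_uM
    return field_


def gen_dilution_series(
    concentrations: list[float], spec: ImageSpec
) -> list[CountImage]:
    """Uniform images at each concentration, sharing CPP/PT/V_eff.

    Emulates a dye dilution series used to verify detector linearity.
    Seeds derive from the spec seed so each image is independent but the
    series is reproducible.
    """
    if len(concentrations) == 0:
        raise ValueError("concentration list must be non-empty")
    images = []
    for i, c in enumerate(concentrations):
        sub = ImageSpec(
            shape=spec.shape, concentration_field=float(c), cpp=spec.cpp,
            pixel_dwell=spec.pixel_dwell, v_eff=spec.v_eff,
            allow_saturation=spec.allow_saturation, seed=spec.seed + 1000 * (i + 1),
        )
        images.append(gen_attachment_image(sub))
    return images


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------


def gen_frap_series(
    mobile_fraction: float,
    k: float,
    pre_bleach: float = 1000.0,
    post_bleach: float = 400.0,
    duration: float = 300.0,
    dt: float = 5.0,
    drift: float = 0.0,
    noise_rel: float = 0.01,
    n_pre: int = 5,
    seed: int = 0,
) -> FrapCurve:
    """Generate a FRAP bleach/control trace pair.

    The bleached-region trace recovers as
    ``post + (pre - post) * M * (1 - exp(-k t))``; both traces share a
    multiplicative acquisition-bleaching drift ``exp(-drift * (t - t0))``
    and carry independent Gaussian noise of relative sigma ``noise_rel``.
    Defaults emulate a 5-min movie at 5 s resolution with 5 pre-bleach
    frames.
    """
    if not 0 <= mobile_fraction <= 1:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if k <= 0:
        raise ValueError("recovery rate k must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not post_bleach < pre_bleach:
        raise ValueError("post_bleach must be below pre_bleach")
    rng = np.random.default_rng(seed)
    t_pre = -dt * np.arange(n_pre, 0, -1)
    t_post = np.arange(0.0, duration + dt / 2, dt)
    times = np.concatenate([t_pre, t_post])

    recovery = post_bleach + (pre_bleach - post_bleach) * mobile_fraction * (
        1.0 - np.exp(-k * t_post)
    )
    bleach = np.concatenate([np.full(n_pre, pre_bleach), recovery])
    control = np.full(times.size, pre_bleach)

    decay = np.exp(-drift * (times - times[0]))
    bleach = bleach * decay
    control = control * decay
    if noise_rel > 0:
        bleach = bleach * (1 + noise_rel * rng.standard_normal(times.size))
        control = control * (1 + noise_rel * rng.standard_normal(times.size))

    truth = {
        "mobile_fraction": mobile_fraction, "k": k,
        "half_time": float(np.log(2.0) / k),
        "pre_bleach": pre_bleach, "post_bleach": post_bleach,
        "drift": drift, "noise_rel": noise_rel, "seed": seed,
    }
    return FrapCurve(
        times=times, bleach_trace=bleach, control_trace=control, truth=truth
    )


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------


def gen_kymograph(
    v: float,
    dt: float = 0.3,
    px_size: float = 0.5,
    n_frames: int = 40,
    n_px: int = 120,
    edge_width: float = 2.0,
    x0: float | None = None,
    cut_frame: int = 0,
    amplitude: float = 100.0,
    baseline: float = 10.0,
    noise: float = 2.0,
    seed: int = 0,
) -> Kymograph:
    """Generate a kymograph with an edge recoiling at constant velocity.

    The edge sits at ``x0`` (um, default 1/4 of the field) until the cut
    and then moves at ``v`` um/s; the cut occurs at the time of the last
    pre-cut frame (``cut_frame - 1``), so the edge has advanced by
    ``v * dt`` at the first post-cut frame — matching how recoil is timed
    from kymographs of ablation movies. Intensity across the edge is a
    logistic step of width ``edge_width`` pixels plus Gaussian noise.

    If the edge leaves the field of view the truth positions are truncated
    with a warning.
    """
    if dt <= 0 or px_size <= 0:
        raise ValueError("dt and px_size must be positive")
    if not 0 <= cut_frame < n_frames:
        raise ValueError("cut_frame must lie inside the movie")
    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = 0.25 * n_px * px_size
    times = np.arange(n_frames) * dt
    t_cut = max(cut_frame - 1, 0) * dt
    positions = x0 + v * np.maximum(0.0, times - t_cut)

    fov = n_px * px_size
    valid = positions < fov - 2 * edge_width * px_size
    if not valid.all():
        warnings.warn(
            "edge leaves the field of view; truth positions truncated",
            stacklevel=2,
        )
    x_px = np.arange(n_px) * px_size
    img = np.empty((n_frames, n_px))
    for i, xe in enumerate(positions):
        img[i] = baseline + amplitude / (
            1.0 + np.exp((x_px - xe) / (edge_width * px_size))
        )
    img += noise * rng.standard_normal(img.shape)

    truth = {
        "v": v, "x0": x0, "cut_frame": cut_frame,
        "positions_um": positions[valid],
        "valid_frames": int(valid.sum()), "seed": seed,
    }
    return Kymograph(image=img, dt=dt, px_size=px_size, truth=truth)
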