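"""Fluorescence correlation spectroscopy models, fitting and calibration.

FCS autocorrelation curves are fitted with 3D-diffusion models carrying one
or two diffusive components and one or two non-fluorescent dark states
(triplet transitions on the 1-20 us scale and photochemical flickering of
yellow fluorescent proteins on the ~200-600 us scale). The fits yield the
number of particles in the detection volume N, the diffusion time tau_diff,
and the dark fractions T1/T2, from which two calibration products follow:

* the effective detection volume ``V_eff = S * (4*pi*D*tau_diff)**1.5``
  from a reference dye of known diffusion coefficient (Rhodamine 6G,
  D = 414 um^2/s), and
* the molecular brightness (counts per particle)
  ``CPP = <I>/N = <I> * G(0) * (1 - T1 - T2)``.

Model ids follow the PyCorrFit naming used in the field: ``T-3D`` (one
dark state, one diffusing component), ``T-3D-3D`` (one dark state, two
components) and ``T+T+3D+3D`` (two dark states, two components).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_IDS",
    "AutocorrelationCurve",
    "FcsFitResults",
    "DetectionVolume",
    "CppResult",
    "AcfModel",
    "acf_model",
    "fit_acf",
    "detection_volume",
    "cpp_from_fit",
    "cpp_with_global_dark_fractions",
    "brightness_ratio",
]

MODEL_IDS = ("T-3D", "T-3D-3D", "T+T+3D+3D")

#: dark-state residence-time windows (s): triplet 1-20 us, flickering 200-600 us
TRIPLET_WINDOW = (1e-6, 20e-6)
FLICKER_WINDOW = (200e-6, 600e-6)


@dataclass(frozen=True)
class AutocorrelationCurve:
    """Measured or synthetic autocorrelation curve G(tau).

    Attributes
    ----------
    lags : ndarray
        Lag times in s, strictly increasing and positive.
    G : ndarray
        Correlation amplitudes (dimensionless, baseline-subtracted).
    intensity_mean : float or None
        Mean detector count rate <I> in Hz, needed for brightness.
    duration : float or None
        Recording duration in s.
    truth : dict or None
        Generating parameters when synthetic.
    """

    lags: np.ndarray
    G: np.ndarray
    intensity_mean: float | None = None
    duration: float | None = None
    truth: dict | None = None

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        G = np.asarray(self.G, dtype=float)
        if lags.ndim != 1 or lags.shape != G.shape:
            raise ValueError("lags and G must be 1-D arrays of equal length")
        if lags.size == 0:
            raise ValueError("lag grid must be non-empty")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(G)):
            raise ValueError("G must be finite")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "G", G)

    @classmethod
    def from_csv(cls, path, *, intensity_mean=None) -> "AutocorrelationCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            lags=df.iloc[:, 0].to_numpy(float),
            G=df.iloc[:, 1].to_numpy(float),
            intensity_mean=intensity_mean,
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"lag_s": self.lags, "G": self.G}).to_csv(path, index=False)


@dataclass(frozen=True)
class DetectionVolume:
    """Effective confocal detection volume from a reference-dye fit."""

    v_eff: float  # L
    d_ref: float  # um^2/s
    tau_diff_ref: float  # s
    s: float

    @property
    def v_eff_fl(self) -> float:
        return self.v_eff * 1e15


@dataclass(frozen=True)
class CppResult:
    """Molecular brightness (counts per particle)."""

    cpp: float  # Hz per molecule
    intensity_mean: float  # Hz
    g0: float
    t1: float
    t2: float


# ---------------------------------------------------------------------------
# model function
# ---------------------------------------------------------------------------


def _diffusion_term(lags, components, s):
    """Normalised 3D diffusion sum: Sum_i F_i/[(1+t/td)(1+t/(S^2 td))^0.5]."""
    out = np.zeros_like(lags, dtype=float)
    for tau_d, frac in components:
        if tau_d <= 0:
            raise ValueError("diffusion times must be positive")
        out += frac / ((1.0 + lags / tau_d) * np.sqrt(1.0 + lags / (s**2 * tau_d)))
    return out


def _dark_term(lags, dark):
    """Dark-state factor (1 - Sum T + Sum T_k e^{-t/tau_k}) / (1 - Sum T).

    The additive convention keeps the zero-lag identity
    G(0) * (1 - Sum T) * N = 1 exact for any number of dark states, which is
    what makes CPP = <I>/N = <I>*G(0)*(1-T1-T2) an identity.
    """
    t_sum = sum(t for t, _ in dark)
    if t_sum >= 1:
        raise ValueError("total dark fraction must be < 1")
    num = np.full_like(lags, 1.0 - t_sum, dtype=float)
    for t_frac, tau_t in dark:
        if not 0 <= t_frac < 1:
            raise ValueError("dark fractions must satisfy 0 <= T < 1")
        if tau_t <= 0:
            raise ValueError("dark-state residence times must be positive")
        num += t_frac * np.exp(-lags / tau_t)
    return num / (1.0 - t_sum)


def acf_model(
    model_id: str,
    params: dict,
    lags: np.ndarray | Sequence[float],
) -> np.ndarray:
    """Evaluate G(tau) for one of the supported model forms.

    Parameters
    ----------
    model_id : {"T-3D", "T-3D-3D", "T+T+3D+3D"}
    params : dict
        Keys: ``n`` (particles in focus), ``components`` (list of
        ``(tau_diff_s, fraction)``, fractions summing to 1), ``dark``
        (list of ``(T, tau_trip_s)``), ``s`` (axis ratio, default 5).
    lags : array of lag times in s.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; use one of {MODEL_IDS}")
    lags = np.asarray(lags, dtype=float)
    n = params["n"]
    if n <= 0:
        raise ValueError("n must be positive")
    components = list(params["components"])
    dark = list(params.get("dark", []))
    s = float(params.get("s", 5.0))
    n_comp = {"T-3D": 1, "T-3D-3D": 2, "T+T+3D+3D": 2}[model_id]
    n_dark = {"T-3D": 1, "T-3D-3D": 1, "T+T+3D+3D": 2}[model_id]
    if len(components) != n_comp:
        raise ValueError(f"{model_id} requires {n_comp} diffusive component(s)")
    if len(dark) != n_dark:
        raise ValueError(f"{model_id} requires {n_dark} dark state(s)")
    fsum = sum(f for _, f in components)
    if abs(fsum - 1.0) > 1e-6:
        raise ValueError("component fractions must sum to 1")
    return (1.0 / n) * _diffusion_term(lags, components, s) * _dark_term(lags, dark)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FcsFitResults:
    """Fitted FCS parameters.

    ``components`` are sorted fastest-first; by convention only the first
    diffusion time is physically interpreted (protein diffusion), a second
    component being a descriptive term for slow long-tail behaviour in the
    crowded intracellular environment.
    """

    model_id: str
    n: float
    components: list[tuple[float, float]]  # (tau_diff_s, fraction)
    dark: list[tuple[float, float]]  # (T, tau_trip_s)
    s: float
    residual_rms: float
    converged: bool
    intensity_mean: float | None = None
    perr: dict | None = field(default=None, repr=False)
    curve: AutocorrelationCurve | None = field(default=None, repr=False)

    @property
    def tau_diff(self) -> float:
        """Primary (fastest) diffusion time in s."""
        return self.components[0][0]

    @property
    def total_dark_fraction(self) -> float:
        return sum(t for t, _ in self.dark)

    def g0(self) -> float:
        """Full-model zero-lag amplitude 1/(N*(1-Sum T))."""
        return 1.0 / (self.n * (1.0 - self.total_dark_fraction))

    def g_model(self, lags) -> np.ndarray:
        return acf_model(
            self.model_id,
            {"n": self.n, "components": self.components, "dark": self.dark,
             "s": self.s},
            lags,
        )

    def summary(self) -> str:
        lines = [
            f"FCS fit ({self.model_id}, S = {self.s:g} fixed)",
            "-" * 40,
            f"N (particles in focus) : {self.n:.3f}",
        ]
        for i, (td, f) in enumerate(self.components, 1):
            lines.append(
                f"component {i}           : tau_diff = {td * 1e6:.1f} us, "
                f"fraction = {f:.3f}"
            )
        for i, (t, tt) in enumerate(self.dark, 1):
            lines.append(
                f"dark state {i}          : T = {t:.3f}, tau = {tt * 1e6:.1f} us"
            )
        lines.append(f"G(0)                   : {self.g0():.4g}")
        lines.append(f"residual rms           : {self.residual_rms:.3g}")
        lines.append(f"converged              : {self.converged}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.curve
        if c is not None:
            ax.semilogx(c.lags, c.G, ".", ms=3, label="data")
            ax.semilogx(c.lags, self.g_model(c.lags), "-", label="fit")
        ax.set_xlabel("lag time (s)")
        ax.set_ylabel("G")
        ax.legend()
        return ax


class AcfModel:
    """Nonlinear least-squares model for an autocorrelation curve.

    The axis ratio S of the detection volume is fixed (default 5). For
    two-component fits the lag grid is restricted to lags > ``min_lag``
    (default 1 us), matching how intracellular curves are fitted.

    Parameters
    ----------
    curve : AutocorrelationCurve
    model_id : {"T-3D", "T-3D-3D", "T+T+3D+3D"}
    s : float
        Detection-volume axis ratio, fixed during the fit.
    min_lag : float or None
        Discard lags at or below this value (s). Default 1 us for the
        two-component models, none for T-3D.
    weights : ndarray, "relative", or None
        Optional per-lag sigma for weighted least squares (default
        unweighted). ``"relative"`` uses sigma proportional to \|G\|,
        appropriate when the per-lag scatter is a constant fraction of the
        amplitude.
    """

    def __init__(self, curve: AutocorrelationCurve, model_id: str = "T-3D",
                 s: float = 5.0, min_lag: float | None = None,
                 weights: np.ndarray | str | None = None):
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {model_id!r}")
        self.curve = curve
        self.model_id = model_id
        self.s = float(s)
        if min_lag is None:
            min_lag = 1e-6 if model_id in ("T-3D-3D", "T+T+3D+3D") else 0.0
        self.min_lag = float(min_lag)
        if isinstance(weights, str):
            if weights != "relative":
                raise ValueError("weights must be an array, 'relative' or None")
            gabs = np.abs(curve.G)
            weights = np.maximum(gabs, 1e-3 * gabs.max())
        self.weights = weights

    # parameter vectors, bounds and starts per model ----------------------
    def _pack_spec(self, lags, G):
        g0 = float(G[0])
        n0 = 1.0 / g0 if g0 > 0 else 10.0
        # lag where G first drops to half its initial value
        below = np.nonzero(G <= 0.5 * g0)[0]
        td0 = float(lags[below[0]]) if below.size else float(lags[lags.size // 2])
        td0 = max(td0, 2e-6)
        big = lags[-1]
        if self.model_id == "T-3D":
            names = ["n", "td1", "t1", "tt1"]
            p0 = [n0, td0, 0.1, np.sqrt(np.prod(TRIPLET_WINDOW))]
            lo = [1e-6, 1e-7, 0.0, TRIPLET_WINDOW[0]]
            hi = [1e9, big, 0.9, TRIPLET_WINDOW[1]]
        elif self.model_id == "T-3D-3D":
            names = ["n", "td1", "td2", "f1", "t1", "tt1"]
            p0 = [n0, td0, 10 * td0, 0.7, 0.1, np.sqrt(np.prod(TRIPLET_WINDOW))]
            lo = [1e-6, 1e-7, 1e-7, 0.0, 0.0, TRIPLET_WINDOW[0]]
            hi = [1e9, big, big, 1.0, 0.9, TRIPLET_WINDOW[1]]
        else:  # T+T+3D+3D
            names = ["n", "td1", "td2", "f1", "t1", "tt1", "t2", "tt2"]
            p0 = [n0, td0, 10 * td0, 0.7, 0.1,
                  np.sqrt(np.prod(TRIPLET_WINDOW)), 0.1,
                  np.sqrt(np.prod(FLICKER_WINDOW))]
            lo = [1e-6, 1e-7, 1e-7, 0.0, 0.0, TRIPLET_WINDOW[0], 0.0,
                  FLICKER_WINDOW[0]]
            hi = [1e9, big, big, 1.0, 0.9, TRIPLET_WINDOW[1], 0.9,
                  FLICKER_WINDOW[1]]
        return names, np.array(p0), np.array(lo), np.array(hi)

    def _unpack(self, theta):
        if self.model_id == "T-3D":
            n, td1, t1, tt1 = theta
            comps = [(td1, 1.0)]
            dark = [(t1, tt1)]
        elif self.model_id == "T-3D-3D":
            n, td1, td2, f1, t1, tt1 = theta
            comps = [(td1, f1), (td2, 1.0 - f1)]
            dark = [(t1, tt1)]
        else:
            n, td1, td2, f1, t1, tt1, t2, tt2 = theta
            comps = [(td1, f1), (td2, 1.0 - f1)]
            dark = [(t1, tt1), (t2, tt2)]
        return n, comps, dark

    def _eval(self, theta, lags):
        n, comps, dark = self._unpack(theta)
        if sum(t for t, _ in dark) >= 0.999:
            return np.full_like(lags, np.inf)
        return acf_model(
            self.model_id,
            {"n": n, "components": comps, "dark": dark, "s": self.s},
            lags,
        )

    def fit(self) -> FcsFitResults:
        c = self.curve
        sel = c.lags > self.min_lag
        lags, G = c.lags[sel], c.G[sel]
        if lags.size < 20:
            raise ValueError("need at least 20 lag points above min_lag")
        names, p0, lo, hi = self._pack_spec(lags, G)
        p0 = np.clip(p0, lo, hi)
        w = self.weights[sel] if self.weights is not None else np.ones_like(G)

        def resid(theta):
            return (self._eval(theta, lags) - G) / w

        sol = optimize.least_squares(
            resid, p0, bounds=(lo, hi), method="trf", max_nfev=20000
        )
        converged = bool(sol.success)
        if not converged:
            logger.warning("FCS fit did not converge: %s", sol.message)
        n, comps, dark = self._unpack(sol.x)
        comps = sorted(comps, key=lambda cf: cf[0])  # fastest first
        rms = float(np.sqrt(np.mean((self._eval(sol.x, lags) - G) ** 2)))

        perr = None
        try:
            jac = sol.jac
            dof = max(lags.size - sol.x.size, 1)
            cov = np.linalg.pinv(jac.T @ jac) * (2 * sol.cost / dof)
            perr = dict(zip(names, np.sqrt(np.abs(np.diag(cov)))))
        except Exception:  # noqa: BLE001 - diagnostics only
            pass

        return FcsFitResults(
            model_id=self.model_id, n=float(n), components=comps,
            dark=[(float(t), float(tt)) for t, tt in dark], s=self.s,
            residual_rms=rms, converged=converged,
            intensity_mean=c.intensity_mean, perr=perr, curve=c,
        )


def fit_acf(
    curve: AutocorrelationCurve,
    model_id: str = "T-3D",
    s: float = 5.0,
    min_lag: float | None = None,
    weights: np.ndarray | str | None = None,
) -> FcsFitResults:
    """Fit an autocorrelation curve; see :class:`AcfModel`."""
    return AcfModel(curve, model_id, s=s, min_lag=min_lag, weights=weights).fit()


# ---------------------------------------------------------------------------
# calibration products
# ---------------------------------------------------------------------------

#: published diffusion coefficient of Rhodamine 6G in water (um^2/s)
RHODAMINE_6G_D = 414.0


def detection_volume(d: float, tau_diff: float, s: float = 5.0) -> DetectionVolume:
    """Effective detection volume V_eff = S * (4*pi*D*tau_diff)**(3/2).

    Parameters
    ----------
    d : float
        Diffusion coefficient of the calibration dye in um^2/s
        (Rhodamine 6G: 414 um^2/s).
    tau_diff : float
        Fitted diffusion time of the dye in s.
    s : float
        Axis ratio of the (ellipsoidal) detection volume.

    Returns
    -------
    DetectionVolume with v_eff in litres (1 um^3 = 1 fL = 1e-15 L).
    """
    if d <= 0 or tau_diff <= 0 or s <= 0:
        raise ValueError("d, tau_diff and s must be positive")
    v_um3 = s * (4.0 * np.pi * d * tau_diff) ** 1.5
    return DetectionVolume(v_eff=v_um3 * 1e-15, d_ref=d, tau_diff_ref=tau_diff, s=s)


def cpp_from_fit(intensity_mean: float, fit: FcsFitResults) -> CppResult:
    """Molecular brightness CPP = <I> * G(0) * (1 - T1 - T2) = <I>/N.

    G(0) is the full-model zero-lag amplitude 1/(N*(1-T1-T2)), so the dark
    correction cancels exactly and CPP equals the mean count rate per
    fitted particle.
    """
    t_total = fit.total_dark_fraction
    if t_total >= 1:
        raise ValueError("total dark fraction must be < 1")
    g0 = fit.g0()
    if g0 <= 0:
        raise ValueError("G(0) must be positive")
    cpp = intensity_mean * g0 * (1.0 - t_total)
    t1 = fit.dark[0][0] if fit.dark else 0.0
    t2 = fit.dark[1][0] if len(fit.dark) > 1 else 0.0
    return CppResult(cpp=float(cpp), intensity_mean=float(intensity_mean),
                     g0=float(g0), t1=float(t1), t2=float(t2))


def cpp_with_global_dark_fractions(
    intensity_mean: float, g0: float, t1_avg: float, t2_avg: float
) -> CppResult:
    """Brightness with globally averaged dark fractions (free-fluorophore case).

    When flickering cannot be separated from diffusion (fast free
    fluorophore), the dark fractions are borrowed as averages from matched
    sensor-protein measurements at the same excitation power:
    ``CPP = <I> * <G(0)> * (1 - <T1> - <T2>)``.
    """
    if t1_avg + t2_avg >= 1:
        raise ValueError("averaged dark fractions must sum below 1")
    if g0 <= 0:
        raise ValueError("G(0) must be positive")
    cpp = intensity_mean * g0 * (1.0 - t1_avg - t2_avg)
    return CppResult(cpp=float(cpp), intensity_mean=float(intensity_mean),
                     g0=float(g0), t1=float(t1_avg), t2=float(t2_avg))


def brightness_ratio(
    cpp_sample: Sequence[float], cpp_reference: Sequence[float]
) -> tuple[float, float]:
    """Median brightness ratio sample/reference, with a dispersion estimate.

    A ratio near 1 indicates the sample is monomeric relative to the
    reference fluorophore; near 2, dimeric. Returns ``(ratio, mad_ratio)``
    where the dispersion is the median absolute deviation of
    sample/median(reference).
    """
    sample = np.asarray(cpp_sample, dtype=float)
    ref = np.asarray(cpp_reference, dtype=float)
    if sample.size == 0 or ref.size == 0:
        raise ValueError("both CPP lists must be non-empty")
    ref_med = float(np.median(ref))
    if ref_med == 0:
        raise ValueError("reference median brightness is zero")
    ratios = sample / ref_med
    return float(np.median(ratios)), float(np.median(np.abs(ratios - np.median(ratios))))
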