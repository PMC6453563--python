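"""FLIM-FRET lifetime analysis for molecular tension sensors.

This module turns TCSPC photon-arrival histograms into donor fluorescence
lifetimes, FRET efficiencies and, via fixed-lifetime biexponential
decomposition, the fraction of mechanically engaged (open) sensor molecules.

The analysis chain mirrors standard tension-sensor FLIM practice:

1. segment the bright target structure (attachment sites) inside a
   hand-drawn ROI with three-class multi-Otsu thresholding,
2. pool all photons inside the mask into one decay histogram per sample,
3. fit the decay tail with a monoexponential ``A*exp(-t/tau)`` to obtain
   the donor lifetime ``tau`` (quality-filtered on its relative standard
   error),
4. compute the FRET efficiency ``E = 1 - tau_DA/tau_D``,
5. decompose sensor decays into a no-FRET (open, lifetime ~ donor alone)
   and a FRET (closed) component with both lifetimes fixed, convert photon
   fractions to molecule fractions (photon yield is proportional to
   lifetime), and
6. normalise against a zero-force control carrying the same dark-acceptor
   fraction to obtain the engaged fraction N_open/N_total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.draw import polygon2mask
from skimage.filters import median as median_filter
from skimage.filters import threshold_multiotsu
from skimage.morphology import footprint_rectangle

logger = logging.getLogger(__name__)

__all__ = [
    "PhotonDecayHistogram",
    "RegionMask",
    "LifetimeFitResults",
    "BiexpFitResults",
    "FretResult",
    "EngagedFractionResult",
    "MonoExpTailModel",
    "BiexpFixedModel",
    "build_mask",
    "fit_monoexponential_tail",
    "fret_efficiency",
    "qc_filter",
    "calibrate_reference_lifetimes",
    "fit_biexponential_fixed",
    "engaged_fraction",
    "intermolecular_fret_control",
    "CalibrationError",
    "DegenerateThresholdError",
]


class CalibrationError(RuntimeError):
    """Raised when reference-lifetime calibration cannot be performed."""


class DegenerateThresholdError(ValueError):
    """Raised when an ROI has too few intensity levels for 3-class Otsu."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhotonDecayHistogram:
    """Time-binned donor photon counts within one laser period.

    Parameters
    ----------
    bin_centers : ndarray
        Bin centre times in ns, uniformly spaced.
    counts : ndarray
        Non-negative photon counts per bin.
    bin_width : float
        Bin width in ns (0.08 ns for the standard TCSPC configuration).
    window : float
        Laser period / acquisition window in ns (12.5 ns at 80 MHz).
    truth : dict or None
        Ground-truth generating parameters when the histogram is synthetic.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    bin_width: float
    window: float
    truth: dict | None = None

    def __post_init__(self):
        bc = np.asarray(self.bin_centers, dtype=float)
        ct = np.asarray(self.counts)
        if bc.shape != ct.shape:
            raise ValueError("bin_centers and counts must have equal length")
        if np.any(ct < 0):
            raise ValueError("counts must be non-negative")
        diffs = np.diff(bc)
        if bc.size > 1 and not np.allclose(diffs, self.bin_width, rtol=1e-6):
            raise ValueError("bins must be uniform with spacing bin_width")
        n_expected = int(self.window / self.bin_width + 1e-9)
        if bc.size != n_expected:
            raise ValueError(
                f"expected {n_expected} whole bins in the window, got {bc.size}"
            )
        object.__setattr__(self, "bin_centers", bc)
        object.__setattr__(self, "counts", ct)

    @property
    def n_photons(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_csv(cls, path, *, window: float | None = None) -> "PhotonDecayHistogram":
        """Read a two-column CSV (bin_center_ns, counts)."""
        import pandas as pd

        df = pd.read_csv(path)
        bc = df.iloc[:, 0].to_numpy(dtype=float)
        counts = df.iloc[:, 1].to_numpy()
        bw = float(np.median(np.diff(bc)))
        if window is None:
            window = bc.size * bw
        return cls(bin_centers=bc, counts=counts, bin_width=bw, window=window)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"bin_center_ns": self.bin_centers, "counts": self.counts}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class RegionMask:
    """Boolean segmentation mask restricted to an ROI polygon."""

    mask: np.ndarray
    roi_polygon: np.ndarray | None
    n_pixels: int

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class FretResult:
    """FRET efficiency from donor lifetimes: E = 1 - tau_DA / tau_D."""

    efficiency: float
    tau_DA: float
    tau_D: float


@dataclass(frozen=True)
class EngagedFractionResult:
    """Engaged sensor fraction after zero-force-control normalisation."""

    f_engaged: float
    f_raw_TS: float
    f_raw_control: float


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------


def build_mask(image, roi: Sequence[Sequence[float]] | None = None) -> RegionMask:
    """Segment the brightest structure inside an ROI.

    The ROI pixels are median-filtered (3x3), thresholded into three classes
    with multi-Otsu, and the brightest class (holes filled) becomes the mask.

    Parameters
    ----------
    image : CountImage or ndarray
        Photon-count image.
    roi : sequence of (row, col) vertices, optional
        Closed polygon in pixel coordinates. ``None`` uses the whole image.

    Returns
    -------
    RegionMask
    """
    counts = np.asarray(getattr(image, "counts", image))
    if counts.ndim != 2:
        raise ValueError("image must be 2-D")
    if roi is None:
        roi_mask = np.ones(counts.shape, dtype=bool)
        roi_poly = None
    else:
        roi_poly = np.asarray(roi, dtype=float)
        if roi_poly.ndim != 2 or roi_poly.shape[0] < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")
        roi_mask = polygon2mask(counts.shape, roi_poly)
        if not roi_mask.any():
            raise ValueError("ROI polygon lies outside the image")

    smoothed = median_filter(
        counts.astype(float), footprint_rectangle((3, 3))
    )
    vals = smoothed[roi_mask]
    if np.unique(vals).size < 3:
        raise DegenerateThresholdError(
            "ROI has fewer than 3 distinct intensity levels; cannot apply "
            "3-class multi-Otsu thresholding"
        )
    try:
        thresholds = threshold_multiotsu(vals, classes=3)
    except ValueError as exc:  # pragma: no cover - skimage internal guard
        raise DegenerateThresholdError(str(exc)) from exc

    bright = np.zeros(counts.shape, dtype=bool)
    bright[roi_mask] = smoothed[roi_mask] > thresholds[-1]
    bright = ndimage.binary_fill_holes(bright)
    bright &= roi_mask
    return RegionMask(mask=bright, roi_polygon=roi_poly, n_pixels=int(bright.sum()))


# ---------------------------------------------------------------------------
# monoexponential tail fit
# ---------------------------------------------------------------------------


def _default_tail_start(hist: PhotonDecayHistogram) -> float:
    """Start of the decay tail: peak bin + 0.5 ns (skips the rise/IRF)."""
    peak = hist.bin_centers[int(np.argmax(hist.counts))]
    return float(peak + 0.5)


@dataclass
class LifetimeFitResults:
    """Results of a monoexponential tail fit.

    Attributes
    ----------
    tau : float
        Fluorescence lifetime in ns.
    amplitude : float
        Decay amplitude (counts/bin at t = 0).
    background : float
        Fitted constant background (counts/bin); 0 when not fitted.
    rel_error : float
        Relative standard error of tau (sigma_tau / tau) from the fit
        covariance.
    tail_start : float
        First time (ns) included in the fit.
    converged : bool
    at_bounds : bool
        True when tau ended on a fit bound (result untrustworthy).
    n_points : int
    model : MonoExpTailModel
    """

    tau: float
    amplitude: float
    background: float
    rel_error: float
    tail_start: float
    converged: bool
    at_bounds: bool = False
    n_points: int = 0
    model: "MonoExpTailModel | None" = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            "Monoexponential tail fit",
            "------------------------",
            f"tau            : {self.tau:.4f} ns",
            f"amplitude      : {self.amplitude:.1f} counts/bin",
            f"background     : {self.background:.2f} counts/bin",
            f"rel. std error : {100 * self.rel_error:.2f} %",
            f"tail start     : {self.tail_start:.2f} ns",
            f"n points       : {self.n_points}",
            f"converged      : {self.converged}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay data and fit on a log-count axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.model.hist
        ax.semilogy(h.bin_centers, np.maximum(h.counts, 0.5), ".", ms=3,
                    label="data")
        t = h.bin_centers[h.bin_centers >= self.tail_start]
        ax.semilogy(
            t,
            self.amplitude * np.exp(-t / self.tau) + self.background,
            "-",
            label=f"tau = {self.tau:.2f} ns",
        )
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("photons / bin")
        ax.legend()
        return ax


class MonoExpTailModel:
    """Weighted monoexponential model for the tail of a photon decay.

    Fits ``A * exp(-t/tau) (+ b)`` to all bins at or after ``tail_start``
    with Poisson weights ``1/max(count, 1)``.

    Parameters
    ----------
    hist : PhotonDecayHistogram
    tail_start : float or None
        Start of the fitted tail in ns; default is the histogram peak
        position plus 0.5 ns.
    fit_background : bool
        Include a constant background term ``b``.
    """

    def __init__(self, hist: PhotonDecayHistogram, tail_start: float | None = None,
                 fit_background: bool = False):
        self.hist = hist
        self.tail_start = (
            _default_tail_start(hist) if tail_start is None else float(tail_start)
        )
        self.fit_background = bool(fit_background)

    def _tail(self):
        sel = self.hist.bin_centers >= self.tail_start
        return self.hist.bin_centers[sel], self.hist.counts[sel].astype(float)

    def fit(self, tau_bounds: tuple[float, float] = (1e-3, 100.0)) -> LifetimeFitResults:
        t, y = self._tail()
        failed = LifetimeFitResults(
            tau=np.nan, amplitude=np.nan, background=0.0, rel_error=np.inf,
            tail_start=self.tail_start, converged=False, n_points=int(t.size),
            model=self,
        )
        if t.size < (3 if self.fit_background else 2) or y.sum() <= 0:
            return failed

        sigma = np.sqrt(np.maximum(y, 1.0))
        # log-linear start values from the positive counts
        pos = y > 0
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        tau0 = float(np.clip(-1.0 / slope if slope < 0 else 3.0, *tau_bounds))
        a0 = float(np.exp(intercept))

        if self.fit_background:
            def model(tt, a, tau, b):
                return a * np.exp(-tt / tau) + b

            p0 = [a0, tau0, max(y.min(), 0.0)]
            lo = [0.0, tau_bounds[0], 0.0]
            hi = [np.inf, tau_bounds[1], np.inf]
        else:
            def model(tt, a, tau):
                return a * np.exp(-tt / tau)

            p0 = [a0, tau0]
            lo = [0.0, tau_bounds[0]]
            hi = [np.inf, tau_bounds[1]]

        try:
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=p0, sigma=sigma, absolute_sigma=True,
                bounds=(lo, hi), maxfev=10000,
            )
            # second pass with model-based Poisson variances: weighting by
            # observed counts biases tau low (upward fluctuations get
            # underweighted); the expected counts are the correct variance
            sigma2 = np.sqrt(np.maximum(model(t, *popt), 1.0))
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=popt, sigma=sigma2, absolute_sigma=True,
                bounds=(lo, hi), maxfev=10000,
            )
        except (RuntimeError, ValueError):
            return failed

        tau = float(popt[1])
        var_tau = float(pcov[1, 1])
        rel_error = np.sqrt(var_tau) / tau if np.isfinite(var_tau) and tau > 0 else np.inf
        at_bounds = bool(
            np.isclose(tau, tau_bounds[0], rtol=1e-3)
            or np.isclose(tau, tau_bounds[1], rtol=1e-3)
        )
        if at_bounds:
            logger.warning("lifetime fit hit bound: tau=%.3g ns", tau)
        return LifetimeFitResults(
            tau=tau,
            amplitude=float(popt[0]),
            background=float(popt[2]) if self.fit_background else 0.0,
            rel_error=float(rel_error),
            tail_start=self.tail_start,
            converged=True,
            at_bounds=at_bounds,
            n_points=int(t.size),
            model=self,
        )


def fit_monoexponential_tail(
    hist: PhotonDecayHistogram,
    tail_start: float | None = None,
    fit_background: bool = False,
) -> LifetimeFitResults:
    """Fit the decay tail with a monoexponential; see :class:`MonoExpTailModel`."""
    return MonoExpTailModel(hist, tail_start, fit_background).fit()


# ---------------------------------------------------------------------------
# FRET efficiency and QC
# ---------------------------------------------------------------------------


def fret_efficiency(tau_DA: float, tau_D: float) -> FretResult:
    """FRET efficiency from donor lifetimes, E = 1 - tau_DA/tau_D.

    tau_DA is the donor lifetime in presence of the acceptor, tau_D the
    lifetime of the donor alone (median of donor-only controls under the
    same conditions).
    """
    if tau_D <= 0:
        raise ValueError("tau_D must be positive")
    if tau_DA <= 0:
        raise ValueError("tau_DA must be positive")
    return FretResult(efficiency=1.0 - tau_DA / tau_D, tau_DA=tau_DA, tau_D=tau_D)


def qc_filter(
    fits: Sequence[LifetimeFitResults], max_rel_error: float = 0.05
) -> list[LifetimeFitResults]:
    """Drop fits whose lifetime relative standard error exceeds the cut-off.

    The default 5% cut-off is used for bright samples; dim samples
    conventionally use 10%. Non-converged fits are always dropped.
    """
    if max_rel_error <= 0:
        raise ValueError("max_rel_error must be positive")
    kept = [f for f in fits if f.converged and f.rel_error <= max_rel_error]
    n_excluded = len(fits) - len(kept)
    if n_excluded:
        logger.info(
            "qc_filter: excluded %d/%d fits (rel_error > %.0f%% or not converged)",
            n_excluded, len(fits), 100 * max_rel_error,
        )
    return kept


# ---------------------------------------------------------------------------
# biexponential decomposition with fixed lifetimes
# ---------------------------------------------------------------------------


@dataclass
class BiexpFitResults:
    """Fixed-lifetime biexponential decomposition of a sensor decay.

    The decay is modelled as ``A1*exp(-t/tau_noFRET) + A2*exp(-t/tau_FRET)``.
    ``photon_fraction_noFRET`` (p) is the share of detected photons from the
    no-FRET species, ``A1*tau1 / (A1*tau1 + A2*tau2)``. Because FRET
    quenches donor emission in proportion to the lifetime, the *molecule*
    fraction of the no-FRET species is

        f_raw = (p/tau1) / (p/tau1 + (1-p)/tau2) = A1 / (A1 + A2).
    """

    tau_noFRET: float
    tau_FRET: float
    photon_fraction_noFRET: float
    molecule_fraction_noFRET: float
    rel_error: float
    amplitudes: tuple[float, float]
    converged: bool
    clipped: bool = False
    model: "BiexpFixedModel | None" = field(default=None, repr=False)

    @property
    def f_raw(self) -> float:
        return self.molecule_fraction_noFRET

    def summary(self) -> str:
        lines = [
            "Fixed-lifetime biexponential fit",
            "--------------------------------",
            f"tau_noFRET (fixed)      : {self.tau_noFRET:.3f} ns",
            f"tau_FRET (fixed)        : {self.tau_FRET:.3f} ns",
            f"photon fraction noFRET  : {self.photon_fraction_noFRET:.4f}",
            f"molecule fraction noFRET: {self.molecule_fraction_noFRET:.4f}",
            f"rel. std error (f_raw)  : {100 * self.rel_error:.2f} %",
            f"converged               : {self.converged}"
            + ("  [amplitude clipped at 0]" if self.clipped else ""),
        ]
        return "\n".join(lines)


class BiexpFixedModel:
    """Biexponential decay model with both lifetimes fixed.

    With the lifetimes fixed, the model is linear in the amplitudes, so the
    weighted least-squares solution is closed-form; negative amplitudes are
    refit with a non-negativity constraint and flagged.

    Parameters
    ----------
    hist : PhotonDecayHistogram
    tau_noFRET, tau_FRET : float
        Fixed lifetimes in ns, ``tau_FRET < tau_noFRET``.
    tail_start : float or None
        Default: histogram peak + 0.5 ns.
    """

    def __init__(self, hist: PhotonDecayHistogram, tau_noFRET: float,
                 tau_FRET: float, tail_start: float | None = None):
        if not tau_FRET < tau_noFRET:
            raise ValueError("tau_FRET must be smaller than tau_noFRET")
        if tau_FRET <= 0:
            raise ValueError("lifetimes must be positive")
        self.hist = hist
        self.tau_noFRET = float(tau_noFRET)
        self.tau_FRET = float(tau_FRET)
        self.tail_start = (
            _default_tail_start(hist) if tail_start is None else float(tail_start)
        )

    def fit(self) -> BiexpFitResults:
        h = self.hist
        sel = h.bin_centers >= self.tail_start
        t = h.bin_centers[sel]
        y = h.counts[sel].astype(float)
        if t.size < 2 or y.sum() <= 0:
            return BiexpFitResults(
                tau_noFRET=self.tau_noFRET, tau_FRET=self.tau_FRET,
                photon_fraction_noFRET=np.nan, molecule_fraction_noFRET=np.nan,
                rel_error=np.inf, amplitudes=(np.nan, np.nan), converged=False,
                model=self,
            )

        w = 1.0 / np.sqrt(np.maximum(y, 1.0))  # sqrt of Poisson weights
        X = np.column_stack(
            [np.exp(-t / self.tau_noFRET), np.exp(-t / self.tau_FRET)]
        )
        Xw = X * w[:, None]
        yw = y * w
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        clipped = False
        if np.any(coef < 0):
            coef, _ = optimize.nnls(Xw, yw)
            clipped = True
            logger.warning("biexponential fit: negative amplitude clipped at 0")

        a1, a2 = float(coef[0]), float(coef[1])
        total = a1 + a2
        if total <= 0:
            f_raw = np.nan
            p = np.nan
            rel = np.inf
            converged = False
        else:
            f_raw = a1 / total
            p1 = a1 * self.tau_noFRET
            p2 = a2 * self.tau_FRET
            p = p1 / (p1 + p2)
            # delta-method SE of f_raw from the WLS covariance
            try:
                cov = np.linalg.inv(Xw.T @ Xw)
                grad = np.array([a2, -a1]) / total**2
                se = float(np.sqrt(grad @ cov @ grad))
            except np.linalg.LinAlgError:
                se = np.inf
            rel = se / f_raw if f_raw > 0 else np.inf
            converged = True
        return BiexpFitResults(
            tau_noFRET=self.tau_noFRET, tau_FRET=self.tau_FRET,
            photon_fraction_noFRET=float(p), molecule_fraction_noFRET=float(f_raw),
            rel_error=float(rel), amplitudes=(a1, a2), converged=converged,
            clipped=clipped, model=self,
        )


def fit_biexponential_fixed(
    hist: PhotonDecayHistogram,
    tau_noFRET: float,
    tau_FRET: float,
    tail_start: float | None = None,
) -> BiexpFitResults:
    """Decompose a decay into fixed no-FRET/FRET components; see
    :class:`BiexpFixedModel`."""
    return BiexpFixedModel(hist, tau_noFRET, tau_FRET, tail_start).fit()


# ---------------------------------------------------------------------------
# reference-lifetime calibration
# ---------------------------------------------------------------------------


def calibrate_reference_lifetimes(
    donor_only_hists: Sequence[PhotonDecayHistogram],
    control_hists: Sequence[PhotonDecayHistogram],
    tail_start: float | None = None,
    min_fret_photon_fraction: float = 0.02,
) -> tuple[float, float]:
    """Determine the fixed lifetimes (tau_noFRET, tau_FRET).

    tau_noFRET is the median monoexponential lifetime of donor-only
    histograms (the open sensor's lifetime is close to the free donor's
    because opening extends the linker far beyond the Foerster radius).
    tau_FRET is the median of biexponential fits on zero-force-control
    histograms with tau_noFRET held fixed: the control is fully closed, so
    its fast component is the FRET lifetime and its slow component reports
    dark (non-fluorescent) acceptors.

    Raises
    ------
    CalibrationError
        If all fits fail, or the control data contain no identifiable FRET
        species.
    """
    if not donor_only_hists or not control_hists:
        raise CalibrationError("both calibration lists must be non-empty")

    taus = []
    for h in donor_only_hists:
        res = fit_monoexponential_tail(h, tail_start)
        if res.converged and not res.at_bounds:
            taus.append(res.tau)
    if not taus:
        raise CalibrationError("all donor-only monoexponential fits failed")
    tau_nofret = float(np.median(taus))

    tau_frets = []
    for h in control_hists:
        sel = h.bin_centers >= (
            _default_tail_start(h) if tail_start is None else tail_start
        )
        t = h.bin_centers[sel]
        y = h.counts[sel].astype(float)
        if y.sum() <= 0:
            continue
        sigma = np.sqrt(np.maximum(y, 1.0))

        def model(tt, a1, a2, tau_f):
            return a1 * np.exp(-tt / tau_nofret) + a2 * np.exp(-tt / tau_f)

        a_scale = float(y.max())
        try:
            popt, _ = optimize.curve_fit(
                model, t, y,
                p0=[0.3 * a_scale, 0.7 * a_scale, 0.5 * tau_nofret],
                sigma=sigma, absolute_sigma=True,
                bounds=([0, 0, 0.05 * tau_nofret], [np.inf, np.inf, 0.95 * tau_nofret]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        a1, a2, tau_f = popt
        photon_share_fret = a2 * tau_f / (a1 * tau_nofret + a2 * tau_f + 1e-300)
        if photon_share_fret < min_fret_photon_fraction:
            # no identifiable FRET species in this control decay
            continue
        if tau_f >= 0.94 * tau_nofret:
            # FRET lifetime indistinguishable from the no-FRET lifetime
            continue
        tau_frets.append(float(tau_f))
    if not tau_frets:
        raise CalibrationError(
            "tau_FRET unidentifiable: control decays show no FRET component"
        )
    return tau_nofret, float(np.median(tau_frets))


# ---------------------------------------------------------------------------
# engaged fraction
# ---------------------------------------------------------------------------


def engaged_fraction(
    biexp_TS: BiexpFitResults, biexp_control: BiexpFitResults
) -> EngagedFractionResult:
    """Engaged sensor fraction N_open/N_total from TS and zero-force fits.

    The control's apparent no-FRET molecule fraction measures the
    dark-acceptor fraction d; a fraction f of mechanically open sensors
    among the fluorescent-acceptor population then yields
    ``f_raw_TS = d + (1 - d) * f``, so

        f_engaged = (f_raw_TS - f_raw_C) / (1 - f_raw_C).

    A negative value (TS below control) is returned with a warning and
    should be read as 0 within noise.
    """
    if not (biexp_TS.converged and biexp_control.converged):
        raise ValueError("both biexponential fits must have converged")
    f_ts = biexp_TS.molecule_fraction_noFRET
    f_c = biexp_control.molecule_fraction_noFRET
    if f_c >= 1.0:
        raise ValueError(
            "control no-FRET fraction is 1: engaged fraction undefined"
        )
    f_eng = (f_ts - f_c) / (1.0 - f_c)
    if f_eng < 0:
        warnings.warn(
            "engaged fraction is negative (TS below zero-force control); "
            "interpret as 0 within noise",
            stacklevel=2,
        )
    return EngagedFractionResult(
        f_engaged=float(f_eng), f_raw_TS=float(f_ts), f_raw_control=float(f_c)
    )


def intermolecular_fret_control(
    het_E: Sequence[float], homo_E_baseline: Sequence[float]
) -> float:
    """Median FRET-efficiency offset of heterozygous donor/acceptor animals
    over the homozygous donor-only baseline.

    A value indistinguishable from 0 shows intermolecular FRET between
    neighbouring sensor molecules is negligible.
    """
    het = np.asarray(het_E, dtype=float)
    homo = np.asarray(homo_E_baseline, dtype=float)
    if het.size == 0 or homo.size == 0:
        raise ValueError("both efficiency lists must be non-empty")
    return float(np.median(het) - np.median(homo))
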