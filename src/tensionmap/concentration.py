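"""Photon-count image calibration to absolute concentration, density, stress.

A confocal image acquired in photon-counting mode stores, per pixel, the
number of photons detected during the pixel dwell time PT. Dividing by the
molecular brightness (CPP, Hz per molecule, from FCS on the same cell)
converts counts into numbers of molecules in the detection volume,

    N(x, y) = I(x, y) / (CPP * PT),

and the Avogadro constant with the FCS-calibrated detection volume V_eff
turns molecules into molar concentration,

    c(x, y) = N(x, y) / (N_A * V_eff).

Downstream, the number of molecules at a membrane-apposed adhesion divided
by the membrane area inside the focal volume gives a surface density, and

    stress = force_threshold * density * engaged_fraction

(with pN/um^2 = Pa) estimates the molecularly transmitted tissue stress.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .flim import RegionMask

logger = logging.getLogger(__name__)

__all__ = [
    "AVOGADRO",
    "SATURATION_RATE_HZ",
    "CountImage",
    "ConcentrationMap",
    "DensityStress",
    "counts_to_molecules",
    "molecules_to_concentration",
    "mean_attachment_concentration",
    "linearity_check",
    "membrane_area_in_focus",
    "surface_density",
    "tissue_stress",
    "relative_levels",
    "ellipse_cross_section",
]

AVOGADRO = 6.02214076e23  # 1/mol
#: detector saturation threshold (Hz); pixels at or above are excluded
SATURATION_RATE_HZ = 2e6


@dataclass(frozen=True)
class CountImage:
    """Photon-counting confocal image.

    Attributes
    ----------
    counts : ndarray
        Integer photon counts per pixel.
    pixel_dwell : float
        Pixel dwell time PT in s (50 us in the standard configuration).
    pixel_size : float or None
        Pixel edge length in um, if known.
    metadata : dict
    truth : dict or None
        Generating parameters (including the concentration field) when
        synthetic.
    """

    counts: np.ndarray
    pixel_dwell: float
    pixel_size: float | None = None
    metadata: dict = field(default_factory=dict)
    truth: dict | None = None

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.pixel_dwell <= 0:
            raise ValueError("pixel dwell time must be positive")
        object.__setattr__(self, "counts", counts)

    @property
    def count_rate(self) -> np.ndarray:
        """Per-pixel count rate in Hz."""
        return self.counts / self.pixel_dwell

    @property
    def saturated(self) -> np.ndarray:
        """Boolean map of pixels at or above the saturation threshold."""
        return self.count_rate >= SATURATION_RATE_HZ

    @classmethod
    def from_tiff(cls, path, pixel_dwell: float, **kw) -> "CountImage":
        import tifffile

        return cls(counts=tifffile.imread(path), pixel_dwell=pixel_dwell, **kw)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.counts.astype(np.uint16))


@dataclass(frozen=True)
class ConcentrationMap:
    """Pixel-wise molecule numbers and molar concentration.

    ``molecules`` is the number of molecules in the detection volume per
    pixel; ``concentration_uM`` the equivalent concentration in uM. Pixels
    flagged in ``excluded`` (detector saturation) carry NaN and are ignored
    by the statistics helpers.
    """

    molecules: np.ndarray
    concentration_uM: np.ndarray
    v_eff: float  # L
    cpp: float  # Hz
    excluded: np.ndarray | None = None

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.concentration_uM.astype(np.float32))


@dataclass(frozen=True)
class DensityStress:
    """Membrane density and the stress it transmits."""

    membrane_area: float  # um^2
    surface_density: float  # molecules / um^2
    force_threshold: float  # pN
    engaged_fraction: float
    stress_kPa: float


# ---------------------------------------------------------------------------
# image calibration (counts -> molecules -> concentration)
# ---------------------------------------------------------------------------


def counts_to_molecules(
    image: CountImage, cpp: float, oligomerization_factor: float = 1.0
) -> np.ndarray:
    """Convert photon counts to molecules per detection volume.

    ``N(x,y) = I(x,y) / (CPP * PT)``, assuming monomeric particles
    (``oligomerization_factor`` molecules per diffusing particle, default
    1, as verified by the brightness ratio against the free fluorophore).
    Saturated pixels (count rate >= 2 MHz) are set to NaN and excluded from
    downstream statistics.
    """
    if cpp <= 0:
        raise ValueError("CPP must be positive")
    molecules = image.counts / (cpp * image.pixel_dwell) * oligomerization_factor
    sat = image.saturated
    if sat.any():
        logger.warning(
            "counts_to_molecules: %d saturated pixel(s) excluded", int(sat.sum())
        )
        molecules = molecules.astype(float)
        molecules[sat] = np.nan
    return molecules


def molecules_to_concentration(
    molecules: np.ndarray, v_eff: float, cpp: float = np.nan
) -> ConcentrationMap:
    """Convert molecule numbers to a molar concentration map (uM).

    ``c(x,y) = N(x,y) / (N_A * V_eff)`` with V_eff in litres; the result is
    reported in uM (1 mol/L = 1e6 uM).
    """
    if v_eff <= 0:
        raise ValueError("V_eff must be positive")
    molecules = np.asarray(molecules, dtype=float)
    conc_uM = molecules / (AVOGADRO * v_eff) * 1e6
    excluded = ~np.isfinite(molecules)
    return ConcentrationMap(
        molecules=molecules, concentration_uM=conc_uM, v_eff=v_eff, cpp=cpp,
        excluded=excluded if excluded.any() else None,
    )


def calibrate_image(image: CountImage, cpp: float, v_eff: float) -> ConcentrationMap:
    """Full counts -> molecules -> concentration calibration of one image."""
    return molecules_to_concentration(
        counts_to_molecules(image, cpp), v_eff, cpp=cpp
    )


def mean_attachment_concentration(
    conc: ConcentrationMap, mask: RegionMask | np.ndarray
) -> float:
    """Mean concentration (uM) over the masked attachment pixels.

    One value per image (i.e. per animal); saturated pixels are ignored.
    """
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    vals = conc.concentration_uM[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid (unsaturated) pixels inside the mask")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# linearity check (dilution series)
# ---------------------------------------------------------------------------


def linearity_check(
    series: list[CountImage], true_concentrations: list[float]
) -> tuple[float, float]:
    """Log-log regression of mean counts on known dye concentration.

    Verifies detector linearity over a dilution series: the slope of
    log10(mean counts) vs log10(concentration) should be 1 over the full
    working range. Saturated or zero-mean images are excluded with a
    warning.

    Returns
    -------
    (slope, r_squared)
    """
    if len(series) != len(true_concentrations):
        raise ValueError("series and concentrations must have equal length")
    means, concs = [], []
    for img, c in zip(series, true_concentrations):
        mean_counts = float(img.counts.mean())
        if c <= 0 or mean_counts <= 0:
            warnings.warn(
                f"linearity_check: image at {c} uM has zero mean counts; excluded",
                stacklevel=2,
            )
            continue
        if mean_counts / img.pixel_dwell >= SATURATION_RATE_HZ:
            warnings.warn(
                f"linearity_check: image at {c} uM is saturated; excluded",
                stacklevel=2,
            )
            continue
        means.append(mean_counts)
        concs.append(c)
    concs = np.asarray(concs)
    if len(means) < 3 or np.log10(concs.max() / concs.min()) < 2:
        raise ValueError(
            "need >= 3 unsaturated concentrations spanning >= 2 decades"
        )
    x = np.log10(concs)
    y = np.log10(means)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return float(slope), float(r2)


# ---------------------------------------------------------------------------
# membrane density and tissue stress
# ---------------------------------------------------------------------------


def membrane_area_in_focus(
    single_plane_area: float = 0.63, n_membranes: int = 2,
    ruffle_factor: float = 2.0,
) -> float:
    """Total membrane area (um^2) inside the focal volume.

    The default single-plane cross-section (0.63 um^2 for a 0.32 fL focal
    volume with 5:1 axis ratio) is doubled for the two apposed membranes
    (muscle and tendon) and doubled again for membrane ruffling, giving
    about 2.5 um^2.
    """
    if single_plane_area <= 0 or n_membranes <= 0 or ruffle_factor <= 0:
        raise ValueError("all arguments must be positive")
    return single_plane_area * n_membranes * ruffle_factor


def ellipse_cross_section(
    v_eff_fl: float, s: float = 5.0, convention: str = "geometric"
) -> float:
    """Central long-axis cross-section (um^2) of an ellipsoidal focal volume.

    Helper for exploring geometric conventions; it does NOT reproduce the
    0.63 um^2 convention used for the default membrane area, which is
    therefore taken as an input rather than computed.

    With short semi-axis a (x = y) and long semi-axis c = s*a:
    ``geometric`` treats v_eff as a solid ellipsoid (4/3 pi a^2 c);
    ``gaussian`` treats it as a Gaussian volume (pi^{3/2} w^2 z with
    w = a, z = c). The returned area is pi*a*c.
    """
    v_um3 = v_eff_fl  # 1 fL = 1 um^3
    if convention == "geometric":
        a = (3.0 * v_um3 / (4.0 * np.pi * s)) ** (1.0 / 3.0)
    elif convention == "gaussian":
        a = (v_um3 / (np.pi**1.5 * s)) ** (1.0 / 3.0)
    else:
        raise ValueError("convention must be 'geometric' or 'gaussian'")
    c = s * a
    return float(np.pi * a * c)


def surface_density(molecules_in_focus: float, membrane_area: float) -> float:
    """Molecules per um^2 of membrane inside the focal volume."""
    if membrane_area <= 0:
        raise ValueError("membrane area must be positive")
    if molecules_in_focus < 0:
        raise ValueError("molecule count must be non-negative")
    return molecules_in_focus / membrane_area


def tissue_stress(
    force_threshold: float, density: float, engaged_fraction: float
) -> float:
    """Lower-bound tissue stress in kPa.

    ``stress = force_threshold (pN) * density (molecules/um^2) *
    engaged_fraction``; 1 pN/um^2 = 1 Pa, so the product in pN/um^2 is
    divided by 1000 for kPa. A lower bound because individual molecules may
    bear more than the sensor's force threshold.
    """
    if force_threshold < 0 or density < 0:
        raise ValueError("force and density must be non-negative")
    if not 0 <= engaged_fraction <= 1:
        raise ValueError("engaged_fraction must be in [0, 1]")
    return force_threshold * density * engaged_fraction / 1000.0


# ---------------------------------------------------------------------------
# relative protein levels
# ---------------------------------------------------------------------------


def relative_levels(
    images: list[CountImage],
    masks: list[RegionMask | np.ndarray],
    groups: list[str],
    reference_group: str,
):
    """Masked mean intensities normalised to a reference group's median.

    For each image the mean intensity over its attachment mask is computed;
    all values are divided by the median of the ``reference_group`` images
    (the reference median is thereby set to 1). Images with empty masks are
    dropped with a warning. Returns a pandas DataFrame with columns
    ``group`` and ``relative_intensity``.
    """
    import pandas as pd

    if not (len(images) == len(masks) == len(groups)):
        raise ValueError("images, masks and groups must have equal length")
    rows = []
    for i, (img, mask, grp) in enumerate(zip(images, masks, groups)):
        m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
        if not m.any():
            warnings.warn(f"relative_levels: image {i} has an empty mask; dropped",
                          stacklevel=2)
            continue
        rows.append({"group": grp, "mean_intensity": float(img.counts[m].mean())})
    df = pd.DataFrame(rows)
    ref = df.loc[df["group"] == reference_group, "mean_intensity"]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_median = float(ref.median())
    if ref_median == 0:
        raise ValueError("reference group median intensity is zero")
    df["relative_intensity"] = df["mean_intensity"] / ref_median
    return df[["group", "relative_intensity"]]
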