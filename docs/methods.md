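# Methods

This note documents the models implemented in `tensionmap`, their
assumptions, the defaults and why, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter.

## FLIM-FRET lifetime analysis

**Model.** Donor fluorescence decays are treated as (mixtures of)
exponentials sampled into uniform TCSPC bins. The standard configuration is
an 80 MHz pulsed laser (12.5 ns period) binned at 0.08 ns; 156 whole bins
tile the period (the 0.02 ns remainder is not recorded). Only the decay
*tail* is fitted, starting by default 0.5 ns after the histogram peak,
which skips the rise/instrument-response region and makes an explicit IRF
model unnecessary. A constant background term is off by default (photon
counting in a clean emission band) but can be enabled for real data.

**Weighting and bias.** Tail fits are weighted least squares with Poisson
variances. Weighting by the *observed* counts biases the lifetime low,
because upward fluctuations receive less weight; the fit therefore runs a
second pass with variances taken from the first-pass model prediction,
which removes the bias (verified to within one standard error of the mean
over 200 replicates at 10⁵ and 10⁶ photons). The reported `rel_error` is
the standard error of τ from the fit covariance divided by τ; quality
control excludes fits above 5% (bright samples) or 10% (dim samples).

**Engaged fraction.** The sensor decay is decomposed as
A₁e^(−t/τ_noFRET) + A₂e^(−t/τ_FRET) with both lifetimes fixed:
τ_noFRET from monoexponential fits of donor-only samples (the opened
sensor's donor is effectively acceptor-free because linker extension far
exceeds the Förster radius), τ_FRET from biexponential fits of the
zero-force control with τ_noFRET held fixed. With the lifetimes fixed the
problem is linear in the amplitudes and solved in closed form (non-negative
least squares when an amplitude would go negative, flagged). Photon
fractions p_i ∝ A_iτ_i; since FRET reduces donor photon yield in
proportion to the lifetime, molecule fractions are amplitude fractions,
f_raw = A₁/(A₁+A₂). The zero-force control carries the same
dark-(non-fluorescent-)acceptor fraction d as the sensor sample, so
f_raw,TS = d + (1−d)·f and

    f_engaged = (f_raw,TS − f_raw,C) / (1 − f_raw,C).

Subtract-and-rescale is used rather than plain division because it returns
0 when sensor and control coincide and 1 when the sensor is fully open;
the alternative is exposed nowhere because it has neither property.
Per-animal pooling: one histogram (all photons in the mask) and one fit per
animal; group statistics use medians.

**Masking.** The target structure is segmented inside a hand-drawn ROI by
3×3 median filtering followed by three-class multi-Otsu thresholding; the
mask is the brightest class with holes filled. Degenerate ROIs (fewer than
three distinguishable levels) raise an error rather than returning a noise
mask. Note that re-thresholding an already-masked image is *not* the
identity: a masked image has only two intensity populations left, so the
second Otsu threshold necessarily splits the bright mode and the mask
shrinks. The guaranteed property is containment (re-masking never leaks
outside the original mask), and that is what the tests assert.

## FCS models and calibration

**Model forms.** G(τ) = (1/N) · D(τ) · X(τ) with a normalised 3D-diffusion
sum D(τ) = Σ F_i (1+τ/τ_i)⁻¹ (1+τ/(S²τ_i))^(−1/2) over one or two
components and a dark-state factor

    X(τ) = (1 − ΣT + Σ T_k e^(−τ/τ_trip,k)) / (1 − ΣT).

The additive form (rather than a product of single-state factors) is used
for two dark states because it keeps the zero-lag identity
G(0)·(1−ΣT)·N = 1 exact, which is what makes the brightness relation
CPP = ⟨I⟩·G(0)·(1−T₁−T₂) = ⟨I⟩/N an identity rather than an
approximation; it also matches the convention of the standard fitting
software for these models. For a single dark state the two forms coincide.

**Fitting.** Trust-region nonlinear least squares with S fixed at 5.
Bounds encode the physical assignments: triplet residence 1–20 µs,
photochemical flickering 200–600 µs. Two-component fits use lags > 1 µs.
Initialisation: N from 1/G(first lag), τ_d from the half-amplitude lag,
dark fractions 0.1 at the centre of their windows. Components are sorted
fastest-first and only the first diffusion time is interpreted (the second
is a descriptive slow-tail term). Unweighted residuals by default;
`weights="relative"` (σ ∝ |G|) is appropriate — and used in the built-in
pipeline — when the per-lag scatter is a constant fraction of the
amplitude, as it is for the synthetic curves. With two dark states the
flicker term partially trades against slow diffusion; at 2% relative noise
this leaves a ~5% median bias on N that no weighting removes (it is a
genuine identifiability limit of the model family), which is why particle
numbers from the single-dark-state model are preferred for calibration
whenever the sample allows it.

**Calibration products.** V_eff = S·(4π·D·τ_diff)^{3/2} with the reference
dye's published D (Rhodamine 6G, 414 µm²/s); 25 µs diffusion time gives
0.235 fL. Brightness CPP = ⟨I⟩/N. For fast-diffusing free fluorophores
whose flickering cannot be separated from diffusion, the curve is fitted
with flicker absorbed into a second diffusive term and the dark-fraction
correction borrows the *averaged* T₁, T₂ from matched sensor-protein
measurements at the same excitation power.

## Image calibration, density, stress

Counts convert to molecules as N(x,y) = I(x,y)/(CPP·PT) under a monomer
assumption (brightness ratio against the free fluorophore ≈ 1; an
oligomerisation factor is exposed, default 1), and to concentration as
c = N/(N_A·V_eff), reported in µM. Pixels at or above the 2 MHz detector
saturation rate are excluded (NaN) from all downstream statistics.
Detector linearity is verified on a dilution series via the log-log slope
of mean counts against concentration.

The membrane area in the focal volume is an *input* (default 0.63 µm²
single-plane cross-section × 2 membranes × 2-fold ruffling ≈ 2.5 µm²): the
published 0.63 µm² value cannot be reproduced from the focal volume by
either the solid-ellipsoid or the Gaussian-volume convention for the
central cross-section, so the package treats it as a given and provides
`ellipse_cross_section` only as a clearly-labelled exploration helper.
Stress is the exact product σ = F·ρ·f with pN/µm² ≡ Pa, a lower bound
since engaged molecules may bear more than the sensor threshold.

## FRAP and recoil

FRAP traces are normalised by (bleach/its pre-bleach mean) ÷ (control/its
pre-bleach mean) — removing any multiplicative drift shared by the two
regions — then affinely rescaled to pre-bleach = 1, first post-bleach = 0.
The recovery M·(1−e^(−kt)) is fitted on post-bleach frames only. Kymograph
edges are located per time row by the maximum of the smoothed absolute
gradient, refined by a background-subtracted gradient-magnitude centroid
over ±5 px (subpixel precision ~0.2 px at 50:1 contrast); rows whose
gradient peak falls below a robust z-score of 10 over the row's noise
floor end the track. Recoil speed conventions: single-plane movies (0.3 s
frames) use the displacement between the first two post-cut frames
("initial recoil velocity"); z-stack movies (5.3 s per stack) compare the
first post-cut frame with the pre-cut position ("average early velocity").
The single-plane baseline can be switched to the last pre-cut frame.

## Synthetic-data generators

The generators emulate, with Poisson/Gaussian noise and attached ground
truth: TCSPC decays (photon shares ∝ molecule fraction × lifetime, matching
the photon-correction logic of the estimator; optional Gaussian IRF blur,
default off), analytical FCS curves with multiplicative per-lag noise
(default 2% relative, a typical 40 s in-vivo recording), photon-count
images from the forward model counts = c·N_A·V_eff·CPP·PT (refusing fields
that would exceed the 2 MHz cap), FRAP pairs with shared bleaching drift,
and kymographs with a logistic edge recoiling at constant speed (the cut
is timed at the last pre-cut frame so every velocity convention measures
the same v). All generators are bit-reproducible under a fixed seed.

They deliberately do **not** model: detector dead time, afterpulsing and
pile-up (counts are kept below the 2 MHz cap where these are negligible);
Brownian-dynamics photon traces (curves are fitted, not traces); optical
PSF structure beyond the ellipsoidal focal volume; camera noise. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimators under the stated noise models, not robustness to instrument
artefacts outside them.

**Default study conditions** used by the built-in pipeline and the
acceptance script: donor lifetime 3.0 ns, FRET lifetime 1.5 ns,
dark-acceptor fraction 0.25, 10⁶ photons per decay, 5 animals per group;
reference dye τ_diff 25 µs with N = 4 in focus; sensor protein N = 20,
τ_diff 0.5 ms (plus a 5 ms slow tail, fraction 0.2), triplet 0.15 @ 10 µs,
flicker 0.10 @ 400 µs, 10 recordings per animal; attachment band 30.9 µM
on a 5.9 µM interior; imaging brightness 200 Hz/molecule at 50 µs dwell
(kept under the saturation cap at band concentrations); FRAP M = 0.6,
t½ = 25 s, 5 s frames, 0.2%/s drift; recoil 5 µm/s at 0.3 s frames.
Problem sizes in tests and the acceptance script (100–200 replicates,
64–128 px images) are chosen so every Monte-Carlo median is stable to well
inside its tolerance.

## Known limitations

- The biexponential decomposition assumes exactly two lifetimes; partially
  stretched sensors with intermediate FRET are absorbed into the two-state
  fractions.
- The two-dark-state FCS model has the identifiability limit noted above.
- The engaged-fraction normalisation assumes sensor and control share the
  same dark-acceptor fraction and maturation behaviour.
- Concentration calibration assumes the imaging and FCS measurements share
  CPP (same excitation power and detection path) and that particles are
  monomeric.
- Kymograph tracking assumes a single dominant edge per row.
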