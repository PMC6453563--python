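# tensionmap

Quantitative analysis of genetically encoded molecular tension sensors in
living tissue: FLIM-FRET lifetime analysis, FCS-based brightness and
detection-volume calibration, absolute-concentration imaging, membrane
density and tissue-stress estimation, plus FRAP and laser-ablation recoil
quantification. Every stage is exercisable on synthetic data with known
ground truth, so the whole pipeline is testable without any raw microscopy
download.

## Who this is for

Labs measuring piconewton-scale forces across adhesion proteins (talin,
vinculin, E-cadherin, ...) with FRET tension-sensor modules, who want a
tested, scriptable replacement for ad-hoc spreadsheet/MATLAB analysis of:

- TCSPC decay histograms (donor lifetime, FRET efficiency, fraction of
  mechanically engaged molecules),
- FCS autocorrelation curves (particle number, diffusion time, dark-state
  fractions, molecular brightness),
- photon-counting confocal images (molecules and molar concentration per
  pixel),
- FRAP recovery series and ablation kymographs.

## The quantities it computes

**FRET efficiency from donor lifetimes.** With τ_DA the donor lifetime in
presence of the acceptor and τ_D the donor-only lifetime,

    E = 1 − τ_DA / τ_D.

Lifetimes come from weighted monoexponential fits of the decay-histogram
tail; fits with relative lifetime error above 5% (10% for dim samples) are
excluded.

**Engaged sensor fraction.** Sensor decays are decomposed as
A₁·e^(−t/τ_noFRET) + A₂·e^(−t/τ_FRET) with both lifetimes fixed from
calibration samples (donor-only and zero-force control). Because FRET
quenches donor emission in proportion to lifetime, molecule fractions
follow from photon fractions as f_raw = A₁/(A₁+A₂). The zero-force
control's apparent no-FRET fraction measures the non-fluorescent-acceptor
fraction d, and

    N_open/N_total = (f_raw,TS − f_raw,C) / (1 − f_raw,C).

**FCS calibration.** Autocorrelation curves are fitted with 3D-diffusion
models with one or two diffusive components and one or two dark states
(PyCorrFit-style T-3D, T-3D-3D, T+T+3D+3D forms), axis ratio S = 5 fixed.
A reference dye of known D (Rhodamine 6G, 414 µm²/s) gives the detection
volume

    V_eff = S · (4π·D·τ_diff)^{3/2},

and the molecular brightness (counts per particle) is

    CPP = ⟨I⟩/N = ⟨I⟩ · G(0) · (1 − T₁ − T₂).

**Concentration maps and tissue stress.** Photon-count images convert to
molecules N(x,y) = I(x,y)/(CPP·PT) and concentration
c(x,y) = N(x,y)/(N_A·V_eff); the masked attachment-site mean, the membrane
area in the focal volume, and the engaged fraction combine into a
lower-bound tissue stress

    σ = F_sensor × (molecules/µm²) × N_open/N_total      (pN/µm² = Pa).

**Dynamics.** FRAP recovery is fitted as M·(1−e^(−kt)) after
control-corrected normalisation (mobile fraction M, half time ln2/k);
ablation recoil velocities come from subpixel edge tracking of kymographs.

## Worked example

```python
import numpy as np
from tensionmap import flim, fcs, concentration as conc, synthetic as syn

# synthetic calibration + sensor decays (1e6 photons each; the tension-sensor
# sample has 13.2% open sensors and a 25% dark-acceptor fraction)
donor   = syn.gen_decay_histogram(syn.DecaySpec(components=((3.0, 1.0),),
                                                total_photons=1e6, seed=1))
control = syn.gen_decay_histogram(syn.sensor_decay_spec(0.0,   0.25, 1e6, seed=2))
ts      = syn.gen_decay_histogram(syn.sensor_decay_spec(0.132, 0.25, 1e6, seed=3))

tau_nofret, tau_fret = flim.calibrate_reference_lifetimes([donor], [control])
fit_ts = flim.fit_biexponential_fixed(ts, tau_nofret, tau_fret)
fit_c  = flim.fit_biexponential_fixed(control, tau_nofret, tau_fret)
res = flim.engaged_fraction(fit_ts, fit_c)

# FCS calibration of the detection volume with a reference dye
curve = syn.gen_fcs_curve(syn.FcsSpec(n_particles=4.0,
        diffusion_times=((25e-6, 1.0),), dark_states=((0.15, 5e-6),),
        noise_rel=0.01, seed=4))
fit = fcs.fit_acf(curve, "T-3D")
vol = fcs.detection_volume(414.0, fit.tau_diff, 5.0)

density = conc.surface_density(1000, conc.membrane_area_in_focus(0.63, 2, 2))
stress  = conc.tissue_stress(7.0, density, res.f_engaged)
```

This prints (via the corresponding f-strings):

```
tau_noFRET = 2.991 ns, tau_FRET = 1.511 ns
f_raw(TS) = 0.353, f_raw(control) = 0.252
engaged fraction N_open/N_total = 0.135
tau_diff = 25.3 us  ->  V_eff = 0.239 fL
density = 397 molecules/um^2
stress = 0.37 kPa
```

The calibration recovers the generating lifetimes (3.0/1.5 ns), the
engaged fraction comes back at 0.135 for a true 0.132, and 1000 molecules
in the focal volume on ~2.5 µm² of membrane with 13.5% engagement at a
7 pN force threshold transmit 0.37 kPa.

A command-line interface wraps the same functions
(`tensionmap simulate|flim|fcs|concmap|stress|frap|recoil|run`); see
`tensionmap --help`.

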