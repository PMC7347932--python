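# Methods

## Problem and approach

Synchrotron X-ray fluorescence (XRF) nano-imaging of thin brain
sections measures trace-element count maps at 25–50 nm pixel pitch, but
per-pixel count rates for elements such as Fe and Zn sit near the
detection limit. This package implements a quasi-correlative analysis
in which ultrastructural compartment masks — drawn by hand on TEM
mosaics of an adjacent thin section — are registered onto the XRF grid,
and elemental signals are quantified per compartment from mask-summed
spectra rather than per pixel. Summing the spectra of all N pixels of a
compartment before fitting improves the signal-to-noise ratio by
~sqrt(N) at no cost for a linear amplitude model (the package asserts
this sum-then-fit / fit-then-sum equivalence on noiseless data).

## Contrast model

The elemental contrast of compartment *i* against the nuclear reference
*n* is the relative count rate

    Δ_{i,n} = (S_i/N_i − S_n/N_n) / (S_n/N_n),

with S the summed fitted counts of the element over the compartment
mask, N the pixel count, and propagated uncertainty

    σ_Δ = (Δ + 1) · sqrt((σ_{S_i}/S_i)² + (σ_{S_n}/S_n)²).

σ_S is the fit uncertainty when S comes from a spectral fit, and the
Poisson value sqrt(S) when S is a raw integrated count; which path was
used is recorded in the output tables. The nuclear reference is the
nucleus mask minus the nucleolus and the P-rich perinuclear rim, which
carry distinct compositions. Across-neuron averages Δ ± SD are reported
only when the relative uncertainty σ_Δ/|Δ| is below 30% and at least
three measurements survive (|Δ| is used in the denominator because
depletion contrasts are negative). The spatially uniform Si signal of
the support membrane serves as an internal control whose compartment
contrasts must be statistically zero.

Assumptions: counts are independent Poisson variables per pixel and
channel; masks from the adjacent section represent the analysed section
to within ~1 pixel (the registration gate below); compartments are
compositionally uniform at the scale of the mask.

## Spectral fitting

A deliberately simple, fully documented fitter stands in for full
fundamental-parameter fitting engines. Each element contributes a
Gaussian Kα peak plus a tied Kβ peak (fixed per-element intensity
ratio) at tabulated energies, with the shared silicon-drift-detector
width model FWHM(E) = sqrt(noise² + 2.355²·F·3.85e-3·E) (defaults:
noise 0.10 keV FWHM, Fano factor F = 0.114). Amplitudes are solved by
non-negative weighted least squares; weights are seeded from observed
counts (1/max(c,1)) and reweighted once by the fitted expectation,
because observed-count weights alone bias amplitudes low in sparse
per-pixel spectra. The background is linear in energy inside the fit
range by default; a SNIP-style iterative-clipping estimator is
available by configuration. σ_S comes from the covariance of the
weighted linear solve. Escape peaks, pile-up, detector tailing and
energy recalibration are out of scope; equivalence with any specific
published fitting package is not claimed — only the (S, σ_S) contract.
Requested element pairs whose Kα lines coincide at the detector
resolution (closer than a quarter of the local peak σ) are rejected as
a singular design.

## Registration

TEM masks are carried onto the XRF grid by a similarity transform
(translation, rotation, isotropic scale) estimated from manually picked
fiducial pairs by the closed-form least-squares (Umeyama) solution.
Reflections are excluded: consecutive sections are same-handed.
Labels are categorical, so resampling is nearest-neighbour; pixels
mapping outside the source raster become background. Pixel centers sit
at integer coordinates, origin top-left, x = column, y = row, 0-based,
in all file formats. A registration is rejected when the fiducial RMS
residual exceeds 1 XRF pixel (configurable), the registration
uncertainty the analysis budget assumes.

## Calibration

Counts convert to areal masses against a certified thin multilayer
reference standard with internal Si normalisation:

    am_X = am_Fe,std · (f_Fe/f_X) · (t_Si/t_Si,std)
                     · (S_X/S_Si) / (S_Fe,std/S_Si,std),
    f_X = σ_X · ξ_X / A_X,

where σ_X is the K fluorescence production cross-section at the
excitation energy (cm²/g), ξ_X the detector efficiency at the Kα
energy, A_X the atomic mass, and t the Si₃N₄ membrane thicknesses of
the sample and standard mounts. The uncertainty ε_X follows the same
formula with the standard's certificate uncertainty in place of its
areal mass, so ε_X/am_X is constant per element — the budget is
certificate-dominated. Concentrations follow as c = am/(t·ρ) in ppm,
with defaults t = 500 nm and ρ = 1 g/cm³ for chemically fixed brain
tissue. The shipped constants table and standard record
(`src/nanoxrf/data/`) are documented nominal/synthetic values: the
cross-sections are order-of-magnitude values from standard X-ray data
tables and the standard certificate is a stand-in, so absolute
accuracy on real beamline data requires replacing both; every analysis
the package validates is either a printed-value consistency check
(c = am/(t·ρ)) or an internal round-trip, which are invariant to the
specific constants used.

## Granule detection

Fe/S-rich granules are sub-micron cytoplasmic regions whose Fe or S
counts exceed the cytoplasmic mean by k standard deviations (k = 2
default). Thresholds are computed per element over *all* cytoplasm
pixels in one pass (no exclusion of bright structures, matching the
stated procedure; a one-iteration refinement that recomputes the
statistics excluding first-pass granules is available behind a flag,
off by default). The two exceedance masks are combined by union;
8-connected components of ≥ 2 pixels become granules — the size floor
rejects single-pixel shot-noise exceedances. No hole filling or
watershed splitting is applied, since either would silently alter the
area statistics. Granules are measured for area (pixel count × pixel
area, size split at 0.07 µm² into small/large), calibrated Fe and S
areal masses and their ratio, mean-over-background ratios against the
granule-free cytoplasm, and within-granule σ/mean per element.
Detection is invariant under global rescaling of a map, granule labels
are confined to the cytoplasm, and granule + background counts equal
the cytoplasm total exactly on integer maps.

False-positive behaviour under the null: on a flat Poisson cytoplasm
the per-pixel exceedance probability at k = 2 is ≈ 2.3% per element, so
the expected number of chance ≥2-pixel components scales with the mask
area (roughly 4·N·p² for N pixels at union probability p) and is tens
of components on a 10⁴-pixel mask, while the flagged area stays ≈ 2% of
the cytoplasm. The test-suite validates the detector against an
independent Bernoulli-field cluster oracle rather than against a zero
count; with real granules present, detections at 5× background are
unambiguous (100% recovery in the validation experiments).

## Synthetic phantom

The phantom generates what the analysis assumes: a procedural neuron
geometry (neuropil field, cytoplasm and nucleus ellipses, nucleolus,
P-rich perinuclear rim drawn as an underlying ellipse that the nucleus
overwrites, optional mitochondria/RER/lipofuscin blobs), independent
per-pixel Poisson counts at per-class expected rates, a uniform Si
membrane channel, and granules rendered as S-core disks with optional
Fe-rich annular rims (sub-pixel geometry handled by center-of-pixel
inclusion). Classes declared later overwrite earlier ones, giving a
deterministic z-order. One integer seed drives organelle placement,
granule placement and noise through deterministically derived
substreams; identical (spec, seed) reproduces maps bit-for-bit.

Default rates are obtained by pushing the shipped reference table of
compartment areal masses through the inverse of the calibration
relation at a nominal membrane level of 20 000 Si counts/pixel, so
phantom → pipeline round-trips exercise the counts → mass chain end to
end. Per-pixel matrix background levels are not published for this
preparation; the membrane/dwell levels here are declared preset
defaults, not inferred values. The nucleolus preset applies enrichment
factors of +66% P, +22% S, +53% Ca, +65% Fe and +47% Zn over the
nucleus. Two granule presets encode the biological contrast of
interest: "ctrl" (fewer, smaller, homogeneous S-dominated granules)
and "asyn" (more, larger granules with strong Fe rims), which
reproduce the ordering higher mean Fe/S ratio and higher Fe
variability in the α-synuclein-like condition.

What the phantom does **not** emulate: photon transport
(self-absorption, secondary fluorescence, escape/pile-up), scan-motion
artefacts, section-to-section morphology differences between the TEM
and XRF sections, spatially structured (non-Poisson) background, or
hand-tracing error in masks beyond the fiducial-jitter model. Passing
tests therefore demonstrate the correctness and calibration of the
estimators under the stated statistical model, not robustness to every
instrumental artefact of real beamline data.

## Validation experiment sizes

The seeded experiments (`nanoxrf.experiments`) use: 200 equal-rate
replicates on 96×96 grids for 2σ coverage; 100 seeds on 128×128
nucleus/nucleolus phantoms for enrichment recovery; 50 seeds of
100×100 flat cytoplasm for the detector null; 10 seeds × 10 inserted
granules for recovery; these sizes keep Monte-Carlo standard errors
well inside the asserted tolerances while the whole suite runs in
seconds. Coverage assertions use the binomial tolerance of the
replicate count around the nominal 95.45% of a 2σ interval.

## Known limitations

- No chemical speciation; granule composition is elemental only.
- No 3-D reasoning: granules in a 500 nm section need not extend into
  the adjacent 80 nm TEM section, so TEM co-localization is reported
  as overlap fractions with unmatched granules expected.
- Compartment masks are inputs; no automatic segmentation of TEM
  mosaics and no elastic registration.
- Absolute quantification accuracy is bounded by the constants table
  and standard certificate supplied by the user.
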