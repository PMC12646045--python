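# Methods

## Source model

The tunable source is described entirely by a calibration table: control
voltage versus center wavelength, plus the wavelength-dependent
instantaneous linewidth (FWHM) and relative efficiency (spectral
irradiance delivered to the sample, peak-normalized).  The shipped default
emulates the characterized AOTF: a monotone decreasing linear
voltage→wavelength map over 0–10 V / 1040–575 nm, linewidth rising
linearly from 2.5 nm at 575 nm to 9 nm at 1040 nm, and a smooth efficiency
bump peaking near 800 nm.  Voltage→wavelength interpolation is monotone
piecewise cubic (PCHIP): it passes exactly through the nodes and cannot
overshoot, so the inverse map is well defined; it is computed by solving
the cubic pieces, which closes the round trip to machine precision.
Linewidth and efficiency interpolate linearly in wavelength.

The instantaneous line is modeled as a Gaussian.  The true AOTF line shape
is not known to this model; the Gaussian choice makes the coherence
envelope and the swept-source roll-off available in closed form
(`gaussian_line_visibility`), and every place that relies on it is
cross-checked numerically against quadrature of the sampled line.

Coherence length uses the convention l_c = λ₀²/(2Δλ) (micrometres, with
λ₀ and Δλ in nanometres).  An alternative `gaussian_envelope` convention —
the FWHM in OPD of the fringe envelope of a Gaussian spectrum,
(4 ln 2/π)·λ₀²/Δλ — is available as an explicit option because published
"coherence length" figures mix conventions freely; it is never the
default.

The fiber mode count is the step-index estimate M = V²/2 per polarization,
V = πd·NA/λ.  The wavelength is a required argument (M ∝ 1/λ²); at 850 nm
the default 200 µm / 0.39 NA fiber carries ≈41,600 modes.

Speckle: modes propagate with differential delays exceeding the coherence
length, so they superpose in intensity.  Each mode contributes an
independent fully developed speckle pattern (exponential intensity
statistics), and active mode mixing adds further independent realizations
within one exposure; the contrast std/mean of the summed image follows
1/√(n_modes·n_averages).  A single static mode therefore gives contrast 1,
which is the high-contrast case a short fiber shows in practice.  This is
a statistical model only: no field propagation, no mode degeneracies, no
polarization.

## Sequence design

TD shaping places `n_steps` (default 64) wavelengths uniformly across the
target support and assigns dwell times ∝ S(λ)/η(λ), compensating the
source's spectral slope.  Dwells are quantized to the 3 µs crystal
response with largest-remainder redistribution, so the total equals the
exposure within one quantum.  The RF-driver (50 µs) and acoustic (3 µs)
latencies shift the emitted command timeline 53 µs ahead of the camera
exposure; the shift is applied once and is idempotent.

Parametric targets are defined so that the *density* FWHM equals the
requested FWHM: the rectangle has width F; the Gaussian is truncated at a
total support of F/0.6 (±1.96σ); the Blackman window (0.42, 0.5, 0.08)
spans F/0.4054.  The Gaussian truncation is deliberate: it yields the
~10 dB-per-step sidelobe ladder (measured on the analytic fringe
envelopes: rectangle −13.2 dB, truncated Gaussian −31.5 dB, Blackman
−58.6 dB) that motivates spectral apodization in the first place.

Equal spectral FWHM does **not** equalize the axial main lobe exactly: the
sinc response of a rectangle is ≈0.603 λ₀²/Δλ wide (depth FWHM) versus
≈0.441 λ₀²/Δλ for a Gaussian — a ~25% spread.  Claims of "same axial
resolution" across shapes are qualitative; the tests assert the sidelobe
ordering, not main-lobe equality.

Predicted integrated spectra are the dwell- and efficiency-weighted sum of
the instantaneous Gaussian lines.  Because the line has finite width, the
achievable spectrum is the target convolved with the line: smooth targets
(Gaussian, Blackman, LED-like) round-trip to within a few percent RMS of
peak at a linewidth of a tenth of the target FWHM, but a rectangle's
discontinuous edges blur by the linewidth no matter how the dwells are
chosen — the edge error alone contributes ≈12% RMS at that linewidth, and
non-negative dwell profiles cannot cancel it (an optional Richardson–Lucy
pre-compensation, off by default, sharpens features but converges to a
reblur floor of ≈9% for the rectangle).  The designer's own error —
predicted versus target⊗line — stays below 5% for every shape, and that is
the property the test suite enforces alongside the smooth-target round
trips.

SS sweeps place `n_frames` wavelengths at exactly uniform wavenumber
spacing between 2π/λ_max and 2π/λ_min (endpoints included); uniformity is
asserted at construction, not assumed.  Exposure shaping sets per-frame
weights ∝ 1/η(λ), normalized to a maximum of 1, making η·weight constant
to 1e-9 for any strictly positive efficiency profile.

## Signal formation

All OPDs use the double-pass convention Δ = 2·z·n_medium; depth axes
report OPD/2.  The interference model is reference-dominant: a phantom is
a list of discrete reflectors (depth, amplitude reflectivity √R, optional
spectral response), and reflector–reflector cross terms are neglected, as
is standard when R_ref ≫ R_s.  Operations broadcast over scalar A-line
inputs or 2-D reflectivity maps.

TD: I_p = I_DC + Σ_r 2√(R_ref R_r)|γ(Δ_r)| cos(arg γ + φ_p), with γ the
unit-power fringe envelope of the illumination spectrum (trapezoidal
quadrature on its own k grid).  The 4-phase demodulation recovers the
coherent reflector sum exactly in the noiseless model, so the axial-scan
simulator evaluates that sum directly; the equality with explicit
phase-stepped demodulation is a test, not an assumption.

SS: frame_n = w_n η_n [DC + Σ_r 2√(R_ref R_r) V_n(Δ_r) cos(k_n Δ_r)],
where V_n is the closed-form Gaussian visibility of the instantaneous line
at λ_n — the origin of the sensitivity roll-off.  The reference stack
repeats the acquisition with the object arm blocked.  Optional shot noise
is Poisson with the relative intensity scale mapped to the camera full
well (a relative value of 1.0 = full well); no read noise, no excess
source noise by default.

## Reconstruction

Order of operations: reference subtraction → per-frame gain flattening
(exposure weights × efficiency, as declared by the plan/stack) → k-mean
removal → apodization (Hamming 0.54/0.46 default) → zero padding (×8
default) → FFT along k.  The k-mean removal exists because blocking the
object arm also removes the sample's own incoherent backscatter, so
subtraction leaves that single-arm intensity in the signal; for strong
reflectors it would otherwise dominate the zeroth Fourier order.

Depth bin m sits at z_m = m·2π/(N_pad·δk)/2.  The conjugate-free depth
range is (π/δk)/4 — Nyquist OPD, halved for depth, halved again because
the sample surface is placed at zero OPD to keep the mirror image out of
the usable range; the full single-sided range (π/δk)/2 is available behind
a flag.  For 250 frames over 650–950 nm this gives 64.1 µm.

FWHM is measured on amplitude (not intensity) profiles by linear
interpolation of the half-maximum crossings.  The peak sidelobe is the
highest local maximum outside the main lobe (bounded by the first local
minima around the peak), excluding the DC bin; a profile with no sidelobe
above a −240 dB numerical floor returns the floor with a warning.

The roll-off curve simulates a unit mirror at each requested OPD and
records the reconstructed peak in dB relative to the smallest OPD.  With a
linewidth profile ∝ λ² (constant Δk across frames) the fringe envelope has
the same width at every frame; tuning that width to 72 µm FWHM reproduces
an attenuation of −13.9 dB at 55 µm OPD.  This is a model-conditional
statement: with linewidth constant in λ instead, the short-wavelength
frames wash out faster and the attenuation deepens by ≈1.4 dB.

## Spectroscopy

The Mie solver computes a_n, b_n with the logarithmic-derivative downward
recurrence (started 16 orders above the Wiscombe truncation
n_max = ⌈x + 4x^{1/3} + 2⌉) and upward Riccati–Bessel recurrences, for real
relative index and size parameter x ∈ (0, 500).  Q_back =
(1/x²)|Σ(2n+1)(−1)ⁿ(a_n−b_n)|².  The test suite cross-checks it against an
independent direct evaluation built on scipy's spherical Bessel functions
(agreement ≈1e-14) and against the Rayleigh closed form at small x.
"Backscattering coefficient" is interpreted as the efficiency Q_back; the
cross-section is Q_back·π(d/2)².  Default indices: polystyrene 1.59 in
agar/water 1.34; silica (1.45) is selectable.

Constant-coherence-length families assign Δλ_i = λ_i²/(2l_c), which makes
the fringe-envelope width — hence the probed axial volume — the same for
every center (the k-space FWHM is π/l_c independent of λ_i); the simulated
axial FWHM varies by <0.1% across 750–950 nm.

Segmentation is a deliberate minimum: pixels above mean + kσ, 8-connected
components, area-filtered, labeled in raster order.  Touching blobs merge;
matching a learning-based segmenter is a non-goal.  Particle spectra take
the maximum amplitude inside each mask per wavelength.  PCA filtering
(scikit-learn, mean-centered; an uncentered SVD variant is a flag)
reconstructs each spectrum from the first n components (default 3) and
reports per-component explained-variance fractions.

The synthetic bead stack places log-normal-brightness Gaussian blobs on a
jittered grid (guaranteeing segmentable, non-merging particles), injects
the Q_back spectrum of each particle's class — 990 nm bead, 505 nm bead,
or an aggregate modeled as a 5 µm effective sphere at a 30% rate — and
adds additive Gaussian noise (σ = 5% of the typical peak, clipped at
zero).  Classification assigns each PCA-filtered, norm-normalized spectrum
to the nearest normalized template.  This generator emulates the contrast
between classes and the aggregate contamination, not the diffraction
physics of real images: no PSF growth with wavelength, no speckle, no
camera nonlinearity, no focal drift.  Passing the ≥90% recovery test shows
the segmentation→extraction→PCA→matching chain is sound under realistic
spectral contrast and noise, not that a physical experiment would reach
the same score.

## Numerical choices and problem sizes

Simulations default to A-line (scalar) mode; image mode exists but tests
use scalars for speed.  Default problem sizes — 250-frame sweeps, 2048-
point spectral grids, 200-particle bead fields on 420×420 px images, 20
replicates for speckle statistics — run the full suite in well under a
minute and each headline figure in seconds.  Randomness always flows
through an explicit numpy Generator seed; rerunning any pipeline with the
same configuration is bit-reproducible (CSV/JSON outputs byte-identical,
seed and config hash recorded in every manifest).

## Known limitations

No aberration or pupil optics, no spatial-coherence cross-talk model, no
dispersion or motion correction, no polarization, no absorbing (complex-
index) Mie, no reflector–reflector interference, no camera readout model
beyond full-well Poisson noise.  The mode count and speckle model are
statistical conventions, not electromagnetic solutions.
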