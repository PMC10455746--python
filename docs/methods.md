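# Methods

## The measurement problem

A β-TCP scaffold and the hydroxyapatite (HA) that osteogenically induced
cells deposit are both calcium phosphates, and both scatter strongly at the
ν1 phosphate shift near 960 cm⁻¹. Absolute phosphate peak heights therefore
cannot distinguish cell-formed mineral from the scaffold. The workflow in
this package relies on quantities that are invariant to the overall
intensity scale of a spectrum — band *ratios* and the *width* of the
apatite band — so that mineral deposited on a polymer-coated scaffold
(where the coating attenuates the core's phosphate signal) becomes
detectable as a shift in those relative quantities.

## Raman pipeline

Order is fixed and fingerprinted into every output:
background subtraction → baseline correction → Savitzky–Golay smoothing →
metrics.

**Background subtraction.** The measured background (dish + medium) is
linearly interpolated onto the spectrum's axis and subtracted pointwise;
outside the background's range its edge values are held. Disjoint axes are
an error.

**Baseline.** Default `modpoly`, order 3: fit a polynomial to the working
signal, clip the signal to lie at or below the fit, refit; iterate to a
relative change below 1e−6 (cap 100 iterations, non-convergence flagged in
metadata, never silent). The polynomial is fitted in a rescaled abscissa
(numpy `Polynomial.fit`) so order-3 fits over a 1200 cm⁻¹ axis stay well
conditioned. Clip-and-refit settles onto the smooth underside of the
spectrum, excluding peaks without needing peak detection. An
`endpoint_linear` alternative (line through the terminal points) is
provided for short windows. A pure polynomial of the fitted order is
removed to numerical precision; on peak-bearing spectra, band heights are
preserved to within ~2 % (tested).

**Smoothing.** Savitzky–Golay, polynomial order 2, 7-point window
(`scipy.signal.savgol_filter`, `mode="interp"`): each interior point takes
the value of the LS parabola on its centered window; edge points evaluate
the parabola fitted to the terminal window. The test suite checks equality
(1e−10) against a brute-force per-point windowed `polyfit` oracle, so the
library call is pinned to the definition rather than trusted.

**Band heights.** The height at a named band is the maximum intensity
within ±5 cm⁻¹ (configurable) of the nominal center — tolerant of small
calibration offsets, at the cost of a slight upward bias under noise that
cancels in ratios between bands treated identically. Defaults: PLA 874,
HA ν1 960, P–O 971, phenylalanine 1004 (the canonical ring-breathing
position; the ratio definitions name Phe without a wavenumber), carbonate
1070, νP–O 1091, amide III 1244, P=O 1374 cm⁻¹.

**Ratios.** HA/Phe = I(960)/I(1004), HA/amide III = I(960)/I(1244),
carbonate/HA = I(1070)/I(960). The HA band is configurable (971 instead of
960) since the band list includes both phosphate features. Zero
denominators raise, naming the band.

**Crystallinity.** `A·exp(−(x−μ)²/(2s²)) + c` is fitted over
900–1000 cm⁻¹ by trust-region least squares (tolerances 1e−8).
Initialization: μ at the in-window argmax, A = max − min, c = min, s from
the half-maximum crossing width. FWHM = 2·√(2 ln 2)·s; the crystallinity
index is 1/FWHM in cm. The offset c makes the fit robust to residual
baseline (an offset-free variant is available); a flat window or a σ pinned
at its bounds is reported `converged=False` with diagnostics rather than a
number. Note that the 900–1000 cm⁻¹ window spans both the 960 and the
971 cm⁻¹ phosphate bands, so on a two-band phosphate doublet the fitted
width describes the composite apatite envelope — which is also what the
index means on real scaffold spectra.

**Mapping sets.** Per-spectrum metrics are summarized as mean ± sample SD;
spectra on which any stage fails are excluded and the exclusion count is
reported, never hidden.

## Flexure

σ = 3PL/(2wb²) with P the breaking load (N), L the support span (mm), w/b
the width/thickness (mm) averaged from three caliper readings each. The
modulus comes from the OLS slope m of the load–deflection record restricted
to 20–80 % of peak load — the standard linear-region convention for brittle
ceramics, since no machine-software algorithm is public — via
E = mL³/(4wb³) (rectangular-section beam theory). A_g is the crosshead
deflection at maximum load, reported in mm, not converted to strain. Fewer
than five points in the window is an error, not a silent fit.

## Mass balance

CE and WAC divide by the *final* weight (coated / wet), so both lie in
[0, 100). Content intermediates are recomputed from raw weights. All group
summaries use the sample SD (n−1); this convention reproduces the bundled
reference tables' printed summary values. Comparisons against printed
percentages tolerate ±0.05 pp where computed from raw weights, and ±0.1 pp
where the table's own one-decimal rounding propagates.

## Degradation

Deliberately descriptive — the study design reports measured curves, so no
kinetic model is fitted here; the exponential form lives only in the
generator. Summaries report initial/final levels, total change, and the
maximum absolute finite-difference rate. Threshold crossings interpolate
linearly between bracketing samples; for pH the expected crossing is
downward (acidification), for conductivity upward, overridable.

## Statistics

Unpaired tests default to Welch (the water-absorption groups have visibly
unequal variances); pooled is a flag, and both verdicts agree on the
bundled tables. One-way ANOVA pairs use Tukey–Kramer HSD
(`scipy.stats.tukey_hsd`), which handles the unequal cohort sizes (6
uncoated vs 8 coated). Two-way ANOVA (statsmodels OLS, type-II) requires a
complete layout with cell n ≥ 2 — no imputation — and its planned
contrasts (primary-factor levels within each second-factor level, Welch)
are Šídák-adjusted: p_adj = 1 − (1 − p)^m. Degenerate inputs (zero variance
everywhere) report t = 0, p = 1 with a flag instead of NaN. qPCR fold
induction is donor-wise by default (matched control per gene × donor);
mean-wise is a flag. Stars follow the 0.05/0.01/0.001/0.0001 convention.

## Synthetic data

Generators define the test conditions; they are pure functions of their
model including the seed, and every generated object carries its ground
truth in `meta`.

* **Spectra**: sums of Gaussian bands over a polynomial baseline plus
  additive Gaussian noise on a 600–1800 cm⁻¹, 1 cm⁻¹ grid. Default
  amplitudes sketch a coated scaffold (strong phosphate doublet, clear PLA
  band, weaker matrix bands; HA σ = 8 cm⁻¹). Mapping sets multiply band
  amplitudes by Normal(1, jitter) per spectrum (jitter 0.05, n ≈ 90–148 in
  map-scale tests), emulating spatial heterogeneity. Not emulated: cosmic
  rays, detector nonlinearity, peak-shape asymmetry — so passing tests
  validate the pipeline's arithmetic, not robustness to those artifacts.
* **Flexure**: load = m·δ with m = 4Ewb³/L³, additive load noise
  (default bars 45×6×6 mm, span 40 mm; default noise 0.05 N on a 30 N
  break load), terminated and pinned at the break load. Noiseless curves
  invert exactly through `elastic_modulus`.
* **Masses**: weight_after = weight_before/(1 − f)·Normal(1, σ) —
  multiplicative weighing noise (default σ = 0.02), floored so coating
  mass is never negative; noiseless rows give CE = 100·f identically.
* **Degradation**: pH(t) = ph_inf + (ph0 − ph_inf)e^(−rt) (defaults 7 → 2);
  conductivity rises with initial slope `cond_rate` and saturates on the
  series-duration timescale (the bounded form is a modeling choice; only
  boundedness matters to the tests). Default duration 180 days at 5-day
  sampling. Noisy pH is clipped to the physical [0, 14] after generation.

Noise magnitudes are package defaults declared here and in config — no
instrument specification exists to derive them from.

## Problem sizes and numerical choices

Monte-Carlo checks use 100 seeds (flexure recovery, FWHM recovery at 2 %
noise); mapping-set contrasts use 20 spectra per condition at 5 % jitter;
mass-table convergence uses 1000 rows. Reports serialize floats through a
fixed-precision formatter and contain no timestamps, making full pipeline
reruns byte-identical for a given config — the determinism property is
itself under test.

## Known limitations

Phenomenological generators only: no hydrolysis chemistry, no cell model,
no instrument transfer function. The baseline's "arithmetic operation" in
vendor software is unspecified, so modpoly is a defensible stand-in, not a
reimplementation. Peak heights are raw maxima, not fitted amplitudes
(fitted amplitudes are available through the Gaussian fit for the apatite
band only). Strength statistics beyond mean ± SD (e.g. Weibull) are out of
scope.
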