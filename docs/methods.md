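# Methods

## Processing model

A spectrum is an absorbance trace A(ν̃) on a strictly ascending
wavenumber grid (internally always ascending; display convention is the
caller's business). The processing chain is fixed and order-sensitive:

1. **Vector normalization** over the full recorded range: A ← A/‖A‖₂.
   This removes pathlength/cell-mass scale differences between samples.
   It is idempotent and invariant to positive rescaling of the input.
   Normalization precedes any cropping so that region choice cannot
   change the normalization constant.
2. **Savitzky-Golay second derivative**: a local least-squares polynomial
   (default order 2) over a moving window (default 21 points), evaluated
   as the second derivative at the window centre and scaled by 1/Δν̃² so
   the output is per cm⁻². Half-windows at the edges are trimmed, not
   padded: padding invents data and no marker band lies near the
   acquisition edges. The filter requires a uniform grid (0.1% of the
   median step); non-uniform input must be resampled (linear
   interpolation, no extrapolation) first.
3. **Markers or PCA** on the second-derivative spectra.

### Band amplitudes and the four markers

Band intensity is the magnitude of the deepest second-derivative minimum
within ±8 cm⁻¹ (configurable) of the nominal band position; ties break
toward the wavenumber nearest the centre. A search window rather than a
fixed grid point absorbs small calibration drifts; an exact-point variant
exists for sensitivity checks. Magnitudes rather than signed values keep
the ratios positive (second-derivative intensities are negative at
absorption maxima). The four ratios are 1740/2960, 2920/2960, 3012/2960
and 1630/1650 cm⁻¹. Because numerator and denominator come from the same
spectrum, every marker is exactly invariant to positive global rescaling
of the raw spectrum — so the normalization step cannot change a marker,
and SG attenuation (see below) cancels as well.

Markers are computed per spectrum and then averaged per group (not
computed from group-average spectra). Control-relative reporting divides
each marker by the control-group mean, mapping the control mean to 1.

`classify_effect` places a treatment mean on the control→stress axis via
p = (treatment − control)/(stress − control): p ≤ tol is `protective`,
p ≥ 1 − tol `stress_like`, in between `partial`; if the stress and
control means are closer than tol·|control| the marker distinguishes
nothing and everything is `no_effect`. Default tol = 0.15 — the three-way
comparison this encodes is qualitative, and the threshold is exposed in
the API. The p-based labels are affine-invariant; the degenerate-marker
guard is necessarily referenced to the control scale.

### PCA

Mean-centered SVD of the spectra matrix over a closed wavenumber window;
no per-wavenumber variance scaling (standard in spectroscopy — unit
variance would erase band-intensity structure). Explained-variance
fractions are σᵢ²/Σσ². Signs are fixed deterministically: the
largest-magnitude element of each loading is made positive. Region
presets: full 4000–900, fingerprint 1900–900, lipid 3200–2800 cm⁻¹.
(Figure captions in the source literature vary between 1900–900 and
1800–900 for the protein window; the presets follow the analysis text
and the discrepancy is simply noted.) The default input is the
preprocessed (normalized, second-derivative) collection; raw-normalized
input is a caller choice.

### Assays

Conjugated dienes: c = A₂₃₃/(ε·l) with ε = 27000 M⁻¹cm⁻¹, path length
defaulting to 1 cm (configurable), reported in μM per 10⁶ cells. TBARS:
an ordinary-least-squares calibration line absorbance-on-concentration
over TMP standards (1.25–20 μM ≡ MDA 1:1), inverted for samples —
the standard analytical-chemistry direction; both regression directions
coincide exactly when R² = 1. Blank subtraction is assumed upstream.
Negative back-calculated concentrations are flagged, not clipped, so
group statistics keep the information.

### Statistics

One-way ANOVA from the between/within sum-of-squares decomposition;
Tukey HSD with q = |mean_i − mean_j|/√(MSW/2·(1/nᵢ + 1/nⱼ))
(Tukey–Kramer for unbalanced groups) and p-values from the
studentized-range distribution (scipy's numerical implementation,
well below 1e-4 error). Compact letters use the insert-and-absorb
algorithm and are deterministic given sorted labels. Each marker and
assay is tested separately at α = 0.05; no correction is applied across
the four markers — a documented limitation.

## Synthetic data generator

The generator emulates the treatment design of the cell experiments:
control, H₂O₂, and for each compound the three schemes alone / before /
after H₂O₂ (20 groups, default 6 samples per group; the per-group count
mirrors the few-replicates scale of bulk-cell FTIR experiments). A single
scalar δ ∈ [0, 1] ("oxidation level") drives all effects:

- each band is a Gaussian with amplitude base·(1 + gain·δ); default
  gains: 1740 +0.8, 2920 −0.3, 3012 −0.4, 1650 −0.25, 1630 +0.25, and
  0 for 2960, 2850, 1545. Directions encode the oxidative-stress
  signature (aldehyde up, CH₂ and olefinic down, amide redistribution);
  magnitudes are declared synthetic conventions, exposed in the config,
  not measured values.
- assay absorbances are linear in δ before noise (CD directly; TBARS via
  a true MDA concentration of 1 + 8δ μM read through the calibration
  line with slope 0.05 μM⁻¹).
- per-group δ_eff = clip(δ_stress·(1 − protection) + prooxidant_offset,
  0, 1), identical in the before/after schemes. Default protection: Cat
  1.0, Cap 0.9, CfA 0.5, Qc 0.45, GA 0.35, ChA 0.3; Qc alone carries a
  prooxidant offset of 0.12. This encodes the qualitative pattern of the
  cell experiments: catechin/capsaicin most protective, phenolic acids
  weaker, quercetin intermediate with a mild prooxidant action.

Gaussian line shapes (not Voigt) were chosen because the second
derivative of a Gaussian has the closed-form centre depth A/σ², enabling
analytic oracles. Grid: 800–4000 cm⁻¹ at 2 cm⁻¹ (1601 points),
consistent with ~6 cm⁻¹ effective resolution after smoothing. Intensity
noise is i.i.d. Gaussian (SD 0.003 a.u. against band amplitudes of
0.1–0.9) with a small linear baseline; one seed drives the whole
experiment through per-sample spawned substreams, so experiments are
reproducible yet samples independent.

What the generator does **not** emulate: Mie/ATR optical distortion,
water-vapor and CO₂ artifacts, correlated (pink) instrument noise,
cell-to-cell biochemical covariance beyond the single δ factor, and
wet-chemistry variability of the assays (extraction efficiency,
reaction yield). Tests passing on this generator therefore demonstrate
the correctness and calibration of the analysis chain, not robustness to
every artifact of real cell spectra.

## Numerical behaviour and known limitations

- **SG attenuation.** With the default 21-point window at 2 cm⁻¹ the
  measured second-derivative depth of a σ = 8 cm⁻¹ Gaussian is ≈ 0.31 of
  the analytic A/σ². Attenuation is linear, so it cancels exactly in
  same-spectrum band ratios and in ratios across oxidation levels; the
  analytic-depth checks in the tests therefore run on dense grids with
  short windows, where the SG estimate tracks the true derivative.
- **Amide cross-talk.** The 1630 and 1650 cm⁻¹ amide I components lie
  20 cm⁻¹ apart while the default filter spans 40 cm⁻¹, so each band's
  fit window contains the other band. Their second-derivative minima mix:
  the 1630/1650 ratio responds strongly and monotonically to the
  programmed amide redistribution (direction and ordering are correct,
  and the stress group is reliably extreme), but its numeric factor
  overshoots the programmed (1+0.25δ)/(1−0.25δ) — by roughly half again
  at δ = 1 under default settings. This mirrors the real-world caveat of
  second-derivative band ratios on strongly overlapped envelopes; only
  the three lipid markers, whose bands are well separated, recover their
  programmed factors quantitatively (within 3%, in practice ≤ 0.4%).
  Band deconvolution (curve fitting) would be the remedy and is out of
  scope.
- Degenerate inputs are errors, not silent results: all-zero spectra,
  zero reference-band amplitude, identical-spectra PCA, zero-variance
  ANOVA, singular calibrations.
- Problem sizes in the shipped tests and acceptance script (60–120
  spectra × 1601 points, 1000 statistical replicates) were chosen as
  desk-scale experiments that exercise every code path while keeping a
  full run in the order of a minute.
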