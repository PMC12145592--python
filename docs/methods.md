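# Methods

This note documents the models, numerical conventions and design choices
behind `nirferm`, in the spirit of a package vignette: what is simulated and
why, what the algorithms do exactly, and what the tests do and do not
demonstrate about real spectrometer data.

## Spectral simulator

**Beer–Lambert band model.** Each constituent absorbs as a sum of Gaussian
bands; the noiseless absorbance of a sample with concentrations cᵢ (g/L) on
the wavenumber grid ν is

    A₀(ν) = L · ( Σᵢ cᵢ · Σ_b αᵢᵦ exp(−(ν − νᵢᵦ)² / 2σᵢᵦ²) + W(ν) )

with pathlength L in mm, band amplitudes α in AU/(g/L)/mm, and a fixed water
background W (AU/mm). The default library encodes only qualitative facts
about this chemistry: every constituent has C–H 1st-overtone bands
(~6200–5600 cm⁻¹) and combination bands (~4800–4000 cm⁻¹); per constituent
the summed combination amplitude is exactly 10× the summed overtone
amplitude; the diol/ketol products (2,3-BDO, acetoin) absorb several-fold
more strongly per g/L than the sugars; all five signatures are mutually
distinguishable (pairwise cosine < 1 − 10⁻³). No extinction coefficients for
this matrix are published, so the specific centers/widths/amplitudes are
invented, documented defaults, overridable by passing a custom library.

**Measurement chain.** Per sample, in order: affine scatter a·A₀ + b with
a ~ N(1, σ_mult), b ~ N(0, σ_add) (SNV is exactly the correction for this
family); fiber attenuation as +(−log₁₀ τ); additive channel noise
N(0, σ_noise); hard clipping at the absorbance ceiling; finally *rail
instability* on the clipped channels. The last term deserves explanation:
with clipping alone, saturated channels are constants, which a linear model
simply ignores — removing them from the calibration would then be cosmetic.
Physically, a detector at its rail reports an unstable absorbance: roughly
constant intensity noise maps to absorbance noise proportional to 10^A, so a
channel pinned at ceiling A_sat wobbles by about σ_noise · 10^(A_sat − 1)
(the unsaturated working range being ~1 AU). With this term the saturated
regions are actively harmful if retained, which is why the workflow removes
them — and the package's paired simulations show the removal improving
normalized RMSEP in ≥ 8/10 campaigns. Setting `rail_noise_sd=0` restores
pure clipping (saturated channels exactly at the ceiling).

**Instrument profiles** (all constants tunable; unpublished ones invented):

| profile | axis | L (mm) | σ_noise (AU) | notes |
|---|---|---|---|---|
| `lab_at_line` | 12,003–3772 cm⁻¹, 8 cm⁻¹ | 0.2 | 5·10⁻⁴ | FT instrument, filtered samples |
| `low_cost_at_line` | 2000–2450 nm, 1 nm | 0.2 | 4.8 × 5·10⁻⁴ | MEMS instrument; the 4.8× encodes the measured noise ratio |
| `lab_on_line` | 9503–4000 cm⁻¹, 8 cm⁻¹ | 2.0 | 5·10⁻⁴ | fiber probe: attenuation τ = 0.5, larger scatter (unfiltered broth), ceiling 3.0 AU |

The water background (strong 5150 cm⁻¹ combination band, O–H fundamental
tail below ~4300 cm⁻¹, weak 6900 cm⁻¹ overtone) is sized so that at 2 mm
plus fiber loss the 5400–4800 cm⁻¹ band and everything below 4300 cm⁻¹
exceed the 3.0 AU ceiling — reproducing the on-line saturation regions —
while the 0.2 mm at-line configurations stay on scale everywhere.

**Fermentation kinetics.** A deliberately coarse discrete-time model whose
goal is the *correlation structure* of real campaigns, not mechanistic
fidelity: glucose is consumed preferentially (xylose uptake repressed by a
factor ρ = 0.2 until glucose is nearly exhausted); a three-state Markov
dissolved-oxygen chain (low/optimal/high) allocates consumed sugar to
products by state-dependent yields; glycerol and 2,3-BDO are irreversible,
while acetoin is an intermediate that accumulates under DO excess and is
reduced to 2,3-BDO when DO recovers. This induces the qualitative
correlations seen in practice (products positively correlated with time and
each other, sugars negatively with products, acetoin more weakly).
Mass balance holds stepwise: total product formed ≤ Σ yields(state)·Δsugar.
Campaigns jitter initial sugars and uptake rates ±20% across experiments and
optionally contaminate experiments (one sample gets ethanol/lactic/acetic at
~5 g/L) to exercise the 2.5 g/L exclusion filter.

**Reference measurements.** HPLC-like references add N(0, σ) error
(default σ = 0.5 g/L, clipped at zero); glucose error is multiplied by the
dilution factor ⌈c/36⌉ needed to reach the 6–36 g/L calibration range, so
samples above ~80 g/L carry ≥ 3× the base error. This both caps achievable
model accuracy realistically and produces the funnel-shaped glucose
residuals that the heteroscedasticity screen is designed to catch.

## Preprocessing numerics

* Fixed order: pre-truncation → saturated-region removal → SNV → SG
  derivative → post-truncation. Mean centering is *not* part of this chain:
  it is split-aware (validation rows are centered with the calibration mean)
  and lives inside model fitting.
* SNV uses the n−1 standard deviation (the common chemometrics convention;
  any consistent choice only rescales rows). Constant rows raise an error
  naming the sample.
* The SG derivative is with respect to channel *index*, unscaled by physical
  spacing — models are therefore not portable across resolutions without
  refitting. Edges are trimmed ((w−1)/2 per side), never padded.
* Grids uniform in the stored unit or in its reciprocal are accepted (the
  low-cost axis is uniform in nm, hence non-uniform after conversion to the
  canonical cm⁻¹ representation; the index-based derivative is well defined
  either way). When region removal has left gaps, SG runs independently
  within each contiguous uniform run so that no derivative spans a seam;
  each run loses its own edges. Uniformity tolerance: 10⁻⁶ relative.
* The SG window is selectable over the odd values 3–21 by running the full
  preprocess + PLS LOO protocol per candidate and minimizing the mean
  range-normalized RMSECV, ties toward the smaller window.

## Splits

One whole experiment is always held out (`unique` set) to measure
generalization across fermentation runs; "representative" is operationalized
deterministically as the experiment whose mean preprocessed spectrum is
nearest the grand mean. PCA for the Kennard–Stone split is computed *after*
removing the unique experiment (no information leak), retaining the smallest
number of components reaching 95% cumulative variance. Kennard–Stone
(greedy max–min, initialized at the farthest pair, ties to the lowest index)
selects the *calibration* set — the conventional use, since KS picks the
most spread-covering subset — of size round((1−f)·n), f = 0.40 for the
lab-grade at-line dataset and 0.25 for the smaller low-cost/on-line ones;
rounding is half-away-from-zero.

## PLS

The orthogonal-scores algorithm with both X- and Y-deflation (some
implementations skip Y-deflation; predictions are identical, internals are
not). Weights come from the SVD of XₐᵀYₐ — for one response this reduces to
the normalized covariance vector — and are sign-normalized (largest-magnitude
element positive) so fits are bit-reproducible. The coefficient stack B_a is
kept for every a ≤ A, so a single PLS-2 decomposition supports per-response
component truncation: LOO-CV (each fold refits from scratch, including
centering) yields an RMSECV curve per constituent and the smallest a within
10⁻¹² of the curve's minimum is selected. A one-standard-error rule was
considered and rejected: the protocol selects by minimum cross-validated
performance alone. On flat RMSECV tails this strict-minimum rule lets the
selected count wander among statistically indistinguishable values; tests
therefore assert that few components suffice via the curve (the ≤ 8-component
minimum is within 5% of the global minimum) rather than pinning the argmin.
If the X–Y covariance is exhausted early (noiseless low-rank data),
extraction stops and the coefficient stack repeats its last entry, leaving
predictions unchanged for larger counts. A PLS-1-per-response mode is
available behind a flag.

## Evaluation

RMSEC/RMSECV/RMSEP/RMSEP_unq per constituent, each also divided by the
constituent's calibration-set range for cross-constituent and cross-dataset
comparison. The heteroscedasticity screen replaces a visual check with a
reproducible proxy — one-sided Spearman correlation between |residual| and
prediction, flag at p < 0.05 — and always emits the residual-vs-predicted
table so the visual check remains possible. The spectral noise analysis
snaps 10 evenly spaced targets on 4480–4300 cm⁻¹ (the most
constituent-associated slice of the combination region) to each instrument's
nearest retained channel, averages the per-channel SD across ≥ 2 replicate
blanks, and reports each instrument's mean SD as a ratio to the first
(reference) instrument. Its default preprocessing is the SG derivative
*without* SNV: SNV rescales every blank by its own spread, which would
conflate the two instruments' different water-spectrum shapes with their
channel noise; the index-based SG filter applies the same linear operator on
both grids and preserves the noise ratio. Any other `PreprocessConfig` can
be passed explicitly.

## Problem sizes

Simulated studies use sizes chosen to make the statistical comparisons
stable while keeping any single analysis in seconds: the feasibility replica
uses the designed n = 40; campaign simulations use 4–8 experiments × 5–10
samples; repeated-seed comparisons use 10–100 replicates (e.g. 50 seeds for
the noise-ratio estimate, 8 noise levels × 10 seeds for the monotonicity
check, 100 campaigns for split integrity).

## What the synthetic data do and do not show

The simulator reproduces the *mechanisms* the workflow exists to handle:
Beer–Lambert mixing, affine scatter, instrument-dependent noise and range,
pathlength-driven saturation, reference-measurement error with dilution
effects, campaign-level correlation structure and occasional contamination.
It does not reproduce real NIR band shapes, temperature and water-activity
effects on the water background, cell-mass Mie scattering spectra,
instrument drift over months, or hydrolysate matrix chemistry. Passing tests
therefore demonstrate that the pipeline is a correct and internally
consistent implementation of the workflow and that its comparative findings
(instrument ordering, value of saturated-region removal, noise-ratio
estimation) follow from those mechanisms — not that a model trained on these
synthetic spectra would transfer to a physical spectrometer.

## Known limitations

* Contaminant species are excluded, not modeled spectrally; there is no
  outlier diagnostics beyond the concentration filter.
* The DO model is a Markov caricature; it cannot represent feedback control.
* LOO-CV is O(n) full refits per candidate window; for n in the thousands a
  blocked CV would be preferable (the study datasets are hundreds of
  samples).
* No uncertainty intervals on predictions; the workflow reports point RMSEs.
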