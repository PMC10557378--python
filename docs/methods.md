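# Methods

## Problem and model

PGE₂, PGD₂ and Δ12-PGD₂ are positional/geometric isomers of C₂₀H₃₂O₅ and
cannot be separated by mass alone. As silver-cationized ions
([M+¹⁰⁷Ag]⁺, m/z 459.1295) subjected to MS³ through the water-loss product
(459.13 → 441.12), the isomers differ strongly in the relative abundances of
three product-ion channels: m/z 331.0 (C8–C9 cleavage, PGE₂-specific),
m/z 341.0 (C6–C7 cleavage, Δ12-PGD₂-characteristic) and m/z 333.2 (H₂O + AgH
loss, common to all three but far more abundant for the PGD₂-type ring).

For a triplet of channel intensities the relative abundances are
rᵢ = Iᵢ / (I₃₃₁ + I₃₃₃ + I₃₄₁). The calibration model is trained on
mixtures of known composition:

1. %Δ12-PGD₂ = f(r₃₃₁, r₃₄₁), an ordinary-least-squares second-degree
   polynomial surface (6 coefficients);
2. r₃₃₁ = g(%PGE₂), a third-degree polynomial (4 coefficients), inverted
   numerically at prediction time;
3. %PGD₂ = 100 − %PGE₂ − %Δ12-PGD₂ (closure).

Prediction order is PGE₂ → Δ12-PGD₂ → PGD₂. Raw predictions must lie in
[−10, 110] %; otherwise the pixel/sample is flagged invalid and excluded
from downstream statistics. For display, valid fractions outside [0, 100] %
render as 0; the stored data keep raw values plus validity flags.

**Root selection.** g(p) = r may have up to three real roots. The policy is
deterministic: restrict to [−10, 110], prefer roots in [0, 100], and break
remaining ties by proximity to the minimizer of |g(p) − r| on a 0.01 % grid
over the preferred interval. No admissible root ⇒ invalid. The model
coefficients are never hard-coded: product-ion yields depend on the CID
settings, so the model must always be re-fitted to calibration data acquired
under the settings of the measurement it will predict.

## Mass engine

All m/z arithmetic routes through one pinned table of monoisotopic atomic
masses (¹⁰⁷Ag = 106.905092 Da, electron = 0.000549 Da). Cations are
electron-corrected (−mₑ, ≈1.2 ppm at m/z 459); neutrals never are.
Product-ion assignment enumerates neutral losses as element-bounded
subformulas of the precursor ion over C/H/O, optionally including
¹⁰⁷AgH-containing losses (silver leaving as a hydride with the charge kept
by the organic fragment), ranks candidates by |ppm error| and breaks ties
toward the loss with fewer heavy atoms.

With this table the recomputed ppm errors of the published product-ion
assignments agree with the printed values within ±0.3 ppm for 10 of 13
rows. Three printed ppm values (for measured 333.0252, 397.1291 and
413.1245) are not reconcilable with their own printed measured m/z at
4-decimal precision under any standard constants (rounding the measured
value to 4 decimals moves ppm by at most ±0.15 at these masses); the
recomputed values (+0.44, −0.06, +1.12 ppm) are reported as computed.

## Spectra and channels

The mzML reader and writer are deliberately small lxml-based
implementations covering centroided scans, 32/64-bit float arrays (plain or
zlib), scan times, MSⁿ isolation chains and analyzer metadata. Profile-mode
scans are rejected. Channel extraction takes the most intense centroid in
the tolerance window (5 ppm for high-resolution scans, 0.4 amu for ion-trap
scans; per-channel override), tie-breaking by proximity to the target.
Flow-injection averaging uses a fixed-duration window (default 2.3 min);
when the window is not given it is auto-positioned to maximize summed TIC,
since the placement within an injection is otherwise unconstrained.

## Imaging

Pixels are defined by the MS³ duty cycle: width = stage speed × cycle
period (0.02 mm/s × 1.55 s → 31 μm), height = line step (100 μm). The
acquisition-rate figure of 1.55 Hz printed alongside this geometry is only
consistent with a 1.55 s *period*; the geometry type therefore stores a
period in seconds and offers an explicit Hz-converting constructor.
Interlaced SIM scans are aligned to pixels by nearest scan time.
Quantitation is one-point: per-pixel analyte/internal-standard ratio times
the standard's known concentration (0.5 μM PGD₂-d₉ in the intended use).

Filtering: the tissue mask retains pixels with the m/z 333.2 channel at or
above 30 counts (inclusive boundary); the S/N filter retains a pixel's
channel iff intensity/noise is strictly above 5, with the noise level
estimated per channel as median + 1.4826 × MAD over off-tissue pixels (a
robust scale; swappable via an explicit `noise_levels` argument, requiring
≥ 20 off-tissue pixels otherwise). A pixel failing any channel is invalid
in all three fraction images. Both filters are idempotent and commute.

## Synthetic generator

The generator is the testing ground for every stage and defines the study
conditions:

* **Signature matrix** (yields per isomer, channels 331/333/341, base peak
  = 1): PGE₂ (1.0, 0.05, 0.01); PGD₂ (0.02, 1.0, 0.02); Δ12-PGD₂
  (0.02, 1.0, 0.35). The 5 % shared-channel yield of PGE₂ and the <2 %
  placements are anchored to the observed standard spectra; the Δ12 341
  yield is a free parameter fixed at 0.35.
* **Mixing law**: channel intensity = total × Σ fraction × yield, equal
  ionization/fragmentation efficiency per isomer. Relative abundances are
  therefore *rational* functions of the fractions — the behaviour the
  polynomials approximate, which is why fitted R² is high but not 1.
* **Noise**: proportional Gaussian (CV 3 %) plus additive Gaussian (SD 1 %
  of the tissue-level base peak), clipped at zero; one seeded generator per
  artifact.
* **Design**: 21-point ternary simplex lattice (20 % step: pure standards,
  binary mixtures, interior) plus the equimolar point, 3 technical
  replicates (66 samples), total intensity 10⁵ counts standing for the 3 μM
  calibration level.
* **Interference**: complex-matrix backgrounds are emulated by adding a
  uniform [0, 5 %]-of-total budget, randomly split between channels 331 and
  333 (341 is untouched; no interferences were observed on it).
* **Phantom**: 20 × 40 grid with off-tissue border, an AM-pole-like region
  ((35, 15, 50) %, full signal), an M-pole-like region (weaker signal) and
  an epithelium-like stripe; interlaced SIM + MS³ scans per line with a
  constant internal-standard channel. Off-tissue signal is ~3 orders of
  magnitude below tissue so the mask threshold separates it.

A second generator (`make_consistent_training_set`) produces data lying
*exactly* on a known surface + cubic (the surface linear in r₃₄₁ so it can
be inverted in closed form). It is the recovery oracle: refitting must give
R² = 1 and near-zero hold-out RMSE. The rational forward model, by
contrast, has an irreducible polynomial-approximation floor of ≈1.5–2 %
RMSE for PGE₂/PGD₂ even without noise, because r₃₃₁ depends weakly on the
Δ12 fraction through the shared denominator while g() is a function of
%PGE₂ alone. End-to-end phantom ROI means consequently carry a ≈1.5–2 %
systematic offset at the AM-pole composition; this floor, not noise,
dominates low-noise recovery accuracy.

What passing synthetic tests do **not** show about real data: instrument
drift, per-isomer efficiency differences, chromatographic carryover,
isobaric interferences beyond the modelled additive background, and spatial
oversampling effects are all outside the generator.

## Validation

Hold-out cross-validation follows the calibration design: 10 % of samples
(random, disjoint, at least one) held out, 50 iterations, per-isomer RMSE
of predicted vs true percentages, averaged over iterations per isomer (not
pooled). Splits come from one seeded generator recorded in the result.
Under the default noise the mean RMSE is ≈2 % (PGE₂), ≈3 % (Δ12-PGD₂) and
≈3.5–4 % (PGD₂) — all below 5 %, with PGD₂ always largest because closure
accumulates the other two errors. Problem sizes throughout (66-sample
calibration sets, 800-pixel phantoms, 50 CV iterations) were chosen so the
whole suite runs in seconds while keeping estimator variance well below the
tolerances being checked.

## Known limitations

* Only the three modelled isomers; minor isomers (8-iso-PGE₂ etc.) sharing
  the channels are not predicted and would bias results if abundant.
* No uncertainty propagation beyond hold-out RMSE.
* The mzML subset reader targets centroided MSConvert-style output; exotic
  encodings (numpress, ion-mobility arrays) are out of scope.
* Oversampling across lines is not modelled; each line is an independent
  pixel row.
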