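# Methods

`ovonir` models the full analysis chain of a spectrometer-based egg
candler: Vis/NIR transmittance spectra of intact eggs are simulated,
calibrated to relative transmittance, pretreated, classified into normal /
bloody / yolk-destroyed with PLS-DA, and reduced from ~2000 instrument
wavelengths to a handful of physically meaningful bands. This note
documents the models, the defaults and the reasoning behind the open
design choices.

## The classification problem

Candling an intact egg in transmission mode yields one intensity spectrum
per scan. Three spectral signatures carry the class information:

* **Bloody eggs** contain hemoglobin, whose α-band absorbs near 577 nm
  (with further bands at 539 and 415 nm); transmitted intensity drops
  locally at 577 nm.
* **Yolk-destroyed eggs** transmit less light overall (yolk material
  disperses through the albumen) and show a distinct local intensity
  offset in the 590–600 nm region relative to normal eggs.
* **Protoporphyrin IX** (PPIX), the brown-shell pigment, absorbs at 539,
  589 and 643 nm in *every* brown egg. It is a structured nuisance that
  overlaps the hemoglobin bands and is the reason bloody-egg detection in
  brown eggs is hard.

The shell's calcium carbonate blocks light below ~550 nm, so the usable
signal sits in a narrow visible window; the working range is restricted to
500–680 nm and band selection to 550–600 nm, where the class-discriminating
chemistry lives.

## Synthetic spectrum generator

No measured spectra ship with this package, so a generator produces
datasets with the statistical structure the analysis assumes. A raw scan
is

    B(λ) = m · L(λ) · S(λ) · exp(−ℓ·j · Σᵢ cᵢ Gᵢ(λ)) · a
           + baseline(λ) + s · L(λ) · S(λ)^γ + d + ε(λ),   clipped at 0

with:

* `L(λ)` — lamp envelope. Silver-coated halogen: support 400–700 nm,
  maximum inside the blood-sensitive 565–585 nm window. Gold-coated:
  support 500–1100 nm, broad maximum near 800 nm. Envelopes are Gaussian
  peaks multiplied by a sine taper that reaches zero exactly at the
  support edges.
* `S(λ)` — shell transmission, a logistic sigmoid centred at 550 nm
  (scale 12 nm), encoding the calcium-carbonate cutoff.
* `Gᵢ(λ)` — unit-height Gaussian absorber bands: hemoglobin at
  415/539/577 nm (relative strengths 3.0/0.6/0.8), PPIX at 539/589/643 nm
  (0.5/0.4/0.8), and a yolk-destruction feature at 596 nm. Band sd is
  4.5 nm (hemoglobin α-band FWHM is ≈10 nm); the yolk feature uses 5 nm.
  A broader width would smear the 577 nm information across the whole
  550–600 nm selection window and no selector could be expected to
  localize it — the band sharpness is what makes "which wavelength?" a
  well-posed question.
* class parameters (per-class mean concentrations, drawn log-normally per
  egg with sd 0.25 on the log scale):

  | class | hemoglobin | PPIX | yolk feature | attenuation a |
  |---|---|---|---|---|
  | normal | 0.3 | 0.6 | 0 | 1.00 |
  | bloody | 1.4 | 0.6 | 0 | 0.95 |
  | yolk-destroyed | 0.3 | 0.6 | 0.45 | 0.75 |

  Bloody attenuation is nearly neutral on purpose: blood chiefly announces
  itself through the 577 nm band, not through overall brightness, so the
  wavelength selectors must find the band rather than read a global
  intensity shift. Yolk-destroyed eggs combine a strong global attenuation
  with the 596 nm feature.
* `ℓ` and `s` — the measurement-geometry condition maps to a (path-length
  scale, stray-light fraction) pair: condition 1 → (1.0, 0.10),
  2 → (1.2, 0.02), 3 → (1.1, 0.05). Stray light is lamp-shaped,
  partially filtered by the shell to a per-scan random degree γ∈[0,1]
  (light grazing the shell edge), and the same geometric sloppiness
  jitters the optical path per scan (`j`, log-normal with sd equal to the
  stray fraction). These two mechanisms are what make condition 1
  measurably worse than condition 2 — a per-scan constant offset alone
  would be removed by any scatter correction and the geometry effect
  would vanish.
* `m` — per-scan multiplicative scatter, log-normal sd 0.12.
* `baseline` — per-scan random offset + slope, amplitude 0.003.
* `d` — a constant dark-current offset (0.02) present in **every**
  measurement including the white reference; the dark reference is this
  offset alone, so calibration divides it out exactly.
* `ε` — additive detector noise, sd 0.008, split equally between a white
  component and a spectrally smooth component correlated over 1.5 nm
  (readout drift / source flicker). The correlated part matters for band
  selection: with purely independent noise, near-duplicate columns 0.5 nm
  apart each earn a real (noise-averaging) partial-F contribution and
  forward stepwise regression would keep them all.

The default design is 50 eggs per class × 3 classes × 5 rotations = 750
scans per lamp × condition cell; rotations share the egg's latent
concentrations and redraw every per-scan term. All randomness flows from
one integer seed through spawned `numpy.random` streams, so a config is
bit-reproducible.

**What the generator does not emulate:** real lamp spectral power
distributions, shell-colour variation between breeds, detector
nonlinearity, wavelength miscalibration, and egg-size covariance with
shell thickness. Passing tests therefore demonstrate that the *pipeline*
recovers the structure the generator encodes — not that a physical
instrument would reach the same accuracies.

## Calibration

Relative transmittance is T = (B − D)/(W − D) with W and D each the mean
of 10 reference scans. Wavelengths where W − D falls below 1% of its
maximum carry no usable light (outside the lamp support the difference is
pure reference noise) and are flagged undefined (NaN); they are dropped by
the range restriction before any modelling. The guard is deliberately far
above machine epsilon: a tighter guard would pass noise ratios through as
"transmittance".

## Preprocessing

Mean/max/range normalization, SNV, MSC, and Savitzky–Golay 1st/2nd
derivatives (window 11, polynomial order 2, derivative scaled per nm,
edges refit on the truncated window). All are pure per-spectrum transforms
except MSC, whose reference spectrum (training column mean) is learned on
the calibration set only and replayed on validation rows. A "minimum
normalization" variant is deliberately absent: no evaluation in this
package uses it.

## PLS-DA

Classes are coded numerically (0 normal, 1 bloody, 2 yolk-destroyed) and a
single-response PLS1 NIPALS model is fitted to column-centred X and
centred y — one β vector per model, which is what the weighted-coefficient
selector needs. Class assignment thresholds the continuous score at 0.5
and 1.5 (nearest label; a boundary score goes to the upper class). The
latent-variable count A is chosen by stratified K-fold cross-validation
(default 10-fold, A ≤ 20) with the one-standard-error convention: the
smallest A whose CV misclassification is within one SE of the minimum.
This collapses to A = 1 for an uninformative response instead of chasing
fold noise. Sign convention: the first nonzero element of every weight
vector is forced positive, making decompositions comparable across
implementations.

Reported metrics: 3×3 confusion table; per-class one-vs-rest accuracy
(Tp+Tn)/(Tp+Tn+Fp+Fn); recall and precision per class (undefined values
reported as missing, never as 0); total accuracy = trace of the confusion
matrix / n.

## Band selection

* **WRC** — the weighted regression coefficient wβ_j = β_j · sd_j
  (equivalent to the coefficient of a fit on autoscaled X, up to one
  positive constant). Interior local maxima of |wβ| (plateaus collapse to
  their centre) are ranked by |wβ_j| × mean intensity, because a large
  coefficient at a wavelength with no light contributes nothing
  exploitable; the top k (default 5) are kept. Inside the cascade the
  coefficient curve is first smoothed with a short Savitzky–Golay pass
  (window 17, order 2) so each physical absorption feature appears as one
  ranked peak instead of a cluster of sampling-noise wiggles; `wrc_select`
  itself implements the literal peak definition.
* **SFS** — greedy forward selection of k = 3 columns minimizing the
  cross-validated misclassification of a PLS-DA model on the candidate
  set; ties break toward the lower wavelength.
* **SPA** — the successive projections algorithm: from every start column,
  repeatedly add the column with the largest norm after projection onto
  the orthogonal complement of the selected span (k = 3); chains are
  scored by the misclassification of a PLS-DA model on an internal seeded
  70/30 split, and the best chain wins.
* **Pooling** — the sorted, de-duplicated union of the three selectors'
  picks (de-duplication by column index; two picks 0.5 nm apart are
  distinct columns even if they print as the same integer nm).
* **Forward stepwise** — OLS of the numeric label on the pooled columns,
  entering at each step the candidate with the smallest partial-F p-value
  if it clears the threshold; thresholds 0.05, 0.01, 0.001, 0.0001 plus a
  pass-through row that keeps the pooled set. Forward-only entry makes
  the selections provably nested across thresholds. No multiplicity
  correction is applied (none is part of the procedure being modelled).

The cascade runs the three selectors on the calibration rows restricted
to 550–600 nm — the region where the coefficient curve concentrates its
weight — then pools, prunes, refits PLS-DA per band set (A by CV) and
evaluates on the held-out rows. The cascade operates on raw (unpretreated)
transmittance by default: per-spectrum normalizations such as SNV
redistribute localized absorption information across the whole axis, which
inflates apparent relevance of non-chemical wavelengths and degrades band
interpretability. Any `PreprocessSpec` can still be applied upstream via
the pipeline configuration.

## Numerical choices

* NIPALS stops with an error if the X–y covariance norm falls below 1e-14
  (excess components on exhausted data).
* SPA treats projected norms below 1e-12 as rank exhaustion and stops the
  chain early, recording the event in its trace.
* MSC rejects slopes ≤ 1e-12 (spectrum uncorrelated with the reference).
* Stepwise stops early when fewer than three residual degrees of freedom
  would remain.
* The stepwise tie-break (identical p-values) and the SFS tie-break both
  favour the lower wavelength; selector traces are fully deterministic
  given a seed.

## Problem sizes

The test suite and the acceptance script work at the study's native scale
(750 spectra × 2068 wavelengths per cell, 525/225 split); oracle
equivalence checks use small random matrices (20×10, 15×30, 45×6) where
brute-force references are exact. The full 6-cell × 8-pretreatment grid
lives in `analysis/03_full_band_models.py`.

## Known limitations

* The 0/1/2 numeric coding imposes an ordering on the classes; a single
  PLS1 score must place bloody between normal and yolk-destroyed. The
  generator's classes are compatible with such an ordering; datasets
  without it would need PLS2/one-hot variants, which are out of scope.
* Splitting is by scan, not by egg: rotations of one egg can land on both
  sides of the 70/30 split, so validation accuracy is optimistic relative
  to an egg-held-out design. This mirrors the modelled procedure and is
  kept deliberately.
* Stepwise p-values inherit the same pseudo-replication and are
  anti-conservative; they are used as a ranked pruning device, not as
  inference.
* `choose_components`' one-SE rule is a convention; other defensible rules
  (minimum, paired-t) pick slightly different A on noisy data.
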