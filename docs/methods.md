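# Methods

## The classification problem

An intraoperative DRS probe touches tissue at a measurement location and
records three replicate spectra on two spectrometers (visible 400–1100 nm,
near-infrared 900–1700 nm). Ground truth comes from histopathology of the
marked location: fat, healthy colorectal wall, or tumor, with the depth of
the first tumor tissue below the measurement surface and the lateral
extent of tumor on the section. The task is a three-class discrimination
with two clinically motivated twists: a location only counts as tumor if
tumor lies within the probe's sensing depth, and the decision threshold
must be movable to a regime where false negatives are forbidden.

## Preprocessing

Per band, `(raw − dark) / (white − dark)` with the patient's own reference
frames removes lamp spectrum, fiber throughput and detector offset;
negative values (noise below the dark level) are clipped to zero since
reflectance is non-negative. The two bands are resampled onto one uniform
grid (default 5 nm, giving 261 features over 400–1700 nm) and blended with
a linear cross-fade across their 900–1100 nm overlap — a deliberate choice
over a hard cut, which would leave a step discontinuity a linear
classifier could latch onto. Finally each spectrum is divided by its value
at 800 nm, obtained by linear interpolation so the grid need not contain
800 exactly; the operation is idempotent and scale-invariant, which the
tests assert. The merged single-vector representation of the two bands is
this package's choice; per-band feature vectors would be an alternative.

## The cascade

Stage 1 is a linear SVM, fat vs {wall, tumor} (merged for training);
stage 2 a linear SVM on wall and tumor spectra only. At prediction, a
spectrum with a positive stage-1 score is fat and never reaches stage 2;
otherwise it is tumor iff its stage-2 score strictly exceeds the tumor
threshold (default 0). Ties therefore go to the healthy side,
deterministically and consistently with the threshold semantics below.
The SVM cost parameter defaults to 1.0 and there is no feature scaling
beyond the 800 nm normalization — the discriminant operates on the
normalized spectra directly. After fitting, only the weight vector and
bias of each stage are retained (the fit is a deterministic convex
problem, so refitting reproduces them bit-for-bit).

For threshold sweeps a single monotone per-spectrum tumor score is needed
even for spectra routed to fat; the cascade tumor score is defined as
`min(−s_fat, s_stage2)` — tumor-like only if non-fat *and* on the tumor
side of stage 2. The analogous wall score is `min(−s_fat, −s_stage2)`.
These scores drive the one-vs-all ROC curves and the zero-FN calibration.

## Cross-validation

The fold unit is the measurement location, keeping the three replicates of
a site together — replicate leakage across folds is the worst optimism
distortion available here. Folds are stratified by class; an optional
grouped mode additionally keeps every patient inside one fold (default
off). The k-fold split is repeated (default 10×10) with reshuffled folds;
metrics are computed per repeat and reported as mean ± SD. Location-level
results use the majority vote of the three replicate predictions (ties
broken toward tumor, then wall — the cautious direction) and the mean of
the replicate tumor scores.

## Metrics

All multi-class results are scored one-vs-all. MCC is computed directly
from the 2×2 counts; when any marginal is zero the conventional value 0 is
returned (the tests verify MCC equals the Pearson correlation of the two
binary label vectors on every small table). Sensitivity/specificity with
an empty denominator are reported as undefined (`None`), not zero. The
weighted accuracy is the per-class accuracy weighted by per-class item
counts. ROC curves sweep all distinct score thresholds (anchored at (0,0)
and (1,1)); AUC is the trapezoid integral, equal to the normalized
Mann–Whitney statistic.

## Depth procedures

A location is labeled tumor when tumor lies within `max_depth_mm`
(default 1.5 mm ≈ the sensing depth at 1.29 mm fiber separation) of the
surface; within that depth but with lateral extent under 0.5 mm the
histology correlation is inconclusive and the location is excluded.
Tumor-class locations deeper than the rule are labeled wall — that is what
the probe actually sees. The depth sweep re-runs the whole relabel → drop
excluded → cross-validate cycle per candidate depth (default grid 0, 1,
1.5, 2, 3, 4, ∞ mm); bins with no tumor locations are flagged `empty`,
bins with fewer than k flagged `insufficient`, never silently dropped.

## Zero-false-negative operating point

Calibration uses *out-of-fold* location scores only (resubstitution scores
would make FN = 0 trivially optimistic), averaged over replicates and
repeats. The threshold is placed at the midpoint between the minimum
tumor score and the largest healthy score strictly below it; if no score
lies below, a small epsilon below the minimum tumor score. Calling tumor
requires strictly exceeding the threshold, so a healthy location tied
exactly with the minimum tumor score counts as a false positive. This
placement guarantees FN = 0 on the calibration subset and provably
minimizes FP subject to that constraint (tested against brute-force
enumeration). The calibrated threshold is then applied to the
surgeon-uncertain locations, collapsed to healthy (fat ∪ wall) vs tumor,
and both raters' 2×2 tables against histopathology are reported.

## The synthetic generator

What it emulates: class-specific absorption (Gaussian pseudo-chromophore
bands for oxy/deoxyhemoglobin, water, lipid — fixed module constants, not
literature extinction tables) and power-law scattering feed the
extrapolated-boundary dipole solution of the diffusion approximation at
the 1.29 mm separation; spectra are imprinted on a blackbody-shaped white
reference with a dark offset and multiplicative Gaussian noise (default
1 % of signal), split into the two instrument bands; buried tumors mix
toward an overlying-wall spectrum with weight `exp(−depth/1.29 mm)` —
the simplest model that reproduces the qualitative decline of tumor
detectability with depth.

Default study conditions: 32 patients with 4 fat / 3 wall / 2 tumor
locations each (echoing the fat-heavy imbalance of the reference study),
3 replicates per location, tumor depth = 25 % surface mass plus an
exponential tail (scale 2 mm, truncated at 6 mm) so every depth bin is
populated, 35 % of tumor locations inconclusive (extent < 0.5 mm), 20 % of
locations judged uncertain by the surgeon, who then over-calls tumor on
healthy tissue at rate 0.69 (and errs at 2 % when certain). Tissue optical
parameters are plausible in vivo values chosen once — fat: strong lipid
band, little blood/water; wall: watery perfused muscle; tumor: roughly
double the wall's blood at lower oxygen saturation, steeper scattering
slope — they are not fitted to any measurement.

What it does **not** emulate: specular contamination, probe-pressure and
blood-pooling artifacts, fibrosis/inflammation as separate tissue states,
inter-patient covariance of optical parameters beyond patient-wise
reference gain, and wavelength-dependent detector noise. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
its qualitative behaviours (class separability ordering, depth decline,
threshold trade-off) follow from the physics built into the generator —
not that the quantitative accuracies transfer to real surgical data. On
the defaults the synthetic classes separate more cleanly than real tissue
does (per-class MCC ≈ 0.92–1.0 vs the ~0.73–0.83 reported in vivo), which
is acceptable because the acceptance checks are structural (thresholded
from below or qualitative orderings), not point reproductions.

## Numerical choices

* Diffusion reflectance uses an index-matched boundary (A = 1); the
  monotonicity contracts (strictly positive, strictly decreasing in μa)
  are what downstream code relies on and are property-tested.
* Band stitching interpolates linearly; the cross-fade weight is linear in
  wavelength across the actual band overlap.
* Degenerate inputs raise typed errors (`white = dark`, non-overlapping
  bands, non-positive 800 nm anchor, class absent at training, class
  smaller than k at fold construction, empty calibration subset).
* All randomness is `numpy.random.default_rng` seeded from a single
  top-level seed; per-repeat fold seeds are drawn from it, so every result
  is bit-reproducible.
* Problem sizes in the test-suite and acceptance script (8–32 patients,
  k = 5–10, 1–10 repeats, two-point depth grids where only the contrast
  matters) are the package's default desk-scale choices; the library
  accepts arbitrary sizes.

## Known limitations

The generator's separability is optimistic (see above). Patient-level
grouping is off by default; with strong per-patient effects in real data
the grouped mode should be preferred. The zero-FN guarantee is a property
of the calibration subset only — on new locations false negatives remain
possible, exactly as in the clinical procedure it mirrors.
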