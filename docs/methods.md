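# Methods

This note documents the models, defaults and numerical choices behind
`hippomrs`, and what the synthetic data do and do not establish.

## Signal model and spectral fitting

A free induction decay is modelled as a sum of damped complex exponentials
(Lorentzian lineshape):

    s(t_n) = Σ_k a_k · exp(iφ_k) · exp((−π·lw_k + i·2π·f_k)·t_n) + ε_n

with amplitudes `a_k` (arbitrary units, proportional to concentration ×
contributing protons × relaxation attenuation), frequency offsets `f_k` (Hz
from the transmitter, converted from ppm via the 123.25 MHz proton frequency
at 3 T), linewidth `lw` (Hz; for a Lorentzian this equals the
frequency-domain FWHM) and circular complex Gaussian noise `ε_n` of
per-channel SD σ. Prior knowledge enters as hard constraints: the five
metabolite peaks (NAA 2.01, Cho 3.20, Cr 3.03, Glx 2.35, Ins 3.56 ppm) have
phases fixed at 0, amplitudes ≥ 0, frequencies free within ±0.1 ppm of the
nominal shift, and a single linewidth that is free on NAA and tied equal on
the other peaks. The water reference is fitted with one Lorentzian whose
global phase is free (water is unsuppressed and its phase is independent of
the metabolite phasing).

**Preprocessing.** Zero-order phasing maximises the integral of the real
spectrum; taken over the full bandwidth (which carries all the metabolite
signal) this integral equals `N·Re(s[0])` by the DFT sum identity, so the
maximiser is `φ = −angle(s[0])` — exact for phase-rotated sums of zero-phase
Lorentzians and unbiased under noise, whereas a sub-window integral picks up
a dispersion-tail bias from peaks near the window edge. Apodization then
multiplies the FID by `exp(−π·1 Hz·t)`, adding 1 Hz of Lorentzian line
broadening (an apodized Lorentzian stays in the model class, so exact
recovery is preserved; reported linewidths are generated + 1 Hz).

**Optimisation.** Trust-region reflective least squares on the stacked
real/imaginary residual with an analytic Jacobian; tolerances 1e-10 on cost
and 1e-12 on step/gradient, at most 500 function evaluations. Starting
amplitudes come from magnitude-spectrum peak heights in ±0.1 ppm windows
(converted by the discrete-Lorentzian height relation
`height ≈ a/(1 − e^(−π·lw·Δt))`), starting linewidth 6 Hz.

**Noise, SNR, CRLB.** The noise SD is estimated from the final 10 % of the
FID (signals of ≥ 4 Hz linewidth have decayed to < 1e-3 of their initial
value by 0.37 s), pooling real and imaginary parts; if the signal was
apodized, the tail estimate is referenced back to the unapodized level by
the RMS of the apodization window over the tail, since SNR and the
Cramér–Rao computation assume stationary noise at the original amplitude.
SNR is defined as the tallest fitted metabolite peak in the real absorption
spectrum over 0–4 ppm divided by the frequency-domain noise SD (σ·√N); FWHM
is the fitted linewidth. Amplitude CRLBs are computed from the full joint
Fisher information `JᵀJ/σ²` at the solution — correlations between
overlapping peaks included — and reported as a percentage of the amplitude
(flagged non-finite for amplitudes pinned at zero). Monte-Carlo calibration
(200 noise realisations at the default SNR ≈ 25) puts the empirical
amplitude scatter within about 10 % of the reported bound.

**Quality control.** A spectrum enters the analysis only if SNR ≥ 15,
FWHM ≤ 16 Hz, and CRLB < 20 % (strict) for every metabolite used downstream;
the CRLB gate is configurable to a per-metabolite subset.

## Voxel placement

Placement maximises the overlap between a fixed-size box (default
10×10×15 mm) and the hippocampus mask. Overlap is the count of mask cells
whose centres fall inside the box, times the cell volume — matching the
segmentation's own discretisation. Box faces are half-open
(−s/2 ≤ d < s/2 per axis) so an aligned lattice is counted exactly once per
cell and the counted volume never exceeds the box volume. Candidates form a
1 mm translation grid anchored at the mask centroid and padded by one box
length around the mask's bounding box; the scan is exhaustive (for
axis-aligned boxes the per-axis membership tests factorise, so the whole
lattice is a single three-way contraction; exhaustive-search equivalence is
tested against a plain triple loop). Rotations are off by default and can be
scanned in 5° increments — the placement description mentions only
translation, but the location file records per-axis angulation, so both are
supported. Ties are broken by distance to the mask centroid, then
lexicographically: fully deterministic. Left and right hippocampi are
optimised independently.

`overlap_between` (the percentage of a reference box encompassed by a
follow-up box) uses dense point sampling of the reference box at a
configurable resolution (0.5 mm default). `map_placement` applies a 4×4
affine: the rotational part (polar decomposition via SVD) composes with the
placement rotation; non-rigid affines rescale the edge lengths by the
singular values with a warning. Tissue fractions count segmentation cell
centres per class inside the box; hippocampus labels count as gray matter.

**Repeat-session overlap.** At follow-up the recorded week-0 placement is
re-prescribed on the scanner, so session-to-session variability is modelled
as a small rigid perturbation of the recorded box — per-axis Gaussian
translation (SD 0.5 mm) and rotation (SD 1°), typical of automated voxel
prescription. Twenty simulated subjects × six sessions give a mean overlap
near 90 %. A mask-jitter helper (`jittered_phantom_spec`) exists for
experiments where the segmentation itself is perturbed.

## Absolute quantification

Concentrations use the internal-water reference formula (see README) with
`C_W = 55.51 mol/kg` (pure-water molality, kept as the conventional
default), proton counts water 2, NAA 3 (CH₃), tCho 9 (N(CH₃)₃), tCr 3
(CH₃), Ins 6, Glx 2, and a 3 T relaxation table (ms): water 1100/80,
NAA 1400/250, tCho 1150/220, tCr 1240/160, Glx 1200/180, Ins 1100/200.
All of these are configuration, not code constants. The relaxation factors
are implemented as `f^T1 = 1 − e^(−TR/T1)` and `f^T2 = e^(−TE/T2)` — the
physically consistent forms (a saturation factor must be < 1; T2 decay
accrues over the echo time). One `te_ms` enters both the water and
metabolite T2 factors; acquiring the water reference at a different TE
would need a second timing parameter and is a known simplification. CSF
carries no metabolite signal, so `C_cor = C_raw·V_total/(V_total − V_CSF)`
(computed ratio-first so V_CSF = 0 is an exact identity). Bilateral
averaging takes the arithmetic mean when both sides pass QC, falls back to
a flagged single side, and returns a reasoned missing value when neither
passes.

## Statistical analysis

All tests are two-sided at α = 0.05 with no multiplicity correction.

- **Group comparisons**: pooled-variance Student t (df = n₁+n₂−2; the
  pooled form, not Welch, reproduces published df and t values from group
  summaries) and Pearson χ² on 2×2 tables without continuity correction.
- **Trend over treatment weeks**: a linear-in-week contrast inside a
  one-way across-week ANOVA; the contrast t and its p ("p for trend").
  Calibration note: on longitudinal data with strong subject effects the
  week-wise MSE overstates the contrast variance, making this form
  conservative; its type-I error is verified at the nominal 5 % on
  independent week samples.
- **Covariate adjustment**: OLS of the response on a group indicator plus
  age, gender, age of onset and illness duration; the group coefficient's
  t/p is reported. Zero-variance or collinear columns raise an error naming
  the column.
- **Test–retest reliability**: two-way mixed-effects, single-measure,
  consistency ICC — ICC(3,1) = (MS_subjects − MS_error)/(MS_subjects +
  MS_error) for two sessions — cross-checked against `pingouin`'s ICC(C,1);
  values > 0.7 flag good reliability.
- **Stepwise logistic regression**: bidirectional selection on Wald
  p-values (entry < 0.05, removal > 0.10), deterministic tie-breaks by term
  order; covariates compete for selection by default (a force-covariates
  mode exists). Perfect separation is detected and handled by a small-ridge
  fallback with the result flagged. With five pure-noise candidates the
  familywise probability that anything enters is 1 − 0.95⁵ ≈ 23 %, which
  the null-calibration test asserts.
- **ROC**: Mann–Whitney AUC with ties counted half; DeLong 95 % CI;
  operating threshold by the Youden index; validation sets are scored with
  the training threshold held fixed, with the refractory (RD) class
  positive.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

**Phantom.** Concentric ellipsoidal CSF/GM/WM shells inside a 90×110×90 mm
grid at 1 mm isotropic resolution, with two disjoint 8×8×10 mm-semi-axis
hippocampal ellipsoids. No atlas realism is attempted — the phantom exists
to give the placement and tissue-fraction code exact geometric ground truth.

**FIDs.** TE 35 ms, TR 2000 ms, 5000 Hz spectral width, 2048 points, 128
averages; 5 Hz generated linewidths; complex noise SD 80/√128 per channel,
which lands the processed spectra at SNR ≈ 20–30 — the range typical of
hippocampal single-voxel acquisitions at 3 T. `from_concentrations` encodes
known concentrations through the inverse of the quantification formula so
the full chain can be checked for exact recovery.

**Cohort.** 26 RD, 41 n-RD, 20 HC; weeks 0–6. Baselines (mmol/kg): NAA 8.2,
tCho 1.55, tCr 6.9, Glx 8.8, Ins 5.4, with between-subject SDs of roughly
10 %. Group trajectories emulate the qualitative response pattern: tCho
rises from week 2 in both patient groups (more in n-RD), NAA rises from
week 2 in n-RD but only from week 3 in RD, Glx rises from week 3, Ins and
tCr stay flat; week-3 between-group contrasts on tCho and NAA are sized to
be detectable at n = 26/41. Within-visit noise SDs are set so the
healthy-control test–retest ICCs reproduce the observed reliability
pattern — good (≈ 0.75–0.9) for NAA, tCho, tCr, Ins and poor (≈ 0.6) for
Glx, whose 3 T measurement is intrinsically noisy. Each patient carries a
latent response propensity η ~ N(0,1): the realised week-6 HDRS reduction
is the group mean reduction + 0.12·η, and the metabolite rises share the
same η through per-metabolite couplings (NAA 0.30, tCho 0.10, Glx 0.30
mmol/kg per SD on the week ramp), which is what makes early metabolite
changes prognostic. The HDRS decline has a subject-specific onset delay
(SD 1.5 weeks, renormalised to reach the full reduction at week 6) plus
visit noise (SD 2 points): clinical response latency varies between
patients, so the early HDRS change predicts the final outcome less well
than the early metabolite change — the ordering the prediction analysis
rests on. Covariates (age, gender, onset age, illness duration) are drawn
independently of group by default, with an optional onset-age shift knob.
The response label is recomputed from the realised HDRS values (n-RD iff
the week-6 reduction is ≥ 50 %, the boundary counting as response;
reduction 0.25 counts as partial response); it agrees with the generative
group for ≈ 90 % of subjects.

**What passing tests show.** The synthetic cohort has Gaussian noise,
no missing visits, no scanner drift, no macromolecule baseline and a
single-composite Glx. Green tests therefore establish that the estimators,
corrections and selection machinery are correct and calibrated under their
stated assumptions — not that the clinical effect sizes or the published
odds ratios/AUCs would be reproduced on real patients, whose data are not
available.

## Problem sizes

Defaults throughout are the study's acquisition and cohort sizes (2048-point
FIDs, 26/41/20 subjects × 7 visits, validation 22/35). Monte-Carlo checks
use 200 noise realisations for CRLB calibration, 500 replicates for null
calibration and selection power, 40 cohorts for AUC medians, and 20
simulated subjects × 6 sessions for repeat-placement overlap — sizes at
which the binomial/Monte-Carlo error is comfortably below the asserted
margins while the whole suite stays interactive.

## Known limitations

- Gaussian/Voigt lineshapes, baseline and macromolecule modelling,
  eddy-current and drift correction are out of scope.
- The trend ANOVA treats weeks as independent groups (see above); a
  mixed-effects trend would be more efficient on longitudinal data.
- The CRLB assumes white stationary noise; after apodization this makes the
  reported bound mildly conservative.
- Registration is consumed as an affine, never computed; segmentation is
  synthetic, never estimated from images.
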