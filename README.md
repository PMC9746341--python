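# hippomrs

Hippocampal single-voxel ¹H-MRS quantification and antidepressant
treatment-response prediction.

## The problem

In major depressive disorder, at least six weeks of treatment are usually
needed before a non-response can be declared. Quantitative proton MR
spectroscopy of the hippocampus offers a way to shorten that window: the
concentrations of choline-containing compounds (tCho) and N-acetyl-aspartate
(NAA) begin to rise within 2–3 weeks in patients who will eventually respond,
before the clinical rating scale (HDRS-17) separates the groups. `hippomrs`
implements the full analysis chain needed to study and exploit that signal:

1. **Voxel placement** (`hippomrs.voxelplace`) — place a fixed 10×10×15 mm
   acquisition box on a hippocampus segmentation mask by exhaustively scanning
   a candidate grid for the position of maximal overlap; persist placements in
   a `Voxel_Location.txt` file; map them across spaces with an affine; report
   cross-session geometric overlap and GM/WM/CSF tissue fractions.
2. **Spectral fitting** (`hippomrs.spectral`) — AMARES-style time-domain
   nonlinear least squares of the free induction decay with hard prior
   knowledge: five Lorentzian peaks (NAA, Cho, Cr, Glx, Ins), phases fixed at
   0, one shared linewidth tied to NAA, non-negative amplitudes, bounded
   frequencies. Cramér–Rao lower bounds come from the joint Fisher
   information; quality control gates at SNR ≥ 15, FWHM ≤ 16 Hz, CRLB < 20 %.
3. **Absolute quantification** (`hippomrs.quantify`) — internal-water
   referencing with relaxation correction,
   `C_M = (S_M/S_W)·C_W·(n_W/n_M)·(f_W^T1/f_M^T1)·(f_W^T2/f_M^T2)` with
   `f^T1 = 1 − e^(−TR/T1)`, `f^T2 = e^(−TE/T2)`, `C_W = 55.51 mol/kg`,
   followed by CSF partial-volume correction
   `C_cor = C_raw · V_total/(V_total − V_CSF)` and bilateral averaging.
4. **Statistics and prediction** (`hippomrs.stats`, `hippomrs.predict`) —
   pooled-variance t tests, 2×2 χ², linear-in-week trend contrasts,
   covariate-adjusted linear models, consistency ICC for test–retest
   reliability, Pearson correlations of differentiated scores, bidirectional
   stepwise logistic regression (Wald entry p < 0.05, removal p > 0.10) of the
   week-6 refractory / non-refractory (RD / n-RD, split at 50 % HDRS
   reduction) label, and ROC analysis with DeLong confidence intervals and
   Youden operating points.
5. **Synthetic data** (`hippomrs.synthdata`) — every input the pipeline needs
   with known ground truth: brain-like label volumes with ellipsoidal
   hippocampi, water-suppressed and water-reference FIDs (TE 35 ms, TR
   2000 ms, 5000 Hz, 2048 points, 128 averages), and a longitudinal
   RD / n-RD / healthy-control cohort whose tCho/NAA/Glx trajectories diverge
   from weeks 2–3 onward while Ins and tCr stay flat.

## Worked example

```python
from hippomrs import (AcquisitionParams, AmaresModel, CohortSpec,
                      GroundTruthSpectrum, ResponsePredictionModel,
                      generate_cohort, generate_fid)
from hippomrs.spectral import preprocess

acq = AcquisitionParams()                      # TE 35 ms, TR 2 s, 5 kHz, 2048 pts
truth = GroundTruthSpectrum(noise_sd=80.0)     # 5 Lorentzians + complex noise
fid, water = generate_fid(truth, acq, seed=7)
fit = AmaresModel(preprocess(fid)).fit()
print(fit.summary())

cohort = generate_cohort(CohortSpec(seed=5))   # 26 RD / 41 n-RD / 20 HC, weeks 0-6
results = ResponsePredictionModel.from_cohort(cohort, week_pair=(0, 3)).fit()
print(results.summary())
```

prints

```
AMARES fit results
==================
converged: True   iterations: 5
noise SD (time domain): 6.833
SNR: 22.54   FWHM: 5.96 Hz   RSS: 7.095e+04

  peak    amplitude  freq (ppm)  lw (Hz)    CRLB%
   NAA       24.797      2.0101    5.956     2.64
   Cho       12.891      3.1992    5.956     4.67
    Cr       18.693      3.0312    5.956     3.33
   Glx       15.649      2.3494    5.956     3.92
   Ins       29.649      3.5605    5.956     2.29

Stepwise logistic regression — outcome: label
retained terms: d_tcho, d_naa
        term      beta     S.E.      Wald         P              OR (95% CI)
      d_tcho    -7.002    2.462     8.086   0.00446    0.001 (0.000~0.114)
       d_naa    -1.853    0.757     5.988   0.01441    0.157 (0.036~0.692)
training ROC: AUC = 0.840 (95% CI 0.742-0.939), sens = 0.758, spec = 0.853 at threshold 0.111
```

The spectral fit recovers the five amplitudes with a shared ~6 Hz linewidth
(5 Hz generated plus 1 Hz apodization) and per-peak Cramér–Rao bounds of a few
percent, passing all three QC gates. On the simulated cohort, the stepwise
screen retains the week-0→3 tCho and NAA changes — both with odds ratios
below 1, i.e. a larger early metabolite *rise* predicts a *lower* risk of
remaining refractory — and the combined linear predictor discriminates the
week-6 outcome with an AUC of 0.84.

## Command-line pipeline

The `hippomrs` console script chains the stages
`simulate → place → fit → quantify → analyze → predict`:

```bash
hippomrs run-all --outdir out --seed 1          # or each stage individually
```

Each stage reads the previous stage's files from `--outdir`, writes CSV/JSON
outputs plus a provenance log, and is fully reproducible from config + seed.
A YAML config (see `hippomrs.config.PipelineConfig`) overrides any generator,
QC, search or statistics parameter; unknown keys are rejected by name.

## Limitations

The synthetic cohort is a qualitative emulation — Gaussian noise, no dropout,
no scanner drift, single-composite Glx — so pipeline results on it validate
the machinery, not clinical effect sizes. See `docs/methods.md` for the full
model description, parameter rationale and numerical choices.
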