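# Methods

`gaitnirs` implements the full analysis chain of a longitudinal pediatric
fNIRS study of robotic-assisted gait training (RAGT): continuous-wave optical
recordings acquired during a block-design walking task at three training
sessions (T0, T1, T2), converted to hemoglobin concentration changes, reduced
to per-channel activation amplitudes, and linked to the children's gross
motor function (GMFM-88). Because no patient recordings ship with the
package, a synthetic-data generator with known ground truth stands in for
them; every stage is validated by parameter recovery against that truth.

## Optics: modified Beer–Lambert law

Raw two-wavelength intensities I(t) are converted to optical-density changes
ΔOD(t) = −ln(I(t)/Ī), with Ī the mean intensity over a configurable baseline
window (default: the whole recording — only signal *variations* feed the
GLM, so the baseline choice shifts the intercept, never the task β).
Concentration changes follow from the 2×2 linear system

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HHb(λ)·ΔHHb] · d · DPF(λ)

solved per channel and sample. Conventions that matter:

* **Natural-log OD throughout.** The bundled extinction table
  (`data/extinction_coefficients.csv`, Gratzer/Kollias compilation at
  760/850 nm, cm⁻¹/M) is stored in the published base-10 convention and
  multiplied by ln 10 on load. Keeping one convention end to end eliminates
  the silent factor-2.303 error class.
* **DPF** from the general (wavelength, age) equation — a cubic polynomial
  in λ plus a power law in age — with the published coefficient set bundled
  as `data/dpf_coefficients.json`. DPF is computed per participant from age;
  at 10 y it is ≈5.68 (760 nm) and ≈4.62 (850 nm).
* **Separations** are configuration, not data: 30 mm for the 34 long
  channels, 8 mm for the 4 short channels. Short channels are inverted with
  the same MBLL using their own separation; their concentrations serve only
  as nuisance regressors.
* The probe layout (16 sources, 10 detectors) is a schematic 2-D scalp map
  built in code; positions are used for nearest-short-channel pairing and
  plotting only. Channel→Brodmann-area annotations are a static versioned
  table (`data/channel_brodmann.csv`) covering the channels with published
  labels; the rest are blank.

The inversion is the exact inverse of the forward map (round-trip relative
error ≤1e−9 on random draws), and the map is linear — both are enforced by
tests.

## Preprocessing

Stage order is wavelet → band-pass → short-channel regression (configurable);
artifact spikes are removed first because they corrupt both the IIR filter
and the regression if left in. Short channels pass through the same wavelet
and filter stages before being used as regressors.

* **Wavelet artifact suppression.** Per channel: discrete wavelet
  decomposition (Daubechies-5, depth ⌊log₂N⌋−4 by default), a robust
  Gaussian model of each detail level's coefficients (MAD scale,
  median-centered), coefficients in the two-sided α=0.1 tail set to zero,
  inverse transform trimmed to the input length. This suppresses transient
  spikes by ≥80% while keeping clean signals at r>0.95 to their input — but
  it is not free: on block-design signals it also clips some genuine coarse-
  scale response energy, contributing roughly −3% systematic bias to the
  recovered β (see "Recovery accuracy" below).
* **Band-pass.** 3rd-order Butterworth prototype, 0.01–0.4 Hz, applied
  forward–backward (zero phase; the effective magnitude response is
  6th-order). The reflect-padding length is set to ~3/f_low seconds — with a
  0.01 Hz low cut the default few-sample padding would leak edge transients
  hundreds of seconds into the series.
* **Short-separation regression.** Per long channel y and its paired,
  same-chromophore short-channel series s: y′ = y − (⟨y,s⟩/⟨s,s⟩)s. The
  residual is exactly orthogonal to the regressor and the operation is
  idempotent. Pairing defaults to the nearest short channel on the scalp
  map; one short channel may serve many long channels. Regression is
  per-chromophore (HbO with HbO, HHb with HHb) — an assumption, since joint
  variants exist. A zero-variance short channel passes its long channels
  through unchanged with a logged warning.

## GLM

Each channel/chromophore series is modelled as Y = Xβ + ε with ordinary
least squares. The task regressor is the active-block boxcar convolved with
a canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1:6 —
pediatric responses may deviate; parameters are exposed) and normalized to
unit peak, so the task β reads directly as peak response amplitude in µM.
Remaining columns: intercept and a linear drift (the band-pass already
removes slower trends; higher orders risk collinearity with the 0.01 Hz
high-pass). Standard errors are the naive OLS ones — group inference
operates on β point estimates only, so serial-correlation prewhitening is a
documented extension, not a default.

**Matched filtering.** The zero-phase band-pass is not transparent at the
block fundamental (1/60 Hz): its squared magnitude there is ≈0.955, so
regressing filtered data on an unfiltered regressor biases β by about −5%.
The pipeline therefore applies the *identical* filter operator to the task
column (`fit_hemoglobin(..., filter_spec=...)`). Intercept and drift columns
stay unfiltered — they model exactly the components the filter leaves near
zero. `build_design` itself never filters.

### Recovery accuracy

On the full synthetic chain (simulate → optics → preprocess → GLM) at the
generator defaults, the per-channel median relative error of the task β over
20 seeds is ≤9% for both chromophores (test-enforced at <10%). The residual
bias is dominated by the wavelet stage's clipping of coarse detail
coefficients plus imperfect artifact removal; with artifacts disabled and
the wavelet stage skipped the chain is unbiased to <1%.

## Synthetic data

The generator is the package's stand-in for the (non-deposited) patient
recordings and defines the study conditions:

* 10 blocks of 30 s active / 30 s rest (600 s at 10 Hz; sampling rate is a
  free parameter of the simulator, 10 Hz being typical for CW-fNIRS and
  above all modelled oscillators).
* HRF-locked activation per long channel; default amplitudes 0.5–1.0 µM HbO
  with HHb = −⅓·HbO (antiphase BOLD-like response).
* Physiological oscillators: cardiac ≈1.5 Hz (pediatric), Mayer ≈0.1 Hz,
  respiration ≈0.3 Hz, plus two very slow drift tones, each with random
  phase and slow amplitude modulation. Mayer/respiration/drift form the
  *shared superficial component*: short channels carry it with gain 1, long
  channels with per-channel gains in [0.5, 1.5]. Cardiac is per-channel.
* Motion artifacts: Gaussian-bump spikes (0.5–2 s wide, 2–5 µM, ~5 per
  recording) and occasional baseline steps (±0.2–0.5 µM, ~1 per recording)
  at Poisson-random times, common-mode across channels with per-channel
  scale.
* White sensor noise, 0.05 µM.
* Concentrations are forward-mapped through the same MBLL the optics module
  inverts and exponentiated to intensities, so the inversion is exact by
  construction up to the per-channel baseline constant (absorbed by the GLM
  intercept).

Cohorts: n subjects × sessions (default 8 × T0/T1/T2). Designated
informative channels (default 7, 12, 14) gain ~0.25 µM per session step
(per-subject variation 0.15); GMFM-88 at the last session equals the
baseline score (drawn from 10–30, matching the severely affected cohort)
plus 60 points per µM of mean informative-channel β change, plus clinical
noise (default SD 3), clipped to [0, 100]. A second generator
(`generate_beta_cohort`) draws β tables directly — channel means + subject
random effects + session effect + noise — for group-statistics and
regression experiments that need hundreds of cohorts; the signal-level
generator validates that the GLM actually delivers such tables.

What the generator does *not* emulate: real optode-scalp coupling variation,
hair/pigmentation attenuation, non-stationary heart rate, task-correlated
systemic arousal (the superficial component is task-independent by design),
and anatomical variability. Passing tests therefore demonstrate internal
consistency of the chain under a standard contamination model, not clinical
validity on real recordings.

## Group statistics

* **Channel-wise RM-ANOVA** across sessions with Greenhouse–Geisser ε
  estimated from the double-centered session covariance; corrected dfs
  df1 = ε(k−1), df2 = ε(k−1)(n−1) (fractional, as in the study's reported
  F-statistics; the correction is implied by those fractional dfs even
  though never named). ε is clipped to [1/(k−1), 1]. The per-channel n is
  data-driven, never assumed equal to the cohort size — the published
  statistics themselves imply fewer complete cases than participants on
  some channels. Bonferroni family: number of channels per chromophore.
* **Post-hoc paired t** for all session pairs, Bonferroni-corrected with
  family = channels × contrasts per chromophore (34 × 3 = 102 by default) —
  the most conservative reading of correcting for "channels and
  comparisons". Zero-variance differences are reported as undefined, not
  NaN.
* **Wilcoxon signed-rank** for the clinical scales, with the exact
  two-sided p computed by full enumeration of the 2ⁿ sign assignments for
  n ≤ 20 (midranks for ties; zeros dropped by default, Pratt handling by
  flag) and the tie-corrected normal approximation alongside. For the
  8-subject all-positive GMFM-88 change, the exact p is 2/256 = 0.0078
  (0.008 at three decimals) with |z| ≈ 2.52.
* **Shapiro–Wilk** gates parametric vs nonparametric reporting (delegated
  to scipy).
* MAS spasticity grades are ordinal {0, 1, 1+, 2, 3, 4} with "1+" encoded
  as 1.5 to preserve order.

Type-I control: on null cohorts (no session effect) the corrected
significant-channel fraction averages ≈0.1% over 200 seeds — Bonferroni plus
GG correction is conservative, as intended.

## Outcome regression

β-values feed a GMFM-88 estimator: greedy forward wrapper feature selection
driving a Gaussian-process regressor (constant × squared-exponential + white
noise kernel; features and target standardized within each training fold;
hyperparameters by marginal-likelihood maximization with seeded restarts)
under leave-one-subject-out cross-validation. All rows of a subject are held
out together. Reported: Pearson r (with p) of the pooled out-of-sample
predictions vs observations, and RMSE **on the stated scale of the target**
(`target_scale` in the report) — the scale is never normalized silently,
because a raw-scale RMSE and a normalized one differ by two orders of
magnitude and the report must say which it is.

Three feature/target layouts are supported, since the pairing of "β at T0
and T2 as input, GMFM-88 as output" is open: one row per subject×timepoint
(default), concatenated sessions → final score, and Δβ → ΔGMFM. Feature
selection may run once on the full table (the simpler, leakier variant) or
inside every LOSO fold (leakage-safe); both are available, per-fold being
the honest default for reported numbers.

The wrapper's inner objective is the exact closed-form leave-one-out
residual of the GP (r_i = [K⁻¹y]_i/[K⁻¹]_ii) with hyperparameters fit once
per candidate set — identical in spirit to refitting per inner fold at a
fraction of the cost; the outer LOSO loop always refits per fold. The
empty-model baseline is the same GP given a constant input (i.e., the
shrunken training mean), so a feature is only selected if it beats
shrinkage itself; on pure-noise features the median selected-set size stays
≤2.

### A caveat on cross-validated correlation at small n

With a leakage-safe pipeline, a shrinkage regressor that (correctly) finds
no signal predicts each held-out subject near its training-fold mean
m₋ᵢ = (Σy − yᵢ)/(n−1) — an exact linear function of −yᵢ. The pooled
out-of-sample Pearson r is then driven toward −1, not 0, under the null;
at n = 8 the permutation distribution of r concentrates near −1. This is a
known pathology of cross-validated correlation, and it means (a) a strongly
*negative* LOSO r on small cohorts is evidence of no signal, not of
anti-prediction, and (b) significance of a positive r should be judged
against the permutation distribution, not against r = 0. The alternative —
standardizing the target once globally so predictions no longer embed the
fold mean — trades this artifact for target leakage and is deliberately not
done here.

## Numerical and engineering choices

* All randomness flows from explicit integer seeds; a global pipeline seed
  fans out to per-stage seeds via `SeedSequence((seed, stage_id))`, so each
  stage is independently reproducible and reruns are byte-identical.
* Channel numbering is 1-based everywhere user-facing (matching published
  channel maps); internal arrays are 0-based with conversion confined to
  the I/O boundary.
* Recordings serialize to SNIRF v1.0 (HDF5) — readable by independent SNIRF
  implementations — and to a flat long-format CSV with a JSON metadata
  sidecar. β-maps travel as tidy CSV (subject, session, channel,
  chromophore, beta, se), the interchange format between the GLM, the group
  statistics and the regression.
* Degenerate inputs fail loudly and specifically: non-positive intensities
  name the sample and channel, dimension mismatches name the axis, rank
  deficiency names the collinear column, missing channels are listed.

## Problem sizes used in the shipped experiments

Recovery runs use the full study geometry (34+4 channels, 600 s at 10 Hz,
20 seeds). Statistical-calibration experiments use 200 directly-drawn β
cohorts; selection/regression experiments use 100 seeds at n = 8–12
subjects. These sizes make the whole validation suite run comfortably on a
single CPU while keeping Monte-Carlo error well below the asserted margins.

## Known limitations

* OLS ignores serial correlation; β standard errors are optimistic (group
  inference does not use them).
* The wavelet stage's outlier rule removes some genuine coarse-scale task
  energy (≈3% β bias at the defaults).
* The GP kernel is isotropic; no ARD, no alternative kernels.
* No real-data ingestion beyond SNIRF/CSV written by this package (foreign
  SNIRF files lack the metadata sidecar the reader requires).
* Short-channel pairing is geometric, not physiological.
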