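# Methods

## Signal models

Each voxel's time series is modelled as a GLM `y = Xβ + ε` whose task columns
encode one of four cognitive processes of a distractor/choice-RT trial:

1. **DistractorPerception** — unit impulses at distractor-image onsets.
2. **SalienceAttribution** — the same impulses plus a parametric RT
   modulator: impulses at the same times with amplitudes `rt_i − mean(rt)`
   (mean-free *before* convolution, so the modulator is orthogonal to the
   mean response in amplitude space; below-mean RTs give negative spikes).
3. **TaskExecution** — unit impulses at the motor responses,
   `onset + 0.200 s + rt_i` (the 200 ms is the delay between image onset and
   the response cue).
4. **ModulatedTaskExecution** — response-locked impulses plus the same
   mean-free RT modulator at response times.

All events are impulses (duration 0): the 200 ms image / 150 ms cue / 400 ms
image sequence is treated as a single point event per trial, since the
processes of interest are brief relative to the HRF. Missed/incorrect trials
are pooled into one stimulus-locked nuisance regressor (per-event columns
are available but rank-hazardous at low error counts). Six motion
regressors enter unconvolved; drift is modelled by an orthonormal
discrete-cosine basis with `K = floor(2 · T / cutoff)` columns
(cutoff 128 s) appended to every design rather than filtered out of the
data, so all models see identical data. A constant completes the design.

### HRF

Canonical double gamma: difference of two gamma densities with peak delay
6 s, undershoot delay 16 s, unit dispersions, peak:undershoot ratio 6,
length 32 s, sampled on a microtime grid of `dt = TR/16` and peak-normalised
to 1 (the scale is absorbed by the regression weights and cancels in model
comparison). Regressors are built by placing delta sticks on the microtime
grid, convolving, and reading out at the middle of each TR (reference slice
at TR/2). The `onset` parameter shifts the kernel and is how the simulator
realises voxel-wise hemodynamic latency.

### Temporal derivatives

The 8-model space adds, per task column, the finite difference
`(s(t) − s(t − 1 s)) / 1 s` of the convolved microtime signal. The 1 s
secant step (rather than an instantaneous derivative) is the convention for
canonical-HRF temporal derivatives: the span of {regressor, derivative} then
contains the regressor delayed by any amount up to ~1 s almost exactly,
which is what makes the derivative space a control for regional hemodynamic
latency. Derivative columns are not orthogonalised against their base
columns; model comparison is invariant to the within-model column basis.

## Evidence

Noise is whitened with a single pooled AR(1) coefficient per subject,
estimated from the lag-1 autocorrelation of OLS residuals of the
richest model and clipped to [0, 0.95]; the same whitening is applied to the
data and to every model's design so that evidence differences reflect only
the task columns. Per-voxel AR(1) is available behind a flag.

With whitened data, a normal-gamma prior `NG(μ, Λ, a, b)` over (β, noise
precision) is conjugate and the log marginal likelihood is closed-form:

```
log p(y) = ½log|Λ| − ½log|Λ'| + a·log b − a'·log b'
           + logΓ(a') − logΓ(a) − (n/2)·log 2π
```

with `Λ' = XᵀX + Λ`, `μ' = Λ'⁻¹(Xᵀy + Λμ)`, `a' = a + n/2`,
`b' = b + ½(yᵀy + μᵀΛμ − μ'ᵀΛ'μ')`. A flat prior makes this improper, so
evidence is **cross-validated**: rows are split into contiguous folds
(default 2; the natural folds are sessions when several exist), the
posterior from the training complement (noninformative start:
μ=0, Λ=0, a=b=0) becomes a proper prior, the held-out fold is scored, and
fold scores are summed. cvLME penalises complexity out-of-sample without
hand-set priors and is comparable across non-nested models. Implementation
notes: log-determinants via Cholesky; all computation in log space; the
per-voxel map path is algebraically identical but vectorised over voxels
(shared fold Cholesky factors). Event columns whose events fall entirely
inside a held-out block (e.g. a lone error-trial nuisance event) would make
the training precision singular; such columns are dropped from that fold's
design (train and test alike) — they are shared nuisance, so comparability
across models is unaffected.

A consequence worth knowing: on pure-noise voxels the winner distribution is
*not* uniform over the 2 × 2 space — the dimensionality penalty makes the
simpler, unmodulated models win ~95% of noise voxels (locking splits
50/50). Chance levels quoted for replicability (100/K %) refer to
independent uniform labellings, not to the noise-voxel winner distribution.

## Group inference

Random-effects Bayesian model selection treats the optimal model as varying
across subjects: given the subjects × models cvLME matrix per voxel, a
variational Dirichlet posterior is iterated (responsibilities
`g_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα))`, `α = α₀ + Σ_n g_nk`) to convergence
(`max|Δα| < 1e-6`, cap 1000 iterations, flat prior α₀ = 1). Likeliest
frequency is the Dirichlet mode `(α_k − 1)/(Σα − K)` when all `α_k > 1`,
else the mean `α_k/Σα` (the mode lies on the simplex boundary there).
Exceedance probability is exact via the Beta distribution for K = 2 and
Monte-Carlo otherwise (10⁶ samples for vector calls; 10⁴ per voxel for maps,
configurable; counts partition the samples so EPs sum to 1). LF and EP give
the same ranking up to Monte-Carlo noise at near-ties. Winner maps take the
LF argmax with ties broken deterministically to the lowest model index.

## Replicability and reporting

A voxel is replicable when two analyses assign it the same nonzero winner;
the replicability percentage is taken over the intersection mask. The
within-subject variant uses each subject's cvLME argmax per session, with a
percentile bootstrap (default 1000 resamples, 2.5/97.5) over subjects for
the 95% CI. Winner maps are decomposed into connected components per model
(26-neighbourhood by default, matching the boundary-drawing rule;
6/18 available), with unweighted centres of mass mapped through the affine,
a minimum reported cluster size of 10 voxels, and per-(cluster, region)
atlas-overlap rows: overlap voxels, % of cluster, region size within the
ROI and % thereof, total region size and % thereof. Atlases must be
resampled to the analysis grid with nearest-neighbour interpolation first.

## Synthetic bench

The generator emulates the study design: 120 trials (40 per valence),
ISIs balanced over {4, 5, 6, 7} s (mean exactly 5.5 s), first onset at 6 s,
TR 0.756 s, run length = trials + 30 s tail (~913 scans at full scale).
RTs are `subject_mean + condition_effect + N(0, 72 ms)` with non-positive
draws resampled; subject means are drawn `N(390 ms, 40 ms)`; condition
effects default to +12 ms (negative vs neutral, the emulated study's
session-1 value) and +6 ms (positive vs neutral, half the negative effect —
the printed tables give no positive-valence value); 2% of trials are
missed/incorrect. Reaction-time SDs per subject therefore average ~72 ms.

The spatial bench is a 20³ voxel grid at 2 mm with four 5³ signal blocks at
mutually separated corners, one per generative process, on a pure-noise
background. Per signal voxel the generative signal is the process's event
train (stimulus-locked processes include all image onsets; response-locked
ones only correct responses) convolved with the HRF shifted by that voxel's
latency, scaled by the amplitude map, plus the mean-free RT-modulation term
scaled by the rt-beta map for processes 2 and 4. Defaults: amplitude 1% of
the baseline (100), rt-beta 7 %/s (a ±1 SD RT deviation modulates the
response by ±~50% of the mean amplitude), noise AR(1) ρ = 0.3 with
stationary SD 1% (a realistic temporal noise level for smoothed 3 T EPI),
cosine drift within the high-pass band at 0.5% SD, and small random-walk
motion weakly coupled into every voxel so the motion-regressor path is
exercised. N = 20 subjects, 2 sessions sharing the ground truth. Everything
is bit-reproducible from (config, seed) via spawned seed sequences.

Reduced desk scale for tests and benchmarks: 10³ grid, 3³ blocks, 48 trials
(the nearest count balancing 3 conditions and 4 ISIs), one session. At this
scale the end-to-end group recovery experiment runs in seconds and assigns
100% of block voxels to their generative processes at default SNR.

### What the bench shows — and what it does not

- **RT variability is the information source for RT-linked processes.** With
  `trial_sd = 0` the mean-free modulator is (near-)empty, the modulated
  models reduce to their unmodulated twins, and recovery of processes 2/4
  drops from ≥80% to ≤25% (at exact ties the deterministic tie-break gives
  the unmodulated twin), while processes 1/3 are unaffected.
- **Latency confound control is SNR-limited at desk scale.** With voxel-wise
  hemodynamic onsets drawn uniformly within ±1 s on early-process voxels and
  the 8-model space at the full 120-trial design, early→late flips occur
  mostly at voxels whose delay (≳ +0.3 s) pushes the response near the
  motor-locked train (~0.59 s later on average). The derivative models fit
  those voxels essentially exactly, but the extra column costs ~1 log of
  cross-validated evidence while the late base model's misfit is only
  ~1.2 logs at contrast-to-noise 1 — so per-voxel winners still flip at
  roughly a third of early voxels. At contrast-to-noise 2 the flip rate
  falls below 20%. The direction of the control is always correct (mean
  evidence ranks early + derivative above late), but single-voxel winner
  maps need higher effective SNR — e.g. the spatial smoothing of a real
  analysis, which this bench deliberately does not emulate.
- The bench makes no attempt at physiological noise structure, spatial
  autocorrelation, nonlinear BOLD saturation, or realistic motion; passing
  tests demonstrate correctness and statistical behaviour of the pipeline,
  not performance on real scanner data.

## Quality control and configuration

Subjects are excluded when more than 10 of 120 responses are missed or
incorrect, or when more than 7.5% of volumes have framewise displacement
above 0.5 mm (strict inequalities; FD is read from the confounds table —
computing FD from realignment parameters is a preprocessing concern and out
of scope). All such constants live as named defaults in `RunConfig`, every
CLI stage writes a manifest (config, hash, seed, versions), and re-running
with the same manifest reproduces outputs bit for bit.

## Design choices that were genuinely open

- Microtime resolution TR/16 and TR/2 sampling offset (common convention;
  unstated in the emulated analysis).
- One pooled AR(1) coefficient per subject rather than per voxel (guarantees
  evidence comparability; per-voxel available).
- 2 contiguous cvLME folds for single-session runs (the natural
  session-folds do not exist within a run).
- Pooled nuisance regressor for error trials (configurable per-event).
- Percentile bootstrap for the within-subject CI; subject-level winners by
  cvLME argmax (the subject-level analogue of the group winner).
- Intersection mask when two analyses' masks differ.
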