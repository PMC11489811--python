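# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Behavioral model and fitting

Binary "narrower"/"wider" judgments of pictured bodies are modelled as
Bernoulli draws with

P(wider | x) = lapse/2 + (1 − lapse) · (1 − e^−(a·x)^β),

stimulus BMI *x* in kg/m², scale *a* (1/(kg/m²)), slope β (dimensionless),
and an optional lapse rate (default 0; a standard psychophysics robustness
knob, not part of the core model). Parameters are estimated by maximizing
the Bernoulli likelihood of the trial-level data — statistically proper for
binary responses, unlike least squares on proportions — in
log-parameterization (enforcing positivity) with L-BFGS-B from a fixed
multi-start grid: PSE candidates at the 15/30/50/70/85% quantiles of the
presented BMIs crossed with β ∈ {1, 3, 6, 12}. The fixed grid makes the fit
deterministic; a dispersed-restart check in the suite confirms the same
optimum is found. Degenerate slices (all responses identical, fewer than
two distinct BMIs) return a flagged non-converged record, never a silent
estimate. If responses *decrease* with BMI, the fit flips them and sets an
`inverted` flag, making the fit agnostic to response-key coding.

The "fitted BMI" is the curve's inverse at a criterion probability,
default 0.5 — the point of subjective equality (PSE), the standard
psychometric summary; it is configurable because other criteria (e.g. the
1 − e⁻¹ point at 1/a) are in use. Closed form:
x = (−ln(1 − c))^(1/β) / a.

Body perception indices divide an estimate by its reference (× 100): the
subject's actual BMI (body task), the bar-matching BMI (bar task, default
19.61 kg/m² — the constant used in the BPI formula; the alternative 19.79
from the stimulus description is exposed in config), or measured
circumference (metric task, where the index is the mean of the per-part
waist/arm/thigh ratios). The AN median split assigns BPI ≤ median → AN1
("slight overestimation"), > median → AN2; ties go to AN1 and a degenerate
all-equal split warns.

Group statistics: 2 (task) × 2 (group) mixed ANOVA (delegated to pingouin)
plus independent-samples t-tests with Cohen's d; Welch's correction is
applied when Levene's test rejects variance homogeneity at 0.05, which
reproduces the fractional degrees of freedom convention of mainstream
statistics software.

## Synthetic study generator

The generator emulates the study design so that every downstream stage has
realistic, structured input:

* **Stimuli** — 66 pictures, 11 per category, BMIs uniform within the six
  category ranges A [12.19, 14.74] … F [32.46, 56.26] kg/m². The paper-side
  design fixes only the total of 66 and the ranges; the equal per-category
  split is the natural default and is configurable.
* **Sequences** — each stimulus 3 times (198 trials/task), 800 ms
  presentation, ISI 1250 ± 500 ms, pseudo-random with at most three
  consecutive stimuli of one category. Sequences are built incrementally:
  each position draws uniformly (weighted by remaining presentations) among
  stimuli whose category would not extend a run past the limit, restarting
  on dead ends. Whole-sequence rejection sampling would satisfy the same
  constraint but its acceptance probability decays exponentially with
  sequence length and is impractical beyond a few repetitions; the
  incremental sampler is equivalent in distribution up to the run
  constraint, and a χ² test in the suite confirms category transitions stay
  uniform.
* **Cohort** — default 29 AN / 30 HC (the MEG sample sizes). Actual BMIs
  follow the reported group means/SDs (AN 15.6 ± 1.34, HC 20.34 ± 1.98).
  Latent body-task perception indices are drawn at AN 125 ± 15% (median
  near the reported 124.98) and HC 104 ± 10%; bar-task indices at
  100 ± 8% for both groups, encoding the study's central behavioral
  finding (self-referential overestimation in AN only). Slopes β are
  log-normal around 6, a typical psychometric steepness at these stimulus
  spacings.
* **Recordings** — per trial, Hanning-windowed dipole bursts at designated
  shell sites are scaled by an effect specification over the
  (task, category, group) cells and projected through the leadfield, plus
  white sensor noise (default 50 fT at 20 nAm bursts, a realistic
  magnetometer regime) and an optional 60 Hz line component to exercise
  the bandstop. The default effect specification mirrors the study's
  findings: a task effect ordered body > bar > viewing, a quadratic
  body-picture profile (extreme BMIs strongest), and an AN-specific
  descending linear trend confined to ≥ 200 ms in a focal site set.
  Integer seeds are folded with per-operation tags so that reusing one
  seed across generator stages cannot correlate their random streams.

What the generator does **not** emulate: realistic noise covariance
(sensor noise is white), ocular/cardiac artifacts, head movement,
inter-individual anatomy, reaction times, or rendered body images (only
BMI metadata). Passing tests therefore demonstrate correctness of the
analysis machinery under the stated generative model, not robustness to
every pathology of real recordings.

## Preprocessing

Zero-phase (forward–backward) Butterworth filters: third-order 0.1 Hz
high-pass, fourth-order 48 Hz low-pass, optional fourth-order 60 ± 1.5 Hz
bandstop. The stated filter orders are implemented per pass; the
forward–backward application doubles the effective roll-off, which is the
conventional reading of "12/24 dB/oct" annotations alongside 3rd/4th-order
zero-phase designs. Filtering precedes the 600 → 300 Hz polyphase
downsampling so the band limit doubles as anti-aliasing (the narrative
order of the acquisition chain is ambiguous on this; bandlimiting first is
the safe choice, and a suite test shows the two orders agree to < 1% RMS
on band-limited signals). Epochs span −200…600 ms (240 samples at
300 Hz); baseline is the mean over −150…0 ms.

Artifact screening is a transparent z-score screen over per-trial features
(worst-channel peak-to-peak, maximum gradient, mean variance; trials with
any feature z > 4 are rejected) with an analogous cross-channel screen and
optional nearest-neighbour interpolation. The elaborate statistical
artifact-control method referenced in this literature is a separate
published procedure; the screen here is deliberately simple and documented,
with the same interface so a full implementation could drop in.

## Source model

The source space is a Fibonacci-lattice shell (deterministic, no RNG) of
350 sites at 87% of the head radius — approximately grey-matter depth —
with orthonormal tangential bases; "dipole pairs" (MEG) are the two
tangential orientations (the radial one is magnetically silent in a
spherical conductor), "triples" (EEG) add the radial orientation.

Forward solutions use spherical-conductor theory: the analytic closed-form
dipole field for MEG (sensors are radial magnetometers 20% above the
scalp, a stand-in for axial gradiometers), and for EEG the Legendre-series
potential of a current dipole in a homogeneous sphere (σ = 0.33 S/m,
150 terms; at shell fraction 0.87 the truncation error is below 1e-9),
average-referenced. Tests verify the field identities these models must
satisfy: radial-dipole silence, the volume-current cancellation of the
radial field component, the central-dipole closed form, and zero column
sums under the average reference. A three-shell EEG model and realistic
head geometry are out of scope.

The inverse is W = Lᵀ(LLᵀ + λ·s·I)⁻¹ with s = trace(LLᵀ)/n_sensors, which
makes λ dimensionless so the conventional values 0.1 (MEG) and 0.2 (EEG)
are directly usable. No depth weighting or noise normalization is applied
(plain L2-MNE). At λ = 0 the operator equals the Moore–Penrose
pseudoinverse for full-row-rank leadfields; rank-deficient systems raise
with advice to use λ > 0. Activity is the Euclidean norm over each site's
orientation moments, reported in nAm.

## Mass-univariate statistics

For each (site, time) point the mixed RM-ANOVA is computed via orthonormal
contrast scores: for an effect over within-factor subset S, the Kronecker
product of Helmert rows (factors in S) and normalized averaging vectors
(factors not in S) maps each subject's cell means to scores; the effect SS,
its group interaction SS and its own error stratum follow from group means
and residuals of those scores. This reproduces the classic univariate
decomposition exactly (verified against a loop-and-means textbook oracle
for all seven effects and against R's `car::Anova` type-III and pingouin
on mixed two-way designs). With unequal group sizes the within main
effects use unweighted group means (SPSS-style type III). The
Greenhouse–Geisser ε is computed per point from the pooled within-group
covariance of the scores and applied when ε < 0.75 (the common convention
operationalizing "corrected if necessary"); parametric pointwise p-values
define the cluster-forming threshold.

Clusters are connected components of suprathreshold points under
"Delaunay neighbour on the shell (convex-hull triangulation) at the same
sample, or same site at ±1 sample"; the cluster statistic is the mass
(sum of F), with the max-statistic variant available via the null
distribution itself. Permutation schemes: effects involving group permute
group labels across subjects (exact, since between-subject labels are
exchangeable under the null); pure within effects permute the involved
factor's levels within each subject; within×within interactions permute
levels of the involved factors per subject, which is approximate and
relies on cell exchangeability. Cluster p = (1 + #{null ≥ mass}) /
(1 + n_perm), the finite-sample-valid estimator; n_perm defaults to 1000
in the statistics layer. Same-effect clusters that touch under the
adjacency are merged (masses add; the merged cluster keeps its smallest
member p as conservative bookkeeping).

Polynomial contrasts use orthogonal-polynomial weights from a QR
factorization of the level-index powers; for six levels these are
proportional to the classic integer tables (linear −5…5; quadratic
5, −1, −4, −4, −1, 5). Trends are tested as F = t² of the per-subject
contrast scores (one-sample against zero; independent-samples between
groups for trend differences), with partial η² = F/(F + df₂). Post hoc
t-tests are paired within subjects (Cohen's d from the difference SD) and
Welch-corrected between groups when Levene's test fires.

### Calibration

The family-wise error rate of the whole thresholding + clustering +
max-mass procedure is estimated on pure-noise datasets (Gaussian, 40 shell
sites × 30 samples, 10 subjects per group, six picture levels, 300
permutations, both alphas 0.05) for the picture × group interaction — the
design's headline group-specific effect, and the appropriate unit because
cluster permutation controls the error rate per effect tested. Over 200
replicates the empirical rate must not exceed 0.05 plus twice the binomial
standard error; `scripts/acceptance.py` recomputes this from scratch.

## Pipeline and problem sizes

`RunConfig` pins every analysis parameter to the study value (filters,
rates, epoch and baseline windows, 350 sites at 0.87, λ 0.1/0.2, 50–550 ms
window, α 0.05 at both levels) and every simulation size to a desk-scale
default (8 + 8 subjects, 64 sensors, 200 permutations) so a full default
run completes in minutes on one CPU; `RunConfig.paper_preset()` switches
to the study cohort (29 + 30) and 1000 permutations. The suite's
end-to-end recovery check uses 4 + 4 subjects, 24 sensors, a 60-site shell,
one stimulus repetition and 100 permutations per run — the smallest
configuration at which all three injected effects are reliably separable —
and requires the recovered structure (task ordering, positive quadratic
picture trend, AN-descending interaction trend with mid-latency onset) in
at least 4 of 5 seeded runs. All randomness descends from a single seed
through `numpy` seed sequences; identical configuration and seed give a
byte-identical report.

## Known limitations

* The univariate mixed ANOVA assumes balanced within-subject crossings;
  missing cells raise rather than being imputed.
* The interaction permutation scheme for within×within effects is
  approximate (documented above); the group-involving schemes are exact.
* The EEG forward model is a homogeneous sphere; skull/scalp conductivity
  layering would scale topographies but not change the pipeline's logic.
* Minimum-norm reconstructions are spatially smeared and depth-biased, as
  inherent to the plain L2 prior; localization tests therefore assert
  peak-neighbourhood recovery, not exact site identity, and sites outside
  the helmet's sensitive volume are not localizable.
* The clinical instruments, recruitment logistics and hardware-specific
  steps of a real study (head-position tracking, individual head models)
  are out of scope.
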