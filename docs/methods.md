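# Methods

`statedyn` implements an end-to-end analysis of latent brain-state dynamics
during a cognitive task and their relation to behavior: a switching linear
dynamical system (switching LDS) over multi-ROI fMRI time series, state
dynamics summaries (occupancy rate, mean lifetime, per-state functional
connectivity), trial-level behavioral models (ex-Gaussian reaction-time
distributions and the drift-diffusion model), and cross-validated
brain-behavior prediction with permutation inference. Because no suitable
public dataset packages all of these ingredients with ground truth, the
package includes a first-class synthetic cohort generator; every
quantitative claim the test suite makes is a property of the method
(recovery, exactness, calibration), not a reproduction of any empirical
dataset.

## The switching LDS

Observed data are per-subject matrices `y_t ∈ R^R` (R = 11 ROIs spanning
salience, frontoparietal and default-mode networks; sampling interval
TR = 0.49 s). The generative model shared by the whole cohort is

    s_t | s_{t-1} ~ Markov(Π),            s_1 ~ π0
    x_t = A_{s_t} x_{t-1} + w_t,          w_t ~ N(0, Q_{s_t}),  x_1 ~ N(0, I)
    y_t = C x_t + v_t,                    v_t ~ N(0, diag(r))

with discrete state `s_t ∈ {1..K}`, latent trajectory `x_t ∈ R^d` (default
d = 3, one dimension per network mode), a factor loading `C` shared across
states, and state-specific linear-Gaussian dynamics `(A_k, Q_k)`. Each
state is therefore "a dynamical process in a common latent subspace": states
differ in how the latent networks couple and decay, which induces
state-specific observed covariance (time-varying functional connectivity)
without sliding windows. Subjects contribute independent chains under
shared parameters (the initial distribution re-applies at each subject
boundary), so state labels are comparable across the cohort.

### Inference

Structured variational EM with the factorization `q(s) q(x)`:

* **E-s:** exact HMM forward-backward over states, with per-timepoint
  emission scores `E_q(x)[log N(x_t; A_k x_{t-1}, Q_k)]`.
* **E-x:** the responsibilities mix the per-state Gaussian potentials into
  a block-tridiagonal precision over `x_{1:T}`; an information-form
  forward-elimination/back-substitution solver returns means, marginal
  covariances, lag-one cross-covariances and the log-determinant (exact
  Gaussian inference, batched across subjects of equal run length).
* **M:** closed-form updates for `C, A_k, Q_k, diag(r), Π, π0` with a
  ridge of 1e-6·I on covariance updates to prevent collapse.

The ELBO is evaluated once per cycle (after E-s) and is monotone up to the
ridge perturbation; convergence is a relative ELBO change below 1e-6
(cap 500 iterations). With K = 1 the procedure is exact EM for a linear
dynamical system and the ELBO equals the Kalman-filter log-likelihood
(verified to 1e-13). Restarts (default 10) differ in initialization seed;
the best final ELBO wins, ties broken by the lowest restart index.

### Initialization

K-means on sliding-window covariance descriptors (window 15 TRs, stride 1,
upper-triangle vectorized, z-scored across windows; window features sorted
canonically before clustering so the fit is invariant to subject order)
gives hard labels, softened to 0.9/uniform responsibilities. A refinement
stage then runs 10 EM iterations of a *marginal* Gaussian-emission HMM
(full per-state covariance on the observations, no temporal latent
structure) before the variational EM starts. This stage exists because
coordinate ascent on the structured family is sticky: started directly from
the window-based labels it reliably converges to merged-state optima
(aligned accuracy ~0.56 on the easy preset), while the marginal-HMM
refinement moves labels close to the true switch points and the full model
then reaches ~0.89. Both stages are deterministic given the seed.

### Model selection and degenerate states

`select_num_states` fits each K in a range and reports ELBO and
BIC = −2·ELBO + p·log(T_total). BIC is the default selector: the ELBO
itself is non-decreasing in K (nesting), so it cannot choose a finite K.
The latent dimension d defaults to 3 and can be selected the same way.
States whose posterior responsibility never exceeds 1e-3 are reported as
pruned, never silently renumbered.

### State covariance

Two estimators of per-state connectivity: *model* — the stationary
model-implied covariance `C Σ_k Cᵀ + diag(r)` with `Σ_k` solving the
discrete Lyapunov equation of state k (errors on unstable dynamics); and
*empirical* — the responsibility-weighted sample covariance of the
observations. The two agree exactly for white (A = 0) states; for
persistent dynamics the empirical within-state covariance also contains
relaxation transients after each switch, so the estimators agree only as
dwell times grow. Correlation matrices are obtained by standardizing.

## State-dynamics metrics

Occupancy rate is the fraction of timepoints assigned to a state (hard
argmax by default — posterior-weighted "soft" occupancy is provided for
sensitivity analysis); mean lifetime is the average maximal-run length, in
TRs and seconds. Boundary-truncated runs are included in the lifetime
average (the plain-language definition); for a Markov chain the expected
lifetime is 1/(1 − Π_kk) TRs and the simulated estimates match it within
two standard errors. Group contrasts use Welch two-sample t-tests with
Benjamini–Hochberg FDR across states (q = 0.05); link-wise contrasts
between two states use paired t-tests over the upper-triangle edges with
BH-FDR at q = 0.001, and the resulting significant-link mask feeds the
connectivity-based prediction.

## Behavioral models

All RTs are seconds internally (`rt_ms` columns are converted on read).
Responded trials faster than 0.15 s are flagged as contaminants and
excluded from model fits; omissions are excluded from RT fits but count as
errors for accuracy.

**ex-Gaussian.** Density of Normal(mu, sigma) + Exponential(tau) computed
via a two-branch erfcx formulation that is stable for small tau/sigma.
MLE by bounded L-BFGS-B from a moment start (tau0 = sd·(skew/2)^(1/3),
mu0 = mean − tau0); tau is bounded below at 1e-4 s and flagged when the
bound binds. The implied-moment identities (mean = mu + tau,
var = sigma² + tau²) hold for every fit by construction of the family.

**Drift-diffusion.** Two-boundary Wiener process with boundary separation
`a`, drift `v`, non-decision time `t`, diffusion coefficient 1 and
unbiased start z = a/2; upper boundary = correct response (accuracy
coding). The first-passage density uses the small-time/large-time series
with per-element term counts for absolute error below 1e-10 and an
automatic switch to whichever series needs fewer terms. Per-subject MLE
over (a, v, t) starts from the EZ-diffusion closed-form inversion with two
fallback starts; an optional shrinkage mode refits every subject with a
ridge penalty toward cohort means (a deliberate, deterministic substitute
for hierarchical MCMC estimation, which is out of scope). EZ-diffusion
itself (accuracy + RT mean/variance → (a, v, t), with the 1/(2n) edge
corrections) is kept as an independent closed-form route and agrees with
the MLE within 10% at n = 5000.

The DDM simulator is Euler–Maruyama at 1 ms steps with a Brownian-bridge
within-step crossing correction (without it the discrete scheme
overestimates mean decision time by ~3%); optional 2% uniform contaminant
trials; RTs beyond the 1.5 s response window become omissions.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's task/scan scale: T = 700 volumes at TR = 0.49 s, 11 ROIs,
K = 4 latent states, 96 trials with uniform 1–4 s jittered ITIs, and a
cohort split into a typically-developing group and an ADHD-like group.

* **States.** Default per-state stationary latent covariances encode four
  distinct connectivity regimes — S1 task-optimal (strong positive SN–FPN
  coupling), S2 non-optimal (DMN-dominated, negative SN–DMN coupling), S3
  SN–FPN anticoupled, S4 positive SN–DMN coupling — with `A_k` sharing the
  eigenvectors of `Σ_k` (distinct decay rates along each state's own
  covariance modes; `Q_k = Σ_k − A_k Σ_k A_kᵀ` is PSD by construction).
  These defaults were designed against an identifiability diagnostic
  (pairwise symmetric KL of the model-implied observed covariances, and
  decode accuracy of a marginal Gaussian-HMM with the true parameters) so
  that the snr = 1 "easy" preset is a genuine recovery regime; at snr = 1
  the Bayes-level decode is ~0.90, which bounds what any fitting procedure
  can achieve.
* **Dwell structure.** Transition diagonal 0.95 (mean dwell 20 TRs ≈ 10 s).
  The ADHD-like group gets a shifted matrix (S1 stay 0.92, S2 stay 0.96),
  so its stationary occupancy moves away from the task-optimal state and
  toward the non-optimal state — the generator's analogue of the group
  differences the analysis is meant to detect.
* **SNR.** Observation noise is diagonal with total variance set so that
  trace(signal covariance)/trace(noise) equals the requested snr
  (presets: easy = 1.0, hard = 0.3).
* **Behavior.** Per-subject DDM parameters are drawn from cohort
  distributions; couplings tie a parameter to a state's realized occupancy
  with either an explicit slope or a target population correlation
  (slope = r·sd_noise/(sd_occ·√(1−r²))). Defaults: occupancy(S1) → drift
  rate with target r = 0.5, occupancy(S2) → inattention with target
  r = 0.4; group baselines separate inattention scores (ADHD-RS scale
  0–27). Each subject's *true* ex-Gaussian parameters are defined by
  moment-matching the subject's DDM RT distribution (mean, variance and
  third central moment of the symmetric-start first-passage time, obtained
  in closed form from the Laplace transform `cosh(vb)/cosh(b√(v²+2s))`,
  b = a/2): tau³ = m₃/2, sigma² = var − tau², mu = mean + t − tau. This
  makes tau and v intrinsically negatively coupled — both models describe
  the same RTs — deterministically and without Monte-Carlo noise.
* **Motion.** Six column-standardized Gaussian random walks stand in for
  realignment parameters. They are regressed out during prep but do not
  corrupt the simulated BOLD signal; motion-artifact coupling is one of
  several realistic features the generator does *not* emulate (others:
  hemodynamic convolution, event-locked activity, scanner drift beyond
  what the DCT filter removes, spatial voxel structure). Passing tests
  therefore demonstrate correctness of the machinery under the model's
  assumptions, not robustness to those violations.

## Time-series preparation

Fixed order: first eigenvariate (when voxel-level data exist) → regression
on the six motion parameters (no derivatives/squares) → high-pass at
0.008 Hz → per-column z-scoring. The high-pass is regression on a
discrete-cosine drift basis (components below the cutoff), which is
deterministic, transient-free and idempotent; z-scoring makes the state
model scale-free, so fitted state covariances are on a correlation-like
scale. Head-motion exclusion rules (max displacement > 5 mm, mean
scan-to-scan > 0.5 mm) are computed as QC flags, never silent drops.

## Brain-behavior linking

Dimensional analyses use Pearson correlations (two-sided t-transform p)
and OLS with nuisance covariates (age, gender, IQ, head motion) reporting
standardized betas. Multivariate prediction is leave-one-out
cross-validated with training-fold-only feature scaling:

* RBF SVR (C = 1, epsilon = 0.1, kernel scale 1/#features) for symptom
  prediction from occupancy/lifetime features;
* linear SVM (C = 1) for group classification;
* elastic net (l1_ratio 0.5, lambda by inner cross-validation over a
  geometric grid) for predicting drift rate from state-S1 connectivity
  links, with features pre-selected by the S1-vs-S2 paired-t contrast.

Inference is by target/label permutation with the *full LOOCV re-run per
permutation* and p = (1 + #{null ≥ observed})/(1 + n_perm), so p is never
zero and the test is exact under exchangeability. An optional curtailment
stops permuting once rejection at a given level has become impossible; the
accept/reject decision is provably identical to the full test.

Two elastic-net modes: "pooled" computes the link mask once on all
subjects before LOOCV (the common convention of selecting features on the
full sample), "nested" recomputes it inside every training fold. Because
the mask depends only on the FC contrast — never on the prediction
target — permuting the target leaves it fixed and both modes remain
validly calibrated under the null; measured null LOOCV-r is slightly
*negative* in both (the familiar cross-validation anti-correlation
artifact), not inflated. Inside nested
training folds the FDR(0.001) mask is frequently empty on weak data; the
selection then falls back to the 10 smallest-p links, deterministically
and identically for observed and permuted fits.

Hyperparameters are fixed (no per-dataset tuning) to keep the permutation
tests honest. A known consequence: the LOOCV-prediction-r statistic of the
fixed RBF SVR has high sampling variance, and its power for a planted
r = 0.5 association at n = 50 is only ~0.65–0.70 even though the same
effect is detected ~97% of the time by a direct correlation test. This is
a property of the statistic, not an implementation artifact (it is
unchanged under C = 10 or different feature counts).

## Validation experiment sizes

The benchmark experiments (statedyn.evaluation, run both by
tests/test_acceptance.py and scripts/acceptance.py) use these sizes,
chosen once as a desk-scale validation budget on one CPU:

* switching-LDS recovery: 20 subjects × 700 TRs, 10 restarts;
* oracle equivalences: T ≤ 8 instances (enumeration/joint-Gaussian);
* Markov identities: one chain of 10⁵ steps;
* behavioral recovery: n = 5000 fits (5 seeds for the ex-Gaussian
  median), 100 simulated subjects at n = 96 for drift recovery;
* calibration: 200 null runs per method (n = 24 subjects for SVR/SVM,
  20 for the elastic net; 99 permutations, 49 for the elastic net);
  power: 30 runs (SVR, planted r = 0.5 at n = 50), 20 runs (SVM, 1.5-sd
  two-feature shift at n = 26/26), 20 runs (elastic net, planted link at
  n = 40), 49 permutations;
* end-to-end sign recovery: 8 full pipeline runs at n = 50 subjects,
  2 restarts per fit.

## Known limitations

* The variational family factorizes q(s)q(x); the bound is tight only when
  states are unambiguous at every timepoint, and coordinate ascent can
  retain merged-state optima on weakly separated data (hence the
  marginal-HMM refinement and restarts).
* Parameter estimates are point estimates (empirical-Bayes flavor), not
  posteriors; uncertainty in occupancy/lifetime is not propagated into the
  brain-behavior analyses.
* The DDM fits assume no starting-point bias and no inter-trial
  variability parameters; all-correct subjects leave the drift weakly
  identified (flagged, not dropped).
* Generator realism gaps listed above; in particular the synthetic
  motion regressors are pure nuisance, so motion-regression efficacy on
  real artifacts is untested here.
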