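# statedyn

Latent brain-state dynamics from multi-ROI task-fMRI time series, and their
relation to behavior.

Children with attention deficits show elevated intra-individual response
variability (IIRV) and slowed evidence accumulation during even simple
choice tasks, and a long-standing hypothesis ties these behavioral
phenotypes to fluctuations between task-optimal and task-non-optimal brain
states in the salience (SN), frontoparietal (FPN) and default-mode (DMN)
networks. Testing that hypothesis requires (1) an unsupervised model of
time-varying brain states that does not impose sliding windows or task
boundaries, (2) latent-variable models of the behavior itself, and (3)
cross-validated linking of the two with honest inference. `statedyn`
packages all three for researchers in computational neuroimaging and
cognitive modeling, together with a synthetic cohort generator with known
ground truth so every step is testable.

## The models

**Switching linear dynamical system.** A hidden Markov chain
`s_t ∈ {1..K}` (transition matrix Π) selects among K linear-Gaussian
dynamical regimes in a shared low-dimensional factor subspace of the R
observed ROI signals:

    x_t = A_{s_t} x_{t-1} + w_t,   w_t ~ N(0, Q_{s_t})
    y_t = C x_t + v_t,             v_t ~ N(0, diag(r))

Each state is a distinct dynamical process with its own implied functional
connectivity. Fitting is structured variational EM (exact forward-backward
over states, exact block-tridiagonal Gaussian smoothing of the latent
trajectory, closed-form M-steps) with seeded restarts; subjects share all
parameters, so state labels are comparable across a cohort. From the
posterior state sequences the package computes each state's **occupancy
rate** (fraction of time occupied), **mean lifetime** (dwell time before a
switch; expectation 1/(1−Π_kk) for a Markov chain) and per-state
connectivity matrices.

**Behavior.** Per-subject reaction-time distributions are fit by
maximum-likelihood **ex-Gaussian** (mu, sigma, tau — tau indexes the
slow-response tail linked to attentional lapses) and by the
**drift-diffusion model** via the Wiener first-passage-time likelihood
(boundary separation `a`, drift rate `v`, non-decision time `t`), with
EZ-diffusion closed forms as an independent cross-check.

**Linking.** Pearson correlations and covariate-adjusted regressions;
leave-one-out cross-validated RBF SVR (symptom prediction), linear SVM
(group classification) and elastic net on state-connectivity links (drift
prediction), each with exact permutation p-values obtained by re-running
the full cross-validation per permutation.

## Worked example

Generate a 20-subject synthetic cohort in the snr = 1 regime, fit the
4-state model, and test the headline brain-behavior coupling (the
generator ties drift rate to occupancy of the task-optimal state S1 with
population r = 0.5):

```python
import numpy as np
from statedyn import synth, slds, metrics, behavior, linking

cfg = synth.easy_preset(n_subjects=20, seed=7)
cohort = synth.generate_cohort(cfg)

model, posts = slds.fit_switching_lds(cohort.timeseries, K=4, d=3,
                                      n_restarts=3, seed=7)
hard = [p.hard_sequence for p in posts]
perm, acc = slds.align_states(hard, cohort.ground_truth["state_sequences"],
                              K=4)
print(f"aligned state accuracy: {acc:.3f}")

occ = np.stack([metrics.occupancy_rate(perm[h], n_states=4) for h in hard])
print("mean occupancy per state:", np.round(occ.mean(axis=0), 3))

v_hat = []
for sub in cohort.subjects:
    tr = cohort.trials[sub]
    keep = np.isfinite(tr["rt_s"])
    v_hat.append(behavior.fit_ddm(tr[keep]).v)
r, p = linking.pearson_with_p(occ[:, 0], v_hat)
print(f"occupancy(S1) vs fitted drift rate: r = {r:.2f}, p = {p:.1e}")
```

Output:

```
aligned state accuracy: 0.890
mean occupancy per state: [0.224 0.274 0.242 0.259]
occupancy(S1) vs fitted drift rate: r = 0.74, p = 1.7e-04
```

89% of timepoints are assigned to the correct generator state (after
Hungarian label alignment); the four states occupy roughly a quarter of
the run each (this cohort mixes typical and ADHD-like dwell structure);
and the fitted drift rates correlate positively with fitted S1 occupancy —
the synthetic analogue of "engaging the task-optimal state speeds evidence
accumulation". The observed r = 0.74 exceeds the planted population
r = 0.5 in this particular 20-subject draw; estimation noise and sampling
variability move it in either direction.

The same flow is available as a CLI over plain-text inputs/outputs:

```bash
statedyn run-all --out run1 --seed 7     # simulate→prep→fit→metrics→behavior→link→report
statedyn validate run1/data
```

See `docs/methods.md` for the model details, numerical choices and
limitations.

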