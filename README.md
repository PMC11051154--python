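# respshift

Psychometric models for detecting **examinee strategy differences** on
timed ability tests — both *between* persons (latent classes with different
item-difficulty patterns) and *within* persons (mid-test shifts from
construct-driven to erratic responding) — and for turning those detections
into **corrected, validity-improved ability estimates**.

It is aimed at psychometricians and testing researchers who have a person ×
item matrix of scored responses plus per-item response times (the typical
export of a computerized test) and, optionally, an external criterion score
such as a general-aptitude composite.

## Models

**Between-person classes: mixture Rasch.** The Rasch model gives
P(X<sub>ij</sub> = 1 | θ<sub>j</sub>, β<sub>i</sub>) =
exp(θ<sub>j</sub> − β<sub>i</sub>) / (1 + exp(θ<sub>j</sub> − β<sub>i</sub>)).
The mixture extension lets each latent class *g* carry its own centered
difficulty vector β<sub>ig</sub>, so classes capture qualitatively
different solution strategies. Within-class difficulties are estimated by
conditional maximum likelihood (raw-score conditioning via elementary
symmetric functions), class structure by EM; solutions are compared with
−2lnL, AIC and (approximate) chi-square tests, and profiled by regressing
item difficulty and item mean log-RT on cognitive-complexity covariates.

**Within-person shifts: a joint accuracy + RT state model.** Log response
times follow ln RT<sub>ij</sub> ~ N(τ<sub>j</sub> − γ<sub>i</sub>,
σ²<sub>s</sub>) with person speed τ, item time intensity γ, and a
*state-specific* residual variance: a construct-driven state (small σ²₁)
and an erratic state (large σ²₂) that also has its own accuracy parameters.
State sequences follow either a lag-1 Markov chain (Dirichlet(1,1) priors
on initial/transition rows) or a per-person change point k<sub>j</sub>
(uniform prior), estimated by Gibbs sampling with forward-filtering /
backward-sampling for states. Responses labeled erratic are trimmed,
abilities re-estimated by EAP with fixed difficulties, the criterion
correlation disattenuated by the post-trim reliability, and the gain tested
against a count-preserving bootstrap null.

## Worked example

```python
from respshift import (GibbsConfig, get_scenario, simulate_joint,
                       gibbs_fit_changepoint, characterize_states,
                       fit_rasch_cml, mask_from_states, validity_table)

sim = simulate_joint(get_scenario("late_shift_cp"), seed=11)   # 301 x 30
cfg = GibbsConfig(n_chains=2, burn_in=1000, n_iter=1000, seed=5)
post = gibbs_fit_changepoint(sim.dataset, cfg, mode="residual")

report = characterize_states(post)
print(report.sigma2.round(3), report.accuracy.round(3), report.disengaged_state)
# [0.187 1.427] [0.646 0.308] 2

diff = fit_rasch_cml(sim.dataset.responses)
mask = mask_from_states(post.modal_states())
table = validity_table(sim.dataset, diff, sim.truth["criterion"],
                       masks={"cp_trim": mask})
print(table[["trim", "adjusted_r", "r2"]].head(2).to_string(index=False))
#    trim  adjusted_r       r2
# no_trim    0.587300 0.344921
# cp_trim    0.604071 0.364902
```

Reading: the sampler recovers the two response states — residual variance
0.187 vs 1.427 (≈ 7.6× inflation) with per-state accuracy .646 vs .308 —
and flags state 2 as disengaged. Trimming those responses and rescoring
raises the disattenuated criterion correlation from .587 to .604
(variance explained .345 → .365) on this synthetic replicate.

The same pipeline is scriptable from the shell:

```bash
respshift simulate --scenario late_shift_cp --seed 11 --out run/
respshift joint run/ --structure cp-residual --burnin 1000 --iters 1000 --seed 5 --out run/fit/
respshift validate run/ --trim cp-residual --out run/validity/
```

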