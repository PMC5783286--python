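# resolvemsm

Continuous-time multistate models with a **latent absorbing "resolved" state**,
for disease processes observed intermittently at clinic visits.

## The problem

Many chronic conditions are tracked as a patient moves among a handful of
severity states — for example disability categories derived from the Health
Assessment Questionnaire in psoriatic arthritis.  Two complications combine
badly:

1. **Panel observation.**  The state is seen only at visit times; transition
   times are interval-censored.
2. **Unobservable resolution.**  Some patients *resolve*: after an unknown
   point in time they will never experience symptoms again.  Resolution is
   never observed — a symptom-free visit looks identical whether the patient
   has resolved or is only temporarily symptom-free.

`resolvemsm` models this by expanding the state space: "no symptoms" is
partitioned into a latent absorbing resolved state **R** and a transient
temporary non-disability state **D0**, followed by severity states
**D1 … Dm** connected through adjacent levels only:

```
R  <-  D0  <->  D1  <->  ...  <->  Dm
```

## The model

Transition intensities follow a proportional-hazards form,

&nbsp;&nbsp;&nbsp;&nbsp;λ<sub>rs</sub>(z) = λ<sub>rs</sub> · exp(β′<sub>rs</sub> z),

and interval transition probabilities are matrix exponentials
P(Δt) = exp(Q·Δt) of the resulting generator Q (time-homogeneous Markov).
With fully known states, a subject's likelihood is the product of interval
transition probabilities conditional on the first state.  Under the real
observation scheme, the observed code 0 ("no disability") is *ambiguous*
between R and D0, and the likelihood marginalises over every latent
assignment consistent with the censored state sets Ω (Ω = {R, D0} for code
0, a singleton otherwise):

&nbsp;&nbsp;&nbsp;&nbsp;L<sub>i</sub>(Θ) = Σ<sub>x ∈ Ω<sub>1</sub>×…×Ω<sub>m</sub></sub>
∏<sub>j</sub> p<sub>x<sub>j</sub> x<sub>j+1</sub></sub>(Δt<sub>j</sub>) · P(X(t<sub>0</sub>) = x<sub>0</sub>),

evaluated in linear time by a hidden-Markov-style forward recursion over Ω.
On top of this sit:

- maximum-likelihood estimation over (log λ, β) with Wald intervals
  (exponentiated for baselines),
- a **boundary likelihood-ratio test** of "no resolution" (λ<sub>D0→R</sub> = 0),
  referred to a 50:50 mixture of χ²₁ and a point mass at zero,
- **probability-of-resolution** estimates p<sub>s0,R</sub>(t) with
  parametric-simulation confidence intervals,
- a simulator (latent Gillespie paths → panel observation → masking) and a
  replicate study harness reproducing the standard four-state benchmark
  scenarios, plus a synthetic five-state clinic-like cohort generator.

## Worked example

`examples/fit_masked_panel.py` simulates one benchmark cohort (480 subjects,
annual visits over 8 years, a balanced binary covariate), masks the R/D0
labels into the ambiguous code 0, and fits under both regimes:

```
parameter                    complete                partial
D0->R               0.46 (0.41, 0.51)      0.43 (0.36, 0.52)
D0->D1                0.39 (0.3, 0.5)      0.36 (0.26, 0.49)
D1->D0              0.63 (0.52, 0.75)      0.62 (0.52, 0.74)
D1->D2              0.54 (0.44, 0.66)      0.54 (0.44, 0.66)
D2->D1              0.43 (0.36, 0.51)      0.43 (0.36, 0.51)
D0->D1:z              0.86 (0.5, 1.2)        0.93 (0.5, 1.4)
...
```

Each cell is the MLE with its 95% Wald interval (generating values: baseline
0.4–0.6, β = 1).  The two regimes agree except for the transitions out of
D0 — exactly where not knowing "resolved vs temporarily symptom-free" loses
information, so the partial-observation intervals are wider there and only
there.

Testing for the existence of resolution
(`examples/boundary_test_for_resolution.py`):

```
with resolution   T =   97.556   p = 2.62e-23
no resolution     T =    0.565   p = 0.226
```

Other examples cover probabilities of resolving by initial state with
confidence intervals (`probability_of_resolving.py`), a miniature replicate
study showing the identifiability failure under slow dynamics
(`replicate_study.py`), and the analytic resolved-fraction curve
(`analytic_resolved_fraction.py`).

A thin CLI mirrors the library:

```sh
resolvemsm simulate --scenario 1 --reps 2 --seed 7 --out-dir out/
resolvemsm fit --data out/panel_rep000.csv --config examples/four_state_model.yaml \
    --regime partial --null-no-resolution --out fit.json
resolvemsm study --scenario 2 --reps 20 --seed 0 --out study_s2
```

## Data formats

**Panel CSV** — one row per visit: `subject_id,time,state_code`, then one
column per covariate; times in decimal years; codes are `0` (ambiguous
no-disability) or `D1 … Dm` (and `R`/`D0` in revealed-label data).
**Model config** — YAML listing states, allowed transitions, per-transition
covariates and initial values; see `examples/four_state_model.yaml`.

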