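"""Estimate the probability that a patient has resolved before t years.

Fits the model to a masked Scenario-1 cohort, then reports
p_{s0,R}(t) = P(resolved before t | initial state s0) with 95% confidence
intervals obtained by simulating parameter vectors from the estimator's
asymptotic normal distribution.  Milder initial states resolve sooner.
"""

from resolvemsm import (
    fit_mle,
    generate_scenario_dataset,
    resolution_probability,
    scenario_config,
)

cfg = scenario_config(1)
sim = generate_scenario_dataset(cfg, "partial", seed=5)
fit = fit_mle(sim.subjects, cfg.space, cfg.true_parameters())

print(f"{'t (years)':>9s}  " + "  ".join(f"{s0:>22s}" for s0 in ("D0", "D1", "D2")))
for t in (2.0, 5.0, 8.0):
    cells = []
    for s0 in ("D0", "D1", "D2"):
        est = resolution_probability(fit, s0, t, {"z": 0.0}, n_draws=1000, seed=1)
        cells.append(f"{est.estimate:.3f} ({est.lower:.3f}, {est.upper:.3f})")
    print(f"{t:9.0f}  " + "  ".join(f"{c:>22s}" for c in cells))

print(
    "\nEach cell: estimated probability of having resolved before t years "
    "for a z=0 patient,\nwith a 95% parametric-simulation interval."
)
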