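"""Fit the latent-resolution model to a masked panel dataset.

Simulates one Scenario-1 cohort (480 subjects, annual visits over 8 years),
masks the resolved/temporary labels into the ambiguous code "0", fits the
model under both observation regimes, and prints the estimates side by side.
The partial-regime intervals for the two transitions out of D0 are wider:
that is exactly the information lost by not knowing whether a symptom-free
visit means "resolved" or "temporarily symptom-free".
"""

import numpy as np

from resolvemsm import (
    fit_mle,
    format_estimate,
    generate_scenario_dataset,
    mask_dataset,
    scenario_config,
    wald_intervals,
)

cfg = scenario_config(1)
sim = generate_scenario_dataset(cfg, "complete", seed=42)
masked = mask_dataset(sim)

truth = cfg.true_parameters()
rng = np.random.default_rng(7)
init = truth.unpack(
    truth.pack(cfg.space) + rng.uniform(-0.3, 0.3, truth.n_free(cfg.space)), cfg.space
)

fits = {
    "complete": fit_mle(sim.subjects, cfg.space, init, regime="complete"),
    "partial": fit_mle(masked.subjects, cfg.space, init, regime="partial"),
}

print(f"{'parameter':14s} {'complete':>22s} {'partial':>22s}")
names = list(wald_intervals(fits["complete"]))
for name in names:
    row = [format_estimate(*wald_intervals(fits[r])[name]) for r in ("complete", "partial")]
    print(f"{name:14s} {row[0]:>22s} {row[1]:>22s}")
print(
    "\nEach cell is the MLE with its 95% Wald interval (exponentiated for "
    "baseline intensities).\nMasking R/D0 widens only the D0->R and D0->D1 rows."
)
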