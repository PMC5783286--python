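"""Expected fraction of a cohort resolved by time t, computed analytically.

No simulation: the absorption probability exp(Q(z)·t)[s0, R] is averaged
over the design's initial-state allocation and covariate distribution.
Under the uniform-covariate convention (the covariate accelerating every
transition including resolution) the year-8 values are 0.71 and 0.22 for
the two standard scenarios; under the design convention (no covariate on
resolution) they are lower.
"""

from resolvemsm import expected_resolved_proportion, scenario_config

print(f"{'t':>4s} {'S1 design':>10s} {'S1 uniform':>11s} {'S2 design':>10s} {'S2 uniform':>11s}")
for t in (2.0, 4.0, 8.0, 16.0):
    row = []
    for scenario in (1, 2):
        cfg = scenario_config(scenario)
        row.append(expected_resolved_proportion(cfg, t))
        row.append(expected_resolved_proportion(cfg, t, covariate_on_resolution=1.0))
    print(f"{t:4.0f} {row[0]:10.3f} {row[1]:11.3f} {row[2]:10.3f} {row[3]:11.3f}")

print(
    "\n'design': covariate acts on every transition except resolution "
    "(the simulation design);\n'uniform': it also accelerates resolution."
)
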