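# Four-state model: resolved R, temporary non-disability D0, and two
# disability severity states. Initial values are starting points for the
# optimiser, not estimates. Transitions without a `covariates` entry carry
# no covariate effect (here: resolution).
states: [R, D0, D1, D2]
transitions:
  - {from: D0, to: R, init: 0.3}
  - {from: D0, to: D1, init: 0.3, covariates: {z: 0.0}}
  - {from: D1, to: D0, init: 0.5, covariates: {z: 0.0}}
  - {from: D1, to: D2, init: 0.5, covariates: {z: 0.0}}
  - {from: D2, to: D1, init: 0.3, covariates: {z: 0.0}}
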