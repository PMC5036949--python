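# Spherical clusters, unequal radii, equal populations, well separated.
name: s5_1
description: three spherical Gaussians with different radii, equal thirds
n: 4000
components:
  - mean: [0.0, 0.0]
    cov: [[0.25, 0.0], [0.0, 0.25]]
    weight: 0.3333333333333333
  - mean: [3.0, 0.0]
    cov: [[0.25, 0.0], [0.0, 0.25]]
    weight: 0.3333333333333333
  - mean: [1.5, 10.0]
    cov: [[9.0, 0.0], [0.0, 9.0]]
    weight: 0.3333333333333334
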