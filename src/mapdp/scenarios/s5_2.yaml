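# Spherical clusters, equal radii, unequal populations (69/29/2%).
name: s5_2
description: three spherical Gaussians, equal radii, 69/29/2 percent split
n: 4000
components:
  - mean: [-6.0, 0.0]
    cov: [[1.0, 0.0], [0.0, 1.0]]
    weight: 0.69
  - mean: [4.0, 0.0]
    cov: [[1.0, 0.0], [0.0, 1.0]]
    weight: 0.29
  - mean: [4.0, 4.4]
    cov: [[1.0, 0.0], [0.0, 1.0]]
    weight: 0.02
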