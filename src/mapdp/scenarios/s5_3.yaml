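# Spherical clusters, equal radii and density, plus two outlier pairs.
name: s5_3
description: three equal spherical Gaussians with two far outlier pairs
n: 4000
components:
  - mean: [0.0, 0.0]
    cov: [[1.0, 0.0], [0.0, 1.0]]
    weight: 0.3333333333333333
  - mean: [5.0, 0.0]
    cov: [[1.0, 0.0], [0.0, 1.0]]
    weight: 0.3333333333333333
  - mean: [2.5, 4.3]
    cov: [[1.0, 0.0], [0.0, 1.0]]
    weight: 0.3333333333333334
outlier_groups:
  - center: [90.0, 90.0]
    n: 2
    spread: 0.3
  - center: [-40.0, 45.0]
    n: 2
    spread: 0.3
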