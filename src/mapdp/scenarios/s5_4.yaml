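# Elliptical clusters, equal volume and density, one rotated 45 degrees.
name: s5_4
description: three equal-volume ellipses, one rotated, no appreciable overlap
n: 4000
components:
  - mean: [0.0, 0.0]
    cov: [[9.0, 0.0], [0.0, 0.25]]
    weight: 0.3333333333333333
  - mean: [0.0, 3.0]
    cov: [[9.0, 0.0], [0.0, 0.25]]
    weight: 0.3333333333333333
  - mean: [12.0, 1.5]
    cov: [[4.625, 4.375], [4.375, 4.625]]
    weight: 0.3333333333333334
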