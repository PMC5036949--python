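# Elliptical clusters, different volumes and densities, significant overlap.
name: s5_6
description: three overlapping ellipses, 30/5/65 percent split
n: 4000
components:
  - mean: [0.0, 0.0]
    cov: [[4.0, 1.0], [1.0, 1.0]]
    weight: 0.30
  - mean: [3.2, 2.2]
    cov: [[0.6, 0.0], [0.0, 0.6]]
    weight: 0.05
  - mean: [-1.0, 5.0]
    cov: [[5.0, -1.5], [-1.5, 2.0]]
    weight: 0.65
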