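# Elliptical clusters, different volumes/geometries/densities, trivially separated.
name: s5_5
description: three well-separated ellipses, 12/28/60 percent split
n: 4000
components:
  - mean: [0.0, 0.0]
    cov: [[2.0, 0.0], [0.0, 0.5]]
    weight: 0.12
  - mean: [14.0, 7.0]
    cov: [[1.0, 0.3], [0.3, 1.0]]
    weight: 0.28
  - mean: [-12.0, 16.0]
    cov: [[3.0, 0.0], [0.0, 1.0]]
    weight: 0.60
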