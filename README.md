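# quadpat

Point patterns from photographed grassland quadrats: rectification,
second-order statistics, and Monte Carlo null-model tests.

Mapping every individual plant in a grassland plot used to mean crawling
over it with a ruler. A faster field protocol photographs the plot one
50 cm × 50 cm sub-block at a time, digitizes each plant in the images, and
converts pixel coordinates to plot coordinates using the sub-block corners
as control points. `quadpat` implements the complete computational side of
that workflow for spatial ecologists:

- **rectify** — fit a planar projective transform (homography) per
  sub-block from ≥ 4 pixel↔metre control points, map the digitized plants
  into the plot frame, clip each sub-block to its cell, and assemble a
  single plot-wide point pattern with a full audit trail (rejected points,
  merged edge duplicates).
- **analyze** — translation-edge-corrected estimators of Ripley's
  K(r) and the pair correlation function g(r) = (2πr)⁻¹ dK(r)/dr on a
  uniform distance grid (default 0.05–2.5 m in 0.05 m steps). Under
  complete spatial randomness (CSR) g(r) = 1; g > 1 indicates aggregation
  at distance r and g < 1 regularity.
- **null models** — pointwise min–max simulation envelopes of g(r) from
  199 replicates of either the homogeneous Poisson process (CSR) or a
  heterogeneous Poisson process whose intensity λ(x, y) is estimated from
  the data by Epanechnikov kernel smoothing (bandwidth R = 1.0 m by
  default). With 199 replicates the pointwise type I error rate is
  2/200 = 0.01. Each distance bin is classified aggregated / consistent /
  regular, and the "aggregated at 0–x m" scale is reported.
- **replicates** — replicated plots are combined into a single weighted
  g(r) with pair-count weights wᵢ = nᵢ²/Σnⱼ², and a reliability protocol
  compares two measurements of the same plants (e.g. photographs versus
  ruler) by mutual-nearest-neighbour matching and paired t tests on the
  coordinates and on the per-bin g(r) values.
- **synth** — generators for CSR, Thomas cluster, Matérn type-II
  hard-core and linear-gradient Poisson processes, plus synthetic
  photo-digitization fixtures with known homographies and pixel noise, so
  the whole pipeline is testable end to end without field data.

## Worked example

```python
import numpy as np
import quadpat as qp

rng = np.random.default_rng(11)
plot = qp.Window(0, 0, 5, 5)
pattern = qp.gen_thomas(plot, kappa=1.0, mu=8.0, sigma=0.05, rng=rng)
print(f"simulated Thomas pattern: n = {pattern.n}")

r = qp.make_rgrid(r_max=2.5, dr=0.05)
g = qp.estimate_pcf(pattern, r)
print(f"g(0.05) = {g.values[0]:.2f}, g(0.5) = {g.values[9]:.2f}")

res = qp.run_envelope_test(
    pattern, qp.NullModelSpec("homogeneous", nsim=199, seed=5), r
)
print(f"aggregated at 0-{res.aggregation_scale:.2f} m; "
      f"{sum(l == 'consistent' for l in res.labels)}/50 bins consistent with CSR")
```

prints

```
simulated Thomas pattern: n = 141
g(0.05) = 30.98, g(0.5) = 0.83
aggregated at 0-0.20 m; 31/50 bins consistent with CSR
```

The cluster process has dispersal scale σ = 0.05 m, so pairs concentrate
within ~2σ of each other: g(r) is far above 1 at 0.05 m, and the envelope
test flags aggregation out to 0.20 m — the scale summary an ecologist
would report — while most larger distances stay inside the CSR envelope.

The same analyses are available from the shell:

```sh
quadpat simulate thomas --seed 11 --out pattern.csv
quadpat envelope pattern.csv --null homogeneous --nsim 199 --seed 5 --out env.csv
quadpat combine env1.csv env2.csv env3.csv --out combined.csv
quadpat reliability photo.csv ruler.csv --out table.csv
```

Every command writes a JSON sidecar recording its settings and seed; runs
with identical inputs and seeds are byte-identical.

## Documentation

See `docs/methods.md` for the statistical model, estimator definitions,
parameter defaults, and known limitations.
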