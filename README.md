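# cac — computer-aided contouring for radiologic tumor measurement

Unidimensional tumor measurement (the RECIST 1.1 longest diameter) is the
workhorse endpoint of solid-tumor trials, and it is notoriously
irreproducible: different readers place contours and calipers
differently, and the resulting interobserver variability can flip a
response call. `cac` implements an interactive contouring method built to
remove that variability, together with the measurement, response
classification and multi-reader agreement statistics needed to validate
it. It is aimed at researchers studying reader variability and at
developers of quantitative-imaging pipelines.

## The method

A CT slice is modelled as an 8-connected weighted bi-directed pixel
graph. The cost of the link from pixel *u* into pixel *v* is

```
c(u, v) = w_zx · S_zx(v) + w_g · S_g(v) · len(u, v) + w_d · S_d(u, v)
```

with `S_zx` a binary Laplacian zero-crossing feature, `S_g = 1 − G/max G`
the inverted normalized gradient magnitude, `S_d` a penalty on links not
perpendicular to the local gradient, and `len` the geometric step length
(√2 for diagonal links). A lesion boundary is then a minimum-cost closed
path, found with Dijkstra's algorithm restricted to a *band* of pixels
around a rough user trajectory:

1. seed pixels are sampled at equal arc length along the trajectory;
2. **pass one** chains band-restricted optimal paths between consecutive
   seeds;
3. **pass two** picks the lowest-cost pixel of every pass-one segment as
   a refined seed and re-runs the chained search.

Because the refined seeds snap to strong edges, different hand-drawn
trajectories around the same lesion converge to the same contour — the
reproducibility property that makes the measurement reader-independent.
Contours on slices between user-contoured *key slices* are found
automatically by interpolating matched boundary points in z and running
the same two-pass search around the interpolated estimate.

From the contours the package measures the longest in-plane diameter
(extranodal lesions) or the longest perpendicular short axis (lymph
nodes), in 2D mode or in 3D mode (on the maximum-area slice of the
volumetric contour set), classifies response per RECIST 1.1
(CR / PR / SD / PD against baseline and nadir sums), and computes the
agreement statistics used in multi-reader studies: per-lesion CV,
pairwise Pearson matrices with "correlation with others" summaries,
two-way ICC, Fleiss' kappa and quorum-vote fractions.

## Worked example

Five simulated readers contour the same synthetic lesion with different
mouse trajectories; five others measure it manually with noisy endpoint
placement:

```python
import numpy as np
import cac
from cac.contour_engine import smooth_contour

spec = cac.PhantomSpec(shape="lobulated", size_px=64, radius_px=14.0, seed=7)
ph = cac.render_phantom(spec)
img = ph.volume[0]
field = cac.compute_cost_field(img)

diams = []
for reader_seed in range(5):
    traj = cac.simulate_trajectory(ph.truth.contours[0], jitter_px=4.0,
                                   seed=reader_seed)
    contour = cac.two_pass_contour(img, traj, field)
    diams.append(cac.longest_diameter(smooth_contour(contour, 7))[0])

print("analytic diameter:", round(ph.diameter_mm, 2), "mm")
print("five simulated readers:", [round(d, 2) for d in diams], "mm")
```

prints

```
analytic diameter: 30.38 mm
five simulated readers: [30.35, 30.35, 30.35, 30.35, 30.35] mm
```

all five contouring measurements are identical (CV 0%) and within 0.1%
of the analytic truth, while the manual arm of the same phantom
(`cac.simulate_manual_readings`) spreads over 25–36 mm (CV ≈ 13% for
this draw). The same flow is available from the shell via the `cac`
command (`phantom`, `segment`, `propagate`, `measure`, `evaluate`,
`agreement` subcommands).

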