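# rhomboclone

Statistical analysis of clonal lineage restriction at rhombomere boundaries.

During hindbrain segmentation the neural tube subdivides into rhombomeres
(r1–r7), transient compartments whose boundaries restrict cell movement.
Clonal labelling experiments mark single progenitor cells and ask, once
boundaries are morphologically visible, whether each labelled clone
**crosses** a rhombomeric boundary, **respects** it (abuts without
crossing), or sits in the **middle** of its rhombomere reaching neither
boundary.  `rhomboclone` provides the statistical machinery for such
experiments: it tests whether the observed mixture of behaviours could
arise by chance from clone geometry alone, or whether boundaries actively
restrict cell dispersion.

It is aimed at developmental biologists and biostatisticians analysing
clone tables (one row per clone with the three standard length
measurements), and at anyone wanting a fully simulated, seeded test-bed for
this class of lineage-restriction analyses.

## The model

Each clone is reduced to two dimensionless numbers in an idealised unit
rhombomere `[0, 1]` (0 = anterior): the centre position `x = a/b` and the
radius `r = (c/2)/b`, where `a` is the distance from clone centre to the
anterior boundary, `b` the rhombomere's anteroposterior (AP) length at that
level, and `c` the clone's AP extent.

The chance (null) model assumes (1) clone centres uniform on `[0, 1]`,
(2) radius independent of position, and (3) radius lognormal,
`ln R ~ N(μ, σ²)`, with defaults `μ = −1.34`, `σ = 0.64`.  A clone at
position `x` crosses its nearest boundary (distance `d = min(x, 1−x)`) iff
`R > d`, so for `x ∈ (0, ½]`

```
L(x) = P(R > x) = 1 − Φ((ln x − μ)/σ),      L(x) = L(1−x) on [½, 1)
```

with `Φ` the standard normal CDF.  Integrating over uniform positions gives
the chance probability of crossing, `p_cross = 2∫₀^½ L(x) dx ≈ 0.57`.  A
measurement-error margin `δ` (calibrated so that the chance probability of
*respecting* is 0.22) splits the non-crossing clones into respecters
(`d − δ < r ≤ d`) and middle clones.  Observed category counts are tested
against `(p_cross, p_respect, p_middle)` with a classical trinomial
χ² goodness-of-fit test (df = 2); assumption checks (KS uniformity of
positions, KS lognormality of radii, size–position correlation) and two
empirical crossing-probability curves (binned fractions and a circular
binomial spline fitted to the binary crossing indicator) complete the
analysis.

Because the boundaries of the pooled idealised rhombomere are identified
(every posterior boundary is the next rhombomere's anterior boundary), the
spline smoother uses a periodic basis with period 1.

## Worked example

Reproduce the goodness-of-fit table for a published-style experiment where
116 bounded clones were scored as 12 crossing, 34 respecting and 70 middle,
against chance probabilities (0.57, 0.22, 0.21):

```
$ rhomboclone report --counts 12,34,70 --probs 0.57,0.22,0.21
category  observed  expected  chi2_discrepancy
   cross      12.0      66.1              44.3
 respect      34.0      25.5               2.8
  middle      70.0      24.4              85.5
   total     116.0     116.0             132.6
df = 2, p < 1e-15
```

Chance predicts ~66 crossing clones; only 12 were seen, and middle clones
are three times over-represented — the chance model is rejected
overwhelmingly (χ² = 132.6, df = 2), the statistical signature of boundary
restriction.

The same pipeline run end-to-end on a simulated *null* clone table (no
boundary effect) fails to reject, as it should:

```
$ rhomboclone simulate --model null --n 116 --seed 42 --out demo.tsv
$ rhomboclone analyze demo.tsv --out demo_report
$ cat demo_report/gof.tsv        # chi2 total = 0.25, p = 0.88
$ cat demo_report/checks.tsv     # KS-uniform p = 0.51, KS-lognormal p = 0.67,
                                 # size-position correlation = -0.15
```

`rhomboclone nullmodel` prints `L(x)` on a grid together with the
calibrated margin (`delta = 0.1419`) and the null category probabilities
`(0.5704, 0.2200, 0.2096)`.

## Library surface

```python
from rhomboclone import (
    LognormalRadiusModel, CategoryCounts, chisq_gof,
    simulate_null_clones, simulate_restricted_clones, SimulationConfig,
)

model = LognormalRadiusModel()            # mu=-1.34, sigma=0.64
delta = model.calibrate_delta(0.22)       # 0.1419
probs = model.category_probabilities(delta)
gof = chisq_gof(CategoryCounts(n_cross=12, n_respect=34, n_middle=70), probs)
```

The simulators are pure functions of their seeded configs; the *restricted*
generator adds a single restriction-strength parameter `beta` (a would-be
crossing clone is truncated to abutment with probability `beta`), providing
a generative alternative for power studies.

Note on the implied mean radius: the model's arithmetic mean radius
`exp(μ + σ²/2) ≈ 0.32` sits close to, but not exactly at, the empirical
average radius of 0.30 typically reported for such data — the two are
different estimators and are not asserted equal anywhere in the package.

## Acceptance script

`scripts/acceptance.py` recomputes the package's two headline quantities
from scratch: the chance boundary-crossing probability (adaptive quadrature
of `L`, cross-checked against a 10⁷-draw Monte-Carlo simulation) and the
mean log radius recovered by fitting the lognormal model to an n = 10,000
sample from the null clone simulator.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
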