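# metastim

Tools for two-cue depth psychophysics: build cue-conflict ("metamer")
slant/tilt stimuli, generate factorial trial designs, simulate a synthetic
observer, estimate texture/disparity cue weights from perceived surface
orientations under a constrained vector-sum model, and test pre/post
cue-reweighting.

It is aimed at vision scientists studying how the visual system combines
texture-gradient and binocular-disparity information about 3D surface
orientation, and at anyone who needs a tested reference implementation of
the constrained vector-sum weight estimator.

## The model

A planar surface's pose is described by slant σ (rotation away from the
frontoparallel plane) and tilt τ (direction of the normal's projection
onto that plane); its unit normal is
**n**(σ, τ) = (sin σ cos τ, sin σ sin τ, cos σ).
A cue-conflict stimulus presents a texture cue at pose **n**_t and a
disparity cue at **n**_d. The perceived normal is modeled as the weighted
vector sum

&nbsp;&nbsp;&nbsp;&nbsp;**n**_p = w_t **n**_t + w_d **n**_d,

subject to the unit-norm constraint ‖w_t **n**_t + w_d **n**_d‖ = 1 and the
alignment constraint **n**_p · (w_t **n**_t + w_d **n**_d) = 1. In the
(w_d, w_t) plane the first constraint is an ellipse (centered at the
origin, rotated by −π/4, semi-axes 1/√(1 ∓ **n**_d·**n**_t)) and the
second a line; for percepts in the cue plane the line is tangent to the
ellipse and the tangency point is the closed-form solution, otherwise the
system is solved in the least-squares sense by Levenberg–Marquardt.
Because of the ellipse constraint the weights do not sum to one:
non-negative solutions satisfy w_t + w_d ≥ 1, with equality only at zero
conflict. Negative weights (percepts outside the cue wedge) are reported,
never clipped.

The analysis side estimates one weight pair per trial, averages within
design cells (σ_c × τ_c × discrepancy) per subject and phase, fits the
log-slant trend of w_d with per-tilt offsets (OLS plus a subject-level
bootstrap), and compares pre- vs post-training weights with a paired
sign-flip permutation test, max-T corrected over each 3 × 3 cell grid.

## Worked example

```python
import numpy as np
from metastim import (
    judgment_design, WeightField, ObserverNoise, simulate_study,
    estimate_trial_weights, aggregate, fit_trend, pre_post_test,
)

design = judgment_design()                       # 90 trials, 18 configs
field = WeightField()                            # generative w_d map
noise = ObserverNoise(kappa=150.0, seed=0)       # directional response noise
records = simulate_study(design, field, noise, n_subjects=10, group="ATD")
records = estimate_trial_weights(records)        # one (w_t, w_d) per trial
wmap = aggregate(records)
trend = fit_trend(wmap, n_boot=500, seed=0)
print(f"log-slant slope {trend.slope:.3f}, CI {trend.slope_ci}")
res = pre_post_test(wmap, n_perm=2000, seed=0)
print(f"significant cells: {int(res.table.significant.sum())} / {len(res.table)}")
```

Output:

```
log-slant slope -0.249, CI (-0.27716516549799725, -0.22175293730645274)
significant cells: 18 / 18
```

The slope is the fitted coefficient of w_d on ln σ_c in the pre phase
(the generative preset uses −0.25: disparity is down-weighted on steeper
surfaces), and all 18 design cells (9 per discrepancy condition) show a
significant post-training drop in w_d, the signature of reweighting
toward the texture cue after joint-control training.

A command-line interface mirrors the library:
`metastim design|render|simulate|estimate|analyze|prepost|run` (see
`metastim --help`).

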