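# pathmap

Voxel-wise moderated-mediation path analysis for group fMRI studies.

`pathmap` asks, at every voxel of the brain, whether a group difference in
task performance is *transmitted through* brain activity — not merely
whether activity differs between groups, or whether activity predicts
performance, but whether the causal chain

```
age group (A)  →  brain activity (B)  →  task performance (C)
```

holds, with the brain→performance path allowed to differ by group.  It is
aimed at cognitive-aging and clinical neuroimaging researchers who have
per-subject first-level contrast images (e.g. task-switch > single-task)
and a behavioral performance score (e.g. the switch cost in seconds), and
who want path-model inference rather than a one-equation group map.

## The model

At each voxel two regressions are fit (A coded young = 0, old = 1):

```
B = β0 + a·A + ε                        (mediator equation)
C = β0 + b·B + c′·A + v·A·B + ε         (moderated outcome equation)
```

Rewriting the outcome equation as `C = β0 + c′·A + (b + v·A)·B + ε` shows
that the brain→performance slope is conditional on group.  The indirect
(mediated) effect of group on performance is therefore also conditional:

```
Ind = a·(b + v·A)      →   Ind_young = a·b ,   Ind_old = a·b + a·v
```

If the interaction `v` is not significant at the height threshold
(p < 0.05, strict), the model degenerates to simple mediation
(`C = β0 + b·B + c′·A + ε`) and the indirect effect `a·b` is common to
both groups.  Significance of indirect effects uses 5000 age-group
**stratified** bootstrap resamples (each resample preserves the two group
sizes exactly) with **bias-corrected percentile** confidence intervals
(BCa and plain percentile are available).  Voxels supporting moderated
mediation (significant interaction *and* a significant indirect effect in
at least one group) and voxels supporting simple mediation (significant
indirect effect, non-significant interaction) form two mutually exclusive
maps; each is thresholded at 50 contiguous voxels (18-connectivity by
default) and reported as a cluster table with peak coordinates in
template-space millimeters.

A reversed formulation `B = β0 + g·A + h·C + j·A·C + ε` (the way standard
packages would model the same three variables, with brain as the
dependent measure) is provided for comparison; it tests a different
causal ordering and generally yields different interaction statistics.

## Worked example

The conditional-indirect arithmetic on published-style peak coefficients:

```python
>>> import pathmap as pm
>>> pm.conditional_indirect(a=0.625, b=-0.021, v=0.109, group=1).value
0.05500...   # old group:   a·b + a·v = +0.055
>>> pm.conditional_indirect(a=0.625, b=-0.021, v=0.109, group=0).value
-0.013125    # young group: a·b       = -0.013
```

Full inference at one voxel of a synthetic cohort (39 young / 45 old,
one embedded effect region with a = 0.625, b = −0.021, v = 0.109):

```python
import numpy as np
import pathmap as pm

spec = pm.SynthSpec(seed=42)
subjects, dataset, truth = pm.generate_cohort(spec)
peak = spec.effect_regions[0].center
col = np.flatnonzero((dataset.voxel_index_map == peak).all(axis=1))[0]

X = np.column_stack([subjects["group"], dataset.data[:, col]])
est = pm.ModeratedMediation(n_resamples=5000, random_state=1)
est.fit(X, subjects["performance"])
```

which prints (via the estimator's fitted attributes):

```
model: moderated
a = +0.482, b = -0.014, c' = +0.036, v = +0.095
indirect (young): -0.007  95% BC CI [-0.025, +0.006]
indirect (old):   +0.039  95% BC CI [+0.010, +0.074]*
```

The arbitration kept the interaction (v̂ = 0.095, near its generative
value 0.109); the indirect effect is significant for the old group only —
greater activity in older adults predicting slower performance — which is
exactly the moderated-mediation signature the method is built to detect.

The same analysis runs whole-brain from the shell:

```bash
pathmap simulate --out sim/                 # synthetic cohort + trial CSV
pathmap run --subjects sim/subjects.csv --images sim/images.csv \
            --mask sim/images/mask.nii.gz --out results/ --seed 1
pathmap report --maps results/maps --out tables/
```

`run` writes per-voxel NIfTI maps (a, b, c′, v, t/p maps, indirect
effects and CI bounds, model label), the two exclusive cluster tables as
TSV, and a JSON run manifest (seed, settings, input hashes).

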