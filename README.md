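# cortexproxy

Decode deeper brain activity from the brain's surface.

Scalp-based functional recordings (EEG, MEG, fNIRS) are depth-limited: they
see the cortex but not the structures it encloses. Because the cortex is
densely functionally connected with the rest of the brain, a multivariate
model trained on surface signals can nonetheless *track* interior activity.
`cortexproxy` implements that idea for resting-state fMRI as a tested,
reusable pipeline, for researchers who want to quantify how much information
about deep regions and distributed networks reaches a depth-limited shell of
cortex.

## What it computes

Given 4-D BOLD runs, a whole-brain mask, network template maps and atlas ROI
masks, the pipeline:

1. **Surface masks** — from the brain mask *A*, a subsurface mask
   *B* = {voxels deeper than *m* mm from background} is built with a
   voxel-size-scaled Euclidean distance transform, an inferior-exclusion mask
   *C* accumulates downward translations of *B*, and the surface is
   *A* − *B* − *C* (default *m* = 10 mm, sweepable 5–20 mm).
2. **Preprocessing** — voxelwise nuisance regression (WM and CSF mean series,
   6 motion parameters, orthogonal polynomial drift up to order 4) followed by
   6 mm FWHM Gaussian smoothing.
3. **Targets** — the label series *y*(*t*) per target: the unweighted ROI mean
   for anatomical regions, or stage-1 spatial regression of each volume on the
   network templates.
4. **Decoding** — linear ε-insensitive support vector regression
   ŷ(*t*) = **w**·**x**(*t*) + *b* from surface voxels (C = 100, ε = 0.1) or
   from sparse volumetric subdivisions (SVM-light default C = 1/mean‖x‖²).
   Accuracy is the Pearson *r* between ŷ and *y* on the held-out run,
   averaged over the two split-half directions.
5. **Significance** — "wavestrap" surrogates: a db4 multilevel DWT of the
   training labels with each level's detail coefficients permuted (levels from
   ⌊log₂(T/(L−1))⌋, the approximation untouched) yields a null distribution of
   accuracies; p-values are Benjamini–Hochberg corrected across the family of
   targets × feature modes.
6. **Group maps and subdivisions** — per-subject weight maps are combined with
   a voxelwise one-sample t-test, thresholded at FDR p < 0.05, clustered at
   26-connectivity (≥ 5 voxels), and clusters are recursively bisected by the
   plane **v**·**x** = *b* through the midpoint of each cluster's farthest
   voxel pair until every piece has ≤ 40 voxels (2,560 mm³ at 4 mm isotropic).
   Each subdivision's mean series is one sparse feature.

A synthetic resting-state generator (`cortexproxy.synthetic`) produces
multi-subject datasets with known latent network series, interior ROIs,
superior-surface patches, drift, nuisance signals and noise, so every stage is
testable end to end without scanner data.

## Worked example

```python
from cortexproxy import (
    ExperimentConfig, SyntheticSpec, run_experiment, depth_sweep_slope,
)

cfg = ExperimentConfig(
    synthetic=SyntheticSpec(noise_sd=0.0, n_subjects=1, n_networks=2,
                            t_len=96, seed=5),
    thicknesses_mm=(5.0, 10.0),
    target_kinds=("roi-mean",),
    n_surrogates=19,
    seed=5,
)
df, _ = run_experiment(cfg)
print(df[["subject", "target", "thickness_mm", "mean_r", "p"]].to_string(index=False))
```

prints

```
 subject        target  thickness_mm   mean_r    p
       1 net1:roi-mean           5.0 0.999923 0.05
       1 net2:roi-mean           5.0 0.999941 0.05
       1 net1:roi-mean          10.0 0.999923 0.05
       1 net2:roi-mean          10.0 0.999941 0.05
```

Each row is one subject × target × mask thickness: `mean_r` is the
cross-validated decoding accuracy (here ≈ 1 because the data are noiseless,
so the surface carries the interior signal exactly), and `p = 0.05` is the
smallest p-value attainable with 19 wavestrap surrogates — the true model
beat every surrogate.

The same entry points are available from the shell:

```bash
cortexproxy simulate --out-dir data --seed 7 --n-subjects 1
cortexproxy surface-mask --brain-mask data/brain_mask.nii.gz --thickness-mm 10 --out-prefix mask
cortexproxy run --config experiment.yaml --seed 7 --out-dir results
```

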