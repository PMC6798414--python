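# camrad

Intratumoural heterogeneity analysis for dynamic contrast-enhanced MRI
(DCE-MRI) of breast tumours: unsupervised decomposition of pixel kinetics
into vascular compartments by convex analysis of mixtures (CAM), radiomic
feature extraction from the whole tumour and its kinetic subregions,
survival stratification of those features, and a radiogenomic map linking
prognostic features to gene co-expression modules and multigene signatures.

The package is aimed at imaging and radiogenomics researchers who want the
full pipeline — or any single stage — as tested, scriptable Python, together
with a synthetic-data module that generates images, survival tables and
expression matrices with known ground truth, so every stage can be validated
without any cohort download.

## The model

Because of the partial volume effect, the enhancement time-series `x(i)` of
tumour pixel `i` mixes the kinetics of several tissue compartments:

    x(i) = Σ_j K_j(i) · a_j ,   K_j(i) ≥ 0 ,  Σ_j K_j(i) = 1 ,

where `a_j` is the nonnegative enhancement curve of compartment `j` (of J
total) and `K_j(i)` the tissue proportions at pixel `i`.  CAM recovers the
`a_j` as corners of the scatter simplex of pixel clusters: affinity
propagation reduces the N pixels to M exemplars `{x_m}`, and an exhaustive
search over all C(M, J) exemplar subsets minimises the total error margin

    δ_m = min ‖x_m − Σ_j w_j x_j‖₂   over the simplex  w ≥ 0, Σ w = 1,

summed over all exemplars.  Proportions follow by simplex-constrained least
squares; J can be selected by a minimum-description-length score, and with
J = 3 the compartments are labelled plasma input, fast flow and slow flow
from their wash-in/wash-out shape.  Downstream, 14 radiomic features
(histogram skewness/kurtosis/median, GLCM energy/maximum
probability/correlation on the precontrast and early-subtraction series,
plus volume and compactness) feed univariate and multivariate Cox models
with Benjamini-Hochberg correction, optimal log-rank cutoff stratification,
co-expression module eigengene correlation, and elastic-net gene signatures
transferable to independent expression cohorts.

## Worked example

```python
import numpy as np
from camrad.synthetic import generate_kinetic_curves, generate_mixture_image
from camrad.cam import CamDecomposition

tp = np.arange(0.0, 8.5, 1.0)                      # minutes
curves = generate_kinetic_curves(3, tp, seed=2)     # ground-truth compartments
tumour = generate_mixture_image(curves, shape=(12, 12, 6),
                                corner_fraction=0.05, noise_sigma=0.0, seed=3)
cam = CamDecomposition(n_compartments=3, random_state=0).fit(
    tumour.pixel_matrix, timepoints=tp)
print(cam.roles_)
print(np.round(cam.curves_, 3))
print(cam.subregions(1e-2).masks["fast_flow"].sum(), "fast-flow pixels")
```

prints

```
('slow_flow', 'fast_flow', 'plasma_input')
[[0.000e+00 1.890e-01 3.790e-01 5.360e-01 6.590e-01 7.490e-01 8.110e-01
  8.480e-01 8.650e-01]
 [0.000e+00 3.820e-01 8.400e-01 1.029e+00 9.920e-01 8.390e-01 6.530e-01
  4.800e-01 3.380e-01]
 [0.000e+00 1.048e+00 3.830e-01 6.100e-02 7.000e-03 1.000e-03 0.000e+00
  0.000e+00 0.000e+00]]
216 fast-flow pixels
```

— the decomposition recovers the three generator curves exactly on
noise-free data, and the role labels name which recovered curve is which:
the third row peaks at the first postcontrast minute and washes out almost
completely (plasma input), the second peaks mid-series (fast flow), the
first rises throughout (slow flow).  Of the 224 tumour pixels, the 216
whose fast-flow proportion exceeds the 1e-2 nontriviality threshold join
the fast-flow subregion; mixture pixels belong to several subregions.

The same stages run from the shell:

```bash
camrad synth --kind image --seed 1 --out-dir work
camrad decompose work/series.nii.gz --mask work/mask.nii.gz --out-dir work/cam
camrad features work/series.nii.gz --mask work/mask.nii.gz \
       --subregion-dir work/cam --out work/features.tsv
camrad run-all --seed 0 --out-dir work/full    # full synthetic pipeline
```

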