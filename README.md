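# cmflv

Left-ventricle segmentation for myocardial perfusion SPECT by
continuous max-flow with a kernel statistical shape prior.

Myocardial perfusion imaging (MPI) reconstructs the 3-D uptake of a
radiotracer in heart muscle.  Delineating the left-ventricular (LV)
myocardial shell in these volumes is hard: counts are Poisson-sparse,
edges are soft, and perfusion defects punch holes in the very structure
being segmented.  `cmflv` is a toolkit for this problem, aimed at
nuclear-medicine image analysts and methods researchers: a globally
optimal convex segmentation core, a low-parameter cardiac shape model
with a kernel-space statistical prior, a synthetic phantom generator
for controlled noise experiments, and quantitative evaluation plus an
optimal-transport surface comparison for studying how acquisition
geometry distorts the segmented shapes.

## The model

Segmentation is posed as the convex-relaxed two-phase min-cut over
labels λ(x) ∈ [0, 1]:

    min_λ  ∫ (1 − λ) C_s + λ C_t + C |∇λ| dx,

solved exactly by its dual — a continuous max-flow with source, sink
and spatial flows capped by (C_s, C_t, C) and coupled through
∇·p = p_s − p_t — via the standard augmented-Lagrangian multiplier
algorithm with Chambolle-type projections.  Thresholding the relaxed
label yields the binary mask.

Capacities come from Chan–Vese terms, C_s = w(I − c₀)², C_t = w(I − c₁)²,
optionally augmented with the per-voxel log-likelihood ratio of
inside/outside intensity histograms ("KLCV") — the pointwise statistic
whose region sum is the Kullback–Leibler divergence, better matched to
Poisson counts than a symmetric L2 fit.

Shape knowledge enters through a six-parameter LV shell (two
half-ellipse profile curves rotated about the long axis, plus a
reciprocal-curvature basal cap) and a kernel-PCA Mahalanobis energy
over shape descriptors with regularized covariance
Σ = VΛVᵀ + λ⊥(I − VVᵀ).  Energy-preferred candidate shells are blended
into a prior image I_prior and mixed with the data as

    I_eff = (λ_w I + μ_w I_prior) / (λ_w + μ_w),

so the alternation — pose estimate, prior blend, density re-estimate,
max-flow — keeps every sub-problem globally solvable.

## Worked example

Generate a noisy phantom, segment it, and score the result:

```python
import cmflv

vol, truth, _ = cmflv.make_phantom(cmflv.PhantomSpec())     # 64³, 4.8 mm
noisy = cmflv.add_poisson_noise(vol, target_psnr=8.0, seed=1)

candidates, model = cmflv.default_prior_bank()
mask, lam, diag = cmflv.segment_asm(noisy, model, candidates,
                                    cmflv.InteractionConfig())

print({k: round(v, 3) for k, v in
       cmflv.metrics(cmflv.confusion(mask, truth)).items()})
```

```
{'accuracy': 0.996, 'precision': 0.535, 'recall': 0.823, 'iou': 0.479, 'dice': 0.648}
```

At 8 dB the pipeline recovers the shell (Dice ≈ 0.65 against the
generator's ground truth; precision is depressed by partial-volume
halo voxels).  Dropping the noise target to −2 dB — below the method's
working threshold — collapses every metric toward 0, while between 6
and 12 dB the Dice stays flat within 0.1: the two regimes of the noise-
robustness experiment.

The same steps are available from the shell:

```sh
cmflv phantom --psnr 8 --seed 1 --out vol.nii --truth truth.nii
cmflv segment --in vol.nii --out mask.nii
cmflv eval --pred mask.nii --truth truth.nii
cmflv surfdist --masks masks/ --groups groups.csv --out pvals.csv
```

`surfdist` compares segmented surfaces per acquisition geometry:
marching-cubes clouds, pairwise debiased (un)balanced Sinkhorn
divergences at blur ε = 1e-3, and a one-sample Wilcoxon signed-rank
test on the upper-triangular distance matrix (exact null up to n = 25),
with the median distance reported as effect size.

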