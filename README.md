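# virtsamp

**Virtual neuropathologic block sampling on brain MRI: precision, accuracy,
and functional-connectivity consequences.**

Neuropathologic assessment of dementia samples a few standard cortical
blocks — middle frontal gyrus (MFG), middle/superior temporal gyri (MSTG),
inferior parietal lobule (IPL), primary visual cortex (V1) — from 4 mm
coronal slabs, using gross landmarks such as the anterior commissure to
pick the slab.  `virtsamp` simulates that bench protocol *in silico* on
volumetric images and quantifies how well it targets tissue, for
neuropathologists, neuroimagers, and brain-bank methodologists who want to
know whether landmark-guided sampling hits the region it is meant to hit —
and how much neuroimaging guidance would help.

## What it computes

For each subject and region the package builds a **subject-specific** block
(landmark-anchored bench emulation), a **reference** block (the
template-defined target mapped into the subject's anatomy — the ground
truth of "what should have been sampled"), and two improvements:

* the **guided** block — the subject-specific block translated in whole-slab
  steps along the anterior-posterior axis to maximize overlap with the
  reference (exhaustive search);
* the **optimal** block — the subject-specific block under the best
  6-DOF rigid motion (multi-start derivative-free search on a smoothed
  overlap surrogate with a supersampled polish; reported overlap always
  recomputed on hard binary masks).

Accuracy is percent overlap with the reference,
`100 · |S ∩ R| / |R|`; by nesting of the three strategies,
`overlap(optimal) ≥ overlap(guided) ≥ overlap(subject-specific)` holds for
every subject and region.  Precision is the voxelwise count of subjects
whose blocks cover each template voxel.  Method comparisons use the
Wilcoxon matched-pairs signed-rank test (exact for small n) and Poisson
regression of overlap counts with a log-exposure offset and subject-
clustered sandwich standard errors.  The functional consequence of
sampling error is assessed by seed-based connectivity: Pearson
correlations of each block's mean BOLD series to a 264-region set, with
per-region subject-specific-vs-reference differences tested by a sign-flip
permutation null (1,000 permutations, empirical top/bottom 5% thresholds).

Because no imaging data ship with the package, a **phantom generator**
produces a fully synthetic cohort with known ground truth: an MNI-like
template, subjects derived from it by known rigid + smooth nonlinear
deformations, a jittered anterior-commissure-like landmark that drives
block placement, and BOLD-like timeseries with a planted community
covariance.  Every analysis is validated against this ground truth.

## Worked example

Generate a small cohort and run the accuracy stage:

```sh
virtsamp synth scratch/demo -n 6 --seed 7
virtsamp accuracy --cohort scratch/demo --seed 7
```

which prints the per-region accuracy summary (percent overlap with the
reference; mean over 6 subjects):

```
roi_label           method  n      mean        sd    median        q1        q3       iqr
      IPL           guided  6 62.215888 17.556483 60.890175 49.329268 75.959305 26.630037
      IPL          optimal  6 95.059411  2.325184 94.842899 93.362216 96.283067  2.920851
      IPL subject_specific  6 23.074960 37.024397  0.000000  0.000000 40.487805 40.487805
      MFG           guided  6 59.973668 14.162681 64.752809 49.204091 70.922821 21.718730
      MFG          optimal  6 96.687353  2.421653 96.817286 94.841996 98.174486  3.332489
      MFG subject_specific  6 28.751611 32.114436 19.276869  1.511226 54.567606 53.056380
     MSTG           guided  6 57.133702 16.856156 54.720058 48.216421 57.519977  9.303556
     MSTG          optimal  6 98.126073  0.643749 98.020334 97.863160 98.589125  0.725965
     MSTG subject_specific  6 23.099973 27.812347 12.607945  0.000000 47.580951 47.580951
       V1           guided  6 67.754290 20.575393 66.431500 59.915622 75.049773 15.134151
       V1          optimal  6 97.499487  2.176487 98.049654 96.935176 98.515564  1.580388
       V1 subject_specific  6 12.618799 27.309209  0.000000  0.000000  5.779110  5.779110
```

Reading: bench-style subject-specific sampling captures only ~13–29% of the
intended tissue on average (often 0% — the wrong slab entirely), choosing
the right slab with imaging guidance raises this to ~57–68%, and freely
re-orienting the cut (the rigid-body upper bound) to ~95–98%.  The
remaining gap is the nonlinear anatomical difference a rigid cut cannot
absorb.  `virtsamp precision`, `virtsamp connectivity`, and `virtsamp all`
run the other stages; every stage also has a library entry point
(`virtsamp.pipeline.run_*`) and writes TSV/NIfTI/JSON outputs when given
`--output`.

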