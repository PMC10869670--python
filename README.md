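# sdsa — synthetic digital subtraction angiography

Digital subtraction angiography (DSA) delivers some of the highest
radiation doses in diagnostic imaging, and dose is directly proportional to
the number of frames acquired. `sdsa` implements a post-processing route to
dose reduction: acquire (or simulate acquiring) fewer frames, fit a
parametric contrast-transit model to every voxel's time–intensity series,
and regenerate the dropped frames by resampling the fitted curves — a
*synthetic DSA* (sDSA). The package is aimed at imaging researchers who
want to quantify how far angiographic frame rates can be cut before
reconstruction fidelity degrades.

## Model

Each voxel's first-pass time–intensity curve is modeled as a gamma-variate
function

```
SI(t) = A (t − AT)^α exp(−(t − AT)/β)   for t > AT,   0 otherwise
```

with amplitude `A`, shape `α > 0`, timescale `β > 0` (seconds) and contrast
arrival time `AT`. The curve is unimodal with its peak at
`Tmax = AT + αβ`. Frame-rate reduction (FRR) keeps every 2nd, 3rd, or 4th
frame (nominal 50%, 66%, 75% reductions); the model is fit per voxel to the
retained samples by bounded trust-region least squares, and the full-rate
series is regenerated by sampling the fit on the original time grid.
Reconstruction fidelity against the ground-truth series is the per-voxel
time-averaged relative error

```
R(t) = |SI_o(t) − SI_s(t)| / SI_o(t)
```

masked where the denominator is noise-dominated, summarized as mean ± SD
over valid voxels and rendered as green (≤ 3%) to red (≥ 15%) heatmaps.

A `reader_stats` module implements the statistics used to design and
analyze observer studies of synthetic angiograms: the 4-item 1–5 rubric
(composite 4–20), Kendall's coefficient of concordance W with mid-rank tie
correction, the coefficient of variation, and per-group sample size for a
two-sample t-test via the noncentral t distribution.

Because no public angiographic series ship with the package, a `phantom`
module generates desk-scale studies with known voxelwise gamma-variate
ground truth: a procedural vessel tree with arterial (AT 0.5–1.5 s),
capillary (1.5–3 s) and venous (3–5 s) compartments on a noise background.

## Worked example

```python
from sdsa import FrrScheme, PhantomSpec, generate_phantom, synthesize_study
from sdsa.evaluation import default_epsilon, error_map

phantom = generate_phantom(PhantomSpec(shape=(64, 64), seed=1, noise_sigma=0.0))
stack = phantom["stack"]                      # 16 frames @ 2 fps, 64x64
study = synthesize_study(stack, FrrScheme("FRR75"))
emap = error_map(stack, study["sdsa"], default_epsilon(stack))
s = emap.summary
print(f"FRR75 mean voxel error {100*s['mean']:.1f}% +- {100*s['sd']:.1f}% "
      f"over {s['n_valid']} valid voxels")
```

prints

```
FRR75 mean voxel error 26.2% +- 75.0% over 673 valid voxels
```

i.e. dropping 3 of every 4 frames of this 16-frame study leaves only 4
samples per voxel, and the average reconstruction error across enhancing
voxels rises to ~26% (at 50% reduction the same study reconstructs to
under 1% mean error). The same pipeline is available from the shell:

```
sdsa full --seed 1 --out results/   # phantom -> reduce -> fit -> sDSA -> report
```

which writes the reduced/synthetic stacks, error heatmaps, a per-scheme CSV
report and a reproducibility manifest.

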