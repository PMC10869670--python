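# Methods

## Contrast-transit model

A voxel traversed by a first-pass contrast bolus is modeled by the
four-parameter gamma-variate

    SI(t) = A (t − AT)^α exp(−(t − AT)/β)   (t > AT; 0 otherwise)

- `A` (amplitude, intensity units ≥ 0) sets the scale; note the *peak*
  intensity is `A (αβ)^α e^{−α}`, which can be orders of magnitude smaller
  than `A` for sharp transits.
- `α` (dimensionless > 0) and `β` (seconds > 0) shape wash-in and wash-out.
- `AT` (seconds ≥ 0) is the contrast arrival time.

Derived quantities: `Tmax = AT + αβ` (time of peak) and the leave time
`LT`, defined here as the post-peak time at which the curve decays to 5% of
its peak (the fraction is configurable; the washout limb is monotone, so
`LT` is found by bracketed root search). `LT` is descriptive only — nothing
downstream consumes it.

The model is single-pass: recirculation, extravascular leakage and vessel
overlap are deliberately out of scope. All times are seconds; frame
indices are 0-based; the conversion between the two lives solely in
`TimeGrid` (frame `k` at `origin + k / frame_rate`).

## Frame-rate reduction

`FRR50/66/75` retain every 2nd/3rd/4th frame, always starting at frame 0 so
the pre-arrival baseline is sampled (keep-first convention). "66%" is
implemented as exact stride 3; the label is the rounded nominal reduction.
The reduced stack's frame rate is the original divided by the stride.

## Per-voxel fitting

1. **Noise scale.** `σ` is the median absolute deviation of the pooled
   voxelwise first-difference series, scaled by 1.4826/√2. On clipped-at-zero
   synthetic data ~25% of background differences are exactly 0, biasing σ
   low by roughly a third; the consequence is a conservative background
   threshold (marginal voxels get fitted rather than skipped), not an
   accuracy loss.
2. **Classification.** Peak below `k·σ` (default `k = 3`) or a non-positive
   series → `background` (reconstructs as zero baseline). Fewer than 4
   samples → `fallback_interp` (4 free parameters need 4 points).
3. **Initial guess.** `AT₀` = latest pre-peak sample at ≤ 10% of peak;
   `Tmax₀` = argmax sample; `α₀` from a two-point log-domain estimate using
   the rising-limb sample nearest half-peak (points near the peak make the
   estimate degenerate); `β₀ = (Tmax₀ − AT₀)/α₀`; amplitude from the peak
   value. All components are clamped into the bound box.
4. **Solver.** Bounded trust-region least squares (TRF) on
   `(log A, α, β, AT)` with peak-normalized values and an analytic
   Jacobian. The log-amplitude transform is essential: `A` spans ~5 orders
   of magnitude across the physiological `(α, β)` range. Default bounds:
   `α ∈ [0.05, 20]`, `β ∈ [0.01, 60] s`, `AT ∈ [0, last sample time]`.
5. **Multistart.** Deterministic candidates over (arrival, shape): the
   first start places `AT` at the midpoint of the bracket between the last
   non-enhancing and first enhancing sample — the expected arrival under a
   flat prior on that interval — which also sets where the fit lands when
   the data do not pin `AT` (see identifiability below). Restarts stop
   early once a start reaches the noise floor.
6. **Convergence.** Solver tolerances scale with the noise level: series
   that are numerically noise-free (`σ ≤ 10⁻⁹·peak`) are polished to
   machine precision with a 10× evaluation budget — fast-transit voxels
   whose samples span many decades need this for parameter accuracy —
   while noisy fits use the configured tolerance (default 1e-10, 100
   evaluations). A solver that exhausts its budget while the residual is
   already numerically exact (flat valley) or at the measurement noise
   floor is treated as converged; genuine non-convergence returns
   `failed`, and such voxels reconstruct by piecewise-linear interpolation
   of the retained samples, as do too-short series.

Fitting is strictly per voxel; no spatial coupling.

## Identifiability

With an `n`-frame study at stride `s`, a voxel retains `⌈n/s⌉` samples, of
which only those after `AT` constrain `(A, α, β)`:

- **≥ 5 informative samples** (strictly over-determined): noise-free
  recovery is exact (relative error < 10⁻³, in practice ~10⁻¹⁵).
- **Exactly 4**: the system is exactly determined and can admit multiple
  exact interpolants — a fit with zero residual but wrong parameters.
- **≤ 3**: a one-dimensional family of exact fits exists (a valley); the
  solution is selected by the arrival-midpoint start, not by the data.

A default phantom (16 frames at 2 fps, venous arrivals up to 5 s) contains
voxels of all three regimes at FRR50, which is why parameter-recovery
statements in the tests are stratified by informative-sample count. The
same arithmetic explains noisy quarter-rate fits: at FRR75 a 16-frame study
leaves exactly 4 samples for 4 parameters, the least-squares optimum
interpolates the noise, and parameter variance is governed by sampling
geometry rather than optimizer quality — median Tmax error across
enhancing voxels is ~6–7% at 2% noise (venous voxels, with 1–3 informative
samples, sit near 20%; arterial near 3%). More frames, not better
optimization, is what improves this regime.

## Synthesis

The sDSA samples every fitted voxel's curve on the original grid;
background voxels emit zeros; fallback/failed voxels interpolate retained
samples linearly with constant extrapolation. Retained frames are by
default also replaced by model samples (temporally consistent smoothness);
`keep_acquired` passes them through verbatim. Negative model values cannot
occur under the bounds but are clamped defensively.

## Error metric

Per frame and voxel, `R(t) = |SI_o − SI_s| / SI_o`, defined only where
`SI_o > ε`; per voxel the arithmetic mean over defined frames; per study
mean ± sample SD over voxels defined at ≥ 1 frame. The default guard is
`ε = max(3σ, 0.01·max intensity)`: the metric is singular at zero
denominator, and even in a noise-free series the intensity just after
arrival is arbitrarily small — a ratio against less than 1% of the study's
dynamic range carries no information. Errors are stored as fractions and
reported in percent. Heatmaps clip to the green (≤ 3%) → red (≥ 15%)
display convention, with masked voxels neutral gray.

## Phantom

Random-walk vessel segments (width tapering 6→3 voxels arterial, 4→2
venous, 2→1 capillary) are rasterized onto a class mask, arterial drawn
last so trunks win overlaps. Each enhancing voxel draws independent
kinetics from its compartment: `AT ~ U(0.5, 1.5)` s arterial,
`U(1.5, 3)` s capillary, `U(3, 5)` s venous; `α ~ U(1.5, 4)`;
`β ~ U(0.3, 1.2)` s; peak `~ U(0.3, 1)·max intensity` (default 100).
Gaussian noise of sd `noise_sigma·max intensity` is added and clipped at 0.
Defaults: 64×64, 16 frames at 2 fps (the study floor for meaningful
quarter-rate fitting), 2% noise. All randomness flows from one seed.

What the phantom does *not* emulate: anatomically realistic vasculature,
vessel overlap in projection, recirculation, contrast dispersion
correlations between neighboring voxels (kinetics are drawn i.i.d. per
voxel), X-ray physics (scatter, beam hardening), or patient motion (an
optional per-frame global integer translation exists for robustness
experiments but is off by default). Passing tests therefore demonstrate
correctness of the model, fitting, synthesis and metric machinery on
curves of the assumed family — not clinical performance on real DSA runs,
where model misfit (recirculation, overlap) adds error the phantom cannot
show.

## Reader-study statistics

- Composite score: sum of four 1–5 items (arterial, capillary, venous,
  overall quality), range 4–20; out-of-range items are rejected.
- Kendall's W: mid-ranks within each rater (rubric scores are heavily
  tied), tie-corrected denominator `m²(n³−n) − mΣ(t³−t)`; p-value from the
  `χ² = m(n−1)W` approximation on `n−1` df. Undefined (raises) when every
  rater scores all subjects identically.
- Coefficient of variation: `100·sd/mean`, sample sd throughout (n−1).
- Sample size: smallest per-group `n` such that a **two-sided** two-sample
  pooled-variance t-test reaches the requested power, computed from the
  noncentral t at `df = 2n − 2` by integer search (floor n = 2). Sidedness
  is a convention choice (two-sided is the standard default); the result
  is per group. For 16 ± 2 vs 13 ± 3 at α = 0.05 and power 0.75 this gives
  12 (11 reaches 0.747).
- Summary table: per (reduction level, reader) and per-level totals with
  mean, sample sd, range and 95% t-based CI; singleton groups leave
  dispersion blank.

## Problem sizes and numerical conventions

Desk-scale defaults keep every pipeline run in seconds-to-minutes on one
core: 64×64×16 studies (~4k voxels, ~800–1,300 fitted) for headline
numbers, 24×24 for unit fixtures. Determinism is exact: identical inputs,
configuration and seed give bit-identical stacks, maps and CSV reports
(no unseeded randomness anywhere; voxel fits are order-independent).
Ties in the argmax of a series resolve to the earliest frame (numpy
convention). Degenerate inputs raise typed errors rather than propagating
NaNs: zero-size grids, non-increasing time vectors, all-zero series passed
to the initial guess, constant rating matrices, zero-mean CV, zero effect
sizes.

## Known limitations

- At FRR75 on 16-frame studies the fit is exactly determined; reported
  quarter-rate parameter accuracy is noise-limited by construction.
- The relative-error metric is undefined on non-enhancing voxels; summary
  statistics speak only for voxels above the guard.
- `estimate_noise` assumes temporally uncorrelated noise in a
  predominantly non-enhancing field of view; it is biased low on
  zero-clipped data and would be biased high on stacks dominated by
  enhancing voxels.
- DICOM support covers reading multi-frame XA with CineRate/FrameTime
  metadata; writing DICOM and biplane pairing are out of scope.
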