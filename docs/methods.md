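# Methods

## Forward model

A 2-D multislice acquisition of an isotropic HR volume `G` (grid
convention: axis order (z, y, x), voxel centre of index `i` at
`origin + i·spacing`, all lengths in mm) is modelled in four steps:

1. **Geometric transform** `T_k` into the stack frame. Orthogonal
   stacks are exact axis permutations (no interpolation). Shifted
   stacks translate along the slice axis; rotational stacks rotate
   about the volume's z axis about the grid centre. Both resample with
   linear interpolation; samples outside the source grid take a
   declared *fill* intensity (the scene background: the bath intensity
   for the tube phantom, 0/air for the biological phantom) so that
   support edges do not ring dark.
2. **Slice-profile blur** `H`: a 1-D Gaussian along the slice-select
   axis with FWHM equal to the slice thickness, matching the
   excitation profile of a multislice sequence. The discrete kernel
   uses σ = FWHM/(2√(2 ln 2)), truncation at ±3σ (<0.3 % mass lost) and
   renormalisation to unit sum, so constant volumes are conserved
   exactly.
3. **Decimation** `D`: point sampling of the blurred volume at the
   slice centres. Slice j is centred at `(j + 1/2)·AR − 1/2` in HR
   index units (the first slice is centred in its slab; contiguous
   slices), where AR = slice thickness / inplane spacing. The blur
   carries all through-plane partial-volume effect; no inplane
   degradation is applied because multislice stacks are acquired at
   full inplane resolution. In code, blur+decimation is applied as one
   cached banded matrix along the slice axis — mathematically identical
   to convolve-then-sample (asserted against that oracle in the tests)
   but AR× cheaper, which matters inside the reconstruction loop.
4. **Noise**: additive Gaussian of sd σ (default), or Rician
   (magnitude of signal plus complex Gaussian noise) for realism of
   magnitude MR images. Gaussian is the default because its moments
   make the metric calibrations exact; with Rician noise the background
   acquires a Rayleigh floor (mean σ√(π/2)) that biases background-ROI
   statistics, which is documented rather than corrected.

Upsampling (the adjoint-direction interpolator) is linear between
slice centres along the slice axis only, clamped beyond the terminal
slice centres so no signal is fabricated outside the acquired extent.

## Reconstruction

Plain additive Irani–Peleg IBP. The initial estimate averages the
upsampled, inverse-transformed stacks; each iteration simulates the
acquisitions on the current estimate (noise-free), measures the
residual `e(i) = max_k ‖f_k − f̂_k(i)‖` (max-abs per-stack norm by
default; RMS also recorded), and adds the 1/N-averaged back-projected
difference stacks. The back-projection kernel *is* the linear
upsampling interpolator — no separate BP filter, no relaxation factor.
Voxels outside a stack's inverse-transformed support (e.g. world-grid
corners never covered by a rotated view) are excluded from that stack's
contribution and the averaging denominator adapts per voxel.

Stopping: `residual_threshold` defaults to 1e-3 × the observed stacks'
dynamic range and `max_iterations` to 20. Noiseless problems converge
(the AR = 1 case reaches 1e-6 of the dynamic range in under ten
iterations); noisy problems never reach the threshold and stop at the
iteration cap.

**Semi-convergence.** With noisy stacks this plain update re-injects
the observation noise every iteration. Well-conditioned components fit
the noise once and stop; nearly-null components (frequencies attenuated
by every view's slice profile) accumulate back-projected noise roughly
linearly with iteration count. Reconstruction fidelity therefore peaks
after a few iterations and background noise grows monotonically — the
textbook reason IBP is run shallow or regularised in practice. This
drives a known limitation of the geometry comparison (below).

## Phantoms

**Resolution phantom** — five parallel cylinders (0.7 mm outer
diameter rendered entirely as signal void: the sealed air-filled tubes
give no signal, and whether the thin quartz wall contributes signal is
not distinguishable, so the full OD is void), wall-to-wall gaps of
0.7 mm (1.4 mm centre pitch), in a uniform bright bath (intensity 100
vs 0). Cylinder membership is computed on a 3×3×3 sub-voxel grid and
averaged in the one-voxel band straddling the surface — a hard mask
would alias and contaminate edge measurements. Tubes have a finite
length (default spans the FOV; settable) so that total void volume is
orientation-invariant. The oblique orientation tilts the tube axis by
the given angles (first in the xy plane, then in the yz plane); the
tube **row** is taken as the component of the slice-select (z) axis
orthogonal to the tilted tube axis — the row stays as close to the
slice axis as the tilt permits, which is the worst case for
through-plane partial-volume mixing and the configuration the oblique
experiment is meant to probe. The row direction of the physical rack
is otherwise underdetermined by the tilt angles alone.

**Biological phantom** — an embryo analogue built from nested
supersampled ellipsoids: dark surround (0, the Fluorinert analogue), a
body of uniform tissue (60), a liver-like organ (100) whose sharp
closed boundary hosts the 20 boundary-normal edge profiles, a
homogeneous brain-like sphere (85) for the SNR signal ROI, and thin
bright shells and rods (120, 1–3 voxels wide) as rib/fine-structure
analogues. A seed jitters organ semi-axes by ±2 %. The generator also
emits its own region map: 9×9×9 ROIs (signal, background noise,
high/low contrast pair) and the edge segments, so ROI placement is
reproducible rather than hand-picked. The noise ROI sits at the centre
of a face, in air but inside the acquired support of every rotated
stack (corners are not covered by rotated views). Profile windows are
0.32 of the mean liver semi-axis plus 2.5 voxels on each side, capped
so they never leave body tissue. These clearance guarantees are exact
for grids ≥ 96³ (verified across seeds); at the 64³ minimum the 9³
signal ROI's corners graze the brain boundary and one of twenty
profiles can pass near a rod — quantitative runs use ≥ 96³.

What the phantom deliberately does *not* emulate: anatomical texture
(regions are piecewise constant, so homogeneity-based metrics are
cleaner than in tissue), intensity non-uniformity, susceptibility or
motion artefacts, and scanner-side registration error between stacks
(all stacks are generated in exactly known frames). Passing tests on
this phantom therefore validate the algorithmic pipeline, not
robustness to real-data misalignment.

## Metrics

SNR = mean(signal ROI) / sd(noise ROI); CNR = |mean_h − mean_l| /
max(sd_h, sd_l); both raise an explicit error when the relevant sd is
zero (undefined, not infinite). Edge profiles are sampled at 0.25 HR
pixel along boundary-normal segments (supersampling stabilises fits on
near-voxel edges; a3 stays per-HR-pixel because coordinates are in
pixels), fitted by bounded nonlinear least squares with data-driven
initialisation; descending profiles are flipped so a3 > 0, and
non-converged fits are dropped and counted, never imputed. Edge width
is 4.4/a3 pixels; 4.4 agrees with the analytic 10–90 % logistic rise
2 ln 9 = 4.394 to two significant figures. Tube modulation detects
local minima with prominence ≥ 5 % of the profile's dynamic range
(chosen a priori as comfortably above the post-reconstruction noise
ripple) and scores their mean depth relative to the flanking maxima,
normalised by the dynamic range; fewer than five detected minima score
0 (unresolved).

## Study conditions

The geometry comparison runs on the biological phantom at 128³ voxels
of 0.05 mm (desk-scale stand-in for the 512² embryo scans; reachable
sizes are a config knob), ARs 4 and 6, noise σ = 4 on a 0–120 intensity
scale (single-stack background SNR ≈ 25, matching the low-20s to
low-40s range of real embryo acquisitions), five replicate seeds, and
3 min per stack for the time accounting. Replicate/cell seeds derive
from each replicate seed via `numpy.random.SeedSequence` with spawn key
(geometry code, AR, stack index), so any cell is independently
re-runnable. The acceptance *script* runs the same comparison at 96³
with three seeds to stay lightweight; the tube-resolvability experiment
(oblique rack, AR 5, 128², σ = 2 against a bath of 100) runs at full
size in both.

## Known limitations

* **SNR ordering across geometries.** On real scans, orthogonal SRR
  has been observed to deliver the highest SNR, rotational next,
  shifted last, all above the interpolated baseline. This clean
  simulation does not reproduce that chain at any stopping point, and
  the mechanism is structural: at initialisation (pure averaging) SNR
  ranks by stack count (rotational 6 > shifted N > orthogonal 3), while
  under deeper IBP iteration noise growth ranks by conditioning —
  orthogonal fits the noisy data fastest — and every SRR volume falls
  below the single-stack baseline, which involves no iterative noise
  re-injection. The orderings that do emerge robustly here:
  orthogonal ≥ rotational in SNR at full iteration depth, edge width
  rotational ≤ shifted < interpolated, and the acquisition-time
  advantage of the orthogonal plan. Real-acquisition effects absent
  from this simulation (notably registration/resampling losses in
  rotated and shifted stacks) are the plausible source of the
  remaining discrepancy.
* **Oblique interpolated baseline.** With the stated tilt angles the
  tube axis is ~51° off the slice axis, which caps the row's
  slice-axis component at 0.78; the tubes then stay ~0.9 mm apart
  inplane and a single interpolated stack retains five genuine (if
  shallow, modulation ≈ 0.33) minima instead of failing outright. The
  fully row-aligned case does produce the complete pattern, including
  baseline failure.
* Arbitrary oblique *slice* orientations, regularised or least-squares
  SRR variants, slice-to-volume motion registration, k-space effects
  and physical signal modelling (T1/T2, flip angle) are out of scope.
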