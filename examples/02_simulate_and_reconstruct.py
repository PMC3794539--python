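"""Simulate three orthogonal multislice stacks and reconstruct by IBP.

Each low-resolution stack keeps the high-resolution inplane grid but is
blurred by a Gaussian slice profile (FWHM = slice thickness) and sampled
once per slice along its slice-select axis.  Iterative back-projection
then fuses the three views into an isotropic volume.
"""

import numpy as np

import srrkit as sk

spec = sk.PhantomSpec(grid_shape=(96, 96, 96), spacing=(0.203,) * 3,
                      tube_length_mm=15.0)
hr = sk.make_resolution_phantom(spec)
bg = spec.background_intensity

ar = 4  # slice thickness = 4 x inplane voxel size ("1:1:4")
model = sk.AcquisitionModel(
    inplane_spacing=0.203, slice_thickness=ar * 0.203, noise_sigma=0.0
)
plan = sk.plan_orthogonal(model.slice_thickness, model.inplane_spacing)
stacks = [
    sk.simulate_lr_stack(hr, g, model, seed=k, fill=bg)
    for k, g in enumerate(plan.geometries)
]
print(f"simulated {len(stacks)} stacks, {stacks[0].n_slices} slices each "
      f"(HR grid {hr.shape})")

recon, trace = sk.ibp_reconstruct(stacks, sk.IBPConfig(fill=bg))
init = sk.ibp_initialize(stacks, sk.IBPConfig(fill=bg))

rms_init = np.sqrt(np.mean((init.data - hr.data) ** 2))
rms_final = np.sqrt(np.mean((recon.data - hr.data) ** 2))
print(f"IBP ran {trace.iterations_run} iterations "
      f"(converged: {trace.converged})")
print(f"residual trace (max-abs): "
      + ", ".join(f"{r:.1f}" for r in trace.residuals[:6]) + ", ...")
print(f"RMS error vs ground truth: initialisation {rms_init:.2f} "
      f"-> final {rms_final:.2f} (intensity units on a 0-100 scale)")
print("-> on noiseless stacks the iterations steadily sharpen the averaged")
print("   initial estimate.  With noisy stacks IBP semi-converges: fidelity")
print("   peaks after a few iterations and then the volume starts fitting")
print("   noise, which is why the iteration cap matters (see docs/methods).")
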