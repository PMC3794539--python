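"""Build the 5-tube resolution phantom and probe its line profile.

The phantom mimics a rack of sealed quartz capillaries (0.7 mm outer
diameter, 0.7 mm wall-to-wall gaps) immersed in a bright contrast bath:
the tubes are signal voids.  The tube-modulation score of a profile
across the tube row is 1.0 for perfectly resolved tubes and 0.0 when
fewer than five minima are detectable.
"""

import numpy as np

import srrkit as sk

spec = sk.PhantomSpec(
    kind="resolution",
    grid_shape=(96, 96, 96),
    spacing=(0.203, 0.203, 0.203),  # 128-matrix inplane resolution, mm
    tube_length_mm=15.0,
)
phantom = sk.make_resolution_phantom(spec)
layout = sk.resolution_phantom_layout(spec)

profile = sk.extract_line_profile(
    phantom, layout.profile_start_mm, layout.profile_end_mm, 400
)
modulation = sk.tube_modulation(profile, spec.n_tubes)

print(f"grid {phantom.shape}, spacing {phantom.spacing[0]} mm")
print(f"intensity range: {phantom.data.min():.0f} (tube voids) "
      f"to {phantom.data.max():.0f} (bath)")
print(f"tube modulation of the ground-truth profile: {modulation:.3f}")
print("-> close to 1.0: all five tubes are fully resolved in the HR phantom.")

# tilt the rack obliquely to every grid axis (worst partial-volume case)
oblique = sk.PhantomSpec(
    kind="resolution", grid_shape=(96, 96, 96), spacing=(0.203,) * 3,
    orientation=(40.0, 55.0), tube_length_mm=15.0,
)
ob_layout = sk.resolution_phantom_layout(oblique)
print(f"oblique tube axis (z,y,x): {np.round(ob_layout.tube_axis, 3)}")
print(f"oblique row axis  (z,y,x): {np.round(ob_layout.row_axis, 3)}")
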