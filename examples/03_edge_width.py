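"""Sigmoid edge-spread fitting and the 4.4/a3 edge-width rule.

An intensity profile across a sharp boundary is fitted with the
logistic edge model f(x) = a1 + a2 / (1 + exp(-a3 (x - a4))).  The
10-90% rise length of the logistic is 2 ln 9 / a3 ~= 4.4 / a3 pixels,
so a fitted a3 of 4.4 means the edge rises over exactly one voxel.
"""

import numpy as np

import srrkit as sk
from srrkit.metrics import LineProfile, sigmoid_edge_model

x = np.arange(0.0, 60.0, 0.25)  # supersampled at 1/4 pixel

for a3 in (4.4, 2.2, 1.1):
    profile = LineProfile(x_pixels=x, values=sigmoid_edge_model(x, 10.0, 90.0, a3, 30.0))
    fit = sk.fit_sigmoid_edge(profile)
    print(f"true a3 = {a3:4.1f}  ->  fitted a3 = {fit.a3:6.3f}, "
          f"edge width = {sk.edge_width_pixels(fit):.3f} px")

print()
rng = np.random.default_rng(0)
noisy = sigmoid_edge_model(x, 10.0, 90.0, 4.4, 30.0) + rng.normal(0, 1.8, x.size)  # ~2% noise
fit = sk.fit_sigmoid_edge(LineProfile(x_pixels=x, values=noisy))
print(f"with 2% noise: fitted a3 = {fit.a3:.3f} "
      f"(edge width {sk.edge_width_pixels(fit):.3f} px)")
print("-> widths of 1, 2 and 4 px are recovered from the slopes; "
      "noise perturbs a3 by a few percent.")
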