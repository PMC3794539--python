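# srrkit

Super-resolution reconstruction (SRR) of isotropic MR volumes from
anisotropic 2-D multislice stacks, built to compare **acquisition
geometries** for small-animal imaging.

In vivo mouse MRI is usually acquired as 2-D multislice stacks whose
inplane resolution (50–100 µm) is 5–10× finer than the slice-select
resolution (500–1000 µm), because a fully isotropic 3-D acquisition
would take hours under anesthesia and gating. SRR recovers an isotropic
high-resolution (HR) volume from several low-resolution (LR) stacks that
view the same field of view differently. Three stack-set geometries are
in common use, and they differ in both image quality and scan time:

* **shifted** — N stacks sub-voxel-shifted along the slice axis,
  N = slice thickness / inplane voxel size;
* **rotational** — six stacks whose slice axis rotates in 30° steps
  about the magnet z axis;
* **orthogonal** — three stacks sliced along the axial, coronal and
  sagittal planes.

`srrkit` provides every stage as a library: digital phantoms (a 5-tube
resolution phantom and an embryo-like biological phantom with built-in
ROI/edge layouts), the multislice forward model, Irani–Peleg iterative
back-projection (IBP), and the image-quality metrics used to compare
the results.

## The model

Each observed LR stack is modelled as

```
f_k = D H T_k G + n_k,     k = 1..N
```

where `G` is the true HR volume, `T_k` the stack's rigid geometry
(shift, rotation, or axis permutation), `H` a 1-D Gaussian slice-profile
blur along the slice-select axis with FWHM equal to the slice thickness,
`D` point sampling at the slice centres, and `n_k` acquisition noise.
IBP starts from the average of the upsampled, realigned stacks,

```
G(0) = (1/N) Σ_k T_k⁻¹ upsample(f_k)
```

and iterates

```
G(i+1) = G(i) + (1/N) Σ_k T_k⁻¹ upsample( f_k − D H T_k G(i) )
```

until the residual `e(i) = max_k ‖f_k − f̂_k(i)‖` drops below a preset
threshold or an iteration cap is reached.

Image quality is quantified by SNR = S/σ_n (signal-ROI mean over
background-noise sd), CNR = |S_h − S_l| / max(σ_h, σ_l), and the edge
width of a logistic fit `f(x) = a1 + a2/(1 + exp(−a3(x − a4)))` to
boundary profiles: the 10–90 % rise length is `4.4/a3` HR pixels
(4.4 ≈ 2 ln 9), so `a3 = 4.4` means a one-voxel edge. A
*tube-modulation* score (depth of the five tube minima in a line
profile, 0 when fewer than five are detected) quantifies whether the
resolution phantom's tubes are resolved.

## Worked example

`examples/04_geometry_comparison.py` runs the full pipeline on a 64³
embryo-like phantom at voxel aspect ratio 1:1:4 with matched noise:

```
    geometry  ar   snr   cnr  mean_edge_width_pixels  acquisition_minutes
       truth   1 20.83  9.92                    1.32                  NaN
interpolated   4 26.54 10.10                    5.42                  3.0
     shifted   4 19.30  7.46                    2.08                 12.0
  rotational   4 11.37  5.41                    1.61                 18.0
  orthogonal   4 11.78  4.90                    1.43                  9.0
```

Reading the table: every SRR geometry roughly recovers the ground
truth's edge sharpness (1.4–2.1 px vs 1.3 px) while the single-stack
interpolated baseline stays blurred (5.4 px); the orthogonal plan needs
only 3 stacks (9 min) against 12–18 min for the others. SNR after the
full 20 IBP iterations is *lower* than the baseline's because plain IBP
re-injects observation noise each iteration — see
`docs/methods.md` for why, and for what early stopping does instead.

The other examples show the resolution phantom
(`01_resolution_phantom.py`), a noiseless simulate→reconstruct round
trip whose RMS error drops from 2.27 to 0.23 intensity units
(`02_simulate_and_reconstruct.py`), and edge-width recovery
(`03_edge_width.py`).

A thin CLI mirrors the pipeline stages:

```sh
srrkit phantom --kind resolution --grid-size 96 --out hr.nii.gz
srrkit simulate --hr hr.nii.gz --geometry orthogonal --ar 4 --fill 100 --out stacks/
srrkit reconstruct --stacks stacks/ --fill 100 --out recon.nii.gz
srrkit compare --config config.yaml --out run/
```

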