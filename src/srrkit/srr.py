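"""Irani-Peleg iterative back-projection (IBP) super-resolution core.

The HR estimate is initialised as the voxelwise average of the
upsampled, inverse-transformed LR stacks.  Each iteration then
(1) simulates the imaging process on the current estimate (slice-profile
blur + decimation, no noise), (2) measures the residual
``e(i) = max_k || f_k - fhat_k^(i) ||``, and (3) back-projects the
upsampled difference stacks into the world frame, averaging with 1/N
weighting and adding the result to the estimate.  Iterations stop when
``e(i)`` falls below a preset threshold or a maximum count is reached.

The back-projection kernel equals the upsampling interpolator (linear);
there is no separate BP filter and no relaxation factor — this is the
plain additive Irani-Peleg update.  Voxels outside a stack's
inverse-transformed support (e.g. world-grid corners never seen by a
rotated view) are excluded from that stack's contribution, and the 1/N
denominator adapts per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .acquisition import LRStack, simulate_lr_stack, upsample_stack
from .geometry import transform_volume
from .volume import Volume


@dataclass
class IBPConfig:
    """Stopping rule and interpolation settings of the IBP loop.

    ``residual_threshold=None`` resolves at run time to 1e-3 times the
    dynamic range of the observed stacks (the preset threshold of the
    stopping rule); with that default, noiseless problems converge and
    noisy runs stop on ``max_iterations``.  ``fill`` is the intensity
    assumed outside a stack's support (the scene background).
    """

    max_iterations: int = 20
    residual_threshold: Optional[float] = None
    residual_norm: str = "max_abs"
    interpolation: str = "linear"
    target_spacing: Optional[float] = None
    fill: float = 0.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.residual_threshold is not None and self.residual_threshold < 0:
            raise ValueError("residual_threshold must be >= 0")
        if self.residual_norm not in ("max_abs", "rms"):
            raise ValueError(f"unknown residual norm {self.residual_norm!r}")

    def to_dict(self) -> dict:
        return {
            "max_iterations": self.max_iterations,
            "residual_threshold": self.residual_threshold,
            "residual_norm": self.residual_norm,
            "interpolation": self.interpolation,
            "target_spacing": self.target_spacing,
            "fill": self.fill,
        }


@dataclass
class ConvergenceTrace:
    """Per-iteration residuals e(i) of one reconstruction.

    ``residuals`` follows the configured stopping norm; both norms are
    recorded for audit regardless of which one stops the loop.
    """

    residuals: list[float] = field(default_factory=list)
    residuals_max_abs: list[float] = field(default_factory=list)
    residuals_rms: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False
    threshold: float = float("nan")


def _stack_norm(diff: np.ndarray, norm: str) -> float:
    if norm == "max_abs":
        return float(np.max(np.abs(diff)))
    if norm == "rms":
        return float(np.sqrt(np.mean(diff**2)))
    raise ValueError(f"unknown residual norm {norm!r}")


def _backproject(stack: LRStack, config: IBPConfig) -> Volume:
    """Upsample one stack and map it back to the world frame."""
    up = upsample_stack(stack, interpolation=config.interpolation)
    return transform_volume(
        up, stack.geometry, "inverse", interpolation=config.interpolation, fill=config.fill
    )


def _support_mask(stack: LRStack, config: IBPConfig) -> np.ndarray:
    """World-frame voxels that receive genuine data from this stack."""
    ones = Volume(np.ones(stack.hr_shape), spacing=(stack.hr_spacing,) * 3, origin=stack.origin)
    back = transform_volume(
        ones, stack.geometry, "inverse", interpolation=config.interpolation, fill=0.0
    )
    return back.data > 1.0 - 1e-6


def _masked_mean(
    stacks: Sequence[LRStack],
    config: IBPConfig,
    masks: Optional[Sequence[np.ndarray]] = None,
    default: float = 0.0,
) -> Volume:
    if masks is None:
        masks = [_support_mask(s, config) for s in stacks]
    num = None
    den = None
    template = None
    for stack, mask in zip(stacks, masks):
        vol = _backproject(stack, config)
        if num is None:
            num = np.zeros_like(vol.data)
            den = np.zeros(vol.data.shape)
            template = vol
        num += np.where(mask, vol.data, 0.0)
        den += mask
    covered = den > 0
    out = np.full(num.shape, default, dtype=np.float64)
    np.divide(num, den, out=out, where=covered)
    return template.with_data(out)


def ibp_initialize(stacks: Sequence[LRStack], config: Optional[IBPConfig] = None) -> Volume:
    """Initial HR estimate: mean of the upsampled stacks, each
    geometrically transformed back to the world orientation; voxels a
    stack never saw are excluded from that voxel's mean."""
    if not stacks:
        raise ValueError("need at least one LR stack")
    config = config or IBPConfig()
    return _masked_mean(stacks, config, default=config.fill)


def ibp_simulate(hr_est: Volume, stacks: Sequence[LRStack], fill: float = 0.0) -> list[LRStack]:
    """Simulate each observed stack's acquisition (noise-free) on the
    current HR estimate."""
    out = []
    for s in stacks:
        model = replace(s.model, noise_sigma=0.0)
        out.append(simulate_lr_stack(hr_est, s.geometry, model, fill=fill))
    return out


def ibp_residual(
    observed: Sequence[LRStack], simulated: Sequence[LRStack], norm: str = "max_abs"
) -> float:
    """e = max over stacks of the per-stack norm of (f_k - fhat_k)."""
    if len(observed) != len(simulated):
        raise ValueError(
            f"observed ({len(observed)}) and simulated ({len(simulated)}) stack counts differ"
        )
    return max(_stack_norm(o.data - s.data, norm) for o, s in zip(observed, simulated))


def ibp_update(
    hr_est: Volume,
    observed: Sequence[LRStack],
    simulated: Sequence[LRStack],
    config: Optional[IBPConfig] = None,
    masks: Optional[Sequence[np.ndarray]] = None,
) -> Volume:
    """One additive IBP step: back-project the difference stacks and add
    their (per-voxel support-weighted) average to the estimate."""
    config = config or IBPConfig()
    if len(observed) != len(simulated):
        raise ValueError("observed and simulated stack lists must align")
    diffs = [o.with_data(o.data - s.data) for o, s in zip(observed, simulated)]
    correction = _masked_mean(diffs, config, masks=masks, default=0.0)
    return hr_est.with_data(hr_est.data + correction.data)


def ibp_reconstruct(
    stacks: Sequence[LRStack], config: Optional[IBPConfig] = None
) -> tuple[Volume, ConvergenceTrace]:
    """Run the full IBP loop; deterministic (no randomness inside).

    Returns the final HR estimate and the convergence trace.  Raises if
    non-finite values appear mid-iteration, naming the iteration.
    """
    if not stacks:
        raise ValueError("need at least one LR stack")
    config = config or IBPConfig()
    threshold = config.residual_threshold
    if threshold is None:
        lo = min(float(s.data.min()) for s in stacks)
        hi = max(float(s.data.max()) for s in stacks)
        threshold = 1e-3 * (hi - lo)
    masks = [_support_mask(s, config) for s in stacks]
    est = _masked_mean(stacks, config, masks=masks, default=config.fill)
    trace = ConvergenceTrace(threshold=threshold)
    for i in range(1, config.max_iterations + 1):
        simulated = ibp_simulate(est, stacks, fill=config.fill)
        diffs = [o.data - s.data for o, s in zip(stacks, simulated)]
        e_max = max(_stack_norm(d, "max_abs") for d in diffs)
        e_rms = max(_stack_norm(d, "rms") for d in diffs)
        e = e_max if config.residual_norm == "max_abs" else e_rms
        if not np.isfinite(e):
            raise RuntimeError(f"non-finite residual at IBP iteration {i}")
        trace.residuals.append(e)
        trace.residuals_max_abs.append(e_max)
        trace.residuals_rms.append(e_rms)
        trace.iterations_run = i
        if e < threshold:
            trace.converged = True
            break
        if i == config.max_iterations:
            break
        est = ibp_update(est, stacks, simulated, config, masks=masks)
        if not np.all(np.isfinite(est.data)):
            raise RuntimeError(f"non-finite estimate at IBP iteration {i}")
    return est, trace
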