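"""Compound-scaling rules for the convolutional feature extractor.

A compound-scaled CNN grows its depth, channel width and input resolution
jointly by powers of fixed bases: for a compound coefficient ``phi`` the
multipliers are ``depth = alpha**phi``, ``width = beta**phi`` and
``resolution = gamma**phi``.  The defaults (alpha=1.2, beta=1.1,
gamma=1.15) give, at phi=1, a 1.2x deeper, 1.1x wider network operating on
1.15x larger inputs than the unscaled baseline.

This module also houses the small sizing rules the backbone layers share:
same-padding width for odd kernels, strided output size under the
same-padding convention, and the squeeze-excitation channel reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidConfigError

__all__ = [
    "ScalingConfig",
    "ScalingMultipliers",
    "compound_scale",
    "padding_for_kernel",
    "conv_output_size",
    "se_channels",
]

#: All stride-2 stages must divide the input evenly, so resolutions are
#: snapped to a multiple of this.
RESOLUTION_STEP = 32


@dataclass(frozen=True)
class ScalingConfig:
    """Bases and compound coefficient of the scaling rule.

    Parameters
    ----------
    alpha : float
        Depth base (dimensionless, >= 1).
    beta : float
        Width base (dimensionless, >= 1).
    gamma : float
        Resolution base (dimensionless, >= 1).
    phi : float
        Compound coefficient (>= 0); phi=0 leaves the baseline unscaled.
    base_resolution : int
        Side length in pixels of the unscaled input.
    """

    alpha: float = 1.2
    beta: float = 1.1
    gamma: float = 1.15
    phi: float = 1.0
    base_resolution: int = 224

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "phi"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise InvalidConfigError(f"{name} must be a finite number, got {value!r}")
        if self.alpha < 1 or self.beta < 1 or self.gamma < 1:
            raise InvalidConfigError(
                "scaling bases alpha, beta, gamma must all be >= 1 "
                f"(got {self.alpha}, {self.beta}, {self.gamma})"
            )
        if self.phi < 0:
            raise InvalidConfigError(f"compound coefficient phi must be >= 0, got {self.phi}")
        if self.base_resolution < RESOLUTION_STEP:
            raise InvalidConfigError(
                f"base_resolution must be >= {RESOLUTION_STEP}, got {self.base_resolution}"
            )


@dataclass(frozen=True)
class ScalingMultipliers:
    """Derived multipliers and the resulting input resolution."""

    depth: float
    width: float
    resolution: float
    input_resolution: int


def _round_to_multiple(x: float, step: int = RESOLUTION_STEP) -> int:
    # round-half-up so e.g. 240.0 -> 256 deterministically
    return step * int(math.floor(x / step + 0.5))


def compound_scale(config: ScalingConfig) -> ScalingMultipliers:
    """Evaluate the compound-scaling rule.

    Returns the depth/width/resolution multipliers ``alpha**phi``,
    ``beta**phi``, ``gamma**phi`` and the scaled input resolution,
    ``base_resolution * gamma**phi`` rounded to the nearest multiple of 32
    so that every stride-2 stage divides evenly.

    Examples
    --------
    >>> compound_scale(ScalingConfig()).depth
    1.2
    >>> compound_scale(ScalingConfig(phi=0)).input_resolution
    224
    """
    if not isinstance(config, ScalingConfig):
        raise InvalidConfigError("compound_scale expects a ScalingConfig")
    depth = config.alpha ** config.phi
    width = config.beta ** config.phi
    resolution = config.gamma ** config.phi
    input_resolution = _round_to_multiple(config.base_resolution * resolution)
    return ScalingMultipliers(depth, width, resolution, max(input_resolution, RESOLUTION_STEP))


def padding_for_kernel(kernel_size: int) -> int:
    """Same-padding width ``(f - 1) / 2`` for an odd kernel size ``f``."""
    if not isinstance(kernel_size, (int,)) or kernel_size < 1:
        raise InvalidConfigError(f"kernel size must be a positive integer, got {kernel_size!r}")
    if kernel_size % 2 == 0:
        raise InvalidConfigError(f"even kernel size {kernel_size} is unsupported (no symmetric padding)")
    return (kernel_size - 1) // 2


def conv_output_size(input_size: int, stride: int) -> int:
    """Spatial output size ``ceil(input / stride)`` under same padding.

    With stride 1 the spatial dimensions are preserved exactly.
    """
    if input_size < 1 or stride < 1:
        raise InvalidConfigError(
            f"input_size and stride must be >= 1 (got {input_size}, {stride})"
        )
    return -(-input_size // stride)


def se_channels(c_in: int, omega: int) -> int:
    """Bottleneck width ``floor(c_in / omega)`` of the squeeze-excitation
    pathway, clamped to a minimum of one channel."""
    if c_in < 1 or omega < 1:
        raise InvalidConfigError(f"c_in and omega must be >= 1 (got {c_in}, {omega})")
    return max(1, c_in // omega)
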