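"""Radial basis function weights and Fisher z correlation transforms.

These are the two numerical primitives of the full-brain correlation
model: a Gaussian RBF spreads each electrode's information over nearby
MNI locations, and the Fisher z-transformation makes correlations
approximately additive so they can be averaged across sessions and
patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

#: Correlations are clipped to +/-(1 - CLIP_EPS) before the z-transform
#: so that |r| = 1 never produces an infinite z value.
CLIP_EPS = 1e-6


@dataclass(frozen=True)
class RbfKernelSpec:
    """Gaussian RBF kernel ``exp(-||x - y||^2 / lambda_width)``.

    Parameters
    ----------
    lambda_width : float
        Spatial smoothing scale in squared MNI millimeters. Larger values
        spread an electrode's information further. Default 20, the value
        used for all the reference analyses.
    """

    lambda_width: float = 20.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_width) or self.lambda_width <= 0:
            raise ValueError(
                f"lambda_width must be a positive finite number, got {self.lambda_width}"
            )


@dataclass(frozen=True)
class WeightMatrix:
    """RBF weights from model locations (targets) to electrode locations.

    ``weights[i, j] = exp(-||targets[i] - sources[j]||^2 / lambda)``;
    entries lie in (0, 1], with 1 exactly for coincident points.
    """

    targets: np.ndarray  # (M, 3)
    sources: np.ndarray  # (N, 3)
    weights: np.ndarray  # (M, N)
    kernel: RbfKernelSpec


def rbf_weights(
    targets: np.ndarray,
    sources: np.ndarray,
    kernel: RbfKernelSpec | float = RbfKernelSpec(),
) -> WeightMatrix:
    """Evaluate the Gaussian RBF between every target and source location.

    Parameters
    ----------
    targets : (M, 3) array of MNI coordinates in mm.
    sources : (N, 3) array of MNI coordinates in mm.
    kernel : RbfKernelSpec or float
        Kernel specification; a bare float is taken as ``lambda_width``.
    """
    if not isinstance(kernel, RbfKernelSpec):
        kernel = RbfKernelSpec(float(kernel))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if targets.shape[1] != 3 or sources.shape[1] != 3:
        raise ValueError("locations must be (n, 3) arrays of MNI mm coordinates")
    if not (np.isfinite(targets).all() and np.isfinite(sources).all()):
        raise ValueError("locations must be finite")
    sq = cdist(targets, sources, metric="sqeuclidean")
    return WeightMatrix(
        targets=targets,
        sources=sources,
        weights=np.exp(-sq / kernel.lambda_width),
        kernel=kernel,
    )


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transformation ``z = (log(1+r) - log(1-r)) / 2``.

    Input correlations are clipped to ``+/-(1 - 1e-6)`` so perfect
    correlations map to a large finite z rather than infinity.
    """
    r = np.clip(np.asarray(r, dtype=float), -1.0 + CLIP_EPS, 1.0 - CLIP_EPS)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inv(z: np.ndarray | float) -> np.ndarray | float:
    """Inverse Fisher transform ``r = (exp(2z) - 1) / (exp(2z) + 1)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out
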