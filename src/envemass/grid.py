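"""The lattice of candidate monoisotopic positions.

An isotopic envelope is (nearly) periodic: aggregated clusters sit ~1.0024 Da
apart.  The grid {delta + k*zeta} captures that comb.  The step zeta is
estimated by circular statistics — peaks are wound onto a circle of
circumference zeta and the winding that concentrates them most (minimal
circular variance) is the inter-cluster spacing.  The phase delta is the
argument of the probability-weighted complex mean.  A prediction is finished
by rounding it to the nearest grid node and applying a small relative
correction lambda that recenters the error distribution (cluster spacings
drift slightly across the envelope, so the extrapolated node is biased by a
few ppb of the mass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.optimize import minimize_scalar

LAMBDA_RELATIVE = "relative"
LAMBDA_PER_NODE = "absolute_per_node"


@dataclass(frozen=True)
class GridModel:
    """Grid step (Da), canonical shift (Da) and the relative correction."""

    zeta: float
    delta: float
    lambda_corr: float = 0.0
    lambda_mode: str = LAMBDA_RELATIVE

    def __post_init__(self):
        if not 0.99 < self.zeta < 1.02:
            raise ValueError(f"grid step {self.zeta} outside the physical window")
        if self.lambda_mode not in (LAMBDA_RELATIVE, LAMBDA_PER_NODE):
            raise ValueError(f"unknown lambda mode: {self.lambda_mode!r}")
        object.__setattr__(self, "delta", _canonical(self.delta, self.zeta))


def _canonical(delta: float, zeta: float) -> float:
    """Reduce a shift into [-zeta/2, zeta/2)."""
    return (delta + zeta / 2) % zeta - zeta / 2


def circular_transform(masses, probs, zeta: float, weighted: bool = True) -> np.ndarray:
    """Wind peaks onto a circle of circumference ``zeta``.

    Each mass maps to the angle 2*pi*mass/zeta; angles are rotated so the
    circular mean (probability-weighted unless ``weighted`` is False) sits at
    zero, then mapped back to positions in [-zeta/2, zeta/2].
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    masses = np.asarray(masses, dtype=float)
    probs = np.asarray(probs, dtype=float)
    angles = 2 * np.pi * masses / zeta
    weights = probs if weighted else np.ones_like(probs)
    mean_angle = np.angle(np.sum(weights * np.exp(1j * angles)))
    wrapped = np.angle(np.exp(1j * (angles - mean_angle)))
    return wrapped * zeta / (2 * np.pi)


def _transform_variance(masses, probs, zeta: float) -> float:
    positions = circular_transform(masses, probs, zeta)
    mean = np.dot(probs, positions)
    return float(np.dot(probs, (positions - mean) ** 2))


def optimal_zeta(
    spectrum,
    search: Tuple[float, float] = (0.998, 1.008),
    n_scan: int = 2001,
    tol: float = 1e-7,
) -> float:
    """Grid step minimizing the circular variance of the wound spectrum.

    A dense scan over the search interval locates the basin; bounded scalar
    minimization then refines the optimum to ``tol``.  Single-peak spectra
    are rejected (their transform variance is identically zero).
    """
    masses = np.asarray(spectrum.masses, dtype=float)
    probs = np.asarray(spectrum.normalized_probs, dtype=float)
    if masses.size < 2:
        raise ValueError("zeta estimation needs at least two peaks")
    lo, hi = search
    candidates = np.linspace(lo, hi, n_scan)
    variances = [_transform_variance(masses, probs, z) for z in candidates]
    best = int(np.argmin(variances))
    blo = candidates[max(best - 1, 0)]
    bhi = candidates[min(best + 1, n_scan - 1)]
    result = minimize_scalar(
        lambda z: _transform_variance(masses, probs, z),
        bounds=(blo, bhi),
        method="bounded",
        options={"xatol": tol},
    )
    return float(result.x)


def universal_zeta(m_avg: float, gamma0: float, gamma_avg: float) -> float:
    """Linear universal grid step: gamma0 + gamma_avg * M_avg."""
    if m_avg < 0:
        raise ValueError("average mass must be non-negative")
    return gamma0 + gamma_avg * m_avg


def estimate_delta(spectrum, zeta: float) -> float:
    """Grid shift from the complex mean of the wound spectrum.

    delta = (zeta / 2 pi) * arg sum_p prob * exp(2 pi i mass / zeta),
    canonicalized into [-zeta/2, zeta/2).  For concentrated envelopes this
    coincides with the direct minimizer of the probability-weighted squared
    circular distance between peaks and grid nodes.
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    masses = np.asarray(spectrum.masses, dtype=float)
    probs = np.asarray(spectrum.normalized_probs, dtype=float)
    resultant = np.sum(probs * np.exp(2j * np.pi * masses / zeta))
    if abs(resultant) < 1e-12:
        raise ValueError("indeterminate grid shift: peaks are circularly uniform")
    return _canonical(float(np.angle(resultant)) * zeta / (2 * np.pi), zeta)


def round_to_grid(m_hat: float, grid: GridModel) -> float:
    """Snap a mass to the nearest grid node and apply the lambda correction.

    Ties between two equidistant nodes resolve toward the lower mass (the
    monoisotopic variant is the lightest).  In ``relative`` mode the selected
    node is scaled by (1 + lambda); in ``absolute_per_node`` mode lambda
    accumulates once per grid index.
    """
    steps = (m_hat - grid.delta) / grid.zeta
    k = math.ceil(steps - 0.5)  # nearest integer, half-way cases downward
    node = grid.delta + k * grid.zeta
    if grid.lambda_mode == LAMBDA_RELATIVE:
        return node * (1.0 + grid.lambda_corr)
    return node + grid.lambda_corr * k
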