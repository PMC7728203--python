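"""Directional statistics for growth kernels.

Every cue acting on a growth cone (drift fields, soluble-factor gradients,
intrinsic random motion, directional persistence, tissue structure) is encoded
as a 3D multivariate Gaussian: the mean vector is the directional bias, the
covariance the anisotropic mobility. Independent cues combine by convolution,
which for Gaussians is simply the sum of means and the sum of covariances.
The next step direction is then drawn from the *angular* marginal of the
combined Gaussian — the projected-normal (general angular Gaussian)
distribution on the unit sphere — discretized on a Fibonacci lattice,
restricted to the aperture cone around the persistence axis, and sampled by
discrete inversion.

The angular density of a 3D Gaussian N(mu, Sigma) projected onto the sphere is

    f(y) = (2*pi)^(-1) |Sigma|^(-1/2) (y' S y)^(-3/2)
           * exp(0.5 * (alpha^2 - mu' S mu)) * M2(alpha),

with S = Sigma^-1, alpha = (y' S mu) / sqrt(y' S y) and
M2(a) = (1 + a^2) Phi(a) + a phi(a) the second moment of a unit-variance
normal truncated at zero. For mu = 0, Sigma = I this reduces to the uniform
density 1/(4*pi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy.special import ndtr  # standard normal CDF, vectorized

logger = logging.getLogger("ramify.kernels")

__all__ = [
    "MGDParams",
    "AngularDensity",
    "KuhnEstimate",
    "mgd_from_cue",
    "drift_kernel",
    "soluble_kernel",
    "random_walk_kernel",
    "persistence_kernel",
    "structure_kernel",
    "convolve",
    "m2",
    "gagd_density",
    "build_angular_grid",
    "angular_density_from_kernel",
    "restrict_aperture",
    "draw_direction",
    "kuhn_length",
    "orthonormal_frame",
]

_EPS_REG = 1e-8
_SQRT_2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Gaussian kernel parameters
# ---------------------------------------------------------------------------

@dataclass
class MGDParams:
    """Mean vector and covariance of one 3D Gaussian growth kernel.

    ``mu`` is in voxel units per step; ``sigma`` must be symmetric and
    positive semi-definite (it is regularized by ``eps * I`` before any
    inversion, so delta-like kernels with ``sigma -> 0`` are legal).
    """

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(3)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(3, 3)
        if not np.all(np.isfinite(self.mu)) or not np.all(np.isfinite(self.sigma)):
            raise ValueError("MGD parameters must be finite")
        asym = np.abs(self.sigma - self.sigma.T).max()
        if asym > 1e-9:
            raise ValueError(f"covariance not symmetric (max asymmetry {asym:g})")
        self.sigma = 0.5 * (self.sigma + self.sigma.T)
        lo = np.linalg.eigvalsh(self.sigma)[0]
        if lo < -1e-9:
            logger.warning("covariance not PSD (min eigenvalue %g); regularizing", lo)
            self.sigma = self.sigma - (lo - _EPS_REG) * np.eye(3)

    def regularized(self, eps: float = _EPS_REG) -> "MGDParams":
        """Return a copy with ``eps * I`` added, safe for inversion."""
        return MGDParams(self.mu, self.sigma + eps * np.eye(3))


def convolve(kernels: Sequence[MGDParams]) -> MGDParams:
    """Combine independent Gaussian cues into a single Gaussian.

    The sum of independent Gaussian random vectors is Gaussian with summed
    means and summed covariances, so convolving the cue densities is exact.
    """
    kernels = list(kernels)
    if not kernels:
        raise ValueError("cannot convolve an empty kernel list")
    mu = np.sum([k.mu for k in kernels], axis=0)
    sigma = np.sum([k.sigma for k in kernels], axis=0)
    return MGDParams(mu, sigma)


# ---------------------------------------------------------------------------
# Cue -> kernel builders (mean-vector / covariance pairs)
# ---------------------------------------------------------------------------

def drift_kernel(vector: np.ndarray, eps: float = _EPS_REG) -> MGDParams:
    """Deterministic drift: mean along the field vector, delta-like covariance."""
    return MGDParams(np.asarray(vector, float), eps * np.eye(3))


def soluble_kernel(gradient: np.ndarray, beta: float = 1.0, gamma: float = 1.0,
                   attractive: bool = True) -> MGDParams:
    """Chemotactic cue: mean +/- beta * grad(c), isotropic covariance gamma * I."""
    sign = 1.0 if attractive else -1.0
    return MGDParams(sign * beta * np.asarray(gradient, float), gamma * np.eye(3))


def random_walk_kernel(sigma: float | Sequence[float] = 1.0) -> MGDParams:
    """Unbiased random motion: zero mean, diagonal covariance diag(sigma^2)."""
    s = np.broadcast_to(np.asarray(sigma, float), (3,))
    if np.any(s <= 0):
        raise ValueError("random-walk sigma must be positive")
    return MGDParams(np.zeros(3), np.diag(s ** 2))


def persistence_kernel(history: Sequence[np.ndarray], memory: int,
                       sigma: float = 1.0) -> MGDParams:
    """Directional persistence: mean is the sum of the last ``memory`` unit
    step directions, covariance isotropic."""
    hist = list(history)[-memory:] if memory > 0 else []
    mu = np.sum(hist, axis=0) if hist else np.zeros(3)
    return MGDParams(mu, sigma ** 2 * np.eye(3))


def structure_kernel(tensor: np.ndarray, gradient: np.ndarray,
                     alpha: float = 1.0, gain: float = 1.0) -> MGDParams:
    """Structural guidance from the local structure tensor.

    The tensor's strong eigenvectors point *across* structures (along image
    gradients), its weak eigenvector *along* them. Growth should align with
    structures, so the eigenvalues are mapped to their "dual"
    ``lam_i -> lam_min + lam_max - lam_i`` (largest variance along the weakest
    gradient direction), trace-normalized, and scaled by ``alpha``. The mean
    is the smoothed intensity gradient scaled by ``gain``, biasing growth
    toward high-intensity structures.
    """
    tensor = np.asarray(tensor, float).reshape(3, 3)
    tensor = 0.5 * (tensor + tensor.T)
    lam, vecs = np.linalg.eigh(tensor)  # ascending eigenvalues
    dual = lam[0] + lam[-1] - lam
    tr = dual.sum()
    if tr <= 1e-30:
        sigma = alpha * np.eye(3) / 3.0  # structureless voxel: isotropic
    else:
        sigma = alpha * (vecs * (dual / tr)) @ vecs.T
    return MGDParams(gain * np.asarray(gradient, float), sigma)


_CUE_KINDS = ("drift", "soluble", "random_walk", "persistence", "structure")


def mgd_from_cue(cue_kind: str, local_data, params: dict | None = None) -> MGDParams:
    """Dispatch a cue of a given kind to its kernel builder.

    ``local_data`` is the field vector (drift), gradient (soluble),
    ``(tensor, gradient)`` pair (structure), the direction history
    (persistence), or ignored (random_walk). ``params`` carries the cue
    weights (``beta``, ``gamma``, ``sigma``, ``memory``, ``alpha``, ``gain``).
    """
    params = dict(params or {})
    if cue_kind == "drift":
        return drift_kernel(local_data, **params)
    if cue_kind == "soluble":
        return soluble_kernel(local_data, **params)
    if cue_kind == "random_walk":
        return random_walk_kernel(**params)
    if cue_kind == "persistence":
        memory = int(params.pop("memory", len(local_data)))
        return persistence_kernel(local_data, memory, **params)
    if cue_kind == "structure":
        tensor, gradient = local_data
        return structure_kernel(tensor, gradient, **params)
    raise ValueError(f"unknown cue kind {cue_kind!r}; expected one of {_CUE_KINDS}")


# ---------------------------------------------------------------------------
# Angular marginal (projected normal / angular Gaussian)
# ---------------------------------------------------------------------------

def m2(alpha):
    """Second moment of a standard normal shifted by ``alpha`` and truncated
    at zero: ``M2(a) = (1 + a^2) Phi(a) + a phi(a) = int_0^inf u^2 phi(u - a) du``."""
    a = np.asarray(alpha, dtype=float)
    phi = np.exp(-0.5 * a * a) / _SQRT_2PI
    out = (1.0 + a * a) * ndtr(a) + a * phi
    return out if out.ndim else float(out)


def m2_quadrature(alpha: float) -> float:
    """Adaptive-quadrature evaluation of the defining integral (test oracle)."""
    val, _ = integrate.quad(
        lambda u: u * u * np.exp(-0.5 * (u - alpha) ** 2) / _SQRT_2PI,
        0.0, np.inf)
    return val


def gagd_density(y: np.ndarray, kernel: MGDParams, eps: float = _EPS_REG):
    """Projected-normal density on the unit sphere for one or many directions.

    ``y`` has shape (3,) or (n, 3) and must hold unit vectors. Singular
    covariances are regularized by ``eps * I`` before inversion. The density
    integrates to 1 over the sphere.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    sigma = kernel.sigma + eps * np.eye(3)
    S = np.linalg.inv(sigma)
    det = np.linalg.det(sigma)
    mu = kernel.mu
    q = np.einsum("ni,ij,nj->n", Y, S, Y)
    a = Y @ (S @ mu)
    alpha = a / np.sqrt(q)
    m0 = mu @ S @ mu
    # alpha^2 <= mu' S mu by Cauchy-Schwarz, so the exponent is <= 0 and may
    # only underflow (delta-like kernels then rely on the grid fallback)
    expo = np.minimum(0.5 * (alpha * alpha - m0), 0.0)
    with np.errstate(under="ignore"):
        dens = (np.exp(expo) * m2(alpha)
                / (2.0 * np.pi * np.sqrt(det) * q ** 1.5))
    return float(dens[0]) if single else dens


# ---------------------------------------------------------------------------
# Discretized densities on the sphere
# ---------------------------------------------------------------------------

@dataclass
class AngularDensity:
    """A probability density discretized on a grid of sphere directions.

    ``weights`` are per-node solid angles (steradians); a normalized density
    satisfies ``sum(weights * density) == 1`` over its support.
    """

    directions: np.ndarray  # (n, 3) unit vectors
    weights: np.ndarray     # (n,) steradians
    density: np.ndarray     # (n,) nonnegative

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.weights * self.density))

    def normalized(self) -> "AngularDensity":
        mass = self.total_mass
        if mass <= 0:
            raise ValueError("cannot normalize a zero-mass density")
        return AngularDensity(self.directions, self.weights, self.density / mass)


def build_angular_grid(n_nodes: int = 2000) -> AngularDensity:
    """Near-uniform Fibonacci lattice on the sphere with equal solid-angle
    weights ``4 pi / n`` and the uniform density ``1/(4 pi)``."""
    if n_nodes < 12:
        raise ValueError("need at least 12 grid nodes")
    i = np.arange(n_nodes)
    z = 1.0 - (2.0 * i + 1.0) / n_nodes
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    w = np.full(n_nodes, 4.0 * np.pi / n_nodes)
    dens = np.full(n_nodes, 1.0 / (4.0 * np.pi))
    return AngularDensity(dirs, w, dens)


def angular_density_from_kernel(kernel: MGDParams, grid: AngularDensity,
                                mask: np.ndarray | None = None) -> AngularDensity:
    """Evaluate the projected-normal density of ``kernel`` on a sphere grid.

    The result is renormalized on the grid so quadrature error never
    accumulates. If the density underflows everywhere (extremely peaked
    delta-like kernels), all mass is placed on the node closest to the mean
    direction. ``mask`` optionally restricts evaluation (and support) to a
    subset of nodes, which is what the aperture fast path uses.
    """
    dens = np.zeros(len(grid.directions))
    idx = slice(None) if mask is None else mask
    dens[idx] = gagd_density(grid.directions[idx], kernel)
    mass = np.sum(grid.weights * dens)
    if mass <= 0.0 or not np.isfinite(mass):
        logger.debug("angular density underflow; falling back to delta at mean")
        dens[:] = 0.0
        sub = np.flatnonzero(np.ones(len(dens), bool) if mask is None else mask)
        mu = kernel.mu
        axis = mu / np.linalg.norm(mu) if np.linalg.norm(mu) > 0 else np.array([0, 0, 1.0])
        best = sub[np.argmax(grid.directions[sub] @ axis)]
        dens[best] = 1.0 / grid.weights[best]
        return AngularDensity(grid.directions, grid.weights, dens)
    return AngularDensity(grid.directions, grid.weights, dens / mass)


def restrict_aperture(density: AngularDensity, axis: np.ndarray,
                      omega_deg: float) -> AngularDensity:
    """Zero the density outside the cone of half-angle ``omega_deg`` about
    ``axis`` and renormalize over the cap.

    The aperture implements the maximum allowed curvature of a growing edge
    (and thereby local self-avoidance). If the cap captures no probability
    mass, the node nearest to the axis carries all of it.
    """
    if not 0.0 <= omega_deg <= 180.0:
        raise ValueError("aperture must lie in [0, 180] degrees")
    axis = np.asarray(axis, float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("aperture axis must be nonzero")
    axis = axis / nrm
    if omega_deg >= 180.0:
        return density.normalized()
    cosom = np.cos(np.deg2rad(omega_deg))
    dots = density.directions @ axis
    mask = dots >= cosom - 1e-12
    dens = np.where(mask, density.density, 0.0)
    mass = np.sum(density.weights * dens)
    if mass <= 0.0:
        logger.debug("no mass inside aperture cap; delta at nearest node")
        dens = np.zeros_like(dens)
        best = int(np.argmax(dots))
        dens[best] = 1.0 / density.weights[best]
        return AngularDensity(density.directions, density.weights, dens)
    return AngularDensity(density.directions, density.weights, dens / mass)


def draw_direction(density: AngularDensity, rng: np.random.Generator) -> np.ndarray:
    """Draw one grid direction with probability proportional to
    ``weight * density`` (discrete inversion; bounded cost, reproducible)."""
    p = density.weights * density.density
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot sample from a zero-mass density")
    cdf = np.cumsum(p)
    u = rng.random() * total
    idx = int(np.searchsorted(cdf, u, side="right"))
    idx = min(idx, len(cdf) - 1)
    return density.directions[idx].copy()


# ---------------------------------------------------------------------------
# Persistence analysis
# ---------------------------------------------------------------------------

@dataclass
class KuhnEstimate:
    """Kuhn length and exponential-decay persistence length of a trajectory."""

    kuhn_length: float
    persistence_length: float
    cos_by_lag: np.ndarray = field(repr=False)


def kuhn_length(positions: np.ndarray, step_length: float | None = None,
                max_lag: int | None = None) -> KuhnEstimate:
    """Estimate the Kuhn length of a uniform-step polyline.

    The estimator is ``dl * sum_lag <cos theta(lag)>`` where
    ``<cos theta(lag)>`` averages the direction correlation over all start
    indices (the lag-0 self term contributes 1). A straight n-step line gives
    ``n * dl``; an uncorrelated walk gives ``~ dl``. The persistence length is
    obtained from an exponential fit ``<cos theta(lag)> = exp(-lag*dl/l_p)``
    over the leading positive-correlation lags (``inf`` for a perfectly
    straight line).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 3:
        raise ValueError("need at least 3 positions")
    steps = np.diff(pos, axis=0)
    lens = np.linalg.norm(steps, axis=1)
    if np.any(lens == 0):
        raise ValueError("zero-length step in trajectory")
    if step_length is None:
        step_length = float(lens.mean())
    dirs = steps / lens[:, None]
    n = len(dirs)
    lags = n if max_lag is None else min(max_lag + 1, n)
    cos_by_lag = np.empty(lags)
    for d in range(lags):
        cos_by_lag[d] = np.mean(np.sum(dirs[: n - d] * dirs[d:], axis=1))
    kuhn = step_length * float(np.sum(cos_by_lag))

    # exponential-decay fit over the initial strictly positive run
    upto = 1
    while upto < lags and cos_by_lag[upto] > 0:
        upto += 1
    if upto <= 1:
        lp = step_length  # decorrelated after one step
    else:
        x = np.arange(upto)
        logc = np.log(cos_by_lag[:upto])
        slope = np.polyfit(x, logc, 1)[0] if upto > 1 else 0.0
        lp = np.inf if slope >= -1e-12 else -step_length / slope
    return KuhnEstimate(kuhn, float(lp), cos_by_lag)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` (unit) to an orthonormal frame."""
    axis = np.asarray(axis, float)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2
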