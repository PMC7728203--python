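"""Multilayer 3D growth environment.

The environment is a stack of co-registered scalar volumes ("channels"):
tissue structure, soluble-cue concentrations, and an integer occupancy layer
recording which voxels are crossed by which network edges. Derived fields —
Gaussian-derivative gradients and the six unique components of the structure
tensor — are computed lazily per channel and cached until the channel is
replaced (environments may be dynamic).

Conventions: volumes are indexed ``[x, y, z]``; voxel centers sit at integer
coordinates; agents move in continuous coordinates within the closed box
``[0, shape_i - 1]`` per axis; the containing voxel of a position is the
nearest integer triple. Trilinear interpolation between voxel centers gives
continuous lookups of every derived field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

logger = logging.getLogger("ramify.environment")

__all__ = [
    "OutOfBoundsError",
    "LocalCues",
    "EnvironmentStack",
    "compute_gradient_field",
    "compute_structure_tensor_field",
    "assemble_tensor",
    "required_search_field",
    "DEFAULT_IMPRINT_RADIUS",
]

#: unique structure-tensor components, row-major upper triangle
TENSOR_COMPONENTS = ("xx", "xy", "xz", "yy", "yz", "zz")
_TENSOR_PAIRS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))

#: voxels traversed by a segment always have centers within half a cube
#: diagonal of it, so this imprint radius guarantees every polyline sample's
#: containing voxel is labeled.
DEFAULT_IMPRINT_RADIUS = float(np.sqrt(3.0) / 2.0)


class OutOfBoundsError(ValueError):
    """A continuous position left the volume domain."""


def compute_gradient_field(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-derivative gradient (d/dx, d/dy, d/dz) of a 3D volume.

    ``sigma`` is the derivative scale in voxels; ``sigma == 0`` falls back to
    central differences. Boundary handling is 'reflect', which keeps ramps
    linear in the interior. The operator is linear in the input.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={channel.ndim}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite values")
    if sigma == 0:
        return np.stack(np.gradient(channel))
    out = np.empty((3,) + channel.shape)
    for ax in range(3):
        order = [0, 0, 0]
        order[ax] = 1
        out[ax] = ndimage.gaussian_filter(channel, sigma, order=order, mode="reflect")
    return out


def compute_structure_tensor_field(channel: np.ndarray, sigma_grad: float = 1.0,
                                   sigma_window: float = 2.0) -> np.ndarray:
    """Six unique components of the structure tensor of a 3D volume.

    ``J_ab = G_{sigma_window} * (d_a I * d_b I)`` with the gradient taken at
    scale ``sigma_grad``. Returns shape ``(6,) + volume.shape`` in the order
    ``xx, xy, xz, yy, yz, zz``. Per voxel the assembled 3x3 tensor is
    symmetric positive semi-definite up to filter round-off.
    """
    if sigma_window < 0:
        raise ValueError("sigma_window must be >= 0")
    g = compute_gradient_field(channel, sigma_grad)
    out = np.empty((6,) + g.shape[1:])
    for c, (a, b) in enumerate(_TENSOR_PAIRS):
        prod = g[a] * g[b]
        out[c] = (prod if sigma_window == 0
                  else ndimage.gaussian_filter(prod, sigma_window, mode="reflect"))
    return out


def assemble_tensor(components: np.ndarray) -> np.ndarray:
    """Assemble a symmetric 3x3 tensor from the six unique components."""
    xx, xy, xz, yy, yz, zz = components
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


def required_search_field(merge_radius: float) -> int:
    """Smallest cube half-width guaranteed to contain the containing voxel of
    every edge sample within the merge range ``2 * R_c`` of a cone."""
    return int(np.ceil(2.0 * merge_radius + 1.0)) - 1


def _trilinear(fields: np.ndarray, position: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of stacked fields ``(..., X, Y, Z)`` at one
    continuous position (voxel centers at integer coordinates)."""
    shape = np.array(fields.shape[-3:])
    i0 = np.floor(position).astype(int)
    i0 = np.minimum(np.maximum(i0, 0), shape - 2)
    f = position - i0
    x0, y0, z0 = i0
    c = fields[..., x0:x0 + 2, y0:y0 + 2, z0:z0 + 2]
    wx = np.array([1 - f[0], f[0]])
    wy = np.array([1 - f[1], f[1]])
    wz = np.array([1 - f[2], f[2]])
    return np.einsum("...ijk,i,j,k->...", c, wx, wy, wz)


@dataclass
class LocalCues:
    """Everything the environment tells a growth cone at one position:
    interpolated channel values, gradients, structure tensors, an optional
    constant drift, and the edge identifiers found in the search field."""

    position: np.ndarray
    values: dict[str, float]
    gradients: dict[str, np.ndarray]
    tensors: dict[str, np.ndarray]
    drift: np.ndarray | None = None
    occupancy_hits: frozenset = frozenset()


class EnvironmentStack:
    """Named scalar volumes plus lazily derived fields and an occupancy layer.

    Parameters
    ----------
    channels : mapping of name -> 3D array
        All channels must share one shape.
    structural : iterable of channel names
        Channels for which structure tensors are computed (guidance cues).
    sigma_grad, sigma_window : float
        Feature scales (voxels) of the gradient and the tensor window; the
        window should exceed the gradient scale to capture orientation.
    """

    def __init__(self, channels: Mapping[str, np.ndarray], *,
                 structural: Iterable[str] = (), spacing: float = 1.0,
                 sigma_grad: float = 1.0, sigma_window: float = 2.0):
        if not channels:
            raise ValueError("need at least one channel")
        self.channels: dict[str, np.ndarray] = {}
        shape = None
        for name, vol in channels.items():
            vol = np.asarray(vol, dtype=float)
            if vol.ndim != 3:
                raise ValueError(f"channel {name!r} is not 3D")
            if shape is None:
                shape = vol.shape
            elif vol.shape != shape:
                raise ValueError("all channels must share one shape")
            self.channels[name] = vol
        self.shape: tuple[int, int, int] = tuple(shape)
        self.spacing = float(spacing)
        self.structural = tuple(structural)
        self.sigma_grad = float(sigma_grad)
        self.sigma_window = float(sigma_window)
        self.occupancy = np.zeros(self.shape, dtype=np.int32)
        self._spill: dict[tuple[int, int, int], set[int]] = {}
        self._edge_keys: list = [None]  # index 0 = empty
        self._edge_index: dict = {}
        self._grad: dict[str, np.ndarray] = {}
        self._tensor: dict[str, np.ndarray] = {}

    def fresh_copy(self) -> "EnvironmentStack":
        """A new stack sharing the (read-only) channels and cached derived
        fields, but with empty occupancy — one simulation per copy."""
        out = EnvironmentStack(self.channels, structural=self.structural,
                               spacing=self.spacing,
                               sigma_grad=self.sigma_grad,
                               sigma_window=self.sigma_window)
        out._grad = dict(self._grad)
        out._tensor = dict(self._tensor)
        return out

    # -- channels and derived fields ------------------------------------

    def set_channel(self, name: str, volume: np.ndarray) -> None:
        """Replace or add a channel; cached derived fields are invalidated."""
        volume = np.asarray(volume, dtype=float)
        if volume.shape != self.shape:
            raise ValueError("channel shape mismatch")
        self.channels[name] = volume
        self._grad.pop(name, None)
        self._tensor.pop(name, None)

    def gradient(self, name: str) -> np.ndarray:
        if name not in self._grad:
            self._grad[name] = compute_gradient_field(self.channels[name],
                                                      self.sigma_grad)
        return self._grad[name]

    def structure_tensor(self, name: str) -> np.ndarray:
        if name not in self._tensor:
            self._tensor[name] = compute_structure_tensor_field(
                self.channels[name], self.sigma_grad, self.sigma_window)
        return self._tensor[name]

    # -- geometry -------------------------------------------------------

    def contains(self, position: np.ndarray) -> bool:
        p = np.asarray(position, float)
        return bool(np.all(p >= 0.0) and np.all(p <= np.array(self.shape) - 1.0))

    def containing_voxel(self, position: np.ndarray) -> tuple[int, int, int]:
        return tuple(int(v) for v in np.rint(np.asarray(position, float)))

    # -- occupancy ------------------------------------------------------

    def register_edge(self, key) -> int:
        idx = self._edge_index.get(key)
        if idx is None:
            idx = len(self._edge_keys)
            self._edge_keys.append(key)
            self._edge_index[key] = idx
        return idx

    def edge_key(self, index: int):
        return self._edge_keys[index]

    def imprint_segment(self, edge_key, p0: np.ndarray, p1: np.ndarray,
                        radius: float = DEFAULT_IMPRINT_RADIUS) -> None:
        """Label all voxels whose centers lie within ``radius`` of the segment
        (plus the containing voxels of both endpoints) with the edge id.

        Idempotent; on collision the earlier label wins and the newcomer goes
        to a spillover map so every overlapping edge stays findable.
        """
        p0 = np.asarray(p0, float)
        p1 = np.asarray(p1, float)
        if not (self.contains(p0) and self.contains(p1)):
            raise OutOfBoundsError("segment endpoint outside the volume")
        idx = self.register_edge(edge_key)
        shape = np.array(self.shape)
        lo = np.maximum(np.floor(np.minimum(p0, p1) - radius).astype(int), 0)
        hi = np.minimum(np.ceil(np.maximum(p0, p1) + radius).astype(int), shape - 1)
        axes = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        centers = np.stack([X, Y, Z], axis=-1).astype(float)
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0.0:
            dist2 = np.sum((centers - p0) ** 2, axis=-1)
        else:
            t = np.clip(((centers - p0) @ d) / L2, 0.0, 1.0)
            closest = p0 + t[..., None] * d
            dist2 = np.sum((centers - closest) ** 2, axis=-1)
        mask = dist2 <= radius * radius
        vox = np.stack([X[mask], Y[mask], Z[mask]], axis=-1)
        vox = np.concatenate([vox, [self.containing_voxel(p0),
                                    self.containing_voxel(p1)]], axis=0)
        for v in map(tuple, vox):
            cur = self.occupancy[v]
            if cur == 0:
                self.occupancy[v] = idx
            elif cur != idx:
                self._spill.setdefault(v, set()).add(idx)

    def edges_near(self, position: np.ndarray, search_field: int = 1) -> frozenset:
        """Edge keys imprinted in the ``(2*search_field + 1)^3`` voxel cube
        centered on the containing voxel of ``position``."""
        cx, cy, cz = self.containing_voxel(position)
        r = int(search_field)
        shape = self.shape
        sl = tuple(slice(max(c - r, 0), min(c + r + 1, s))
                   for c, s in zip((cx, cy, cz), shape))
        hits = set(np.unique(self.occupancy[sl]))
        hits.discard(0)
        if self._spill:
            spill = self._spill
            for x in range(sl[0].start, sl[0].stop):
                for y in range(sl[1].start, sl[1].stop):
                    for z in range(sl[2].start, sl[2].stop):
                        extra = spill.get((x, y, z))
                        if extra:
                            hits |= extra
        return frozenset(self._edge_keys[i] for i in hits)

    # -- sampling -------------------------------------------------------

    def sample_local_cues(self, position: np.ndarray, search_field: int = 1,
                          drift: np.ndarray | None = None) -> LocalCues:
        """Trilinear lookup of every channel, gradient and tensor field at a
        continuous position, plus occupancy hits from the search cube.

        Raises :class:`OutOfBoundsError` for positions outside the domain —
        the caller then marks the cone 'out of bounds'.
        """
        p = np.asarray(position, dtype=float)
        if not self.contains(p):
            raise OutOfBoundsError(f"position {p} outside volume {self.shape}")
        values = {n: float(_trilinear(v, p)) for n, v in self.channels.items()}
        gradients = {n: _trilinear(self.gradient(n), p) for n in self.channels}
        tensors = {n: assemble_tensor(_trilinear(self.structure_tensor(n), p))
                   for n in self.structural}
        hits = self.edges_near(p, search_field)
        return LocalCues(position=p, values=values, gradients=gradients,
                         tensors=tensors, drift=drift, occupancy_hits=hits)
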