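"""Growth-cone agents: the per-step event state machine and kernel-driven step.

Each growing edge has a cone at its tip. Every step the cone first decides on
at most one event — merge with a nearby edge, bifurcate, branch off a
daughter, or terminate (fixed precedence: physical contact dominates,
splitting precedes stochastic death) — and otherwise grows: the active cue
kernels are convolved, projected onto the sphere, restricted to the aperture
cone around the persistence axis, and one direction is drawn.

Merging follows the shortest-distance rule: among all candidate sample points
of nearby edges, the closest one is selected and accepted iff its squared
distance is at most ``(2 R_c)^2``. The cone's own recent trail (the last
``m + 1`` sample points it or its ancestor chain laid down, tracked across
edge splits) is excluded, so loops with *older* own trajectory remain legal
network features while instant self-merging is impossible.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentStack
from .kernels import (AngularDensity, angular_density_from_kernel, convolve,
                      draw_direction, orthonormal_frame)

logger = logging.getLogger("ramify.cones")

__all__ = [
    "ConeParameters",
    "GrowthCone",
    "EventOutcome",
    "decide_event",
    "try_merge",
    "branch_direction",
    "bifurcation_directions",
    "advance",
    "free_walk",
]

EVENTS = ("grow", "branch", "bifurcate", "merge", "terminate", "reactivate",
          "exit")
STATES = ("growing", "merged", "terminated", "out_of_bounds")


@dataclass
class ConeParameters:
    """Per-cone parameters with the field-typical defaults.

    Probabilities are per-step Bernoulli rates at the configured step length;
    rescale them when changing ``step_length``. ``aperture_deg`` is the cone
    half-angle of maximal deviation from the persistence axis per step.
    """

    aperture_deg: float = 25.0
    step_length: float = 1.0
    step_sigma: float = 0.0          # > 0: Gaussian step length truncated at 0
    theta_bran_deg: float = 75.0
    theta_bif_deg: float = 75.0
    p_bran: float = 0.02
    p_bif: float = 0.02
    p_term: float = 0.001
    p_reac: float = 0.001
    p_merge: float = 1.0             # merge acceptance given a contact
    memory: int = 5
    search_field: int = 1
    merge_radius: float = 0.5        # R_c; contact range is 2 * R_c
    merge_min_age: int = 5           # refractory steps before merging is allowed

    def __post_init__(self) -> None:
        for name in ("p_bran", "p_bif", "p_term", "p_reac", "p_merge"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not 0.0 < self.theta_bran_deg < 180.0:
            raise ValueError("branching angle must lie in (0, 180)")
        if not 0.0 < self.theta_bif_deg < 180.0:
            raise ValueError("bifurcation angle must lie in (0, 180)")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")
        if self.step_length <= 0:
            raise ValueError("step length must be positive")


@dataclass
class GrowthCone:
    """State of one growth agent."""

    cid: str
    params: ConeParameters
    rng: np.random.Generator
    positions: list = field(default_factory=list)   # full history of 3D points
    directions: list = field(default_factory=list)  # unit step directions
    state: str = "growing"
    first_node: str | None = None
    last_node: str | None = None
    edge_key: str | None = None      # currently growing edge
    age: int = 0                     # own growth steps taken
    retired: bool = False            # replaced by bifurcation daughters
    recent: deque = field(default_factory=deque)  # (edge_key, sample_idx)

    @property
    def position(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def direction(self) -> np.ndarray | None:
        return self.directions[-1] if self.directions else None

    def persistence_axis(self) -> np.ndarray | None:
        """Sum of the last ``memory`` step directions (the memory drift), or
        the last direction for memory-less cones."""
        m = self.params.memory
        if m > 0 and self.directions:
            axis = np.sum(self.directions[-m:], axis=0)
            if np.linalg.norm(axis) > 1e-12:
                return axis
        return self.directions[-1] if self.directions else None

    def remember_sample(self, edge_key: str, index: int) -> None:
        # at least the trailing two samples are always excluded from merge
        # candidates: with step length <= 2 R_c the segment just laid down is
        # unavoidably within contact range of the tip
        self.recent.append((edge_key, index))
        while len(self.recent) > max(self.params.memory, 2) + 1:
            self.recent.popleft()

    def rebase_recent(self, old_key: str, first_key: str, second_key: str,
                      offset: int) -> None:
        """Re-index remembered samples after an edge the cone walked on was
        split at sample ``offset`` into ``first_key`` / ``second_key``."""
        self.recent = deque(
            ((second_key, i - offset) if i >= offset else (first_key, i))
            if k == old_key else (k, i)
            for k, i in self.recent)


@dataclass
class EventOutcome:
    """Exactly one event per cone per step."""

    event: str
    created_cones: tuple = ()
    created_node: str | None = None
    merge_target: tuple | None = None  # (edge_key, sample_index, point)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def try_merge(cone: GrowthCone, candidates, merge_radius: float):
    """Select the candidate sample point minimizing squared distance to the
    cone, accept iff ``min <= (2 R_c)^2`` (inclusive); ties break toward the
    lowest ``(edge key, sample index)``.

    ``candidates`` is an iterable of ``(edge_key, sample_index, point)``;
    entries in the cone's recent-trail exclusion set are skipped.
    Returns the accepted candidate or ``None``.
    """
    excluded = set(cone.recent)
    pos = cone.position
    best = None
    best_d2 = np.inf
    for key, idx, point in candidates:
        if (key, idx) in excluded:
            continue
        d2 = float(np.sum((np.asarray(point, float) - pos) ** 2))
        if d2 < best_d2 - 1e-15 or (
                abs(d2 - best_d2) <= 1e-15
                and best is not None and (key, idx) < (best[0], best[1])):
            best = (key, idx, np.asarray(point, float))
            best_d2 = d2
    if best is not None and best_d2 <= (2.0 * merge_radius) ** 2:
        return best
    return None


def decide_event(cone: GrowthCone, candidates, rng: np.random.Generator,
                 allow_split: bool = True) -> EventOutcome:
    """Evaluate the per-step events in fixed precedence
    merge -> bifurcate -> branch -> terminate; at most one fires, otherwise
    the cone grows.

    Exactly four uniforms are always drawn so the consumed random stream does
    not depend on what the neighbors did (this is what makes cluster-parallel
    and serial execution bit-identical). ``candidates`` as in
    :func:`try_merge`; ``allow_split`` suppresses branching/bifurcation (e.g.
    at a cone-count cap).
    """
    u_merge, u_bif, u_bran, u_term = rng.random(4)
    p = cone.params
    if cone.age >= p.merge_min_age:
        target = try_merge(cone, candidates, p.merge_radius)
        if target is not None and u_merge < p.p_merge:
            return EventOutcome("merge", merge_target=target)
    if allow_split and u_bif < p.p_bif:
        return EventOutcome("bifurcate")
    if allow_split and u_bran < p.p_bran:
        return EventOutcome("branch")
    if u_term < p.p_term:
        return EventOutcome("terminate")
    return EventOutcome("grow")


def branch_direction(direction: np.ndarray, theta_deg: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit vector at fixed angle ``theta`` from ``direction``, azimuth
    uniform on [0, 2 pi)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    e1, e2 = orthonormal_frame(d)
    theta = np.deg2rad(theta_deg)
    psi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(theta) * d + np.sin(theta) * (np.cos(psi) * e1
                                                + np.sin(psi) * e2)


def bifurcation_directions(direction: np.ndarray, theta_deg: float,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two daughters at mutual angle ``theta`` in a uniformly random plane
    containing the mother direction, which bisects them."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    e1, e2 = orthonormal_frame(d)
    psi = rng.uniform(0.0, 2.0 * np.pi)
    n = np.cos(psi) * e1 + np.sin(psi) * e2
    half = np.deg2rad(theta_deg) / 2.0
    da = np.cos(half) * d + np.sin(half) * n
    db = np.cos(half) * d - np.sin(half) * n
    return da, db


# ---------------------------------------------------------------------------
# Growth step
# ---------------------------------------------------------------------------

def choose_direction(cone: GrowthCone, kernels, sphere: AngularDensity,
                     rng: np.random.Generator) -> np.ndarray:
    """Convolve the cue kernels, evaluate the angular density inside the
    aperture cone around the persistence axis, and draw one direction."""
    combined = convolve(kernels)
    axis = cone.persistence_axis()
    omega = cone.params.aperture_deg
    mask = None
    if axis is not None and omega < 180.0:
        nrm = np.linalg.norm(axis)
        if nrm > 1e-12:
            u = axis / nrm
            mask = sphere.directions @ u >= np.cos(np.deg2rad(omega)) - 1e-12
            if not mask.any():
                mask[int(np.argmax(sphere.directions @ u))] = True
        else:
            logger.debug("degenerate persistence axis; unrestricted draw")
    density = angular_density_from_kernel(combined, sphere, mask=mask)
    return draw_direction(density, rng)


def _draw_step_length(params: ConeParameters, rng: np.random.Generator) -> float:
    if params.step_sigma <= 0:
        return params.step_length
    for _ in range(100):  # Gaussian truncated at zero
        ell = rng.normal(params.step_length, params.step_sigma)
        if ell > 0:
            return float(ell)
    return params.step_length


def advance(cone: GrowthCone, kernels, env: EnvironmentStack | None,
            sphere: AngularDensity, rng: np.random.Generator,
            imprint_radius: float | None = None) -> str:
    """Perform one growth step: draw a direction, move, imprint.

    Returns ``'grow'`` or, if the new position would leave the volume,
    ``'exit'`` — then the position is not committed and the cone state is set
    to 'out of bounds'.
    """
    if cone.state != "growing":
        raise ValueError(f"cannot advance cone in state {cone.state!r}")
    direction = choose_direction(cone, kernels, sphere, rng)
    ell = _draw_step_length(cone.params, rng)
    new_pos = cone.position + ell * direction
    if env is not None and not env.contains(new_pos):
        cone.state = "out_of_bounds"
        return "exit"
    p_old = cone.position
    cone.positions.append(new_pos)
    cone.directions.append(direction)
    cone.age += 1
    if env is not None and cone.edge_key is not None:
        if imprint_radius is None:
            env.imprint_segment(cone.edge_key, p_old, new_pos)
        else:
            env.imprint_segment(cone.edge_key, p_old, new_pos, imprint_radius)
    return "grow"


def free_walk(params: ConeParameters, n_steps: int, rng: np.random.Generator,
              sphere: AngularDensity, cue_kernels=None,
              start_direction=None) -> np.ndarray:
    """Unconstrained walk driven purely by the kernel machinery (no
    environment, no events); used to study persistence and diffusive scaling.

    ``cue_kernels`` is a callable ``cone -> list[MGDParams]``; the default is
    a unit isotropic random-walk kernel plus the persistence drift when the
    cone has memory. Returns the (n_steps + 1, 3) position array.
    """
    from .kernels import persistence_kernel, random_walk_kernel

    if cue_kernels is None:
        def cue_kernels(c: GrowthCone):
            ks = [random_walk_kernel(1.0)]
            if c.params.memory > 0 and c.directions:
                ks.append(persistence_kernel(c.directions, c.params.memory))
            return ks

    d0 = (np.asarray(start_direction, float) if start_direction is not None
          else np.array([0.0, 0.0, 1.0]))
    cone = GrowthCone("walk", params, rng, positions=[np.zeros(3)],
                      directions=[d0 / np.linalg.norm(d0)])
    for _ in range(n_steps):
        advance(cone, cue_kernels(cone), None, sphere, rng)
    return np.asarray(cone.positions)
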