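"""Task environment: targets, rotational perturbations, and input encodings.

The simulated experiment is a centre-out reaching task: on each trial one of
``n_targets`` radially and equally spaced targets is presented, the network
produces a planar force, and the realized hand coordinate is the force passed
through a fixed rotation (a visuomotor rotation or curl force field).  During
baseline trials the rotation angle is zero; during learning trials it is
``rotation_angle``.

Two input encodings of the target direction are provided:

* ``cosine2d`` — the direction θ is encoded as the unit vector
  (cos θ, sin θ).  With this encoding the overlap of two encoded directions
  is cos(θ−θ′), the classic cosine generalization function.
* ``von_mises`` — a bank of ``n_input_units`` direction-tuned input units
  with preferred directions ξ_j equally spaced on [0, 2π) and von Mises
  tuning exp(κ·cos(θ−ξ_j)).  The encoded vector is normalized to unit
  self-overlap so that the generalization function g satisfies g(0)=1 and
  its *shape* (broad for small κ, sharp for large κ) is the only thing that
  varies between conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TaskSpec",
    "InputEncoding",
    "encode_direction",
    "generalization_function",
    "rotation_matrix",
    "rotation_operator",
    "make_target_sequence",
]


class InvalidConfigError(ValueError):
    """Raised for inconsistent task or encoding configuration."""


@dataclass(frozen=True)
class TaskSpec:
    """Centre-out task specification.

    Parameters
    ----------
    n_targets : int
        Number K of radially distributed targets; target angles are exactly
        2πk/K for k = 0..K−1.
    target_radius : float
        Length of every target vector.  Only sets the error scale; learning
        speeds are radius-free.
    rotation_angle : float
        Perturbation angle φ (radians) applied during learning trials.
    n_baseline_trials, n_learning_trials : int
        Trial counts for the two phases (100 + 100 by default).
    target_sequence_seed : int
        Seed of the pseudo-random target sequence.  All conditions that are
        compared against each other share the identical sequence.
    """

    n_targets: int = 8
    target_radius: float = 1.0
    rotation_angle: float = math.pi / 4
    n_baseline_trials: int = 100
    n_learning_trials: int = 100
    target_sequence_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise InvalidConfigError("n_targets must be >= 1")
        if self.target_radius <= 0:
            raise InvalidConfigError("target_radius must be positive")
        if self.n_baseline_trials < 0 or self.n_learning_trials < 0:
            raise InvalidConfigError("trial counts must be non-negative")
        if not math.isfinite(self.rotation_angle):
            raise InvalidConfigError("rotation_angle must be finite")

    @property
    def target_angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_targets) / self.n_targets

    def target_vector(self, k: int) -> np.ndarray:
        theta = self.target_angles[k]
        return self.target_radius * np.array([math.cos(theta), math.sin(theta)])


@dataclass(frozen=True)
class InputEncoding:
    """Input encoding of the target direction.

    ``precision`` is the von Mises concentration κ: the larger κ, the sharper
    the tuning of each input unit and the narrower the generalization
    function.  ``normalization`` caches the norm of the raw von Mises bank at
    θ=0 (informational; encoding always normalizes exactly per direction).
    """

    kind: str = "cosine2d"  # {"cosine2d", "von_mises"}
    n_input_units: int = 100
    precision: float = 1.0
    unit_preferred_dirs: np.ndarray | None = field(default=None, repr=False)
    normalization: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ("cosine2d", "von_mises"):
            raise InvalidConfigError(f"unknown encoding kind {self.kind!r}")
        if self.kind == "von_mises":
            if self.n_input_units < 1:
                raise InvalidConfigError("n_input_units must be >= 1")
            if not (self.precision > 0) or not math.isfinite(self.precision):
                raise InvalidConfigError("precision (kappa) must be positive")
            if self.unit_preferred_dirs is None:
                dirs = 2.0 * np.pi * np.arange(self.n_input_units) / self.n_input_units
                object.__setattr__(self, "unit_preferred_dirs", dirs)
            if self.normalization is None:
                raw = np.exp(self.precision * np.cos(self.unit_preferred_dirs))
                object.__setattr__(self, "normalization", float(np.linalg.norm(raw)))

    @property
    def dim(self) -> int:
        return 2 if self.kind == "cosine2d" else self.n_input_units


def encode_direction(theta: float, enc: InputEncoding) -> np.ndarray:
    """Encode direction ``theta`` as a unit-self-overlap input vector.

    Deterministic in ``(theta, enc)``.  For ``von_mises`` the raw tuning bank
    exp(κ·cos(θ−ξ_j)) is divided by its Euclidean norm so the self-overlap is
    exactly 1 for every θ (the normalization the generalization function
    requires, g(0)=1).
    """
    if not np.isfinite(theta):
        raise InvalidConfigError("theta must be finite")
    if enc.kind == "cosine2d":
        return np.array([math.cos(theta), math.sin(theta)])
    # von Mises bank; subtract kappa for overflow safety (cancels in the norm)
    log_raw = enc.precision * (np.cos(theta - enc.unit_preferred_dirs) - 1.0)
    raw = np.exp(log_raw)
    return raw / np.linalg.norm(raw)


def generalization_function(enc: InputEncoding, delta: float) -> float:
    """Overlap g(delta) of the encodings of two directions delta apart.

    g(0) = 1 by normalization.  For ``cosine2d``, g(delta) = cos(delta); for
    ``von_mises`` the overlap is evaluated at the reference direction θ=0
    (with equally spaced preferred directions it is θ-independent up to the
    granularity of the unit bank, and even in delta).
    """
    if not np.isfinite(delta):
        raise InvalidConfigError("delta must be finite")
    if enc.kind == "cosine2d":
        return float(math.cos(delta))
    x0 = encode_direction(0.0, enc)
    x1 = encode_direction(delta, enc)
    return float(x0 @ x1)


def rotation_matrix(phi: float) -> np.ndarray:
    """Proper 2×2 rotation by ``phi`` (determinant 1)."""
    if not np.isfinite(phi):
        raise InvalidConfigError("phi must be finite")
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s], [s, c]])


def rotation_operator(dim: int, phi: float, plane: np.ndarray | None = None) -> np.ndarray:
    """Rotation by ``phi`` in a 2-plane of R^dim.

    ``plane`` is a (dim, 2) matrix with orthonormal columns spanning the
    rotation plane; the identity acts on its orthogonal complement.  With
    ``dim=2`` and the default plane this is exactly :func:`rotation_matrix`.
    Used for the high-dimensional task variant, where the perturbation is a
    rotation in a random 2-plane of the output space.
    """
    if plane is None:
        plane = np.eye(dim)[:, :2]
    b1, b2 = plane[:, 0], plane[:, 1]
    c, s = math.cos(phi), math.sin(phi)
    eye = np.eye(dim)
    return (
        eye
        + (c - 1.0) * (np.outer(b1, b1) + np.outer(b2, b2))
        + s * (np.outer(b2, b1) - np.outer(b1, b2))
    )


def make_target_sequence(spec: TaskSpec) -> np.ndarray:
    """Seeded pseudo-random target-index sequence for both phases.

    Length ``n_baseline_trials + n_learning_trials``; the same spec yields an
    identical sequence, so conditions compared against each other experience
    the same target order.
    """
    n = spec.n_baseline_trials + spec.n_learning_trials
    rng = np.random.default_rng(spec.target_sequence_seed)
    return rng.integers(0, spec.n_targets, size=n)


def with_rotation(spec: TaskSpec, phi: float) -> TaskSpec:
    """Copy of ``spec`` with a different rotation angle."""
    return replace(spec, rotation_angle=phi)
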