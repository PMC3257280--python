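"""Network state and the single-trial forward pass for all model variants.

The base model is a linear rate network: input x (the encoded target
direction), activities u = W·x + activity noise, force f = D·u, and realized
hand coordinate y = R(φ)·f, where R(φ) is the rotational perturbation.
Variants: a saturating (tanh) activation, linear recurrent connections
(activities solve the linear fixed point u = W·x + K·u), and rectified
muscle units (muscles can pull but cannot push).

The squared error is E = ½‖y* − y‖²; the ½ convention keeps the gradient
free of a stray factor of 2 and only rescales the effective learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .decoders import DecoderSample
from .task import rotation_operator

__all__ = [
    "NetworkState",
    "NoiseSpec",
    "ForwardResult",
    "forward",
    "rectified_force",
    "rectified_muscle_readout",
    "saturating_activation",
    "make_state",
]


class InstabilityError(RuntimeError):
    """Recurrent weights with spectral radius >= 1: no stable fixed point."""


@dataclass(frozen=True)
class NoiseSpec:
    """Noise amplitudes: activity noise σ_u (added to u each trial),
    plasticity noise / synaptic drift σ_w (added to W each update), and the
    drift of an adaptable decoder."""

    activity_sd: float = 0.0
    plasticity_sd: float = 0.0
    decoder_plasticity_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.activity_sd, self.plasticity_sd, self.decoder_plasticity_sd) < 0:
            raise ValueError("noise standard deviations must be non-negative")


@dataclass
class NetworkState:
    """Mutable learner state: weights, decoder, and model-variant switches."""

    weights: np.ndarray
    decoder: DecoderSample
    recurrent: Optional[np.ndarray] = None
    activation: str = "linear"  # {"linear", "saturating"}
    muscle_model: str = "linear"  # {"linear", "rectified"}
    muscle_pull_dirs: Optional[np.ndarray] = None
    perturbation_plane: Optional[np.ndarray] = None  # (M, 2), for M > 2
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if not np.issubdtype(self.weights.dtype, np.floating):
            self.weights = self.weights.astype(float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if self.recurrent is not None:
            rho = max(abs(np.linalg.eigvals(self.recurrent)))
            if rho >= 1.0:
                raise InstabilityError(f"recurrent spectral radius {rho:.3f} >= 1")
        if self.muscle_model == "rectified" and (
            self.muscle_pull_dirs is None or len(self.muscle_pull_dirs) == 0
        ):
            raise ValueError("rectified muscle model requires non-empty muscle_pull_dirs")

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def rotation(self, phi: float) -> np.ndarray:
        return rotation_operator(self.decoder.n_outputs, phi, self.perturbation_plane)

    # -- snapshot I/O (plain text, one CSV per matrix) ----------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "weights.csv", self.weights, delimiter=",")
        self.decoder.to_csv(d / "decoder.csv")
        if self.recurrent is not None:
            np.savetxt(d / "recurrent.csv", self.recurrent, delimiter=",")

    @staticmethod
    def load(directory) -> "NetworkState":
        d = Path(directory)
        weights = np.atleast_2d(np.loadtxt(d / "weights.csv", delimiter=","))
        decoder = DecoderSample.from_csv(d / "decoder.csv")
        rec_path = d / "recurrent.csv"
        recurrent = np.loadtxt(rec_path, delimiter=",") if rec_path.exists() else None
        return NetworkState(weights=weights, decoder=decoder, recurrent=recurrent)


@dataclass
class ForwardResult:
    """One trial's forward pass: activities, force, hand coordinate, error."""

    activities: np.ndarray
    pre_noise_activities: np.ndarray
    force: np.ndarray
    hand: np.ndarray
    error_vector: np.ndarray
    squared_error: float
    muscle_drives: Optional[np.ndarray] = None


def saturating_activation(z: np.ndarray) -> np.ndarray:
    """Odd sigmoid with unit slope at the origin (tanh); range (−1, 1)."""
    return np.tanh(z)


def rectified_force(drives: np.ndarray, pull_dirs: np.ndarray) -> np.ndarray:
    """Net planar force of rectified muscles: Σⱼ max(0, driveⱼ)·p̂ⱼ.

    Each muscle pulls along its direction p̂ⱼ = (cos βⱼ, sin βⱼ) with the
    non-negative part of its commanded drive; negative drives produce no
    force (muscles cannot push).
    """
    pull_dirs = np.asarray(pull_dirs, dtype=float)
    if pull_dirs.size == 0:
        raise ValueError("pull_dirs must be non-empty")
    P = np.column_stack([np.cos(pull_dirs), np.sin(pull_dirs)])  # (P, 2)
    return P.T @ np.maximum(0.0, np.asarray(drives, dtype=float))


def rectified_muscle_readout(
    activities: np.ndarray, dec: DecoderSample, pull_dirs: np.ndarray
) -> np.ndarray:
    """Muscle-unit readout of the population: drives are the projections of
    the linear force D·u onto the pull directions; the net force is the
    rectified sum, normalized by P/4 so the large-P limit matches the linear
    readout (Σⱼ relu(p̂ⱼ·v)·p̂ⱼ → (P/4)·v for equally spaced directions)."""
    pull_dirs = np.asarray(pull_dirs, dtype=float)
    if pull_dirs.size == 0:
        raise ValueError("pull_dirs must be non-empty")
    linear_force = dec.matrix @ activities
    P = np.column_stack([np.cos(pull_dirs), np.sin(pull_dirs)])
    drives = P @ linear_force
    return rectified_force(drives, pull_dirs) / (len(pull_dirs) / 4.0)


def _muscle_drives(state: NetworkState, activities: np.ndarray) -> np.ndarray:
    P = np.column_stack(
        [np.cos(state.muscle_pull_dirs), np.sin(state.muscle_pull_dirs)]
    )
    return P @ (state.decoder.matrix @ activities)


def forward(
    state: NetworkState,
    x: np.ndarray,
    target: np.ndarray,
    phi: float,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> ForwardResult:
    """Run one trial: input → activities → force → rotated hand coordinate.

    Deterministic when ``noise.activity_sd`` is zero.  ``rng`` supplies the
    activity-noise draws; required only when ``activity_sd > 0``.
    """
    z = state.weights @ x
    if state.recurrent is not None:
        if state.activation != "linear":
            raise NotImplementedError("recurrent dynamics are linear-only")
        u_det = np.linalg.solve(np.eye(state.n_neurons) - state.recurrent, z)
    elif state.activation == "saturating":
        u_det = saturating_activation(z)
    else:
        u_det = z
    if noise.activity_sd > 0:
        if rng is None:
            raise ValueError("rng required when activity_sd > 0")
        u = u_det + noise.activity_sd * rng.standard_normal(u_det.shape)
    else:
        u = u_det
    drives = None
    if state.muscle_model == "rectified":
        drives = _muscle_drives(state, u)
        force = rectified_force(drives, state.muscle_pull_dirs) / (
            len(state.muscle_pull_dirs) / 4.0
        )
    else:
        force = state.decoder.matrix @ u
    hand = state.rotation(phi) @ force
    err = np.asarray(target, dtype=float) - hand
    return ForwardResult(
        activities=u,
        pre_noise_activities=u_det,
        force=force,
        hand=hand,
        error_vector=err,
        squared_error=0.5 * float(err @ err),
        muscle_drives=drives,
    )


def make_state(
    dec: DecoderSample,
    input_dim: int = 2,
    recurrent: np.ndarray | None = None,
    activation: str = "linear",
    muscle_model: str = "linear",
    n_muscles: int = 8,
    perturbation_plane: np.ndarray | None = None,
    dtype=float,
) -> NetworkState:
    """Fresh learner with zero initial weights (the pre-baseline state).

    ``dtype`` sets the weight accumulator precision; ``np.longdouble``
    pushes the numerical error floor of long noise-free runs well below the
    float64 cancellation limit (used when checking exact closed-form
    equivalence over many orders of error magnitude).
    """
    pull = None
    if muscle_model == "rectified":
        pull = 2.0 * np.pi * np.arange(n_muscles) / n_muscles
    return NetworkState(
        weights=np.zeros((dec.n_neurons, input_dim), dtype=dtype),
        decoder=dec,
        recurrent=recurrent,
        activation=activation,
        muscle_model=muscle_model,
        muscle_pull_dirs=pull,
        perturbation_plane=perturbation_plane,
    )
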