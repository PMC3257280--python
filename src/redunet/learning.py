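"""Trial-to-trial learning rules.

The reference rule is gradient descent on the squared error with synaptic
decay and drift:

    W ← (1−λ)·W + η·N·Dᵀ·R(φ)ᵀ·(y* − y)·xᵀ + σ_w·Ξ

(linear case; the chain rule runs through the activation, the recurrent
fixed point, or the rectified muscles for the other variants).  The explicit
×N factor — the decoder's ``update_gain`` — makes the per-neuron activity
change independent of N, so varying N changes redundancy, not the raw
plasticity magnitude.  For an adaptable decoder, D descends the same error
(back-propagation).  Two stochastic-gradient rules are provided in the
standard Werfel–Fiete form: weight perturbation (probe W with a Gaussian
perturbation, move opposite the error change) and node perturbation (probe
the activities instead).  Both are unbiased estimators of the gradient rule
in the small-perturbation limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    ForwardResult,
    NetworkState,
    NoiseSpec,
    forward,
    rectified_force,
)

__all__ = [
    "LearningSpec",
    "gradient_step",
    "decoder_step",
    "weight_perturbation_step",
    "node_perturbation_step",
    "trial_step",
    "error_gradient",
]


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class LearningSpec:
    """Learning-rule configuration.

    learning_rate : η, the per-trial step (0.2 by default).
    rate_scaling : "times_N" applies the decoder's update gain (the ×N of the
        planar rule); "optimal" means the caller substitutes the closed-form
        optimal rate for η before running (resolved at condition setup).
    decay : λ, multiplicative synaptic decay per trial, in [0, 1).
    decoder_rate : η_D for an adaptable decoder (0 ⇒ decoder fixed; 0.1 and
        0.05 are the values used by the adaptable-decoder and high-dimensional
        experiments respectively).
    recurrent_rate : gradient rate on recurrent weights (0 ⇒ fixed).
    rule : {"gradient", "weight_perturbation", "node_perturbation"}.
    perturbation_sd : σ_p of the stochastic-rule probes.
    """

    learning_rate: float = 0.2
    rate_scaling: str = "times_N"
    decay: float = 0.0
    decoder_rate: float = 0.0
    recurrent_rate: float = 0.0
    rule: str = "gradient"
    perturbation_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidSpecError("learning_rate must be positive")
        if not 0.0 <= self.decay < 1.0:
            raise InvalidSpecError("decay must be in [0, 1)")
        if self.rule not in ("gradient", "weight_perturbation", "node_perturbation"):
            raise InvalidSpecError(f"unknown rule {self.rule!r}")
        if self.rule != "gradient" and self.perturbation_sd <= 0:
            raise InvalidSpecError("perturbation_sd must be positive for stochastic rules")
        if self.rate_scaling not in ("times_N", "optimal"):
            raise InvalidSpecError(f"unknown rate_scaling {self.rate_scaling!r}")


def _backprop_to_z(state: NetworkState, fwd: ForwardResult, phi: float) -> np.ndarray:
    """Descent direction dE/dz (negated), z being the pre-activation W·x."""
    g_f = state.rotation(phi).T @ fwd.error_vector
    if state.muscle_model == "rectified":
        P = np.column_stack(
            [np.cos(state.muscle_pull_dirs), np.sin(state.muscle_pull_dirs)]
        )
        # subgradient convention: count a muscle at exactly zero drive as
        # active, so learning can leave the all-zero start
        active = (fwd.muscle_drives >= 0).astype(float)
        g_u = state.decoder.matrix.T @ (P.T @ (active * (P @ g_f)))
        g_u /= len(state.muscle_pull_dirs) / 4.0
    else:
        g_u = state.decoder.matrix.T @ g_f
    if state.recurrent is not None:
        return np.linalg.solve(np.eye(state.n_neurons) - state.recurrent.T, g_u)
    if state.activation == "saturating":
        return (1.0 - fwd.pre_noise_activities**2) * g_u
    return g_u


def error_gradient(state: NetworkState, fwd: ForwardResult, x: np.ndarray, phi: float) -> np.ndarray:
    """dE/dW for the current trial (before any gain or learning rate)."""
    return -np.outer(_backprop_to_z(state, fwd, phi), x)


def _gain(state: NetworkState, spec: LearningSpec) -> float:
    return state.decoder.update_gain if spec.rate_scaling in ("times_N", "optimal") else 1.0


def _decay_and_drift(
    state: NetworkState, spec: LearningSpec, noise: NoiseSpec, rng: np.random.Generator | None
) -> None:
    if spec.decay > 0:
        state.weights *= 1.0 - spec.decay
    if noise.plasticity_sd > 0:
        if rng is None:
            raise ValueError("rng required when plasticity_sd > 0")
        state.weights += noise.plasticity_sd * rng.standard_normal(state.weights.shape)


def gradient_step(
    state: NetworkState,
    fwd: ForwardResult,
    x: np.ndarray,
    phi: float,
    spec: LearningSpec,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """One gradient-descent update of W (decay first, then gradient, then
    drift); increments the trial index and returns the mutated state."""
    g_z = _backprop_to_z(state, fwd, phi)
    delta = spec.learning_rate * _gain(state, spec) * np.outer(g_z, x)
    if spec.decay > 0:
        state.weights *= 1.0 - spec.decay
    state.weights += delta
    if noise.plasticity_sd > 0:
        if rng is None:
            raise ValueError("rng required when plasticity_sd > 0")
        state.weights += noise.plasticity_sd * rng.standard_normal(state.weights.shape)
    state.trial_index += 1
    return state


def decoder_step(
    state: NetworkState,
    fwd: ForwardResult,
    phi: float,
    spec: LearningSpec,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Back-propagation update of an adaptable decoder:

        D ← D + η_D·R(φ)ᵀ·(y* − y)·uᵀ/N + η_D·σ_D·Ξ

    Must be applied with the forward result that the same trial's W update
    used, so both updates see the pre-update decoder.
    """
    if spec.decoder_rate <= 0:
        raise InvalidSpecError("decoder_step called but decoder_rate is 0 (fixed decoder)")
    e = fwd.error_vector
    u = fwd.activities
    delta = spec.decoder_rate * np.outer(state.rotation(phi).T @ e, u) / state.n_neurons
    if noise.decoder_plasticity_sd > 0:
        if rng is None:
            raise ValueError("rng required when decoder_plasticity_sd > 0")
        delta = delta + spec.decoder_rate * noise.decoder_plasticity_sd * rng.standard_normal(
            state.decoder.matrix.shape
        )
    state.decoder.set_matrix(state.decoder.matrix + delta)
    return state


def _recurrent_step(
    state: NetworkState, fwd: ForwardResult, phi: float, spec: LearningSpec
) -> None:
    """Gradient update of recurrent weights through the linear fixed point,
    with spectral-radius clipping at 0.95 to preserve solvability."""
    g_u = state.decoder.matrix.T @ (state.rotation(phi).T @ fwd.error_vector)
    g_u = np.linalg.solve(np.eye(state.n_neurons) - state.recurrent.T, g_u)
    K = state.recurrent + spec.recurrent_rate * np.outer(g_u, fwd.pre_noise_activities)
    rho = max(abs(np.linalg.eigvals(K)))
    if rho >= 0.95:
        K *= 0.95 / rho
    state.recurrent = K


def weight_perturbation_step(
    state: NetworkState,
    x: np.ndarray,
    target: np.ndarray,
    phi: float,
    spec: LearningSpec,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> ForwardResult:
    """Weight-perturbation trial: probe W with Gaussian Ψ (sd σ_p), compare
    the perturbed error E⁺ with the unperturbed E, and update

        W ← W − η·N·((E⁺ − E)/σ_p²)·Ψ   (+ decay and drift).

    Returns the unperturbed forward result (the trial's recorded error).
    """
    fwd = forward(state, x, target, phi, noise, rng)
    psi = spec.perturbation_sd * rng.standard_normal(state.weights.shape)
    probe = NetworkState(
        weights=state.weights + psi,
        decoder=state.decoder,
        recurrent=state.recurrent,
        activation=state.activation,
        muscle_model=state.muscle_model,
        muscle_pull_dirs=state.muscle_pull_dirs,
        perturbation_plane=state.perturbation_plane,
    )
    fwd_plus = forward(probe, x, target, phi, noise, rng)
    coeff = (
        spec.learning_rate
        * _gain(state, spec)
        * (fwd_plus.squared_error - fwd.squared_error)
        / spec.perturbation_sd**2
    )
    if spec.decay > 0:
        state.weights *= 1.0 - spec.decay
    state.weights -= coeff * psi
    if noise.plasticity_sd > 0:
        state.weights += noise.plasticity_sd * rng.standard_normal(state.weights.shape)
    state.trial_index += 1
    return fwd


def node_perturbation_step(
    state: NetworkState,
    x: np.ndarray,
    target: np.ndarray,
    phi: float,
    spec: LearningSpec,
    noise: NoiseSpec,
    rng: np.random.Generator,
) -> ForwardResult:
    """Node-perturbation trial: probe the activities u with Gaussian ψ and
    update W ← W − η·N·((E⁺ − E)/σ_p²)·ψ·xᵀ (+ decay and drift)."""
    fwd = forward(state, x, target, phi, noise, rng)
    psi = spec.perturbation_sd * rng.standard_normal(state.n_neurons)
    u_pert = fwd.activities + psi
    if state.muscle_model == "rectified":
        P = np.column_stack(
            [np.cos(state.muscle_pull_dirs), np.sin(state.muscle_pull_dirs)]
        )
        drives = P @ (state.decoder.matrix @ u_pert)
        force = rectified_force(drives, state.muscle_pull_dirs) / (
            len(state.muscle_pull_dirs) / 4.0
        )
    else:
        force = state.decoder.matrix @ u_pert
    err = np.asarray(target, float) - state.rotation(phi) @ force
    e_plus = 0.5 * float(err @ err)
    coeff = (
        spec.learning_rate
        * _gain(state, spec)
        * (e_plus - fwd.squared_error)
        / spec.perturbation_sd**2
    )
    if spec.decay > 0:
        state.weights *= 1.0 - spec.decay
    state.weights -= coeff * np.outer(psi, x)
    if noise.plasticity_sd > 0:
        state.weights += noise.plasticity_sd * rng.standard_normal(state.weights.shape)
    state.trial_index += 1
    return fwd


def trial_step(
    state: NetworkState,
    x: np.ndarray,
    target: np.ndarray,
    phi: float,
    spec: LearningSpec,
    noise: NoiseSpec,
    rng: np.random.Generator | None = None,
) -> ForwardResult:
    """Run one complete trial under ``spec.rule`` and return the trial's
    (unperturbed, pre-update) forward result."""
    if spec.rule == "weight_perturbation":
        return weight_perturbation_step(state, x, target, phi, spec, noise, rng)
    if spec.rule == "node_perturbation":
        return node_perturbation_step(state, x, target, phi, spec, noise, rng)
    fwd = forward(state, x, target, phi, noise, rng)
    if state.recurrent is not None and spec.recurrent_rate > 0:
        _recurrent_step(state, fwd, phi, spec)
    gradient_step(state, fwd, x, phi, spec, noise, rng)
    if spec.decoder_rate > 0:
        decoder_step(state, fwd, phi, spec, noise, rng)
    return fwd
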