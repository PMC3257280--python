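"""Closed-form learning-dynamics analysis.

For the noise-free linear model with a fixed decoder and a single repeated
target, the error obeys the linear recursion

    e_{t+1} = (I − η·Ã)·e_t,      Ã = R(φ)·A·R(φ)ᵀ,

so in the eigenbasis of Ã each error mode contracts by (1 − η·λ_k) per trial
and the squared-error curve is

    E_t = ½·Σ_k (1 − η·λ_k)^{2t} · ẽ_{0,k}².

Learning speed is governed by the smallest eigenvalue of A (the slowest
mode).  For planar outputs trace(A) is fixed (1 for the homogeneous
decoder), so λ_min ≤ trace/2 with equality iff A is isotropic — which holds
in the large-N limit of any sampling distribution with isotropic second
moments.  This module exposes the analytic curve, the speed bound, the
optimal learning rate, the residual-error fixed point under synaptic decay
and drift, and the generalization-weighted motor-command update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .decoders import DecoderSample, build_A, eigensystem_2x2
from .task import InputEncoding, TaskSpec, generalization_function, rotation_matrix

__all__ = [
    "TheoryResult",
    "analytic_curve",
    "learning_speed_bound",
    "optimal_learning_rate",
    "modal_learning_speed",
    "residual_error_with_decay",
    "command_update_prediction",
    "multi_target_speed_check",
    "analyze_decoder",
]


class NoLearningError(ValueError):
    """All eigenvalues are zero: no error mode is corrected."""


class DivergenceError(RuntimeError):
    """Contraction factors outside the unit circle: dynamics diverge."""


@dataclass
class TheoryResult:
    """Analysis of one decoder sample at one learning rate."""

    A: np.ndarray
    eigenvalues: np.ndarray
    contraction_factors: np.ndarray
    predicted_curve: np.ndarray
    optimal_rate: float
    learning_speed: float
    residual_error: float

    def as_row(self) -> dict:
        return {
            "lambda_max": self.eigenvalues[0],
            "lambda_min": self.eigenvalues[-1],
            "speed": self.learning_speed,
            "optimal_rate": self.optimal_rate,
            "residual_error": self.residual_error,
        }


def analytic_curve(
    A: np.ndarray, eta: float, initial_error_vector: np.ndarray, n_trials: int
) -> np.ndarray:
    """Noise-free squared-error curve E_t, t = 0..n_trials−1.

    ``A`` is the operator acting on the error (pass R·A·Rᵀ if the initial
    error is expressed in hand coordinates under a rotation).  E_0 equals
    ½‖e_0‖² and each eigen-component contracts by (1−η·λ_k)² per trial.
    """
    A = np.asarray(A, dtype=float)
    lam, V = np.linalg.eigh(A)
    e0 = V.T @ np.asarray(initial_error_vector, dtype=float)
    t = np.arange(n_trials)
    factors = (1.0 - eta * lam) ** 2
    return 0.5 * (e0**2 @ np.power.outer(factors, t))


def learning_speed_bound(dec: DecoderSample, tol: float = 1e-6) -> tuple[float, bool]:
    """(λ_min, is_maximal) for a planar decoder sample.

    λ_min is the smaller eigenvalue of A; it is bounded by trace(A)/2 (= ½
    for unit-norm force vectors) and attains the bound iff A is isotropic —
    the self-averaging condition.
    """
    A = build_A(dec)
    lam, _ = eigensystem_2x2(A)
    lam_min = float(lam[-1])
    return lam_min, bool(abs(lam_min - 0.5 * np.trace(A)) < tol)


def optimal_learning_rate(eigenvalues: np.ndarray, tol: float = 1e-12) -> float:
    """η* minimizing the worst-mode contraction max_k (1 − η·λ_k)².

    Closed form 2/(λ_min⁺ + λ_max) over the positive eigenvalues (1/λ for a
    single positive mode); zero modes cannot be improved by any η.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    pos = lam[lam > tol]
    if pos.size == 0:
        raise NoLearningError("no positive eigenvalues: learning cannot proceed")
    return float(2.0 / (pos.min() + pos.max()))


def modal_learning_speed(eigenvalues: np.ndarray, eta: float) -> float:
    """Slowest-mode exponential rate of the squared error,
    s = −2·ln(max_k |1 − η·λ_k|); the exponent a single-exponential fit to
    the noise-free curve approaches."""
    worst = float(np.max(np.abs(1.0 - eta * np.asarray(eigenvalues, dtype=float))))
    if worst >= 1.0:
        return 0.0
    if worst == 0.0:
        return math.inf
    return -2.0 * math.log(worst)


def residual_error_with_decay(
    A: np.ndarray,
    eta: float,
    decay: float,
    drift_sd: float,
    target: np.ndarray,
    phi: float = 0.0,
    n_neurons: int | None = None,
) -> float:
    """Asymptotic mean squared error under synaptic decay and drift.

    With decay λ the error recursion gains a restoring term toward the
    unlearned state: e_{t+1} = ((1−λ)I − η·Ã)·e_t + λ·y*, whose fixed point
    is ē = λ·(λI + η·Ã)⁻¹·y*.  Synaptic drift adds zero-mean output noise
    with per-trial covariance σ_w²·R·(A/N)·Rᵀ, whose stationary covariance Σ
    solves the discrete Lyapunov equation Σ = MΣMᵀ + C.  The asymptotic
    error is ½(‖ē‖² + tr Σ); decay and drift contribute additively (cross
    terms vanish in expectation).
    """
    A = np.asarray(A, dtype=float)
    dim = A.shape[0]
    if dim == 2:
        R = rotation_matrix(phi)
        A_tilde = R @ A @ R.T
    else:
        A_tilde = A
    M = (1.0 - decay) * np.eye(dim) - eta * A_tilde
    if np.max(np.abs(np.linalg.eigvals(M))) >= 1.0:
        raise DivergenceError("unstable configuration: |(1−λ)I − ηÃ| has modes ≥ 1")
    y_star = np.asarray(target, dtype=float)
    e_bar = decay * np.linalg.solve(decay * np.eye(dim) + eta * A_tilde, y_star)
    var_term = 0.0
    if drift_sd > 0:
        if n_neurons is None:
            raise ValueError("n_neurons required when drift_sd > 0")
        C = drift_sd**2 * A_tilde / n_neurons
        sigma = solve_discrete_lyapunov(M, C)
        var_term = float(np.trace(sigma))
    return 0.5 * (float(e_bar @ e_bar) + var_term)


def command_update_prediction(
    A: np.ndarray,
    enc: InputEncoding,
    theta_trained: float,
    theta_probe: float,
    eta: float,
    error_vector: np.ndarray,
    phi: float,
) -> np.ndarray:
    """Predicted single-trial change of the motor command at a probe
    direction after one update at the trained direction:

        Δy(θ_probe) = η·g(θ_trained − θ_probe)·R·A·Rᵀ·e.

    The generalization function g — the overlap of the two input encodings —
    is the only place the encoding enters: the update to the command
    transfers across directions exactly as much as the inputs overlap.
    """
    g = generalization_function(enc, theta_trained - theta_probe)
    R = rotation_matrix(phi)
    return eta * g * (R @ np.asarray(A, float) @ R.T) @ np.asarray(error_vector, float)


def multi_target_speed_check(dec: DecoderSample, task: TaskSpec, eta: float) -> bool:
    """Check the alignment condition that extends the single-target analysis
    to rotating through multiple targets: along a simulated noise-free run
    the error must stay aligned with its own update (eᵀ·Ã·e ≥ 0 whenever the
    error is non-negligible) and the total error must decrease.
    """
    from .experiments import Condition, run_repetition  # deferred: avoids cycle

    A = build_A(dec)
    R = rotation_matrix(task.rotation_angle)
    A_tilde = R @ A @ R.T
    cond = Condition(label="check", n_neurons=dec.n_neurons, task=task)
    curve = run_repetition(cond, repetition_seed=dec.seed, decoder=dec, return_errors=True)
    e0_sq = curve.errors[0]
    aligned = True
    for e_vec in curve.error_vectors:
        if 0.5 * e_vec @ e_vec > 1e-12 * max(e0_sq, 1.0):
            if float(e_vec @ A_tilde @ e_vec) < 0:
                aligned = False
    decreased = curve.errors[-1] <= curve.errors[0] + 1e-12
    return bool(aligned and decreased)


def analyze_decoder(
    dec: DecoderSample,
    eta: float = 0.2,
    initial_error_vector: np.ndarray | None = None,
    n_trials: int = 100,
    decay: float = 0.0,
    drift_sd: float = 0.0,
    phi: float = math.pi / 4,
    target: np.ndarray | None = None,
) -> TheoryResult:
    """Full closed-form analysis of one decoder at one operating point."""
    A = build_A(dec)
    lam = np.sort(np.linalg.eigvalsh(A))[::-1]
    if target is None:
        target = np.array([1.0, 0.0]) if A.shape[0] == 2 else np.eye(A.shape[0])[0]
    if initial_error_vector is None:
        if A.shape[0] == 2:
            R = rotation_matrix(phi)
            initial_error_vector = (np.eye(2) - R) @ target
        else:
            initial_error_vector = target
    if A.shape[0] == 2:
        R = rotation_matrix(phi)
        curve = analytic_curve(R @ A @ R.T, eta, initial_error_vector, n_trials)
    else:
        curve = analytic_curve(A, eta, initial_error_vector, n_trials)
    residual = 0.0
    if decay > 0 or drift_sd > 0:
        residual = residual_error_with_decay(
            A, eta, decay, drift_sd, target, phi=phi, n_neurons=dec.n_neurons
        )
    return TheoryResult(
        A=A,
        eigenvalues=lam,
        contraction_factors=np.abs(1.0 - eta * lam),
        predicted_curve=curve,
        optimal_rate=optimal_learning_rate(lam),
        learning_speed=modal_learning_speed(lam, eta),
        residual_error=residual,
    )
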