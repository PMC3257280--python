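"""Experiment orchestration: protocols, repetitions, sweeps, statistics.

The canonical protocol mirrors a visuomotor-rotation adaptation session:
100 baseline trials with no perturbation (the network learns to reach the
targets), then 100 learning trials under the rotation.  The recorded
learning curve is the per-trial squared error of the learning phase only.
A repetition draws a fresh decoder sample; all conditions being compared
share the identical target sequence and the identical list of repetition
seeds (paired design, matching the paired sign-rank statistics).

Learning speed is the exponent s of an exponential a·exp(−s·t) + c fitted
to a learning curve.  Curve variance — the across-repetition variance of
the error at each trial, averaged over trials — measures the stability of
learning under activity and plasticity noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .decoders import (
    DecoderDistribution,
    DecoderSample,
    sample_decoder,
    tuning_summary,
)
from .learning import LearningSpec, trial_step
from .network import NoiseSpec, make_state
from .task import InputEncoding, TaskSpec, encode_direction, make_target_sequence

__all__ = [
    "Condition",
    "ExperimentPlan",
    "LearningCurve",
    "SpeedFit",
    "run_repetition",
    "run_condition",
    "stream_averaged_speed",
    "fit_speed",
    "curve_variance",
    "redundancy_sweep",
    "redundancy_vs_tasks_sweep",
    "compare_conditions",
    "count_circular_modes",
    "baseline_tuning",
]

_DIVERGENCE_FACTOR = 1e6


@dataclass(frozen=True)
class Condition:
    """One experimental condition: network size, decoder family, rule, task."""

    label: str
    n_neurons: int
    decoder_dist: DecoderDistribution = field(default_factory=DecoderDistribution.uniform)
    learning: LearningSpec = field(default_factory=LearningSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    encoding: InputEncoding = field(default_factory=InputEncoding)
    task: TaskSpec = field(default_factory=TaskSpec)
    n_tasks: Optional[int] = None  # output dimension T of the high-dim variant
    recurrent_radius: float = 0.0
    activation: str = "linear"
    muscle_model: str = "linear"


@dataclass(frozen=True)
class ExperimentPlan:
    """A set of conditions run with shared target sequence and paired seeds."""

    conditions: tuple
    n_repetitions: int = 1000
    shared_target_seed: int = 0
    base_rng_seed: int = 0

    def repetition_seeds(self) -> list[int]:
        root = np.random.SeedSequence(self.base_rng_seed)
        return [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(self.n_repetitions)]


@dataclass
class LearningCurve:
    """Per-trial squared errors of the learning phase of one repetition."""

    errors: np.ndarray
    condition_label: str
    repetition_seed: int
    diverged: bool = False
    error_vectors: Optional[list] = None
    baseline_errors: Optional[np.ndarray] = None
    baseline_weights: Optional[np.ndarray] = None


@dataclass
class SpeedFit:
    """Exponential fit a·exp(−s·t) + c to a learning curve."""

    speed: float
    amplitude: float
    offset: float
    fit_residual: float
    converged: bool


def _repetition_rngs(
    repetition_seed: int, noise_stream: int = 0
) -> tuple[int, np.random.Generator, np.random.Generator]:
    """Decoder seed plus independent noise / setup RNG streams."""
    decoder_seed = int(repetition_seed) % 2**31
    noise_rng = np.random.default_rng(
        np.random.SeedSequence((repetition_seed, 9157, noise_stream))
    )
    setup_rng = np.random.default_rng(np.random.SeedSequence((repetition_seed, 311)))
    return decoder_seed, noise_rng, setup_rng


def _make_recurrent(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    K = rng.standard_normal((n, n)) / math.sqrt(n)
    rho = max(abs(np.linalg.eigvals(K)))
    return K * (radius / rho)


def _run_highdim(
    cond: Condition,
    repetition_seed: int,
    decoder: Optional[DecoderSample],
    return_errors: bool,
    keep_state: bool,
    noise_stream: int = 0,
) -> LearningCurve:
    """High-dimensional-task protocol: T output dimensions, a single fixed
    unit input, and a rotation in a seeded random 2-plane of the output
    space as the perturbation."""
    task = cond.task
    decoder_seed, noise_rng, setup_rng = _repetition_rngs(repetition_seed, noise_stream)
    T = cond.n_tasks
    dec = decoder or sample_decoder(DecoderDistribution.highdim(T), cond.n_neurons, decoder_seed)
    target = setup_rng.standard_normal(T)
    target *= task.target_radius / np.linalg.norm(target)
    x = setup_rng.standard_normal(2)
    x /= np.linalg.norm(x)
    if T == 2:
        plane = np.eye(2)
    else:
        plane, _ = np.linalg.qr(setup_rng.standard_normal((T, 2)))
    state = make_state(dec, input_dim=2, perturbation_plane=plane)
    spec, noise = cond.learning, cond.noise
    baseline_errors = np.empty(task.n_baseline_trials)
    for t in range(task.n_baseline_trials):
        fwd = trial_step(state, x, target, 0.0, spec, noise, noise_rng)
        baseline_errors[t] = fwd.squared_error
    errors = np.empty(task.n_learning_trials)
    vectors = [] if return_errors else None
    diverged = False
    for t in range(task.n_learning_trials):
        fwd = trial_step(state, x, target, task.rotation_angle, spec, noise, noise_rng)
        errors[t] = fwd.squared_error
        if return_errors:
            vectors.append(fwd.error_vector)
        if not np.isfinite(errors[t]) or errors[t] > _DIVERGENCE_FACTOR * max(errors[0], 1e-12):
            diverged = True
    return LearningCurve(
        errors=errors,
        condition_label=cond.label,
        repetition_seed=repetition_seed,
        diverged=diverged,
        error_vectors=vectors,
        baseline_errors=baseline_errors,
        baseline_weights=state.weights.copy() if keep_state else None,
    )


def run_repetition(
    cond: Condition,
    repetition_seed: int,
    decoder: Optional[DecoderSample] = None,
    return_errors: bool = False,
    keep_state: bool = False,
    dtype=float,
    noise_stream: int = 0,
) -> LearningCurve:
    """One repetition: fresh decoder, baseline phase (φ=0), learning phase
    (φ=rotation_angle); returns the learning-phase curve.

    Curves whose error exceeds 10⁶× the initial learning-phase error are
    flagged ``diverged`` (and excluded from speed averages downstream).
    ``keep_state`` stores a copy of the post-baseline weights, from which
    preferred directions and modulation depths are read.
    """
    if cond.n_tasks is not None:
        return _run_highdim(
            cond, repetition_seed, decoder, return_errors, keep_state, noise_stream
        )
    task, enc = cond.task, cond.encoding
    decoder_seed, noise_rng, setup_rng = _repetition_rngs(repetition_seed, noise_stream)
    dec = decoder or sample_decoder(cond.decoder_dist, cond.n_neurons, decoder_seed)
    recurrent = None
    if cond.recurrent_radius > 0:
        recurrent = _make_recurrent(cond.n_neurons, cond.recurrent_radius, setup_rng)
    state = make_state(
        dec,
        input_dim=enc.dim,
        recurrent=recurrent,
        activation=cond.activation,
        muscle_model=cond.muscle_model,
        dtype=dtype,
    )
    seq = make_target_sequence(task)
    inputs = [encode_direction(theta, enc) for theta in task.target_angles]
    targets = [task.target_vector(k) for k in range(task.n_targets)]
    spec, noise = cond.learning, cond.noise
    n_base = task.n_baseline_trials
    baseline_errors = np.empty(n_base)
    for t in range(n_base):
        k = seq[t]
        fwd = trial_step(state, inputs[k], targets[k], 0.0, spec, noise, noise_rng)
        baseline_errors[t] = fwd.squared_error
    baseline_weights = state.weights.copy() if keep_state else None
    errors = np.empty(task.n_learning_trials)
    vectors = [] if return_errors else None
    diverged = False
    for t in range(task.n_learning_trials):
        k = seq[n_base + t]
        fwd = trial_step(
            state, inputs[k], targets[k], task.rotation_angle, spec, noise, noise_rng
        )
        errors[t] = fwd.squared_error
        if return_errors:
            vectors.append(fwd.error_vector)
        if not np.isfinite(errors[t]) or errors[t] > _DIVERGENCE_FACTOR * max(errors[0], 1e-12):
            diverged = True
    return LearningCurve(
        errors=errors,
        condition_label=cond.label,
        repetition_seed=repetition_seed,
        diverged=diverged,
        error_vectors=vectors,
        baseline_errors=baseline_errors,
        baseline_weights=baseline_weights,
    )


def _exp_model(t, a, s, c):
    return a * np.exp(-s * t) + c


def fit_speed(curve) -> SpeedFit:
    """Least-squares exponential fit a·exp(−s·t) + c with a, s, c ≥ 0.

    Multi-start over decay-rate initializations; a non-decreasing (or
    constant) curve yields s = 0 with ``converged=True``.
    """
    errors = curve.errors if isinstance(curve, LearningCurve) else np.asarray(curve, float)
    if errors.size < 10:
        raise ValueError("need at least 10 trials to fit a speed")
    t = np.arange(errors.size, dtype=float)
    e0, e_end = errors[0], float(np.mean(errors[-max(3, errors.size // 10) :]))
    if not np.all(np.isfinite(errors)):
        return SpeedFit(math.nan, math.nan, math.nan, math.inf, False)
    if e0 <= e_end or np.ptp(errors) < 1e-300:
        resid = float(np.sum((errors - errors.mean()) ** 2))
        return SpeedFit(0.0, 0.0, float(errors.mean()), resid, True)
    best = None
    scale = max(e0 - e_end, 1e-300)
    for s0 in (0.01, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0):
        try:
            popt, _ = optimize.curve_fit(
                _exp_model,
                t,
                errors,
                p0=[scale, s0, max(e_end, 1e-300)],
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum((_exp_model(t, *popt) - errors) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return SpeedFit(math.nan, math.nan, math.nan, math.inf, False)
    (a, s, c), resid = best
    return SpeedFit(float(s), float(a), float(c), resid, True)


def curve_variance(curves: Sequence[LearningCurve]) -> float:
    """Across-repetition variance of the per-trial error (unbiased, ddof=1),
    averaged over the learning trials."""
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    errs = np.array([c.errors for c in curves])
    if errs.ndim != 2:
        raise ValueError("curves must have equal length")
    return float(np.var(errs, axis=0, ddof=1).mean())


def stream_averaged_speed(
    cond: Condition, repetition_seed: int, n_streams: int = 12
) -> SpeedFit:
    """Speed of one decoder sample under a stochastic rule, fitted to the
    curve averaged over ``n_streams`` independent perturbation streams.

    Conditional Monte Carlo: the decoder (the quantity whose effect on speed
    is under study) is held fixed while the rule's own stochasticity is
    averaged out, which isolates the redundancy effect from estimator noise.
    """
    dec = sample_decoder(cond.decoder_dist, cond.n_neurons, int(repetition_seed) % 2**31)
    curves = [
        run_repetition(cond, repetition_seed, decoder=dec, noise_stream=m).errors
        for m in range(n_streams)
    ]
    return fit_speed(np.mean(curves, axis=0))


def run_condition(
    cond: Condition,
    n_repetitions: int,
    rep_seeds: Optional[Sequence[int]] = None,
    collect_curves: bool = False,
) -> dict:
    """Run repetitions of one condition; fitted speeds with divergent curves
    excluded (NaN) and counted."""
    if rep_seeds is None:
        rep_seeds = list(range(n_repetitions))
    speeds = np.full(len(rep_seeds), np.nan)
    curves = []
    n_excluded = 0
    for i, seed in enumerate(rep_seeds):
        curve = run_repetition(cond, seed)
        if collect_curves:
            curves.append(curve)
        if curve.diverged:
            n_excluded += 1
            continue
        fit = fit_speed(curve)
        if fit.converged:
            speeds[i] = fit.speed
        else:
            n_excluded += 1
    out = {"label": cond.label, "speeds": speeds, "n_excluded": n_excluded}
    if collect_curves:
        out["curves"] = curves
    return out


def compare_conditions(speeds_a: np.ndarray, speeds_b: np.ndarray) -> dict:
    """Paired Wilcoxon signed-rank comparison of two speed samples.

    Pairs with NaN in either sample are dropped; identical samples give
    p = 1 and zero effect.  ``direction`` is the sign of median(b − a).
    """
    a = np.asarray(speeds_a, float)
    b = np.asarray(speeds_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    diff = b - a
    if np.all(diff == 0):
        return {"statistic": 0.0, "p_value": 1.0, "direction": 0, "n": int(a.size)}
    res = stats.wilcoxon(a, b)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "direction": int(np.sign(np.median(diff))),
        "n": int(a.size),
    }


def _summary_table(results: list[dict], extra_cols: Optional[dict] = None) -> pd.DataFrame:
    rows = []
    for res in results:
        speeds = res["speeds"]
        ok = np.isfinite(speeds)
        row = {
            "label": res["label"],
            "n_reps": int(speeds.size),
            "mean_speed": float(np.mean(speeds[ok])) if ok.any() else math.nan,
            "sd_speed": float(np.std(speeds[ok], ddof=1)) if ok.sum() > 1 else math.nan,
            "n_excluded": res["n_excluded"],
        }
        if extra_cols:
            row.update({k: v[len(rows)] for k, v in extra_cols.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def redundancy_sweep(
    n_list: Sequence[int] = (10, 50, 100, 1000),
    n_repetitions: int = 200,
    base_seed: int = 0,
    decoder_dist: Optional[DecoderDistribution] = None,
    learning: Optional[LearningSpec] = None,
    noise: Optional[NoiseSpec] = None,
    encoding: Optional[InputEncoding] = None,
    task: Optional[TaskSpec] = None,
    collect_curves: bool = False,
    **cond_kwargs,
) -> dict:
    """Fitted learning speed versus the number of neurons N.

    Returns a summary table (mean ± sd speed per N), the raw paired speed
    samples, and a power-law fit speed_gain ≈ a·N^b of the speed relative to
    the smallest N.
    """
    decoder_dist = decoder_dist or DecoderDistribution.uniform()
    learning = learning or LearningSpec()
    noise = noise or NoiseSpec()
    encoding = encoding or InputEncoding()
    task = task or TaskSpec()
    plan = ExperimentPlan(
        conditions=tuple(
            Condition(
                label=f"N={n}",
                n_neurons=n,
                decoder_dist=decoder_dist,
                learning=learning,
                noise=noise,
                encoding=encoding,
                task=task,
                **cond_kwargs,
            )
            for n in n_list
        ),
        n_repetitions=n_repetitions,
        base_rng_seed=base_seed,
    )
    seeds = plan.repetition_seeds()
    results = [
        run_condition(c, n_repetitions, seeds, collect_curves=collect_curves)
        for c in plan.conditions
    ]
    table = _summary_table(results)
    table.insert(1, "n_neurons", list(n_list))
    out = {
        "table": table,
        "speeds": {res["label"]: res["speeds"] for res in results},
        "rep_seeds": seeds,
    }
    if len(n_list) >= 2:
        means = table["mean_speed"].to_numpy()
        gains = means / means[0]
        log_n = np.log(np.asarray(n_list, float))
        slope, intercept = np.polyfit(log_n, np.log(np.maximum(gains, 1e-300)), 1)
        out["power_law"] = {"prefactor": float(np.exp(intercept)), "exponent": float(slope)}
    if collect_curves:
        out["curves"] = {res["label"]: res["curves"] for res in results}
    return out


def redundancy_vs_tasks_sweep(
    n_list: Sequence[int] = (20, 200),
    t_list: Sequence[int] = (2, 10),
    n_repetitions: int = 200,
    base_seed: int = 0,
    learning: Optional[LearningSpec] = None,
    noise: Optional[NoiseSpec] = None,
    task: Optional[TaskSpec] = None,
) -> dict:
    """Fitted speed over the (N, T) grid of the high-dimensional variant.

    T is the output dimension (number of constrained tasks); the decoder is
    the Gaussian/√N family, so redundancy is the gap between N and T.
    """
    learning = learning or LearningSpec()
    noise = noise or NoiseSpec()
    task = task or TaskSpec(n_targets=1)
    conditions, pairs = [], []
    for n in n_list:
        for t_dim in t_list:
            if t_dim > n:
                continue
            conditions.append(
                Condition(
                    label=f"N={n},T={t_dim}",
                    n_neurons=n,
                    learning=learning,
                    noise=noise,
                    task=task,
                    n_tasks=t_dim,
                )
            )
            pairs.append((n, t_dim))
    plan = ExperimentPlan(
        conditions=tuple(conditions), n_repetitions=n_repetitions, base_rng_seed=base_seed
    )
    seeds = plan.repetition_seeds()
    results = [run_condition(c, n_repetitions, seeds) for c in conditions]
    table = _summary_table(results)
    table.insert(1, "n_neurons", [p[0] for p in pairs])
    table.insert(2, "n_tasks", [p[1] for p in pairs])
    return {
        "table": table,
        "speeds": {res["label"]: res["speeds"] for res in results},
        "rep_seeds": seeds,
    }


def count_circular_modes(
    angles: np.ndarray, n_bins: int = 36, min_contrast: float = 1.5
) -> list[float]:
    """Mode centres of a circular sample, from a smoothed histogram.

    The smoothed circular histogram is thresholded halfway between its
    minimum and maximum; each contiguous above-threshold segment counts as
    one mode (circular-mean centre).  If the overall contrast max/min is
    below ``min_contrast`` the sample is treated as uniform (no modes).
    Robust to both sharp peaks and broad plateau-shaped modes in
    preferred-direction histograms.
    """
    angles = np.mod(np.asarray(angles, float), 2 * np.pi)
    counts, edges = np.histogram(angles, bins=n_bins, range=(0.0, 2 * np.pi))
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kernel /= kernel.sum()
    padded = np.concatenate([counts[-2:], counts, counts[:2]])
    smooth = np.convolve(padded, kernel, mode="valid")
    lo, hi = smooth.min(), smooth.max()
    if hi < min_contrast * max(lo, 1e-300):
        return []
    above = smooth > 0.5 * (lo + hi)
    if above.all():
        return []
    centres = 0.5 * (edges[:-1] + edges[1:])
    # rotate so the scan starts in a below-threshold bin, then walk segments
    start = int(np.argmin(above))
    modes = []
    segment: list[int] = []
    for off in range(1, n_bins + 1):
        i = (start + off) % n_bins
        if above[i]:
            segment.append(i)
        elif segment:
            z = np.exp(1j * centres[segment]) @ smooth[segment]
            modes.append(float(np.mod(np.angle(z), 2 * np.pi)))
            segment = []
    if segment:
        z = np.exp(1j * centres[segment]) @ smooth[segment]
        modes.append(float(np.mod(np.angle(z), 2 * np.pi)))
    return sorted(modes)


def baseline_tuning(cond: Condition, rep_seeds: Sequence[int]) -> dict:
    """Pooled preferred directions and modulation depths of the
    post-baseline network over several repetitions."""
    pds, depths = [], []
    for seed in rep_seeds:
        curve = run_repetition(cond, seed, keep_state=True)
        summary = tuning_summary(curve.baseline_weights)
        pds.append(summary.preferred_dirs)
        depths.append(summary.modulation_depths)
    return {
        "preferred_dirs": np.concatenate(pds),
        "modulation_depths": np.concatenate(depths),
    }
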