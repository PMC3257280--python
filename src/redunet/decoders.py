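"""Decoder sampling, the learning operator A, and neuron tuning summaries.

Each of the N neurons contributes a force vector (its decoder column): a
direction (FD) and an amplitude (FA).  The decoder matrix D maps neural
activities to output force.  Four sampling families are supported:

* ``homogeneous_uniform`` — unit amplitude, direction uniform on [0, 2π);
  the Rokni-style homogeneous decoder.
* ``gaussian_unimodal`` — planar Gaussian force vectors (one mode).
* ``gaussian_bimodal`` — two-component planar Gaussian mixture (bimodal
  force-direction distribution).
* ``gaussian_highdim`` — i.i.d. Gaussian T×N decoder divided by √N, for the
  high-dimensional task variant where the output dimension T is varied.

Scaling convention: the planar families divide the raw force vectors by N so
that the learning operator A = (1/N)·Σ d̂ᵢd̂ᵢᵀ — whose eigenvalues set the
per-mode error contraction — does not explicitly depend on N.  The high-dim
family divides by √N, making A = DDᵀ a Wishart-type matrix whose smallest
eigenvalue approaches (1−√(T/N))²: the gap between N and T, i.e. the
redundancy, governs learning speed.

Learning speed is maximal exactly when A is isotropic (all eigenvalues equal
to trace/2 for planar outputs), which holds in the N→∞ limit whenever the
sampling distribution has equal marginal second moments and zero cross
moment — the self-averaging property.  The empirical deviation from that
condition for a finite sample is :func:`self_averaging_residual`, which
shrinks as N^(−1/2) (Monte-Carlo fluctuation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DecoderDistribution",
    "DecoderSample",
    "TuningSummary",
    "sample_decoder",
    "build_A",
    "eigensystem_2x2",
    "self_averaging_residual",
    "tuning_summary",
]

_FAMILIES = (
    "homogeneous_uniform",
    "gaussian_unimodal",
    "gaussian_bimodal",
    "gaussian_highdim",
    "custom",
)


class InvalidDistributionError(ValueError):
    pass


def _check_cov(cov: np.ndarray, name: str) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
        raise InvalidDistributionError(f"{name} must be a symmetric 2x2 matrix")
    if np.linalg.eigvalsh(cov)[0] <= 0:
        raise InvalidDistributionError(f"{name} must be positive-definite")
    return cov


@dataclass(frozen=True)
class DecoderDistribution:
    """A force-vector sampling distribution (family + parameters).

    Planar families are rescaled at sampling time so that E[‖d̂‖²] equals
    ``target_trace`` (default 1, matching the homogeneous family); the trace
    of A sets the effective behavioural learning rate and keeping it common
    makes speeds comparable across families.
    """

    family: str = "homogeneous_uniform"
    params: dict = field(default_factory=dict)
    target_trace: Optional[float] = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidDistributionError(f"unknown family {self.family!r}")
        if self.family == "gaussian_unimodal":
            _check_cov(self.params.get("cov", np.eye(2)), "cov")
        if self.family == "gaussian_bimodal":
            _check_cov(self.params.get("cov1", np.eye(2)), "cov1")
            _check_cov(self.params.get("cov2", np.eye(2)), "cov2")
            w = self.params.get("weight", 0.5)
            if not 0.0 < w < 1.0:
                raise InvalidDistributionError("mixture weight must be in (0, 1)")

    # -- constructors -------------------------------------------------------
    @staticmethod
    def uniform() -> "DecoderDistribution":
        """Homogeneous decoder: unit FA, uniform FD."""
        return DecoderDistribution("homogeneous_uniform", {}, target_trace=None)

    @staticmethod
    def unimodal(mean=(0.0, 0.0), cov=None, target_trace: float | None = 1.0) -> "DecoderDistribution":
        """Unimodal planar Gaussian.  The zero-mean isotropic default gives a
        uniform preferred-direction distribution and satisfies the
        self-averaging (isotropy) conditions exactly."""
        cov = np.eye(2) if cov is None else np.asarray(cov, float)
        return DecoderDistribution(
            "gaussian_unimodal", {"mean": np.asarray(mean, float), "cov": cov}, target_trace
        )

    @staticmethod
    def bimodal(
        mean1=(3.0, 0.0),
        mean2=(-3.0, 0.0),
        cov1=None,
        cov2=None,
        weight: float = 0.5,
        target_trace: float | None = 1.0,
    ) -> "DecoderDistribution":
        """Bimodal planar Gaussian mixture.

        The default places antipodal modes at ±(3, 0) with covariance
        diag(1, 10) = cI − μμᵀ (c = 10).  This choice makes the mixture's
        second moments exactly isotropic (E[a²] = E[b²] = 10, E[ab] = 0), so
        the self-averaging conditions hold while the force-direction
        histogram remains clearly bimodal at 0 and π — a skewed-bimodal PD
        distribution with maximal learning speed, as required for the
        distribution-independence experiment.
        """
        if cov1 is None:
            cov1 = np.diag([1.0, 10.0])
        if cov2 is None:
            cov2 = np.diag([1.0, 10.0])
        return DecoderDistribution(
            "gaussian_bimodal",
            {
                "mean1": np.asarray(mean1, float),
                "mean2": np.asarray(mean2, float),
                "cov1": np.asarray(cov1, float),
                "cov2": np.asarray(cov2, float),
                "weight": weight,
            },
            target_trace,
        )

    @staticmethod
    def highdim(n_outputs: int) -> "DecoderDistribution":
        """i.i.d. Gaussian decoder with ``n_outputs`` output dimensions."""
        if n_outputs < 1:
            raise InvalidDistributionError("n_outputs must be >= 1")
        return DecoderDistribution("gaussian_highdim", {"n_outputs": n_outputs}, target_trace=None)

    # -- moments ------------------------------------------------------------
    def second_moment(self) -> np.ndarray:
        """E[d̂ d̂ᵀ] of the *unscaled* distribution (planar families)."""
        if self.family == "homogeneous_uniform":
            return 0.5 * np.eye(2)
        if self.family == "gaussian_unimodal":
            m, c = self.params["mean"], self.params["cov"]
            return np.outer(m, m) + c
        if self.family == "gaussian_bimodal":
            w = self.params["weight"]
            m1, m2 = self.params["mean1"], self.params["mean2"]
            c1, c2 = self.params["cov1"], self.params["cov2"]
            return w * (np.outer(m1, m1) + c1) + (1 - w) * (np.outer(m2, m2) + c2)
        if self.family == "gaussian_highdim":
            return np.eye(self.params["n_outputs"])
        raise InvalidDistributionError("second_moment undefined for custom family")

    def sampling_scale(self) -> float:
        """Factor applied to raw samples so E[‖d̂‖²] = target_trace."""
        if self.target_trace is None:
            return 1.0
        tr = float(np.trace(self.second_moment()))
        return math.sqrt(self.target_trace / tr)


class DecoderSample:
    """A concrete decoder: N raw force vectors plus the scaled matrix D.

    ``raw_vectors`` has shape (N, M); ``matrix`` is D = raw.T / N for planar
    families and raw.T / √N for the high-dimensional family.  ``update_gain``
    is the factor multiplying the gradient so that the output-space update is
    η·A·e in both conventions (the explicit ×N of the planar learning rule).
    """

    def __init__(self, raw_vectors: np.ndarray, family: str, family_params: dict, seed: int):
        raw = np.asarray(raw_vectors, dtype=float)
        if raw.ndim != 2:
            raise InvalidDistributionError("raw_vectors must be 2-D (N, M)")
        self.raw_vectors = raw
        self.family = family
        self.family_params = family_params
        self.seed = seed
        self.n_neurons = raw.shape[0]
        self.n_outputs = raw.shape[1]
        if family == "gaussian_highdim":
            self._scale = 1.0 / math.sqrt(self.n_neurons)
        else:
            self._scale = 1.0 / self.n_neurons
        self.matrix = raw.T * self._scale

    @property
    def update_gain(self) -> float:
        # planar: gain N makes N·DDᵀ = A; high-dim: DDᵀ is already A
        return self.n_neurons if self._scale == 1.0 / self.n_neurons else 1.0

    def copy(self) -> "DecoderSample":
        return DecoderSample(self.raw_vectors.copy(), self.family, self.family_params, self.seed)

    def set_matrix(self, matrix: np.ndarray) -> None:
        """Overwrite D (adaptable-decoder learning), keeping raw in sync."""
        self.matrix = np.asarray(matrix, dtype=float)
        self.raw_vectors = self.matrix.T / self._scale

    # -- fixture I/O --------------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(
            self.raw_vectors, columns=[f"raw_{i}" for i in range(self.n_outputs)]
        )
        df.insert(0, "neuron", np.arange(self.n_neurons))
        df["family"] = self.family
        df["seed"] = self.seed
        df.to_csv(path_or_buf, index=False)

    @staticmethod
    def from_csv(path_or_buf) -> "DecoderSample":
        df = pd.read_csv(path_or_buf)
        raw_cols = [c for c in df.columns if c.startswith("raw_")]
        return DecoderSample(
            df[raw_cols].to_numpy(float), str(df["family"].iloc[0]), {}, int(df["seed"].iloc[0])
        )


@dataclass
class TuningSummary:
    """Preferred directions (angles in [−π, π)) and modulation depths."""

    preferred_dirs: np.ndarray
    modulation_depths: np.ndarray


def sample_decoder(dist: DecoderDistribution, n_neurons: int, seed: int) -> DecoderSample:
    """Draw a decoder of ``n_neurons`` force vectors; reproducible from seed."""
    if n_neurons < 1:
        raise InvalidDistributionError("n_neurons must be >= 1")
    rng = np.random.default_rng(seed)
    if dist.family == "homogeneous_uniform":
        psi = rng.uniform(0.0, 2.0 * np.pi, size=n_neurons)
        raw = np.column_stack([np.cos(psi), np.sin(psi)])
    elif dist.family == "gaussian_unimodal":
        raw = rng.multivariate_normal(
            dist.params["mean"], dist.params["cov"], size=n_neurons, method="cholesky"
        )
        raw *= dist.sampling_scale()
    elif dist.family == "gaussian_bimodal":
        pick = rng.random(n_neurons) < dist.params["weight"]
        raw = np.empty((n_neurons, 2))
        n1 = int(pick.sum())
        if n1:
            raw[pick] = rng.multivariate_normal(
                dist.params["mean1"], dist.params["cov1"], size=n1, method="cholesky"
            )
        if n_neurons - n1:
            raw[~pick] = rng.multivariate_normal(
                dist.params["mean2"], dist.params["cov2"], size=n_neurons - n1, method="cholesky"
            )
        raw *= dist.sampling_scale()
    elif dist.family == "gaussian_highdim":
        raw = rng.standard_normal((n_neurons, dist.params["n_outputs"]))
    else:
        raise InvalidDistributionError("cannot sample the custom family")
    return DecoderSample(raw, dist.family, dict(dist.params), seed)


def build_A(dec: DecoderSample) -> np.ndarray:
    """Learning operator A = (1/N)·Σᵢ d̂ᵢ d̂ᵢᵀ (symmetric PSD, M×M)."""
    return dec.raw_vectors.T @ dec.raw_vectors / dec.n_neurons


def eigensystem_2x2(A: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigen-decomposition of a symmetric 2×2 matrix.

    Returns eigenvalues sorted descending and the orthonormal eigenvectors as
    columns of a 2×2 matrix, so A = V·diag(λ)·Vᵀ.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (2, 2) or abs(A[0, 1] - A[1, 0]) > tol:
        raise ValueError("A must be symmetric 2x2")
    a, b, c = A[0, 0], A[0, 1], A[1, 1]
    half_tr = 0.5 * (a + c)
    disc = math.hypot(0.5 * (a - c), b)
    lam1, lam2 = half_tr + disc, half_tr - disc
    if disc < 1e-300:  # multiple of the identity
        return np.array([lam1, lam2]), np.eye(2)
    # eigenvector of lam1: (A - lam2 I) column with larger norm
    v1 = np.array([a - lam2, b])
    alt = np.array([b, c - lam2])
    if np.linalg.norm(alt) > np.linalg.norm(v1):
        v1 = alt
    v1 = v1 / np.linalg.norm(v1)
    v2 = np.array([-v1[1], v1[0]])
    return np.array([lam1, lam2]), np.column_stack([v1, v2])


def self_averaging_residual(dec: DecoderSample) -> float:
    """Empirical deviation of the sampled force vectors from isotropy.

    For the homogeneous family this is max(|mean cos²ψ − ½|, |mean sin²ψ − ½|,
    |mean sin ψ cos ψ|); for the other planar families the analogous deviation
    of the per-neuron second-moment matrix from (trace/2)·I.  It is zero iff
    the empirical self-averaging conditions hold exactly, and its typical size
    decays as N^(−1/2).
    """
    if dec.n_outputs != 2:
        raise ValueError("self_averaging_residual requires 2 output dimensions")
    S = build_A(dec)
    half_tr = 0.5 * (S[0, 0] + S[1, 1])
    return float(max(abs(S[0, 0] - half_tr), abs(S[1, 1] - half_tr), abs(S[0, 1])))


def tuning_summary(weights: np.ndarray) -> TuningSummary:
    """PD and modulation depth of each neuron from its input-weight row.

    Under cosine (2-D) input encoding a neuron with weight row w has activity
    w·(cos θ, sin θ) = ‖w‖·cos(θ − PD): PD is the planar angle of w and the
    modulation depth is ‖w‖.
    """
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[1] != 2:
        raise ValueError("tuning_summary requires an N x 2 weight matrix (cosine2d encoding)")
    pd_angles = np.arctan2(W[:, 1], W[:, 0])
    pd_angles = np.where(pd_angles >= np.pi, pd_angles - 2 * np.pi, pd_angles)
    depths = np.linalg.norm(W, axis=1)
    return TuningSummary(preferred_dirs=pd_angles, modulation_depths=depths)
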