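# Methods

## Model

The learner is a linear rate network adapting over discrete trials.  On a
trial with target direction θ_k the input is the encoded direction
**x**(θ_k); hidden activities are **u** = W**x** + σ_u ξ (ξ i.i.d. standard
normal); the output force is **f** = D**u**; and the realized hand
coordinate is **y** = R(φ)**f**.  Movements are reduced to their endpoint:
there are no within-trial dynamics, delays, or trajectories.  The
perturbation is always a rotation, standing in for either a visuomotor
rotation or a curl force field.  A session is 100 baseline trials (φ = 0)
followed by 100 learning trials (φ = 45° by default); the learning curve is
the per-trial squared error E = ½‖**y*** − **y**‖² of the learning phase.

Weights follow gradient descent with decay and drift,

    W ← (1 − λ)W + η·N·Dᵀ R(φ)ᵀ (y* − y) xᵀ + σ_w Ξ.

The explicit ×N factor (the decoder's `update_gain`) cancels the 1/N
decoder scaling so that the *per-neuron* activity change at a given error
is independent of N: changing N changes redundancy, not the raw amount of
plasticity.  The ½ in the error definition is a convention that absorbs
the gradient's factor of 2; it only rescales the effective learning rate.

### Learning operator and the redundancy argument

For a fixed decoder and a single repeated target the error obeys
e_{t+1} = (I − ηÃ)e_t with Ã = R A Rᵀ and A = (1/N)Σ d̂ᵢd̂ᵢᵀ, giving the
closed-form curve E_t = ½Σ_k (1−ηλ_k)^{2t} ẽ²_{0,k}.  Unit-amplitude force
vectors fix trace(A) = 1, so λ_min ≤ ½ with equality iff A = ½I.  A is a
Monte-Carlo average of outer products: whenever the sampling distribution
has equal marginal second moments and zero cross moment, A → (trace/2)·I
with fluctuations of order N^(−1/2).  Redundancy (large N at fixed output
dimension) is therefore necessary and sufficient for maximal learning
speed.  `self_averaging_residual` measures the finite-sample deviation
max(|A₁₁−tr/2|, |A₂₂−tr/2|, |A₁₂|); the package verifies the N^(−1/2)
median scaling empirically.

"Learning speed" has two operational definitions that agree in the
noise-free limit: the theory module's modal rate −2·ln(max_k|1−ηλ_k|), and
the experiments module's exponent s of a least-squares fit of
a·exp(−s·t)+c (a, s, c ≥ 0, multi-start initialization) to a simulated
curve.  With interleaved targets the fitted exponent mixes modes and is
smaller than the single-target modal rate; all cross-condition comparisons
therefore use the same protocol on both sides.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| η (learning_rate) | 0.2 | per-trial gradient step; quasi-optimal for the near-isotropic operator (η* = 2/(λ₁+λ₂) ≈ 2 rescaled by the error convention), and the redundancy ranking is η-independent |
| K (n_targets) | 8 | standard centre-out target count (radially, equally spaced) |
| φ (rotation_angle) | π/4 | typical adaptation-experiment rotation magnitude |
| target_radius | 1 | sets the error scale only; speeds are radius-free (0.3 in the saturating-activation experiment, see below) |
| trials | 100 + 100 | baseline + learning phase (300 learning trials in the generalization experiment, see below) |
| λ (decay) | 0 | multiplicative synaptic decay per trial; λ > 0 produces a residual error floor |
| σ_u, σ_w | 0 | activity and plasticity (drift) noise SDs; noise experiments use 0.1 and 0.02 |
| η_D (decoder_rate) | 0 | adaptable-decoder (backprop) rate; 0.1 in the adaptable-decoder experiment, 0.05 in the dimensionality experiment |
| σ_p (perturbation_sd) | 0.01 | probe SD of the weight/node-perturbation rules; the gradient estimate is unbiased to O(σ_p²) |
| κ (precision) | free | von Mises input sharpness; broad/narrow experiment uses 2 / 20 |
| M_in (n_input_units) | 100 | von Mises bank size |
| repetitions | 1000 nominal | experiments default to 1000; shipped tests and the acceptance script run 50–200 repetitions, which give adequate power for every ordering tested while keeping runs at desk scale |

## Decoder families (the synthetic-data generator)

The generator produces the only "data" in this study: random decoders,
target sequences, and noise streams.  Families:

* **homogeneous_uniform** — unit force amplitude, direction uniform on
  [0, 2π); trace(A) = 1 exactly.
* **gaussian_unimodal** — planar Gaussian force vectors; the default is
  zero-mean isotropic, which satisfies the self-averaging conditions
  exactly and yields a uniform preferred-direction (PD) histogram with a
  right-skewed (Rayleigh) amplitude distribution.
* **gaussian_bimodal** — two antipodal Gaussian modes at ±(3, 0) with
  covariance diag(1, 10).  The covariance is c·I − μμᵀ (c = 10), the
  unique antipodal-mixture shape whose second moments are isotropic
  (E[a²] = E[b²], E[ab] = 0); the PD histogram is skewed-bimodal at 0/π
  while learning speed remains maximal.  A two-mode mixture with isotropic
  *covariance* cannot satisfy these conditions (its second-moment matrix
  is μμᵀ + Σ, anisotropic for any μ ≠ 0), which is why the covariance must
  be elongated orthogonally to the mode axis.
* **gaussian_highdim** — i.i.d. Gaussian T×N decoder divided by √N for the
  task-dimensionality experiment; A = DDᵀ is Wishart-type with
  λ_min ≈ (1−√(T/N))², so the N−T gap, not N itself, sets the speed.

Planar Gaussian families are rescaled at sampling time so E[‖d̂‖²] = 1,
matching the homogeneous trace; the absolute trace is a behavioural
calibration constant outside this package's scope, and a common trace keeps
η = 0.2 stable and speeds comparable across families.

PDs and modulation depths are read from the post-baseline weight rows
(angle and norm): under cosine encoding, gradient learning from zero
weights drives each row along its neuron's force-vector image, so the
weight-based and decoder-based definitions coincide in the noise-free
limit.

What the generator does **not** emulate: real motor-cortex firing
statistics (spiking, rates ≥ 0, Fano factors), electrode-sampling biases
in PD surveys, trial-to-trial target-direction autocorrelations, or any
fitted correspondence to recorded data.  Passing tests show the *model's*
claims are reproduced, not that cortex implements this model.

## Experiment protocols

All conditions compared against each other share an identical seeded
target sequence and an identical list of repetition seeds (each repetition
draws a fresh decoder).  Paired comparisons use the Wilcoxon signed-rank
test.  Curves whose error exceeds 10⁶× the initial learning-phase error
are flagged divergent, excluded from speed averages, and counted.

* **Redundancy sweep** — N ∈ {10, 50, 100, 1000}; mean ± sd fitted speed,
  power-law fit of the speed gain versus N.
* **Distribution independence** — unimodal vs bimodal families at matched
  N and paired seeds; PD-histogram modes counted on a smoothed circular
  histogram thresholded halfway between its extremes (plateau-robust), a
  sample with max/min contrast < 1.5 counting as uniform.
* **Task dimensionality** — grid (N, T) ∈ {20, 200} × {2, 10}; a single
  fixed unit input, a T-dimensional unit target, and a 45° rotation in a
  seeded random 2-plane of the output space as the perturbation.
  Significance is asserted for the two designed contrasts (T-ordering at
  N = 20, N-ordering at T = 10); the T-contrast at N = 200 is small
  because the least-squares fit weights early trials, where the
  N-independent trace dominates, and is checked directionally.
* **Noise robustness** — across-repetition variance of the per-trial error
  (unbiased estimator, averaged over trials) under σ_u = 0.1 or
  σ_w = 0.02.  Both noise sources enter the output through D, whose 1/N
  scaling averages them out: the variance ratio N=10 : N=1000 is ≈ 100.
* **Generalization shape** — von Mises inputs, broad κ = 2 vs narrow
  κ = 20, with a 300-trial learning phase.  Two deliberate choices here.
  First, κ = 2: for κ ≲ 1 the encodings of all directions become nearly
  collinear, the rotation-error pattern couples only to the first circular
  harmonic of g (which vanishes as g flattens), and "broader is faster"
  inverts — the measured speed is proportional to that harmonic, maximal
  near κ ≈ 3.  κ = 2 is broad while remaining in the regime of the claim.
  Second, 300 trials: per-trial progress under direction-specific transfer
  is ~2–4× slower than under cosine inputs, and within 100 trials the slow
  error mode (the one carrying the N-dependence) is not yet expressed.
* **Learning rules** — weight and node perturbation in the standard
  single-probe form; the update uses the same ×N gain as the gradient
  rule, without which speed would scale as 1/N and no rule-independent
  redundancy effect could exist.  Because the single-probe gradient
  estimate injects per-trial output noise of order η·‖e‖ (comparable to
  the contraction signal), per-repetition fitted speeds are dominated by
  estimator noise; the rule experiments therefore fit the curve averaged
  over 12 independent perturbation streams of the *same* decoder
  (conditional Monte Carlo), isolating the decoder-driven speed the claim
  is about.
* **Decay residual** — asymptotic error from the fixed point
  ē = λ(λI + ηÃ)⁻¹y* plus the stationary drift covariance from the
  discrete Lyapunov equation Σ = MΣMᵀ + σ_w²Ã/N, validated against
  5000-trial simulated tails.  The monotone residual-vs-λ_min comparison
  averages over the eight target directions, since the single-target
  residual also depends on eigenvector alignment; with trace fixed the
  direction-averaged residual is strictly decreasing in λ_min.

## Model variants

* **Saturating activation** — elementwise tanh (odd, unit slope at 0),
  applied before activity noise.  The bounded activities cap the
  producible force at ‖f‖ ≲ 2/π for the unit decoder, so this variant's
  experiments use target_radius = 0.3 to keep the task feasible.
* **Rectified muscles** — 2P antagonist muscles with equally spaced pull
  directions; each muscle's drive is the projection of the linear force
  onto its pull direction, its activation is the drive's positive part,
  and the net force is normalized by P/4 so the many-muscle limit matches
  the linear readout.  The gradient uses the subgradient-1-at-0 convention
  so learning can leave the all-zero initial state.
* **Recurrent connections** — activities solve the linear fixed point
  u = Wx + Ku in one linear solve (spectral radius of K < 1 enforced);
  an optional gradient rule on K backpropagates through the fixed point
  and clips the spectral radius at 0.95.  This is a reconstruction of the
  recurrent variant, not a claim about any particular published
  implementation.
* **Adaptable decoder** — D descends the same error,
  D ← D + η_D Rᵀ(y*−y)uᵀ/N (+ η_D-scaled drift), applied after the same
  trial's W update so both see the pre-update decoder.

## Numerical choices

* Zero initial weights; the baseline phase reaches the pre-perturbation
  solution (with 8 targets the baseline residual after 100 trials is
  ~10⁻⁵ of the initial error; tests that require exact convergence extend
  the baseline).
* von Mises encodings are normalized per direction (divide by the current
  bank norm), making the self-overlap exactly 1 for every θ; a single
  precomputed constant cannot achieve this at large κ, where the bank's
  summed overlap varies visibly around the unit grid.  g is evaluated at
  the reference direction 0 and is even by grid symmetry.
* The closed-form-equivalence check runs the simulator with extended
  precision (`dtype=np.longdouble`): after the error has decayed ten
  orders of magnitude, float64 weight-accumulator rounding leaves a
  relative gap of ~10⁻¹⁰ between simulation and theory; with longdouble
  accumulators the comparison sits at ~10⁻¹³, reflecting the mathematics
  rather than the floating-point floor.
* The 2×2 eigensolver is the closed-form quadratic with the
  better-conditioned eigenvector column chosen explicitly; the isotropic
  case short-circuits to the identity basis.
* `fit_speed` multi-starts the exponential fit over seven decay-rate
  initializations and returns the least-SSE solution; non-decreasing
  curves return s = 0 as a converged fit.
* Repetition seeds come from `numpy.random.SeedSequence` spawning, with
  separate child streams for decoder sampling, noise, and condition setup,
  so runs are bitwise reproducible and conditions are paired by
  construction.

## Limitations

* The theory is exact only for the linear, fixed-decoder, single-target,
  noise-free case; all other claims are simulation-backed orderings.
* The adaptable-decoder dynamics have no closed-form speed; that variant
  is simulation-only.
* Stochastic-rule speeds are meaningful only after stream averaging at
  the shipped repetition counts; raw per-repetition fits under weight or
  node perturbation are estimator-noise-dominated.
* The absolute error and speed scales are conventional (unit trace, unit
  radius, the ½ error convention); only comparisons across conditions are
  interpretable, not absolute magnitudes.
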