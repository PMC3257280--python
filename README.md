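# redunet

Why does the motor cortex employ vastly more neurons than it has muscles to
drive?  `redunet` is a simulator and closed-form theory for one proposed
answer: **neuronal redundancy maximizes learning speed**.  It models
trial-by-trial motor adaptation (visuomotor rotation or curl force field) in
a linear rate network whose N neurons drive M = 2 outputs through a decoder
of force vectors, and shows — analytically and by simulation — that the
speed of error reduction reaches its maximum if and only if N is large
enough for the sampled force vectors to self-average.

The package is aimed at computational-neuroscience researchers who want to
regenerate, stress-test, or extend this result from configuration files at
desk scale: every experiment is seeded, runs in seconds-to-minutes, and is
exposed both as a Python API and a CLI.

## The model

On trial *t* with target direction θ, the network receives the encoded
input **x**(θ) (a unit cosine pair, or a normalized von Mises tuning bank),
produces activities **u** = W_t **x** + σ_u ξ, a force **f** = D **u**, and
a hand coordinate **y** = R(φ) **f**, where R(φ) is the rotational
perturbation (φ = 0 during baseline).  Weights descend the squared error
E = ½‖**y*** − **y**‖²:

    W_{t+1} = (1 − λ) W_t + η N Dᵀ R(φ)ᵀ (y* − y) xᵀ + σ_w Ξ

with learning rate η = 0.2, synaptic decay λ, and drift σ_w.  For a fixed
decoder and a single target the error obeys e_{t+1} = (I − η Ã) e_t with
Ã = R A Rᵀ and the **learning operator**

    A = (1/N) Σ_i d̂_i d̂_iᵀ,

so the squared error is a sum of modes contracting as (1 − η λ_k)² per
trial.  Because trace(A) = 1 for unit force vectors, the slowest mode obeys
λ_min ≤ ½, with equality exactly when A is isotropic — which the
Monte-Carlo fluctuation argument makes an N → ∞ property: the gap to the
bound shrinks as N^(−1/2).  Hence redundancy (N ≫ M), and nothing else,
maximizes learning speed; the package verifies that the conclusion survives
non-uniform decoder distributions, an adaptable (backprop) decoder,
recurrent connections, tanh activations, rectified ("pull-only") muscles,
weight/node-perturbation learning, activity/plasticity noise, higher task
dimensionalities, and different generalization-function shapes.

## Worked example

```python
from redunet import (DecoderDistribution, sample_decoder, analyze_decoder,
                     redundancy_sweep)

dec = sample_decoder(DecoderDistribution.uniform(), n_neurons=1000, seed=1)
res = analyze_decoder(dec, eta=0.2)
print(f"lambda_min = {res.eigenvalues[-1]:.4f}  (bound 0.5)")
print(f"modal speed = {res.learning_speed:.4f}   optimal eta = {res.optimal_rate:.3f}")

sweep = redundancy_sweep(n_list=(10, 100, 1000), n_repetitions=50, base_seed=0)
print(sweep["table"][["n_neurons", "mean_speed", "sd_speed"]].to_string(index=False))
```

prints

```
lambda_min = 0.4770  (bound 0.5)
modal speed = 0.2005   optimal eta = 2.000
 n_neurons  mean_speed  sd_speed
        10    0.092430  0.005464
       100    0.098054  0.001063
      1000    0.098746  0.000255
```

At N = 1000 the sampled operator is nearly isotropic (λ_min = 0.477 against
the bound ½), so the single-target error contracts at the near-maximal
modal rate −2 ln(1 − 0.2 λ_min) ≈ 0.20 per trial, and one step of the
optimal rate η* = 2/(λ₁+λ₂) ≈ 2 would cancel the error almost entirely.
The sweep fits a·exp(−s·t)+c to each 100-trial adaptation curve (8
interleaved targets, 45° rotation): mean speed rises with N and saturates —
the gain from 100 → 1000 neurons is a fraction of the gain from 10 → 100 —
while the across-sample spread collapses, because with more neurons a
random decoder is almost surely near-isotropic.

The same experiments are available from a shell, e.g.

```bash
redunet sweep-redundancy --n 10 --n 100 --n 1000 --reps 200 --outdir out/
redunet sweep-tasks --n 20 --n 200 --t 2 --t 10 --reps 200 --outdir out/
redunet theory-report --outdir out/
```

each writing CSV tables plus a JSON manifest of the configuration and seeds.

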