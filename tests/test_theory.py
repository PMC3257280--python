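"""Closed-form learning-curve theory against simulation and oracles."""

import numpy as np
import pytest

from redunet import (
    Condition,
    DecoderDistribution,
    InputEncoding,
    LearningSpec,
    NoiseSpec,
    TaskSpec,
    analytic_curve,
    analyze_decoder,
    build_A,
    command_update_prediction,
    forward,
    learning_speed_bound,
    make_state,
    modal_learning_speed,
    multi_target_speed_check,
    optimal_learning_rate,
    residual_error_with_decay,
    rotation_matrix,
    run_repetition,
    sample_decoder,
    trial_step,
)
from redunet.decoders import DecoderSample
from redunet.theory import DivergenceError, NoLearningError

QUIET = NoiseSpec()


class TestAnalyticCurve:
    def test_zero_rate_constant(self):
        curve = analytic_curve(0.5 * np.eye(2), 0.0, np.array([1.0, 0.0]), 10)
        assert np.allclose(curve, 0.5)

    def test_isotropic_hand_evaluated(self):
        """A = ½I, η = 0.2: every mode contracts by 0.9 per trial, so
        E_t = 0.81^t · E₀ with E₀ = ½."""
        e0 = np.array([1.0, 0.0])
        curve = analytic_curve(0.5 * np.eye(2), 0.2, e0, 20)
        assert np.allclose(curve, 0.5 * 0.81 ** np.arange(20), rtol=1e-12)

    def test_initial_energy_conserved(self, rng):
        """Change to the eigenbasis preserves the initial error energy."""
        for _ in range(20):
            B = rng.standard_normal((2, 2))
            A = B @ B.T
            e0 = rng.standard_normal(2)
            curve = analytic_curve(A, 0.2, e0, 5)
            assert curve[0] == pytest.approx(0.5 * e0 @ e0, rel=1e-12)

    @pytest.mark.parametrize("n_neurons", [10, 1000])
    def test_matches_simulation_exactly(self, n_neurons):
        """Noise-free single-target simulation reproduces the closed-form
        curve to 1e−10 relative at every trial."""
        task = TaskSpec(n_targets=1)
        R = rotation_matrix(task.rotation_angle)
        for seed in range(10):
            dec = sample_decoder(DecoderDistribution.uniform(), n_neurons, seed)
            cond = Condition(label="eq", n_neurons=n_neurons, task=task)
            curve = run_repetition(cond, seed, decoder=dec, return_errors=True,
                                   dtype=np.longdouble)
            A_rot = R @ build_A(dec) @ R.T
            predicted = analytic_curve(A_rot, 0.2, curve.error_vectors[0], 100)
            rel = np.abs(curve.errors.astype(float) - predicted) / predicted
            assert rel.max() < 1e-10


class TestSpeedBound:
    def test_orthogonal_pair_is_maximal(self):
        psi = np.array([0.0, np.pi / 2])
        dec = DecoderSample(np.column_stack([np.cos(psi), np.sin(psi)]),
                            "custom", {}, seed=0)
        lam_min, maximal = learning_speed_bound(dec)
        assert lam_min == pytest.approx(0.5)
        assert maximal

    def test_single_neuron_cannot_learn_orthogonally(self):
        dec = DecoderSample(np.array([[1.0, 0.0]]), "custom", {}, seed=0)
        lam_min, maximal = learning_speed_bound(dec)
        assert lam_min == pytest.approx(0.0, abs=1e-15)
        assert not maximal

    def test_near_maximal_fraction_grows_with_n(self):
        """The fraction of decoder samples with λ_min > 0.45 rises
        monotonically with N: redundancy makes maximal speed typical."""
        fractions = []
        for n in (10, 100, 1000):
            hits = sum(
                learning_speed_bound(
                    sample_decoder(DecoderDistribution.uniform(), n, s)
                )[0] > 0.45
                for s in range(200)
            )
            fractions.append(hits / 200)
        assert fractions[0] < fractions[1] < fractions[2]


class TestOptimalRate:
    def test_isotropic_one_trial_convergence(self):
        assert optimal_learning_rate(np.array([0.5, 0.5])) == pytest.approx(2.0)

    def test_two_modes_balances_contractions(self):
        eta = optimal_learning_rate(np.array([0.6, 0.4]))
        assert eta == pytest.approx(2.0)
        assert max(abs(1 - eta * 0.6), abs(1 - eta * 0.4)) == pytest.approx(0.2)

    def test_single_mode_exact_zero(self):
        assert optimal_learning_rate(np.array([0.7, 0.0])) == pytest.approx(1 / 0.7)

    def test_all_zero_rejected(self):
        with pytest.raises(NoLearningError):
            optimal_learning_rate(np.zeros(2))

    def test_matches_grid_search(self, rng):
        """Closed form agrees with a dense grid search of the worst-mode
        contraction for random spectra."""
        for _ in range(50):
            lam = np.sort(rng.uniform(0.05, 1.0, 2))[::-1]
            eta_star = optimal_learning_rate(lam)
            grid = np.linspace(1e-4, 1.1 / lam[-1], 20001)
            worst = np.max(np.abs(1 - np.outer(grid, lam)), axis=1)
            assert abs(eta_star - grid[np.argmin(worst)]) < 2 * (grid[1] - grid[0])

    def test_modal_speed_definition(self):
        assert modal_learning_speed(np.array([0.5, 0.5]), 0.2) == pytest.approx(
            -2 * np.log(0.9)
        )
        assert modal_learning_speed(np.array([0.5, 0.0]), 0.2) == 0.0


class TestResidualError:
    def test_no_decay_no_drift_zero(self):
        A = 0.5 * np.eye(2)
        assert residual_error_with_decay(A, 0.2, 0.0, 0.0, np.array([1.0, 0.0])) == 0.0

    def test_unstable_configuration_rejected(self):
        A = np.diag([10.0, 10.0])
        with pytest.raises(DivergenceError):
            residual_error_with_decay(A, 0.5, 0.0, 0.0, np.array([1.0, 0.0]))

    def test_matches_long_simulation(self):
        """Fixed-point residual equals the 5000-trial simulated tail
        average within 2% (decay only: deterministic check)."""
        task = TaskSpec(n_targets=1, n_baseline_trials=0, n_learning_trials=5000)
        for seed in range(5):
            dec = sample_decoder(DecoderDistribution.uniform(), 50, seed)
            decay = 0.01 + 0.01 * seed
            cond = Condition(label="d", n_neurons=50, task=task,
                             learning=LearningSpec(decay=decay))
            curve = run_repetition(cond, seed, decoder=dec)
            sim = float(np.mean(curve.errors[-1000:]))
            theory = residual_error_with_decay(
                build_A(dec), 0.2, decay, 0.0, np.array([1.0, 0.0]),
                phi=task.rotation_angle, n_neurons=50,
            )
            assert sim == pytest.approx(theory, rel=0.02)

    def test_residual_decreases_with_lambda_min(self):
        """At fixed decay, more isotropic operators (larger λ_min) leave
        less residual error.  The residual at a single target also depends
        on the eigenvector alignment, so the comparison averages over the
        eight target directions; with trace(A) fixed at 1 the averaged
        residual is a strictly decreasing function of λ_min."""
        task = TaskSpec()
        residuals = []
        lam_mins = []
        for seed in range(50):
            dec = sample_decoder(DecoderDistribution.uniform(), 30, seed)
            A = build_A(dec)
            lam_mins.append(np.linalg.eigvalsh(A)[0])
            per_target = [
                residual_error_with_decay(A, 0.2, 0.03, 0.0, task.target_vector(k),
                                          phi=np.pi / 4, n_neurons=30)
                for k in range(task.n_targets)
            ]
            residuals.append(np.mean(per_target))
        order = np.argsort(lam_mins)
        assert np.all(np.diff(np.array(residuals)[order]) <= 1e-12)


class TestCommandUpdate:
    def test_full_transfer_at_trained_direction(self, uniform_decoder):
        """The predicted command change at the trained direction matches a
        single simulated trial exactly (noise-free)."""
        dec = uniform_decoder(100, seed=3)
        A = build_A(dec)
        state = make_state(dec)
        # baseline-train, then apply one perturbed trial
        spec = LearningSpec()
        x = np.array([1.0, 0.0])
        tgt = np.array([1.0, 0.0])
        for _ in range(200):
            trial_step(state, x, tgt, 0.0, spec, QUIET)
        phi = np.pi / 4
        before = forward(state, x, tgt, phi, QUIET)
        trial_step(state, x, tgt, phi, spec, QUIET)
        after = forward(state, x, tgt, phi, QUIET)
        predicted = command_update_prediction(
            A, InputEncoding(), 0.0, 0.0, 0.2, before.error_vector, phi
        )
        assert np.allclose(after.hand - before.hand, predicted, atol=1e-8)

    def test_orthogonal_probe_no_transfer(self):
        out = command_update_prediction(
            0.5 * np.eye(2), InputEncoding(), 0.0, np.pi / 2, 0.2,
            np.array([0.3, -0.1]), 0.0,
        )
        assert np.allclose(out, 0.0, atol=1e-16)

    def test_narrow_tuning_transfers_less_and_matches_simulation(self, uniform_decoder):
        """Narrow (κ=20) von Mises inputs transfer less of an update to a
        π/4 probe than broad (κ=2); the predicted probe-direction change
        agrees with a paired simulation within 5%."""
        dec = uniform_decoder(500, seed=4)
        A = build_A(dec)
        phi = np.pi / 4
        probe_changes = {}
        for kappa in (2.0, 20.0):
            enc = InputEncoding(kind="von_mises", precision=kappa)
            from redunet import encode_direction

            x_train = encode_direction(0.0, enc)
            x_probe = encode_direction(np.pi / 4, enc)
            tgt = np.array([1.0, 0.0])
            state = make_state(dec, input_dim=enc.dim)
            spec = LearningSpec()
            for _ in range(300):
                trial_step(state, x_train, tgt, 0.0, spec, QUIET)
            before = forward(state, x_probe, tgt, phi, QUIET)
            fwd = forward(state, x_train, tgt, phi, QUIET)
            import redunet.learning as learning

            learning.gradient_step(state, fwd, x_train, phi, spec, QUIET)
            after = forward(state, x_probe, tgt, phi, QUIET)
            simulated = after.hand - before.hand
            predicted = command_update_prediction(
                A, enc, 0.0, np.pi / 4, 0.2, fwd.error_vector, phi
            )
            assert np.linalg.norm(simulated - predicted) < 0.05 * np.linalg.norm(
                predicted
            )
            probe_changes[kappa] = np.linalg.norm(simulated)
        assert probe_changes[20.0] < probe_changes[2.0]


class TestMultiTarget:
    def test_no_perturbation_trivially_aligned(self, uniform_decoder):
        dec = uniform_decoder(100, seed=5)
        task = TaskSpec(rotation_angle=0.0)
        assert multi_target_speed_check(dec, task, 0.2)

    def test_rotation_learning_aligned(self, uniform_decoder):
        dec = uniform_decoder(100, seed=6)
        assert multi_target_speed_check(dec, TaskSpec(), 0.2)

    def test_single_target_reduces_to_analytic(self, uniform_decoder):
        dec = uniform_decoder(200, seed=7)
        assert multi_target_speed_check(dec, TaskSpec(n_targets=1), 0.2)


class TestSpectrumProperties:
    def test_elementwise_ordered_spectra_give_dominating_curves(self):
        """If both eigenvalues of (a) are at least those of (b), (a)'s
        analytic curve lies at or below (b)'s at every trial."""
        e0 = np.array([0.6, 0.8])
        fast = analytic_curve(np.diag([0.5, 0.45]), 0.2, e0, 100)
        slow = analytic_curve(np.diag([0.45, 0.3]), 0.2, e0, 100)
        assert np.all(fast <= slow + 1e-15)

    def test_redundancy_ranking_invariant_to_learning_rate(self):
        """The ranking of modal speeds across decoders is the same at
        η = 0.05, 0.2, and the optimal rate."""
        decs = [sample_decoder(DecoderDistribution.uniform(), n, 1)
                for n in (10, 50, 1000)]
        rankings = []
        for eta_mode in (0.05, 0.2, "optimal"):
            speeds = []
            for dec in decs:
                lam = np.linalg.eigvalsh(build_A(dec))
                eta = optimal_learning_rate(lam) if eta_mode == "optimal" else eta_mode
                speeds.append(modal_learning_speed(lam, eta))
            rankings.append(np.argsort(speeds).tolist())
        assert rankings[0] == rankings[1] == rankings[2]

    def test_analyze_decoder_summary(self, uniform_decoder):
        res = analyze_decoder(uniform_decoder(1000, seed=8))
        assert res.eigenvalues[0] >= res.eigenvalues[1]
        assert res.eigenvalues[1] <= 0.5 * np.trace(res.A) + 1e-12
        assert res.predicted_curve[0] >= res.predicted_curve[-1]
        row = res.as_row()
        assert row["optimal_rate"] == pytest.approx(
            2 / (res.eigenvalues[0] + res.eigenvalues[1])
        )
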