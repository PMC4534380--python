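"""Decision criterion, trial execution and confidence read-outs."""

import numpy as np
import pytest
from dataclasses import replace

from battm import (
    BattmConfig,
    Belief,
    StimulusSpec,
    confidence,
    make_stimulus,
    make_stimulus_batch,
    post_decision_confidence,
    redecision_fraction,
    run_trial,
    run_trials,
    simulate_condition,
)


class TestConfidence:
    def test_standard_normal_mode_value(self, phi):
        belief = Belief(mean=phi[0], cov=np.eye(2))
        assert confidence(belief, phi[0]) == pytest.approx(
            1.0 / (2.0 * np.pi), rel=1e-12
        )

    def test_symmetric_belief_gives_equal_confidences(self, mu0, phi):
        belief = Belief(mean=mu0, cov=4.0 * np.eye(2))
        c = confidence(belief, phi)
        assert c[0] == pytest.approx(c[1], rel=1e-12)

    def test_density_values_can_exceed_one(self, phi):
        belief = Belief(mean=phi[0], cov=1e-3 * np.eye(2))
        assert confidence(belief, phi[0]) > 1.0

    def test_singular_covariance_raises(self, phi):
        belief = Belief(mean=phi[0], cov=np.zeros((2, 2)))
        with pytest.raises(np.linalg.LinAlgError):
            confidence(belief, phi[0])

    def test_plateau_confidence_decreases_with_dynamics_uncertainty(self):
        """More expected state noise widens the posterior: the confidence
        level reached after settling is lower for larger q."""
        spec = StimulusSpec(noise_level=2.0, schedule=((0, 800.0),))
        trace = make_stimulus(spec, seed=5)
        plateaus = {}
        for q in (0.5, 1.0):
            rec = run_trial(trace, replace(BattmConfig(), q=q), t0_mode="onset")
            plateaus[q] = rec.confidence[-50:, 0].mean()
        assert plateaus[1.0] < plateaus[0.5]


class TestRunTrial:
    def test_reaction_times_include_nondecision_time(self):
        spec = StimulusSpec(noise_level=2.0, schedule=((0, 800.0),))
        batch = simulate_condition(spec, BattmConfig(r=2.2, q=0.1), 50, seed=0)
        rts = batch.rt_ms[batch.choice >= 0]
        assert len(rts) > 0
        assert np.all(rts >= 200.0)

    def test_unreachable_bound_times_out_every_trial(self):
        cfg = replace(BattmConfig(), lambda_thresh=1e9)
        spec = StimulusSpec(noise_level=2.0, schedule=((0, 800.0),))
        batch = simulate_condition(spec, cfg, 20, seed=0)
        assert np.all(batch.timeout)
        assert np.all(batch.choice == -1)

    def test_low_noise_gives_perfect_accuracy(self):
        """Below s=2 any sensible sensory uncertainty decides perfectly."""
        cfg = BattmConfig(r=2.2, q=0.1)
        spec = StimulusSpec(noise_level=0.5, schedule=((0, 1100.0),))
        batch = simulate_condition(spec, cfg, 200, seed=1, stop_early=True)
        assert batch.accuracy(true_alt=0) == 1.0

    def test_batch_equals_single_trial_runs(self, cfg):
        spec = StimulusSpec(noise_level=4.0, schedule=((0, 400.0), (1, 400.0)))
        obs, truth = make_stimulus_batch(spec, 3, seed=9)
        batch = run_trials(obs, truth, cfg, collect_traces=True)
        from battm import StimulusTrace

        for i in range(3):
            single = run_trial(
                StimulusTrace(observations=obs[i], truth=truth, spec=spec), cfg
            )
            assert np.allclose(single.confidence, batch.confidence[i])
            assert np.allclose(single.means, batch.traces["mean"][i])
            if single.choice is None:
                assert batch.choice[i] == -1
            else:
                assert single.choice == batch.choice[i]
                assert single.rt_ms == batch.rt_ms[i]

    def test_onset_mode_adds_motor_latency_to_rt(self):
        spec = StimulusSpec(noise_level=2.0, schedule=((0, 800.0),))
        obs, truth = make_stimulus_batch(spec, 10, seed=2)
        cfg = BattmConfig(r=2.2, q=0.1)
        dead = run_trials(obs, truth, cfg, t0_mode="dead_time")
        onset = run_trials(obs, truth, cfg, t0_mode="onset")
        assert np.all(onset.rt_ms[onset.choice >= 0] >= cfg.T0_ms)
        # accumulation starts earlier in onset mode, so crossings are earlier
        both = (dead.choice >= 0) & (onset.choice >= 0)
        assert np.mean(onset.cross_step[both]) < np.mean(dead.cross_step[both])

    def test_overshoot_when_sensory_uncertainty_too_low(self):
        """r far below the true noise level drives the state past the
        fixed point; a matched r does not."""
        spec = StimulusSpec(noise_level=4.7, schedule=((0, 800.0),))
        trace = make_stimulus(spec, seed=4)
        rec_low = run_trial(trace, BattmConfig(r=1.0, q=0.1), t0_mode="onset")
        rec_ok = run_trial(trace, BattmConfig(r=2.2, q=0.1), t0_mode="onset")
        assert rec_low.means.max() > 11.5
        assert rec_ok.means.max() < rec_low.means.max()

    def test_reaction_time_is_u_shaped_in_sensory_uncertainty(self):
        """Paired stimuli at s=4.7: too little sensory uncertainty slows
        decisions through overshoots (and costs accuracy), too much slows
        them through sluggish accumulation; a matched r is fastest."""
        spec = StimulusSpec(noise_level=4.7, schedule=((0, 1100.0),))
        obs, truth = make_stimulus_batch(spec, 200, seed=6)
        rt, acc = {}, {}
        for r in (1.5, 4.0, 8.0):
            batch = run_trials(obs, truth, BattmConfig(r=r, q=0.1))
            rt[r] = np.nanmean(batch.rt_ms[batch.decided])
            acc[r] = batch.accuracy(true_alt=0)
        assert rt[1.5] > rt[4.0] < rt[8.0]
        assert acc[1.5] < acc[4.0]


class TestRedecisionFraction:
    def test_trivial_bounds(self, switch_spec, cfg):
        """Criterion met at every step gives 1.0; never met gives 0.0."""
        from battm import TrialRecord, make_stimulus

        trace = make_stimulus(switch_spec, seed=0)
        rec = run_trial(trace, cfg, t0_mode="onset")
        lam = rec.cfg.lambda_thresh
        always = replace(rec, confidence=np.full_like(rec.confidence, 2 * lam))
        assert redecision_fraction(always) == 1.0
        never = replace(rec, confidence=np.full_like(rec.confidence, lam / 2))
        assert redecision_fraction(never) == 0.0
        assert isinstance(rec, TrialRecord)

    def test_flexibility_ordering_in_dynamics_uncertainty(self, switch_spec):
        """Larger q re-decides faster after the switch, so more time is
        spent in the correct state."""
        fracs = {}
        for q in (0.1, 0.5, 1.0):
            batch = simulate_condition(
                switch_spec, BattmConfig(r=2.4, q=q), 150, seed=3,
                t0_mode="onset",
            )
            fracs[q] = float(np.mean(redecision_fraction(batch)))
        assert fracs[0.1] < fracs[0.5] < fracs[1.0]

    def test_single_record_matches_batch(self, switch_spec, cfg):
        trace = make_stimulus(switch_spec, seed=12)
        rec = run_trial(trace, cfg, t0_mode="onset")
        batch = run_trials(
            trace.observations, trace.truth, cfg, t0_mode="onset"
        )
        assert redecision_fraction(rec) == pytest.approx(
            float(redecision_fraction(batch)[0])
        )

    def test_early_stopped_batch_rejected(self, switch_spec, cfg):
        batch = simulate_condition(
            switch_spec, cfg, 5, seed=1, stop_early=True
        )
        if batch.n_steps_run < batch.confidence.shape[1]:
            with pytest.raises(ValueError):
                redecision_fraction(batch)


class TestPostDecisionConfidence:
    def test_at_crossing_equals_threshold_or_above(self):
        spec = StimulusSpec(noise_level=2.0, schedule=((0, 800.0),))
        rec = run_trial(make_stimulus(spec, seed=8), BattmConfig(r=2.2, q=0.1))
        val, truncated = post_decision_confidence(rec, extra_ms=0.0)
        assert val >= rec.cfg.lambda_thresh
        assert not truncated

    def test_non_decreasing_for_noise_free_preferred_stimulus(self, cfg):
        """With the stimulus frozen at the chosen prototype, continued
        accumulation cannot lower confidence."""
        spec = StimulusSpec(noise_level=0.0, schedule=((0, 800.0),))
        rec = run_trial(make_stimulus(spec, seed=0), cfg)
        assert rec.choice == 0
        seg = rec.confidence[rec.cross_step : rec.cross_step + 25, 0]
        assert np.all(np.diff(seg) >= -1e-12)

    def test_truncation_flag_near_trial_end(self, cfg):
        spec = StimulusSpec(noise_level=0.0, schedule=((0, 280.0),))
        rec = run_trial(make_stimulus(spec, seed=0), cfg)
        assert rec.choice is not None
        val, truncated = post_decision_confidence(rec, extra_ms=500.0)
        assert truncated
        assert val == rec.confidence[-1, rec.choice]

    def test_undecided_trial_raises(self):
        cfg = replace(BattmConfig(), lambda_thresh=1e9)
        spec = StimulusSpec(noise_level=2.0, schedule=((0, 400.0),))
        rec = run_trial(make_stimulus(spec, seed=0), cfg)
        with pytest.raises(ValueError):
            post_decision_confidence(rec)
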