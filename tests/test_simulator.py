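import numpy as np
import pytest

from gazesim.core import Params, Zone, ZoneDistribution
from gazesim.memory import MemoryState, filter_step, invert
from gazesim.saliency import AOISaliencyStream
from gazesim.simulator import (
    GazeState,
    Protocol,
    ProtocolError,
    TrialTimeline,
    draw_next_position,
    experiment_uniforms,
    fused_distribution,
    simulate_experiment,
    simulate_trial,
)
from gazesim.synth import protocol_streams
from gazesim.topdown import TopDownConfig, top_down_distribution
from gazesim.saliency import bottom_up_distribution


def fused_oracle(td, bu, mem_inverted):
    masses = td * bu * mem_inverted
    return masses / masses.sum()


def uniform_stream(n_steps, value=1.0):
    arr = np.full((n_steps, 4), value)
    return AOISaliencyStream(arr, arr.copy())


class TestTrialTimeline:
    def test_windows_and_onset(self, timeline):
        assert timeline.t_er == 100
        assert timeline.n_steps == 200
        assert timeline.anticipatory_window == range(50, 100)
        assert timeline.detection_window == range(100, 200)

    def test_rejects_unknown_condition(self):
        with pytest.raises(ProtocolError):
            TrialTimeline(condition="XX")


class TestFusedDistribution:
    def test_uniform_factors_give_uniform(self, timeline):
        state = GazeState(Zone.EYES, MemoryState.uniform())
        # p_hit -> 1/4 limit makes the memory factor uniform
        params = Params(theta=0.5, p_hit=0.2500001)
        cfg = TopDownConfig(base_priors=(0.25, 0.25, 0.25, 0.25))
        dist = fused_distribution(
            state, (np.ones(4), np.ones(4)), 10, timeline, params, cfg
        )
        np.testing.assert_allclose(dist.probs, 0.25, atol=1e-6)

    def test_identity_factors_leave_top_down(self, timeline):
        state = GazeState(Zone.MOUTH, MemoryState.uniform())
        params = Params(beta=5, gamma=0, theta=0.5, p_hit=0.2500001)
        cfg = TopDownConfig(learning_enabled=True)
        t = timeline.t_er + 5
        tl = TrialTimeline(trial=4)
        dist = fused_distribution(
            state, (np.ones(4), np.ones(4)), t, tl, params, cfg
        )
        expected = top_down_distribution(t, 4, cfg, params, tl.t_er)
        np.testing.assert_allclose(dist.probs, expected.probs, atol=1e-6)

    def test_matches_enumeration_oracle(self, timeline, rng):
        cfg = TopDownConfig(learning_enabled=True)
        for _ in range(100):
            params = Params(
                beta=float(rng.uniform(0, 5)), gamma=float(rng.uniform(0, 2)),
                theta=float(rng.uniform(0, 1)),
            )
            belief = rng.dirichlet(np.ones(4))
            pos = Zone(int(rng.integers(4)))
            static, dynamic = rng.random(4) + 0.01, rng.random(4) + 0.01
            t = int(rng.integers(0, 200))
            trial = int(rng.integers(1, 20))
            tl = TrialTimeline(trial=trial)
            state = GazeState(pos, MemoryState(belief))
            dist = fused_distribution(state, (static, dynamic), t, tl, params, cfg)
            td = top_down_distribution(t, trial, cfg, params, tl.t_er).probs
            bu = bottom_up_distribution(static, dynamic, params.theta).probs
            mem = invert(
                filter_step(MemoryState(belief), pos, params.epsilon, params.p_hit)
            ).probs
            np.testing.assert_allclose(dist.probs, fused_oracle(td, bu, mem),
                                       atol=1e-12)


class TestDrawNextPosition:
    def test_degenerate_distribution(self, rng):
        dist = ZoneDistribution((1.0, 0.0, 0.0, 0.0))
        assert all(
            draw_next_position(dist, rng) is Zone.EYES for _ in range(100)
        )

    def test_frequencies_match_uniform_distribution(self):
        rng = np.random.default_rng(99)
        dist = ZoneDistribution.uniform()
        draws = np.array([int(draw_next_position(dist, rng)) for _ in range(100_000)])
        freqs = np.bincount(draws, minlength=4) / len(draws)
        # binomial standard error at p=0.25, n=1e5
        se = np.sqrt(0.25 * 0.75 / 100_000)
        np.testing.assert_allclose(freqs, 0.25, atol=3 * se)

    def test_same_seed_reproduces_sequence(self):
        dist = ZoneDistribution((0.4, 0.3, 0.2, 0.1))
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            seqs.append([int(draw_next_position(dist, rng)) for _ in range(200)])
        assert seqs[0] == seqs[1]


class TestSimulateTrial:
    def test_trajectory_contract(self, timeline, rng):
        traj = simulate_trial(
            timeline, uniform_stream(200), Params(), TopDownConfig(), rng
        )
        assert len(traj) == 200
        assert traj.zones[0] == int(Zone.EYES)
        assert set(np.unique(traj.zones)) <= {0, 1, 2, 3}

    def test_same_seed_identical_trajectories(self, timeline):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            runs.append(simulate_trial(
                timeline, uniform_stream(200), Params(), TopDownConfig(), rng
            ).zones)
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_stream_length_mismatch_rejected(self, timeline, rng):
        with pytest.raises(ProtocolError):
            simulate_trial(timeline, uniform_stream(100), Params(),
                           TopDownConfig(), rng)

    def test_occupancy_matches_markov_stationary_oracle(self):
        """With memory near the fast-forgetting limit the chain over
        positions is Markov: the diluted belief is almost uniform, so the
        memory factor depends only on the previous draw.  Long-run zone
        frequencies must match the stationary distribution of that 4x4
        chain."""
        eps = 0.2499  # dilution ~ (1 - 4 eps) -> 0: belief resets each step
        p_hit = 0.9
        params = Params(beta=0.0, gamma=0.0, theta=0.5, epsilon=eps, p_hit=p_hit)
        cfg = TopDownConfig(learning_enabled=False)
        priors = np.array(cfg.base_priors)

        # transition matrix oracle: row i = fused distribution after viewing i
        P = np.zeros((4, 4))
        for i in range(4):
            belief = np.full(4, 0.25) * (1 - 4 * eps) + eps
            lik = np.full(4, (1 - p_hit) / 3)
            lik[i] = p_hit
            post = belief * lik
            post /= post.sum()
            mem = (1 - post) / 3
            fused = priors * 0.25 * mem  # uniform bottom-up
            P[i] = fused / fused.sum()
        evals, evecs = np.linalg.eig(P.T)
        stat = np.real(evecs[:, np.argmax(np.real(evals))])
        stat /= stat.sum()

        n_steps = 60_000
        tl = TrialTimeline(n_speech_steps=n_steps // 2,
                          n_nonspeech_steps=n_steps // 2)
        rng = np.random.default_rng(4)
        traj = simulate_trial(tl, uniform_stream(n_steps), params, cfg, rng)
        freqs = np.bincount(traj.zones, minlength=4) / len(traj)
        # near-uniform-belief approximation + Monte-Carlo error
        np.testing.assert_allclose(freqs, stat, atol=0.01)


class TestSimulateExperiment:
    def test_default_design_counts(self, small_protocol, small_streams):
        result = simulate_experiment(small_protocol, small_streams)
        assert set(result.zones) == {"ER", "LP"}
        for arr in result.zones.values():
            assert arr.shape == (4, 5, 200)
        df = result.to_frame()
        assert len(df) == 2 * 4 * 5 * 200

    def test_er_only_design(self):
        p = Protocol(conditions=("ER",), n_virtual_participants=3, n_trials=4,
                     master_seed=1)
        result = simulate_experiment(p, protocol_streams(p))
        assert set(result.zones) == {"ER"}
        assert result.zones["ER"].shape == (3, 4, 200)

    def test_missing_condition_stream_rejected(self, small_protocol, small_streams):
        streams = {"ER": small_streams["ER"]}
        with pytest.raises(ProtocolError):
            simulate_experiment(small_protocol, streams)

    def test_master_seed_reproducibility(self, small_protocol, small_streams):
        a = simulate_experiment(small_protocol, small_streams)
        b = simulate_experiment(small_protocol, small_streams)
        for cond in a.zones:
            np.testing.assert_array_equal(a.zones[cond], b.zones[cond])
        import dataclasses
        other = dataclasses.replace(small_protocol, master_seed=8)
        c = simulate_experiment(other, protocol_streams(other))
        assert any(
            not np.array_equal(a.zones[cond], c.zones[cond]) for cond in a.zones
        )

    def test_precomputed_uniforms_match_default_path(self, small_protocol,
                                                     small_streams):
        uniforms = experiment_uniforms(small_protocol)
        a = simulate_experiment(small_protocol, small_streams, uniforms=uniforms)
        b = simulate_experiment(small_protocol, small_streams)
        for cond in a.zones:
            np.testing.assert_array_equal(a.zones[cond], b.zones[cond])


class TestQualitativeEffects:
    def test_learning_raises_late_trial_anticipatory_eyes_score(self):
        """Strong learning (beta at grid max, gamma=2) must raise the
        group-mean anticipatory Eyes-Mouth score at the last trial over the
        second trial; without the learned component (beta=0) the two are
        statistically indistinguishable."""
        from gazesim.analysis import window_preferences

        def trial_scores(beta, seed):
            p = Protocol(conditions=("ER",), master_seed=seed,
                         params=Params(beta=beta, gamma=2.0, theta=0.0))
            res = simulate_experiment(p, protocol_streams(p))
            pref = window_preferences(res.zones["ER"], p.timeline, "anticipatory")
            return pref.mean(axis=0)  # per-trial group means

        strong = trial_scores(5.0, seed=21)
        assert strong[18] > strong[1]

        diffs = np.array([
            trial_scores(0.0, seed=500 + s)[18] - trial_scores(0.0, seed=500 + s)[1]
            for s in range(10)
        ])
        # no learning: trial-19 minus trial-2 difference centered on zero
        assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))

    def test_theta_monotonically_favors_static_eyes(self):
        """With static saliency concentrated on Eyes, a theta=1 run spends
        more time on Eyes than a theta=0 run, all else equal."""
        occup = {}
        for theta in (0.0, 1.0):
            p = Protocol(conditions=("ER",), n_virtual_participants=10,
                         master_seed=3, params=Params(beta=0.5, gamma=1.0,
                                                      theta=theta))
            res = simulate_experiment(p, protocol_streams(p))
            occup[theta] = (res.zones["ER"] == int(Zone.EYES)).mean()
        assert occup[1.0] > occup[0.0]
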