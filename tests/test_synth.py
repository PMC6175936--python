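"""Generator contracts: determinism, task timing, and rate fidelity of the
inhomogeneous-Poisson spike, lick, and saccade models."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from dacue.core import EventTimes, TimingConfig
from dacue.synth import (
    LickModel,
    ResponseKernel,
    SaccadeModel,
    SynthParams,
    default_kernels,
    generate_licks,
    generate_saccades,
    generate_session,
    generate_spike_train,
    intensity,
)

EVENTS = EventTimes(fp_onset=0.75, cs_onset=1.6, cs_offset=2.6, reward_time=2.5)


def _sessions_equal(a, b):
    for ta, tb in zip(a.trials, b.trials):
        if ta.events != tb.events or ta.value_label != tb.value_label:
            return False
        for nid in ta.spikes:
            if not np.array_equal(ta.spikes[nid], tb.spikes[nid]):
                return False
        if not np.array_equal(ta.licks, tb.licks):
            return False
    return True


class TestSessionGeneration:
    def test_determinism(self, small_params):
        assert _sessions_equal(generate_session(small_params, 5),
                               generate_session(small_params, 5))

    def test_adding_trials_preserves_earlier_ones(self, small_params):
        longer = dataclasses.replace(small_params,
                                     n_trials_inact=small_params.n_trials_inact + 15)
        a = generate_session(small_params, 5)
        b = generate_session(longer, 5)
        assert _sessions_equal(a, dataclasses.replace(b, trials=b.trials[:len(a.trials)]))

    def test_cs_delay_jitter_range(self, session_default):
        delays = np.array([t.events.cs_onset - t.events.fp_onset
                           for t in session_default.trials])
        assert np.all((delays >= 0.7) & (delays <= 1.2))

    def test_block_structure(self, session_default, default_params):
        assert session_default.block_start == default_params.n_trials_pre
        conds = [t.condition for t in session_default.trials]
        assert conds[:60] == ["pre"] * 60
        assert conds[60:] == ["inactivation"] * 60

    def test_value_labels_near_half(self):
        """Fraction of LR trials lies in the 99% binomial interval of 1/2."""
        p = dataclasses.replace(SynthParams(), n_trials_pre=4000, n_trials_inact=0,
                                neuron_ids=(), lick_model=LickModel(0.0, 0.0))
        s = generate_session(p, 11)
        n_lr = sum(t.value_label == "LR" for t in s.trials)
        lo, hi = sps.binom.interval(0.99, 4000, 0.5)
        assert lo <= n_lr <= hi

    def test_negative_intensity_rejected_before_simulation(self):
        bad = dataclasses.replace(
            SynthParams(), baseline_rate=2.0,
            kernels=(ResponseKernel("CS", 0.085, 0.015, -10.0, 0.0),))
        with pytest.raises(ValueError, match="negative"):
            generate_session(bad, 0)


class TestSpikeTrain:
    def test_homogeneous_mean_count(self):
        """With all kernel amplitudes zero the process is Poisson(baseline*T):
        mean spike count over many trials is inside the 99% CI of 20."""
        rng = np.random.default_rng(21)
        counts = [generate_spike_train(EVENTS, "LR", "pre", 5.0, (), 4.0, rng).size
                  for _ in range(2000)]
        se = np.sqrt(20.0 / 2000)
        assert abs(np.mean(counts) - 20.0) < 2.58 * se

    def test_kernel_adds_gaussian_mass(self):
        """A single bump of amplitude A and width sigma contributes
        A*sigma*sqrt(2*pi) expected spikes per trial."""
        k = ResponseKernel("CS", 0.085, 0.015, 30.0, 30.0)
        rng = np.random.default_rng(22)
        counts = [generate_spike_train(EVENTS, "LR", "pre", 0.0, (k,), 4.0, rng).size
                  for _ in range(3000)]
        expected = 30.0 * 0.015 * np.sqrt(2 * np.pi)
        se = np.sqrt(expected / 3000)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_psth_matches_intensity(self):
        """Empirical PSTH converges to lambda(t) pointwise within 3 SE."""
        params = SynthParams()
        rng = np.random.default_rng(23)
        n_trials, width = 5000, 0.02
        edges = np.arange(0.0, 4.0 + 1e-9, width)
        acc = np.zeros(edges.size - 1)
        for _ in range(n_trials):
            st = generate_spike_train(EVENTS, "LR", "pre", params.baseline_rate,
                                      params.kernels, 4.0, rng)
            acc += np.histogram(st, bins=edges)[0]
        rate = acc / (n_trials * width)
        centers = edges[:-1] + width / 2
        lam = intensity(centers, EVENTS, "LR", "pre", params.baseline_rate,
                        params.kernels)
        se = np.sqrt(lam / (n_trials * width))
        assert np.all(np.abs(rate - lam) < 3.2 * se + 0.05 * lam)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError, match="lambda_max"):
            generate_spike_train(EVENTS, "LR", "pre", 0.0, (), 4.0,
                                 np.random.default_rng(0))

    def test_sorted_output(self):
        rng = np.random.default_rng(3)
        st = generate_spike_train(EVENTS, "SR", "pre", 8.0, default_kernels(),
                                  4.0, rng)
        assert np.all(np.diff(st) >= 0)


class TestLicks:
    def test_no_rates_no_licks(self):
        out = generate_licks(EVENTS, "LR", "pre", LickModel(0.0, 0.0), 4.0,
                             np.random.default_rng(0))
        assert out.size == 0

    def test_equal_rates_yield_no_value_difference(self):
        """anticipatory == baseline makes the process homogeneous, so the
        LR-SR rate difference in the cue-reward window averages to ~0."""
        model = LickModel(baseline_rate=2.0, anticipatory_rate=2.0)
        rng = np.random.default_rng(9)
        diffs = []
        for _ in range(800):
            lr = generate_licks(EVENTS, "LR", "pre", model, 4.0, rng)
            sr = generate_licks(EVENTS, "SR", "pre", model, 4.0, rng)
            w = (EVENTS.cs_onset, EVENTS.reward_time)
            width = w[1] - w[0]
            diffs.append((np.sum((lr >= w[0]) & (lr < w[1]))
                          - np.sum((sr >= w[0]) & (sr < w[1]))) / width)
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se + 1e-9

    def test_anticipatory_window_placement(self):
        """With zero baseline, LR licks live in [CS onset, reward) and SR
        licks in [CS offset, reward)."""
        model = LickModel(baseline_rate=0.0, anticipatory_rate=30.0)
        rng = np.random.default_rng(10)
        lr_ev = EVENTS
        sr_ev = EventTimes(0.75, 1.6, 2.6, 2.9)
        lr = generate_licks(lr_ev, "LR", "pre", model, 4.0, rng)
        sr = generate_licks(sr_ev, "SR", "pre", model, 4.0, rng)
        assert np.all((lr >= lr_ev.cs_onset) & (lr < lr_ev.reward_time))
        assert np.all((sr >= sr_ev.cs_offset) & (sr < sr_ev.reward_time))


class TestSaccades:
    def test_shift_recovery(self):
        """A 53 ms injected shift at the affected direction is recovered
        within +/-6 ms (SE of a difference of means at n=100, SD=20)."""
        model = SaccadeModel()
        recs = generate_saccades(model, 100, 17)
        for direction in model.directions:
            pre = [r.latency_ms for r in recs
                   if r.condition == "pre" and r.target_direction == direction]
            post = [r.latency_ms for r in recs
                    if r.condition == "inactivation" and r.target_direction == direction]
            delta = np.mean(post) - np.mean(pre)
            target = 53.0 if direction == model.affected_direction else 0.0
            assert abs(delta - target) < 6.0

    def test_latency_floor(self):
        model = SaccadeModel(latency_mean_ms=60.0, latency_sd_ms=30.0)
        recs = generate_saccades(model, 300, 2)
        assert min(r.latency_ms for r in recs) > model.min_latency_ms

    def test_determinism(self):
        a = generate_saccades(SaccadeModel(), 20, 4)
        b = generate_saccades(SaccadeModel(), 20, 4)
        assert [r.latency_ms for r in a] == [r.latency_ms for r in b]
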