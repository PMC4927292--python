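"""Generator contracts: the forward model must invert the correction cascade."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfretkit import (
    BindingSimConfig,
    CorrectionSet,
    TraceSimConfig,
    gamma_corrected_efficiency,
    simulate_binding_trace,
    simulate_cohort,
    simulate_fret_trace,
)
from smfretkit.errors import ConfigError
from smfretkit.synth import read_traces, write_traces


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            {"state_efficiencies": [1.5]},
            {"state_efficiencies": []},
            {"transition_rates": [[0.0, -1.0], [1.0, 0.0]], "state_efficiencies": [0.1, 0.9]},
            {"frame_interval": 0.0},
            {"gamma": 0.0},
            {"alpha": 1.0},
            {"beta": -0.1},
            {"noise_sd": -1.0},
            {"total_intensity": 0.0},
        ],
    )
    def test_invalid_trace_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            TraceSimConfig(**bad)

    @pytest.mark.parametrize(
        "bad", [{"k_off": 0.0}, {"k_on": -1.0}, {"concentration": 0.0}]
    )
    def test_invalid_binding_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            BindingSimConfig(**bad)


class TestFretTrace:
    def test_symmetric_state_gives_equal_channels(self):
        """E = 0.5 with no distortions puts half the signal in each channel."""
        cfg = TraceSimConfig(
            state_efficiencies=[0.5],
            transition_rates=[[0.0]],
            noise_sd=0.0,
            alpha=0.0,
            beta=0.0,
            gamma=1.0,
            donor_bleach_rate=0.0,
            acceptor_bleach_rate=0.0,
            n_frames=20,
        )
        tr = simulate_fret_trace(cfg, seed=0)
        np.testing.assert_allclose(tr.donor, 500.0)
        np.testing.assert_allclose(tr.acceptor, 500.0)

    @pytest.mark.parametrize("alpha", [0.0, 0.165, 0.4])
    @pytest.mark.parametrize("beta", [0.0, 0.017, 0.2])
    @pytest.mark.parametrize("gamma", [0.5, 1.0, 1.66])
    def test_correction_round_trip_machine_precision(self, alpha, beta, gamma):
        """Correcting a noiseless trace with the generating (alpha, beta,
        gamma) returns the ground-truth efficiency to <= 1e-12."""
        cfg = TraceSimConfig(
            state_efficiencies=[0.19, 0.83],
            transition_rates=[[0.0, 0.5], [0.8, 0.0]],
            noise_sd=0.0,
            alpha=alpha,
            beta=beta,
            gamma=gamma,
            donor_bleach_rate=0.0,
            acceptor_bleach_rate=0.0,
            n_frames=200,
        )
        tr = simulate_fret_trace(cfg, seed=3)
        cs = CorrectionSet(alpha=alpha, beta=beta, gamma=gamma)
        e = gamma_corrected_efficiency(tr.donor, tr.acceptor, cs)
        np.testing.assert_allclose(e, tr.truth.efficiency_path, atol=1e-12)

    def test_seed_determinism(self):
        cfg = TraceSimConfig(n_frames=50)
        a = simulate_fret_trace(cfg, seed=11)
        b = simulate_fret_trace(cfg, seed=11)
        assert np.array_equal(a.donor, b.donor)
        assert np.array_equal(a.acceptor, b.acceptor)

    def test_bleach_time_exponential_mean(self):
        """Empirical mean acceptor bleach time matches 1/rate within 3 SE."""
        cfg = TraceSimConfig(acceptor_bleach_rate=0.02, n_frames=2)
        ss = np.random.SeedSequence(5)
        times = np.array(
            [simulate_fret_trace(cfg, s).truth.acceptor_bleach_time for s in ss.spawn(3000)]
        )
        se = 50.0 / np.sqrt(times.size)
        assert abs(times.mean() - 50.0) < 3 * se

    def test_post_bleach_levels_noiseless(self):
        """After acceptor bleach the donor reports the full intensity; after
        donor bleach both channels are at background."""
        cfg = TraceSimConfig(
            state_efficiencies=[0.8],
            noise_sd=0.0,
            alpha=0.0,
            beta=0.0,
            gamma=1.5,
            acceptor_bleach_rate=0.05,
            donor_bleach_rate=0.01,
            n_frames=1000,
        )
        for s in np.random.SeedSequence(2).spawn(20):
            tr = simulate_fret_trace(cfg, s)
            f_ab, f_db = tr.truth.acceptor_bleach_frame, tr.truth.donor_bleach_frame
            end = f_db if f_db is not None else len(tr)
            if f_ab is not None and f_ab < end:
                np.testing.assert_allclose(tr.donor[f_ab:end], 1000.0)
                np.testing.assert_allclose(tr.acceptor[f_ab:end], 0.0)
            if f_db is not None:
                np.testing.assert_allclose(tr.donor[f_db:], 0.0)
                np.testing.assert_allclose(tr.acceptor[f_db:], 0.0)


class TestBindingTrace:
    def test_balanced_rates_give_half_occupancy(self):
        """k_off = k_on*c implies 50 % bound time; tolerance is 3x the
        large-T SD of the occupancy of a symmetric two-state chain,
        sd ~= 0.5*sqrt(2*tau_c/T) with correlation time tau_c = 0.5 s."""
        cfg = BindingSimConfig(
            k_off=1.0, k_on=10.0, concentration=0.1, noise_sd=0.0, n_frames=20000
        )
        tr = simulate_binding_trace(cfg, seed=9)
        frac = tr.truth.efficiency_path.mean()
        assert abs(frac - 0.5) < 3 * 0.5 * np.sqrt(2 * 0.5 / 2000.0)

    def test_true_bound_dwell_mean(self):
        """Ground-truth bound dwells are exponential with mean 1/k_off."""
        cfg = BindingSimConfig(
            k_off=2.16, k_on=10.0, concentration=0.1, noise_sd=0.0, n_frames=30000
        )
        dwells = []
        for s in np.random.SeedSequence(4).spawn(5):
            tr = simulate_binding_trace(cfg, s)
            t, states = tr.truth.event_times, tr.truth.event_states
            ends = np.append(t[1:], len(tr) * tr.frame_interval)
            complete = slice(0, len(t) - 1)  # last dwell is cut by the window
            d = (ends - t)[complete][states[complete] == 1]
            dwells.extend(d)
        dwells = np.asarray(dwells)
        mean, se = dwells.mean(), dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert dwells.size > 5000
        assert abs(mean - 1 / 2.16) < 3 * se

    def test_empty_trace(self):
        tr = simulate_binding_trace(BindingSimConfig(n_frames=0), seed=0)
        assert len(tr) == 0

    def test_donor_constant_noiseless(self):
        cfg = BindingSimConfig(noise_sd=0.0, donor_level=500.0, n_frames=100)
        tr = simulate_binding_trace(cfg, seed=1)
        np.testing.assert_allclose(tr.donor, 500.0)


class TestCohort:
    def test_single_population(self):
        cfgs = {"popA": TraceSimConfig(n_frames=5)}
        traces = simulate_cohort(cfgs, {"popA": 1.0}, 10, seed=0)
        assert all(t.truth.subpopulation == "popA" for t in traces)

    def test_mixture_counts_binomial(self):
        cfgs = {
            "hi": TraceSimConfig(state_efficiencies=[0.83], n_frames=2),
            "lo": TraceSimConfig(state_efficiencies=[0.19], n_frames=2),
        }
        traces = simulate_cohort(cfgs, {"hi": 0.5, "lo": 0.5}, 10000, seed=1)
        n_hi = sum(t.truth.subpopulation == "hi" for t in traces)
        assert abs(n_hi - 5000) < 3 * 50  # binomial SD = sqrt(n p q) = 50

    def test_negative_weight_rejected(self):
        cfgs = {"a": TraceSimConfig(n_frames=2), "b": TraceSimConfig(n_frames=2)}
        with pytest.raises(ConfigError):
            simulate_cohort(cfgs, {"a": -0.5, "b": 1.5}, 5, seed=0)

    def test_weights_must_sum_to_one(self):
        cfgs = {"a": TraceSimConfig(n_frames=2)}
        with pytest.raises(ConfigError):
            simulate_cohort(cfgs, {"a": 0.9}, 5, seed=0)

    def test_cohort_determinism(self):
        cfgs = {"a": TraceSimConfig(n_frames=20, noise_sd=50.0)}
        t1 = simulate_cohort(cfgs, {"a": 1.0}, 5, seed=7)
        t2 = simulate_cohort(cfgs, {"a": 1.0}, 5, seed=7)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.donor, b.donor)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    alpha=st.floats(0.0, 0.6),
    beta=st.floats(0.0, 0.6),
    d=st.floats(1.0, 1e4),
    a=st.floats(1.0, 1e4),
)
def test_mixing_map_invertible(alpha, beta, d, a):
    """The (D*, A*) -> (I_D, I_A) mixing is linear and invertible for
    alpha*beta != 1: undoing the leakage recovers the ideal signals."""
    from smfretkit.synth import _mix_channels

    i_d, i_a = _mix_channels(np.array([d]), np.array([a]), alpha, beta)
    d_c = i_d - alpha * i_a
    a_c = i_a - beta * d_c
    np.testing.assert_allclose([d_c[0], a_c[0]], [d, a], rtol=1e-12)


def test_trace_csv_round_trip(tmp_path):
    cfg = TraceSimConfig(n_frames=30, noise_sd=40.0, n_traces=3)
    ss = np.random.SeedSequence(0)
    traces = [simulate_fret_trace(cfg, s, f"m{i}") for i, s in enumerate(ss.spawn(3))]
    path = tmp_path / "traces.csv"
    write_traces(traces, path)
    back = read_traces(path)
    assert [t.molecule_id for t in back] == ["m0", "m1", "m2"]
    for orig, rt in zip(traces, back):
        np.testing.assert_allclose(rt.donor, orig.donor)
        np.testing.assert_allclose(rt.acceptor, orig.acceptor)
        assert rt.frame_interval == pytest.approx(orig.frame_interval)
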