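"""Feature-extraction oracles: OLS, exponential fits, ISI arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from apcphys import features, synth
from apcphys.recordings import (
    ProtocolError,
    StimulusProtocol,
    SweepSet,
    subthreshold_protocol,
    suprathreshold_protocol,
)

from conftest import make_quiet_params

FS = 10_000.0


def _sweepset(traces: dict, step_duration=1.0, pre=0.1, post=0.1):
    proto = StimulusProtocol(
        step_amplitudes=tuple(traces),
        step_duration=step_duration,
        baseline_pre=pre,
        baseline_post=post,
        sampling_rate=FS,
    )
    return SweepSet(proto, {a: np.asarray(v, float) for a, v in traces.items()})


def _step_trace(proto: StimulusProtocol, baseline, step_value):
    v = np.full(proto.n_samples, float(baseline))
    v[proto.onset_index : proto.offset_index] = step_value
    return v


def _gaussian_spike_trace(proto, baseline, spike_times_s, peak=35.0, sigma_ms=0.2):
    t = proto.time()
    v = np.full(proto.n_samples, float(baseline))
    for ts in spike_times_s:
        v = np.maximum(
            v,
            baseline
            + (peak - baseline) * np.exp(-0.5 * ((t - ts) / (sigma_ms / 1000.0)) ** 2),
        )
    return v


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        train = features.detect_spikes(np.full(1000, -65.0), FS)
        assert len(train) == 0

    def test_three_template_spikes_found_at_peaks(self):
        proto = StimulusProtocol(step_amplitudes=(100.0,))
        times = [0.3, 0.5, 0.7]
        v = _gaussian_spike_trace(proto, -65.0, times)
        train = features.detect_spikes(v, FS)
        assert len(train) == 3
        assert np.allclose(train.spike_times, times, atol=1.0 / FS)

    def test_nonfinite_rejected(self):
        v = np.full(100, -65.0)
        v[10] = np.nan
        with pytest.raises(ValueError):
            features.detect_spikes(v, FS)


class TestInputResistance:
    def test_ideal_ohmic_exact(self):
        proto = subthreshold_protocol()
        r = 100.0  # MOhm
        traces = {
            a: _step_trace(proto, -65.0, -65.0 + a * r / 1000.0)
            for a in proto.step_amplitudes
        }
        ss = SweepSet(proto, traces)
        assert features.input_resistance(ss) == pytest.approx(100.0, abs=1e-9)

    @given(
        st.lists(
            st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=11,
            max_size=11,
        )
    )
    @settings(max_examples=20, deadline=None)
    def test_equals_normal_equations_oracle(self, jitter):
        """The extractor is *exactly* the OLS slope: compare against the
        closed-form normal equations on arbitrarily perturbed steady states."""
        proto = subthreshold_protocol()
        amps = np.array(proto.step_amplitudes)
        dv = amps * 0.12 + np.array(jitter)
        ss = SweepSet(
            proto,
            {a: _step_trace(proto, -65.0, -65.0 + d) for a, d in zip(amps, dv)},
        )
        x = amps - amps.mean()
        slope = float(x @ (dv - dv.mean()) / (x @ x)) * 1000.0
        assert features.input_resistance(ss) == pytest.approx(slope, abs=1e-6)

    def test_unbiased_under_noise(self):
        proto = subthreshold_protocol()
        rng = np.random.default_rng(0)
        estimates = []
        for _ in range(50):
            ss = SweepSet(
                proto,
                {
                    a: _step_trace(proto, -65.0, -65.0 + a * 0.15)
                    + rng.normal(0, 0.2, proto.n_samples)
                    for a in proto.step_amplitudes
                },
            )
            estimates.append(features.input_resistance(ss))
        # 50 estimates; the mean must sit within ~4 SEM of 150 MOhm
        sem = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 150.0) < 4.0 * max(sem, 0.05)

    def test_too_few_amplitudes(self):
        proto = StimulusProtocol(step_amplitudes=(-50.0, 50.0))
        ss = SweepSet(proto, {a: _step_trace(proto, -65, -65) for a in (-50.0, 50.0)})
        with pytest.raises(ProtocolError):
            features.input_resistance(ss)


class TestTimeConstant:
    def test_pure_exponential_recovered(self):
        proto = StimulusProtocol(step_amplitudes=(-50.0,))
        t = proto.time()
        onset = proto.baseline_pre
        tau = 0.010
        v = -65.0 - 8.0 * (1 - np.exp(-np.clip(t - onset, 0, None) / tau))
        v[t < onset] = -65.0
        ss = SweepSet(proto, {-50.0: v})
        assert features.time_constant(ss) == pytest.approx(10.0, rel=0.01)

    def test_generator_rc_cell_recovered(self):
        p = make_quiet_params(spike_threshold=100.0)
        ss = synth.simulate_membrane(p, subthreshold_protocol(), seed=0)
        tau_true = p.membrane_capacitance / p.leak_conductance
        assert features.time_constant(ss) == pytest.approx(tau_true, rel=0.01)


class TestSag:
    def test_passive_membrane_no_sag(self):
        p = make_quiet_params(spike_threshold=100.0)
        ss = synth.simulate_membrane(p, subthreshold_protocol(), seed=0)
        # residual settling gives a small *negative* value; sag is never
        # spuriously positive on a passive membrane
        assert features.sag(ss) < 0.01
        assert abs(features.sag(ss)) < 0.05

    def test_sag_conductance_strictly_increases_sag(self):
        vals = []
        for gsag in (0.0, 0.5, 1.5, 3.0):
            p = make_quiet_params(spike_threshold=100.0, sag_conductance=gsag)
            ss = synth.simulate_membrane(p, subthreshold_protocol(), seed=0)
            vals.append(features.sag(ss))
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_short_step_rejected(self):
        proto = StimulusProtocol(step_amplitudes=(-50.0,), step_duration=0.1)
        ss = SweepSet(proto, {-50.0: _step_trace(proto, -65, -70)})
        with pytest.raises(ProtocolError):
            features.sag(ss)


class TestSuprathresholdFeatures:
    def test_rheobase_first_spiking_amplitude(self):
        proto = suprathreshold_protocol()
        traces = {}
        for a in proto.step_amplitudes:
            if a >= 300.0:
                traces[a] = _gaussian_spike_trace(proto, -65.0, [0.5])
            else:
                traces[a] = np.full(proto.n_samples, -65.0)
        ss = SweepSet(proto, traces)
        assert features.rheobase(ss) == 300.0

    def test_rheobase_nan_when_silent(self):
        proto = suprathreshold_protocol()
        ss = SweepSet(
            proto, {a: np.full(proto.n_samples, -65.0) for a in proto.step_amplitudes}
        )
        assert np.isnan(features.rheobase(ss))

    def test_rheobase_matches_analytic_threshold_current(self):
        """Noiseless integrate-and-fire: the extracted rheobase is the
        smallest grid step at or above gL (V_th - E_L)."""
        # I* = 10 nS * 39.5 mV = 395 pA -> first spiking grid step is 400 pA
        p = make_quiet_params(spike_threshold=-25.5)
        ss = synth.simulate_membrane(p, suprathreshold_protocol(), seed=0)
        assert features.rheobase(ss) == 400.0

    def test_gaussian_spike_width_fwhm(self):
        """For templates whose base sits at the detection threshold the
        extracted width is the Gaussian FWHM 2.355 sigma."""
        proto = suprathreshold_protocol()
        sigma_ms = 0.25
        traces = {a: np.full(proto.n_samples, -0.5) for a in proto.step_amplitudes}
        traces[300.0] = _gaussian_spike_trace(
            proto, -0.5, [0.3, 0.6], peak=40.0, sigma_ms=sigma_ms
        )
        ss = SweepSet(proto, traces)
        width = features.spike_width(ss, rheo=300.0)
        assert width == pytest.approx(2.355 * sigma_ms, rel=0.03)

    def test_max_firing_rate_equals_bruteforce_count(self, fs_sweeps):
        _, sup = fs_sweeps
        proto = sup.protocol
        t0, t1 = proto.baseline_pre, proto.baseline_pre + proto.step_duration
        counts = []
        for amp in sup.amplitudes:
            train = features.detect_spikes(sup.get(amp), proto.sampling_rate)
            counts.append(sum(t0 <= t <= t1 for t in train.spike_times))
        assert features.max_firing_rate(sup) == max(counts) / proto.step_duration

    def test_isi_stats_periodic_train(self):
        proto = suprathreshold_protocol()
        traces = {a: np.full(proto.n_samples, -65.0) for a in proto.step_amplitudes}
        times = list(np.arange(0.2, 1.0, 0.010))
        traces[300.0] = _gaussian_spike_trace(proto, -65.0, times)
        traces[400.0] = _gaussian_spike_trace(proto, -65.0, times)
        ss = SweepSet(proto, traces)
        ar, cv, _ = features.isi_stats(ss, rheo=300.0)
        assert ar == pytest.approx(1.0, abs=1e-6)
        assert cv == pytest.approx(0.0, abs=1e-6)

    def test_isi_stats_arithmetic_oracle(self):
        """ISIs of 10, 12, 15, 20 ms: AR = 2 and CV = sd/mean with the
        sample (n-1) standard deviation."""
        proto = suprathreshold_protocol()
        traces = {a: np.full(proto.n_samples, -65.0) for a in proto.step_amplitudes}
        spike_times = 0.2 + np.cumsum([0.0, 0.010, 0.012, 0.015, 0.020])
        traces[300.0] = _gaussian_spike_trace(proto, -65.0, [0.5])
        traces[400.0] = _gaussian_spike_trace(proto, -65.0, spike_times)
        ss = SweepSet(proto, traces)
        ar, cv, _ = features.isi_stats(ss, rheo=300.0)
        isis = np.array([10.0, 12.0, 15.0, 20.0])
        assert ar == pytest.approx(2.0, abs=0.01)
        assert cv == pytest.approx(np.std(isis, ddof=1) / isis.mean(), abs=0.01)

    def test_isi_sweep_fallback_noted(self):
        proto = StimulusProtocol(step_amplitudes=(800.0, 850.0))
        times = list(np.arange(0.2, 0.9, 0.010))
        traces = {
            800.0: _gaussian_spike_trace(proto, -65.0, times),
            850.0: _gaussian_spike_trace(proto, -65.0, times),
        }
        ss = SweepSet(proto, traces)
        ar, cv, notes = features.isi_stats(ss, rheo=800.0)
        assert notes and "850" in notes[0]


class TestExtractFeatures:
    def test_passive_only_flags(self, fs_sweeps):
        sub, _ = fs_sweeps
        f = features.extract_features(sub, None)
        assert all(f.valid[n] for n in features.SUBTHRESHOLD_FEATURES)
        assert not any(f.valid[n] for n in features.FEATURE_NAMES[3:])

    def test_full_extraction_valid_and_idempotent(self, fs_sweeps, fs_features):
        assert all(fs_features.valid[n] for n in features.FEATURE_NAMES)
        again = features.extract_features(*fs_sweeps)
        assert np.array_equal(again.to_array(), fs_features.to_array())

    def test_invariant_to_trailing_baseline(self, fs_params):
        """Padding the post-step baseline never changes any feature."""
        protoA = subthreshold_protocol()
        ssA = synth.simulate_membrane(fs_params, protoA, seed=21)
        protoB = StimulusProtocol(
            step_amplitudes=protoA.step_amplitudes, baseline_post=0.2
        )
        extra = protoB.n_samples - protoA.n_samples
        ssB = SweepSet(
            protoB,
            {
                a: np.concatenate([ssA.get(a), np.full(extra, ssA.get(a)[-1])])
                for a in ssA.amplitudes
            },
        )
        fA = features.extract_features(ssA)
        fB = features.extract_features(ssB)
        assert np.array_equal(
            fA.to_array(features.SUBTHRESHOLD_FEATURES),
            fB.to_array(features.SUBTHRESHOLD_FEATURES),
        )
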