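"""Current-trace analytics: event detection on synthetic ground truth,
log-normal dwell fits, event rates, and the grafting-density estimators."""
import math

import numpy as np
import pytest

from fgpore.synthetic_data import TraceSpec, gen_trace, lognormal_params
from fgpore.trace_analysis import (
    CurrentTrace,
    Event,
    detect_events,
    dwell_lognormal_fit,
    event_rate,
    grafting_from_conductance,
    noise_psd,
    psd_slope,
    read_trace,
    sauerbrey_spacing,
    triangular_spacing,
    write_events,
)


def flat_trace(seed=0, duration=10.0, fs=50000.0, sd=0.003):
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    return CurrentTrace(current=7.0 + rng.normal(0, sd, n), sampling_rate=fs,
                        voltage=100.0)


class TestDetection:
    def test_pure_noise_yields_no_events(self):
        assert detect_events(flat_trace(), entry_threshold=6.0) == []

    def test_injected_events_recovered_unbiased(self):
        spec = TraceSpec(duration=120.0, event_rate=1.5, seed=4)
        trace, truth = gen_trace(spec)
        events = detect_events(trace)
        assert len(events) >= 0.95 * len(truth)
        st = dwell_lognormal_fit(events)
        true_mean = np.mean([e.dwell for e in truth])
        true_dg = np.mean([e.blockade for e in truth])
        assert np.mean([e.dwell for e in events]) == pytest.approx(true_mean, rel=0.1)
        assert st.blockade_mean == pytest.approx(true_dg, rel=0.1)

    def test_baseline_shift_invariance(self):
        spec = TraceSpec(duration=30.0, seed=5)
        trace, _ = gen_trace(spec)
        shifted = CurrentTrace(current=trace.current + 2.5,
                               sampling_rate=trace.sampling_rate,
                               voltage=trace.voltage)
        e1 = detect_events(trace)
        e2 = detect_events(shifted)
        assert len(e1) == len(e2)
        assert np.allclose([e.blockade for e in e1], [e.blockade for e in e2],
                           rtol=1e-6)

    def test_blockade_scales_inversely_with_voltage(self):
        spec = TraceSpec(duration=30.0, seed=6)
        trace, _ = gen_trace(spec)
        half_v = CurrentTrace(current=trace.current,
                              sampling_rate=trace.sampling_rate, voltage=50.0)
        e1 = detect_events(trace)
        e2 = detect_events(half_v)
        assert np.allclose([e.blockade for e in e2],
                           [2 * e.blockade for e in e1], rtol=1e-6)

    def test_merged_overlapping_dips(self):
        # two dips separated by less than the exit region merge into one event
        fs = 50000.0
        n = int(fs)
        current = np.full(n, 7.0)
        current[1000:1015] -= 0.03
        current[1015] -= 0.015  # gap never recrosses the exit threshold
        current[1016:1031] -= 0.03
        rng = np.random.default_rng(0)
        current += rng.normal(0, 0.002, n)
        trace = CurrentTrace(current=current, sampling_rate=fs, voltage=100.0)
        events = detect_events(trace)
        assert len(events) == 1
        assert events[0].dwell == pytest.approx(31 / fs, rel=0.2)

    def test_zero_voltage_rejected(self):
        t = flat_trace()
        t.voltage = 0.0
        with pytest.raises(ValueError, match="voltage"):
            detect_events(t)


class TestDwellStats:
    def test_lognormal_parameter_recovery(self):
        rng = np.random.default_rng(1)
        mu, s = lognormal_params(0.29e-3, 0.16e-3)
        events = [Event(start=0, dwell=d, blockade=0.2, amplitude=0.02)
                  for d in rng.lognormal(mu, s, 2000)]
        st = dwell_lognormal_fit(events)
        assert st.mu_log == pytest.approx(mu, abs=3 * s / math.sqrt(2000))
        assert st.dwell_mean == pytest.approx(0.29e-3, rel=0.05)
        assert st.dwell_sd == pytest.approx(0.16e-3, rel=0.12)

    def test_degenerate_dwells(self):
        events = [Event(start=0, dwell=1e-3, blockade=0.2, amplitude=0.02)
                  for _ in range(30)]
        st = dwell_lognormal_fit(events)
        assert st.sigma_log == 0.0
        assert st.dwell_mean == pytest.approx(1e-3)

    def test_warns_on_few_events(self):
        events = [Event(start=0, dwell=1e-3, blockade=0.2, amplitude=0.02)] * 5
        with pytest.warns(UserWarning, match="unstable"):
            dwell_lognormal_fit(events)


class TestEventRate:
    def test_empty(self):
        assert event_rate([], 10.0) == (0.0, 0.0)

    def test_bare_pore_figure_of_merit(self):
        events = [Event(start=i, dwell=1e-3, blockade=0.2, amplitude=0.02)
                  for i in range(170)]
        rate, se = event_rate(events, 100.0)
        assert rate == pytest.approx(1.7)
        assert se == pytest.approx(math.sqrt(170) / 100.0)

    def test_poisson_coverage(self):
        rng = np.random.default_rng(2)
        lam, T = 1.7, 100.0
        hits = 0
        for _ in range(200):
            n = rng.poisson(lam * T)
            rate, se = event_rate([None] * n, T)
            hits += abs(rate - lam) <= 2 * se
        assert hits >= 0.9 * 200


class TestGrafting:
    def test_printed_wildtype_numbers(self):
        est = grafting_from_conductance(70.0, 12.0, 0.54, pore_radius=24.0,
                                        height=20.0, protein_mw=65700.0)
        assert est.protein_count == 107
        assert est.area_per_protein == pytest.approx(28.0, abs=0.5)
        assert est.spacing == pytest.approx(5.7, abs=0.1)
        assert est.in_pore_density == pytest.approx(320.0, abs=10.0)

    def test_printed_mutant_numbers(self):
        est = grafting_from_conductance(70.3, 34.6, 0.34, pore_radius=25.0,
                                        height=20.0, protein_mw=62100.0)
        assert est.protein_count == 105
        assert est.spacing == pytest.approx(5.9, abs=0.1)

    def test_no_conductance_drop_rejected(self):
        with pytest.raises(ValueError):
            grafting_from_conductance(50.0, 50.0, 0.5, 24.0)

    def test_triangular_spacing_inverse(self):
        a = 5.7
        assert triangular_spacing(math.sqrt(3) / 2 * a**2) == pytest.approx(a)


class TestSauerbrey:
    def test_standard_convention_reproduces_5p6_nm(self):
        # -60 Hz on the third overtone, standard constant, square lattice
        res = sauerbrey_spacing(-60.0, overtone=3, protein_mw=65700.0,
                                convention="divide_overtone", lattice="square")
        assert res.spacing == pytest.approx(5.6, abs=0.1)

    def test_multiply_convention_differs(self):
        res = sauerbrey_spacing(-60.0, overtone=3, protein_mw=65700.0,
                                convention="multiply_overtone", lattice="square")
        assert res.spacing != pytest.approx(5.6, abs=0.1)

    def test_areal_mass_linear_in_shift(self):
        r1 = sauerbrey_spacing(-30.0)
        r2 = sauerbrey_spacing(-60.0)
        assert r2.areal_mass == pytest.approx(2 * r1.areal_mass)

    def test_adsorption_requires_negative_shift(self):
        with pytest.raises(ValueError):
            sauerbrey_spacing(0.0)

    def test_zero_molecular_weight(self):
        with pytest.raises(ValueError):
            sauerbrey_spacing(-60.0, protein_mw=0.0)


class TestNoise:
    def test_pink_noise_psd_slope(self):
        spec = TraceSpec(duration=30.0, event_rate=0.0, white_noise_sd=0.0,
                         pink_amplitude=1e-5, pink_exponent=1.0, seed=3)
        trace, truth = gen_trace(spec)
        assert truth == []
        assert psd_slope(trace, 1.0, 200.0) == pytest.approx(-1.0, abs=0.25)

    def test_white_noise_psd_flat(self):
        slope = psd_slope(flat_trace(), 10.0, 1000.0)
        assert slope == pytest.approx(0.0, abs=0.15)


class TestIO:
    def test_trace_and_event_round_trip(self, tmp_path):
        spec = TraceSpec(duration=2.0, seed=7)
        trace, _ = gen_trace(spec)
        tpath = tmp_path / "trace.tsv"
        np.savetxt(tpath, np.c_[trace.times, trace.current])
        back = read_trace(tpath, voltage=trace.voltage)
        assert back.sampling_rate == pytest.approx(trace.sampling_rate, rel=1e-6)
        assert np.allclose(back.current, trace.current)
        events = detect_events(trace)
        epath = tmp_path / "events.tsv"
        write_events(events, epath)
        data = np.loadtxt(epath, skiprows=1)
        assert data.shape[0] == len(events)
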