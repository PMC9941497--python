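"""Signal chain: smoothing, bands, events, QC, scoring, aggregation."""

import numpy as np
import pytest

from perivasc.dynamics import (
    BANDS,
    band_decompose,
    detect_oscillation_events,
    pvs_area,
    qc_side_correlation,
    score_sleep_states,
    scoring_accuracy,
    smooth_savgol,
    summarize_episodes,
)
from perivasc.synth import (
    Hypnogram,
    HypnogramSpec,
    SleepState,
    StateBandParams,
    VesselTrace,
    make_ecog_emg,
    make_hypnogram,
    make_vessel_trace,
)


class TestSavgol:
    def test_cubic_polynomial_reproduced_exactly(self):
        t = np.linspace(0, 5, 500)
        y = 2 - t + 0.3 * t ** 2 - 0.05 * t ** 3
        out = smooth_savgol(y, fs=100.0)
        assert np.allclose(out, y, atol=1e-9)

    def test_constant_preserved(self):
        out = smooth_savgol(np.full(300, 7.5), fs=100.0)
        assert np.allclose(out, 7.5)

    def test_noise_variance_reduced_at_least_threefold(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 10, 1000)
        truth = 1 + 0.5 * t - 0.02 * t ** 3
        noisy = truth + rng.normal(0, 0.1, t.size)
        out = smooth_savgol(noisy, fs=100.0)
        sl = slice(20, -20)  # exclude filter edge effects
        assert (np.var((noisy - truth)[sl])
                / np.var((out - truth)[sl])) >= 3.0

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="window"):
            smooth_savgol(np.zeros(100), fs=20.0)


class TestBandDecompose:
    def test_vlf_sinusoid_lands_in_vlf_band(self):
        fs = 100.0
        t = np.arange(0, 300, 1 / fs)
        sig = np.sin(2 * np.pi * 0.2 * t)
        bands = band_decompose(sig, fs)
        v_in = np.var(bands["VLF"])
        assert v_in >= 0.90 * np.var(sig)
        assert np.var(bands["LF"]) <= 0.05 * np.var(sig)

    def test_dc_offset_only_in_continuous_band(self):
        fs = 100.0
        sig = np.full(int(60 * fs), 5.0)
        bands = band_decompose(sig, fs)
        assert np.median(bands["continuous"]) == pytest.approx(5.0, rel=1e-6)
        for name in ("VLF", "LF", "respiratory", "cardiac"):
            assert np.max(np.abs(bands[name])) < 1e-6

    def test_cardiac_sinusoid_rejected_from_vlf(self):
        fs = 100.0
        t = np.arange(0, 200, 1 / fs)
        sig = np.sin(2 * np.pi * 10.0 * t)
        bands = band_decompose(sig, fs)
        # the VLF filter's startup transient rings for tens of seconds;
        # judge leakage away from the trace edges
        interior = slice(int(50 * fs), -int(50 * fs))
        assert np.var(bands["cardiac"][interior]) >= 0.90 * np.var(sig)
        assert np.max(np.abs(bands["VLF"][interior])) < 0.01

    def test_low_fs_rejects_cardiac_band(self):
        with pytest.raises(ValueError, match="cardiac"):
            band_decompose(np.zeros(1000), fs=25.0)


def brute_force_events(y, fs):
    """Independent O(n) scan: strict neighbour extrema + alternation."""
    mins, maxs = [], []
    kinds = []
    idx = []
    for i in range(1, len(y) - 1):
        if y[i] > y[i - 1] and y[i] > y[i + 1]:
            idx.append(i)
            kinds.append(1)
        elif y[i] < y[i - 1] and y[i] < y[i + 1]:
            idx.append(i)
            kinds.append(-1)
    keep = []
    for i, k in zip(idx, kinds):
        if keep and keep[-1][1] == k:
            if (k == 1 and y[i] > y[keep[-1][0]]) or \
               (k == -1 and y[i] < y[keep[-1][0]]):
                keep[-1] = (i, k)
        else:
            keep.append((i, k))
    mins = [i for i, k in keep if k == -1]
    maxs = [i for i, k in keep if k == 1]
    out = []
    for m in mins:
        later = [p for p in maxs if p > m]
        if not later:
            break
        p = later[0]
        pp = (later[1] - p) / fs if len(later) > 1 else np.nan
        out.append((m, p, y[p] - y[m], pp))
    return out


class TestOscillationEvents:
    def test_sinusoid_amplitude_and_period(self):
        fs = 100.0
        f, a = 0.5, 1.7
        t = np.arange(0, 20, 1 / fs)
        ev = detect_oscillation_events(a * np.sin(2 * np.pi * f * t), fs)
        amps = [e.pt_amplitude for e in ev]
        pps = [e.pp_period for e in ev if np.isfinite(e.pp_period)]
        assert np.allclose(amps, 2 * a, rtol=0.01)
        assert np.allclose(pps, 1 / f, atol=1 / fs)

    def test_constant_signal_no_events(self):
        assert detect_oscillation_events(np.zeros(1000), 100.0) == []

    def test_agrees_with_brute_force_on_random_band_signal(self):
        rng = np.random.default_rng(3)
        fs = 100.0
        sig = band_decompose(rng.standard_normal(5000), fs)["LF"]
        ev = detect_oscillation_events(sig, fs)
        ref = brute_force_events(sig, fs)
        assert len(ev) == len(ref)
        for e, (m, p, amp, pp) in zip(ev, ref):
            assert e.pt_amplitude == pytest.approx(amp)
            assert e.t_peak == pytest.approx(p / fs)
            if np.isfinite(pp):
                assert e.pp_period == pytest.approx(pp)

    def test_two_summed_in_band_sinusoids_match_brute_force(self):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        sig = np.sin(2 * np.pi * 0.15 * t) + 0.4 * np.sin(
            2 * np.pi * 0.25 * t + 1.0)
        ev = detect_oscillation_events(sig, fs)
        ref = brute_force_events(sig, fs)
        assert [e.pt_amplitude for e in ev] == pytest.approx(
            [r[2] for r in ref])


class TestQC:
    def test_parallel_edges_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        left = np.cumsum(rng.normal(0, 0.1, 500))
        ok, r = qc_side_correlation(left, left + 3.0, "lumen")
        assert ok and r == pytest.approx(1.0)

    def test_independent_noise_fails(self):
        rng = np.random.default_rng(1)
        ok, r = qc_side_correlation(rng.normal(0, 1, 500),
                                    rng.normal(0, 1, 500), "endfoot")
        assert not ok and abs(r) < 0.2

    def test_threshold_is_inclusive(self):
        # construct series with known correlation ~0.8 via mixing
        rng = np.random.default_rng(2)
        n = 200_000
        shared = rng.normal(0, 1, n)
        a = shared + rng.normal(0, 0.5, n)
        b = shared + rng.normal(0, 0.5, n)
        ok, r = qc_side_correlation(a, b, "lumen")
        assert r == pytest.approx(0.8, abs=0.005)
        assert ok == (r >= 0.8)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            qc_side_correlation(np.ones(200), np.arange(200.0), "lumen")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100"):
            qc_side_correlation(np.arange(50.0), np.arange(50.0), "lumen")


class TestScoring:
    def test_round_trip_accuracy_on_ten_minute_hypnograms(self):
        for hs, ps_seed in ((0, 1), (1, 2)):
            h = make_hypnogram(HypnogramSpec(n_cycles=2, ma_rate=0.01),
                               seed=hs)
            ps = make_ecog_emg(h, seed=ps_seed)
            acc = scoring_accuracy(h, score_sleep_states(ps))
            assert acc >= 0.95

    def test_theta_delta_below_half_is_never_rem(self):
        """A delta-dominant low-EMG segment scores NREM, not REM."""
        h = Hypnogram([(SleepState.WBS, 0.0, 15.0),
                       (SleepState.NREM, 15.0, 135.0)])
        ps = make_ecog_emg(h, seed=0)
        scored = score_sleep_states(ps)
        t = np.arange(20.0, 130.0, 0.5)
        labels = scored.states_at(t)
        is_nrem = np.array([l == SleepState.NREM for l in labels])
        assert is_nrem.mean() > 0.95
        assert not any(l == SleepState.REM for l in labels)

    def test_half_second_emg_burst_not_scored_as_ma(self):
        """Arousals below 1 s are not microarousals."""
        h = Hypnogram([(SleepState.WBS, 0.0, 15.0),
                       (SleepState.NREM, 15.0, 135.0)])
        ps = make_ecog_emg(h, seed=4)
        i0 = int(60.0 * ps.fs)
        ps.emg[i0:i0 + int(0.5 * ps.fs)] *= 8.0  # 0.5 s burst
        scored = score_sleep_states(ps)
        assert not any(iv[0] == SleepState.MA for iv in scored.intervals)

    def test_nan_input_rejected(self):
        from perivasc.synth import PhysioSignals

        ps = PhysioSignals(ecog=np.full(1000, np.nan),
                           emg=np.zeros(1000), fs=500.0)
        with pytest.raises(ValueError, match="NaN"):
            score_sleep_states(ps)


class TestSummaries:
    def make_sine_trace(self, a_rel=0.1, f=0.2, T=120.0, fs=100.0):
        """Lumen-only oscillation with a constant endfoot tube."""
        t = np.arange(0, T, 1 / fs)
        lumen = 20.0 * (1 + a_rel / 2 * np.sin(2 * np.pi * f * t))
        endfoot = np.full_like(t, 28.0)
        states = np.array([SleepState.NREM] * len(t), dtype=object)
        return VesselTrace(vessel_id="v", kind="penetrating_arteriole",
                           fs=fs, t=t, lumen_d=lumen, endfoot_d=endfoot,
                           pvs_w=endfoot - lumen, state_per_sample=states)

    def test_single_sinusoid_relative_area_amplitude(self):
        # drive at the VLF band's centre frequency where the zero-phase
        # Butterworth gain is unity
        f = np.sqrt(0.1 * 0.3)
        tr = self.make_sine_trace(a_rel=0.05, f=f)
        # episode interior to the trace: the band filters run over the
        # whole recording, so their edge transients stay outside
        h = Hypnogram([(SleepState.NREM, 20.0, 100.0)])
        out = summarize_episodes(tr, h)
        vlf = [s for s in out if s.band == "VLF"][0]
        # lumen-only oscillation: area P-T amplitude equals
        # pi/4 (d_max^2 - d_min^2); relative to the median area
        d_hi, d_lo = 20.0 * 1.025, 20.0 * 0.975
        a_area = np.pi / 4 * (d_hi ** 2 - d_lo ** 2)
        a_expected = a_area / np.median(pvs_area(tr.lumen_d, tr.endfoot_d))
        assert vlf.a_rel == pytest.approx(a_expected, rel=0.02)
        assert vlf.p_pp == pytest.approx(1 / f, rel=0.02)
        assert vlf.state == SleepState.NREM

    def test_two_episode_median_is_midpoint(self):
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        a1, a2 = 0.04, 0.12
        amp = np.where(t < 60, a1, a2)
        lumen = 20.0 * (1 + amp / 2 * np.sin(2 * np.pi * 0.2 * t))
        endfoot = np.full_like(t, 28.0)
        states = np.array([SleepState.NREM] * len(t), dtype=object)
        tr = VesselTrace("v", "penetrating_arteriole", fs, t, lumen,
                         endfoot, endfoot - lumen, states)
        h = Hypnogram([(SleepState.NREM, 0.0, 60.0),
                       (SleepState.NREM, 60.0, 120.0)])
        out = summarize_episodes(tr, h)
        vlf = [s for s in out if s.band == "VLF"][0]
        singles = []
        for t0, t1, a in ((0.0, 60.0, a1), (60.0, 120.0, a2)):
            h1 = Hypnogram([(SleepState.NREM, t0, t1)])
            s1 = [s for s in summarize_episodes(tr, h1)
                  if s.band == "VLF"][0]
            singles.append(s1.a_rel)
        assert vlf.n_episodes == 2
        assert vlf.a_rel == pytest.approx(np.mean(singles), rel=0.05)

    def test_state_without_episodes_absent(self):
        tr = self.make_sine_trace()
        h = Hypnogram([(SleepState.NREM, 0.0, 120.0)])
        out = summarize_episodes(tr, h)
        assert all(s.state == SleepState.NREM for s in out)

    def test_respiratory_cardiac_flagged_unreliable(self):
        tr = self.make_sine_trace()
        h = Hypnogram([(SleepState.NREM, 0.0, 120.0)])
        out = summarize_episodes(tr, h)
        for s in out:
            assert s.unreliable == (s.band in ("respiratory", "cardiac"))


class TestRoundTrip:
    def test_generated_band_amplitudes_recovered_within_ten_percent(self):
        """Known VLF/LF relative amplitudes survive the full chain."""
        spec = HypnogramSpec(wbs_s=10, nrem_s=45, is_s=15, rem_s=15,
                             was_s=10, n_cycles=7)
        h = make_hypnogram(spec, seed=11)
        p = StateBandParams(noise_sd=0.03)
        tr = make_vessel_trace(h, p, seed=12)
        from perivasc.dynamics import smooth_savgol as sg

        lum = sg(tr.lumen_d, tr.fs)
        bands = band_decompose(lum, tr.fs)
        n_checked = 0
        n_episodes = 0
        for state in (SleepState.NREM, SleepState.IS):
            for band in ("VLF", "LF"):
                target = p.bands[state][band][0]
                recovered = []
                for s, t0, t1 in h.episodes():
                    if s != state:
                        continue
                    i0 = int((t0 - tr.t[0]) * tr.fs)
                    i1 = int((t1 - tr.t[0]) * tr.fs)
                    ev = detect_oscillation_events(bands[band][i0:i1],
                                                   tr.fs)
                    if ev:
                        amp = np.mean([e.pt_amplitude for e in ev])
                        recovered.append(
                            amp / np.median(lum[i0:i1]))
                n_episodes += len(recovered)
                assert np.median(recovered) == pytest.approx(target,
                                                             rel=0.10)
                n_checked += 1
        assert n_checked == 4 and n_episodes >= 20
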