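"""Signal chain: smoothing, band decomposition, oscillation events,
quality control, sleep scoring and episode aggregation.

Vessel-diameter series are denoised with a Savitzky–Golay filter (0.1 s
window, order 3) and decomposed into five frequency bands with zero-phase
order-3 Butterworth filters: continuous (0–0.1 Hz), VLF (0.1–0.3 Hz),
LF (0.3–1 Hz), respiratory (1–4 Hz) and cardiac (4–15 Hz).  In each band,
alternating local extrema define oscillation events: the peak-to-trough
(P–T) amplitude of each trough→peak pair and the peak-to-peak (P–P)
period between consecutive maxima.  Episode aggregation follows the
two-level scheme of the source measurements: mean within an episode
(a contiguous single-state span), median across episodes per
(vessel, state, band).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, savgol_filter, sosfiltfilt
from scipy.stats import pearsonr

from perivasc.synth import (
    Hypnogram,
    PhysioSignals,
    SleepState,
    VesselTrace,
)


@dataclass(frozen=True)
class BandDef:
    name: str
    f_lo: float
    f_hi: float


#: the five analysis bands
BANDS: tuple[BandDef, ...] = (
    BandDef("continuous", 0.0, 0.1),
    BandDef("VLF", 0.1, 0.3),
    BandDef("LF", 0.3, 1.0),
    BandDef("respiratory", 1.0, 4.0),
    BandDef("cardiac", 4.0, 15.0),
)

BAND_BY_NAME = {b.name: b for b in BANDS}

#: bands whose endfoot/PVS amplitudes sit at the optical resolution limit
#: in the recordings this pipeline emulates; computed but flagged
UNRELIABLE_PVS_BANDS = frozenset({"respiratory", "cardiac"})


def smooth_savgol(signal: np.ndarray, fs: float, window_s: float = 0.1,
                  order: int = 3) -> np.ndarray:
    """Savitzky–Golay smoothing with a 0.1 s window and order 3.

    The window is the odd sample count nearest to ``window_s * fs``.
    """
    w = int(round(window_s * fs))
    if w % 2 == 0:
        w += 1
    if w < order + 2:
        raise ValueError(
            f"window of {w} samples too short for order {order}; need "
            f"fs >= {(order + 2) / window_s:.0f} Hz")
    return savgol_filter(np.asarray(signal, dtype=float), w, order)


def band_decompose(signal: np.ndarray, fs: float,
                   bands: tuple[BandDef, ...] = BANDS
                   ) -> dict[str, np.ndarray]:
    """Zero-phase order-3 Butterworth decomposition into the five bands.

    The continuous band is the 0.1 Hz low-pass. A band whose upper edge
    reaches the Nyquist frequency is rejected.
    """
    signal = np.asarray(signal, dtype=float)
    out: dict[str, np.ndarray] = {}
    for b in bands:
        if fs <= 2 * b.f_hi:
            raise ValueError(
                f"fs={fs} Hz cannot resolve band {b.name} "
                f"(upper edge {b.f_hi} Hz)")
        if b.f_lo <= 0:
            sos = butter(3, b.f_hi, btype="lowpass", fs=fs, output="sos")
        else:
            sos = butter(3, [b.f_lo, b.f_hi], btype="bandpass", fs=fs,
                         output="sos")
        out[b.name] = sosfiltfilt(sos, signal)
    return out


@dataclass
class OscillationEvent:
    """One oscillation: a trough→peak pair within a band signal."""

    band: str
    t_trough: float
    t_peak: float
    pt_amplitude: float
    pp_period: float  # NaN for the last peak of a run


def _alternating_extrema(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local minima and maxima with strict alternation.

    Of two same-kind neighbours the more extreme one is kept.  Interior
    extrema only (plateaus treated by first-sample convention).
    """
    dy = np.diff(y)
    # sign of slope, propagating through zero-slope plateaus
    s = np.sign(dy)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    idx = np.nonzero(s[1:] != s[:-1])[0] + 1
    kinds = np.where(s[idx] < 0, 1, -1)  # +1 max, -1 min at index idx
    if len(idx) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    # enforce alternation: among consecutive same-kind extrema keep the
    # more extreme one
    keep_idx: list[int] = []
    keep_kind: list[int] = []
    for i, k in zip(idx, kinds):
        if keep_idx and keep_kind[-1] == k:
            better = (y[i] > y[keep_idx[-1]]) if k == 1 else \
                     (y[i] < y[keep_idx[-1]])
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
            keep_kind.append(k)
    keep_idx_arr = np.array(keep_idx, dtype=int)
    keep_kind_arr = np.array(keep_kind, dtype=int)
    return (keep_idx_arr[keep_kind_arr == -1],
            keep_idx_arr[keep_kind_arr == 1])


def detect_oscillation_events(band_signal: np.ndarray, fs: float,
                              band: str = "", t0: float = 0.0
                              ) -> list[OscillationEvent]:
    """Oscillation events from alternating local extrema.

    Each consecutive (trough, following peak) pair yields an event whose
    P–T amplitude is the signal difference; the P–P period is the time to
    the next peak (NaN for the last).
    """
    y = np.asarray(band_signal, dtype=float)
    mins, maxs = _alternating_extrema(y)
    events: list[OscillationEvent] = []
    if len(mins) == 0 or len(maxs) == 0:
        return events
    for m in mins:
        later = maxs[maxs > m]
        if len(later) == 0:
            break
        p = later[0]
        nxt = later[1] if len(later) > 1 else None
        pp = (nxt - p) / fs if nxt is not None else np.nan
        events.append(OscillationEvent(
            band=band,
            t_trough=t0 + m / fs,
            t_peak=t0 + p / fs,
            pt_amplitude=float(y[p] - y[m]),
            pp_period=float(pp),
        ))
    return events


QC_THRESHOLDS = {"lumen": 0.8, "endfoot": 0.7}


def qc_side_correlation(left_edge: np.ndarray, right_edge: np.ndarray,
                        structure: str) -> tuple[bool, float]:
    """Pearson correlation QC between the two edge-position series.

    Because rigid tissue motion moves both edges of a structure together,
    poor correlation indicates a mistraced edge.  Pass iff r >= 0.8 for
    the lumen or r >= 0.7 for the endfoot tube (inclusive).
    """
    if structure not in QC_THRESHOLDS:
        raise ValueError(f"unknown structure {structure!r}")
    left = np.asarray(left_edge, dtype=float)
    right = np.asarray(right_edge, dtype=float)
    if len(left) < 100:
        raise ValueError("need >= 100 paired samples for the QC correlation")
    if np.ptp(left) == 0 or np.ptp(right) == 0:
        raise ValueError("undefined correlation: constant edge series")
    r = float(pearsonr(left, right).statistic)
    return r >= QC_THRESHOLDS[structure], r


# ---------------------------------------------------------------------------
# Sleep scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoringParams:
    """Rule thresholds for epoch-wise sleep scoring.

    ``emg_threshold`` separates wake from sleep epochs on EMG RMS; if
    None it is set adaptively to the geometric mean of the 10th and 90th
    percentile of epoch RMS.  IS requires sigma power above
    ``is_sigma_rise`` times and delta below ``is_delta_fall`` times the
    running NREM baseline.  Microarousals are wake-scored runs of 1–10 s
    inside NREM/IS whose ECoG total power is below ``ma_power_factor``
    times the NREM baseline.
    """

    epoch_s: float = 1.0
    emg_threshold: Optional[float] = None
    theta_delta_rem: float = 0.5
    is_sigma_rise: float = 2.0
    is_delta_fall: float = 0.6
    ma_power_factor: float = 0.75
    baseline_epochs: int = 60


def _epoch_power(x: np.ndarray, fs: float, epoch: float) -> np.ndarray:
    n_e = int(len(x) / (fs * epoch))
    k = int(round(fs * epoch))
    return (x[:n_e * k].reshape(n_e, k) ** 2).mean(axis=1)


def score_sleep_states(physio: PhysioSignals,
                       params: Optional[ScoringParams] = None) -> Hypnogram:
    """Rule-based epoch-wise sleep scoring from ECoG/EMG.

    Per 1 s epoch: band powers delta 0.5–4, theta 5–9, sigma 9–16 Hz.
    High EMG → wake; low EMG with sigma and theta elevated and delta
    reduced relative to the running NREM baseline → IS; low EMG with
    theta/delta > 0.5 → REM; otherwise NREM.  Wake runs of 1–10 s inside
    NREM/IS with an ECoG total-power drop become MA.  Wake runs adjacent
    to sleep are relabelled contextually (before NREM → WBS, the 10 s
    after REM → WAS), matching how those states are defined.
    """
    if params is None:
        params = ScoringParams()
    ecog = np.asarray(physio.ecog, dtype=float)
    emg = np.asarray(physio.emg, dtype=float)
    if np.any(~np.isfinite(ecog)) or np.any(~np.isfinite(emg)):
        raise ValueError("NaN/inf in physio signals; filter the input first")
    fs = physio.fs

    band_sigs = {}
    for name, (lo, hi) in [("delta", (0.5, 4.0)), ("theta", (5.0, 9.0)),
                           ("sigma", (9.0, 16.0))]:
        sos = butter(3, [lo, hi], btype="bandpass", fs=fs, output="sos")
        band_sigs[name] = sosfiltfilt(sos, ecog)

    delta = _epoch_power(band_sigs["delta"], fs, params.epoch_s)
    theta = _epoch_power(band_sigs["theta"], fs, params.epoch_s)
    sigma = _epoch_power(band_sigs["sigma"], fs, params.epoch_s)
    total = _epoch_power(ecog, fs, params.epoch_s)
    emg_rms = np.sqrt(_epoch_power(emg, fs, params.epoch_s))
    n_e = len(delta)

    thr = params.emg_threshold
    if thr is None:
        # sleep-heavy recordings leave wake in the far upper tail only
        lo, hi = np.percentile(emg_rms, [10, 99])
        thr = float(np.sqrt(max(lo, 1e-12) * max(hi, lo, 1e-12)))
    wake = emg_rms > thr

    # first pass: NREM/REM among low-EMG epochs; REM is low-amplitude
    # theta activity, so it additionally requires delta clearly below the
    # delta level of the surrounding NREM sleep (checked in pass two)
    labels = np.empty(n_e, dtype=object)
    td = theta / np.maximum(delta, 1e-12)
    for i in range(n_e):
        if wake[i]:
            labels[i] = SleepState.QW
        elif td[i] > params.theta_delta_rem:
            labels[i] = SleepState.REM
        else:
            labels[i] = SleepState.NREM

    # second pass: IS against a causal running NREM baseline
    base_d = np.median(delta[labels == SleepState.NREM]) \
        if np.any(labels == SleepState.NREM) else np.median(delta)
    base_s = np.median(sigma[labels == SleepState.NREM]) \
        if np.any(labels == SleepState.NREM) else np.median(sigma)
    base_t = np.median(total[labels == SleepState.NREM]) \
        if np.any(labels == SleepState.NREM) else np.median(total)
    recent_d: list[float] = []
    recent_s: list[float] = []
    for i in range(n_e):
        bd = np.median(recent_d[-params.baseline_epochs:]) if recent_d \
            else base_d
        bs = np.median(recent_s[-params.baseline_epochs:]) if recent_s \
            else base_s
        if labels[i] == SleepState.NREM:
            if (sigma[i] > params.is_sigma_rise * bs
                    and delta[i] < params.is_delta_fall * bd):
                labels[i] = SleepState.IS
            else:
                recent_d.append(delta[i])
                recent_s.append(sigma[i])
        elif labels[i] == SleepState.REM:
            # REM with elevated sigma is IS misread through the ratio rule
            if sigma[i] > params.is_sigma_rise * bs:
                labels[i] = SleepState.IS
            elif delta[i] >= params.is_delta_fall * bd:
                # theta/delta ratio noise inside NREM: delta not reduced,
                # so this is not low-amplitude REM activity
                labels[i] = SleepState.NREM
                recent_d.append(delta[i])
                recent_s.append(sigma[i])

    # single-epoch REM/IS islands inside NREM are ratio noise, not state
    # transitions (real episodes last many epochs)
    runs = _runs(labels)
    for k, (lab, i0, i1) in enumerate(runs):
        if (lab in (SleepState.REM, SleepState.IS) and i1 - i0 == 1
                and k > 0 and k + 1 < len(runs)
                and runs[k - 1][0] == SleepState.NREM
                and runs[k + 1][0] == SleepState.NREM):
            labels[i0:i1] = SleepState.NREM

    # microarousals: short wake runs inside NREM/IS with ECoG power drop
    runs = _runs(labels)
    for k, (lab, i0, i1) in enumerate(runs):
        if lab != SleepState.QW:
            continue
        dur = (i1 - i0) * params.epoch_s
        prev_sleep = k > 0 and runs[k - 1][0] in (SleepState.NREM,
                                                  SleepState.IS)
        next_sleep = k + 1 < len(runs) and runs[k + 1][0] in (
            SleepState.NREM, SleepState.IS)
        # duration rule 1-10 s; the upper bound is inclusive because a
        # sub-10 s arousal can span a full 10 epochs after quantization
        if (prev_sleep and next_sleep and 1.0 <= dur <= 10.0
                and np.mean(total[i0:i1]) < params.ma_power_factor * base_t):
            if i1 - i0 == 1:
                # single-epoch candidate: a sub-second EMG burst can
                # dominate the epoch RMS; require the activation to span
                # both half-epochs (i.e. to truly last >= 1 s)
                k = int(round(fs * params.epoch_s))
                seg = emg[i0 * k:(i0 + 1) * k]
                half = len(seg) // 2
                rms_a = np.sqrt(np.mean(seg[:half] ** 2))
                rms_b = np.sqrt(np.mean(seg[half:] ** 2))
                if min(rms_a, rms_b) <= thr:
                    continue
            labels[i0:i1] = SleepState.MA

    # contextual wake relabels: WBS before NREM, WAS (10 s) after REM
    runs = _runs(labels)
    for k, (lab, i0, i1) in enumerate(runs):
        if lab != SleepState.QW:
            continue
        if k + 1 < len(runs) and runs[k + 1][0] == SleepState.NREM:
            labels[i0:i1] = SleepState.WBS
        if k > 0 and runs[k - 1][0] == SleepState.REM:
            n_was = min(i1 - i0, int(round(10.0 / params.epoch_s)))
            labels[i0:i0 + n_was] = SleepState.WAS

    runs = _runs(labels)
    intervals = [(lab, i0 * params.epoch_s, i1 * params.epoch_s)
                 for lab, i0, i1 in runs]
    return Hypnogram(intervals)


def _runs(labels: np.ndarray) -> list[tuple[SleepState, int, int]]:
    """Contiguous runs [(label, start, stop)), ...] of an object array."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


def scoring_accuracy(truth: Hypnogram, scored: Hypnogram,
                     dt: float = 0.1) -> float:
    """Per-sample label agreement between two hypnograms."""
    t0 = max(truth.t_start, scored.t_start)
    t1 = min(truth.t_end, scored.t_end)
    t = np.arange(t0 + dt / 2, t1, dt)
    a = truth.states_at(t)
    b = scored.states_at(t)
    return float(np.mean(a == b))


# ---------------------------------------------------------------------------
# Episode aggregation
# ---------------------------------------------------------------------------

@dataclass
class BandSummary:
    """Per (vessel, state, band) medians feeding the PVS area law.

    ``a_rel`` is the median relative P–T amplitude of the PVS
    cross-section area oscillation (dimensionless), ``p_pp`` the median
    lumen P–P period (s), ``A_med`` the median PVS cross-section area
    (um^2). ``unreliable`` marks respiratory/cardiac PVS amplitudes that
    sit below the optical resolution limit of the emulated recordings.
    """

    vessel_id: str
    state: SleepState
    band: str
    a_rel: float
    p_pp: float
    A_med: float
    r_lumen_med: float
    r_endfoot_med: float
    n_episodes: int
    unreliable: bool = False


def pvs_area(lumen_d: np.ndarray, endfoot_d: np.ndarray) -> np.ndarray:
    """PVS cross-section area (um^2) from the two diameters."""
    return np.pi / 4.0 * (np.asarray(endfoot_d) ** 2
                          - np.asarray(lumen_d) ** 2)


def summarize_episodes(trace: VesselTrace, hypnogram: Hypnogram,
                       bands: tuple[BandDef, ...] = BANDS[1:],
                       presmooth: bool = True,
                       min_cycles: float = 1.5) -> list[BandSummary]:
    """Aggregate oscillation statistics per (state, band).

    Within each episode (single-state hypnogram interval) the P–T
    amplitudes of the band-filtered PVS area signal are averaged and
    divided by the episode's median area (relative amplitude), and the
    lumen P–P periods are averaged.  Across episodes of a state the
    medians of those per-episode means populate the summary.  Episodes
    too short to hold ``min_cycles`` periods of a band contribute no
    events for it; states with no contributing episode are absent from
    the output.
    """
    fs = trace.fs
    lum = trace.lumen_d
    endf = trace.endfoot_d
    if presmooth:
        lum = smooth_savgol(lum, fs)
        endf = smooth_savgol(endf, fs)
    area = pvs_area(lum, endf)
    area_bands = band_decompose(area, fs, bands)
    lumen_bands = band_decompose(lum, fs, bands)

    # per-episode statistics
    rows: list[dict] = []
    for state, t0, t1 in hypnogram.episodes():
        i0 = int(np.ceil((t0 - trace.t[0]) * fs))
        i1 = int(np.floor((t1 - trace.t[0]) * fs))
        i0, i1 = max(i0, 0), min(i1, len(trace.t))
        if i1 - i0 < 4:
            continue
        a_med_ep = float(np.median(area[i0:i1]))
        r_l = float(np.median(lum[i0:i1])) / 2.0
        r_e = float(np.median(endf[i0:i1])) / 2.0
        for b in bands:
            f_ref = b.f_lo if b.f_lo > 0 else b.f_hi
            if (i1 - i0) / fs < min_cycles / f_ref:
                continue
            ev_a = detect_oscillation_events(area_bands[b.name][i0:i1], fs,
                                             band=b.name)
            ev_l = detect_oscillation_events(lumen_bands[b.name][i0:i1], fs,
                                             band=b.name)
            if not ev_a or not ev_l:
                continue
            amp = float(np.mean([e.pt_amplitude for e in ev_a]))
            periods = [e.pp_period for e in ev_l
                       if np.isfinite(e.pp_period)]
            if not periods:
                continue
            rows.append({
                "state": state, "band": b.name,
                "a_rel": amp / a_med_ep,
                "p_pp": float(np.mean(periods)),
                "A_med": a_med_ep, "r_l": r_l, "r_e": r_e,
            })

    df = pd.DataFrame(rows)
    out: list[BandSummary] = []
    if df.empty:
        return out
    for (state, band), g in df.groupby(["state", "band"], sort=False):
        out.append(BandSummary(
            vessel_id=trace.vessel_id, state=state, band=band,
            a_rel=float(g["a_rel"].median()),
            p_pp=float(g["p_pp"].median()),
            A_med=float(g["A_med"].median()),
            r_lumen_med=float(g["r_l"].median()),
            r_endfoot_med=float(g["r_e"].median()),
            n_episodes=len(g),
            unreliable=band in UNRELIABLE_PVS_BANDS,
        ))
    return out


def summaries_to_frame(summaries: list[BandSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "vessel_id": s.vessel_id, "state": s.state.value, "band": s.band,
        "a_rel": s.a_rel, "p_pp_s": s.p_pp, "A_med_um2": s.A_med,
        "r_lumen_um": s.r_lumen_med, "r_endfoot_um": s.r_endfoot_med,
        "n_episodes": s.n_episodes, "unreliable": s.unreliable,
    } for s in summaries])
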