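"""Synthetic recordings: hypnograms, vessel dynamics, linescans, ECoG/EMG.

The generators emulate the structure of natural-sleep two-photon
experiments in head-fixed mice: a sleep cycle ordered
WBS -> NREM -> IS -> REM -> WAS with optional microarousals, vessel lumen
and astrocyte endfoot-tube diameters carrying state-gated band-limited
vasomotion (VLF/LF largest in NREM/IS, REM dilation with PVS shrinkage,
arousal constriction with PVS enlargement), x-t linescan intensity stacks
with embedded ground truth, and ECoG/EMG with state-specific band powers.

All generators are deterministic for a fixed seed and parameter set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, lfilter, sosfiltfilt


class SleepState(str, Enum):
    """Sleep/wake states of the scoring scheme.

    MA (microarousal) only ever occurs inside NREM or IS spans.
    """

    QW = "QW"          # quiet wakefulness
    WHISK = "WHISK"    # spontaneous whisking
    LOCO = "LOCO"      # locomotion (includes whisking)
    WBS = "WBS"        # wakefulness before sleep (~15 s)
    NREM = "NREM"
    IS = "IS"          # intermediate state
    REM = "REM"
    WAS = "WAS"        # wakefulness after sleep (10 s)
    MA = "MA"          # microarousal (1-10 s, inside NREM/IS)


WAKE_STATES = frozenset(
    {SleepState.QW, SleepState.WHISK, SleepState.LOCO, SleepState.WBS,
     SleepState.WAS, SleepState.MA}
)
SLEEP_STATES = frozenset({SleepState.NREM, SleepState.IS, SleepState.REM})

#: canonical within-cycle order
CYCLE_ORDER = (SleepState.WBS, SleepState.NREM, SleepState.IS,
               SleepState.REM, SleepState.WAS)


@dataclass
class Hypnogram:
    """Ordered, contiguous, non-overlapping labelled intervals."""

    intervals: list[tuple[SleepState, float, float]]

    def __post_init__(self) -> None:
        prev_end = None
        for state, t0, t1 in self.intervals:
            if t1 <= t0:
                raise ValueError(f"interval for {state} has t1 <= t0")
            if prev_end is not None and not np.isclose(t0, prev_end):
                raise ValueError("hypnogram intervals must be contiguous")
            prev_end = t1

    @property
    def t_start(self) -> float:
        return self.intervals[0][1]

    @property
    def t_end(self) -> float:
        return self.intervals[-1][2]

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def states_at(self, t: np.ndarray) -> np.ndarray:
        """State label per sample (object array of SleepState)."""
        t = np.asarray(t, dtype=float)
        edges = np.array([iv[1] for iv in self.intervals] + [self.t_end])
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                      len(self.intervals) - 1)
        labels = np.array([iv[0] for iv in self.intervals], dtype=object)
        return labels[idx]

    def episodes(self) -> list[tuple[SleepState, float, float]]:
        """Alias: each interval is one single-state episode."""
        return list(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.value, t0, t1) for s, t0, t1 in self.intervals],
            columns=["state", "t0_s", "t1_s"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Hypnogram":
        return cls([(SleepState(r.state), float(r.t0_s), float(r.t1_s))
                    for r in df.itertuples()])

    @classmethod
    def from_csv(cls, path: str | Path) -> "Hypnogram":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class HypnogramSpec:
    """Durations (s) of one canonical sleep cycle plus microarousal rate.

    ``ma_rate`` is the Poisson rate (events/s) of microarousals inside
    NREM and IS spans; each microarousal duration is uniform in [1, 10) s.
    """

    wbs_s: float = 15.0
    nrem_s: float = 180.0
    is_s: float = 30.0
    rem_s: float = 60.0
    was_s: float = 10.0
    n_cycles: int = 1
    ma_rate: float = 0.0

    def cycle_durations(self) -> dict[SleepState, float]:
        return {
            SleepState.WBS: self.wbs_s,
            SleepState.NREM: self.nrem_s,
            SleepState.IS: self.is_s,
            SleepState.REM: self.rem_s,
            SleepState.WAS: self.was_s,
        }


def make_hypnogram(spec: HypnogramSpec, seed: int) -> Hypnogram:
    """Generate a hypnogram of ``n_cycles`` canonical sleep cycles.

    Microarousals are inserted as Poisson events within NREM and IS spans
    with durations uniform in [1, 10) s; an MA splits its host interval.
    Identical seed and spec give identical output.
    """
    durations = spec.cycle_durations()
    for name, d in [("wbs_s", spec.wbs_s), ("nrem_s", spec.nrem_s),
                    ("is_s", spec.is_s), ("rem_s", spec.rem_s),
                    ("was_s", spec.was_s)]:
        if d <= 0:
            raise ValueError(f"duration {name} must be positive, got {d}")
    if spec.ma_rate < 0:
        raise ValueError(f"ma_rate must be >= 0, got {spec.ma_rate}")
    if spec.n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {spec.n_cycles}")

    rng = np.random.default_rng(seed)
    intervals: list[tuple[SleepState, float, float]] = []
    t = 0.0
    for _ in range(spec.n_cycles):
        for state in CYCLE_ORDER:
            d = durations[state]
            if spec.ma_rate > 0 and state in (SleepState.NREM, SleepState.IS):
                intervals.extend(_insert_microarousals(
                    state, t, t + d, spec.ma_rate, rng))
            else:
                intervals.append((state, t, t + d))
            t += d
    return Hypnogram(intervals)


def _insert_microarousals(state: SleepState, t0: float, t1: float,
                          rate: float, rng: np.random.Generator
                          ) -> list[tuple[SleepState, float, float]]:
    """Split [t0, t1) of ``state`` by Poisson microarousal events."""
    span = t1 - t0
    n = rng.poisson(rate * span)
    events: list[tuple[float, float]] = []
    if n > 0:
        starts = np.sort(rng.uniform(t0, t1, size=n))
        durs = rng.uniform(1.0, 10.0, size=n)
        last_end = t0 + 0.5  # keep a sliver of host state at the edges
        for s, d in zip(starts, durs):
            e = s + d
            # require >= 2 s of host state between events so consecutive
            # microarousals are not mistaken for one long arousal
            if s >= last_end + 2.0 and e <= t1 - 0.5:
                events.append((s, e))
                last_end = e
    out: list[tuple[SleepState, float, float]] = []
    cursor = t0
    for s, e in events:
        if s > cursor:
            out.append((state, cursor, s))
        out.append((SleepState.MA, s, e))
        cursor = e
    if cursor < t1:
        out.append((state, cursor, t1))
    return out


# ---------------------------------------------------------------------------
# Vessel traces
# ---------------------------------------------------------------------------


def _default_medians(rem_dilation: float, arousal_constriction: float
                     ) -> dict[SleepState, tuple[float, float]]:
    """Per-state (lumen, endfoot) median diameters in um.

    Plausible placeholders for a penetrating arteriole, chosen to follow
    the qualitative pattern of the recordings: REM dilation with PVS
    shrinkage, constriction with PVS enlargement at arousals.
    """
    base_l, base_e = 19.0, 27.5  # NREM baseline
    rem_l = base_l * rem_dilation
    # endfoot follows the dilation only partially -> PVS shrinks in REM
    rem_e = base_e + 0.55 * (rem_l - base_l)
    ma_l = base_l * arousal_constriction
    ma_e = base_e + 0.55 * (ma_l - base_l)
    return {
        SleepState.QW: (20.0, 28.2),
        SleepState.WHISK: (20.8, 28.7),
        SleepState.LOCO: (21.8, 29.4),
        SleepState.WBS: (20.0, 28.2),
        SleepState.NREM: (base_l, base_e),
        SleepState.IS: (19.4, 27.8),
        SleepState.REM: (rem_l, rem_e),
        SleepState.WAS: (19.6, 28.0),
        SleepState.MA: (ma_l, ma_e),
    }


def _default_band_table() -> dict[SleepState, dict[str, tuple[float, float, float]]]:
    """Per (state, band): (lumen a_rel, endfoot a_rel, frequency Hz).

    ``a_rel`` is the relative peak-to-trough amplitude (fraction of the
    state median diameter).  VLF/LF are largest in NREM/IS, present but
    weaker in wake, nearly absent in REM; respiratory and cardiac
    components are small everywhere (near the optical resolution limit in
    the recordings this emulates).
    """
    def row(vlf, lf, resp=0.010, card=0.008, ef=0.30):
        return {
            "VLF": (vlf, vlf * ef, 0.2),
            "LF": (lf, lf * ef, 0.6),
            "respiratory": (resp, resp * ef, 2.0),
            "cardiac": (card, card * ef, 8.0),
        }

    return {
        SleepState.QW: row(0.030, 0.020),
        SleepState.WHISK: row(0.040, 0.030),
        SleepState.LOCO: row(0.080, 0.050),
        SleepState.WBS: row(0.030, 0.020),
        SleepState.NREM: row(0.100, 0.060),
        SleepState.IS: row(0.080, 0.050),
        SleepState.REM: row(0.020, 0.015),
        SleepState.WAS: row(0.035, 0.025),
        SleepState.MA: row(0.030, 0.020),
    }


@dataclass
class StateBandParams:
    """Editable profile of vessel-dynamics parameters.

    ``medians`` maps state -> (lumen, endfoot) median diameter (um);
    ``bands`` maps state -> band name -> (lumen a_rel, endfoot a_rel,
    frequency Hz) with a_rel the relative P-T amplitude.  ``noise_sd`` is
    per-sample Gaussian measurement noise (um) on each diameter;
    ``drift_sd`` the per-sqrt(second) scale of the shared rigid tissue
    drift random walk (um); ``tau_ramp`` the exponential state-transition
    time constant (s).  Defaults are plausible placeholders, not measured
    values, and are meant to be edited (see ``to_yaml``/``from_yaml``).
    """

    medians: dict[SleepState, tuple[float, float]] = field(default_factory=dict)
    bands: dict[SleepState, dict[str, tuple[float, float, float]]] = field(
        default_factory=dict)
    rem_dilation: float = 1.20
    arousal_constriction: float = 0.95
    noise_sd: float = 0.05
    drift_sd: float = 0.3
    tau_ramp: float = 2.0
    fs: float = 100.0

    def __post_init__(self) -> None:
        if not self.medians:
            self.medians = _default_medians(self.rem_dilation,
                                            self.arousal_constriction)
        if not self.bands:
            self.bands = _default_band_table()
        band_edges = {"continuous": (0.0, 0.1), "VLF": (0.1, 0.3),
                      "LF": (0.3, 1.0), "respiratory": (1.0, 4.0),
                      "cardiac": (4.0, 15.0)}
        for state, (lum, endf) in self.medians.items():
            if endf <= lum:
                raise ValueError(
                    f"endfoot median must exceed lumen median for {state}")
        for state, table in self.bands.items():
            for band, (al, ae, f) in table.items():
                if al < 0 or ae < 0:
                    raise ValueError(f"negative amplitude for {state}/{band}")
                lo, hi = band_edges[band]
                if not (lo < f < hi):
                    raise ValueError(
                        f"frequency {f} Hz outside band {band} for {state}")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "medians": {s.value: list(v) for s, v in self.medians.items()},
            "bands": {s.value: {b: list(v) for b, v in tab.items()}
                      for s, tab in self.bands.items()},
            "rem_dilation": self.rem_dilation,
            "arousal_constriction": self.arousal_constriction,
            "noise_sd": self.noise_sd,
            "drift_sd": self.drift_sd,
            "tau_ramp": self.tau_ramp,
            "fs": self.fs,
        }
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StateBandParams":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            medians={SleepState(s): tuple(v)
                     for s, v in data["medians"].items()},
            bands={SleepState(s): {b: tuple(v) for b, v in tab.items()}
                   for s, tab in data["bands"].items()},
            rem_dilation=data["rem_dilation"],
            arousal_constriction=data["arousal_constriction"],
            noise_sd=data["noise_sd"],
            drift_sd=data["drift_sd"],
            tau_ramp=data["tau_ramp"],
            fs=data["fs"],
        )


@dataclass
class VesselTrace:
    """Sampled diameter dynamics for one vessel.

    ``pvs_w`` is identically ``endfoot_d - lumen_d``; ``center_um`` is the
    shared rigid-drift offset of the structure's midline (cancels in
    diameters, visible in linescan edge positions).
    """

    vessel_id: str
    kind: str  # pial_artery | penetrating_arteriole | venule
    fs: float
    t: np.ndarray
    lumen_d: np.ndarray
    endfoot_d: np.ndarray
    pvs_w: np.ndarray
    state_per_sample: np.ndarray
    center_um: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.t,
            "lumen_um": self.lumen_d,
            "endfoot_um": self.endfoot_d,
            "pvs_um": self.pvs_w,
            "state": [s.value for s in self.state_per_sample],
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, vessel_id: str = "v0",
                 kind: str = "penetrating_arteriole") -> "VesselTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        return cls(
            vessel_id=vessel_id, kind=kind, fs=fs, t=t,
            lumen_d=df["lumen_um"].to_numpy(),
            endfoot_d=df["endfoot_um"].to_numpy(),
            pvs_w=df["pvs_um"].to_numpy(),
            state_per_sample=np.array(
                [SleepState(s) for s in df["state"]], dtype=object),
        )


def _exp_ramp(target: np.ndarray, fs: float, tau: float) -> np.ndarray:
    """Causal first-order exponential approach to a piecewise target."""
    if tau <= 0:
        return np.asarray(target, dtype=float).copy()
    target = np.asarray(target, dtype=float)
    a = 1.0 - np.exp(-1.0 / (fs * tau))
    # y[n] = (1-a) y[n-1] + a x[n], started at y[0] = x[0]
    out, _ = lfilter([a], [1.0, a - 1.0], target,
                     zi=np.array([(1.0 - a) * target[0]]))
    return out


def make_vessel_trace(h: Hypnogram, p: StateBandParams, seed: int,
                      vessel_id: str = "v0",
                      kind: str = "penetrating_arteriole") -> VesselTrace:
    """Synthesize lumen/endfoot diameter dynamics over a hypnogram.

    Diameters are state-median levels plus state-gated band-limited
    sinusoids with uniformly random phase per episode, exponentially
    ramped at state transitions (time constant ``p.tau_ramp``), with
    Gaussian measurement noise on each diameter and a shared rigid drift
    recorded in ``center_um``.
    """
    fs = p.fs
    band_edges_max = 15.0
    if fs < 2 * band_edges_max:
        raise ValueError(f"fs={fs} must be at least twice the highest band "
                         "edge (30 Hz)")
    rng = np.random.default_rng(seed)
    n = int(round(h.duration * fs))
    t = h.t_start + np.arange(n) / fs
    states = h.states_at(t)

    # per-sample episode index (phase randomization unit)
    ep_idx = np.zeros(n, dtype=int)
    edges = np.array([iv[1] for iv in h.intervals] + [h.t_end])
    ep_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                     len(h.intervals) - 1)

    lum_med = np.array([p.medians[s][0] for s in states])
    end_med = np.array([p.medians[s][1] for s in states])
    lum = _exp_ramp(lum_med, fs, p.tau_ramp)
    end = _exp_ramp(end_med, fs, p.tau_ramp)

    n_ep = len(h.intervals)
    for band in ("VLF", "LF", "respiratory", "cardiac"):
        phases = rng.uniform(0, 2 * np.pi, size=n_ep)
        a_l = np.array([p.bands[s][band][0] for s in states]) * lum_med
        a_e = np.array([p.bands[s][band][1] for s in states]) * end_med
        f = np.array([p.bands[s][band][2] for s in states])
        # sinusoid amplitude = P-T amplitude / 2
        env_l = _exp_ramp(a_l / 2.0, fs, p.tau_ramp)
        env_e = _exp_ramp(a_e / 2.0, fs, p.tau_ramp)
        osc = np.sin(2 * np.pi * f * t + phases[ep_idx])
        lum = lum + env_l * osc
        end = end + env_e * osc

    lum = lum + rng.normal(0.0, p.noise_sd, size=n)
    end = end + rng.normal(0.0, p.noise_sd, size=n)
    drift = np.cumsum(rng.normal(0.0, p.drift_sd / np.sqrt(fs), size=n))

    if np.any(end <= lum):
        raise ValueError("parameters imply endfoot_d <= lumen_d at some "
                         "sample; reduce amplitudes/noise or widen the PVS")
    return VesselTrace(
        vessel_id=vessel_id, kind=kind, fs=fs, t=t,
        lumen_d=lum, endfoot_d=end, pvs_w=end - lum,
        state_per_sample=states, center_um=drift,
    )


# ---------------------------------------------------------------------------
# Linescan stacks
# ---------------------------------------------------------------------------

@dataclass
class OpticsSpec:
    """Imaging parameters for synthetic x-t linescans.

    ``psf_sd`` is the Gaussian point-spread sd (um), ``noise`` the
    additive Gaussian intensity noise sd (fraction of full scale),
    ``dx`` the spatial sampling (um/sample), ``fov`` the scan length (um),
    ``band_um`` the thickness of each endfoot fluorescence band (um).
    """

    psf_sd: float = 0.4
    noise: float = 0.02
    dx: float = 0.05
    fov: float = 60.0
    band_um: float = 2.0


@dataclass
class LinescanStack:
    """Two-channel x-t intensity stack.

    ``red``/``green`` have shape (n_x, n_t): red is the dextran-filled
    lumen, green the two astrocyte endfoot bands flanking it.
    """

    red: np.ndarray
    green: np.ndarray
    dx: float
    fs: float
    truth: Optional[dict] = None

    @property
    def n_x(self) -> int:
        return self.red.shape[0]

    @property
    def n_t(self) -> int:
        return self.red.shape[1]

    def save(self, tiff_path: str | Path) -> None:
        """Write a 2-page TIFF (red, green; x along rows) + JSON sidecar."""
        import tifffile

        tiff_path = Path(tiff_path)
        arr = np.stack([self.red, self.green]).astype(np.float32)
        tifffile.imwrite(tiff_path, arr)
        sidecar = {"dx_um": self.dx, "fs_hz": self.fs}
        if self.truth is not None:
            sidecar["truth"] = {k: np.asarray(v).tolist()
                                for k, v in self.truth.items()}
        tiff_path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, tiff_path: str | Path) -> "LinescanStack":
        import tifffile

        tiff_path = Path(tiff_path)
        arr = tifffile.imread(tiff_path)
        meta = json.loads(tiff_path.with_suffix(".json").read_text())
        truth = meta.get("truth")
        if truth is not None:
            truth = {k: np.asarray(v) for k, v in truth.items()}
        return cls(red=np.asarray(arr[0], dtype=float),
                   green=np.asarray(arr[1], dtype=float),
                   dx=meta["dx_um"], fs=meta["fs_hz"], truth=truth)


def make_linescan(trace: VesselTrace, optics: OpticsSpec, seed: int
                  ) -> LinescanStack:
    """Render a vessel trace into a two-channel x-t linescan stack.

    The red channel is a boxcar of width ``lumen_d(t)``; the green channel
    is two bands whose outer edges are ``endfoot_d(t)`` apart. Both are
    convolved with a Gaussian PSF and carry additive Gaussian noise.
    Ground-truth diameters are embedded in ``truth``.
    """
    if optics.psf_sd <= 0:
        raise ValueError(f"PSF sd must be positive, got {optics.psf_sd}")
    max_extent = float(np.max(trace.endfoot_d))
    if trace.center_um is not None:
        max_extent += 2 * float(np.max(np.abs(trace.center_um)))
    if max_extent + 6 * optics.psf_sd >= optics.fov:
        raise ValueError(
            f"structure (<= {max_extent:.1f} um) does not fit in the "
            f"{optics.fov} um field of view")

    rng = np.random.default_rng(seed)
    n_x = int(round(optics.fov / optics.dx))
    x = (np.arange(n_x) - (n_x - 1) / 2) * optics.dx
    n_t = len(trace.t)
    center = (trace.center_um if trace.center_um is not None
              else np.zeros(n_t))

    xx = x[:, None] - center[None, :]
    half_l = trace.lumen_d[None, :] / 2.0
    half_e = trace.endfoot_d[None, :] / 2.0
    red = (np.abs(xx) <= half_l).astype(float)
    green = ((np.abs(xx) <= half_e)
             & (np.abs(xx) >= half_e - optics.band_um)).astype(float)

    sd_samples = optics.psf_sd / optics.dx
    red = gaussian_filter1d(red, sd_samples, axis=0, mode="constant")
    green = gaussian_filter1d(green, sd_samples, axis=0, mode="constant")
    if optics.noise > 0:
        red = red + rng.normal(0, optics.noise, red.shape)
        green = green + rng.normal(0, optics.noise, green.shape)

    truth = {"lumen_um": trace.lumen_d.copy(),
             "endfoot_um": trace.endfoot_d.copy(),
             "center_um": center.copy()}
    return LinescanStack(red=red, green=green, dx=optics.dx, fs=trace.fs,
                         truth=truth)


# ---------------------------------------------------------------------------
# ECoG / EMG
# ---------------------------------------------------------------------------

@dataclass
class PhysioSignals:
    """ECoG and EMG traces on a common time base (a.u.)."""

    ecog: np.ndarray
    emg: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if len(self.ecog) != len(self.emg):
            raise ValueError("ecog and emg must have equal length")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self.ecog)) / self.fs
        return pd.DataFrame({"time_s": t, "ecog": self.ecog,
                             "emg": self.emg})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# amplitude weights per state: (delta, theta, sigma, broadband, emg)
_ECOG_WEIGHTS: dict[SleepState, tuple[float, float, float, float, float]] = {
    SleepState.QW: (0.30, 0.30, 0.20, 0.40, 1.00),
    SleepState.WHISK: (0.30, 0.30, 0.20, 0.40, 1.20),
    SleepState.LOCO: (0.25, 0.35, 0.20, 0.45, 1.50),
    SleepState.WBS: (0.30, 0.30, 0.20, 0.40, 1.00),
    SleepState.WAS: (0.30, 0.30, 0.20, 0.40, 1.20),
    SleepState.NREM: (1.00, 0.25, 0.20, 0.10, 0.15),
    SleepState.IS: (0.45, 0.55, 0.65, 0.10, 0.15),
    SleepState.REM: (0.25, 0.70, 0.15, 0.10, 0.08),
    SleepState.MA: (0.15, 0.15, 0.10, 0.20, 1.00),
}

_ECOG_BANDS = {"delta": (0.5, 4.0), "theta": (5.0, 9.0),
               "sigma": (9.0, 16.0), "broad": (16.0, 30.0)}


def make_ecog_emg(h: Hypnogram, seed: int, fs: float = 500.0
                  ) -> PhysioSignals:
    """Synthesize ECoG/EMG with state-specific band power.

    ECoG is a sum of band-limited Gaussian noise carriers, each
    amplitude-modulated by a per-state weight (NREM delta-dominant, IS
    sigma/theta-elevated with reduced delta, REM theta-dominant with
    theta/delta power ratio > 0.5, wake broadband, microarousals with
    reduced total ECoG power).  EMG is band-limited noise, high in
    wake/MA, low in sleep, lowest in REM.
    """
    rng = np.random.default_rng(seed)
    n = int(round(h.duration * fs))
    t = h.t_start + np.arange(n) / fs
    states = h.states_at(t)

    tau = 0.3  # s, envelope ramp at state transitions
    ecog = np.zeros(n)
    for bi, (band, (lo, hi)) in enumerate(_ECOG_BANDS.items()):
        sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        carrier = sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= np.std(carrier)
        w = np.array([_ECOG_WEIGHTS[s][bi] for s in states])
        ecog += _exp_ramp(w, fs, tau) * carrier

    sos_emg = butter(4, [100.0, min(240.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    emg_carrier = sosfiltfilt(sos_emg, rng.standard_normal(n))
    emg_carrier /= np.std(emg_carrier)
    w_emg = np.array([_ECOG_WEIGHTS[s][4] for s in states])
    emg = _exp_ramp(w_emg, fs, tau) * emg_carrier

    return PhysioSignals(ecog=ecog, emg=emg, fs=fs)
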