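"""Synthetic trace-eyeblink-conditioning session generator with ground truth.

Produces multi-rat, multi-session, multi-trial two-channel LFP epochs plus a
concurrent EMG channel with programmable signal structure: 1/f background,
CS-locked evoked broadband transients, condition-dependent induced band
oscillations, low-frequency-phase-modulated high-frequency activity,
lagged inter-site coupling, EMG blink bursts following a learning curve,
and occasional large-amplitude artifact trials.  Every injected component is
enumerated in a ground-truth manifest so downstream estimators can be tested
for recovery without any recorded data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .containers import FISSURE, HILUS, SessionRecording

CHANNELS = (FISSURE, HILUS)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NoiseSpec:
    """1/f background noise: PSD ~ f**-exponent, scaled to rms_uv per channel."""

    exponent: float = 1.0
    rms_uv: float = 10.0


@dataclass
class EvokedSpec:
    """Deterministic broadband transient at CS onset (phase-locked across trials).

    ``session_gain`` multiplies ``gain_uv`` per session (length n_sessions);
    None means a flat gain of 1 in every session.
    """

    gain_uv: float = 0.0
    session_gain: tuple = None
    sigma_s: float = 0.004      # Gaussian envelope width -> ~5-10 ms transient
    carrier_hz: float = 40.0


@dataclass
class InducedEffect:
    """Amplitude-windowed sinusoid with random per-trial phase (raises amplitude,
    not ITC)."""

    freq_hz: float
    window: tuple          # (t0, t1) s relative to CS onset
    channel: str = FISSURE
    amplitude_uv: float = 20.0
    condition: str = "all"  # "all" or "CR"


@dataclass
class PACSpec:
    """HF carrier at ratio*f_low whose envelope is 1 + depth*cos(phi_LF)."""

    f_low_hz: float
    ratio: int
    depth: float
    lf_channel: str = HILUS
    hf_channel: str = FISSURE
    amp_lf_uv: float = 15.0
    amp_hf_uv: float = 10.0
    window: tuple = None   # None -> whole epoch


@dataclass
class LagSpec:
    """Narrow-band stochastic component on ``source`` plus a copy delayed by
    ``lag_samples`` on ``target`` (source leads for positive lag)."""

    freq_hz: float
    lag_samples: int
    source: str = HILUS
    target: str = FISSURE
    amplitude_uv: float = 15.0
    bandwidth_hz: float = 2.0


@dataclass
class EMGSpec:
    noise_sd: float = 1.0
    burst_amp_sd: float = 8.0   # blink burst amplitude in baseline-SD units
    burst_dur_s: float = 0.05
    burst_band_hz: tuple = None  # None: (200, 400) Hz capped below Nyquist


@dataclass
class SimConfig:
    n_rats: int = 8
    n_sessions: int = 8
    n_trials: int = 60
    fs: float = 1000.0
    epoch: tuple = (-1.0, 1.0)
    cs_duration: float = 0.2
    trace_duration: float = 0.5
    us_onset: float = 0.7
    hr_curve: tuple = None          # per-session CR probability; default linear 0.1->0.8
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    evoked: EvokedSpec = field(default_factory=EvokedSpec)
    induced_effects: tuple = ()
    pac_spec: PACSpec = None
    lag_spec: LagSpec = None
    emg: EMGSpec = field(default_factory=EMGSpec)
    artifact_rate: float = 0.0
    artifact_amp_uv: float = 2000.0
    seed: int = 0

    def __post_init__(self):
        if self.hr_curve is None:
            self.hr_curve = tuple(np.linspace(0.1, 0.8, self.n_sessions))
        self.hr_curve = tuple(float(p) for p in self.hr_curve)
        if len(self.hr_curve) != self.n_sessions:
            raise ValueError("hr_curve must have one entry per session")
        if any(not 0.0 <= p <= 1.0 for p in self.hr_curve):
            raise ValueError("hr_curve probabilities must lie in [0, 1]")
        if not (self.epoch[0] <= -0.6 and self.epoch[1] >= self.us_onset):
            raise ValueError("epoch must contain [-0.6 s, us_onset]")
        nyq = self.fs / 2.0
        for eff in self.induced_effects:
            if eff.freq_hz >= nyq:
                raise ValueError(f"induced band {eff.freq_hz} Hz exceeds Nyquist")
        if self.pac_spec is not None:
            if not 0.0 <= self.pac_spec.depth <= 1.0:
                raise ValueError("PAC modulation depth must lie in [0, 1]")
            if self.pac_spec.f_low_hz * self.pac_spec.ratio >= nyq:
                raise ValueError("PAC high-frequency partner exceeds Nyquist")
        if self.lag_spec is not None and self.lag_spec.freq_hz >= nyq:
            raise ValueError("lag band exceeds Nyquist")
        if self.emg.burst_band_hz is None:
            self.emg.burst_band_hz = (min(200.0, 0.4 * nyq), min(400.0, 0.8 * nyq))
        if self.emg.burst_band_hz[1] >= nyq:
            raise ValueError("EMG burst band exceeds Nyquist")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")

    @property
    def n_time(self) -> int:
        return int(round((self.epoch[1] - self.epoch[0]) * self.fs))

    @property
    def times(self) -> np.ndarray:
        return self.epoch[0] + np.arange(self.n_time) / self.fs

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["induced_effects"] = [asdict(e) for e in self.induced_effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseSpec(**d["noise"])
        if "evoked" in d and isinstance(d["evoked"], dict):
            d["evoked"] = EvokedSpec(**d["evoked"])
        if "emg" in d and isinstance(d["emg"], dict):
            d["emg"] = EMGSpec(**d["emg"])
        if d.get("pac_spec") and isinstance(d["pac_spec"], dict):
            d["pac_spec"] = PACSpec(**d["pac_spec"])
        if d.get("lag_spec") and isinstance(d["lag_spec"], dict):
            d["lag_spec"] = LagSpec(**d["lag_spec"])
        d["induced_effects"] = tuple(
            InducedEffect(**e) if isinstance(e, dict) else e
            for e in d.get("induced_effects", ())
        )
        for key in ("epoch", "hr_curve"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(_clean(self.to_dict()), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# component synthesis
# ---------------------------------------------------------------------------

def one_over_f_noise(n: int, fs: float, exponent: float, rms: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ f**-exponent, scaled to target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n)
    x *= rms / max(np.sqrt(np.mean(x**2)), np.finfo(float).tiny)
    return x


def _evoked_wavelet(times: np.ndarray, spec: EvokedSpec, gain: float) -> np.ndarray:
    # deterministic damped broadband wavelet at CS onset -> phase-locked
    env = np.exp(-0.5 * (times / spec.sigma_s) ** 2)
    return gain * env * np.cos(2 * np.pi * spec.carrier_hz * times)


def _window_taper(times: np.ndarray, window: tuple) -> np.ndarray:
    """Hann taper supported on ``window``; zero elsewhere."""
    t0, t1 = window
    taper = np.zeros_like(times)
    inside = (times >= t0) & (times <= t1)
    span = max(t1 - t0, np.finfo(float).tiny)
    taper[inside] = 0.5 * (1 - np.cos(2 * np.pi * (times[inside] - t0) / span))
    return taper


def _narrowband_noise(n: int, fs: float, freq: float, bw: float, rms: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian-spectrum narrow-band noise centred at ``freq`` with the given RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    mask = np.exp(-0.5 * ((f - freq) / bw) ** 2)
    x = np.fft.irfft(spec * mask, n)
    x *= rms / max(np.sqrt(np.mean(x**2)), np.finfo(float).tiny)
    return x


def trial_components(config: SimConfig, session: int, cr: bool, artifact: bool,
                     rng: np.random.Generator) -> dict:
    """Synthesize the named, clean components of one trial.

    Returns a dict mapping component name -> (2, n_time) LFP array
    (channel order ``CHANNELS``) plus the special keys ``"emg_noise"``,
    ``"emg_burst"`` (each (n_time,)) and ``"blink_time"`` (float or None).
    The trial's LFP is exactly the sum of the LFP-valued components.
    """
    t = config.times
    n = t.size
    comps: dict = {}

    noise = np.stack([
        one_over_f_noise(n, config.fs, config.noise.exponent, config.noise.rms_uv, rng)
        for _ in CHANNELS
    ])
    comps["noise"] = noise

    if config.evoked.gain_uv:
        gain = config.evoked.gain_uv
        if config.evoked.session_gain is not None:
            gain *= config.evoked.session_gain[session]
        wav = _evoked_wavelet(t, config.evoked, gain)
        comps["evoked"] = np.stack([wav, wav])

    for i, eff in enumerate(config.induced_effects):
        # random phase per trial: raises amplitude but not intertrial coherence
        theta = rng.uniform(0, 2 * np.pi)
        applies = eff.condition == "all" or (eff.condition == "CR" and cr)
        comp = np.zeros((2, n))
        if applies:
            ch = CHANNELS.index(eff.channel)
            comp[ch] = (eff.amplitude_uv * _window_taper(t, eff.window)
                        * np.cos(2 * np.pi * eff.freq_hz * t + theta))
        comps[f"induced_{i}"] = comp

    if config.pac_spec is not None:
        ps = config.pac_spec
        theta = rng.uniform(0, 2 * np.pi)
        psi = rng.uniform(0, 2 * np.pi)
        phi_lf = 2 * np.pi * ps.f_low_hz * t + theta
        lf = ps.amp_lf_uv * np.cos(phi_lf)
        # HF carrier at ratio*f_low; envelope varies at the LF rate so the
        # LF-filtered envelope phase locks 1:1 to phi_lf
        env = 1.0 + ps.depth * np.cos(phi_lf)
        hf = ps.amp_hf_uv * env * np.cos(ps.ratio * 2 * np.pi * ps.f_low_hz * t + psi)
        if ps.window is not None:
            taper = _window_taper(t, ps.window)
            lf = lf * taper
            hf = hf * taper
        comp = np.zeros((2, n))
        comp[CHANNELS.index(ps.lf_channel)] += lf
        comp[CHANNELS.index(ps.hf_channel)] += hf
        comps["pac"] = comp

    if config.lag_spec is not None:
        ls = config.lag_spec
        driver = _narrowband_noise(n, config.fs, ls.freq_hz, ls.bandwidth_hz,
                                   ls.amplitude_uv, rng)
        comp = np.zeros((2, n))
        comp[CHANNELS.index(ls.source)] += driver
        comp[CHANNELS.index(ls.target)] += np.roll(driver, ls.lag_samples)
        comps["lag"] = comp

    if artifact:
        comp = np.zeros((2, n))
        ch = int(rng.integers(0, 2))
        pos = int(rng.integers(0, n))
        comp[ch, pos] = config.artifact_amp_uv
        comps["artifact"] = comp

    comps["emg_noise"] = config.emg.noise_sd * rng.standard_normal(n)
    blink_time = None
    burst = np.zeros(n)
    if cr:
        # burst drawn to intersect the last 200 ms of the trace period
        resp0 = config.cs_duration + config.trace_duration - 0.2
        resp1 = config.cs_duration + config.trace_duration
        blink_time = rng.uniform(resp0 + 0.02, resp1 - config.emg.burst_dur_s - 0.01)
        nb = int(round(config.emg.burst_dur_s * config.fs))
        carrier = _narrowband_noise(nb, config.fs,
                                    np.mean(config.emg.burst_band_hz),
                                    np.ptp(config.emg.burst_band_hz) / 4.0,
                                    config.emg.burst_amp_sd * config.emg.noise_sd, rng)
        i0 = int(round((blink_time - config.epoch[0]) * config.fs))
        burst[i0:i0 + nb] = carrier * np.hanning(nb)
    comps["emg_burst"] = burst
    comps["blink_time"] = blink_time
    return comps


def simulate_trial(config: SimConfig, session: int, cr: bool, artifact: bool,
                   rng: np.random.Generator):
    """Simulate one trial.

    Returns ``(lfp, emg, gt_row)`` where ``lfp`` is (2, n_time) microvolts in
    channel order ``("fissure", "hilus")``, ``emg`` is (n_time,), and
    ``gt_row`` is a dict with the trial's ground truth.
    """
    comps = trial_components(config, session, cr, artifact, rng)
    lfp = np.zeros((2, config.n_time))
    for name, arr in comps.items():
        if name in ("emg_noise", "emg_burst", "blink_time"):
            continue
        lfp += arr
    emg = comps["emg_noise"] + comps["emg_burst"]
    gt_row = {"cr": bool(cr), "blink_time": comps["blink_time"],
              "artifact": bool(artifact)}
    return lfp, emg, gt_row


def draw_trial_outcomes(config: SimConfig, session: int,
                        rng: np.random.Generator):
    """Draw per-trial (cr, artifact) flags for one session.

    Separated from waveform synthesis so behavioural statistics can be
    studied at scale without synthesizing signals.
    """
    cr = rng.random(config.n_trials) < config.hr_curve[session]
    artifact = rng.random(config.n_trials) < config.artifact_rate
    return cr, artifact


@dataclass
class GroundTruth:
    """Per-trial truth plus the manifest of injected components."""

    trials: pd.DataFrame  # columns: rat, session, trial, cr, blink_time, artifact
    manifest: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=_json_default)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(type(obj))


def build_manifest(config: SimConfig) -> dict:
    """Enumerate every non-noise component the configuration injects."""
    manifest = {"noise": asdict(config.noise), "effects": []}
    if config.evoked.gain_uv:
        manifest["effects"].append({"kind": "evoked", **asdict(config.evoked)})
    for eff in config.induced_effects:
        manifest["effects"].append({"kind": "induced", **asdict(eff)})
    if config.pac_spec is not None:
        manifest["effects"].append({"kind": "pac", **asdict(config.pac_spec)})
    if config.lag_spec is not None:
        manifest["effects"].append({"kind": "lag", **asdict(config.lag_spec)})
    if config.artifact_rate > 0:
        manifest["effects"].append({"kind": "artifact",
                                    "rate": config.artifact_rate,
                                    "amplitude_uv": config.artifact_amp_uv})
    return manifest


def simulate_experiment(config: SimConfig, seed: int = None):
    """Simulate the full experiment.

    Returns ``(sessions, ground_truth)`` where ``sessions`` is a dict keyed by
    ``(rat, session)`` holding :class:`SessionRecording` objects.  The same
    ``(config, seed)`` yields bit-identical output.
    """
    if seed is None:
        seed = config.seed
    root = np.random.SeedSequence(seed)
    events = {"cs_onset": 0.0, "cs_offset": config.cs_duration,
              "us_onset": config.us_onset}
    sessions = {}
    rows = []
    # one independent stream per rat-session keeps output order-invariant
    streams = root.spawn(config.n_rats * config.n_sessions)
    for rat in range(config.n_rats):
        for ses in range(config.n_sessions):
            rng = np.random.default_rng(streams[rat * config.n_sessions + ses])
            cr_flags, art_flags = draw_trial_outcomes(config, ses, rng)
            lfp = np.empty((2, config.n_trials, config.n_time))
            emg = np.empty((config.n_trials, config.n_time))
            for k in range(config.n_trials):
                lfp[:, k], emg[k], gt = simulate_trial(
                    config, ses, cr_flags[k], art_flags[k], rng)
                rows.append({"rat": rat, "session": ses, "trial": k, **gt})
            sessions[(rat, ses)] = SessionRecording(
                lfp=lfp, channels=list(CHANNELS), emg=emg, fs=config.fs,
                epoch=config.epoch, events=dict(events), rat=rat, session=ses)
    trials = pd.DataFrame(rows)
    return sessions, GroundTruth(trials=trials, manifest=build_manifest(config))


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_experiment(path, sessions: dict, ground_truth: GroundTruth = None) -> None:
    """Write sessions to an HDF5 container (/rat<i>/session<j>/...)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for (rat, ses), rec in sessions.items():
            grp = fh.create_group(f"rat{rat}/session{ses}")
            grp.create_dataset("lfp", data=rec.lfp)
            grp.create_dataset("emg", data=rec.emg)
            grp.attrs["fs"] = rec.fs
            grp.attrs["epoch"] = rec.epoch
            grp.attrs["channels"] = [c.encode() for c in rec.channels]
            for name, t in rec.events.items():
                grp.attrs[f"event_{name}"] = t
        if ground_truth is not None:
            fh.attrs["manifest"] = json.dumps(ground_truth.manifest,
                                              default=_json_default)


def read_experiment(path):
    """Read an HDF5 container written by :func:`write_experiment`."""
    import h5py

    sessions = {}
    with h5py.File(path, "r") as fh:
        for rat_key in fh:
            rat = int(rat_key[3:])
            for ses_key in fh[rat_key]:
                ses = int(ses_key[7:])
                grp = fh[rat_key][ses_key]
                events = {k[6:]: float(v) for k, v in grp.attrs.items()
                          if k.startswith("event_")}
                sessions[(rat, ses)] = SessionRecording(
                    lfp=grp["lfp"][()], emg=grp["emg"][()],
                    channels=[c.decode() if isinstance(c, bytes) else str(c)
                              for c in grp.attrs["channels"]],
                    fs=float(grp.attrs["fs"]),
                    epoch=tuple(grp.attrs["epoch"]),
                    events=events, rat=rat, session=ses)
    return sessions
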