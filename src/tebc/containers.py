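"""Shared data containers for epoch-aligned recordings and analytic decompositions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: canonical channel roles for the two analysis sites
FISSURE = "fissure"
HILUS = "hilus"


@dataclass
class SessionRecording:
    """One rat-session of epoch-aligned LFP plus concurrent EMG.

    Attributes
    ----------
    lfp : ndarray, shape (n_channels, n_trials, n_time)
        Epoch-aligned LFP in microvolts.
    channels : list of str
        Channel roles; must be unique (e.g. ``["fissure", "hilus"]``).
    emg : ndarray, shape (n_trials, n_time)
        Concurrent EMG in microvolts.
    fs : float
        Sampling rate in Hz.
    epoch : (float, float)
        Epoch bounds in seconds relative to CS onset.
    events : dict
        Event times in seconds: ``cs_onset``, ``cs_offset``, ``us_onset``.
    rat, session : int
        Identifiers within the experiment.
    artifact : ndarray of bool, shape (n_trials,) or None
        Trials flagged as artifactual (set by artifact rejection).
    """

    lfp: np.ndarray
    channels: list
    emg: np.ndarray
    fs: float
    epoch: tuple
    events: dict
    rat: int = 0
    session: int = 0
    artifact: np.ndarray = None

    def __post_init__(self):
        self.lfp = np.asarray(self.lfp)
        self.emg = np.asarray(self.emg)
        if self.lfp.ndim != 3:
            raise ValueError("lfp must be (channels, trials, time)")
        if self.lfp.shape[0] != len(self.channels):
            raise ValueError("channel role count must match lfp first axis")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel roles must be unique")
        if self.emg.shape != self.lfp.shape[1:]:
            raise ValueError("emg must be (trials, time) matching lfp")
        n_time = self.lfp.shape[2]
        expected = int(round((self.epoch[1] - self.epoch[0]) * self.fs))
        if abs(n_time - expected) > 1:
            raise ValueError("epoch bounds inconsistent with array length")
        for name, t in self.events.items():
            if not (self.epoch[0] <= t <= self.epoch[1]):
                raise ValueError(f"event {name!r} at {t} s outside epoch {self.epoch}")

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[1]

    @property
    def n_time(self) -> int:
        return self.lfp.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to CS onset."""
        return self.epoch[0] + np.arange(self.n_time) / self.fs

    def channel_index(self, role: str) -> int:
        return self.channels.index(role)

    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (s)."""
        return int(round((t - self.epoch[0]) * self.fs))

    def valid_trials(self) -> np.ndarray:
        """Indices of trials not flagged as artifact."""
        if self.artifact is None:
            return np.arange(self.n_trials)
        return np.flatnonzero(~np.asarray(self.artifact))


@dataclass
class AnalyticTFR:
    """Complex narrow-band analytic decomposition of one channel.

    ``data[f, trial, t]`` is the analytic signal of band ``f``; its angle is
    the instantaneous phase in (-pi, pi] and its modulus the amplitude.
    """

    data: np.ndarray  # complex, (n_bands, n_trials, n_time)
    freqs: np.ndarray  # band centre frequencies, Hz
    fs: float
    epoch: tuple
    channel: str = ""
    edge_invalid: np.ndarray = None  # (n_bands,) samples unreliable at each end

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != self.freqs.size:
            raise ValueError("data must be (n_bands, n_trials, n_time)")
        if self.edge_invalid is None:
            self.edge_invalid = np.zeros(self.freqs.size, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.epoch[0] + np.arange(self.n_time) / self.fs

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.data)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.data)

    def time_slice(self, window: tuple) -> slice:
        """Slice of the time axis covering ``window = (t0, t1)`` seconds."""
        i0 = int(round((window[0] - self.epoch[0]) * self.fs))
        i1 = int(round((window[1] - self.epoch[0]) * self.fs))
        return slice(max(i0, 0), min(i1, self.n_time))

    def select_trials(self, idx) -> "AnalyticTFR":
        return AnalyticTFR(
            data=self.data[:, np.asarray(idx), :],
            freqs=self.freqs,
            fs=self.fs,
            epoch=self.epoch,
            channel=self.channel,
            edge_invalid=self.edge_invalid,
        )
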