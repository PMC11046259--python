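"""Trial-averaged oscillation amplitude and intertrial coherence maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AnalyticTFR


@dataclass
class BandTimeMap:
    """A band x time metric map with optional baseline-corrected variant."""

    raw: np.ndarray            # (n_bands, n_time)
    corrected: np.ndarray      # raw minus per-band baseline mean (or None)
    freqs: np.ndarray
    times: np.ndarray
    n_trials: int
    metric: str = ""
    channel: str = ""
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (channel, condition, band_hz, time_s, value)."""
        f, t = np.meshgrid(self.freqs, self.times, indexing="ij")
        value = self.corrected if self.corrected is not None else self.raw
        return pd.DataFrame({
            "channel": self.channel, "condition": self.condition,
            "metric": self.metric, "band_hz": f.ravel(),
            "time_s": t.ravel(), "value": value.ravel(),
        })


def _crop(tfr: AnalyticTFR, window):
    sl = tfr.time_slice(window)
    return sl, tfr.times[sl]


def amplitude_tfr(tfr: AnalyticTFR, analysis_window=(-0.6, 0.6),
                  baseline=(-0.6, -0.1), condition: str = "") -> BandTimeMap:
    """Trial-mean amplitude with the per-band baseline mean subtracted.

    The raw map is the mean over trials of |z(f, t)| restricted to
    ``analysis_window``; the corrected map subtracts, per band, the mean raw
    amplitude over the ``baseline`` interval.
    """
    if tfr.n_trials < 1:
        raise ValueError("no trials")
    sl, times = _crop(tfr, analysis_window)
    raw = np.abs(tfr.data[:, :, sl]).mean(axis=1)
    bl_sl = tfr.time_slice(baseline)
    baseline_mean = np.abs(tfr.data[:, :, bl_sl]).mean(axis=(1, 2))
    corrected = raw - baseline_mean[:, None]
    return BandTimeMap(raw=raw, corrected=corrected, freqs=tfr.freqs,
                       times=times, n_trials=tfr.n_trials,
                       metric="amplitude", channel=tfr.channel,
                       condition=condition)


def itc(tfr: AnalyticTFR, analysis_window=(-0.6, 0.6), baseline=None,
        condition: str = "") -> BandTimeMap:
    """Intertrial coherence: modulus of the trial-mean unit phasor.

    ITC(f, t) = | (1/N) sum_trials exp(i phi_trial(f, t)) |, in [0, 1].
    When ``baseline`` is given the per-band baseline mean is subtracted to
    form the corrected map (the raw map is always retained).
    """
    sl, times = _crop(tfr, analysis_window)
    z = tfr.data[:, :, sl]
    unit = np.exp(1j * np.angle(z))
    raw = np.abs(unit.mean(axis=1))
    corrected = None
    if baseline is not None:
        bl_sl = tfr.time_slice(baseline)
        unit_bl = np.exp(1j * np.angle(tfr.data[:, :, bl_sl]))
        bl = np.abs(unit_bl.mean(axis=1)).mean(axis=1)
        corrected = raw - bl[:, None]
    return BandTimeMap(raw=raw, corrected=corrected, freqs=tfr.freqs,
                       times=times, n_trials=tfr.n_trials, metric="itc",
                       channel=tfr.channel, condition=condition)
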