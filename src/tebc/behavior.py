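"""Eyeblink EMG scoring: conditioned-response detection, hit rates, reaction
times, and across-session learning summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SessionRecording
from .stats import rm_anova_1way

#: last 200 ms of the stimulus-free trace period (s relative to CS onset)
DEFAULT_RESPONSE_WINDOW = (0.5, 0.7)
DEFAULT_BASELINE_WINDOW = (-0.6, 0.0)


def _moving_rms(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving RMS over ``n`` samples (edges use partial windows)."""
    sq = x.astype(float) ** 2
    kernel = np.ones(n)
    num = np.convolve(sq, kernel, mode="same")
    den = np.convolve(np.ones_like(sq), kernel, mode="same")
    return np.sqrt(num / den)


def condition_emg(emg: np.ndarray, fs: float, smooth_s: float = 0.010) -> np.ndarray:
    """Full-wave rectification followed by a moving-RMS smoother."""
    n = max(int(round(smooth_s * fs)), 1)
    return _moving_rms(np.abs(np.asarray(emg, dtype=float)), n)


def detect_cr(emg_epoch: np.ndarray, fs: float, epoch_start: float,
              baseline_window=DEFAULT_BASELINE_WINDOW,
              response_window=DEFAULT_RESPONSE_WINDOW,
              n_sd: float = 3.0, smooth_s: float = 0.010,
              baseline_on: str = "rectified"):
    """Detect a conditioned response in one EMG epoch.

    The EMG is rectified and RMS-smoothed; a CR is scored when the smoothed
    signal exceeds the per-trial baseline mean + ``n_sd`` baseline SD anywhere
    in ``response_window``.  Returns ``(cr, rt)`` with ``rt`` the first
    threshold-crossing time in seconds from CS onset (None when no CR).

    ``baseline_on`` selects which signal supplies the baseline statistics:
    ``"rectified"`` (default) uses the full-wave rectified samples, which keeps
    the Gaussian-noise false-positive rate well under 5%; ``"smoothed"`` uses
    the RMS-smoothed envelope itself (leakier, since the envelope's baseline
    SD is small relative to its response-window extremes).
    """
    emg_epoch = np.asarray(emg_epoch, dtype=float)
    n_time = emg_epoch.shape[-1]
    epoch_end = epoch_start + n_time / fs

    def _slice(window):
        if window[0] < epoch_start - 1e-9 or window[1] > epoch_end + 1e-9:
            raise ValueError(f"window {window} outside epoch "
                             f"({epoch_start:g}, {epoch_end:g})")
        i0 = int(round((window[0] - epoch_start) * fs))
        i1 = int(round((window[1] - epoch_start) * fs))
        return slice(max(i0, 0), min(i1, n_time))

    proc = condition_emg(emg_epoch, fs, smooth_s)
    if baseline_on == "rectified":
        bl = np.abs(emg_epoch)[_slice(baseline_window)]
    elif baseline_on == "smoothed":
        bl = proc[_slice(baseline_window)]
    else:
        raise ValueError("baseline_on must be 'rectified' or 'smoothed'")
    if bl.std() == 0:
        raise ValueError("zero-variance baseline")
    threshold = bl.mean() + n_sd * bl.std()
    resp_sl = _slice(response_window)
    above = proc[resp_sl] > threshold
    if not above.any():
        return False, None
    rt = (resp_sl.start + int(np.argmax(above))) / fs + epoch_start
    return True, float(rt)


def score_session(recording: SessionRecording, **kwargs) -> pd.DataFrame:
    """Score every trial of a session; artifact flags are carried through."""
    rows = []
    art = (np.asarray(recording.artifact) if recording.artifact is not None
           else np.zeros(recording.n_trials, dtype=bool))
    for k in range(recording.n_trials):
        cr, rt = detect_cr(recording.emg[k], recording.fs,
                           recording.epoch[0], **kwargs)
        rows.append({"rat": recording.rat, "session": recording.session,
                     "trial": k, "cr": cr, "rt_s": rt if cr else np.nan,
                     "artifact": bool(art[k])})
    return pd.DataFrame(rows)


def hit_rate(trial_table: pd.DataFrame) -> float:
    """Fraction of non-artifact trials containing a CR."""
    valid = trial_table[~trial_table["artifact"]]
    if len(valid) == 0:
        return np.nan
    return float(valid["cr"].mean())


def summarize_behavior(trial_tables: pd.DataFrame) -> dict:
    """Across-session learning summary.

    ``trial_tables`` is a concatenated per-trial table (columns rat, session,
    trial, cr, rt_s, artifact).  Returns per-session HR (rat x session frame),
    mean RT with SEM, the Pearson correlation of HR with session pooled over
    rats, and a one-way repeated-measures ANOVA for the session effect (rat
    as the repeated factor; skipped with a warning for a single rat).
    """
    df = trial_tables
    valid = df[~df["artifact"]]
    hr = (valid.groupby(["rat", "session"])["cr"].mean()
          .unstack("session").sort_index())
    rts = valid.loc[valid["cr"], "rt_s"].dropna()
    rt_mean = float(rts.mean()) if len(rts) else np.nan
    rt_sem = float(rts.std(ddof=1) / np.sqrt(len(rts))) if len(rts) > 1 else np.nan

    long = hr.stack().reset_index()
    long.columns = ["rat", "session", "hr"]
    if long["hr"].std(ddof=0) == 0 or long["session"].std(ddof=0) == 0:
        pearson_r, pearson_p = 0.0, 1.0
    else:
        pearson_r, pearson_p = [float(v) for v in
                                _pearson(long["session"], long["hr"])]

    anova = None
    if hr.shape[0] >= 2 and hr.shape[1] >= 2 and not hr.isna().any().any():
        anova = rm_anova_1way(hr.to_numpy())
    else:
        import warnings
        warnings.warn("rm ANOVA skipped: needs >= 2 rats with complete sessions")
    return {"hr": hr, "rt_mean_s": rt_mean, "rt_sem_s": rt_sem,
            "pearson_r": pearson_r, "pearson_p": pearson_p, "anova": anova}


def _pearson(x, y):
    from scipy.stats import pearsonr
    r, p = pearsonr(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    return r, p


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False,
              columns=["rat", "session", "trial", "cr", "rt_s", "artifact"])


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
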