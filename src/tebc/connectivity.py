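"""Interareal phase synchronization, n:m phase-amplitude coupling, and
directed phase-transfer-entropy estimation between recording sites."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AnalyticTFR
from .preprocess import FilterBank

PAIR_LABELS = ("H->H", "H->F", "F->H", "F->F")
DEFAULT_WINDOWS = ((0.0, 0.1), (0.1, 0.3), (0.3, 0.5))


# ---------------------------------------------------------------------------
# interareal PLV
# ---------------------------------------------------------------------------

@dataclass
class PLVMap:
    raw: np.ndarray          # (n_bands, n_time), in [0, 1]
    normalized: np.ndarray   # raw / mean shuffled
    shuffle_mean: np.ndarray
    shuffle_raws: np.ndarray  # (n_shuffles, n_bands, n_time)
    freqs: np.ndarray
    times: np.ndarray
    n_shuffles: int


def _raw_plv(unit_a: np.ndarray, unit_b_conj: np.ndarray) -> np.ndarray:
    return np.abs(np.mean(unit_a * unit_b_conj, axis=1))


def interareal_plv(tfr_a: AnalyticTFR, tfr_b: AnalyticTFR,
                   n_shuffles: int = 100,
                   rng: np.random.Generator = None) -> PLVMap:
    """Phase-locking value between two channels with trial-shuffle normalization.

    raw(f, t) = | (1/N) sum_trials exp(i (phi_A - phi_B)) |.  The normalized
    map divides by the mean raw PLV over ``n_shuffles`` surrogates in which
    the trial pairing on channel B is cyclically permuted (never pairing a
    trial with itself), so stimulus-locked but trial-independent phase
    alignment normalizes to ~1.
    """
    n = tfr_a.n_trials
    if n < 2:
        raise ValueError("PLV needs at least 2 trials")
    if n != tfr_b.n_trials or tfr_a.data.shape != tfr_b.data.shape:
        raise ValueError("channels must have aligned trials and bands")
    rng = np.random.default_rng(rng)
    unit_a = np.exp(1j * np.angle(tfr_a.data))
    unit_b_conj = np.exp(-1j * np.angle(tfr_b.data))
    raw = _raw_plv(unit_a, unit_b_conj)
    shuffles = np.empty((n_shuffles,) + raw.shape)
    offsets = rng.integers(1, n, size=n_shuffles)
    for s, off in enumerate(offsets):
        shuffles[s] = _raw_plv(unit_a, np.roll(unit_b_conj, int(off), axis=1))
    shuffle_mean = shuffles.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = raw / shuffle_mean
    return PLVMap(raw=raw, normalized=normalized, shuffle_mean=shuffle_mean,
                  shuffle_raws=shuffles, freqs=tfr_a.freqs, times=tfr_a.times,
                  n_shuffles=n_shuffles)


# ---------------------------------------------------------------------------
# n:m phase-amplitude coupling
# ---------------------------------------------------------------------------

@dataclass
class PACMatrix:
    """PLV-type coupling of LF phase with the phase of the LF-filtered HF
    envelope, indexed (LF band, ratio, laminar pair, window).

    ``post`` holds the analysis-window values and ``pre`` the matching
    pre-stimulus counterparts (window (a, b) mirrored to (-b, -a)).
    Cells without an HF partner band in the bank are NaN.
    """

    post: np.ndarray   # (n_lf, n_ratios, n_pairs, n_windows)
    pre: np.ndarray
    lf_freqs: np.ndarray
    ratios: np.ndarray
    pairs: tuple
    windows: tuple
    hf_band: np.ndarray  # matched HF band index, -1 when absent

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.lf_freqs):
            for j, r in enumerate(self.ratios):
                for k, pair in enumerate(self.pairs):
                    for w, win in enumerate(self.windows):
                        rows.append({
                            "lf_hz": f, "ratio": int(r), "pair": pair,
                            "window": f"{win[0]:g}-{win[1]:g}",
                            "pac_post": self.post[i, j, k, w],
                            "pac_pre": self.pre[i, j, k, w]})
        return pd.DataFrame(rows)


def envelope_phase(tfr: AnalyticTFR, hf_band: int, lf_band: int,
                   bank: FilterBank) -> np.ndarray:
    """Phase of the HF amplitude envelope filtered at the LF band."""
    from scipy.signal import hilbert

    env = np.abs(tfr.data[hf_band])
    env_filt = bank.apply(env, lf_band)
    return np.angle(hilbert(env_filt, axis=-1))


def match_hf_band(bank: FilterBank, lf_freq: float, ratio: int,
                  tol: float = None) -> int:
    """Index of the bank band whose centre is closest to ratio*lf_freq, or -1
    when the nearest centre is further than half a bank step (geometric)."""
    target = ratio * lf_freq
    if target >= bank.fs / 2.0:
        return -1
    b = bank.nearest_band(target)
    if tol is None:
        tol = np.sqrt(bank.band_step()) * 1.001
    if np.exp(abs(np.log(bank.freqs[b] / target))) > tol:
        return -1
    return b


def pac_nm(tfrs: dict, bank: FilterBank, lf_bands,
           ratios=range(2, 10), windows=DEFAULT_WINDOWS,
           match_tol: float = None) -> PACMatrix:
    """n:m phase-amplitude coupling matrix for the four laminar pairs.

    ``tfrs`` maps channel role -> AnalyticTFR for "hilus" and "fissure".
    For each LF band and ratio n, the HF partner is the bank band with centre
    closest to n * f_LF; PAC is | mean over trials and window samples of
    exp(i (phi_LF - phi_env)) | where phi_env is the phase of the HF
    envelope band-filtered at the LF frequency.
    """
    from .containers import FISSURE, HILUS

    lf_bands = np.asarray(list(lf_bands), dtype=int)
    ratios = np.asarray(list(ratios), dtype=int)
    pair_channels = {"H->H": (HILUS, HILUS), "H->F": (HILUS, FISSURE),
                     "F->H": (FISSURE, HILUS), "F->F": (FISSURE, FISSURE)}
    tfr0 = next(iter(tfrs.values()))
    shape = (lf_bands.size, ratios.size, len(PAIR_LABELS), len(windows))
    post = np.full(shape, np.nan)
    pre = np.full(shape, np.nan)
    hf_match = np.full((lf_bands.size, ratios.size), -1, dtype=int)

    win_slices = [tfr0.time_slice(w) for w in windows]
    pre_slices = [tfr0.time_slice((-w[1], -w[0])) for w in windows]

    for i, lf in enumerate(lf_bands):
        f_lf = bank.freqs[lf]
        for j, n in enumerate(ratios):
            hf = match_hf_band(bank, f_lf, int(n), tol=match_tol)
            hf_match[i, j] = hf
            if hf < 0:
                continue
            # envelope phase per channel, computed once per (lf, hf) pair
            env_ph = {role: envelope_phase(tfr, hf, lf, bank)
                      for role, tfr in tfrs.items()}
            for k, pair in enumerate(PAIR_LABELS):
                ph_role, env_role = pair_channels[pair]
                phi_lf = np.angle(tfrs[ph_role].data[lf])
                dphi = np.exp(1j * (phi_lf - env_ph[env_role]))
                for w in range(len(windows)):
                    post[i, j, k, w] = np.abs(dphi[:, win_slices[w]].mean())
                    pre[i, j, k, w] = np.abs(dphi[:, pre_slices[w]].mean())
    return PACMatrix(post=post, pre=pre, lf_freqs=bank.freqs[lf_bands],
                     ratios=ratios, pairs=PAIR_LABELS, windows=tuple(windows),
                     hf_band=hf_match)


# ---------------------------------------------------------------------------
# phase transfer entropy
# ---------------------------------------------------------------------------

@dataclass
class PTEResult:
    te_xy: float       # bits, X -> Y
    te_yx: float
    dte: float         # te_xy - te_yx; positive when X leads
    delay: int
    n_bins: int
    n_samples: int
    low_confidence: bool = False
    surrogates: np.ndarray = None


def _bin_phase(phase: np.ndarray, n_bins: int) -> np.ndarray:
    b = np.floor((np.asarray(phase) + np.pi) / (2 * np.pi) * n_bins).astype(np.int64)
    return np.clip(b, 0, n_bins - 1)


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def transfer_entropy_binned(bx: np.ndarray, by: np.ndarray, delay: int,
                            n_bins: int) -> float:
    """TE X->Y in bits from pre-binned phase sequences (trials x time).

    TE = H(y_t+d, y_t) - H(y_t) - H(y_t+d, y_t, x_t) + H(y_t, x_t), with all
    histograms pooled over trials and window samples.
    """
    yf = by[:, delay:].ravel()
    yp = by[:, :-delay].ravel()
    xp = bx[:, :-delay].ravel()
    joint3 = np.bincount((yf * n_bins + yp) * n_bins + xp,
                         minlength=n_bins**3)
    joint_fp = np.bincount(yf * n_bins + yp, minlength=n_bins**2)
    joint_px = np.bincount(yp * n_bins + xp, minlength=n_bins**2)
    past = np.bincount(yp, minlength=n_bins)
    return (_entropy_bits(joint_fp) - _entropy_bits(past)
            - _entropy_bits(joint3) + _entropy_bits(joint_px))


def phase_te(phase_x: np.ndarray, phase_y: np.ndarray, delay: int,
             n_bins: int = 8, fs: float = None, epoch: tuple = None,
             window: tuple = (0.0, 0.5)) -> PTEResult:
    """Differential phase transfer entropy between two phase time series.

    ``phase_x``/``phase_y`` are (n_trials, n_time) instantaneous phases in
    (-pi, pi].  When ``fs`` and ``epoch`` are given, only samples inside
    ``window`` (seconds relative to CS onset) enter the estimate; otherwise
    the full series is used.  Probabilities come from ``n_bins`` equal-width
    phase-bin histograms pooled over trials and samples.  dTE = TE(X->Y) -
    TE(Y->X) is positive when X leads Y.
    """
    phase_x = np.atleast_2d(phase_x)
    phase_y = np.atleast_2d(phase_y)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase arrays must have equal shape")
    if delay < 1:
        raise ValueError("delay must be a positive sample count")
    if fs is not None and epoch is not None and window is not None:
        i0 = int(round((window[0] - epoch[0]) * fs))
        i1 = int(round((window[1] - epoch[0]) * fs))
        phase_x = phase_x[:, i0:i1]
        phase_y = phase_y[:, i0:i1]
    if phase_x.shape[1] <= delay:
        raise ValueError("window shorter than the prediction delay")
    bx = _bin_phase(phase_x, n_bins)
    by = _bin_phase(phase_y, n_bins)
    n_samples = bx.shape[0] * (bx.shape[1] - delay)
    low = n_samples < 10 * n_bins**3
    if low:
        warnings.warn("phase TE sample count below 10x bin-cell count; "
                      "result flagged low-confidence", stacklevel=2)
    te_xy = transfer_entropy_binned(bx, by, delay, n_bins)
    te_yx = transfer_entropy_binned(by, bx, delay, n_bins)
    return PTEResult(te_xy=te_xy, te_yx=te_yx, dte=te_xy - te_yx,
                     delay=delay, n_bins=n_bins, n_samples=n_samples,
                     low_confidence=low)


def default_te_delay(fs: float, freq: float) -> int:
    """One-cycle prediction horizon in samples."""
    return max(int(round(fs / freq)), 1)
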