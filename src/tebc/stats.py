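"""Inferential machinery: trial equalization, sign-flip Monte Carlo nulls,
Benjamini-Hochberg FDR, cluster-based permutation over temporal adjacency,
repeated-measures ANOVA on regions of interest, and metric-specific group
tests.

All Monte Carlo p-values use the +1-corrected estimator
p = (1 + #{null >= observed}) / (1 + n) and are therefore strictly positive;
all stochastic operations are reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


# ---------------------------------------------------------------------------
# trial equalization
# ---------------------------------------------------------------------------

def equalize_trials(ids_a, ids_b, rng=None):
    """Subsample the larger of two trial-id sets (without replacement) so both
    have size min(|A|, |B|); the smaller set is returned unchanged."""
    ids_a = np.asarray(ids_a)
    ids_b = np.asarray(ids_b)
    if ids_a.size == 0 or ids_b.size == 0:
        raise ValueError("both trial sets must be non-empty")
    rng = np.random.default_rng(rng)
    m = min(ids_a.size, ids_b.size)
    if ids_a.size > m:
        ids_a = np.sort(rng.choice(ids_a, size=m, replace=False))
    if ids_b.size > m:
        ids_b = np.sort(rng.choice(ids_b, size=m, replace=False))
    return ids_a, ids_b


# ---------------------------------------------------------------------------
# sign-flip Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class SignFlipResult:
    observed: np.ndarray      # mean over subjects
    p: np.ndarray             # two-tailed Monte Carlo p (+1-corrected)
    mask: np.ndarray          # p < alpha
    alpha: float
    n: int


def signflip_monte_carlo(diffs: np.ndarray, n: int = 20000,
                         alpha: float = 0.025, rng=None,
                         chunk: int = 2000) -> SignFlipResult:
    """Monte Carlo test of the subject-mean difference against a null built by
    independently negating each subject's difference with probability 0.5.

    ``diffs`` has subjects on the first axis; any trailing map shape is
    supported.  Two-tailed p = 2 * min(upper-tail, lower-tail), each tail
    +1-corrected; significance at ``p < alpha``.
    """
    diffs = np.asarray(diffs, dtype=float)
    n_subj = diffs.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(rng)
    shape = diffs.shape[1:]
    flat = diffs.reshape(n_subj, -1)
    observed = flat.mean(axis=0)
    ge = np.zeros(flat.shape[1], dtype=np.int64)
    le = np.zeros(flat.shape[1], dtype=np.int64)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        signs = rng.integers(0, 2, size=(m, n_subj)) * 2.0 - 1.0
        null_means = signs @ flat / n_subj
        ge += (null_means >= observed).sum(axis=0)
        le += (null_means <= observed).sum(axis=0)
        done += m
    p_hi = (1.0 + ge) / (1.0 + n)
    p_lo = (1.0 + le) / (1.0 + n)
    p = np.minimum(2.0 * np.minimum(p_hi, p_lo), 1.0)
    return SignFlipResult(observed=observed.reshape(shape),
                          p=p.reshape(shape),
                          mask=(p < alpha).reshape(shape),
                          alpha=alpha, n=n)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject all ranks up to the largest i with
    p_(i) <= i q / m.  Returns a boolean mask with the input shape; NaNs are
    never rejected and do not count toward m."""
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    flat = p.ravel()
    valid = ~np.isnan(flat)
    pv = flat[valid]
    m = pv.size
    if m == 0:
        return mask
    order = np.argsort(pv)
    thresh = (np.arange(1, m + 1) * q) / m
    under = pv[order] <= thresh
    if under.any():
        k = np.max(np.flatnonzero(under))
        rej = np.zeros(m, dtype=bool)
        rej[order[:k + 1]] = True
        out = np.zeros(flat.size, dtype=bool)
        out[valid] = rej
        mask = out.reshape(p.shape)
    return mask


# ---------------------------------------------------------------------------
# cluster-based permutation over temporal adjacency
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    band: int
    start: int        # inclusive time index
    stop: int         # exclusive
    t_sum: float
    p: float


@dataclass
class ClusterResult:
    clusters: list
    null_max_tsum: np.ndarray
    t_threshold: float
    t_map: np.ndarray
    alpha: float = 0.05

    def significant(self):
        return [c for c in self.clusters if c.p < self.alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"band": c.band, "start": c.start, "stop": c.stop,
                              "t_sum": c.t_sum, "p": c.p,
                              "significant": c.p < self.alpha}
                             for c in self.clusters])


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.nan_to_num(t)


def _observed_clusters(t_map: np.ndarray, thresh: float):
    """Contiguous same-sign suprathreshold runs per band (temporal adjacency
    only; positive and negative runs are separate clusters)."""
    clusters = []
    for b in range(t_map.shape[0]):
        for sign in (1.0, -1.0):
            mask = sign * t_map[b] > thresh
            edges = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
            starts = np.flatnonzero(edges == 1)
            stops = np.flatnonzero(edges == -1)
            for a, z in zip(starts, stops):
                clusters.append(Cluster(band=b, start=int(a), stop=int(z),
                                        t_sum=float(t_map[b, a:z].sum()),
                                        p=np.nan))
    return clusters


def _max_run_sums(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per row, the maximum sum over contiguous masked runs (0 when none).

    ``values`` and ``mask`` are (n_rows, n_time); scans time with vectorized
    row operations.
    """
    run = np.zeros(values.shape[0])
    best = np.zeros(values.shape[0])
    for t in range(values.shape[1]):
        run = (run + values[:, t]) * mask[:, t]
        np.maximum(best, run, out=best)
    return best


def cluster_permutation(maps_a: np.ndarray, maps_b: np.ndarray,
                        t_alpha: float = 0.025, n_perm: int = 1000,
                        alpha: float = 0.05, rng=None) -> ClusterResult:
    """Cluster-based permutation test of paired per-animal (band, time) maps.

    A pointwise paired t-map is thresholded at the critical t for one-tailed
    ``t_alpha`` per sign; suprathreshold elements are clustered by temporal
    adjacency within band, with positive and negative runs kept separate, and
    each cluster is scored by its t-sum.  The null is the distribution of the
    maximum |t-sum| over ``n_perm`` permutations that exchange the condition
    labels within animal (equivalently, sign flips of each animal's
    difference map); cluster p-values use the +1-corrected tail count.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape or maps_a.ndim != 3:
        raise ValueError("expected matching (n_animals, n_bands, n_time) maps")
    n_subj = maps_a.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 animals")
    rng = np.random.default_rng(rng)
    diffs = maps_a - maps_b
    t_obs = _paired_t(diffs)
    t_crit = float(sstats.t.ppf(1.0 - t_alpha, df=n_subj - 1))
    clusters = _observed_clusters(t_obs, t_crit)

    n_bands, n_time = t_obs.shape
    flat = diffs.reshape(n_subj, -1)
    sq_sum = (flat**2).sum(axis=0)  # invariant under sign flips
    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(2e7 // max(flat.shape[1], 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        signs = rng.integers(0, 2, size=(m, n_subj)) * 2.0 - 1.0
        means = signs @ flat / n_subj
        var = (sq_sum / n_subj - means**2) * (n_subj / (n_subj - 1))
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_perm = means / np.sqrt(var / n_subj)
        t_perm = np.nan_to_num(t_perm).reshape(m * n_bands, n_time)
        best_pos = _max_run_sums(t_perm, t_perm > t_crit)
        best_neg = _max_run_sums(-t_perm, -t_perm > t_crit)
        best = np.maximum(best_pos, best_neg).reshape(m, n_bands)
        null[done:done + m] = best.max(axis=1)
        done += m

    for c in clusters:
        c.p = float((1.0 + np.sum(null >= abs(c.t_sum))) / (1.0 + n_perm))
    return ClusterResult(clusters=clusters, null_max_tsum=null,
                         t_threshold=t_crit, t_map=t_obs, alpha=alpha)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_1way(values: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA; ``values`` is (n_subjects, n_levels).

    Returns F, p and degrees of freedom for the within-subject factor, using
    the subject-by-factor interaction as the error term.  No sphericity
    correction is applied.
    """
    y = np.asarray(values, dtype=float)
    s, a = y.shape
    if s < 2 or a < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels")
    grand = y.mean()
    ss_a = s * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_s = a * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_a - ss_s
    df_a, df_err = a - 1, (a - 1) * (s - 1)
    ms_a = ss_a / df_a
    ms_err = ss_err / df_err
    f = np.inf if ms_err == 0 and ms_a > 0 else (0.0 if ms_a == 0 else ms_a / ms_err)
    p = float(sstats.f.sf(f, df_a, df_err)) if np.isfinite(f) else 0.0
    return {"F": float(f), "p": p, "df": (df_a, df_err),
            "ss": {"factor": ss_a, "subject": ss_s, "error": ss_err}}


def rm_anova_roi(values: np.ndarray) -> dict:
    """Two-way fully repeated-measures ANOVA on ROI means.

    ``values`` is (n_subjects, n_levels_A, n_levels_B) with every subject
    contributing every cell (no imputation).  Each effect is tested against
    its own subject-interaction error term.  Sphericity corrections are not
    applied (noted in the output metadata).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError("values must be (subjects, A, B)")
    if np.isnan(y).any():
        raise ValueError("missing cells are not allowed")
    s, a, b = y.shape
    if s < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_a = s * b * ((m_a - grand) ** 2).sum()
    ss_b = s * a * ((m_b - grand) ** 2).sum()
    ss_ab = s * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_s = a * b * ((m_s - grand) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_sab = ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_sa - ss_sb

    def effect(ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err <= 0:
            f = np.inf if ms_eff > 0 else 0.0
        else:
            f = ms_eff / ms_err
        p = float(sstats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else 0.0
        return {"F": float(f), "p": p, "df": (df_eff, df_err)}

    out = {
        "A": effect(ss_a, a - 1, ss_sa, (a - 1) * (s - 1)),
        "B": effect(ss_b, b - 1, ss_sb, (b - 1) * (s - 1)),
        "AxB": effect(ss_ab, (a - 1) * (b - 1), ss_sab, (a - 1) * (b - 1) * (s - 1)),
        "sphericity_correction": "none",
    }
    return out


# ---------------------------------------------------------------------------
# metric-specific group tests
# ---------------------------------------------------------------------------

@dataclass
class PACGroupResult:
    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray        # BH-FDR rejections across cells
    mean_diff: np.ndarray
    q: float


def pac_group_test(pac_post: np.ndarray, pac_pre: np.ndarray,
                   q: float = 0.05, min_obs: int = 3) -> PACGroupResult:
    """One-sample t-test of (post - pre) PAC per cell across subject-sessions,
    BH-FDR corrected across cells.

    ``pac_post``/``pac_pre`` have subject-session observations on the first
    axis; any trailing cell shape is supported.  Cells with fewer than
    ``min_obs`` finite observations are skipped (NaN p, never rejected).
    """
    post = np.asarray(pac_post, dtype=float)
    pre = np.asarray(pac_pre, dtype=float)
    if post.shape != pre.shape:
        raise ValueError("post and pre must have identical shapes")
    d = post - pre
    n_obs = np.sum(np.isfinite(d), axis=0)
    mean = np.nanmean(np.where(np.isfinite(d), d, np.nan), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = sstats.ttest_1samp(d, 0.0, axis=0, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    skip = n_obs < min_obs
    p = np.where(skip, np.nan, p)
    mask = bh_fdr(p, q)
    return PACGroupResult(t=t, p=p, mask=mask, mean_diff=mean, q=q)


@dataclass
class PTETestResult:
    dte: np.ndarray          # observed per band
    p: np.ndarray            # two-sided Monte Carlo p per band
    mask: np.ndarray         # BH-FDR rejections across bands
    surrogates: np.ndarray   # (n_bands, n_shuffles)
    q: float


def pte_shuffle_test(phase_pairs, delays, n_bins: int = 8,
                     n_shuffles: int = 1000, q: float = 0.05,
                     rng=None, fs: float = None, epoch: tuple = None,
                     window: tuple = (0.0, 0.5)) -> PTETestResult:
    """Trial-shuffle significance test of dTE per frequency band.

    ``phase_pairs`` is a sequence of ``(phase_x, phase_y)`` trial-resolved
    phase arrays, one per band, and ``delays`` the per-band prediction delay
    in samples.  Surrogates permute the trial pairing between channels
    (independent random permutations of channel Y's trial axis — cyclic
    shifts would give only n_trials-1 distinct surrogates and an
    anti-conservative test); the two-sided Monte Carlo p is +1-corrected,
    then BH-FDR is applied across bands.
    """
    from .connectivity import phase_te, _bin_phase, transfer_entropy_binned

    rng = np.random.default_rng(rng)
    n_bands = len(phase_pairs)
    delays = np.broadcast_to(np.asarray(delays, dtype=int), (n_bands,))
    dte = np.empty(n_bands)
    surr = np.empty((n_bands, n_shuffles))
    for b, (px, py) in enumerate(phase_pairs):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = phase_te(px, py, int(delays[b]), n_bins=n_bins, fs=fs,
                           epoch=epoch, window=window)
        dte[b] = res.dte
        px2 = np.atleast_2d(px)
        py2 = np.atleast_2d(py)
        if fs is not None and epoch is not None and window is not None:
            i0 = int(round((window[0] - epoch[0]) * fs))
            i1 = int(round((window[1] - epoch[0]) * fs))
            px2, py2 = px2[:, i0:i1], py2[:, i0:i1]
        bx = _bin_phase(px2, n_bins)
        by = _bin_phase(py2, n_bins)
        n_tr = bx.shape[0]
        d = int(delays[b])
        for s in range(n_shuffles):
            by_s = by[rng.permutation(n_tr)]
            surr[b, s] = (transfer_entropy_binned(bx, by_s, d, n_bins)
                          - transfer_entropy_binned(by_s, bx, d, n_bins))
    # two-sided: surrogate at least as extreme (centred on the surrogate mean)
    centred_obs = np.abs(dte - surr.mean(axis=1))
    centred_surr = np.abs(surr - surr.mean(axis=1, keepdims=True))
    p = (1.0 + (centred_surr >= centred_obs[:, None]).sum(axis=1)) / (1.0 + n_shuffles)
    mask = bh_fdr(p, q)
    return PTETestResult(dte=dte, p=p, mask=mask, surrogates=surr, q=q)
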