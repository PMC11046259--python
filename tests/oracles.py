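"""Independent reference implementations used as test oracles."""

import numpy as np


def naive_phase_te(phase_x, phase_y, delay, n_bins):
    """Triple-loop reference TE (bits) straight from the defining formula."""
    bx = np.floor((np.asarray(phase_x) + np.pi) / (2 * np.pi) * n_bins)
    by = np.floor((np.asarray(phase_y) + np.pi) / (2 * np.pi) * n_bins)
    bx = np.clip(bx, 0, n_bins - 1).astype(int)
    by = np.clip(by, 0, n_bins - 1).astype(int)
    counts = np.zeros((n_bins, n_bins, n_bins))
    for tr in range(bx.shape[0]):
        for t in range(bx.shape[1] - delay):
            counts[by[tr, t + delay], by[tr, t], bx[tr, t]] += 1
    total = counts.sum()
    p3 = counts / total
    te = 0.0
    for yf in range(n_bins):
        for yp in range(n_bins):
            for xp in range(n_bins):
                pj = p3[yf, yp, xp]
                if pj == 0:
                    continue
                p_ypxp = p3[:, yp, xp].sum()
                p_yp = p3[:, yp, :].sum()
                p_yfyp = p3[yf, yp, :].sum()
                te += pj * np.log2((pj / p_ypxp) / (p_yfyp / p_yp))
    return te
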