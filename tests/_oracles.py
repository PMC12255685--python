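"""Independent reference computations used by the test suite.

Everything here is deliberately written against scipy/numpy primitives —
never against the package's own implementation — so that agreement between
the two is evidence, not tautology.
"""

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.stats import gamma as gamma_dist

FS = 3.9063


def ref_hrf(t):
    """Double-gamma reference response (scipy gamma densities)."""
    h = gamma_dist.pdf(t, 6.0 / 0.9, scale=0.9) - 0.35 * gamma_dist.pdf(
        t, 12.0 / 0.9, scale=0.9
    )
    return h / h.max()


def waveform_factor(duration=5.6, fs=FS):
    """Closed form: 5-8 s mean of the detrended, baseline-zeroed unit
    response (HRF x full-duration boxcar, peak 1) on the epoch grid."""
    dt = 1.0 / fs
    t = np.arange(0.0, 32.0, dt)
    k = np.convolve(ref_hrf(t), np.ones(int(round(duration / dt))))
    k /= k.max()
    rel = np.arange(int(round(-5 * fs)), int(round(20 * fs)) + 1)
    tt = rel / fs
    e = np.where(rel >= 0, np.pad(k, (0, 2000))[np.clip(rel, 0, None)], 0.0)
    tc = tt - tt.mean()
    e = e - e.mean() - ((e * tc).sum() / (tc @ tc)) * tc
    e -= e[tt <= 0].mean()
    return e[(tt >= 5) & (tt <= 8)].mean()


def beta_projection(events, amplitudes_by_condition, n_samples, fs=FS,
                    boxcar_divisor=1.67, ar_order=5):
    """Prewhitened-GLS projection oracle for the noiseless beta estimates.

    Rebuilds the simulated response (full-duration boxcars) and the
    analysis design (duration/1.67 boxcars), band-passes the response the
    way the pipeline does, and applies the estimator's own definition
    (OLS -> Yule-Walker AR -> whitened least squares) with local
    arithmetic.  Returns {condition: expected beta}.
    """
    from statsmodels.regression.linear_model import yule_walker

    dt = 1.0 / fs
    h = ref_hrf(np.arange(0.0, 32.0, dt))
    m = n_samples

    def train(analysis):
        out = {}
        for cond in set(events.conditions):
            stim = np.zeros(m)
            for tr in events.for_condition(cond):
                i0 = int(round(tr.onset * fs))
                dur = tr.duration / boxcar_divisor if analysis else tr.duration
                stim[i0:i0 + max(1, int(round(dur * fs)))] = 1.0
            single = np.convolve(h, np.ones(max(1, int(round(
                (5.6 / boxcar_divisor if analysis else 5.6) * fs)))))
            out[cond] = np.convolve(stim, h)[:m] / single.max()
        return out

    sim, ana = train(False), train(True)
    conds = sorted(ana)
    y = sum(amplitudes_by_condition.get(c, 0.0) * sim[c] for c in conds)
    lp = butter(5, 0.25, btype="lowpass", fs=fs, output="sos")
    hp = butter(5, 0.005, btype="highpass", fs=fs, output="sos")
    pad = min(m - 1, 1000)
    y = sosfiltfilt(hp, sosfiltfilt(lp, y, padlen=pad), padlen=pad)
    X = np.column_stack([ana[c] for c in conds] + [np.ones(m)])
    b0, *_ = np.linalg.lstsq(X, y, rcond=None)
    rho, _ = yule_walker(y - X @ b0, order=ar_order, method="mle")
    poly = np.concatenate([[1.0], -rho])
    yw = np.convolve(y, poly)[ar_order:m]
    Xw = np.column_stack([np.convolve(X[:, j], poly)[ar_order:m]
                          for j in range(X.shape[1])])
    coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    return dict(zip(conds, coef[: len(conds)]))


def brute_force_bh(p, q=0.05):
    """Exhaustive step-up rule: largest k with p_(k) <= k q / n."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    k_max = 0
    for k in range(1, n + 1):
        if p[order[k - 1]] <= k * q / n:
            k_max = k
    reject = np.zeros(n, bool)
    reject[order[:k_max]] = True
    return reject
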