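"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit loops, order-statistics
enumeration and generic optimisation, deliberately sharing no code with
the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize


# --------------------------------------------------------------------------
# order statistics


def bf_median(values):
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def bf_quantile(values, q):
    """Type-7 quantile by explicit interpolation between order statistics."""
    s = sorted(values)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


# --------------------------------------------------------------------------
# the sixteen windowed features, loop by loop


def bf_features(window_rr, quantile_order=0.7, prp_low=120.0, prp_high=160.0,
                nn_threshold=50.0):
    rr = [float(v) for v in window_rr]
    n = len(rr)
    k = (n - 1) // 2
    hr = [60000.0 / v for v in rr]

    med = bf_median(hr)
    mad = bf_median([abs(h - med) for h in hr])
    qnt = bf_quantile(hr, quantile_order)
    prp = sum(1 for h in hr if prp_low <= h <= prp_high) / n

    mean_hr = sum(hr) / n
    std_hr = math.sqrt(sum((mean_hr - h) ** 2 for h in hr) / (n - 1))
    drr = [rr[i + 1] - rr[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in drr) / (n - 1))
    pnn50 = 100.0 * sum(1 for d in drr if abs(d) > nn_threshold) / (n - 1)

    var_drr = sum(d * d for d in drr) / len(drr) - (sum(drr) / len(drr)) ** 2
    sd1 = math.sqrt(var_drr / 2.0)
    mean_rr = sum(rr) / n
    var_rr = sum((v - mean_rr) ** 2 for v in rr) / n
    sd2 = math.sqrt(max(2.0 * var_rr - var_drr / 2.0, 0.0))
    tp = sum(
        1
        for j in range(1, n - 1)
        if (rr[j] - rr[j - 1]) * (rr[j + 1] - rr[j]) < 0
    )
    tpr = tp / ((2 * n - 4) / 3)

    d = [(rr[i] - rr[i + 1]) / (rr[i] + rr[i + 1]) for i in range(n - 1)]
    dbar = sum(d) / (n - 1)
    di_yeh = math.sqrt(sum((v - dbar) ** 2 for v in d) / (n - 2))
    big_d = [abs(v) for v in d]
    med_d = bf_median(big_d)
    stv_zug = sum(abs(v - med_d) for v in big_d) / (n - 1)
    stv_huey = 0.0
    for i in range(1, n - 1):
        if (hr[i - 1] - hr[i]) * (hr[i] - hr[i + 1]) < 0:
            stv_huey += abs(hr[i + 1] - hr[i])
    phi = [math.degrees(math.atan(rr[i] / rr[i - 1])) for i in range(1, n)]
    sti_haan = bf_quantile(phi, 0.75) - bf_quantile(phi, 0.25)

    return {
        "hr": hr[k],
        "med": med,
        "mad": mad,
        "qnt": qnt,
        "prp": prp,
        "mean_hr": mean_hr,
        "std_hr": std_hr,
        "rmssd": rmssd,
        "pnn50": pnn50,
        "sd1": sd1,
        "sd2": sd2,
        "tpr": tpr,
        "di_yeh": di_yeh,
        "stv_zug": stv_zug,
        "stv_huey": stv_huey,
        "sti_haan": sti_haan,
    }


# --------------------------------------------------------------------------
# LSVM oracles: generic optimisation of the primal / dual problems


def qp_primal(X, y, gamma):
    """Minimise (||w||^2 + w0^2)/2 + gamma/2 * sum max(0, 1 - y(xw - w0))^2.

    The squared-slack objective is smooth and convex, so a generic
    quasi-Newton solve is an exact oracle for the linear machine.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, t = X.shape

    def fg(z):
        w, w0 = z[:t], z[t]
        viol = np.maximum(1 - y * (X @ w - w0), 0.0)
        f = 0.5 * (w @ w + w0 * w0) + gamma / 2 * viol @ viol
        gw = w - gamma * (X.T @ (y * viol))
        gw0 = w0 + gamma * np.sum(y * viol)
        return f, np.concatenate([gw, [gw0]])

    res = minimize(
        fg, np.zeros(t + 1), jac=True, method="L-BFGS-B",
        options=dict(maxiter=20000, ftol=1e-18, gtol=1e-14),
    )
    return res.x[:t], float(res.x[t])


def qp_dual(Q, max_iter=20000):
    """Minimise 1/2 lam' Q lam - 1' lam subject to lam >= 0 (bound-constrained)."""
    n = Q.shape[0]
    one = np.ones(n)

    def fg(lam):
        g = Q @ lam - one
        return 0.5 * lam @ (Q @ lam) - lam @ one, g

    res = minimize(
        fg, np.zeros(n), jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * n,
        options=dict(maxiter=max_iter, ftol=1e-18, gtol=1e-14),
    )
    return res.x


# --------------------------------------------------------------------------
# aggregation oracle: exhaustive per-beat window recount


def bf_smooth(labels, w, p):
    labels = list(labels)
    n = len(labels)
    out = []
    for i in range(n):
        # the window is the w beats [i - w//2, i + w-1-w//2], clipped
        lo = i - w // 2
        hi = i + (w - 1 - w // 2)
        window = [labels[j] for j in range(max(lo, 0), min(hi, n - 1) + 1)]
        af = sum(1 for v in window if v > 0)
        out.append(1 if 100.0 * af / len(window) > p else -1)
    return out
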