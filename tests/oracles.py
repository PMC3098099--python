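"""Independent brute-force oracles used by the test suite.

These transcribe the documented definitions literally (plain Python
loops, no shared code paths with the implementation) so that the fast
vectorised implementations can be checked against them.
"""

import math

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm, rankdata


def brute_tseng(cy5, cy3, d, l, p, min_size=2, max_iter=500):
    """Literal transcription of the iterative rank-invariant selection
    with boundary exclusion; returns the 0-based selected index list."""
    G = len(cy5)
    r5 = rankdata(cy5)
    r3 = rankdata(cy3)
    S = [g for g in range(G)
         if abs(r5[g] - r3[g]) < d and l < (r5[g] + r3[g]) / 2.0 < G - l]
    if not S:
        raise ValueError("empty initial set")
    for _ in range(max_iter):
        r5s = rankdata([cy5[g] for g in S])
        r3s = rankdata([cy3[g] for g in S])
        new = [g for i, g in enumerate(S)
               if abs(r5s[i] - r3s[i]) < p * len(S)]
        if len(new) < min(min_size, G):
            return S, True  # stalled: keep previous set
        if len(new) == len(S):
            return new, False
        S = new
    return S, False


def brute_invmod(cy5, cy3, p, k, max_iter=10_000):
    """Literal transcription of the modified selection: proportional
    quota per iteration, inclusive boundary ties unless that retains the
    whole set (then probe-index tie-break), stop at |S| <= ceil(kG) or
    on perfect ties.  Returns (selected indices, weights dict)."""
    G = len(cy5)
    r5 = rankdata(cy5)
    r3 = rankdata(cy3)
    S = [g for g in range(G) if abs(r5[g] - r3[g]) < p * G]
    target = math.ceil(k * G)
    for _ in range(max_iter):
        if len(S) <= target:
            break
        r5s = rankdata([cy5[g] for g in S])
        r3s = rankdata([cy3[g] for g in S])
        delta = {g: abs(r5s[i] - r3s[i]) for i, g in enumerate(S)}
        quota = math.ceil(p * len(S))
        if quota >= len(S):
            break  # quota cannot shrink the set
        boundary = sorted(delta.values())[quota - 1]
        keep = [g for g in S if delta[g] <= boundary]
        if len(keep) == len(S):
            if max(delta.values()) == min(delta.values()):
                break  # perfect ties
            below = [g for g in S if delta[g] < boundary]
            at = sorted(g for g in S if delta[g] == boundary)
            keep = below + at[: quota - len(below)]
        S = sorted(keep)
    r5s = rankdata([cy5[g] for g in S])
    r3s = rankdata([cy3[g] for g in S])
    delta = {g: abs(r5s[i] - r3s[i]) for i, g in enumerate(S)}
    maxd = max(delta.values())
    if maxd == 0:
        weights = {g: 1.0 for g in S}
    else:
        weights = {g: (maxd - delta[g]) / maxd for g in S}
    return S, weights


def quadrature_expected_signal(s, mu, sigma, alpha):
    """E[T | S = s] by numerical integration of the posterior
    (truncated-normal form, integrated on the t axis)."""
    mstar = s - mu - sigma**2 / alpha
    hi = max(mstar + 12 * sigma, 12 * sigma)

    def dens(t):
        return norm.pdf(t, loc=mstar, scale=sigma)

    num, _ = quad(lambda t: t * dens(t), 0.0, hi, limit=200)
    den, _ = quad(dens, 0.0, hi, limit=200)
    return num / den


def local_linear_oracle(x_eval, x, y, w, span):
    """Direct tricube-weighted local linear solve at each point (zero
    weights excluded from the fit set entirely)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    keep = w > 0
    xf, yf, wf = x[keep], y[keep], w[keep]
    n = xf.size
    q = min(max(2, math.ceil(span * n)), n)
    out = []
    for x0 in np.atleast_1d(x_eval):
        d = np.abs(xf - x0)
        h = np.sort(d)[q - 1]
        u = d / h
        kern = np.where(u < 1, (1 - u**3) ** 3, 0.0) * wf
        X = np.column_stack([np.ones(n), xf - x0])
        sw = np.sqrt(kern)
        beta = np.linalg.lstsq(X * sw[:, None], yf * sw, rcond=None)[0]
        out.append(beta[0])
    return np.asarray(out)


def pair_count_auc(p, truth):
    """Mann-Whitney AUC by exhaustive pair counting (smaller p ranks
    higher; ties count half)."""
    p = np.asarray(p, float)
    truth = np.asarray(truth).astype(bool)
    pos = p[truth]
    neg = p[~truth]
    total = 0.0
    for pp in pos:
        for nn in neg:
            if pp < nn:
                total += 1.0
            elif pp == nn:
                total += 0.5
    return total / (pos.size * neg.size)


def truncnorm_mean(mean, sd):
    """Analytic mean of N(mean, sd^2) left-truncated at zero."""
    a = -mean / sd
    return mean + sd * norm.pdf(a) / (1.0 - norm.cdf(a))
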