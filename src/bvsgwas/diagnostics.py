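"""Posterior summaries: Bayes factors, evidence classes, HPD, ESS."""

from __future__ import annotations

import numpy as np

#: default prior inclusion probability implied by the Beta(100, 1) mixture
#: proportion prior (prior mean of pi1 under Beta(1, 100))
DEFAULT_PI1_PRIOR = 1.0 / 101.0

BF_STRONG = 10.0
BF_PUTATIVE = 3.2


def bayes_factor(p_hat: float, pi1_prior: float = DEFAULT_PI1_PRIOR) -> float:
    """Posterior odds of inclusion over prior odds.

    BF = [p/(1-p)] / [pi1/(1-pi1)].  ``p_hat == 1`` returns +inf.
    """
    if not (0.0 < pi1_prior < 1.0):
        raise ValueError("pi1_prior must lie strictly in (0, 1)")
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must lie in [0, 1]")
    if p_hat == 1.0:
        return np.inf
    prior_odds = pi1_prior / (1.0 - pi1_prior)
    return (p_hat / (1.0 - p_hat)) / prior_odds


def classify_evidence(bf: float) -> str:
    """Kass-Raftery style call: > 10 'significant', 3.2-10 'putative'."""
    if bf < 0:
        raise ValueError("Bayes factor cannot be negative")
    if bf > BF_STRONG:
        return "significant"
    if bf >= BF_PUTATIVE:
        return "putative"
    return "none"


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` posterior probability.

    Sorted-window method: among all windows of ceil(mass*n) consecutive
    order statistics, the narrowest one.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples for an HPD interval")
    k = max(1, int(np.ceil(mass * n)))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def effective_sample_size(samples: np.ndarray) -> float:
    """ESS = n / (1 + 2 sum rho_t), initial-positive-sequence truncation.

    Autocorrelations are accumulated in Geyer pairs until a pair sum goes
    non-positive.  A zero-variance series returns NaN; anti-correlated
    series are capped at n.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 samples")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0.0:
        return np.nan
    # FFT autocovariance
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        s += pair
        t += 2
    ess = n / (1.0 + 2.0 * s)
    return float(min(ess, n))
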