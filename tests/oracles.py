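"""Independent numerical oracles used by the test suite.

These recompute the statistics from their definitions via plain
arithmetic and numerical quadrature, deliberately avoiding the code
paths in :mod:`ugibvigil.disproportionality` (no conjugate shortcuts,
no shared helpers), so agreement is a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, optimize, stats


def woolf_ror(a, b, c, d, z=1.96):
    est = a * d / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, math.exp(math.log(est) - z * se), math.exp(math.log(est) + z * se)


def evans_prr(a, b, c, d, z=1.96):
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return est, math.exp(math.log(est) - z * se), math.exp(math.log(est) + z * se)


def yates_chi2(a, b, c, d):
    n = a + b + c + d
    num = max(abs(a * d - b * c) - n / 2, 0.0)
    return n * num * num / ((a + b) * (c + d) * (a + c) * (b + d))


def gamma_quantile_quad(shape, rate, prob, tol=1e-10):
    """Quantile of Gamma(shape, rate) by quadrature of the density + brentq."""

    def cdf(x):
        val, _ = integrate.quad(
            lambda t: stats.gamma.pdf(t, shape, scale=1.0 / rate),
            0.0,
            x,
            limit=200,
            epsabs=tol,
            epsrel=tol,
        )
        return val

    hi = shape / rate * 10 + 10.0
    while cdf(hi) < prob:
        hi *= 2
    return optimize.brentq(lambda x: cdf(x) - prob, 1e-300, hi, xtol=1e-13, rtol=1e-13)


def posterior_lambda_pdf(prior, a, e):
    """Unnormalized posterior density of the reporting ratio: prior x Poisson lik."""

    def density(lam):
        g1 = stats.gamma.pdf(lam, prior.alpha1, scale=1.0 / prior.beta1)
        g2 = stats.gamma.pdf(lam, prior.alpha2, scale=1.0 / prior.beta2)
        pri = prior.w * g1 + (1.0 - prior.w) * g2
        return pri * stats.poisson.pmf(a, lam * e)

    return density


def _split_quad(f, lo, hi, center):
    """Integrate f over [lo, hi], splitting at the likely mass center."""
    pieces = sorted({lo, min(max(center, lo), hi), hi})
    total = 0.0
    for x0, x1 in zip(pieces[:-1], pieces[1:]):
        val, _ = integrate.quad(f, x0, x1, limit=400, epsabs=1e-13, epsrel=1e-11)
        total += val
    return total


def ebgm_quadrature(prior, a, e):
    """(EBGM, EBGM05) by direct numerical integration of prior x likelihood."""
    density = posterior_lambda_pdf(prior, a, e)
    center = (a + 1.0) / max(e, 1e-6)
    hi = center * 12 + 20.0
    z = _split_quad(density, 0.0, hi, center)
    mean_log = _split_quad(lambda x: math.log(x) * density(x), 1e-300, hi, center) / z

    def cdf(x):
        return _split_quad(density, 0.0, x, min(center, x)) / z

    q05 = optimize.brentq(lambda x: cdf(x) - 0.05, 1e-12, hi, xtol=1e-13, rtol=1e-12)
    return math.exp(mean_log), q05


def region_counts_bruteforce(flag_sets, methods=("ROR", "PRR", "EBGM", "BCPNN")):
    """Exclusive Venn-region counts by direct power-set comparison."""
    from itertools import combinations

    counts = {"none": 0}
    for k in range(1, len(methods) + 1):
        for combo in combinations(methods, k):
            counts["+".join(combo)] = 0
    for flags in flag_sets:
        active = tuple(m for m in methods if m in flags)
        counts["+".join(active) if active else "none"] += 1
    return counts


def ztpois_pmf_oracle(rate, kmax=60):
    """Zero-truncated Poisson pmf over 1..kmax, independent arithmetic."""
    k = np.arange(1, kmax + 1)
    raw = np.exp(-rate) * rate**k / np.array([math.factorial(int(i)) for i in k])
    return raw / raw.sum()
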