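"""Independent oracle implementations used only by the tests.

Each oracle re-derives a quantity along a different route than the
package: a straight vectorised transcription of the published binary-HGF
update equations, a Gibbs sampler for the random-effects model-frequency
posterior, a noncentral-t formulation of the JZS Bayes factor, and a
brute-force two-way ANOVA for the ICC. They deliberately share no code
with ``advicehgf``.
"""

import numpy as np
from scipy import integrate, stats


def reference_binary_hgf(kappa2, omega2, theta, mu2_0, sigma2_0, mu3_0, sigma3_0, u,
                         phi3=0.0, m3=0.0, mean_reverting=False):
    """Plain transcription of the 3-level binary HGF updates.

    Works in precisions (pi = 1/sigma) throughout, mirroring how the
    update equations are usually printed, rather than the package's
    variance bookkeeping. Returns dict of per-trial arrays.
    """
    u = np.asarray(u, dtype=float)
    n = len(u)
    mu2 = np.empty(n + 1); pi2 = np.empty(n + 1)
    mu3 = np.empty(n + 1); pi3 = np.empty(n + 1)
    mu2[0], pi2[0] = mu2_0, 1.0 / sigma2_0
    mu3[0], pi3[0] = mu3_0, 1.0 / sigma3_0
    muhat1 = np.empty(n); muhat2 = np.empty(n); muhat3 = np.empty(n)
    delta1 = np.empty(n); delta2 = np.empty(n)
    for k in range(n):
        muhat2[k] = mu2[k]
        muhat1[k] = 1.0 / (1.0 + np.exp(-muhat2[k]))
        muhat3[k] = mu3[k] + phi3 * (m3 - mu3[k]) if mean_reverting else mu3[k]
        pihat2 = 1.0 / (1.0 / pi2[k] + np.exp(kappa2 * mu3[k] + omega2))
        pihat3 = 1.0 / (1.0 / pi3[k] + theta)
        delta1[k] = u[k] - muhat1[k]
        pi2[k + 1] = pihat2 + muhat1[k] * (1 - muhat1[k])
        mu2[k + 1] = muhat2[k] + (1.0 / pi2[k + 1]) * delta1[k]
        delta2[k] = (1.0 / pi2[k + 1] + (mu2[k + 1] - muhat2[k]) ** 2) * pihat2 - 1.0
        w2 = np.exp(kappa2 * mu3[k] + omega2) * pihat2
        pi3[k + 1] = pihat3 + 0.5 * kappa2**2 * w2 * (w2 + (2 * w2 - 1) * delta2[k])
        assert pi3[k + 1] > 0, "oracle trajectory ill-posed"
        mu3[k + 1] = muhat3[k] + kappa2 * w2 / (2 * pi3[k + 1]) * delta2[k]
    return {
        "muhat1": muhat1, "muhat2": muhat2, "muhat3": muhat3,
        "mu2": mu2[1:], "mu3": mu3[1:],
        "sigma2": 1.0 / pi2[1:], "sigma3": 1.0 / pi3[1:],
        "delta1": delta1, "delta2": delta2,
    }


def gibbs_bms(lme, alpha0=1.0, n_iter=60_000, burn=5_000, seed=0):
    """Gibbs sampler over the exact random-effects posterior.

    Alternates sampling each subject's model assignment given the
    frequencies with sampling frequencies ~ Dirichlet(alpha0 + counts);
    returns Monte-Carlo estimates of the expected frequencies and the
    exceedance probabilities.
    """
    lme = np.asarray(lme, dtype=float)
    n, k = lme.shape
    rng = np.random.default_rng(seed)
    r = np.full(k, 1.0 / k)
    f_acc = np.zeros(k)
    exc = np.zeros(k)
    kept = 0
    for it in range(n_iter):
        logp = lme + np.log(r)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        cum = p.cumsum(axis=1)
        m = (rng.random((n, 1)) < cum).argmax(axis=1)
        counts = np.bincount(m, minlength=k)
        r = rng.dirichlet(alpha0 + counts)
        if it >= burn:
            f_acc += r
            exc[np.argmax(r)] += 1
            kept += 1
    return f_acc / kept, exc / kept


def beta_exceedance_2(alpha):
    """Exact P(r_1 > r_2) for r ~ Dirichlet(a1, a2): the Beta(a1, a2)
    upper tail beyond 1/2 — closed-form oracle for the two-model
    exceedance probability at given Dirichlet counts."""
    a1, a2 = alpha
    p1 = stats.beta.sf(0.5, a1, a2)
    return np.array([p1, 1.0 - p1])


def jzs_bf10_nct(t, n, r=np.sqrt(2) / 2):
    """JZS BF10 via the noncentral-t route: the marginal likelihood under
    the alternative integrates the noncentral-t density of the observed t
    over a Cauchy(0, r) prior on the standardised effect size."""
    df = n - 1

    def alt(delta):
        return stats.nct.pdf(t, df, delta * np.sqrt(n)) * stats.cauchy.pdf(delta, 0, r)

    m1, _ = integrate.quad(alt, -np.inf, np.inf, limit=400)
    m0 = stats.t.pdf(t, df)
    return m1 / m0


def anova_icc_a1(x, y):
    """ICC(A,1) from an explicit loop-based two-way ANOVA decomposition."""
    data = [[float(a), float(b)] for a, b in zip(x, y)]
    n, k = len(data), 2
    grand = sum(sum(row) for row in data) / (n * k)
    ss_rows = sum(k * (sum(row) / k - grand) ** 2 for row in data)
    col_means = [sum(row[j] for row in data) / n for j in range(k)]
    ss_cols = sum(n * (cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((v - grand) ** 2 for row in data for v in row)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
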