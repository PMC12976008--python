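"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form conjugate algebra used by the
implementation: the EBGM oracle integrates the unnormalized posterior on a
log grid, and the BCPNN oracle samples the Beta posteriors directly.
"""

import numpy as np
from scipy import stats


def ebgm_quadrature(a, e, prior, n_grid=400_001):
    """Posterior geometric mean and 5th percentile of λ by log-grid quadrature.

    Works on u = ln λ with the unnormalized posterior
    prior(λ)·Poisson(a; λE)·λ (Jacobian).  The left integration bound adapts
    to the smallest gamma shape so the power-law tail λ^(shape+a-1) is
    truncated below 1e-13 relative mass.
    """
    shape_min = min(prior.alpha1, prior.alpha2) + a
    u_lo = min(-40.0, -35.0 / shape_min)
    means = [(prior.alpha1 + a) / (prior.beta1 + e),
             (prior.alpha2 + a) / (prior.beta2 + e)]
    u_hi = np.log(max(means)) + 12.0
    u = np.linspace(u_lo, u_hi, n_grid)
    lam = np.exp(u)
    log_prior = np.logaddexp(
        np.log(prior.p) + stats.gamma.logpdf(lam, prior.alpha1, scale=1 / prior.beta1),
        np.log1p(-prior.p) + stats.gamma.logpdf(lam, prior.alpha2, scale=1 / prior.beta2),
    )
    log_post = log_prior + stats.poisson.logpmf(a, lam * e) + u
    log_post -= log_post.max()
    w = np.exp(log_post)
    z = np.trapezoid(w, u)
    mean_log = np.trapezoid(u * w, u) / z
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(u))]) / z
    q05 = np.interp(0.05, cdf, u)
    return float(np.exp(mean_log)), float(np.exp(q05))


def bcpnn_monte_carlo(a, b, c, d, rng, n_draws=100_000):
    """Posterior mean of the information component by Beta sampling.

    Independent Beta posteriors for the joint and the two marginal
    reporting probabilities, with the same margin-tied prior the closed
    form uses.
    """
    n = a + b + c + d
    gamma = (n + 2.0) * (n + 2.0) / ((a + b + 1.0) * (a + c + 1.0))
    p11 = rng.beta(a + 1.0, n - a + gamma - 1.0, n_draws)
    p1 = rng.beta(a + b + 1.0, n - a - b + 1.0, n_draws)
    p2 = rng.beta(a + c + 1.0, n - a - c + 1.0, n_draws)
    ic = np.log2(p11 / (p1 * p2))
    return float(ic.mean())


def dedup_brute_force(demos):
    """Group-by/argmax reference for the deduplication rule (pandas route)."""
    import pandas as pd

    df = pd.DataFrame({
        "caseid": [r.caseid for r in demos],
        "primaryid_int": [int(r.primaryid) for r in demos],
        "date_key": [r.fda_dt.sort_key() for r in demos],
        "idx": range(len(demos)),
    })
    keep = []
    for _, grp in df.groupby("caseid", sort=False):
        best = max(grp.itertuples(), key=lambda t: (t.date_key, t.primaryid_int))
        keep.append(best.idx)
    return {demos[i].primaryid for i in keep}


def pair_counts_brute_force(cohort, comparator, term, level="PT", soc_map=None):
    """Double-loop 2×2 cell counter for one event term."""
    def terms_of(case):
        pts = {r.pt for r in case.reactions}
        if level == "SOC":
            return {soc_map[p] for p in pts}
        return pts

    a = b = c = d = 0
    for case in cohort:
        ts = terms_of(case)
        a += term in ts
        b += len(ts) - (term in ts)
    for case in comparator:
        ts = terms_of(case)
        c += term in ts
        d += len(ts) - (term in ts)
    return a, b, c, d
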