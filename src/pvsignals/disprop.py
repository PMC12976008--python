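"""Disproportionality statistics for spontaneous-report signal detection.

Four estimators over a 2×2 table (a, b, c, d) comparing a drug's reporting
of one event against the rest of the database:

* **ROR** — reporting odds ratio ad/(bc) with a Wald confidence interval on
  the log scale.
* **PRR** — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with the
  Pearson χ² statistic (no continuity correction).
* **BCPNN IC** — the information component log2 P(drug, event)/P(drug)P(event)
  under independent Beta posteriors for the three probabilities; point value
  and lower bound are the exact posterior mean and mean − 1.96·sd, computed
  with digamma/trigamma functions.
* **MGPS EBGM** — empirical-Bayes geometric mean of the relative reporting
  rate λ, where a ~ Poisson(λE) and λ has a two-component gamma mixture
  prior fitted to the whole database by marginal maximum likelihood
  (negative-binomial mixture).  EBGM05 is the posterior 5th percentile.

A drug–event pair is called a signal if it passes any one of the
field-standard per-method thresholds (a ≥ 3 with ROR lower bound > 1;
PRR ≥ 2 with χ² ≥ 4 and a ≥ 3; IC025 > 0; EBGM05 > 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma, gammaln, logsumexp, polygamma

from .contingency import ContingencyTable

LN2 = np.log(2.0)
Z95 = 1.96

# signal thresholds (the standard quartet used in FAERS studies)
MIN_CASES = 3
PRR_MIN = 2.0
CHI2_MIN = 4.0
EBGM05_MIN = 2.0

# BCPNN prior constants (Bate's data-dependent prior: E[IC] ≈ 0 under
# independence): marginal Beta(1, 1) priors, joint Beta(1, γ-1) with γ tied
# to the margins.
_ALPHA1 = _BETA1 = 1.0
_ALPHA = _BETA = 2.0
_GAMMA11 = 1.0


def needs_correction(t: ContingencyTable) -> bool:
    """True when a zero cell makes ROR/PRR undefined without correction."""
    return min(t.cells()) == 0


def _corrected_cells(t: ContingencyTable) -> tuple[float, float, float, float]:
    """Haldane–Anscombe: add 0.5 to every cell iff any cell is zero."""
    if needs_correction(t):
        return tuple(x + 0.5 for x in t.cells())
    return tuple(float(x) for x in t.cells())


def ror_stat(t: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with 95% Wald CI (continuity-corrected if needed)."""
    a, b, c, d = _corrected_cells(t)
    ror = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(ror) - Z95 * se))
    hi = float(np.exp(np.log(ror) + Z95 * se))
    return float(ror), lo, hi


def prr_stat(t: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson χ² (no Yates correction)."""
    a, b, c, d = _corrected_cells(t)
    n = a + b + c + d
    prr = (a / (a + b)) / (c / (c + d))
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(prr), float(chi2)


def bcpnn_stat(t: ContingencyTable) -> tuple[float, float]:
    """Information component: exact posterior mean and 95% lower bound.

    Posteriors (independent, per the BCPNN construction):
    p11 ~ Beta(a+1, N−a+γ−1), p1 ~ Beta(a+b+1, N−a−b+1),
    p2 ~ Beta(a+c+1, N−a−c+1), with γ chosen from the margins so the prior
    is centred on independence.  IC = log2 p11/(p1 p2); its posterior mean
    and variance follow from digamma/trigamma moments of log-Beta variables.
    """
    a, b, c, _ = t.cells()
    n = t.n
    if n <= 0:
        raise ValueError("empty table")
    gamma = _GAMMA11 * (n + _ALPHA) * (n + _BETA) / ((a + b + _ALPHA1) * (a + c + _BETA1))
    ic = (
        digamma(a + _GAMMA11) - digamma(n + gamma)
        - digamma(a + b + _ALPHA1) + digamma(n + _ALPHA)
        - digamma(a + c + _BETA1) + digamma(n + _BETA)
    ) / LN2
    var = (
        polygamma(1, a + _GAMMA11) - polygamma(1, n + gamma)
        + polygamma(1, a + b + _ALPHA1) - polygamma(1, n + _ALPHA)
        + polygamma(1, a + c + _BETA1) - polygamma(1, n + _BETA)
    ) / LN2 ** 2
    ic025 = ic - Z95 * np.sqrt(var)
    return float(ic), float(ic025)


# ---------------------------------------------------------------------------
# MGPS: gamma-mixture empirical-Bayes shrinkage


@dataclass(frozen=True)
class MgpsHyperParams:
    """Two-component gamma prior for λ: P·Γ(α1, β1) + (1−P)·Γ(α2, β2).

    Shapes α, rates β (mean of each component is α/β).  ``loglik`` is the
    marginal log-likelihood at the fitted values; ``n_cells`` the number of
    cells used in the fit.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float
    loglik: float = float("nan")
    converged: bool = True
    n_cells: int = 0

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.p < 1:
            raise ValueError("mixture weight must lie in (0, 1)")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.alpha1, self.beta1, self.alpha2, self.beta2, self.p)


DEFAULT_MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


class MgpsConvergenceError(RuntimeError):
    """Raised when the marginal-likelihood optimizer fails to converge."""

    def __init__(self, message, best_params, grad_norm):
        super().__init__(f"{message} (best-found {best_params}, |grad| = {grad_norm:.3g})")
        self.best_params = best_params
        self.grad_norm = grad_norm


def _nb_logpmf(a, size, e, rate):
    """log NB(a; size, rate/(rate+E)) — marginal of Poisson(λE), λ~Γ(size, rate)."""
    p = rate / (rate + e)
    return (gammaln(a + size) - gammaln(size) - gammaln(a + 1)
            + size * np.log(p) + a * np.log1p(-p))


def mgps_marginal_loglik(params, a, e) -> float:
    """Σ log of the two-component negative-binomial mixture mass."""
    a1, b1, a2, b2, p = params
    p = min(max(p, 1e-12), 1 - 1e-12)
    l1 = np.log(p) + _nb_logpmf(a, a1, e, b1)
    l2 = np.log1p(-p) + _nb_logpmf(a, a2, e, b2)
    return float(logsumexp(np.stack([l1, l2]), axis=0).sum())


def fit_mgps_prior(
    a: Sequence[float],
    e: Sequence[float],
    include_zeros: bool = False,
    start: tuple = DEFAULT_MGPS_START,
    min_cells: int = 100,
) -> MgpsHyperParams:
    """Fit the five gamma-mixture hyperparameters by marginal ML.

    ``a``/``e`` are the observed and expected counts of every database cell.
    By default only cells with a ≥ 1 enter the objective (extracts do not
    enumerate empty cells); set ``include_zeros=True`` when the cell grid is
    fully enumerated.  Optimization runs on unconstrained transformed
    parameters (log shapes/rates, logit weight) with L-BFGS-B.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.shape != e.shape:
        raise ValueError("a and E must have the same length")
    if not include_zeros:
        mask = a >= 1
        a, e = a[mask], e[mask]
    if np.count_nonzero(a >= 1) < min_cells:
        raise ValueError(f"need at least {min_cells} cells with a >= 1 to fit the prior")

    def unpack(theta):
        return (np.exp(theta[0]), np.exp(theta[1]), np.exp(theta[2]),
                np.exp(theta[3]), 1.0 / (1.0 + np.exp(-theta[4])))

    def objective(theta):
        with np.errstate(all="ignore"):
            ll = mgps_marginal_loglik(unpack(theta), a, e)
        return -ll if np.isfinite(ll) else 1e300

    theta0 = np.array([np.log(start[0]), np.log(start[1]), np.log(start[2]),
                       np.log(start[3]), np.log(start[4] / (1 - start[4]))])
    # box on the transformed scale keeps shapes/rates in [e^-9, e^9] and the
    # weight away from the degenerate 0/1 corners
    bounds = [(-9.0, 9.0)] * 4 + [(-12.0, 12.0)]
    res = optimize.minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500})
    if not res.success:
        res2 = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                 options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
        if res2.fun <= res.fun:
            res = res2
    grad = optimize.approx_fprime(res.x, objective, 1e-6)
    fitted = unpack(res.x)
    ll_fit = -res.fun
    ll_start = mgps_marginal_loglik(start, a, e)
    if not np.isfinite(ll_fit) or ll_fit < ll_start - 1e-6:
        raise MgpsConvergenceError("MGPS prior fit did not converge", fitted,
                                   float(np.linalg.norm(grad)))
    return MgpsHyperParams(*fitted, loglik=ll_fit, converged=bool(res.success),
                           n_cells=len(a))


def _posterior_mix(a: float, e: float, prior: MgpsHyperParams):
    """Posterior of λ: weight Q on Γ(α1+a, β1+E), 1−Q on Γ(α2+a, β2+E)."""
    lw1 = np.log(prior.p) + _nb_logpmf(a, prior.alpha1, e, prior.beta1)
    lw2 = np.log1p(-prior.p) + _nb_logpmf(a, prior.alpha2, e, prior.beta2)
    q = float(np.exp(lw1 - np.logaddexp(lw1, lw2)))
    return q, (prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a, prior.beta2 + e)


def ebgm_stat(a: float, e: float, prior: MgpsHyperParams) -> tuple[float, float]:
    """EBGM = exp E[ln λ | a] and EBGM05 = posterior 5th percentile of λ.

    The mean-log uses digamma moments of the gamma components; the
    percentile is found by bisection on the mixture CDF to |ΔCDF| < 1e-9.
    """
    if e <= 0:
        raise ValueError("expected count E must be positive")
    q, (s1, r1), (s2, r2) = _posterior_mix(a, e, prior)
    mean_log = q * (digamma(s1) - np.log(r1)) + (1 - q) * (digamma(s2) - np.log(r2))
    ebgm = float(np.exp(mean_log))

    def cdf(x):
        return (q * stats.gamma.cdf(x, s1, scale=1.0 / r1)
                + (1 - q) * stats.gamma.cdf(x, s2, scale=1.0 / r2))

    lo = 0.0
    hi = max(stats.gamma.ppf(0.999, s1, scale=1.0 / r1),
             stats.gamma.ppf(0.999, s2, scale=1.0 / r2))
    mid = 0.5 * (lo + hi)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f = cdf(mid)
        if abs(f - 0.05) < 1e-9:
            break
        if f < 0.05:
            lo = mid
        else:
            hi = mid
    return ebgm, float(mid)


# ---------------------------------------------------------------------------
# combined signal table


@dataclass(frozen=True)
class SignalStats:
    term: str
    table: ContingencyTable
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    corrected: bool

    @property
    def sig_ror(self) -> bool:
        return self.table.a >= MIN_CASES and self.ror_lo > 1.0

    @property
    def sig_prr(self) -> bool:
        return (self.table.a >= MIN_CASES and self.prr >= PRR_MIN
                and self.chi2 >= CHI2_MIN)

    @property
    def sig_ic(self) -> bool:
        return self.ic025 > 0.0

    @property
    def sig_ebgm(self) -> bool:
        return self.ebgm05 > EBGM05_MIN

    @property
    def any_signal(self) -> bool:
        return self.sig_ror or self.sig_prr or self.sig_ic or self.sig_ebgm


def compute_stats(term: str, t: ContingencyTable, prior: MgpsHyperParams) -> SignalStats:
    ror, lo, hi = ror_stat(t)
    prr, chi2 = prr_stat(t)
    ic, ic025 = bcpnn_stat(t)
    ebgm, ebgm05 = ebgm_stat(t.a, t.expected, prior)
    return SignalStats(term, t, ror, lo, hi, prr, chi2, ic, ic025, ebgm, ebgm05,
                       needs_correction(t))


SIGNAL_COLUMNS = [
    "term", "a", "b", "c", "d", "ror", "ror_lo", "ror_hi", "prr", "chi2",
    "ic", "ic025", "ebgm", "ebgm05", "sig_ror", "sig_prr", "sig_ic",
    "sig_ebgm", "any_signal", "corrected",
]


def detect_signals(
    tables: Mapping[str, ContingencyTable], prior: MgpsHyperParams
) -> pd.DataFrame:
    """All four statistics plus flags for every event term, sorted by a desc."""
    rows = []
    for term, t in tables.items():
        s = compute_stats(term, t, prior)
        rows.append({
            "term": term, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "ror": s.ror, "ror_lo": s.ror_lo, "ror_hi": s.ror_hi,
            "prr": s.prr, "chi2": s.chi2, "ic": s.ic, "ic025": s.ic025,
            "ebgm": s.ebgm, "ebgm05": s.ebgm05,
            "sig_ror": s.sig_ror, "sig_prr": s.sig_prr, "sig_ic": s.sig_ic,
            "sig_ebgm": s.sig_ebgm, "any_signal": s.any_signal,
            "corrected": s.corrected,
        })
    df = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    if len(df):
        df = df.sort_values(["a", "term"], ascending=[False, True], kind="mergesort")
    return df.reset_index(drop=True)


def flags_from_row(row: Mapping) -> dict:
    """Recompute the four flags from the printed cells of a signal-table row.

    Lets an exported CSV be audited without rerunning the pipeline.
    """
    a = int(row["a"])
    return {
        "sig_ror": a >= MIN_CASES and float(row["ror_lo"]) > 1.0,
        "sig_prr": (a >= MIN_CASES and float(row["prr"]) >= PRR_MIN
                    and float(row["chi2"]) >= CHI2_MIN),
        "sig_ic": float(row["ic025"]) > 0.0,
        "sig_ebgm": float(row["ebgm05"]) > EBGM05_MIN,
    }
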