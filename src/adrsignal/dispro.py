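"""Disproportionality statistics on 2x2 contingency tables.

The table convention is ``a`` = target drug & target event, ``b`` = target
drug & other events, ``c`` = other drugs & target event, ``d`` = neither
(in CLEAR usage: exposed/control x abnormal/normal). On top of the
frequentist measures (PRR, ROR, Yule's Q, Yates-corrected chi-square) two
Bayesian shrinkage measures are provided:

* the BCPNN information component IC = log2 p(x,y) / (p(x) p(y)) with
  conjugate Beta priors matched to independence; posterior mean and SD are
  computed exactly via polygamma moments of log-Beta variables (the
  first-order closed forms in the pharmacovigilance literature approximate
  these);
* the gamma-Poisson shrinker: observed counts a ~ Poisson(lambda * E) with
  expected count E = (a+b)(a+c)/N and a two-gamma mixture prior on the
  relative rate lambda, fitted by marginal maximum likelihood across all
  tables; EBGM = exp E[ln lambda | a] and EB05 the posterior 5th percentile.

Signal thresholds follow the conventional criteria: PRR-1.96SE > 1,
ROR-1.96SE > 1, Q-1.96SE > 1, chi-square p < 0.05, IC-2SD > 0, EB05 > 2
(all strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "TwoByTwo",
    "DisproResult",
    "GpsPrior",
    "basic_stats",
    "bcpnn_ic",
    "fit_gps",
    "gps_loglik",
    "eb05",
    "comparator_signals",
    "dispro_result",
]


@dataclass(frozen=True)
class TwoByTwo:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n == 0:
            raise ValueError("table total must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected target-target count under row/column independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass
class DisproResult:
    prr: float = math.nan
    prr_lo: float = math.nan
    ror: float = math.nan
    ror_lo: float = math.nan
    yule_q: float = math.nan
    yule_lo: float = math.nan
    chi2_p: float = math.nan
    ic: float = math.nan
    ic_sd: float = math.nan
    ic_lo: float = math.nan
    ebgm: float = math.nan
    eb05: float = math.nan
    zero_corrected: bool = False


@dataclass(frozen=True)
class GpsPrior:
    """DuMouchel two-gamma mixture prior on the relative rate (shape/rate)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float
    loglik: float = math.nan

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0.0 < self.w < 1.0:
            raise ValueError("mixture weight must lie in (0, 1)")


def basic_stats(t: TwoByTwo, result: DisproResult | None = None) -> DisproResult:
    """PRR, ROR, Yule's Q (each with its 1.96-SE lower bound) and chi-square p.

    Any zero cell triggers the Haldane-Anscombe +0.5 correction for the
    ratio measures (flagged via ``zero_corrected``); the chi-square test
    runs on the raw counts with Yates continuity correction.
    """
    res = result if result is not None else DisproResult()
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        res.zero_corrected = True

    prr = (a / (a + b)) / (c / (c + d))
    se_ln_prr = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    res.prr = prr
    res.prr_lo = math.exp(math.log(prr) - 1.96 * se_ln_prr)

    ror = (a * d) / (b * c)
    se_ln_ror = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    res.ror = ror
    res.ror_lo = math.exp(math.log(ror) - 1.96 * se_ln_ror)

    q = (a * d - b * c) / (a * d + b * c)
    se_q = ((1 - q * q) / 2.0) * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    res.yule_q = q
    res.yule_lo = q - 1.96 * se_q

    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        res.chi2_p = 1.0  # degenerate margin: no evidence of association
    else:
        res.chi2_p = float(stats.chi2_contingency(table, correction=True).pvalue)
    return res


def bcpnn_ic(t: TwoByTwo, result: DisproResult | None = None) -> DisproResult:
    """BCPNN information component with exact log-Beta posterior moments.

    Model: p(x) ~ Beta(1,1), p(y) ~ Beta(1,1) and p(x,y) ~ Beta(1, gamma-1)
    with gamma = (N+2)^2 / ((a+b+1)(a+c+1)) so that the prior satisfies
    E[p(x,y)] = E[p(x)] E[p(y)] (shrinkage toward independence). The IC
    posterior mean and SD follow from digamma/trigamma moments of the three
    (conditionally independent) Beta posteriors; ``ic_lo = ic - 2 sd``.
    """
    res = result if result is not None else DisproResult()
    n = float(t.n)
    cx, cy, cxy = float(t.a + t.b), float(t.a + t.c), float(t.a)
    gamma = (n + 2.0) ** 2 / ((cx + 1.0) * (cy + 1.0))

    def log_beta_moments(alpha: float, beta: float) -> tuple[float, float]:
        mean = special.digamma(alpha) - special.digamma(alpha + beta)
        var = special.polygamma(1, alpha) - special.polygamma(1, alpha + beta)
        return float(mean), float(var)

    m_xy, v_xy = log_beta_moments(cxy + 1.0, n - cxy + gamma - 1.0)
    m_x, v_x = log_beta_moments(cx + 1.0, n - cx + 1.0)
    m_y, v_y = log_beta_moments(cy + 1.0, n - cy + 1.0)

    ln2 = math.log(2.0)
    res.ic = (m_xy - m_x - m_y) / ln2
    res.ic_sd = math.sqrt(v_xy + v_x + v_y) / ln2
    res.ic_lo = res.ic - 2.0 * res.ic_sd
    return res


# ---------------------------------------------------------------------------
# gamma-Poisson shrinker (DuMouchel)
# ---------------------------------------------------------------------------

_DEFAULT_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
_SHAPE_BOUNDS = (1e-4, 50.0)
_W_BOUNDS = (1e-3, 1.0 - 1e-3)


def _nb_logpmf(n: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    # marginal of Poisson(lambda*E) with lambda ~ Gamma(alpha, rate beta)
    return (
        special.gammaln(alpha + n)
        - special.gammaln(alpha)
        - special.gammaln(n + 1.0)
        + alpha * np.log(beta / (beta + e))
        + n * np.log(e / (beta + e))
    )


def gps_loglik(
    params: Sequence[float], counts: np.ndarray, expected: np.ndarray
) -> float:
    """Marginal log-likelihood of the two-gamma mixture over all tables."""
    a1, b1, a2, b2, w = params
    l1 = _nb_logpmf(counts, expected, a1, b1)
    l2 = _nb_logpmf(counts, expected, a2, b2)
    return float(
        np.sum(special.logsumexp([l1 + math.log(w), l2 + math.log1p(-w)], axis=0))
    )


def _tables_to_arrays(tables: Iterable[TwoByTwo]) -> tuple[np.ndarray, np.ndarray]:
    counts = np.array([t.a for t in tables], dtype=float)
    expected = np.array([t.expected_a for t in tables], dtype=float)
    expected = np.maximum(expected, 1e-10)  # margin-zero tables carry no signal
    return counts, expected


def fit_gps(
    tables: Sequence[TwoByTwo], n_starts: int = 10, seed: int = 0
) -> GpsPrior:
    """Fit the mixture hyperparameters by marginal maximum likelihood.

    Bounded L-BFGS-B from the canonical DuMouchel starting point plus
    ``n_starts`` seeded random restarts; the best converged optimum wins.
    """
    if len(tables) < 10:
        raise ValueError("need at least 10 tables for a meaningful GPS fit")
    counts, expected = _tables_to_arrays(tables)

    def objective(params: np.ndarray) -> float:
        return -gps_loglik(params, counts, expected)

    rng = np.random.default_rng(seed)
    starts = [np.array(_DEFAULT_START)]
    lo, hi = _SHAPE_BOUNDS
    for _ in range(n_starts):
        shapes = np.exp(rng.uniform(math.log(max(lo, 1e-3)), math.log(hi), size=4))
        starts.append(np.concatenate([shapes, [rng.uniform(0.1, 0.9)]]))

    bounds = [_SHAPE_BOUNDS] * 4 + [_W_BOUNDS]
    best = None
    for x0 in starts:
        opt = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(opt.fun):
            continue
        if best is None or opt.fun < best.fun:
            best = opt
    if best is None:
        raise RuntimeError("GPS fit failed to converge from every starting point")
    a1, b1, a2, b2, w = best.x
    return GpsPrior(a1, b1, a2, b2, w, loglik=-float(best.fun))


def _posterior_mixture(
    prior: GpsPrior, t: TwoByTwo
) -> tuple[float, float, float, float, float]:
    """(q, shape1, rate1, shape2, rate2) of the posterior over lambda."""
    n = np.array([float(t.a)])
    e = np.array([max(t.expected_a, 1e-10)])
    l1 = float(_nb_logpmf(n, e, prior.alpha1, prior.beta1)[0]) + math.log(prior.w)
    l2 = float(_nb_logpmf(n, e, prior.alpha2, prior.beta2)[0]) + math.log1p(-prior.w)
    q = math.exp(l1 - special.logsumexp([l1, l2]))
    return (
        q,
        prior.alpha1 + t.a,
        prior.beta1 + e[0],
        prior.alpha2 + t.a,
        prior.beta2 + e[0],
    )


def eb05(
    prior: GpsPrior, t: TwoByTwo, result: DisproResult | None = None
) -> DisproResult:
    """EBGM and the posterior 5th percentile (EB05) for one table."""
    res = result if result is not None else DisproResult()
    q, s1, r1, s2, r2 = _posterior_mixture(prior, t)

    mean_log = q * (special.digamma(s1) - math.log(r1)) + (1 - q) * (
        special.digamma(s2) - math.log(r2)
    )
    res.ebgm = math.exp(float(mean_log))

    def cdf(x: float) -> float:
        return q * stats.gamma.cdf(x, s1, scale=1.0 / r1) + (1 - q) * stats.gamma.cdf(
            x, s2, scale=1.0 / r2
        )

    # bracket the 5th percentile between the component quantiles
    q1 = stats.gamma.ppf(0.05, s1, scale=1.0 / r1)
    q2 = stats.gamma.ppf(0.05, s2, scale=1.0 / r2)
    lo = 0.5 * min(q1, q2)
    hi = 2.0 * max(q1, q2)
    while cdf(lo) > 0.05:
        lo *= 0.5
    while cdf(hi) < 0.05:
        hi *= 2.0
    res.eb05 = float(optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-10))
    return res


def dispro_result(t: TwoByTwo, prior: GpsPrior | None = None) -> DisproResult:
    """All disproportionality statistics for one table (GPS only with a prior)."""
    res = DisproResult()
    basic_stats(t, res)
    bcpnn_ic(t, res)
    if prior is not None:
        eb05(prior, t, res)
    return res


def comparator_signals(res: DisproResult) -> dict[str, bool]:
    """The six standalone comparator decisions (strict inequalities)."""
    return {
        "PRR": res.prr_lo > 1.0,
        "ROR": res.ror_lo > 1.0,
        "YULE": res.yule_lo > 1.0,
        "CHI": res.chi2_p < 0.05,
        "BCPNN": res.ic_lo > 0.0,
        "GPS": res.eb05 > 2.0,
    }
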