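"""The four disproportionality estimators on a 2x2 report-count table.

For one drug-event pair the screening table is::

            event   other events
    drug      a          b
    others    c          d

with N = a+b+c+d and the expected count under independence
E = (a+b)(a+c)/N. The estimators are:

* **ROR** — reporting odds ratio (a*d)/(b*c) with a log-scale Wald 95% CI;
  a continuity correction of +0.5 on every cell is applied iff any cell
  is zero.
* **PRR** — proportional reporting ratio [a/(a+b)] / [c/(c+d)], paired
  with the Yates-corrected Pearson chi-square on the raw cells.
* **BCPNN IC** — information component log2((a+0.5)/(E+0.5)) with the
  standard closed-form credibility approximation for the 2.5% and 97.5%
  bounds.
* **MGPS EBGM** — the empirical-Bayes geometric mean of the Poisson rate
  ratio lambda under a two-component gamma-mixture prior fitted by
  maximum marginal likelihood across the whole screen; EB05 is the 5th
  percentile of the posterior mixture.

Signal thresholds default to the conventional rules: ROR — a >= 3 and
lower CI bound > 1; PRR — a >= 3, PRR >= 2 and chi-square >= 4;
BCPNN — IC025 > 0; MGPS — EB05 > 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special, stats

from .errors import ConvergenceError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable", "SignalThresholds", "SignalMetrics", "GPSPrior",
    "ror_estimate", "prr_estimate", "yates_chi2", "bcpnn_ic",
    "mgps_fit_prior", "mgps_posterior_weight", "mgps_ebgm",
    "compute_metrics", "classify",
]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one drug-event pair against the background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValidationError(f"cell {name} must be a count, got {v!r}")
        if self.n == 0:
            raise ValidationError("empty table: N must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, always recomputed from the cells."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class SignalThresholds:
    """Conventional signal rules; printed into every screen output."""

    ror_min_a: int = 3
    ror_lo95_gt: float = 1.0
    prr_min_a: int = 3
    prr_min: float = 2.0
    prr_chi2_min: float = 4.0
    ic025_gt: float = 0.0
    eb05_gt: float = 2.0

    def describe(self) -> str:
        return (
            f"ROR: a>={self.ror_min_a} & lo95>{self.ror_lo95_gt}; "
            f"PRR: a>={self.prr_min_a} & prr>={self.prr_min} "
            f"& chi2>={self.prr_chi2_min}; "
            f"BCPNN: ic025>{self.ic025_gt}; MGPS: eb05>{self.eb05_gt}"
        )


@dataclass
class SignalMetrics:
    """All estimator outputs for one table, with per-algorithm flags."""

    a: int
    expected: float
    ror: float
    ror_lo95: float
    ror_hi95: float
    prr: float
    prr_chi2: float
    ic: float
    ic025: float
    ic975: float
    ebgm: Optional[float] = None
    eb05: Optional[float] = None
    flags: dict = field(default_factory=dict)


def ror_estimate(t: ContingencyTable) -> Tuple[float, float, float]:
    """ROR with 95% Wald CI on the log scale.

    +0.5 is added to every cell iff any cell is zero, keeping the estimate
    finite; the CI uses the (possibly corrected) cells.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, ror * math.exp(-_Z95 * se), ror * math.exp(_Z95 * se))


def yates_chi2(t: ContingencyTable) -> float:
    """Yates-continuity-corrected Pearson chi-square on the raw 2x2 cells."""
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    return n * num * num / denom


def pearson_chi2(t: ContingencyTable) -> float:
    """Uncorrected Pearson chi-square: N(ad-bc)^2 / product of margins."""
    a, b, c, d = t.a, t.b, t.c, t.d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return t.n * (a * d - b * c) ** 2 / denom


def prr_estimate(t: ContingencyTable, yates: bool = True) -> Tuple[float, float]:
    """PRR and its companion chi-square (Yates-corrected by default).

    With a = 0 the PRR is reported as 0 (no continuity correction is
    applied to the ratio); the chi-square is always computed on the raw
    cells. A zero comparator event rate with a > 0 yields +inf.
    """
    chi2 = yates_chi2(t) if yates else pearson_chi2(t)
    if t.a == 0:
        return 0.0, chi2
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValidationError("PRR undefined: an exposure margin is zero")
    rate_drug = t.a / (t.a + t.b)
    if t.c == 0:
        return math.inf, chi2
    rate_other = t.c / (t.c + t.d)
    return rate_drug / rate_other, chi2


def bcpnn_ic(t: ContingencyTable) -> Tuple[float, float, float]:
    """Information component with closed-form 95% credibility bounds.

    ic = log2((a + 0.5) / (E + 0.5)); the bounds use the standard
    power-series approximation in (a + 0.5).
    """
    a = t.a + 0.5
    ic = math.log2(a / (t.expected + 0.5))
    ic025 = ic - 3.3 * a ** -0.5 - 2.0 * a ** -1.5
    ic975 = ic + 2.4 * a ** -0.5 - 0.5 * a ** -1.5
    return ic, ic025, ic975


@dataclass(frozen=True)
class GPSPrior:
    """Two-component gamma mixture prior on the Poisson rate ratio lambda.

    Component i is Gamma(shape alpha_i, rate beta_i); p_mix is the weight
    of component 1.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValidationError("gamma hyperparameters must be positive")
        if not 0 < self.p_mix < 1:
            raise ValidationError("p_mix must lie strictly inside (0, 1)")

    @property
    def mean(self) -> float:
        """Prior mean of lambda."""
        return (self.p_mix * self.alpha1 / self.beta1
                + (1 - self.p_mix) * self.alpha2 / self.beta2)


MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
MGPS_BOUNDS = [(1e-5, 20.0)] * 4 + [(1e-3, 1 - 1e-3)]


def _nb_logpmf(a, alpha, beta, E):
    """log of the gamma-Poisson marginal: NB(a; alpha, beta/(beta+E))."""
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    return (special.gammaln(alpha + a) - special.gammaln(alpha)
            - special.gammaln(a + 1.0)
            + alpha * (np.log(beta) - np.log(beta + E))
            + a * (np.log(np.maximum(E, 1e-300)) - np.log(beta + E)))


def _mixture_loglik(params, a, E):
    a1, b1, a2, b2, p = params
    l1 = _nb_logpmf(a, a1, b1, E) + math.log(p)
    l2 = _nb_logpmf(a, a2, b2, E) + math.log1p(-p)
    return float(np.sum(np.logaddexp(l1, l2)))


def mgps_fit_prior(cells: Sequence[Tuple[float, float]],
                   start: Tuple[float, ...] = MGPS_START,
                   bounds=None) -> GPSPrior:
    """Fit the five mixture hyperparameters by maximum marginal likelihood.

    ``cells`` are the (a, E) pairs of every screened drug-event pair; the
    negative-binomial mixture marginal is maximized over (alpha1, beta1,
    alpha2, beta2, p_mix) by bounded L-BFGS-B from the fixed start point.
    Deterministic given data and start. Fewer than 50 cells triggers a
    warning (the empirical prior is then weakly identified).
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 2 or cells.shape[1] != 2:
        raise ValidationError("cells must be (a, E) pairs")
    if cells.shape[0] < 50:
        log.warning("MGPS prior fitted on only %d cells; "
                    "hyperparameters may be unstable", cells.shape[0])
    a, E = cells[:, 0], cells[:, 1]
    if bounds is None:
        bounds = MGPS_BOUNDS

    res = optimize.minimize(
        lambda p: -_mixture_loglik(p, a, E),
        x0=np.asarray(start, dtype=float),
        method="L-BFGS-B",
        bounds=bounds,
    )
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError(
            f"MGPS hyperparameter fit failed: {res.message}", result=res)
    return GPSPrior(*[float(v) for v in res.x])


def mgps_posterior_weight(a: int, E: float, prior: GPSPrior) -> float:
    """Posterior probability Q that (a, E) came from mixture component 1."""
    l1 = float(_nb_logpmf(a, prior.alpha1, prior.beta1, E)) + math.log(prior.p_mix)
    l2 = float(_nb_logpmf(a, prior.alpha2, prior.beta2, E)) + math.log1p(-prior.p_mix)
    m = max(l1, l2)
    w1 = math.exp(l1 - m)
    return w1 / (w1 + math.exp(l2 - m))


def _posterior_cdf(x, a, E, prior, q):
    c1 = stats.gamma.cdf(x, prior.alpha1 + a, scale=1.0 / (prior.beta1 + E))
    c2 = stats.gamma.cdf(x, prior.alpha2 + a, scale=1.0 / (prior.beta2 + E))
    return q * c1 + (1 - q) * c2


def mgps_ebgm(t: ContingencyTable, prior: GPSPrior) -> Tuple[float, float]:
    """EBGM and EB05 for one table under a fitted prior.

    The posterior on lambda is the gamma mixture
    Q * Gamma(alpha1 + a, beta1 + E) + (1-Q) * Gamma(alpha2 + a, beta2 + E)
    with Q the posterior component weight. EBGM is the posterior geometric
    mean exp(E[ln lambda]) via the digamma function; EB05 is the posterior
    5th percentile found by bracketed root-finding on the mixture CDF.
    """
    a, E = t.a, t.expected
    q = mgps_posterior_weight(a, E, prior)
    mean_log = (q * (special.digamma(prior.alpha1 + a) - math.log(prior.beta1 + E))
                + (1 - q) * (special.digamma(prior.alpha2 + a)
                             - math.log(prior.beta2 + E)))
    ebgm = math.exp(mean_log)

    hi = max(
        stats.gamma.ppf(0.999, prior.alpha1 + a, scale=1.0 / (prior.beta1 + E)),
        stats.gamma.ppf(0.999, prior.alpha2 + a, scale=1.0 / (prior.beta2 + E)),
    )
    lo = 1e-12
    f = lambda x: _posterior_cdf(x, a, E, prior, q) - 0.05
    while f(hi) < 0:
        hi *= 2
    eb05 = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-10)
    return ebgm, eb05


def compute_metrics(t: ContingencyTable,
                    prior: Optional[GPSPrior] = None,
                    thresholds: SignalThresholds = SignalThresholds(),
                    prr_yates: bool = True) -> SignalMetrics:
    """Evaluate all four estimators on one table and classify the flags."""
    ror, lo, hi = ror_estimate(t)
    prr, chi2 = prr_estimate(t, yates=prr_yates)
    ic, ic025, ic975 = bcpnn_ic(t)
    m = SignalMetrics(
        a=t.a, expected=t.expected,
        ror=ror, ror_lo95=lo, ror_hi95=hi,
        prr=prr, prr_chi2=chi2,
        ic=ic, ic025=ic025, ic975=ic975,
    )
    if prior is not None:
        m.ebgm, m.eb05 = mgps_ebgm(t, prior)
    m.flags = classify(m, thresholds)
    return m


def classify(m: SignalMetrics,
             th: SignalThresholds = SignalThresholds()) -> dict:
    """Per-algorithm signal booleans plus 'any' and 'all_four' aggregates."""
    flags = {
        "ror": m.a >= th.ror_min_a and m.ror_lo95 > th.ror_lo95_gt,
        "prr": (m.a >= th.prr_min_a and m.prr >= th.prr_min
                and m.prr_chi2 >= th.prr_chi2_min),
        "bcpnn": m.ic025 > th.ic025_gt,
        "mgps": m.eb05 is not None and m.eb05 > th.eb05_gt,
    }
    flags["any"] = any(flags[k] for k in ("ror", "prr", "bcpnn", "mgps"))
    flags["all_four"] = all(flags[k] for k in ("ror", "prr", "bcpnn", "mgps"))
    return flags
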