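"""Exact and asymptotic inference for 2x2 carrier tables.

Conditional on both margins of a 2x2 table, the case-carrier count follows
Fisher's noncentral hypergeometric distribution indexed by the odds-ratio
parameter psi:

    P(X = k | psi)  proportional to  C(n1, k) * C(n2, K - k) * psi**k

over the support k in [max(0, K - n2), min(K, n1)], with n1 cases, n2
controls and K total carriers. Everything here is built on that conditional
model, computed in log space with exhaustive summation over the (tiny)
support:

* ``fisher_two_sided_p`` — the two-sided Fisher exact test using the
  minimum-likelihood rule: sum the null (psi = 1) probabilities of all
  outcomes no more probable than the observed one.
* ``sample_odds_ratio`` — the unconditional cross-product estimate
  a*d / (b*c) with explicit zero-cell conventions (ZERO when the case cell
  is empty, UNDEFINED when the control cell is).
* ``cmle_odds_ratio`` — the conditional MLE, the psi solving E[X | psi] = a.
* ``exact_ci`` — the exact conditional confidence interval obtained by
  inverting the one-sided noncentral tail tests at alpha/2; zero cells give
  one-sided intervals with a 0 or infinite bound.
* ``chisq_yates_p`` — Pearson's chi-square with the Yates continuity
  correction, the conventional large-sample test for carrier aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

from .types import ContingencyTable2x2, ExactCI, OddsRatioEstimate, OddsRatioKind

# Relative tolerance of the minimum-likelihood rule: outcomes with
# P(k) <= P(a) * (1 + _P_REL_TOL) count toward the two-sided p, guarding
# against ties being lost to rounding.
_P_REL_TOL = 1e-7

# log-psi search bracket for CMLE and CI inversion; exp(70) ~ 2.5e30 is far
# beyond any odds ratio a finite table can support away from its boundary.
_LOG_PSI_MAX = 70.0


@dataclass(frozen=True)
class NoncentralHypergeometricModel:
    """Margins of a 2x2 table plus the noncentrality parameter psi."""

    n1: int
    n2: int
    total_carriers: int
    psi: float = 1.0

    def __post_init__(self) -> None:
        if self.psi < 0:
            raise ValueError(f"psi={self.psi} must be >= 0")
        if not 0 <= self.total_carriers <= self.n1 + self.n2:
            raise ValueError("total carrier count outside [0, n1 + n2]")

    @property
    def support(self) -> range:
        lo = max(0, self.total_carriers - self.n2)
        hi = min(self.total_carriers, self.n1)
        return range(lo, hi + 1)

    @classmethod
    def from_table(cls, t: ContingencyTable2x2, psi: float = 1.0):
        return cls(n1=t.n1, n2=t.n2, total_carriers=t.total_carriers, psi=psi)


def _log_binom(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _log_pmf_vector(n1: int, n2: int, K: int, log_psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Support and normalised log-pmf of the noncentral hypergeometric."""
    lo = max(0, K - n2)
    hi = min(K, n1)
    k = np.arange(lo, hi + 1)
    lw = _log_binom(n1, k) + _log_binom(n2, K - k) + k * log_psi
    return k, lw - logsumexp(lw)


def nchg_pmf(k: int, model: NoncentralHypergeometricModel) -> float:
    """Probability of k case carriers under the conditional model."""
    sup = model.support
    if not sup.start <= k <= sup.stop - 1:
        raise ValueError(f"k={k} outside support [{sup.start}, {sup.stop - 1}]")
    if model.psi == 0.0:
        return 1.0 if k == sup.start else 0.0
    ks, logp = _log_pmf_vector(model.n1, model.n2, model.total_carriers, math.log(model.psi))
    return float(np.exp(logp[k - ks[0]]))


def fisher_two_sided_p(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by the minimum-likelihood rule."""
    K = table.total_carriers
    if K == 0 or K == table.n:
        return 1.0
    ks, logp = _log_pmf_vector(table.n1, table.n2, K, 0.0)
    pmf = np.exp(logp)
    p_obs = pmf[table.a - ks[0]]
    p = float(pmf[pmf <= p_obs * (1.0 + _P_REL_TOL)].sum())
    return min(1.0, p)


def sample_odds_ratio(table: ContingencyTable2x2) -> OddsRatioEstimate:
    """Cross-product odds ratio a*d / (b*c) with zero-cell conventions."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if c == 0:  # covers a = c = 0 as well
        return OddsRatioEstimate(OddsRatioKind.UNDEFINED)
    if a == 0:
        return OddsRatioEstimate(OddsRatioKind.ZERO, 0.0)
    if b == 0 or d == 0:
        # a carrier-saturated arm; the cross-product degenerates
        return OddsRatioEstimate(OddsRatioKind.UNDEFINED)
    return OddsRatioEstimate(OddsRatioKind.FINITE, (a * d) / (b * c))


def conditional_mean(model: NoncentralHypergeometricModel) -> float:
    """E[X | psi] under the noncentral hypergeometric model."""
    if model.psi == 0.0:
        return float(model.support.start)
    ks, logp = _log_pmf_vector(
        model.n1, model.n2, model.total_carriers, math.log(model.psi)
    )
    return float(np.sum(ks * np.exp(logp)))


def cmle_odds_ratio(table: ContingencyTable2x2) -> float:
    """Conditional MLE of psi: the root of E[X | psi] = a.

    Returns 0.0 when a sits at the support minimum and ``math.inf`` at the
    support maximum (the likelihood is then maximised at the boundary).
    """
    sup = NoncentralHypergeometricModel.from_table(table).support
    lo, hi = sup.start, sup.stop - 1
    if lo == hi:
        return 1.0  # degenerate support carries no information
    if table.a == lo:
        return 0.0
    if table.a == hi:
        return math.inf

    n1, n2, K, a = table.n1, table.n2, table.total_carriers, table.a

    def excess(log_psi: float) -> float:
        ks, logp = _log_pmf_vector(n1, n2, K, log_psi)
        return float(np.sum(ks * np.exp(logp))) - a

    root = brentq(excess, -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-10, rtol=1e-12)
    return math.exp(root)


def _upper_tail(n1, n2, K, a, log_psi) -> float:
    ks, logp = _log_pmf_vector(n1, n2, K, log_psi)
    return float(np.exp(logp[ks >= a]).sum())


def _lower_tail(n1, n2, K, a, log_psi) -> float:
    ks, logp = _log_pmf_vector(n1, n2, K, log_psi)
    return float(np.exp(logp[ks <= a]).sum())


def exact_ci(table: ContingencyTable2x2, level: float = 0.95) -> ExactCI:
    """Exact conditional CI for psi by inverting the one-sided tail tests.

    The lower bound solves P_psi(X >= a) = (1 - level)/2 and the upper bound
    P_psi(X <= a) = (1 - level)/2; both tails are monotone in psi so each
    root is bracketed and unique. When a sits at the support minimum the
    lower bound is 0; at the maximum the upper bound is infinite.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level={level} outside (0, 1)")
    alpha = (1.0 - level) / 2.0
    n1, n2, K, a = table.n1, table.n2, table.total_carriers, table.a
    sup = NoncentralHypergeometricModel.from_table(table).support
    lo, hi = sup.start, sup.stop - 1

    if lo == hi:  # margins fully determine the table
        return ExactCI(0.0, math.inf, level)

    if a == lo:
        low = 0.0
    else:
        root = brentq(
            lambda lp: _upper_tail(n1, n2, K, a, lp) - alpha,
            -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-10, rtol=1e-12,
        )
        low = math.exp(root)

    if a == hi:
        high = math.inf
    else:
        root = brentq(
            lambda lp: _lower_tail(n1, n2, K, a, lp) - alpha,
            -_LOG_PSI_MAX, _LOG_PSI_MAX, xtol=1e-10, rtol=1e-12,
        )
        high = math.exp(root)

    return ExactCI(low, high, level)


def chisq_yates_p(table: ContingencyTable2x2) -> float:
    """Pearson chi-square p with the Yates continuity correction (1 df).

    The correction is floored at zero: |ad - bc| smaller than N/2 yields a
    statistic of 0 and p = 1. Any zero margin gives p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = (a + b, c + d, a + c, b + d)
    if n == 0 or 0 in margins:
        return 1.0
    diff = abs(a * d - b * c) - n / 2.0
    if diff < 0.0:
        return 1.0
    stat = n * diff * diff / math.prod(margins)
    return float(chi2.sf(stat, df=1))


def chisq_pearson_p(table: ContingencyTable2x2) -> float:
    """Uncorrected Pearson chi-square p (1 df); used for comparison."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = (a + b, c + d, a + c, b + d)
    if n == 0 or 0 in margins:
        return 1.0
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return float(chi2.sf(stat, df=1))
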