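"""Fixed-effect meta-analysis and Wakefield approximate Bayes factors.

Stratum-level odds ratios (with Wald 95% CIs) are pooled on the log-odds
scale with inverse-variance weights.  The strength of evidence for each
pooled estimate is summarised by Wakefield's approximate Bayes factor

    ABF = sqrt((V + W) / V) * exp(-z^2 W / (2 (V + W)))

where V is the estimate's sampling variance, z its Wald statistic and W the
prior variance of the log odds ratio under the alternative.  W is derived
from a plausibility cap on the odds ratio: a zero-centred normal prior whose
97.5th percentile equals ln(cap).  The Bayes false discovery probability is
then the posterior probability of the null,

    BFDP = ABF * PO / (1 + ABF * PO),   PO = (1 - pi) / pi,

for each prior probability of association pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError, DataError

Z975 = stats.norm.ppf(0.975)
CI_WIDTH_Z = 3.92  # 2 * 1.96, the printed-table Wald convention

DEFAULT_PRIORS = (0.1, 0.05, 0.01)
DEFAULT_OR_CAP = 4.0


def lnor_se_from_ci(or_hat: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Invert a printed OR (95% CI) row to (lnOR, SE) under the Wald convention."""
    if ci_low <= 0 or ci_high <= 0 or or_hat <= 0:
        raise DataError("lnor_se_from_ci: non-positive OR or CI bound")
    if ci_high <= ci_low:
        raise DataError("lnor_se_from_ci: CI bounds not increasing")
    se = (np.log(ci_high) - np.log(ci_low)) / CI_WIDTH_Z
    if se <= 0:
        raise DataError("lnor_se_from_ci: zero-width CI")
    return float(np.log(or_hat)), float(se)


@dataclass
class StratumEstimate:
    """One stratum's odds ratio with its Wald 95% CI."""

    label: str
    or_hat: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low < self.or_hat < self.ci_high):
            raise DataError(
                f"{self.label}: OR {self.or_hat} outside CI ({self.ci_low}, {self.ci_high})"
            )

    @property
    def lnor(self) -> float:
        return lnor_se_from_ci(self.or_hat, self.ci_low, self.ci_high)[0]

    @property
    def se(self) -> float:
        return lnor_se_from_ci(self.or_hat, self.ci_low, self.ci_high)[1]

    @property
    def var(self) -> float:
        return self.se**2


@dataclass
class PooledEstimate:
    or_hat: float
    ci_low: float
    ci_high: float
    p: float
    lnor: float
    se: float
    n_strata: int


def meta_fixed(estimates: list[StratumEstimate]) -> PooledEstimate:
    """Fixed-effect inverse-variance pooling of stratum log odds ratios.

    Summation runs in a canonical (sorted) order so the pooled result is
    bit-identical under permutation of the input list.
    """
    if len(estimates) == 0:
        raise DataError("meta_fixed: empty estimate list")
    theta = np.array([e.lnor for e in estimates])
    w = np.array([1.0 / e.var for e in estimates])
    order = np.lexsort((w, theta))
    theta, w = theta[order], w[order]
    pooled = float(math.fsum(w * theta) / math.fsum(w))
    se = float(math.fsum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(pooled / se)))
    return PooledEstimate(
        or_hat=float(np.exp(pooled)),
        ci_low=float(np.exp(pooled - Z975 * se)),
        ci_high=float(np.exp(pooled + Z975 * se)),
        p=max(p, np.finfo(float).tiny),
        lnor=pooled,
        se=se,
        n_strata=len(estimates),
    )


def prior_variance_from_or_cap(cap: float, coverage: float = 0.975) -> float:
    """Prior lnOR variance W for a zero-centred normal prior capped at ``cap``.

    ``cap`` is the odds ratio the alternative is judged unlikely to exceed;
    it becomes the ``coverage`` quantile of the prior, so
    W = (ln cap / Phi^-1(coverage))^2.
    """
    if cap <= 1:
        raise ConfigError("prior_variance_from_or_cap: cap must exceed 1")
    if not (0.5 < coverage < 1):
        raise ConfigError("prior_variance_from_or_cap: coverage must be in (0.5, 1)")
    return float((np.log(cap) / stats.norm.ppf(coverage)) ** 2)


def abf(theta: float, se: float, W: float) -> float:
    """Wakefield approximate Bayes factor, null versus alternative.

    Values above 1 favour the null.  Equals the ratio of normal marginal
    likelihoods N(theta; 0, V) / N(theta; 0, V + W) with V = se^2.
    """
    if se <= 0:
        raise DataError("abf: standard error must be positive")
    if W <= 0:
        raise ConfigError("abf: prior variance W must be positive")
    V = se**2
    z = theta / se
    return float(np.sqrt((V + W) / V) * np.exp(-(z**2) * W / (2 * (V + W))))


def bfdp(abf_value: float, pi: float) -> float:
    """Bayes false discovery probability at prior probability of association ``pi``."""
    if not (0 < pi <= 1):
        raise ConfigError("bfdp: prior probability must be in (0, 1]")
    if pi == 1.0:
        return 0.0
    po = (1 - pi) / pi
    return float(abf_value * po / (1 + abf_value * po))


@dataclass
class SynthesisResult:
    """Pooled estimate with its ABF and BFDP across priors."""

    label: str
    pooled: PooledEstimate
    W: float
    abf: float
    bfdp_by_prior: dict[float, float] = field(default_factory=dict)


def synthesize(
    label: str,
    estimates: list[StratumEstimate],
    or_cap: float = DEFAULT_OR_CAP,
    priors: tuple[float, ...] = DEFAULT_PRIORS,
) -> SynthesisResult:
    """Pool stratum estimates, then compute ABF and BFDP for each prior."""
    pooled = meta_fixed(estimates)
    W = prior_variance_from_or_cap(or_cap)
    bf = abf(pooled.lnor, pooled.se, W)
    return SynthesisResult(
        label=label,
        pooled=pooled,
        W=W,
        abf=bf,
        bfdp_by_prior={pi: bfdp(bf, pi) for pi in priors},
    )


def bfdp_from_ci(
    or_hat: float,
    ci_low: float,
    ci_high: float,
    or_cap: float = DEFAULT_OR_CAP,
    priors: tuple[float, ...] = DEFAULT_PRIORS,
) -> dict[float, float]:
    """BFDP map straight from a printed OR (95% CI) row."""
    theta, se = lnor_se_from_ci(or_hat, ci_low, ci_high)
    bf = abf(theta, se, prior_variance_from_or_cap(or_cap))
    return {pi: bfdp(bf, pi) for pi in priors}
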