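"""Absolute (cumulative) risk from an odds ratio, and burden-test power.

Cumulative risk converts a carrier odds ratio into a penetrance estimate by
scaling age-band population incidence rates: with piecewise-constant hazards
``lambda(band)`` and the rare-carrier approximation ``lambda_carrier = OR *
lambda`` (valid for carrier frequencies well below 1%, where the OR
approximates the hazard ratio), the risk to ``max_age`` is

    risk = 1 - exp(-OR * sum_bands lambda * width).

Power for the carrier-collapse burden design uses the Wald normal
approximation with expected 2x2 cell counts: the case carrier frequency
implied by (f0, OR) is f1 = f0*OR / (1 + f0*(OR - 1)), the expected standard
error of lnOR is sqrt(sum 1/expected cell), and the two-sided rejection
probability at level alpha follows from a unit-variance normal centred at
lnOR / se.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError


@dataclass
class IncidenceTable:
    """Age-band incidence rates (incident cases per person-year)."""

    bands: pd.DataFrame  # columns: age_lo, age_hi, rate

    def __post_init__(self) -> None:
        b = self.bands
        required = {"age_lo", "age_hi", "rate"}
        if not required.issubset(b.columns):
            raise DataError(f"incidence table needs columns {sorted(required)}")
        b = b.sort_values("age_lo").reset_index(drop=True)
        if (b["rate"] < 0).any():
            raise DataError("incidence table: negative rate")
        if (b["age_hi"] <= b["age_lo"]).any():
            raise DataError("incidence table: empty or inverted age band")
        if not np.allclose(b["age_hi"].iloc[:-1], b["age_lo"].iloc[1:]):
            raise DataError("incidence table: bands not contiguous")
        self.bands = b

    @classmethod
    def from_csv(cls, path: str | Path) -> "IncidenceTable":
        return cls(pd.read_csv(path))

    @classmethod
    def example(cls) -> "IncidenceTable":
        """Packaged synthetic flat-hazard table (see data/incidence_synthetic_flat.csv)."""
        with resources.files("rvburden.data").joinpath(
            "incidence_synthetic_flat.csv"
        ).open() as fh:
            return cls(pd.read_csv(fh))

    def cumulative_hazard(self, max_age: float) -> float:
        """Integrated hazard to ``max_age`` (rectangle rule over bands)."""
        b = self.bands
        if max_age > b["age_hi"].iloc[-1] or max_age <= b["age_lo"].iloc[0]:
            raise DataError(
                f"incidence table covers [{b['age_lo'].iloc[0]}, {b['age_hi'].iloc[-1]}), "
                f"cannot integrate to {max_age}"
            )
        width = np.minimum(b["age_hi"], max_age) - np.minimum(b["age_lo"], max_age)
        return float((b["rate"] * width).sum())


def cumulative_risk(
    incidence: IncidenceTable, or_hat: float, max_age: float = 80
) -> float:
    """Cumulative disease risk to ``max_age`` for a carrier with odds ratio ``or_hat``."""
    if or_hat <= 0:
        raise ConfigError("cumulative_risk: odds ratio must be positive")
    return 1.0 - float(np.exp(-or_hat * incidence.cumulative_hazard(max_age)))


def risk_ci(
    incidence: IncidenceTable, ci_low: float, ci_high: float, max_age: float = 80
) -> tuple[float, float]:
    """Cumulative risk evaluated at each bound of the OR's confidence interval."""
    return (
        cumulative_risk(incidence, ci_low, max_age),
        cumulative_risk(incidence, ci_high, max_age),
    )


# ---------------------------------------------------------------------------
# Power of the carrier-collapse burden design
# ---------------------------------------------------------------------------


@dataclass
class PowerSpec:
    """Design for the burden power calculation.

    Defaults follow the analysed study scale (5951 HGSOC cases, 6115
    controls) at a genome-wide-ish type-I error of 1e-4 for a candidate
    panel.
    """

    n_cases: int = 5951
    n_controls: int = 6115
    f0_grid: tuple[float, ...] = (0.001, 0.002, 0.003, 0.005, 0.01)
    or_grid: tuple[float, ...] = (1.5, 2.0, 3.0, 4.0, 6.0)
    alpha: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("PowerSpec: alpha must be in (0, 1)")
        if any(not (0 < f < 0.5) for f in self.f0_grid):
            raise ConfigError("PowerSpec: carrier frequencies must be in (0, 0.5)")
        if any(o <= 0 for o in self.or_grid):
            raise ConfigError("PowerSpec: odds ratios must be positive")


def case_carrier_freq(f0: float, or_: float) -> float:
    """Case carrier frequency implied by control frequency f0 and odds ratio."""
    return f0 * or_ / (1.0 + f0 * (or_ - 1.0))


def analytic_power(
    n_cases: int, n_controls: int, f0: float, or_: float, alpha: float
) -> tuple[float, bool]:
    """Normal-approximation power for one (f0, OR) point.

    Uses a unit-variance normal for the Wald statistic centred at
    lnOR / se_expected with se_expected from the expected 2x2 cells.  Cheap
    and exact at OR = 1 (power = alpha), but it ignores count discreteness
    and the sampling variation of the SE, which matters at small expected
    carrier counts and extreme alpha — prefer :func:`exact_power` there.
    Returns (power, reliable); ``reliable`` is False when any expected
    carrier cell falls below 1.
    """
    f1 = case_carrier_freq(f0, or_)
    a = n_cases * f1
    b = n_cases * (1 - f1)
    c = n_controls * f0
    d = n_controls * (1 - f0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ncp = np.log(or_) / se
    zcrit = stats.norm.ppf(1 - alpha / 2)
    power = stats.norm.sf(zcrit - ncp) + stats.norm.cdf(-zcrit - ncp)
    return float(power), bool(min(a, c) >= 1)


def exact_power(
    n_cases: int,
    n_controls: int,
    f0: float,
    or_: float,
    alpha: float,
    tail: float = 1e-12,
) -> tuple[float, bool]:
    """Exact rejection probability of the two-sided Wald test.

    Enumerates the joint binomial distribution of carrier counts in cases and
    controls (truncated at ``tail`` mass) and sums the probability of tables
    whose Wald statistic (with the Haldane-Anscombe correction on zero cells,
    mirroring the crude burden test) exceeds the critical value.
    """
    f1 = case_carrier_freq(f0, or_)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    amax = int(stats.binom.isf(tail, n_cases, f1)) + 1
    cmax = int(stats.binom.isf(tail, n_controls, f0)) + 1
    a = np.arange(amax + 1)
    c = np.arange(cmax + 1)
    pa = stats.binom.pmf(a, n_cases, f1)
    pc = stats.binom.pmf(c, n_controls, f0)
    A = a[:, None].astype(float)
    C = c[None, :].astype(float)
    B, D = n_cases - A, n_controls - C
    zero = np.minimum(np.minimum(A, B), np.minimum(C, D)) == 0
    A2, B2, C2, D2 = A + 0.5 * zero, B + 0.5 * zero, C + 0.5 * zero, D + 0.5 * zero
    lnor = np.log(A2 * D2 / (B2 * C2))
    se = np.sqrt(1 / A2 + 1 / B2 + 1 / C2 + 1 / D2)
    reject = np.abs(lnor / se) > zcrit
    power = float((pa[:, None] * pc[None, :] * reject).sum())
    return power, bool(min(n_cases * f1, n_controls * f0) >= 1)


def burden_power(spec: PowerSpec, method: str = "exact") -> pd.DataFrame:
    """Power grid over (f0, OR); columns f0, or, power, reliable.

    ``method`` is "exact" (binomial enumeration of the Wald test, default)
    or "normal" (expected-count approximation).
    """
    fn = {"exact": exact_power, "normal": analytic_power}.get(method)
    if fn is None:
        raise ConfigError(f"burden_power: unknown method {method!r}")
    rows = []
    for f0 in spec.f0_grid:
        for or_ in spec.or_grid:
            power, reliable = fn(spec.n_cases, spec.n_controls, f0, or_, spec.alpha)
            rows.append({"f0": f0, "or": or_, "power": power, "reliable": reliable})
    return pd.DataFrame(rows)
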