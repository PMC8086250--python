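"""Carrier-collapse burden tests and the admixture-maximum-likelihood test.

The burden test collapses all qualifying deleterious variants in a gene (or
gene set) into one carrier indicator per subject, then tests case-control
association either from the crude 2x2 table or by unconditional logistic
regression with stratum covariates (country, sequencing platform).  Odds
ratios carry Wald 95% confidence intervals; p-values are reported both as the
Wald test (which pairs with the CI and matches published tables) and as the
Pearson score chi-square, which is much better calibrated when the expected
carrier counts are small — see docs/methods.md.

For rare missense variants with unknown functional effect, the admixture
maximum likelihood (AML) test models the variant set as a mixture: a
proportion ``alpha`` of variants share a common log odds ratio ``theta``
while the rest are null, and significance is assessed by stratified
case-control label permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

Z975 = stats.norm.ppf(0.975)


@dataclass
class BurdenResult:
    """Collapsed 2x2 counts and association estimate for one gene or set."""

    gene: str
    a: int  # carrier cases
    b: int  # non-carrier cases
    c: int  # carrier controls
    d: int  # non-carrier controls
    or_hat: float
    ci_low: float
    ci_high: float
    p: float  # two-sided Wald p
    p_score: float | None = None  # Pearson chi-square p (crude tables only)
    adjusted_for: list[str] = field(default_factory=list)
    method: str = "crude"
    non_estimable: bool = False
    separation_fallback: bool = False

    @property
    def case_carrier_freq(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def control_carrier_freq(self) -> float:
        return self.c / (self.c + self.d)


def _score_p(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square (score test) p for a 2x2 table, no continuity correction."""
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        return 1.0
    exp = np.array([row1 * col1, row1 * col2, row2 * col1, row2 * col2]) / n
    x2 = (((np.array([a, b, c, d]) - exp) ** 2) / exp).sum()
    return float(stats.chi2.sf(x2, 1))


def crude_or(a: int, b: int, c: int, d: int, gene: str = "") -> BurdenResult:
    """Crude odds ratio with Wald CI/p from a carrier 2x2 table.

    The Haldane-Anscombe 0.5 continuity correction is added to all four
    cells if and only if any cell is zero.  Tables with two zero cells on a
    diagonal are flagged non-estimable.
    """
    if min(a, b, c, d) < 0:
        raise DataError("crude_or: negative cell count")
    non_est = (a == 0 and d == 0) or (b == 0 and c == 0)
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if min(a, b, c, d) == 0 else (a, b, c, d)
    )
    lnor = np.log(aa * dd / (bb * cc))
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    p = float(2 * stats.norm.sf(abs(lnor / se)))
    return BurdenResult(
        gene=gene,
        a=a, b=b, c=c, d=d,
        or_hat=float(np.exp(lnor)),
        ci_low=float(np.exp(lnor - Z975 * se)),
        ci_high=float(np.exp(lnor + Z975 * se)),
        p=max(p, np.finfo(float).tiny),
        p_score=_score_p(a, b, c, d),
        method="crude",
        non_estimable=non_est,
    )


def carrier_flags(
    genotypes: pd.DataFrame,
    classified: pd.DataFrame,
    manifest: pd.DataFrame,
    genes: list[str],
) -> pd.Series:
    """Per-sample carrier indicator over the deleterious variants of ``genes``.

    ``genotypes`` is a long table (sample_id, variant_id, gt) of ACCEPTED
    calls; a sample absent from it is a non-carrier.  Each subject counts
    once regardless of how many qualifying variants it carries.
    """
    qual = classified[
        (classified["gene"].isin(genes)) & (classified["class"] == "deleterious")
    ]["variant_id"]
    hits = genotypes[(genotypes["variant_id"].isin(qual)) & (genotypes["gt"] > 0)]
    flags = pd.Series(False, index=manifest["sample_id"])
    carriers = [s for s in hits["sample_id"].unique() if s in flags.index]
    flags.loc[carriers] = True
    return flags


def collapse_carriers(
    classified: pd.DataFrame,
    genotypes: pd.DataFrame,
    manifest: pd.DataFrame,
    gene: str,
    histotype: str | None = None,
) -> tuple[int, int, int, int]:
    """Collapse to the carrier 2x2 table (a, b, c, d) for one gene.

    ``histotype`` restricts the CASE column to that histotype (controls are
    shared across subsets).  A gene absent from the variant table yields
    empty carrier counts with a warning.
    """
    if gene not in set(classified["gene"]):
        warnings.warn(f"collapse_carriers: gene {gene!r} absent from variant table")
    flags = carrier_flags(genotypes, classified, manifest, [gene])
    return _table_from_flags(flags, manifest, histotype)


def _table_from_flags(
    flags: pd.Series, manifest: pd.DataFrame, histotype: str | None
) -> tuple[int, int, int, int]:
    m = manifest.set_index("sample_id")
    is_case = m["status"] == "case"
    if histotype is not None:
        is_case &= m["histotype"] == histotype
    is_control = m["status"] == "control"
    f = flags.reindex(m.index).fillna(False)
    a = int((f & is_case).sum())
    b = int((~f & is_case).sum())
    c = int((f & is_control).sum())
    d = int((~f & is_control).sum())
    return a, b, c, d


def logistic_burden(
    carrier: pd.Series | np.ndarray,
    is_case: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    gene: str = "",
) -> BurdenResult:
    """Unconditional logistic regression of case status on carrier status.

    Categorical covariates (e.g. country stratum, sequencing platform) are
    expanded to indicator columns.  On complete separation the fit falls back
    to the crude table with a warning.  Convergence: Newton-Raphson to a
    log-likelihood tolerance of 1e-10 within 100 iterations.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(carrier, dtype=float)
    y = np.asarray(is_case, dtype=float)
    if x.sum() == 0:
        raise DataError("logistic_burden: no carriers among analysed subjects")

    a = int((x * y).sum())
    b = int(((1 - x) * y).sum())
    c = int((x * (1 - y)).sum())
    d = int(((1 - x) * (1 - y)).sum())

    cols = [pd.Series(x, name="carrier")]
    adjusted_for: list[str] = []
    if covariates is not None:
        for name in covariates.columns:
            col = covariates[name].reset_index(drop=True)
            if col.nunique() < 2:
                continue  # constant covariate carries no information
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.append(dummies)
            adjusted_for.append(name)
    X = sm.add_constant(pd.concat(cols, axis=1))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(y, X).fit(method="newton", tol=1e-10, maxiter=100, disp=False)
        beta = fit.params["carrier"]
        se = fit.bse["carrier"]
        if not np.isfinite(beta) or not np.isfinite(se) or se > 50:
            raise PerfectSeparationError("degenerate carrier coefficient")
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning, Exception) as exc:
        if isinstance(exc, KeyboardInterrupt):
            raise
        warnings.warn(f"logistic_burden: separation/fit failure ({exc}); crude fallback")
        res = crude_or(a, b, c, d, gene=gene)
        res.separation_fallback = True
        res.adjusted_for = adjusted_for
        return res

    p = float(2 * stats.norm.sf(abs(beta / se)))
    return BurdenResult(
        gene=gene,
        a=a, b=b, c=c, d=d,
        or_hat=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p=max(p, np.finfo(float).tiny),
        p_score=None,
        adjusted_for=adjusted_for,
        method="logistic",
    )


def gene_set_burden(
    genes: list[str],
    classified: pd.DataFrame,
    genotypes: pd.DataFrame,
    manifest: pd.DataFrame,
    adjust: list[str] | None = None,
    histotype: str | None = None,
    label: str | None = None,
) -> BurdenResult:
    """Burden test with carrier = >=1 deleterious variant in ANY gene of the set.

    ``adjust`` names manifest columns (e.g. ["stratum", "platform"]) used as
    categorical covariates in the logistic fit; without covariates or with no
    carriers the crude table is used directly.
    """
    if len(genes) == 0:
        raise ConfigError("gene_set_burden: empty gene set")
    flags = carrier_flags(genotypes, classified, manifest, genes)
    a, bb, c, d = _table_from_flags(flags, manifest, histotype)
    label = label or "+".join(genes)
    m = manifest.set_index("sample_id")
    keep = (m["status"] == "control") | (
        (m["status"] == "case")
        & ((m["histotype"] == histotype) if histotype is not None else True)
    )
    sub = m[keep]
    f = flags.reindex(sub.index).fillna(False)
    if adjust:
        try:
            res = logistic_burden(
                f.to_numpy(),
                (sub["status"] == "case").to_numpy(),
                sub[list(adjust)].reset_index(drop=True),
                gene=label,
            )
        except DataError:
            res = crude_or(a, bb, c, d, gene=label)
    else:
        res = crude_or(a, bb, c, d, gene=label)
    res.a, res.b, res.c, res.d = a, bb, c, d
    return res


def gene_burden(
    gene: str,
    classified: pd.DataFrame,
    genotypes: pd.DataFrame,
    manifest: pd.DataFrame,
    adjust: list[str] | None = None,
    histotype: str | None = None,
) -> BurdenResult:
    """Single-gene burden test (collapse + crude or adjusted logistic)."""
    return gene_set_burden(
        [gene], classified, genotypes, manifest, adjust=adjust, histotype=histotype,
        label=gene,
    )


# ---------------------------------------------------------------------------
# Admixture maximum likelihood (AML) test for rare missense variant sets
# ---------------------------------------------------------------------------


@dataclass
class AmlResult:
    statistic: float
    alpha_hat: float
    theta_hat: float
    p_perm: float
    n_perm: int
    seed: int


def _aml_max_loglik(
    x: np.ndarray,
    k: np.ndarray,
    n_cases: int,
    n_controls: int,
    theta_grid: np.ndarray,
    alpha_grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profile the AML mixture likelihood over (alpha, theta) grids.

    ``x``: carriers among cases per variant, shape (P, V) for P datasets;
    ``k``: total carriers per variant, shape (V,) or (P, V).
    Returns (max log L, log L at alpha=0, argmax indices) each of shape (P,).
    Binomial coefficients cancel in the likelihood-ratio statistic and are
    omitted.
    """
    x = np.atleast_2d(x).astype(float)
    k = np.broadcast_to(np.atleast_2d(k).astype(float), x.shape)
    # carrier-is-a-case probability under common lnOR theta
    p_theta = n_cases * np.exp(theta_grid) / (n_cases * np.exp(theta_grid) + n_controls)
    p0 = n_cases / (n_cases + n_controls)

    l0 = x * np.log(p0) + (k - x) * np.log1p(-p0)  # (P, V)
    lt = (
        x[:, :, None] * np.log(p_theta)[None, None, :]
        + (k - x)[:, :, None] * np.log1p(-p_theta)[None, None, :]
    )  # (P, V, T)

    ll_null = l0.sum(axis=1)  # (P,)
    # mixture log-likelihood relative to the null kernel:
    #   log((1-a) e^l0 + a e^lt) = l0 + log1p(a (e^(lt-l0) - 1))
    # the exponent is clipped to avoid float overflow; clipping only compresses
    # already-enormous likelihood ratios far beyond any decision boundary
    ratio_m1 = np.exp(np.minimum(lt - l0[:, :, None], 700.0)) - 1.0  # (P, V, T)
    best = np.full(x.shape[0], -np.inf)
    arg = np.zeros((x.shape[0], 2), dtype=int)
    for ai, alpha in enumerate(alpha_grid):
        if alpha == 0.0:
            cand = np.broadcast_to(ll_null[:, None], (x.shape[0], len(theta_grid)))
        else:
            # log1p(-1) = -inf is a legitimate zero-likelihood mixture (alpha=1
            # with an impossible variant split); silence the warning only
            with np.errstate(divide="ignore"):
                cand = ll_null[:, None] + np.log1p(alpha * ratio_m1).sum(axis=1)  # (P, T)
        ti = cand.argmax(axis=1)
        val = cand[np.arange(x.shape[0]), ti]
        upd = val > best
        best[upd] = val[upd]
        arg[upd, 0] = ai
        arg[upd, 1] = ti[upd]
    return best, ll_null, arg


def aml_missense_test(
    genotypes: pd.DataFrame,
    manifest: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    theta_grid: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
) -> AmlResult:
    """Admixture maximum likelihood burden test for a rare-variant set.

    ``genotypes``: sample x variant matrix (0/1/2, NaN = missing) already
    restricted to the filtered rare-missense set; ``manifest`` supplies case
    status and stratum.  The likelihood treats each variant's carriers as a
    binomial split between cases and controls; a proportion ``alpha`` of
    variants shares a common log odds ratio ``theta``.  The statistic is the
    likelihood-ratio against alpha=0, and ``p_perm`` comes from case-control
    label permutations within stratum.
    """
    if n_perm < 99:
        raise ConfigError("aml_missense_test: n_perm must be >= 99")
    m = manifest.set_index("sample_id").loc[genotypes.index]
    carriers = (genotypes.fillna(0).to_numpy() > 0)  # (N, V)
    k = carriers.sum(axis=0)
    keep = k > 0
    if not keep.any():
        raise DataError("aml_missense_test: no carried variants after filtering")
    carriers = carriers[:, keep].astype(float)
    k = k[keep]

    y = (m["status"] == "case").to_numpy()
    n_cases, n_controls = int(y.sum()), int((~y).sum())
    if theta_grid is None:
        theta_grid = np.linspace(-3.0, 3.0, 61)
    if alpha_grid is None:
        alpha_grid = np.linspace(0.0, 1.0, 51)

    rng = np.random.default_rng(seed)
    strata = m["stratum"].to_numpy()
    labels = np.tile(y.astype(float), (n_perm + 1, 1))
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        labels[1:, idx] = rng.permuted(labels[1:, idx], axis=1)

    x = labels @ carriers  # (P+1, V) carriers among cases
    best, ll_null, arg = _aml_max_loglik(
        x, k, n_cases, n_controls, theta_grid, alpha_grid
    )
    stat = 2.0 * (best - ll_null)
    stat = np.maximum(stat, 0.0)
    observed = stat[0]
    p_perm = float((1 + (stat[1:] >= observed - 1e-12).sum()) / (n_perm + 1))
    return AmlResult(
        statistic=float(observed),
        alpha_hat=float(alpha_grid[arg[0, 0]]),
        theta_hat=float(theta_grid[arg[0, 1]]) if arg[0, 0] > 0 else 0.0,
        p_perm=p_perm,
        n_perm=n_perm,
        seed=seed,
    )
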