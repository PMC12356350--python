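"""Phenotypic and genetic characterization of latent factors.

Pearson correlation against traditional ECG parameters, multivariable
linear / logistic / Cox regression suites adjusted for age and sex (latent
predictors z-scaled so coefficients are per standard deviation), a linear
additive-dosage variant scan producing GWAS-style summary statistics, the
Li-Ji eigenvalue estimate of the effective number of independent tests, and
Bonferroni threshold arithmetic.

Regression fits go through statsmodels (OLS, Logit) and lifelines
(CoxPHFitter, Efron ties); the variant scan uses a vectorized closed-form
OLS after projecting out the covariates (Frisch-Waugh), which is validated
against statsmodels in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

import statsmodels.api as sm
from lifelines import CoxPHFitter


# ---------------------------------------------------------------------------
# Result containers


@dataclass
class AssociationResult:
    """One fitted regression: per-predictor estimates plus model-level fit."""

    outcome: str
    table: pd.DataFrame          # index predictor; columns coef, se, p [, significant]
    n: int
    adj_r2: float | None = None  # linear models
    llf: float | None = None     # likelihood-based models

    def summary(self) -> str:
        head = f"{self.outcome}: n={self.n}"
        if self.adj_r2 is not None:
            head += f", adjusted R2={self.adj_r2:.4f}"
        if self.llf is not None:
            head += f", log-likelihood={self.llf:.3f}"
        return head + "\n" + self.table.to_string()


@dataclass
class SurvivalResult:
    """Cox proportional-hazards fit: hazard ratios with 95% CIs."""

    table: pd.DataFrame          # index predictor; hr, ci_low, ci_high, coef, se, p
    n: int
    n_events: int
    median_follow_up: float

    def summary(self) -> str:
        return (f"Cox PH: n={self.n}, events={self.n_events}, "
                f"median follow-up={self.median_follow_up:.2f}\n"
                + self.table.to_string())


@dataclass
class MultipleTestingPlan:
    """Bonferroni correction using an effective number of independent tests."""

    alpha: float
    n_nominal: int
    m_eff: float
    threshold: float

    def __post_init__(self) -> None:
        if not (1.0 - 1e-9 <= self.m_eff <= self.n_nominal + 1e-9):
            raise ValueError("m_eff must lie in [1, n_nominal]")


@dataclass
class BonferroniThreshold:
    threshold: float    # full precision
    printed: float      # 3 significant figures

    def __float__(self) -> float:
        return self.threshold


# ---------------------------------------------------------------------------
# Helpers


def _to_frame(x, prefix: str) -> pd.DataFrame:
    if isinstance(x, pd.DataFrame):
        return x
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return pd.DataFrame(x, columns=[f"{prefix}{i + 1}" for i in range(x.shape[1])])


def _zscale(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=0)
    if (sd < 1e-12).any():
        bad = list(sd.index[sd < 1e-12])
        raise ValueError(f"zero-variance predictor columns: {bad}")
    return (df - df.mean()) / sd


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns via the QR diagonal's tiny entries
        _, rr = np.linalg.qr(arr)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] < tol]
        raise ValueError(
            f"design matrix rank deficient (rank {rank} of {arr.shape[1]}); "
            f"offending columns: {bad or 'linearly dependent set'}")


def _design(latents, age, sex, z_scale_latents=True, prefix="f") -> pd.DataFrame:
    L = _to_frame(latents, prefix)
    if z_scale_latents:
        L = _zscale(L)
    parts = [L.reset_index(drop=True)]
    if age is not None:
        parts.append(pd.Series(np.asarray(age, dtype=float), name="age"))
    if sex is not None:
        parts.append(pd.Series(np.asarray(sex, dtype=float), name="sex"))
    X = pd.concat(parts, axis=1)
    return sm.add_constant(X)


# ---------------------------------------------------------------------------
# Correlation


def correlate(latents, params) -> pd.DataFrame:
    """Pearson r between every latent factor and every parameter column.

    Zero-variance columns yield NaN entries (flagged undefined) with a
    warning rather than an error.
    """
    L = _to_frame(latents, "f")
    P = _to_frame(params, "p")
    if len(L) != len(P):
        raise ValueError("latents and params must have equal row counts")
    if len(L) < 3:
        raise ValueError("need at least 3 rows")
    out = np.empty((L.shape[1], P.shape[1]))
    Ls = L.to_numpy(dtype=float)
    Ps = P.to_numpy(dtype=float)
    sl, sp = Ls.std(axis=0), Ps.std(axis=0)
    if (sl < 1e-12).any() or (sp < 1e-12).any():
        warnings.warn("zero-variance column(s): correlation undefined (NaN)",
                      stacklevel=2)
    Lc = Ls - Ls.mean(axis=0)
    Pc = Ps - Ps.mean(axis=0)
    cov = Lc.T @ Pc / len(L)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = cov / np.outer(sl, sp)
    out[:, sp < 1e-12] = np.nan
    out[sl < 1e-12, :] = np.nan
    return pd.DataFrame(out, index=L.columns, columns=P.columns)


# ---------------------------------------------------------------------------
# Regression suites


def fit_continuous(outcome, latents, age=None, sex=None,
                   outcome_name: str = "outcome") -> AssociationResult:
    """OLS of a continuous outcome on z-scaled latents plus age and sex.

    Coefficients are per standard deviation of each latent factor; model fit
    is summarized by the adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1).
    """
    y = np.asarray(outcome, dtype=float)
    X = _design(latents, age, sex)
    if len(y) != len(X):
        raise ValueError("outcome and predictors differ in length")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > p + 2 observations")
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    table = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    return AssociationResult(outcome_name, table, n=int(fit.nobs),
                             adj_r2=float(fit.rsquared_adj))


def compare_models(outcome, latents, traditional_params, age=None, sex=None,
                   outcome_name: str = "outcome") -> pd.DataFrame:
    """Adjusted R^2 of the latent-factor model vs the traditional-parameter
    model for the same outcome and subjects, and their difference."""
    fit_l = fit_continuous(outcome, latents, age, sex, outcome_name)
    fit_t = fit_continuous(outcome, traditional_params, age, sex, outcome_name)
    return pd.DataFrame({
        "outcome": [outcome_name],
        "adj_r2_latents": [fit_l.adj_r2],
        "adj_r2_traditional": [fit_t.adj_r2],
        "difference": [fit_l.adj_r2 - fit_t.adj_r2],
    })


def fit_binary(outcome, latents, age=None, sex=None,
               threshold: float | None = None,
               outcome_name: str = "outcome") -> AssociationResult:
    """Logistic regression (MLE) of a binary outcome on z-scaled latents
    plus age and sex; Wald p-values, optional Bonferroni significance flag."""
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"outcome has a single class ({classes}); cannot fit")
    if not set(classes).issubset({0.0, 1.0}):
        raise ValueError("binary outcome must be coded 0/1")
    X = _design(latents, age, sex)
    _check_rank(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
        raise ValueError(f"perfect separation detected: {exc}") from exc
    table = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    if threshold is not None:
        table["significant"] = table["p"] < threshold
    return AssociationResult(outcome_name, table, n=int(fit.nobs),
                             llf=float(fit.llf))


def fit_survival(time, event, predictors, z_scale: bool = True,
                 prefix: str = "f") -> SurvivalResult:
    """Cox proportional-hazards fit (Efron tie handling) of survival on
    z-scaled predictors; HR = exp(coef), 95% CI = exp(coef +/- 1.96 se)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    X = _to_frame(predictors, prefix)
    if z_scale:
        X = _zscale(X)
    df = X.reset_index(drop=True).copy()
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # Efron by default
    coef = cph.params_
    se = cph.standard_errors_
    table = pd.DataFrame({
        "hr": np.exp(coef),
        "ci_low": np.exp(coef - 1.96 * se),
        "ci_high": np.exp(coef + 1.96 * se),
        "coef": coef,
        "se": se,
        "p": cph.summary["p"],
    })
    return SurvivalResult(table, n=len(df), n_events=int(event.sum()),
                          median_follow_up=float(np.median(time)))


# ---------------------------------------------------------------------------
# Multiple testing


def effective_tests(latents) -> float:
    """Effective number of independent tests among correlated factors.

    Li-Ji eigenvalue measure on the factor correlation matrix:
    ``m_eff = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ]``.
    Accepts either a data matrix (columns = factors) or a correlation
    matrix (square, symmetric, unit diagonal).
    """
    A = np.asarray(latents, dtype=float)
    if A.ndim != 2 or A.shape[1] < 2:
        raise ValueError("need at least 2 factor columns")
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite values")
    is_corr = (A.shape[0] == A.shape[1] and np.allclose(A, A.T)
               and np.allclose(np.diag(A), 1.0))
    if is_corr:
        corr = A
    else:
        sd = A.std(axis=0)
        if np.any(sd < 1e-12):
            raise ValueError("zero-variance factor column")
        corr = np.corrcoef(A, rowvar=False)
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    # guard against eigenvalues like 0.9999999 / 16.0000001 from round-off
    lam = np.round(lam, 9)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def bonferroni(alpha: float, divisor: float) -> BonferroniThreshold:
    """Corrected threshold alpha / divisor, with a 3-significant-figure
    rendering alongside the full-precision value."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if divisor < 1:
        raise ValueError("divisor must be >= 1")
    t = alpha / divisor
    return BonferroniThreshold(t, float(f"{t:.3g}"))


def multiple_testing_plan(latents, alpha: float = 0.05,
                          round_m_eff: bool = True) -> MultipleTestingPlan:
    """Bonferroni plan dividing alpha by the Li-Ji effective test count."""
    A = np.asarray(latents, dtype=float)
    m = effective_tests(A)
    n_nominal = A.shape[1]
    divisor = round(m) if round_m_eff else m
    divisor = min(max(divisor, 1.0), n_nominal)
    return MultipleTestingPlan(alpha, n_nominal, m,
                               threshold=alpha / divisor)


# ---------------------------------------------------------------------------
# Variant scan


def variant_scan(latents, genotypes, age=None, sex=None,
                 effect_allele: str = "A1") -> pd.DataFrame:
    """Additive-dosage linear scan of every latent factor on every variant,
    adjusted for age and sex; GWAS-summary-style tidy output.

    Covariates are projected out of both dosages and factors
    (Frisch-Waugh-Lovell), then per-pair slope, classical SE and Wald p are
    computed in closed form.  Monomorphic variants are flagged and skipped
    (NaN estimates).  Columns: variant, factor, effect_allele, beta, se, p,
    n, skipped.
    """
    from .simulate import GenotypeMatrix  # local import to avoid cycle

    L = _to_frame(latents, "f")
    if isinstance(genotypes, GenotypeMatrix):
        G = pd.DataFrame(np.asarray(genotypes.dosages, dtype=float),
                         columns=genotypes.variant_ids)
    else:
        G = _to_frame(genotypes, "var")
    n = len(L)
    if len(G) != n:
        raise ValueError("latents and genotypes must be aligned on subjects")

    covs = [np.ones(n)]
    if age is not None:
        covs.append(np.asarray(age, dtype=float))
    if sex is not None:
        covs.append(np.asarray(sex, dtype=float))
    C = np.column_stack(covs)
    q_cov = C.shape[1]

    def _resid(M):
        beta_c, *_ = np.linalg.lstsq(C, M, rcond=None)
        return M - C @ beta_c

    Y = _resid(L.to_numpy(dtype=float))
    Gm = G.to_numpy(dtype=float)
    mono = Gm.std(axis=0) < 1e-12
    Gr = _resid(Gm)

    gg = (Gr ** 2).sum(axis=0)               # (m,)
    yy = (Y ** 2).sum(axis=0)                # (K,)
    dof = n - q_cov - 1
    if dof < 1:
        raise ValueError("not enough observations for the scan")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Gr.T @ Y) / gg[:, None]      # (m, K)
        ssr = np.clip(yy[None, :] - beta ** 2 * gg[:, None], 0.0, None)
        se = np.sqrt(ssr / dof / gg[:, None])
        tval = beta / se
    p = 2.0 * sstats.t.sf(np.abs(tval), dof)
    beta[mono, :] = np.nan
    se[mono, :] = np.nan
    p[mono, :] = np.nan

    m, K = beta.shape
    out = pd.DataFrame({
        "variant": np.repeat(G.columns.to_numpy(), K),
        "factor": np.tile(L.columns.to_numpy(), m),
        "effect_allele": effect_allele,
        "beta": beta.ravel(),
        "se": se.ravel(),
        "p": p.ravel(),
        "n": n,
        "skipped": np.repeat(mono, K),
    })
    return out


def scan_to_tsv(scan: pd.DataFrame, path) -> None:
    """Write a variant scan as a GWAS-summary-style TSV."""
    scan.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Disentanglement bookkeeping


def disentanglement_report(latents, variance_threshold: float = 1e-3) -> pd.DataFrame:
    """Per-factor variance, max inter-factor |r|, and the subtle-morphology
    flag (variance below threshold).  Latents must be unstandardized for the
    variances to be meaningful."""
    L = _to_frame(latents, "f")
    A = L.to_numpy(dtype=float)
    var = A.var(axis=0, ddof=0)
    K = A.shape[1]
    max_r = np.zeros(K)
    if K > 1:
        sd = A.std(axis=0)
        ok = sd > 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.corrcoef(A, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        corr[~ok, :] = np.nan
        corr[:, ~ok] = np.nan
        np.fill_diagonal(corr, 0.0)
        max_r = np.nanmax(np.abs(corr), axis=1) if ok.any() else np.full(K, np.nan)
    return pd.DataFrame({
        "factor": L.columns,
        "variance": var,
        "max_abs_r": max_r,
        "subtle_morphology": var < variance_threshold,
    })
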