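"""Nested logistic models for PRS evaluation.

For each polygenic score two nested logistic regressions of case status are
fit: a null model with clinical covariates plus principal components, and a
full model adding the (z-scored) PRS.  The score's incremental contribution
is the difference in Nagelkerke pseudo-R-squared,

    adjusted PRS R2 = R2(full) - R2(null),

with R2 computed against the intercept-only model:

    Cox-Snell R2 = 1 - exp((2/n) * (ll_0 - ll_1))
    Nagelkerke R2 = Cox-Snell / (1 - exp((2/n) * ll_0)).

The PRS odds ratio is exp(beta_PRS) with a Wald 95% CI; with the PRS
z-scored this is the odds ratio per score standard deviation (the headline
scale), and the per-raw-unit ratio is also recorded.  Significance across
multiple scores is controlled by Bonferroni.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from prscad.data_io import PhenotypeTable
from prscad.scoring import PRSVector

logger = logging.getLogger(__name__)

MODEL_COVARIATES = {
    "model1": ("sex", "age", "weight", "t2dm"),
    "model2": ("sex", "age", "weight", "t2dm", "smoking", "sbp", "total_chol"),
}


@dataclass(frozen=True)
class ModelSpec:
    name: str
    n_pcs: int = 0
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.name not in MODEL_COVARIATES:
            raise ValueError(f"unknown model {self.name!r}")
        if not self.covariates:
            object.__setattr__(self, "covariates", MODEL_COVARIATES[self.name])
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    converged: bool
    n: int
    term_names: list[str] = field(default_factory=list)


@dataclass
class AssociationResult:
    pgs_id: str
    model: str
    r2_null: float
    r2_full: float
    adjusted_prs_r2: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    or_scale: str = "per_sd"
    or_per_sd: float | None = None
    or_raw: float | None = None
    or_raw_ci: tuple[float, float] | None = None
    bonferroni_significant: bool = False
    usable: bool = True
    n: int = 0
    n_pcs: int = 0


def fit_logistic(y: np.ndarray, design: np.ndarray,
                 term_names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton, <= 100 iterations).

    ``design`` must already contain the intercept column.  Perfect
    separation or failed convergence yields ``converged=False`` rather than
    an exception; a constant response is an error.
    """
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim != 2 or design.shape[0] != y.shape[0]:
        raise ValueError("design/response shape mismatch")
    if y.shape[0] < design.shape[1]:
        raise ValueError("fewer observations than parameters")
    if np.all(y == y[0]):
        raise ValueError("constant response")
    model = sm.Logit(y, design)
    converged = True
    try:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and reported via converged=False
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0,
                            warn_convergence=False)
        converged = bool(res.mle_retvals.get("converged", False))
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        llf = float(res.llf)
        # runaway coefficients signal (quasi-)separation even when the
        # optimizer reports success
        if not np.all(np.isfinite(bse)) or np.any(np.abs(params) > 1e3):
            converged = False
    except Exception as exc:  # PerfectSeparationError, LinAlgError, ...
        logger.warning("logistic fit failed: %s", exc)
        converged = False
        k = design.shape[1]
        params = np.full(k, np.nan)
        bse = np.full(k, np.nan)
        llf = np.nan
    return LogisticFit(
        coefficients=params, standard_errors=bse, log_likelihood=llf,
        converged=converged, n=int(y.shape[0]),
        term_names=term_names or [f"x{j}" for j in range(design.shape[1])],
    )


def intercept_only_loglik(y: np.ndarray) -> float:
    """Closed-form log-likelihood of the intercept-only logistic model."""
    y = np.asarray(y, dtype=float)
    n = y.size
    n1 = y.sum()
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("constant response")
    p = n1 / n
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


def nagelkerke_r2(loglik_model: float, loglik_intercept_only: float, n: int) -> float:
    """Nagelkerke pseudo-R-squared of a model against the intercept-only fit."""
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_intercept_only == 0:
        raise ValueError("degenerate null log-likelihood")
    if loglik_model < loglik_intercept_only - 1e-8:
        raise ValueError("model log-likelihood below the nested null")
    cox_snell = 1.0 - np.exp((2.0 / n) * (loglik_intercept_only - loglik_model))
    max_cs = 1.0 - np.exp((2.0 / n) * loglik_intercept_only)
    return float(min(max(cox_snell / max_cs, 0.0), 1.0))


def adjusted_prs_r2(r2_full: float, r2_null: float) -> float:
    """Incremental pseudo-R-squared attributable to the PRS term."""
    return r2_full - r2_null


def bonferroni_adjust(p_values, alpha: float = 0.05):
    """Per-test significance flags at the Bonferroni threshold alpha / m."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    threshold = alpha / p.size
    return p < threshold, threshold


def _design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    return np.column_stack([np.ones(len(df))] + [df[t].to_numpy(dtype=float) for t in terms])


def evaluate_prs(prs: PRSVector, phenotypes: PhenotypeTable,
                 pcs: np.ndarray | None, spec: ModelSpec,
                 or_scale: str = "per_sd") -> AssociationResult:
    """Fit the nested model pair for one score and summarize its contribution.

    Samples are matched by id (inner join); rows with missing covariates are
    excluded (complete-case).  ``pcs`` must be row-aligned with
    ``prs.sample_ids``; the first ``spec.n_pcs`` columns enter both models.
    """
    if or_scale not in ("per_sd", "raw"):
        raise ValueError(f"unknown or_scale {or_scale!r}")
    prs_df = pd.DataFrame({"sample_id": [str(s) for s in prs.sample_ids],
                           "_prs_raw": prs.raw_values if prs.raw_values is not None
                           else prs.values})
    if pcs is not None:
        if pcs.shape[0] != len(prs.sample_ids):
            raise ValueError("pcs not aligned with PRS samples")
        if spec.n_pcs > pcs.shape[1]:
            raise ValueError("n_pcs exceeds available PCs")
        for j in range(spec.n_pcs):
            prs_df[f"PC{j+1}"] = pcs[:, j]
    elif spec.n_pcs > 0:
        raise ValueError("n_pcs > 0 but no PCs supplied")

    pheno = phenotypes.df.copy()
    pheno["sample_id"] = pheno["sample_id"].astype(str)
    df = pheno.merge(prs_df, on="sample_id", how="inner")
    n_dropped = len(pheno) - len(df)
    if n_dropped:
        logger.info("evaluate_prs: %d phenotype sample(s) without PRS dropped", n_dropped)
    terms = list(spec.covariates) + [f"PC{j+1}" for j in range(spec.n_pcs)]
    df = df.dropna(subset=terms + ["_prs_raw", "case_status"])

    raw = df["_prs_raw"].to_numpy(dtype=float)
    sd_raw = raw.std()
    if sd_raw == 0:
        raise ValueError(f"{prs.pgs_id}: degenerate score (zero SD)")
    df["_prs_z"] = (raw - raw.mean()) / sd_raw

    y = df["case_status"].to_numpy(dtype=float)
    X_null = _design(df, terms)
    X_full = _design(df, terms + ["_prs_z"])
    fit_null = fit_logistic(y, X_null, ["const"] + terms)
    fit_full = fit_logistic(y, X_full, ["const"] + terms + ["prs"])
    usable = fit_null.converged and fit_full.converged

    n = len(df)
    ll0 = intercept_only_loglik(y)
    if usable:
        r2_null = nagelkerke_r2(fit_null.log_likelihood, ll0, n)
        r2_full = nagelkerke_r2(fit_full.log_likelihood, ll0, n)
        beta = fit_full.coefficients[-1]
        se = fit_full.standard_errors[-1]
        z = beta / se
        p_value = float(min(max(2.0 * sps.norm.sf(abs(z)), 5e-324), 1.0))
        or_per_sd = float(np.exp(beta))
        ci_sd = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        beta_raw = beta / sd_raw
        se_raw = se / sd_raw
        or_raw = float(np.exp(beta_raw))
        ci_raw = (float(np.exp(beta_raw - 1.96 * se_raw)),
                  float(np.exp(beta_raw + 1.96 * se_raw)))
    else:
        r2_null = r2_full = np.nan
        p_value = np.nan
        or_per_sd, ci_sd = np.nan, (np.nan, np.nan)
        or_raw, ci_raw = np.nan, (np.nan, np.nan)

    if or_scale == "per_sd":
        headline, ci = or_per_sd, ci_sd
    else:
        headline, ci = or_raw, ci_raw
    return AssociationResult(
        pgs_id=prs.pgs_id, model=spec.name,
        r2_null=r2_null, r2_full=r2_full,
        adjusted_prs_r2=adjusted_prs_r2(r2_full, r2_null) if usable else np.nan,
        odds_ratio=headline, ci_low=ci[0], ci_high=ci[1],
        p_value=p_value, or_scale=or_scale,
        or_per_sd=or_per_sd, or_raw=or_raw, or_raw_ci=ci_raw,
        usable=usable, n=n, n_pcs=spec.n_pcs,
    )
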