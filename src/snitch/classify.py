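"""Per-CpG trajectory classification.

Each CpG's beta values are modeled against age twice — by ordinary least
squares and by a penalized age smooth — and tested for heteroscedasticity.
After Benjamini-Hochberg adjustment of each p-value family across all CpGs,
labels are assigned with precedence NL -> LI/LD -> VI -> NC:

* NL  — the smooth beats the line by dBIC > 2 and its adjusted p <= alpha;
* LI / LD — significant linear slope (sign gives the direction);
* VI  — no linear trend but significant White heteroscedasticity;
* NC  — none of the above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._pspline import SmoothBatchFit, SmoothEngine
from .io import AnalysisConfig, BetaMatrix, SampleTable, ValidationError

__all__ = [
    "LinearFit",
    "SmoothFit",
    "ClassificationResult",
    "fit_linear_model",
    "fit_smooth_model",
    "white_heteroscedasticity_test",
    "adjust_pvalues_bh",
    "classify_trajectories",
    "predict_reference_trajectory",
    "LABELS",
]

logger = logging.getLogger(__name__)

LABELS = ("NC", "LI", "LD", "VI", "NL")
_ZERO_VAR_TOL = 1e-12


# --------------------------------------------------------------------------- #
# linear model
# --------------------------------------------------------------------------- #


@dataclass
class LinearFit:
    slope: float
    slope_p: float
    residuals: np.ndarray
    loglik: float
    bic: float
    n_params: int
    degenerate: bool = False


def _design(age: np.ndarray, covariates: np.ndarray | pd.DataFrame | None) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    cov = (
        np.asarray(covariates, dtype=float).reshape(age.size, -1)
        if covariates is not None and np.size(covariates)
        else np.empty((age.size, 0))
    )
    return np.column_stack([np.ones(age.size), cov, age])


def fit_linear_model(
    y: np.ndarray,
    age: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> LinearFit:
    """OLS of beta on age (+ covariates); slope and t-test for the age term.

    BIC counts the residual-variance parameter, matching R's ``BIC(lm)``:
    ``-2 loglik + (p + 1) log n``.
    """
    y = np.asarray(y, dtype=float)
    X = _design(age, covariates)
    n, p = X.shape
    if n < p + 2:
        raise ValidationError(f"need at least {p + 2} samples for {p} parameters, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("rank-deficient design: collinear covariate columns")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2_ml = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + rss / (n * sigma2_ml))
    bic = -2 * loglik + (p + 1) * np.log(n)

    degenerate = y.var() <= _ZERO_VAR_TOL or rss / n <= _ZERO_VAR_TOL
    if y.var() <= _ZERO_VAR_TOL:
        return LinearFit(0.0, 1.0, resid, loglik, bic, p + 1, True)
    sigma2 = rss / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(max(sigma2 * XtX_inv[-1, -1], 0.0))
    slope = float(coef[-1])
    if se == 0.0:
        slope_p = 0.0 if abs(slope) > 0 else 1.0
    else:
        slope_p = float(2 * stats.t.sf(abs(slope) / se, n - p))
    return LinearFit(slope, slope_p, resid, loglik, bic, p + 1, degenerate)


# --------------------------------------------------------------------------- #
# smooth model
# --------------------------------------------------------------------------- #


@dataclass
class SmoothFit:
    smooth_p: float
    edf: float
    loglik: float
    bic: float
    fitted: np.ndarray
    basis_dim: int
    degenerate: bool = False
    engine: SmoothEngine | None = field(default=None, repr=False)
    coefs: np.ndarray | None = field(default=None, repr=False)


def fit_smooth_model(
    y: np.ndarray,
    age: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    k: int = 5,
) -> SmoothFit:
    """Penalized cubic-spline smooth of age (basis dimension ``k``, REML ratio)."""
    y = np.asarray(y, dtype=float)
    cov = (
        np.asarray(covariates, dtype=float)
        if covariates is not None and np.size(covariates)
        else None
    )
    engine = SmoothEngine(np.asarray(age, dtype=float), cov, k=k)
    batch = engine.fit_batch(y[None, :])
    return SmoothFit(
        smooth_p=float(batch.smooth_p[0]),
        edf=float(batch.edf_smooth[0]),
        loglik=float(batch.loglik[0]),
        bic=float(batch.bic[0]),
        fitted=batch.fitted[0],
        basis_dim=k,
        degenerate=bool(batch.degenerate[0]),
        engine=engine,
        coefs=batch.coefs[0],
    )


# --------------------------------------------------------------------------- #
# White's heteroscedasticity test
# --------------------------------------------------------------------------- #


def _white_aux_design(exog: np.ndarray, n: int) -> np.ndarray:
    """Auxiliary design: regressors, squares and (if affordable) cross products."""
    exog = np.asarray(exog, dtype=float).reshape(n, -1)
    cols = [np.ones(n)]
    cols.extend(exog.T)
    cols.extend((exog**2).T)
    d = exog.shape[1]
    cross = [exog[:, i] * exog[:, j] for i in range(d) for j in range(i + 1, d)]
    full = cols + cross
    if len(full) > n / 5 and cross:
        logger.warning(
            "White auxiliary design (%d columns) wider than n/5; "
            "falling back to regressors + squares only",
            len(full),
        )
        full = cols
    A = np.column_stack(full)
    # drop duplicated columns (e.g. squares of dummies equal the dummy)
    _, keep = np.unique(np.round(A, 12), axis=1, return_index=True)
    return A[:, np.sort(keep)]


def white_heteroscedasticity_test(
    fit: LinearFit | np.ndarray,
    exog: np.ndarray | pd.DataFrame,
) -> float:
    """White's LM test: n*R^2 from regressing squared residuals on the
    regressors, their squares and pairwise products; chi-square reference.

    ``fit`` may be a :class:`LinearFit` or a raw residual vector; ``exog``
    holds the model regressors without the intercept.
    """
    resid = fit.residuals if isinstance(fit, LinearFit) else np.asarray(fit, dtype=float)
    n = resid.size
    e2 = resid**2
    tss = float(((e2 - e2.mean()) ** 2).sum())
    if tss <= _ZERO_VAR_TOL:
        return 1.0
    A = _white_aux_design(np.asarray(exog, dtype=float), n)
    df = A.shape[1] - 1
    if df < 1 or n <= A.shape[1]:
        return 1.0
    coef, _, _, _ = np.linalg.lstsq(A, e2, rcond=None)
    rss = float(((e2 - A @ coef) ** 2).sum())
    r2 = 1.0 - rss / tss
    statistic = n * max(r2, 0.0)
    return float(stats.chi2.sf(statistic, df))


# --------------------------------------------------------------------------- #
# multiple testing
# --------------------------------------------------------------------------- #


def adjust_pvalues_bh(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValidationError("NaN p-values passed to BH adjustment")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values outside [0,1] passed to BH adjustment")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------- #
# full classification
# --------------------------------------------------------------------------- #


@dataclass
class ClassificationResult:
    """Classification table plus the fitted smooth state needed downstream."""

    table: pd.DataFrame
    samples: SampleTable
    config: AnalysisConfig
    smooth_engine: SmoothEngine = field(repr=False)
    smooth_coefs: np.ndarray = field(repr=False)  # (n_cpg, p+q)

    @property
    def labels(self) -> pd.Series:
        return self.table.set_index("cpg_id")["label"]

    def age_grid(self) -> np.ndarray:
        age = self.samples.age
        step = self.config.grid_step_years
        return np.arange(age.min(), age.max() + 0.5 * step, step)

    def smoothed_trajectories(self, which: str | Sequence[str] = "NL"):
        """Curves for CpGs with the given label(s), predicted on the age grid
        at reference covariates and clipped to [0, 1]."""
        from .fpca_cluster import SmoothedTrajectorySet

        wanted = (which,) if isinstance(which, str) else tuple(which)
        mask = self.table["label"].isin(wanted).to_numpy()
        ids = self.table.loc[mask, "cpg_id"].tolist()
        grid = self.age_grid()
        if not ids:
            return SmoothedTrajectorySet(cpg_ids=[], grid=grid, curves=np.empty((0, grid.size)))
        ref = self.samples.reference_row(list(self.config.covariates)).to_numpy()
        curves = self.smooth_engine.predict(self.smooth_coefs[mask], grid, ref)
        n_clip = int(((curves < 0) | (curves > 1)).sum())
        if n_clip:
            logger.info("clipped %d predicted values to [0,1]", n_clip)
        return SmoothedTrajectorySet(
            cpg_ids=ids, grid=grid, curves=np.clip(curves, 0.0, 1.0)
        )


def _batch_linear(Y: np.ndarray, X: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized OLS of every row of Y on the shared design X."""
    m, n = Y.shape
    p = X.shape[1]
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    coefs = Y @ (X @ XtX_inv)  # m x p
    fitted = coefs @ X.T
    resid = Y - fitted
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2_ml = np.maximum(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2_ml) + 1.0)
    bic = -2 * loglik + (p + 1) * np.log(n)
    sigma2 = rss / (n - p)
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[-1, -1], 0.0))
    slope = coefs[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, np.abs(slope) / np.where(se > 0, se, 1.0), np.inf)
    slope_p = 2 * stats.t.sf(tstat, n - p)
    degenerate = (Y.var(axis=1) <= _ZERO_VAR_TOL) | (rss / n <= _ZERO_VAR_TOL)
    slope_p = np.where(Y.var(axis=1) <= _ZERO_VAR_TOL, 1.0, slope_p)
    slope = np.where(Y.var(axis=1) <= _ZERO_VAR_TOL, 0.0, slope)
    return {
        "slope": slope,
        "slope_p": np.clip(slope_p, 0.0, 1.0),
        "resid": resid,
        "bic": bic,
        "degenerate": degenerate,
    }


def _batch_white(resid: np.ndarray, exog: np.ndarray) -> np.ndarray:
    """Vectorized White test p-values for rows of a residual matrix."""
    m, n = resid.shape
    A = _white_aux_design(exog, n)
    df = A.shape[1] - 1
    e2 = resid**2
    tss = np.einsum("ij,ij->i", e2 - e2.mean(axis=1, keepdims=True),
                    e2 - e2.mean(axis=1, keepdims=True))
    pinv = np.linalg.pinv(A)
    res_aux = e2 - (e2 @ pinv.T) @ A.T
    rss = np.einsum("ij,ij->i", res_aux, res_aux)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > _ZERO_VAR_TOL, 1.0 - rss / np.where(tss > 0, tss, 1.0), 0.0)
    p = stats.chi2.sf(n * np.clip(r2, 0.0, 1.0), df)
    return np.where(tss <= _ZERO_VAR_TOL, 1.0, p)


def classify_trajectories(
    beta: BetaMatrix,
    samples: SampleTable,
    config: AnalysisConfig | None = None,
) -> ClassificationResult:
    """Classify every CpG into NC / LI / LD / VI / NL.

    BH adjustment is performed across all CpGs separately within the linear,
    smooth and White p-value families; dBIC = BIC(LM) - BIC(smooth). A CpG
    whose fits are degenerate (zero variance, perfect fit) is labeled NC with
    p-values forced to 1 rather than aborting the run.
    """
    config = config or AnalysisConfig()
    samples = samples.aligned_to(beta)
    age = samples.age
    if np.unique(age).size < 2:
        raise ValidationError("at least 2 distinct ages are required for model fits")
    cov_design = samples.design(list(config.covariates))
    cov = cov_design.to_numpy() if cov_design.shape[1] else None

    Y = beta.values
    X_lm = _design(age, cov)
    lm = _batch_linear(Y, X_lm)

    engine = SmoothEngine(age, cov, k=config.basis_dim_k)
    sm = engine.fit_batch(Y)

    exog = X_lm[:, 1:]  # regressors without intercept
    p_white = _batch_white(lm["resid"], exog)

    degenerate = lm["degenerate"] | sm.degenerate
    p_lm = np.where(degenerate, 1.0, lm["slope_p"])
    p_gam = np.where(degenerate, 1.0, sm.smooth_p)
    p_white = np.where(degenerate, 1.0, p_white)
    if degenerate.any():
        logger.warning(
            "%d CpGs had degenerate fits (zero variance or perfect fit); labeled NC",
            int(degenerate.sum()),
        )

    p_lm_adj = adjust_pvalues_bh(p_lm)
    p_gam_adj = adjust_pvalues_bh(p_gam)
    p_white_adj = adjust_pvalues_bh(p_white)
    delta_bic = lm["bic"] - sm.bic

    labels = np.full(Y.shape[0], "NC", dtype=object)
    is_nl = (delta_bic > config.delta_bic_threshold) & (p_gam_adj <= config.alpha_gam)
    is_lin = p_lm_adj <= config.alpha_lm
    is_vi = (~is_lin) & (p_white_adj <= config.alpha_white)
    labels[is_vi] = "VI"
    labels[is_lin & (lm["slope"] > 0)] = "LI"
    labels[is_lin & (lm["slope"] < 0)] = "LD"
    labels[is_nl] = "NL"
    labels[degenerate] = "NC"

    table = pd.DataFrame(
        {
            "cpg_id": beta.cpg_ids,
            "label": labels.astype(str),
            "slope": lm["slope"],
            "p_lm": p_lm,
            "p_gam": p_gam,
            "p_white": p_white,
            "p_lm_adj": p_lm_adj,
            "p_gam_adj": p_gam_adj,
            "p_white_adj": p_white_adj,
            "delta_bic": delta_bic,
            "edf": sm.edf_smooth,
            "degenerate": degenerate,
        }
    )
    return ClassificationResult(
        table=table,
        samples=samples,
        config=config,
        smooth_engine=engine,
        smooth_coefs=sm.coefs,
    )


def predict_reference_trajectory(
    fit: SmoothFit,
    samples: SampleTable,
    config: AnalysisConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict a fitted smooth on the cohort age grid at reference covariates.

    Returns ``(grid, curve)`` with the grid running from the minimum to the
    maximum observed age in steps of ``grid_step_years`` and predictions
    clipped to [0, 1].
    """
    if fit.engine is None or fit.coefs is None:
        raise ValidationError("SmoothFit carries no engine state; refit with fit_smooth_model")
    config = config or AnalysisConfig()
    age = samples.age
    step = config.grid_step_years
    if age.max() < age.min():
        raise ValidationError("empty age grid: max(age) < min(age)")
    grid = np.arange(age.min(), age.max() + 0.5 * step, step)
    ref = samples.reference_row(list(config.covariates)).to_numpy()
    n_cov = fit.engine.p - fit.engine.n_null - 1
    curve = fit.engine.predict(fit.coefs, grid, ref if n_cov else None)[0]
    if ((curve < 0) | (curve > 1)).any():
        logger.info("clipped predictions outside [0,1]")
    return grid, np.clip(curve, 0.0, 1.0)
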