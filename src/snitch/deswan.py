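"""Sliding-window detection of age "waves of dysregulation".

For every window center c, samples aged within the half-width below c are
compared with samples within the half-width above c, CpG by CpG, with a
Wilcoxon rank-sum test (on covariate-residualized values) or a two-group
linear model. P-values are BH-adjusted across CpGs within each window, and
the counts of significant CpGs at nested FDR levels trace the wave profile.
A peak is called robust only if it is a local maximum of the count profile at
every FDR level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import adjust_pvalues_bh
from .io import AnalysisConfig, BetaMatrix, SampleTable, ValidationError

__all__ = ["WindowSpec", "DeswanResult", "deswan_counts", "detect_peaks", "wave_overlap"]

logger = logging.getLogger(__name__)

_MIN_GROUP = 5


@dataclass(frozen=True)
class WindowSpec:
    """Window centers (ages, years) and the half-width of each flank."""

    centers: tuple[float, ...] = tuple(float(c) for c in range(31, 78, 2))
    half_width: float = 15.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValidationError("half_width must be > 0")

    @classmethod
    def from_config(cls, config: AnalysisConfig) -> "WindowSpec":
        return cls(
            centers=tuple(config.deswan_center_ages.tolist()),
            half_width=config.deswan_half_width,
        )


@dataclass
class DeswanResult:
    counts: pd.DataFrame               # center, n_tested, n_sig_<level>..., skipped
    fdr_levels: tuple[float, ...]
    pvalues: dict[float, np.ndarray] = field(default_factory=dict, repr=False)
    significant_cpgs: dict[tuple[float, float], list[str]] = field(
        default_factory=dict, repr=False
    )

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        peaks = detect_peaks(self)
        df["is_peak"] = df["center"].isin(peaks)
        return df


def _residualize(Y: np.ndarray, cov: np.ndarray | None) -> np.ndarray:
    """Residuals of each CpG on intercept + covariates over all samples."""
    n = Y.shape[1]
    X = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    pinv = np.linalg.pinv(X)
    return Y - (Y @ pinv.T) @ X.T


def deswan_counts(
    beta: BetaMatrix,
    samples: SampleTable,
    windows: WindowSpec | None = None,
    config: AnalysisConfig | None = None,
    test: str = "wilcoxon-residual",
) -> DeswanResult:
    """Count differentially methylated CpGs around each window center.

    ``beta`` should be restricted to age-associated CpGs (the wave analysis
    is not meaningful on a background of non-correlated sites). At center c
    the groups are ages in [c - hw, c) versus (c, c + hw]; windows with a
    flank of fewer than 5 samples are skipped and flagged. ``test`` is
    ``"wilcoxon-residual"`` (rank-sum on covariate residuals) or ``"linear"``
    (per-window OLS group term with covariates).
    """
    if beta.n_cpg == 0:
        raise ValidationError("no age-associated CpGs supplied to the wave analysis")
    config = config or AnalysisConfig()
    windows = windows or WindowSpec.from_config(config)
    samples = samples.aligned_to(beta)
    age = samples.age
    cov_design = samples.design(list(config.covariates))
    cov = cov_design.to_numpy() if cov_design.shape[1] else None
    Y = beta.values
    if test == "wilcoxon-residual":
        Y_test = _residualize(Y, cov)
    elif test == "linear":
        Y_test = Y
    else:
        raise ValidationError(f"unknown test {test!r}")

    levels = tuple(sorted(config.deswan_fdr_levels, reverse=True))
    rows = []
    pvals: dict[float, np.ndarray] = {}
    sig_sets: dict[tuple[float, float], list[str]] = {}
    for center in windows.centers:
        left = (age >= center - windows.half_width) & (age < center)
        right = (age > center) & (age <= center + windows.half_width)
        if left.sum() < _MIN_GROUP or right.sum() < _MIN_GROUP:
            logger.warning(
                "window at %.0f skipped: flank sizes %d/%d", center, left.sum(), right.sum()
            )
            rows.append({"center": center, "n_tested": 0, "skipped": True,
                         **{f"n_sig_{l:g}": 0 for l in levels}})
            continue
        if test == "wilcoxon-residual":
            p = stats.mannwhitneyu(
                Y_test[:, left], Y_test[:, right], axis=-1, alternative="two-sided"
            ).pvalue
        else:
            p = _window_linear_p(Y, left, right, cov)
        p_adj = adjust_pvalues_bh(np.nan_to_num(p, nan=1.0))
        pvals[center] = p_adj
        row = {"center": center, "n_tested": int(Y.shape[0]), "skipped": False}
        for level in levels:
            hits = p_adj <= level
            row[f"n_sig_{level:g}"] = int(hits.sum())
            sig_sets[(center, level)] = [c for c, h in zip(beta.cpg_ids, hits) if h]
        rows.append(row)

    counts = pd.DataFrame(rows)
    for hi, lo in zip(levels[:-1], levels[1:]):  # nested-threshold invariant
        assert (counts[f"n_sig_{lo:g}"] <= counts[f"n_sig_{hi:g}"]).all()
    return DeswanResult(counts=counts, fdr_levels=levels, pvalues=pvals,
                        significant_cpgs=sig_sets)


def _window_linear_p(Y, left, right, cov) -> np.ndarray:
    """Vectorized OLS p-value of the group indicator within one window."""
    sel = left | right
    group = right[sel].astype(float)
    n = int(sel.sum())
    X = np.column_stack(
        [np.ones(n), group] + ([cov[sel]] if cov is not None else [])
    )
    Ys = Y[:, sel]
    XtX_inv = np.linalg.inv(X.T @ X)
    coefs = Ys @ (X @ XtX_inv)
    resid = Ys - coefs @ X.T
    dof = n - X.shape[1]
    sigma2 = np.einsum("ij,ij->i", resid, resid) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 1e-300))
    t = np.abs(coefs[:, 1]) / se
    return 2 * stats.t.sf(t, dof)


def detect_peaks(result: DeswanResult) -> list[float]:
    """Window centers that are interior local maxima at every FDR level."""
    counts = result.counts[~result.counts["skipped"]].reset_index(drop=True)
    if len(counts) < 3:
        return []
    peaks = []
    for i in range(1, len(counts) - 1):
        robust = all(
            counts.loc[i, f"n_sig_{l:g}"] > counts.loc[i - 1, f"n_sig_{l:g}"]
            and counts.loc[i, f"n_sig_{l:g}"] > counts.loc[i + 1, f"n_sig_{l:g}"]
            for l in result.fdr_levels
        )
        if robust:
            peaks.append(float(counts.loc[i, "center"]))
    return peaks


def wave_overlap(
    result_a: DeswanResult,
    result_b: DeswanResult,
    level: float = 0.05,
) -> pd.DataFrame:
    """Pairwise intersection counts between the unique CpG sets of two runs'
    robust peaks (supports cross-cohort wave comparison)."""
    sets_a = _unique_peak_sets(result_a, level)
    sets_b = _unique_peak_sets(result_b, level)
    data = {
        f"b_{cb:g}": [len(set(sa) & set(sb)) for sa in sets_a.values()]
        for cb, sb in sets_b.items()
    }
    return pd.DataFrame(data, index=[f"a_{ca:g}" for ca in sets_a])


def _unique_peak_sets(result: DeswanResult, level: float) -> dict[float, list[str]]:
    peaks = detect_peaks(result)
    raw = {c: set(result.significant_cpgs.get((c, level), [])) for c in peaks}
    unique = {}
    for c, cpgs in raw.items():
        others = set().union(*(v for k, v in raw.items() if k != c)) if len(raw) > 1 else set()
        unique[c] = sorted(cpgs - others)
    return unique
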