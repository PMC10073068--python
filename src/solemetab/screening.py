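"""Preliminary confounder screen and per-variable univariable statistics.

The confounder screen projects the autoscaled intensity table onto its first
five principal components and reports how strongly each covariate tracks each
component: absolute Pearson r for continuous covariates, the between-group
variance ratio (eta-squared) for categorical ones.

Univariable comparisons between cases and controls use the unpaired two-sample
rank-sum (Mann-Whitney) test — appropriate for the skewed, non-Gaussian
relative intensities — plus the log2 fold-change of group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .preprocess import IntensityMatrix

__all__ = [
    "PCAScreenReport",
    "pca_confounder_screen",
    "wilcoxon_rank_test",
    "log2_fold_change",
    "univariable_table",
]

#: combined group size above which the rank test switches to the tie-corrected
#: normal approximation
EXACT_LIMIT = 50


@dataclass
class PCAScreenReport:
    """Scores, explained variance and covariate associations for the top PCs."""

    scores: pd.DataFrame  # samples x components
    loadings: np.ndarray  # components x variables, orthonormal rows
    explained_variance: np.ndarray  # proportions, nonincreasing
    covariate_assoc: pd.DataFrame  # covariate x component association strength
    flagged: dict[str, bool]  # covariate -> any component association above threshold


def pca_confounder_screen(
    m: IntensityMatrix,
    covariates: pd.DataFrame,
    n_components: int = 5,
    flag_threshold: float = 0.3,
) -> PCAScreenReport:
    """PCA of the autoscaled matrix with per-covariate association strengths.

    ``covariates`` must be indexed by (or aligned to) the matrix's samples.
    Numeric covariates report |Pearson r| with each component; categorical
    covariates report eta-squared (between-group / total variance of the
    component scores).  A covariate is flagged when any of the first
    ``n_components`` associations exceeds ``flag_threshold``.
    """
    m.require_state("autoscaled")
    X = m.values()
    n, p = X.shape
    if n < 6:
        raise ValueError("confounder screen needs at least 6 samples")
    k = min(n_components, n - 1, p)
    if k < n_components:
        warnings.warn(
            f"reducing components from {n_components} to {k} (n={n}, p={p})",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cov = covariates.reindex(m.sample_ids) if covariates.index.size else covariates
    assoc = {}
    flagged = {}
    for name in cov.columns:
        col = cov[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 6:
            x = col.to_numpy(dtype=float)
            vals = [
                abs(float(np.corrcoef(x, scores[:, a])[0, 1])) for a in range(k)
            ]
        else:
            vals = [_eta_squared(col.to_numpy(), scores[:, a]) for a in range(k)]
        assoc[name] = vals
        flagged[name] = max(vals) > flag_threshold
    return PCAScreenReport(
        scores=pd.DataFrame(
            scores, index=m.sample_ids, columns=[f"PC{a + 1}" for a in range(k)]
        ),
        loadings=pca.components_,
        explained_variance=pca.explained_variance_ratio_,
        covariate_assoc=pd.DataFrame(
            assoc, index=[f"PC{a + 1}" for a in range(k)]
        ).T,
        flagged=flagged,
    )


def _eta_squared(groups: np.ndarray, scores: np.ndarray) -> float:
    """Between-group share of the total variance of ``scores``."""
    total = float(((scores - scores.mean()) ** 2).sum())
    if total == 0:
        return 0.0
    between = 0.0
    for g in np.unique(groups):
        sel = scores[groups == g]
        between += len(sel) * (sel.mean() - scores.mean()) ** 2
    return float(between / total)


def wilcoxon_rank_test(x_case, x_control) -> float:
    """Two-sided p-value of the unpaired two-sample rank-sum test.

    Uses the exact null distribution of the Mann-Whitney U statistic when the
    combined sample size is at most ``EXACT_LIMIT`` and the data are tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x_case = np.asarray(x_case, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    if x_case.size < 2 or x_control.size < 2:
        raise ValueError("each group needs at least 2 observations")
    combined = np.concatenate([x_case, x_control])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x_case, x_control, alternative="two-sided", method=method
    )
    return float(res.pvalue)


def log2_fold_change(x_case, x_control) -> float:
    """log2 of the case-to-control ratio of group mean intensities.

    Positive values denote higher relative intensity in cases.
    """
    mc = float(np.mean(np.asarray(x_case, dtype=float)))
    mk = float(np.mean(np.asarray(x_control, dtype=float)))
    if mc <= 0 or mk <= 0:
        raise ValueError(f"group means must be positive (case {mc}, control {mk})")
    return float(np.log2(mc / mk))


def univariable_table(
    X: pd.DataFrame, y: np.ndarray
) -> pd.DataFrame:
    """Per-variable rank-test p-value and log2 fold-change (cases = y==1)."""
    y = np.asarray(y)
    rows = []
    for col in X.columns:
        case = X.loc[y == 1, col].to_numpy()
        ctrl = X.loc[y == 0, col].to_numpy()
        rows.append(
            {
                "bin_id": col,
                "p_value": wilcoxon_rank_test(case, ctrl),
                "log2fc": log2_fold_change(case, ctrl),
            }
        )
    return pd.DataFrame(rows)
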