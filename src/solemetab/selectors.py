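"""The three variable-selection methods and their tuning/evaluation harness.

Each method both predicts class membership and yields a binary selected-variable
set:

* PLS-DA — two-class partial least squares on the 0/1 class indicator; a
  variable is selected when its VIP (variable importance in projection) score
  exceeds 1.  VIP is normalized so the mean squared VIP over variables is
  exactly 1, making VIP > 1 "above-average contribution".
* Lasso — L1-penalized logistic regression; selected variables are those with
  a nonzero coefficient in the final model refit at the cross-validation
  winning penalty.
* Boruta — a random-forest wrapper that appends a shuffled "shadow" copy of
  every variable each iteration and confirms a real variable once its
  importance beats the best shadow significantly more often than a fair coin
  (two-sided binomial test with Holm step-down correction).

Hyperparameters are tuned to out-of-fold balanced accuracy via stratified
5-fold cross-validation repeated 20 times (100 fold-fits per grid point);
predictions are pooled within a repeat and the balanced accuracy averaged over
repeats.  Ties prefer the more parsimonious setting (fewer components, larger
penalty, smaller mtry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import config_context
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .config import AnalysisConfig

__all__ = [
    "METHODS",
    "ModelPerformance",
    "SelectorResult",
    "balanced_accuracy",
    "fit_plsda",
    "lasso_lambda_max",
    "fit_lasso_logistic",
    "boruta_select",
    "tune_and_evaluate",
    "select_variables",
    "standardize",
    "default_grid",
]

METHODS = ("plsda", "lasso", "boruta")


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of the per-class recalls; 0.5 is chance for two classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    classes = np.unique(y_true)
    if classes.size != 2:
        raise ValueError(f"need both classes in y_true, got {classes}")
    recalls = [
        float(np.mean(y_pred[y_true == c] == c)) for c in classes
    ]
    return float(np.mean(recalls))


def standardize(train: np.ndarray, other: np.ndarray | None = None):
    """Column-wise center/scale by the training mean and SD (ddof=1).

    Zero-variance columns map to zero rather than raising — inside bootstrap
    resamples and CV folds a column can become constant by chance, and such a
    column carries no class information either way.
    """
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    ts = (train - mu) / sd
    if other is None:
        return ts
    return ts, (other - mu) / sd


# ---------------------------------------------------------------------------
# PLS-DA


@dataclass
class PLSDAModel:
    pls: PLSRegression = field(repr=False)
    vip: np.ndarray = field(repr=False)
    n_components: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        # class indicator fitted on {0,1}: threshold at the midpoint
        return (self.pls.predict(X).ravel() >= 0.5).astype(int)

    def selected_mask(self) -> np.ndarray:
        return self.vip > 1.0


def fit_plsda(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSDAModel:
    """Two-class PLS regression on the class indicator, with VIP scores.

    VIP_j = sqrt( p * sum_a[ SSY_a * (w_aj/||w_a||)^2 ] / sum_a SSY_a ),
    where SSY_a is the response variance explained by component a.  The
    identity sum_j VIP_j^2 = p holds for every fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} outside [1, min(n-1, p)={min(n - 1, p)}]"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X, y)
    W = pls.x_weights_  # p x A, columns unit-norm
    T = pls.x_scores_  # n x A
    q = pls.y_loadings_.ravel()  # A
    ssy = (q**2) * np.einsum("ia,ia->a", T, T)
    norms = np.linalg.norm(W, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    Wn2 = (W / norms) ** 2
    total = ssy.sum()
    if total <= 0:
        vip = np.ones(p)  # degenerate: response unexplained, all equal by convention
    else:
        vip = np.sqrt(p * (Wn2 @ ssy) / total)
    return PLSDAModel(pls=pls, vip=vip, n_components=n_components)


# ---------------------------------------------------------------------------
# Lasso logistic regression


@dataclass
class LassoLogisticModel:
    model: LogisticRegression = field(repr=False)
    lam: float

    @property
    def coef(self) -> np.ndarray:
        return self.model.coef_.ravel()

    @property
    def intercept(self) -> float:
        return float(self.model.intercept_[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def selected_mask(self) -> np.ndarray:
        return self.coef != 0.0


def lasso_lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every slope coefficient is exactly zero.

    From the gradient of the mean binomial log-likelihood at the null model:
    lambda_max = max_j |x_j . (y - mean(y))| / n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.abs(X.T @ (y - y.mean())).max() / len(y))


def fit_lasso_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> LassoLogisticModel:
    """L1-penalized logistic regression at mean-log-likelihood penalty ``lam``.

    Objective: (1/n) sum_i loss_i + lam * sum_j |beta_j|.  The intercept is
    effectively unpenalized (large ``intercept_scaling`` makes the bias term's
    penalty negligible).
    """
    y = np.asarray(y)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if np.unique(y).size != 2:
        raise ValueError("need both classes present")
    n = len(y)
    C = 1e12 if lam == 0 else 1.0 / (n * lam)
    model = LogisticRegression(
        penalty="l1",
        C=C,
        solver="liblinear",
        intercept_scaling=100.0,
        tol=1e-6,
        max_iter=1000,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return LassoLogisticModel(model=model, lam=lam)


# ---------------------------------------------------------------------------
# Boruta


def _holm_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


@dataclass
class BorutaResult:
    decisions: np.ndarray  # per variable: "confirmed" | "rejected" | "tentative"
    hits: np.ndarray
    n_iterations: int

    def selected_mask(self) -> np.ndarray:
        # tentative counts as not selected: selection must be binary
        return self.decisions == "confirmed"


def boruta_select(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    alpha: float = 0.01,
    max_iter: int = 100,
    seed: int | np.random.Generator | None = None,
) -> BorutaResult:
    """Shadow-feature random-forest selection.

    Each iteration appends an independently shuffled copy of every still
    unresolved variable, fits a random forest on the augmented matrix, and
    scores a "hit" for a real variable whose importance exceeds the best
    shadow importance.  Hit counts are tested against Binomial(iterations,
    1/2), two-sided with Holm step-down correction at ``alpha``; variables
    still unresolved after ``max_iter`` iterations stay tentative.

    """
    if max_iter < 10:
        raise ValueError("max_iter must be >= 10")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need both classes present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = X.shape[1]
    decisions = np.full(p, "tentative", dtype=object)
    hits = np.zeros(p, dtype=int)
    iters = np.zeros(p, dtype=int)
    for _ in range(max_iter):
        active = np.flatnonzero(decisions == "tentative")
        if active.size == 0:
            break
        Xa = X[:, active]
        shadow = rng.permuted(Xa, axis=0)
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            n_jobs=1,
            random_state=int(rng.integers(2**31)),
        )
        with config_context(assume_finite=True):  # inputs are finite by construction
            rf.fit(np.hstack([Xa, shadow]), y)
        imp = rf.feature_importances_
        real_imp, shadow_imp = imp[: active.size], imp[active.size :]
        hits[active[real_imp > shadow_imp.max()]] += 1
        iters[active] += 1
        k = iters[active]
        p_hi = stats.binom.sf(hits[active] - 1, k, 0.5)
        p_lo = stats.binom.cdf(hits[active], k, 0.5)
        confirm = _holm_adjust(np.minimum(2 * p_hi, 1.0)) < alpha
        reject = _holm_adjust(np.minimum(2 * p_lo, 1.0)) < alpha
        decisions[active[confirm]] = "confirmed"
        decisions[active[reject & ~confirm]] = "rejected"
    return BorutaResult(
        decisions=decisions.astype(str), hits=hits, n_iterations=int(iters.max(initial=0))
    )


# ---------------------------------------------------------------------------
# tuning and evaluation


@dataclass
class ModelPerformance:
    method: str
    balanced_accuracy: float
    tuned_hyperparameters: dict
    n_folds: int
    n_repeats: int
    n_fold_fits_per_grid_point: int
    grid_results: list = field(default_factory=list, repr=False)


@dataclass
class SelectorResult:
    method: str
    selected: tuple[int, ...]  # column indices
    scores: np.ndarray = field(repr=False)  # VIP | |coef| | Boruta hit fraction
    hyperparameters: dict = field(default_factory=dict)

    def selected_mask(self, p: int) -> np.ndarray:
        mask = np.zeros(p, dtype=bool)
        mask[list(self.selected)] = True
        return mask


def default_grid(method: str, X: np.ndarray, y: np.ndarray, config: AnalysisConfig):
    """Parsimony-ordered hyperparameter grid for a method on a given dataset."""
    n, p = X.shape
    if method == "plsda":
        comps = [c for c in config.plsda_components if c <= min(n - 1, p)]
        return [{"n_components": c} for c in sorted(comps)]
    if method == "lasso":
        lam_max = lasso_lambda_max(standardize(X), y)
        lam_max = max(lam_max, 1e-12)
        lams = np.geomspace(
            lam_max, lam_max * config.lasso_lambda_min_ratio, config.lasso_n_lambda
        )
        return [{"lam": float(l)} for l in lams]  # descending: most parsimonious first
    if method == "boruta":
        opts = {"sqrt": max(1, round(np.sqrt(p))), "third": max(1, p // 3), "fifth": max(1, p // 5)}
        mtry = sorted({opts[k] for k in config.rf_mtry})
        return [{"max_features": m} for m in mtry]
    raise ValueError(f"unknown method {method!r}")


def _fit_predictor(method, Xs, y, params, config, rng):
    if method == "plsda":
        nc = min(params["n_components"], Xs.shape[0] - 1, Xs.shape[1])
        return fit_plsda(Xs, y, nc)
    if method == "lasso":
        return fit_lasso_logistic(Xs, y, params["lam"])
    if method == "boruta":
        rf = RandomForestClassifier(
            n_estimators=config.rf_trees,
            max_features=params["max_features"],
            n_jobs=1,
            random_state=int(rng.integers(2**31)),
        )
        rf.fit(Xs, y)
        return rf
    raise ValueError(f"unknown method {method!r}")


def _fold_plan(y: np.ndarray, config: AnalysisConfig, rng: np.random.Generator):
    """(train, test) index pairs per repeat; identical across grid points.

    Falls back to leave-pair-out (one case + one control per test set, at most
    100 seeded pairs, a single "repeat") when a class has fewer than
    ``n_folds`` members.
    """
    y = np.asarray(y)
    counts = np.bincount(y)
    if counts.min() < config.n_folds:
        warnings.warn(
            "class with fewer members than folds; falling back to leave-pair-out",
            stacklevel=2,
        )
        cases = np.flatnonzero(y == 1)
        ctrls = np.flatnonzero(y == 0)
        pairs = [(i, j) for i in cases for j in ctrls]
        if len(pairs) > 100:
            pick = rng.choice(len(pairs), size=100, replace=False)
            pairs = [pairs[k] for k in pick]
        all_idx = np.arange(len(y))
        plan = [
            (np.setdiff1d(all_idx, [i, j]), np.array([i, j])) for i, j in pairs
        ]
        return [plan]
    repeats = []
    for _ in range(config.n_repeats):
        skf = StratifiedKFold(
            n_splits=config.n_folds,
            shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        repeats.append([(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)])
    return repeats


def tune_and_evaluate(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: list[dict] | None = None,
    seed: int | np.random.Generator = 0,
    config: AnalysisConfig | None = None,
) -> tuple[ModelPerformance, SelectorResult]:
    """Tune a method's hyperparameters and report out-of-fold balanced accuracy.

    Per grid point, out-of-fold predictions are pooled within each repeat and
    the resulting balanced accuracies averaged over repeats.  Standardization
    is recomputed inside every training fold (no leakage).  The final model is
    refit on the full standardized data at the winning point and supplies the
    selected-variable set.
    """
    config = config or AnalysisConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) < 10:
        raise ValueError("need at least 10 samples to tune")
    if grid is None:
        grid = default_grid(method, X, y, config)
    if not grid:
        raise ValueError("empty hyperparameter grid")

    plan = _fold_plan(y, config, rng)
    grid_results = []
    n_fits = 0
    for params in grid:
        repeat_bas = []
        for folds in plan:
            oof = np.full(len(y), -1)
            for tr, te in folds:
                Xtr, Xte = standardize(X[tr], X[te])
                model = _fit_predictor(method, Xtr, y[tr], params, config, rng)
                oof[te] = model.predict(Xte)
                n_fits += 1
            covered = oof >= 0
            repeat_bas.append(balanced_accuracy(y[covered], oof[covered]))
        grid_results.append((params, float(np.mean(repeat_bas))))
    bas = np.array([ba for _, ba in grid_results])
    best = int(np.argmax(bas))  # grid is parsimony-ordered; ties keep the first
    best_params, best_ba = grid_results[best]

    Xs = standardize(X)
    selector = _final_selection(method, Xs, y, best_params, config, rng)
    perf = ModelPerformance(
        method=method,
        balanced_accuracy=float(best_ba),
        tuned_hyperparameters=dict(best_params),
        n_folds=config.n_folds,
        n_repeats=len(plan),
        n_fold_fits_per_grid_point=n_fits // len(grid),
        grid_results=grid_results,
    )
    return perf, selector


def _final_selection(method, Xs, y, params, config, rng) -> SelectorResult:
    p = Xs.shape[1]
    if method == "plsda":
        model = fit_plsda(Xs, y, min(params["n_components"], Xs.shape[0] - 1, p))
        mask, scores = model.selected_mask(), model.vip
    elif method == "lasso":
        model = fit_lasso_logistic(Xs, y, params["lam"])
        mask, scores = model.selected_mask(), np.abs(model.coef)
    elif method == "boruta":
        res = boruta_select(
            Xs,
            y,
            n_trees=config.boruta_trees,
            alpha=config.boruta_alpha,
            max_iter=config.boruta_max_iter,
            seed=rng,
        )
        mask = res.selected_mask()
        scores = res.hits / max(res.n_iterations, 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SelectorResult(
        method=method,
        selected=tuple(int(i) for i in np.flatnonzero(mask)),
        scores=scores,
        hyperparameters=dict(params),
    )


def select_variables(
    method: str,
    Xs: np.ndarray,
    y: np.ndarray,
    params: dict,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean selected-variable mask for one fitted selector (no tuning)."""
    return _final_selection(method, Xs, y, params, config, rng).selected_mask(Xs.shape[1])
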