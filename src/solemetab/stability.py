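"""Bootstrap selection stability, permutation baseline thresholds, and the
full-pipeline orchestration.

The inferential core: a variable's *stability* under one selection method is
the percentage of stratified bootstrap resamples in which the method selects
it; the *observed stability* averages the three methods (PLS-DA, Lasso,
Boruta), triangulating selectors with unrelated biases.  To judge observed
stabilities, the class labels are permuted (class sizes preserved) and the
whole bootstrap-selection procedure repeated, yielding per-variable *baseline
stabilities* that reflect pure chance selection.  The 99th and 100th
percentiles of the baseline stabilities, averaged over permutations, define
the thresholds T99 and T100 — analogous to expected false-positive rates of
1% and 0%.  A variable is flagged informative when its observed stability
strictly exceeds a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    AnimalRecord,
    SubsetMembers,
    build_subsets,
    classify_outcome,
    match_controls,
)
from .config import AnalysisConfig
from .preprocess import (
    BinCatalog,
    IntensityMatrix,
    normalize_total_intensity,
    replace_negatives,
    select_representative_bins,
)
from .screening import univariable_table
from .selectors import (
    METHODS,
    ModelPerformance,
    select_variables,
    standardize,
    tune_and_evaluate,
)

__all__ = [
    "StabilityReport",
    "bootstrap_stability",
    "observed_stability",
    "baseline_thresholds",
    "flag_informative",
    "run_full_analysis",
    "null_stability_calibration",
    "AnalysisResult",
    "SubsetAnalysis",
]


@dataclass
class StabilityReport:
    """Per-variable stabilities, thresholds and informative flags for one subset."""

    variables: tuple[str, ...]
    stability_plsda: np.ndarray
    stability_lasso: np.ndarray
    stability_boruta: np.ndarray
    observed: np.ndarray  # mean of the three, percent
    T99: float
    T100: float
    provenance: dict = field(default_factory=dict)

    @property
    def above_T99(self) -> np.ndarray:
        return self.observed > self.T99

    @property
    def above_T100(self) -> np.ndarray:
        return self.observed > self.T100

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variables,
                "stability_plsda": self.stability_plsda,
                "stability_lasso": self.stability_lasso,
                "stability_boruta": self.stability_boruta,
                "observed_stability": self.observed,
                "T99": self.T99,
                "T100": self.T100,
                "above_T99": self.above_T99,
                "above_T100": self.above_T100,
            }
        )


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Size-n resample with replacement, drawn within each class."""
    idx = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


def _frozen_params(method, X, y, config, rng) -> dict:
    perf, _ = tune_and_evaluate(method, X, y, seed=rng, config=config)
    return perf.tuned_hyperparameters


def bootstrap_stability(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    B: int = 200,
    seed: int | np.random.Generator = 0,
    config: AnalysisConfig | None = None,
    params: dict | None = None,
) -> np.ndarray:
    """Percent of B stratified bootstrap resamples in which each variable is selected.

    When ``config.tune_within_resample`` is true the method's hyperparameters
    are re-tuned inside every resample, so stability reflects the complete
    selection procedure; otherwise ``params`` (or a single tune on the full
    data) is frozen and reused, the reduced-cost variant.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or AnalysisConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("need both classes present")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    tune_each = config.tune_within_resample
    if not tune_each and params is None:
        # Boruta's selection has no tunable hyperparameter (its forest uses
        # sqrt-mtry internally), so freezing requires no tune for it
        params = {} if method == "boruta" else _frozen_params(method, X, y, config, rng)
    counts = np.zeros(X.shape[1], dtype=int)
    for _ in range(B):
        idx = _stratified_bootstrap(y, rng)
        Xb, yb = X[idx], y[idx]
        if tune_each:
            _, sel = tune_and_evaluate(method, Xb, yb, seed=rng, config=config)
            mask = sel.selected_mask(X.shape[1])
        else:
            mask = select_variables(method, standardize(Xb), yb, params, config, rng)
        counts += mask
    return 100.0 * counts / B


def observed_stability(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 200,
    seed: int | np.random.Generator = 0,
    config: AnalysisConfig | None = None,
    params_by_method: Mapping[str, dict] | None = None,
) -> dict[str, np.ndarray]:
    """Per-method stabilities plus their arithmetic mean ('observed')."""
    config = config or AnalysisConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for method in METHODS:
        params = None if params_by_method is None else params_by_method.get(method)
        out[method] = bootstrap_stability(
            X, y, method, B=B, seed=rng, config=config, params=params
        )
    out["observed"] = np.mean([out[m] for m in METHODS], axis=0)
    return out


def baseline_thresholds(
    X: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 10,
    B: int = 20,
    seed: int | np.random.Generator = 0,
    config: AnalysisConfig | None = None,
    params_by_method: Mapping[str, dict] | None = None,
) -> tuple[float, float, np.ndarray]:
    """T99/T100 thresholds from label-permuted baseline stabilities.

    For each of ``n_permutations`` uniform label shuffles (class sizes
    preserved) the observed-stability computation is repeated with ``B``
    resamples; the per-permutation 99th percentile (linear interpolation) and
    maximum of the per-variable baseline stabilities are averaged over
    permutations.  Returns (T99, T100, permutations x variables baselines).

    Unless ``params_by_method`` pins them explicitly, frozen-mode
    hyperparameters are re-tuned on each permuted dataset, mirroring what the
    observed-stability computation does on the unpermuted labels — the
    permuted replicates run the identical procedure, which is what makes
    observed and baseline stabilities exchangeable under the null.
    """
    if n_permutations < 2:
        raise ValueError("n_permutations must be >= 2")
    config = config or AnalysisConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q99s, q100s, baselines = [], [], []
    for _ in range(n_permutations):
        y_perm = rng.permutation(np.asarray(y))
        stabs = observed_stability(
            X, y_perm, B=B, seed=rng, config=config, params_by_method=params_by_method
        )["observed"]
        baselines.append(stabs)
        q99s.append(float(np.percentile(stabs, 99)))
        q100s.append(float(stabs.max()))
    return float(np.mean(q99s)), float(np.mean(q100s)), np.array(baselines)


def flag_informative(report: StabilityReport) -> tuple[list[str], list[str]]:
    """Variables whose observed stability strictly exceeds T99 / T100."""
    above99 = [v for v, f in zip(report.variables, report.above_T99) if f]
    above100 = [v for v, f in zip(report.variables, report.above_T100) if f]
    return above99, above100


# ---------------------------------------------------------------------------
# full-pipeline orchestration


@dataclass
class SubsetAnalysis:
    members: SubsetMembers
    performances: dict[str, ModelPerformance] | None
    combined_balanced_accuracy: float | None
    univariable: pd.DataFrame | None
    report: StabilityReport | None


@dataclass
class AnalysisResult:
    subsets: list[SubsetAnalysis]
    selected_bins: list[str]
    manifest: dict

    def performance_table(self) -> pd.DataFrame:
        """Per-subset balanced accuracies with the 3-method mean ('combined')."""
        rows = []
        for sa in self.subsets:
            spec = sa.members.spec
            row = {
                "time_point": spec.time_point,
                "parity": spec.parity,
                "outcome": spec.outcome,
                "n_cases": len(sa.members.cases),
                "n_controls": len(sa.members.controls),
                "usable": sa.members.usable,
            }
            if sa.performances is not None:
                for m in METHODS:
                    row[f"ba_{m}"] = sa.performances[m].balanced_accuracy
                row["ba_combined"] = sa.combined_balanced_accuracy
            rows.append(row)
        return pd.DataFrame(rows)

    def stability_table(self, threshold: str = "T99") -> pd.DataFrame:
        """Variables above the chosen threshold across subsets, with log2FC."""
        rows = []
        for sa in self.subsets:
            if sa.report is None:
                continue
            uni = sa.univariable.set_index("bin_id")
            mask = sa.report.above_T99 if threshold == "T99" else sa.report.above_T100
            for v, above in zip(sa.report.variables, mask):
                if not above:
                    continue
                rows.append(
                    {
                        "subset": sa.members.spec.name,
                        "variable": v,
                        "log2fc": float(uni.loc[v, "log2fc"]),
                        "observed_stability": float(
                            sa.report.observed[sa.report.variables.index(v)]
                        ),
                        "T99": sa.report.T99,
                        "T100": sa.report.T100,
                        "above_T100": bool(
                            sa.report.above_T100[sa.report.variables.index(v)]
                        ),
                    }
                )
        cols = [
            "subset", "variable", "log2fc", "observed_stability", "T99", "T100", "above_T100",
        ]
        return pd.DataFrame(rows, columns=cols)


def analyze_subset(
    X: pd.DataFrame,
    y: np.ndarray,
    config: AnalysisConfig,
    seed: int | np.random.Generator,
) -> tuple[dict[str, ModelPerformance], float, pd.DataFrame, StabilityReport]:
    """Run tuning, univariable screening and the stability procedure on one subset."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    performances: dict[str, ModelPerformance] = {}
    frozen: dict[str, dict] = {}
    for method in METHODS:
        perf, _ = tune_and_evaluate(method, Xv, y, seed=rng, config=config)
        performances[method] = perf
        frozen[method] = perf.tuned_hyperparameters
    combined = float(np.mean([performances[m].balanced_accuracy for m in METHODS]))
    uni = univariable_table(X, y)
    params_by_method = None if config.tune_within_resample else frozen
    stabs = observed_stability(
        Xv, y, B=config.B_observed, seed=rng, config=config,
        params_by_method=params_by_method,
    )
    # permutations re-tune on their own labels (params_by_method=None)
    t99, t100, _ = baseline_thresholds(
        Xv, y, n_permutations=config.n_permutations, B=config.B_baseline,
        seed=rng, config=config,
    )
    report = StabilityReport(
        variables=tuple(X.columns),
        stability_plsda=stabs["plsda"],
        stability_lasso=stabs["lasso"],
        stability_boruta=stabs["boruta"],
        observed=stabs["observed"],
        T99=t99,
        T100=t100,
        provenance={
            "B_observed": config.B_observed,
            "n_permutations": config.n_permutations,
            "B_baseline": config.B_baseline,
            "tune_within_resample": config.tune_within_resample,
        },
    )
    return performances, combined, uni, report


def run_full_analysis(
    matrix: IntensityMatrix,
    catalog: BinCatalog,
    records: Sequence[AnimalRecord],
    config: AnalysisConfig | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Preprocess, build the 17 subsets, and analyze each usable one.

    Pipeline: negative replacement, total-intensity normalization and
    representative-bin selection on the full matrix; outcome classification
    and parity-stratified random control matching; then per subset the
    three-method tuning (Table-4-style performance), univariable statistics,
    and the bootstrap/permutation stability report (Table-5-style listing).
    Unusable subsets (fewer than 2 animals in a class) are carried through
    flagged, not dropped.
    """
    config = config or AnalysisConfig()
    master = np.random.SeedSequence(seed)
    match_seed, analysis_seed = master.spawn(2)

    m = normalize_total_intensity(replace_negatives(matrix))
    selected = select_representative_bins(m, catalog, r_threshold=config.r_threshold)

    labels = {r.animal_id: classify_outcome(r) for r in records}
    cases = [a for a, lab in labels.items() if lab in ("new_SH", "new_SU", "chronic_SU")]
    eligible = [a for a, lab in labels.items() if lab == "control"]
    parity_of = {r.animal_id: r.parity_cohort for r in records}
    matched = set(
        match_controls(
            cases, eligible, parity_of,
            seed=int(match_seed.generate_state(1)[0] % 2**31),
            allow_shortfall=True,
        )
    )
    study = [r for r in records if r.animal_id in matched or labels[r.animal_id] not in ("control",)]
    subsets = build_subsets(study, labels={a: labels[a] for a in (r.animal_id for r in study)})

    rng = np.random.default_rng(analysis_seed)
    out: list[SubsetAnalysis] = []
    for sm in subsets:
        if not sm.usable:
            out.append(SubsetAnalysis(sm, None, None, None, None))
            continue
        sample_ids = sm.sample_ids()
        X = m.data.loc[sample_ids, selected]
        y = sm.labels()
        performances, combined, uni, report = analyze_subset(X, y, config, rng)
        out.append(SubsetAnalysis(sm, performances, combined, uni, report))

    manifest = {
        "seed": seed,
        "n_animals": len(records),
        "n_samples": len(matrix.sample_ids),
        "n_bins": len(matrix.bin_ids),
        "n_selected_bins": len(selected),
        "n_cases": len(cases),
        "n_matched_controls": len(matched),
        "config": config.__dict__.copy(),
    }
    return AnalysisResult(subsets=out, selected_bins=selected, manifest=manifest)


def null_stability_calibration(
    n_datasets: int,
    n: int = 100,
    p: int = 85,
    seed: int = 0,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Observed-vs-baseline calibration on replicate null datasets.

    Each replicate draws a dataset whose labels are independent of every
    variable, computes per-variable observed stabilities and the T99/T100
    thresholds with the full procedure, and records the fraction of variables
    strictly above each threshold.  Under the null those fractions should
    average about 1% (T99) and about 0% (T100).
    """
    from .simulate import make_null_dataset

    config = config or AnalysisConfig.reduced()
    children = np.random.SeedSequence(seed).spawn(n_datasets)
    rows = []
    for i, child in enumerate(children):
        data_seed = int(child.generate_state(1)[0] % 2**31)
        m, y = make_null_dataset(n, p, seed=data_seed)
        X = m.values()
        rng = np.random.default_rng(child)
        stabs = observed_stability(
            X, y, B=config.B_observed, seed=rng, config=config
        )["observed"]
        t99, t100, _ = baseline_thresholds(
            X, y, n_permutations=config.n_permutations, B=config.B_baseline,
            seed=rng, config=config,
        )
        rows.append(
            {
                "replicate": i,
                "frac_above_T99": float(np.mean(stabs > t99)),
                "n_above_T100": int(np.sum(stabs > t100)),
                "T99": t99,
                "T100": t100,
                "max_observed": float(stabs.max()),
            }
        )
    return pd.DataFrame(rows)
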