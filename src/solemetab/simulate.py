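"""Synthetic cohort and binned-spectrum generator.

The generator emulates the statistical structure the downstream analysis
assumes, starting at binned integrals (no free-induction decays or peak
shapes):

* animals belong to parity cohorts and draw a most-severe sole-lesion grade
  per time point from per-parity, per-time-point prevalence tables
  (defaults follow the frequencies observed in a ~737-cow Holstein herd);
* latent metabolite concentrations are log-normal (positive, right-skewed);
  each annotated metabolite emits one or more spectral bins sharing the
  latent concentration, with bin-level log-normal noise sized so that sibling
  bins correlate at a configured Pearson r (>= 0.9, so representative-bin
  selection is exercised);
* unlabeled bins arise from their own latent factors, grouped into clusters
  with the same correlation structure, plus a subset of weak baseline bins
  whose additive noise occasionally drives integrals negative;
* case effects are injected multiplicatively on the latent concentration of
  designated metabolites in animals whose lesion outcome matches the effect's
  context, so a log2 fold-change of group means is well defined before
  normalization;
* hemolysis grades are drawn per sample; an optional additive shift models
  hemolysis contamination of a bin subset (off by default).

A fixed seed makes the output bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    GRADES,
    PARITIES,
    SAMPLED_TIME_POINTS,
    TIME_POINTS,
    AnimalRecord,
    classify_outcome,
)
from .preprocess import BinCatalog, IntensityMatrix

__all__ = [
    "InformativeEffect",
    "SimulationConfig",
    "TABLE1_PREVALENCES",
    "simulate_cohort",
    "make_null_dataset",
]

# Most-severe-lesion prevalences per parity cohort and time point, as observed
# frequencies in the source herd (denominators 249 / 245 / 243 animals).
_TABLE1_COUNTS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "first": {
        "T1": (184, 59, 5, 1),
        "T2": (185, 51, 12, 1),
        "T3": (92, 80, 65, 12),
        "T4": (152, 83, 11, 3),
    },
    "second": {
        "T1": (221, 22, 1, 1),
        "T2": (214, 27, 4, 0),
        "T3": (151, 71, 21, 2),
        "T4": (149, 77, 13, 6),
    },
    "third_plus": {
        "T1": (153, 57, 15, 18),
        "T2": (167, 58, 7, 11),
        "T3": (91, 79, 46, 27),
        "T4": (100, 84, 34, 25),
    },
}

TABLE1_PREVALENCES: dict[str, dict[str, dict[str, float]]] = {
    parity: {
        tp: {g: c / sum(counts) for g, c in zip(GRADES, counts)}
        for tp, counts in by_tp.items()
    }
    for parity, by_tp in _TABLE1_COUNTS.items()
}

#: provisional annotations typical of a bovine serum 1H-NMR profile
METABOLITE_NAMES = (
    "alanine", "citrate", "phenylalanine", "valine", "formate", "proline",
    "propylene_glycol", "glucose", "lactate", "acetate", "glycine", "leucine",
    "isoleucine", "lysine", "glutamine", "glutamate", "tyrosine", "histidine",
    "creatinine", "creatine", "3-hydroxybutyrate", "acetoacetate", "acetone",
    "betaine", "choline", "glycerol", "urea", "pyruvate", "succinate",
    "methionine", "threonine", "serine", "dimethylglycine", "mannose",
)

_CASE_LABELS_DEFAULT = ("new_SH", "new_SU", "chronic_SU")


@dataclass(frozen=True)
class InformativeEffect:
    """A planted case/control difference on one metabolite.

    ``log2fc`` is the log2 ratio of case to control latent-concentration
    means; the multiplier 2**log2fc is applied to the latent concentration of
    case animals.  ``time_point`` restricts the effect to one sampled time
    point (None = all); ``case_labels`` restricts which outcome labels count
    as cases for this effect.
    """

    metabolite: str
    log2fc: float
    time_point: str | None = None
    case_labels: tuple[str, ...] = _CASE_LABELS_DEFAULT


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort."""

    n_animals: int = 400
    parity_mix: Mapping[str, float] = field(
        default_factory=lambda: {"first": 0.34, "second": 0.33, "third_plus": 0.33}
    )
    outcome_prevalences: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: TABLE1_PREVALENCES
    )
    n_metabolites: int = 34
    #: pool sampled uniformly for the number of bins each metabolite emits
    bins_per_metabolite: tuple[int, ...] = (1, 1, 2, 3, 4, 5, 6, 6)
    n_unlabeled_noise_bins: int = 93
    n_unlabeled_clusters: int = 51
    within_metabolite_correlation: float = 0.95
    informative_set: tuple[InformativeEffect, ...] = ()
    hemolysis_probs: tuple[float, ...] = (0.68, 0.22, 0.07, 0.02, 0.01)
    #: optional (fraction of bins shifted, additive shift per hemolysis grade)
    hemolysis_effect: tuple[float, float] | None = None
    noise_sd: float = 0.05
    latent_log_sd: float = 0.35
    #: fraction of unlabeled bins that are weak baseline signals with additive noise
    weak_bin_fraction: float = 0.15
    toe_ulcer_prob: float = 0.007
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        _check_probs("parity_mix", self.parity_mix.values())
        for parity, by_tp in self.outcome_prevalences.items():
            for tp, probs in by_tp.items():
                _check_probs(f"outcome_prevalences[{parity}][{tp}]", probs.values())
        _check_probs("hemolysis_probs", self.hemolysis_probs)
        if not (0.9 <= self.within_metabolite_correlation <= 1.0):
            raise ValueError(
                "within_metabolite_correlation must lie in [0.9, 1]; got "
                f"{self.within_metabolite_correlation}"
            )
        for eff in self.informative_set:
            if not np.isfinite(eff.log2fc):
                raise ValueError(f"non-finite log2fc for {eff.metabolite!r}")


def _check_probs(name: str, probs) -> None:
    p = np.asarray(list(probs), dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} is not a probability vector (sum {p.sum()!r})")


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[AnimalRecord], IntensityMatrix, BinCatalog]:
    """Draw a cohort of animals with lesion outcomes and raw binned spectra.

    Returns one intensity row per animal per sampled time point (T1-T3), a
    bin catalog with metabolite annotations, and the animal records.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    records = _draw_animals(config, rng)
    catalog, owner, amplitude, weak = _draw_catalog(config, rng)
    labels = {r.animal_id: classify_outcome(r) for r in records}

    sample_ids = [
        f"{r.animal_id}:{tp}" for r in records for tp in SAMPLED_TIME_POINTS
    ]
    sample_animal = [r for r in records for _ in SAMPLED_TIME_POINTS]
    sample_tp = [tp for _ in records for tp in SAMPLED_TIME_POINTS]
    n_samples = len(sample_ids)

    # latent log-concentrations: one factor per labeled metabolite and per
    # unlabeled cluster, shared by that factor's bins
    factors = sorted({f for f, _ in owner.values()})
    factor_idx = {f: i for i, f in enumerate(factors)}
    base = rng.normal(0.0, 0.5, size=len(factors))  # per-factor typical log level
    latent = base[None, :] + rng.normal(
        0.0, config.latent_log_sd, size=(n_samples, len(factors))
    )

    # inject multiplicative case effects on the latent scale
    for eff in config.informative_set:
        fname = f"met:{eff.metabolite}"
        if fname not in factor_idx:
            raise ValueError(f"informative metabolite {eff.metabolite!r} not simulated")
        col = factor_idx[fname]
        shift = eff.log2fc * np.log(2.0)
        for i in range(n_samples):
            if eff.time_point is not None and sample_tp[i] != eff.time_point:
                continue
            if labels[sample_animal[i].animal_id] in eff.case_labels:
                latent[i, col] += shift

    # bin emission: log v = log amplitude + latent + bin-level noise, with the
    # noise variance set so sibling bins correlate at the configured r
    rho = config.within_metabolite_correlation
    sigma2 = config.latent_log_sd**2
    tau = 0.0 if rho >= 1.0 else np.sqrt(sigma2 * (1.0 - rho) / rho)
    bin_ids = catalog.bin_ids
    values = np.empty((n_samples, len(bin_ids)))
    for j, b in enumerate(bin_ids):
        fname, _ = owner[b]
        col = factor_idx[fname]
        logv = np.log(amplitude[b]) + latent[:, col]
        if tau > 0:
            logv = logv + rng.normal(0.0, tau, size=n_samples)
        values[:, j] = np.exp(logv)

    # weak baseline bins: additive noise at the scale of the bin itself, so a
    # fraction of integrals go negative (as real baseline noise does)
    for j, b in enumerate(bin_ids):
        if weak[b]:
            scale = config.noise_sd * float(np.median(values[:, j]))
            values[:, j] += rng.normal(0.0, max(scale, 1e-12) * 12.0, size=n_samples)

    if config.hemolysis_effect is not None:
        frac, shift_per_grade = config.hemolysis_effect
        n_shift = max(1, int(round(frac * len(bin_ids))))
        shifted = rng.choice(len(bin_ids), size=n_shift, replace=False)
        grades = np.array(
            [sample_animal[i].hemolysis[sample_tp[i]] for i in range(n_samples)]
        )
        values[:, shifted] += np.outer(grades, np.full(n_shift, shift_per_grade))

    matrix = IntensityMatrix(
        pd.DataFrame(values, index=sample_ids, columns=bin_ids), state="raw"
    )
    return records, matrix, catalog


def _draw_animals(config: SimulationConfig, rng: np.random.Generator) -> list[AnimalRecord]:
    parities = rng.choice(
        PARITIES,
        size=config.n_animals,
        p=[config.parity_mix[p] for p in PARITIES],
    )
    records = []
    for i in range(config.n_animals):
        parity = str(parities[i])
        by_tp = config.outcome_prevalences[parity]
        lesion = {
            tp: str(rng.choice(GRADES, p=[by_tp[tp][g] for g in GRADES]))
            for tp in TIME_POINTS
        }
        hemolysis = {
            tp: int(rng.choice(len(config.hemolysis_probs), p=config.hemolysis_probs))
            for tp in SAMPLED_TIME_POINTS
        }
        records.append(
            AnimalRecord(
                animal_id=f"cow{i:05d}",
                parity_cohort=parity,
                lesion=lesion,
                toe_ulcer=bool(rng.random() < config.toe_ulcer_prob),
                hemolysis=hemolysis,
                covariates={
                    "bcs": float(np.round(rng.uniform(2.5, 4.5) * 4) / 4),
                    "milk_yield": float(
                        np.round(rng.normal(45.0 if parity != "first" else 37.0, 5.0), 1)
                    ),
                },
            )
        )
    return records


def _draw_catalog(config: SimulationConfig, rng: np.random.Generator):
    """Lay out labeled and unlabeled bins on the ppm axis.

    Returns the catalog plus per-bin metadata: ``owner`` maps bin_id to its
    latent factor, ``amplitude`` is the bin's multiplicative peak amplitude,
    ``weak`` flags low-intensity baseline bins that receive additive noise.
    """
    names = list(METABOLITE_NAMES[: config.n_metabolites])
    if config.n_metabolites > len(METABOLITE_NAMES):
        names += [f"metab_{k}" for k in range(len(METABOLITE_NAMES), config.n_metabolites)]

    entries: list[tuple[str | None, str]] = []  # (label, factor name)
    for name in names:
        k = int(rng.choice(config.bins_per_metabolite))
        entries.extend((name, f"met:{name}") for _ in range(k))

    n_unl = config.n_unlabeled_noise_bins
    n_clusters = min(config.n_unlabeled_clusters, n_unl)
    if n_unl > 0:
        sizes = np.ones(n_clusters, dtype=int)
        for _ in range(n_unl - n_clusters):
            sizes[rng.integers(n_clusters)] += 1
        for c, size in enumerate(sizes):
            entries.extend((None, f"unl:{c}") for _ in range(size))

    # scatter bins over the ppm axis in random order, non-overlapping
    order = rng.permutation(len(entries))
    width = 0.02
    gaps = rng.uniform(0.005, 0.03, size=len(entries))
    starts = 0.8 + np.concatenate(([0.0], np.cumsum(width + gaps[:-1])))
    rows = []
    owner: dict[str, tuple[str, None]] = {}
    amplitude: dict[str, float] = {}
    weak: dict[str, bool] = {}
    for pos, entry_i in enumerate(order):
        label, fname = entries[entry_i]
        bin_id = f"bin{pos:03d}"
        rows.append(
            {
                "bin_id": bin_id,
                "ppm_low": round(float(starts[pos]), 4),
                "ppm_high": round(float(starts[pos] + width), 4),
                "label": label if label is not None else "",
            }
        )
        owner[bin_id] = (fname, None)
        is_weak = label is None and rng.random() < config.weak_bin_fraction
        weak[bin_id] = is_weak
        amplitude[bin_id] = float(
            rng.lognormal(mean=np.log(0.02) if is_weak else np.log(1.0), sigma=0.4)
        )
    catalog = BinCatalog(pd.DataFrame(rows))
    return catalog, owner, amplitude, weak


def make_null_dataset(
    n: int, p: int, seed: int
) -> tuple[IntensityMatrix, np.ndarray]:
    """Positive intensity matrix with a balanced binary label independent of it.

    Every variable is drawn i.i.d. log-normal regardless of the label, so any
    apparent variable-label association is chance.  Used to calibrate the
    permutation-threshold machinery.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    if p < 2:
        raise ValueError("p must be >= 2")
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=0.0, sigma=0.4, size=(n, p))
    y = np.zeros(n, dtype=int)
    y[n // 2 :] = 1
    m = IntensityMatrix(
        pd.DataFrame(
            values,
            index=[f"s{i:04d}" for i in range(n)],
            columns=[f"v{j:03d}" for j in range(p)],
        ),
        state="raw",
    )
    return m, y
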