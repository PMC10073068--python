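"""Case-control classification of animals and assembly of the 17 analysis subsets.

Animals are assessed at four time points — T1 precalving, T2 calving, T3 early
lactation, T4 late lactation — and per time point carry their most severe sole
lesion grade: ``none``, ``mild_SH`` (mild sole hemorrhage), ``severe_SH``, or
``SU`` (sole ulcer).  Serum is sampled at T1-T3.  Outcomes are defined from the
lesion history:

* ``new_SH``     — severe SH at T3, no severe SH/SU at T1 or T2;
* ``new_SU``     — SU at T3, no severe SH/SU at T1 or T2;
* ``chronic_SU`` — SU at T3 and SU already at T1 or T2;
* ``control``    — no lesion of any grade at T3 and no severe SH/SU at T1, T2 or T4;
* ``excluded``   — second-parity animals, toe-ulcer cases, samples with
  hemolysis grade 3-4, and lesion histories satisfying neither a case nor the
  control definition (e.g. mild SH only at T3).

Analysis proceeds in 17 prespecified subsets crossing time point, parity cohort
and outcome definition; T1 is analyzed in the first-parity cohort only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnimalRecord",
    "SubsetSpec",
    "SubsetMembers",
    "TIME_POINTS",
    "SAMPLED_TIME_POINTS",
    "PARITIES",
    "GRADES",
    "OUTCOMES",
    "SUBSET_SPECS",
    "classify_outcome",
    "build_subsets",
    "match_controls",
    "records_to_frame",
    "frame_to_records",
]

TIME_POINTS = ("T1", "T2", "T3", "T4")
SAMPLED_TIME_POINTS = ("T1", "T2", "T3")
PARITIES = ("first", "second", "third_plus")
GRADES = ("none", "mild_SH", "severe_SH", "SU")
OUTCOMES = ("new_SH", "new_SU", "chronic_SU", "control", "excluded")

#: lesion grades that make an animal "affected with severe SH or SU"
_SEVERE = frozenset({"severe_SH", "SU"})


@dataclass(frozen=True)
class AnimalRecord:
    """Longitudinal lesion history and sample attributes for one animal."""

    animal_id: str
    parity_cohort: str
    lesion: Mapping[str, str]  # time point -> most severe grade
    toe_ulcer: bool = False
    hemolysis: Mapping[str, int] = field(default_factory=dict)  # sampled tp -> 0-4
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parity_cohort not in PARITIES:
            raise ValueError(f"unknown parity cohort {self.parity_cohort!r}")
        for tp, grade in self.lesion.items():
            if grade not in GRADES:
                raise ValueError(f"unknown lesion grade {grade!r} at {tp}")
        for tp, h in self.hemolysis.items():
            if h not in (0, 1, 2, 3, 4):
                raise ValueError(f"hemolysis grade {h!r} at {tp} outside 0-4")


def classify_outcome(a: AnimalRecord) -> str:
    """Assign exactly one outcome label to an animal.

    Precedence: exclusion on study criteria (second parity, toe ulcer,
    hemolysis grade >= 3 at any sampled time point), then chronic_SU, new_SU,
    new_SH, control; histories failing every definition are excluded.
    """
    missing = [tp for tp in TIME_POINTS if tp not in a.lesion]
    if missing:
        raise ValueError(f"animal {a.animal_id!r} missing lesion record at {missing}")
    if a.parity_cohort == "second" or a.toe_ulcer:
        return "excluded"
    if any(h >= 3 for h in a.hemolysis.values()):
        return "excluded"
    t1, t2, t3, t4 = (a.lesion[tp] for tp in TIME_POINTS)
    clean_before = t1 not in _SEVERE and t2 not in _SEVERE
    if t3 == "SU" and ("SU" in (t1, t2)):
        return "chronic_SU"
    if t3 == "SU" and clean_before:
        return "new_SU"
    if t3 == "severe_SH" and clean_before:
        return "new_SH"
    if t3 == "none" and clean_before and t4 not in _SEVERE:
        return "control"
    return "excluded"


@dataclass(frozen=True)
class SubsetSpec:
    """One prespecified (time point x parity x outcome) comparison."""

    time_point: str  # T1 | T2 | T3
    parity: str  # first | third_plus | all
    outcome: str  # new_SH | new_SU | new_SH_SU | all_SU

    @property
    def name(self) -> str:
        return f"{self.time_point}_{self.parity}_{self.outcome}"


def _enumerate_subsets() -> tuple[SubsetSpec, ...]:
    specs: list[SubsetSpec] = []
    for tp in ("T1", "T2", "T3"):
        for oc in ("new_SH", "new_SU"):
            specs.append(SubsetSpec(tp, "first", oc))
    for tp in ("T2", "T3"):
        for oc in ("new_SH", "new_SU"):
            specs.append(SubsetSpec(tp, "third_plus", oc))
    for oc in ("new_SH", "new_SU", "new_SH_SU"):
        specs.append(SubsetSpec("T2", "all", oc))
    for oc in ("new_SH", "new_SU", "new_SH_SU", "all_SU"):
        specs.append(SubsetSpec("T3", "all", oc))
    return tuple(specs)


#: the 17-element enumeration; T1 exists in the first-parity cohort only
SUBSET_SPECS: tuple[SubsetSpec, ...] = _enumerate_subsets()

_CASE_LABELS = {
    "new_SH": ("new_SH",),
    "new_SU": ("new_SU",),
    "new_SH_SU": ("new_SH", "new_SU"),
    "all_SU": ("new_SU", "chronic_SU"),
}


@dataclass(frozen=True)
class SubsetMembers:
    spec: SubsetSpec
    cases: tuple[str, ...]
    controls: tuple[str, ...]
    usable: bool

    def sample_ids(self) -> list[str]:
        return [f"{a}:{self.spec.time_point}" for a in self.cases + self.controls]

    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.cases) + [0] * len(self.controls))


def build_subsets(
    records: Sequence[AnimalRecord],
    labels: Mapping[str, str] | None = None,
) -> list[SubsetMembers]:
    """Assemble the 17 prespecified case-control subsets.

    ``labels`` may carry precomputed outcome labels (e.g. after control
    matching restricted the cohort); otherwise each record is classified here.
    Subsets with fewer than two animals in either class are flagged unusable
    rather than dropped, so the 17-element structure is always emitted.
    """
    if labels is None:
        labels = {r.animal_id: classify_outcome(r) for r in records}
    parity = {r.animal_id: r.parity_cohort for r in records}
    out: list[SubsetMembers] = []
    for spec in SUBSET_SPECS:
        def in_parity(a: str) -> bool:
            return spec.parity == "all" or parity[a] == spec.parity

        case_labels = _CASE_LABELS[spec.outcome]
        cases = tuple(
            r.animal_id
            for r in records
            if labels[r.animal_id] in case_labels and in_parity(r.animal_id)
        )
        controls = tuple(
            r.animal_id
            for r in records
            if labels[r.animal_id] == "control" and in_parity(r.animal_id)
        )
        usable = len(cases) >= 2 and len(controls) >= 2
        out.append(SubsetMembers(spec, cases, controls, usable))
    return out


def match_controls(
    cases: Sequence[str],
    eligible_controls: Sequence[str],
    parity_of: Mapping[str, str],
    seed: int,
    allow_shortfall: bool = False,
) -> list[str]:
    """Randomly select as many controls as cases within each parity cohort.

    Sampling is uniform without replacement and seeded; the eligible pool is
    sorted before sampling so the result does not depend on input ordering.
    A cohort with fewer eligible controls than cases raises, unless
    ``allow_shortfall`` is set, in which case the whole pool is taken and a
    warning issued.
    """
    import warnings

    rng = np.random.default_rng(seed)
    selected: list[str] = []
    cohorts = sorted({parity_of[c] for c in cases})
    for cohort in cohorts:
        n_cases = sum(parity_of[c] == cohort for c in cases)
        pool = sorted(e for e in eligible_controls if parity_of[e] == cohort)
        if len(pool) < n_cases:
            if not allow_shortfall:
                raise ValueError(
                    f"parity cohort {cohort!r}: {n_cases} cases but only "
                    f"{len(pool)} eligible controls (shortfall {n_cases - len(pool)})"
                )
            warnings.warn(
                f"parity cohort {cohort!r}: control shortfall "
                f"({len(pool)} eligible for {n_cases} cases); using all",
                stacklevel=2,
            )
            selected.extend(pool)
            continue
        selected.extend(rng.choice(pool, size=n_cases, replace=False))
    return selected


# ---------------------------------------------------------------------------
# delimited-text round trip for animal metadata


def records_to_frame(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "animal_id": r.animal_id,
            "parity_cohort": r.parity_cohort,
            "toe_ulcer": int(r.toe_ulcer),
        }
        for tp in TIME_POINTS:
            row[f"lesion_{tp}"] = r.lesion.get(tp, "")
        for tp in SAMPLED_TIME_POINTS:
            row[f"hemolysis_{tp}"] = r.hemolysis.get(tp, "")
        for k, v in r.covariates.items():
            row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[AnimalRecord]:
    base = {"animal_id", "parity_cohort", "toe_ulcer"}
    lesion_cols = {f"lesion_{tp}" for tp in TIME_POINTS}
    hemo_cols = {f"hemolysis_{tp}" for tp in SAMPLED_TIME_POINTS}
    cov_cols = [c for c in frame.columns if c not in base | lesion_cols | hemo_cols]
    records = []
    for _, row in frame.iterrows():
        lesion = {
            tp: str(row[f"lesion_{tp}"])
            for tp in TIME_POINTS
            if f"lesion_{tp}" in frame.columns and str(row[f"lesion_{tp}"]) != ""
        }
        hemolysis = {
            tp: int(row[f"hemolysis_{tp}"])
            for tp in SAMPLED_TIME_POINTS
            if f"hemolysis_{tp}" in frame.columns and str(row[f"hemolysis_{tp}"]) != ""
        }
        covariates = {c: row[c] for c in cov_cols if pd.notna(row[c])}
        records.append(
            AnimalRecord(
                animal_id=str(row["animal_id"]),
                parity_cohort=str(row["parity_cohort"]),
                lesion=lesion,
                toe_ulcer=bool(int(row["toe_ulcer"])),
                hemolysis=hemolysis,
                covariates=covariates,
            )
        )
    return records
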