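"""Spectral preprocessing for binned 1H-NMR intensity tables.

The analysis-ready variable set is produced by a fixed pipeline:

    replace_negatives -> normalize_total_intensity -> select_representative_bins -> autoscale

Each step checks the processing ``state`` of its input so the pipeline cannot
be run out of order.  Bin integrals are relative intensities (dimensionless);
normalization divides each sample (row) by its total spectral intensity, so a
normalized row sums to one.  Representative-bin selection reduces redundant
bins — multiple bins of one annotated metabolite, or clusters of mutually
correlated unlabeled bins — to a single variable each, mirroring the reduction
of a full bin table to a compact, weakly correlated variable set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "BinCatalog",
    "IntensityMatrix",
    "PipelineStateError",
    "replace_negatives",
    "normalize_total_intensity",
    "select_representative_bins",
    "autoscale",
]

#: allowed processing states, in pipeline order
STATES = ("raw", "nonneg", "normalized", "autoscaled")


class PipelineStateError(ValueError):
    """Raised when an operation receives a matrix in the wrong processing state."""


@dataclass(frozen=True)
class BinCatalog:
    """Ordered catalog of spectral bins.

    ``table`` has columns ``bin_id`` (unique), ``ppm_low``, ``ppm_high``
    (chemical-shift boundaries, ppm) and ``label`` (metabolite annotation, or
    missing/empty for unlabeled bins).  Bins must be non-overlapping on the
    ppm axis.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"bin_id", "ppm_low", "ppm_high", "label"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        if t["bin_id"].duplicated().any():
            dup = t.loc[t["bin_id"].duplicated(), "bin_id"].iloc[0]
            raise ValueError(f"duplicate bin_id {dup!r}")
        if not (t["ppm_low"] < t["ppm_high"]).all():
            bad = t.loc[~(t["ppm_low"] < t["ppm_high"]), "bin_id"].iloc[0]
            raise ValueError(f"bin {bad!r} has ppm_low >= ppm_high")
        s = t.sort_values("ppm_low")
        overlap = s["ppm_low"].to_numpy()[1:] < s["ppm_high"].to_numpy()[:-1]
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0])
            raise ValueError(
                f"bins {s['bin_id'].iloc[i]!r} and {s['bin_id'].iloc[i + 1]!r} overlap in ppm"
            )

    @property
    def bin_ids(self) -> list[str]:
        return list(self.table["bin_id"])

    def label_of(self, bin_id: str) -> str | None:
        row = self.table.loc[self.table["bin_id"] == bin_id]
        if row.empty:
            raise KeyError(bin_id)
        lab = row["label"].iloc[0]
        return None if _is_unlabeled(lab) else str(lab)

    def labeled_groups(self) -> dict[str, list[str]]:
        """Metabolite label -> bin ids carrying it, in catalog order."""
        groups: dict[str, list[str]] = {}
        for _, row in self.table.iterrows():
            if not _is_unlabeled(row["label"]):
                groups.setdefault(str(row["label"]), []).append(row["bin_id"])
        return groups

    def unlabeled_ids(self) -> list[str]:
        return [
            row["bin_id"]
            for _, row in self.table.iterrows()
            if _is_unlabeled(row["label"])
        ]

    def ppm_low_of(self, bin_id: str) -> float:
        row = self.table.loc[self.table["bin_id"] == bin_id]
        if row.empty:
            raise KeyError(bin_id)
        return float(row["ppm_low"].iloc[0])


def _is_unlabeled(label: object) -> bool:
    return label is None or (isinstance(label, float) and np.isnan(label)) or label == ""


@dataclass(frozen=True)
class IntensityMatrix:
    """Samples x bins relative-intensity table with a processing-state tag."""

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def bin_ids(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def require_state(self, *states: str) -> None:
        if self.state not in states:
            raise PipelineStateError(
                f"operation requires state in {states}, got {self.state!r}"
            )


def replace_negatives(m: IntensityMatrix) -> IntensityMatrix:
    """Replace non-positive bin integrals with one-fifth of the bin's minimum positive value.

    Non-positive integrals arise from baseline noise in low-intensity bins; the
    replacement keeps every value strictly positive ahead of total-intensity
    normalization.  A bin with no positive value at all is unrecoverable and
    raises.
    """
    m.require_state("raw")
    values = m.values().copy()
    for j, bin_id in enumerate(m.bin_ids):
        col = values[:, j]
        pos = col[col > 0]
        if pos.size == 0:
            raise ValueError(f"bin {bin_id!r} has no positive value")
        col[col <= 0] = pos.min() / 5.0
        values[:, j] = col
    out = pd.DataFrame(values, index=m.data.index, columns=m.data.columns)
    return IntensityMatrix(out, state="nonneg")


def normalize_total_intensity(m: IntensityMatrix) -> IntensityMatrix:
    """Divide each sample row by its total spectral intensity (row sum)."""
    m.require_state("nonneg", "normalized")
    values = m.values()
    if not (values > 0).all():
        raise ValueError("normalization requires strictly positive intensities")
    out = values / values.sum(axis=1, keepdims=True)
    return IntensityMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        state="normalized",
    )


def autoscale(m: IntensityMatrix) -> IntensityMatrix:
    """Center each bin and scale to unit sample standard deviation (ddof=1)."""
    m.require_state("normalized", "nonneg", "raw")
    values = m.values()
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"bin {m.bin_ids[int(zero[0])]!r} has zero variance")
    out = (values - mu) / sd
    return IntensityMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        state="autoscaled",
    )


@dataclass
class SelectionReport:
    """Per-bin record of the representative-bin selection."""

    table: pd.DataFrame = field(repr=False)  # bin_id, kept, reason, cluster

    def kept_ids(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "bin_id"])


def select_representative_bins(
    m: IntensityMatrix,
    cat: BinCatalog,
    r_threshold: float = 0.9,
    return_report: bool = False,
):
    """Reduce the bin table to one representative variable per metabolite / cluster.

    The reduction has four stages:

    1. for each annotated metabolite with several bins, keep the bin with the
       highest mean Pearson correlation to its sibling bins (ties broken by
       lowest ppm_low);
    2. drop unlabeled bins whose |r| with any kept labeled bin reaches
       ``r_threshold``;
    3. cluster the remaining unlabeled bins by complete-linkage hierarchical
       clustering on Euclidean distances between standardized bin profiles,
       cutting the tree at the largest number of clusters for which the
       maximum between-cluster pairwise |r| stays below ``r_threshold`` (any
       cut never separates a correlated pair, and this cut merges nothing
       else);
    4. keep one bin per cluster — the one with the highest mean within-cluster
       correlation (ties again by lowest ppm_low).

    Returns the kept bin ids in catalog order (and the per-bin report when
    ``return_report`` is true).  Correlations are computed on the normalized
    intensities; Pearson r is location/scale invariant so this matches
    correlations of the autoscaled data.
    """
    m.require_state("normalized")
    if not (0.0 < r_threshold < 1.0):
        raise ValueError(f"r_threshold must lie in (0,1), got {r_threshold}")
    present = [b for b in cat.bin_ids if b in set(m.bin_ids)]
    values = m.data[present].to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = present[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"bin {bad!r} is constant; correlation undefined")
    corr = np.corrcoef(values, rowvar=False)
    corr = np.atleast_2d(corr)
    idx = {b: i for i, b in enumerate(present)}

    rows: list[dict] = []

    # stage 1: one representative per labeled metabolite
    kept_labeled: list[str] = []
    for label, bins in cat.labeled_groups().items():
        bins = [b for b in bins if b in idx]
        if not bins:
            continue
        if len(bins) == 1:
            rep = bins[0]
        else:
            rep = _best_by_mean_corr(bins, bins, corr, idx, cat)
        kept_labeled.append(rep)
        for b in bins:
            rows.append(
                {
                    "bin_id": b,
                    "kept": b == rep,
                    "reason": f"representative of {label}"
                    if b == rep
                    else f"sibling of {label} representative",
                    "cluster": "",
                }
            )

    # stage 2: prune unlabeled bins collinear with a kept labeled bin
    unlabeled = [b for b in cat.unlabeled_ids() if b in idx]
    remaining: list[str] = []
    for b in unlabeled:
        r_to_labeled = [abs(corr[idx[b], idx[k]]) for k in kept_labeled]
        if r_to_labeled and max(r_to_labeled) >= r_threshold:
            rows.append(
                {
                    "bin_id": b,
                    "kept": False,
                    "reason": "correlated with labeled representative",
                    "cluster": "",
                }
            )
        else:
            remaining.append(b)

    # stages 3-4: cluster remaining unlabeled bins, keep one per cluster
    kept_unlabeled: list[str] = []
    if len(remaining) == 1:
        kept_unlabeled = [remaining[0]]
        rows.append(
            {"bin_id": remaining[0], "kept": True, "reason": "singleton unlabeled", "cluster": "1"}
        )
    elif len(remaining) > 1:
        sub = np.array([idx[b] for b in remaining])
        profiles = values[:, sub]
        profiles = (profiles - profiles.mean(axis=0)) / profiles.std(axis=0, ddof=1)
        z = linkage(pdist(profiles.T, metric="euclidean"), method="complete")
        subcorr = corr[np.ix_(sub, sub)]
        assignment = np.ones(len(remaining), dtype=int)
        for k in range(len(remaining), 0, -1):
            assignment = fcluster(z, t=k, criterion="maxclust")
            if _max_between_cluster_abs_r(subcorr, assignment) < r_threshold:
                break
        for c in np.unique(assignment):
            members = [remaining[i] for i in np.flatnonzero(assignment == c)]
            rep = (
                members[0]
                if len(members) == 1
                else _best_by_mean_corr(members, members, corr, idx, cat)
            )
            kept_unlabeled.append(rep)
            for b in members:
                rows.append(
                    {
                        "bin_id": b,
                        "kept": b == rep,
                        "reason": "cluster representative"
                        if b == rep
                        else "cluster member",
                        "cluster": str(int(c)),
                    }
                )

    kept = set(kept_labeled) | set(kept_unlabeled)
    selected = [b for b in cat.bin_ids if b in kept]
    if return_report:
        order = {b: i for i, b in enumerate(cat.bin_ids)}
        report = pd.DataFrame(rows).sort_values(
            "bin_id", key=lambda s: s.map(order)
        ).reset_index(drop=True)
        return selected, SelectionReport(report)
    return selected


def _best_by_mean_corr(
    candidates: list[str],
    group: list[str],
    corr: np.ndarray,
    idx: dict[str, int],
    cat: BinCatalog,
) -> str:
    """Candidate with the highest mean correlation to the other group members.

    Ties are broken by the lowest ppm_low boundary.
    """
    best: str | None = None
    best_key: tuple[float, float] | None = None
    for b in candidates:
        others = [g for g in group if g != b]
        mean_r = float(np.mean([corr[idx[b], idx[o]] for o in others]))
        key = (-mean_r, cat.ppm_low_of(b))
        if best_key is None or key < best_key:
            best, best_key = b, key
    assert best is not None
    return best


def _max_between_cluster_abs_r(corr: np.ndarray, assignment: np.ndarray) -> float:
    between = ~np.equal.outer(assignment, assignment)
    if not between.any():
        return 0.0
    return float(np.abs(corr[between]).max())
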