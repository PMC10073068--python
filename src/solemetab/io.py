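"""Delimited-text readers/writers for the pipeline's tables.

Everything is tab-separated plain text: the intensity matrix (samples x bins,
header row of bin ids, first column of sample ids), the bin catalog, animal
metadata, and the per-subset result tables.  A JSON run manifest records
inputs, configuration and seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .cohort import AnimalRecord, frame_to_records, records_to_frame
from .preprocess import BinCatalog, IntensityMatrix

__all__ = [
    "write_matrix", "read_matrix",
    "write_catalog", "read_catalog",
    "write_metadata", "read_metadata",
    "write_table", "write_manifest",
]


def write_matrix(m: IntensityMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(path: str | Path, state: str = "raw") -> IntensityMatrix:
    data = pd.read_csv(path, sep="\t", index_col="sample_id")
    return IntensityMatrix(data, state=state)


def write_catalog(cat: BinCatalog, path: str | Path) -> None:
    cat.table.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> BinCatalog:
    table = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    return BinCatalog(table)


def write_metadata(records: list[AnimalRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> list[AnimalRecord]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    return frame_to_records(frame)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
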