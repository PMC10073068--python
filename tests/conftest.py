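import numpy as np
import pandas as pd
import pytest

from solemetab.preprocess import BinCatalog, IntensityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20230401)


def make_catalog(labels: list[str | None]) -> BinCatalog:
    """Catalog with evenly spaced non-overlapping bins and the given labels."""
    rows = []
    for i, lab in enumerate(labels):
        rows.append(
            {
                "bin_id": f"b{i:02d}",
                "ppm_low": 1.0 + 0.1 * i,
                "ppm_high": 1.05 + 0.1 * i,
                "label": lab if lab is not None else "",
            }
        )
    return BinCatalog(pd.DataFrame(rows))


def make_matrix(values: np.ndarray, state: str = "normalized") -> IntensityMatrix:
    n, p = values.shape
    return IntensityMatrix(
        pd.DataFrame(
            values,
            index=[f"s{i}" for i in range(n)],
            columns=[f"b{j:02d}" for j in range(p)],
        ),
        state=state,
    )
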