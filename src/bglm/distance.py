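"""Step II: the N x K Kolmogorov-Smirnov distance matrix.

The two-sample KS statistic sup_x |F_a(x) - F_b(x)| between two empirical
CDFs is computed exactly by scanning the union of the two supports: the
difference of two right-continuous step functions is piecewise constant
and changes only at support points, so the supremum is attained there.
This works on materialized eCDFs alone, which lets a reference panel ship
as distribution summaries without raw patient values, and handles ties
across the two samples exactly (common for integer-valued analytes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ecdf import ECDF, ecdf_eval
from .exceptions import ContractViolationError


def ks_statistic(a: ECDF, b: ECDF) -> float:
    """Exact two-sample KS statistic between two empirical CDFs, in [0, 1]."""
    xs = np.union1d(a.support, b.support)
    diff = np.abs(ecdf_eval(a, xs) - ecdf_eval(b, xs))
    return float(diff.max())


@dataclass
class DistanceMatrix:
    """KS distances between N query-code and K reference-code eCDFs."""

    values: np.ndarray  # shape (N, K), entries in [0, 1]
    query_ids: list[str]
    reference_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.query_ids), len(self.reference_ids)):
            raise ContractViolationError("distance matrix shape does not match labels")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ContractViolationError("KS distances must lie in [0, 1]")

    @property
    def n_query(self) -> int:
        return len(self.query_ids)

    @property
    def n_reference(self) -> int:
        return len(self.reference_ids)

    def row(self, local_code_id: str) -> np.ndarray:
        return self.values[self.query_ids.index(local_code_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.query_ids, columns=self.reference_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="local_code_id")


def build_distance_matrix(
    query_ecdfs: Mapping[str, ECDF],
    reference_ecdfs: Mapping[str, ECDF],
) -> DistanceMatrix:
    """D[i, j] = KS statistic between query eCDF i and reference eCDF j."""
    if not query_ecdfs or not reference_ecdfs:
        raise ContractViolationError("both eCDF maps must be non-empty")
    query_ids = list(query_ecdfs)
    reference_ids = list(reference_ecdfs)
    values = np.empty((len(query_ids), len(reference_ids)))
    for i, q in enumerate(query_ids):
        for j, r in enumerate(reference_ids):
            values[i, j] = ks_statistic(query_ecdfs[q], reference_ecdfs[r])
    return DistanceMatrix(values=values, query_ids=query_ids, reference_ids=reference_ids)
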