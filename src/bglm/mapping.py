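"""Steps II-III: argmin mapping, row standardization and cutoff acceptance.

Each local code is mapped to its nearest reference LOINC code (the argmin
of its distance-matrix row). The row is then standardized to Z-scores and
the mapping is accepted only when the Z-score at the argmin falls strictly
below a cutoff: a very negative Z-score means the best match is an outlier
among the K candidates, i.e. a confident mapping. This thresholding is the
method's false-discovery control; it is deliberately not a formal FDR
estimator such as Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .exceptions import ContractViolationError, DegenerateRowError

logger = logging.getLogger(__name__)

DEFAULT_Z_CUTOFF = -5.0


@dataclass
class MappingRecord:
    """One local code's mapping: nearest LOINC, distance, Z-score, verdict."""

    local_code_id: str
    mapped_loinc: str
    ks_distance: float
    z_score: float  # NaN when the distance row is constant
    accepted: bool


def zscore_row(row: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Standardize a distance row to mean 0 and unit standard deviation.

    ``ddof=1`` (sample standard deviation) is the default, matching the
    convention of mainstream statistical environments; ``ddof=0`` gives the
    population variant.
    """
    row = np.asarray(row, dtype=float)
    if row.size < 2:
        raise ContractViolationError("Z-scores need at least two entries")
    sd = row.std(ddof=ddof)
    if sd == 0:
        raise DegenerateRowError("constant distance row: Z-scores undefined")
    return (row - row.mean()) / sd


def map_and_score(
    D: DistanceMatrix,
    cutoff: float = DEFAULT_Z_CUTOFF,
    ddof: int = 1,
) -> list[MappingRecord]:
    """Map every query code to its argmin LOINC and apply the Z cutoff.

    Ties at the minimum are broken toward the lexicographically smallest
    LOINC code (logged), so output never depends on column order. A code
    whose distances are all equal is unmappable: its record carries a NaN
    Z-score and ``accepted=False``.
    """
    if D.n_reference < 2:
        raise ContractViolationError(
            "at least two reference codes are required (Z-score undefined for K=1)"
        )
    records: list[MappingRecord] = []
    for i, code in enumerate(D.query_ids):
        row = D.values[i]
        dmin = row.min()
        tied = [D.reference_ids[j] for j in np.flatnonzero(row == dmin)]
        if len(tied) > 1:
            logger.warning("code %s: argmin tie among %s; choosing %s", code, tied, min(tied))
        mapped = min(tied)
        try:
            z = float(zscore_row(row, ddof=ddof)[row.argmin()])
            accepted = z < cutoff
        except DegenerateRowError:
            logger.warning("code %s: constant distance row; mapping rejected", code)
            z = math.nan
            accepted = False
        records.append(
            MappingRecord(
                local_code_id=code,
                mapped_loinc=mapped,
                ks_distance=float(dmin),
                z_score=z,
                accepted=accepted,
            )
        )
    return records


def apply_cutoff(records: Sequence[MappingRecord], cutoff: float) -> list[MappingRecord]:
    """Re-threshold existing records at a different cutoff (Z-scores kept)."""
    return [
        MappingRecord(
            local_code_id=r.local_code_id,
            mapped_loinc=r.mapped_loinc,
            ks_distance=r.ks_distance,
            z_score=r.z_score,
            accepted=(not math.isnan(r.z_score)) and r.z_score < cutoff,
        )
        for r in records
    ]


def acceptance_curve(
    cutoffs: Sequence[float],
    records_by_cutoff: Sequence[Sequence[MappingRecord]],
) -> pd.DataFrame:
    """Tabulate accepted-mapping counts along a strictly increasing cutoff grid."""
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ContractViolationError("cutoff grid must be strictly increasing")
    if len(cutoffs) != len(records_by_cutoff):
        raise ContractViolationError("one record list per cutoff required")
    return pd.DataFrame(
        {
            "cutoff": cutoffs,
            "n_accepted": [sum(r.accepted for r in recs) for recs in records_by_cutoff],
        }
    )
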