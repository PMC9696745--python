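"""End-to-end composition of the three mapping steps.

Step I samples reading values per code and builds eCDFs, Step II computes
the KS distance matrix and the per-code argmin mapping, Step III applies
the Z-score cutoff. This module wires them together for the CLI and the
evaluation harness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .distance import DistanceMatrix, build_distance_matrix
from .ecdf import DEFAULT_SAMPLE_SIZE, ECDF, build_ecdfs_for_table, derive_subseed
from .io_tables import LabEventTable
from .mapping import DEFAULT_Z_CUTOFF, MappingRecord, map_and_score


@dataclass
class MappingRun:
    """One full pass: the distance matrix and the scored mapping records."""

    records: list[MappingRecord]
    distance_matrix: DistanceMatrix


def run_mapping(
    query: LabEventTable,
    reference: LabEventTable | Mapping[str, ECDF],
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    master_seed: int = 0,
    cutoff: float = DEFAULT_Z_CUTOFF,
    ddof: int = 1,
) -> MappingRun:
    """Map every query code against the reference panel.

    The reference may be a raw lab-event table (sampled here, from a
    sub-stream independent of the query's) or a precomputed code → eCDF
    panel as produced by ``bglm build-reference``.
    """
    query_ecdfs = build_ecdfs_for_table(
        query, sample_size=sample_size, master_seed=derive_subseed(master_seed, "query")
    )
    if isinstance(reference, LabEventTable):
        reference_ecdfs: Mapping[str, ECDF] = build_ecdfs_for_table(
            reference, sample_size=sample_size, master_seed=derive_subseed(master_seed, "reference")
        )
    else:
        reference_ecdfs = reference
    D = build_distance_matrix(query_ecdfs, reference_ecdfs)
    return MappingRun(records=map_and_score(D, cutoff=cutoff, ddof=ddof), distance_matrix=D)
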