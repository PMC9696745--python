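"""Tabular input/output.

BGLM touches four kinds of tables, all plain CSV with a header row:

* lab-event tables — long format, one observation per row, keyed by a
  local code id (the "query" institution) or a LOINC code (the reference);
* candidate-mapping tables — one external (text-mapper) LOINC candidate per
  local code, e.g. an export from RELMA;
* truth tables — the manually curated local-code → LOINC assignments used
  for evaluation;
* mapping-result tables — BGLM's own output.

Column names are configurable because local EHR extracts vary; values that
do not parse as finite numbers (text results such as "POS"/"NEG") are
dropped with a logged count, since distribution matching is defined only
for quantitative tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ContractViolationError, EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

CODE_COL = "code_id"
VALUE_COL = "value"


@dataclass
class LabEventTable:
    """Long-format lab observations: one (code_id, numeric value) per row."""

    frame: pd.DataFrame  # columns: code_id (str), value (float)
    source_label: str = "query"

    def __post_init__(self) -> None:
        f = self.frame
        if not {CODE_COL, VALUE_COL} <= set(f.columns):
            raise SchemaError(f"LabEventTable frame needs columns {CODE_COL!r}, {VALUE_COL!r}")
        if len(f) == 0:
            raise EmptyInputError("LabEventTable has no rows")
        if not np.isfinite(f[VALUE_COL].to_numpy(dtype=float)).all():
            raise ContractViolationError("LabEventTable contains non-finite values")
        if (f[CODE_COL].astype(str).str.len() == 0).any():
            raise ContractViolationError("LabEventTable contains empty code ids")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def code_ids(self) -> list[str]:
        """Distinct code ids in first-appearance order."""
        return list(dict.fromkeys(self.frame[CODE_COL]))

    def values_for(self, code_id: str) -> np.ndarray:
        vals = self.frame.loc[self.frame[CODE_COL] == code_id, VALUE_COL]
        return vals.to_numpy(dtype=float)

    @classmethod
    def from_records(
        cls, rows: Iterable[tuple[str, float]], source_label: str = "query"
    ) -> "LabEventTable":
        frame = pd.DataFrame(rows, columns=[CODE_COL, VALUE_COL])
        frame[CODE_COL] = frame[CODE_COL].astype(str)
        frame[VALUE_COL] = frame[VALUE_COL].astype(float)
        return cls(frame=frame, source_label=source_label)


@dataclass
class CandidateMappingTable:
    """External-mapper candidates: at most one LOINC per local code."""

    candidates: dict[str, str] = field(default_factory=dict)

    def get(self, local_code_id: str) -> str | None:
        return self.candidates.get(local_code_id)


@dataclass
class TruthTable:
    """Manually mapped local-code → LOINC assignments (the gold standard)."""

    truth: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, local_code_id: str) -> str:
        return self.truth[local_code_id]

    def __contains__(self, local_code_id: str) -> bool:
        return local_code_id in self.truth

    def __len__(self) -> int:
        return len(self.truth)


def read_lab_events(
    path: str | Path,
    code_column: str = CODE_COL,
    value_column: str = VALUE_COL,
    source_label: str = "query",
) -> LabEventTable:
    """Read a long-format lab-event CSV, dropping non-numeric values.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    SchemaError
        If a named column is absent from the header.
    EmptyInputError
        If no row has a parseable finite numeric value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (code_column, value_column):
        if col not in raw.columns:
            raise SchemaError(f"column {col!r} not found in {path} (has {list(raw.columns)})")
    coerced = pd.to_numeric(raw[value_column], errors="coerce")
    keep = np.isfinite(coerced.to_numpy(dtype=float))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_lab_events(%s): dropped %d non-numeric/missing rows", path, n_dropped)
    frame = pd.DataFrame(
        {
            CODE_COL: raw.loc[keep, code_column].astype(str),
            # astype(float) is correctly rounded, so written values re-read exactly
            VALUE_COL: raw.loc[keep, value_column].astype(float),
        }
    ).reset_index(drop=True)
    if len(frame) == 0:
        raise EmptyInputError(f"{path}: no parseable numeric values in column {value_column!r}")
    return LabEventTable(frame=frame, source_label=source_label)


def write_lab_events(table: LabEventTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def read_candidate_mappings(
    path: str | Path,
    code_column: str = "local_code_id",
    loinc_column: str = "candidate_loinc",
) -> CandidateMappingTable:
    """Read an external candidate file; on duplicate codes the first row wins."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str)
    for col in (code_column, loinc_column):
        if col not in raw.columns:
            raise SchemaError(f"column {col!r} not found in {path}")
    candidates: dict[str, str] = {}
    n_dup = 0
    for code, loinc in zip(raw[code_column], raw[loinc_column]):
        if code in candidates:
            n_dup += 1
            continue
        candidates[str(code)] = str(loinc)
    if n_dup:
        logger.warning(
            "read_candidate_mappings(%s): %d duplicate local codes; kept first candidate",
            path,
            n_dup,
        )
    return CandidateMappingTable(candidates=candidates)


def write_candidate_mappings(table: CandidateMappingTable, path: str | Path) -> None:
    pd.DataFrame(
        sorted(table.candidates.items()), columns=["local_code_id", "candidate_loinc"]
    ).to_csv(path, index=False)


def read_truth_table(
    path: str | Path,
    code_column: str = "local_code_id",
    loinc_column: str = "true_loinc",
) -> TruthTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str)
    for col in (code_column, loinc_column):
        if col not in raw.columns:
            raise SchemaError(f"column {col!r} not found in {path}")
    if raw[code_column].duplicated().any():
        dups = raw.loc[raw[code_column].duplicated(), code_column].tolist()
        raise ContractViolationError(f"truth table has duplicate local codes: {dups}")
    return TruthTable(truth=dict(zip(raw[code_column].astype(str), raw[loinc_column].astype(str))))


def write_truth_table(table: TruthTable, path: str | Path) -> None:
    pd.DataFrame(sorted(table.truth.items()), columns=["local_code_id", "true_loinc"]).to_csv(
        path, index=False
    )


def write_mapping_results(records: Sequence, path: str | Path) -> None:
    """Write mapping records as CSV, sorted by local code id.

    Columns: local_code_id, mapped_loinc, ks_distance, z_score, accepted.
    """
    if not records:
        raise ContractViolationError("write_mapping_results: empty record list")
    rows = sorted(
        (
            (r.local_code_id, r.mapped_loinc, r.ks_distance, r.z_score, r.accepted)
            for r in records
        ),
        key=lambda t: t[0],
    )
    pd.DataFrame(
        rows, columns=["local_code_id", "mapped_loinc", "ks_distance", "z_score", "accepted"]
    ).to_csv(path, index=False)


def read_mapping_results(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={"local_code_id": str, "mapped_loinc": str, "accepted": bool},
        float_precision="round_trip",
    )
    expected = ["local_code_id", "mapped_loinc", "ks_distance", "z_score", "accepted"]
    if list(frame.columns) != expected:
        raise SchemaError(f"{path}: expected columns {expected}, found {list(frame.columns)}")
    return frame


def write_ecdf_panel(ecdfs: Mapping[str, "ECDF"], path: str | Path) -> None:  # noqa: F821
    """Serialize eCDFs to long CSV (code, support, cum_prob).

    Floats are written with Python ``repr`` so the panel round-trips exactly;
    this lets a site publish its reference distribution panel without sharing
    raw patient values.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("code,support,cum_prob\n")
        for code, ecdf in ecdfs.items():
            for x, p in zip(ecdf.support, ecdf.cum_prob):
                fh.write(f"{code},{float(x)!r},{float(p)!r}\n")


def read_ecdf_panel(path: str | Path) -> dict[str, "ECDF"]:  # noqa: F821
    from .ecdf import ECDF

    raw = pd.read_csv(
        path,
        dtype={"code": str, "support": float, "cum_prob": float},
        float_precision="round_trip",
    )
    if list(raw.columns) != ["code", "support", "cum_prob"]:
        raise SchemaError(f"{path}: expected columns code,support,cum_prob")
    out: dict[str, ECDF] = {}
    for code in dict.fromkeys(raw["code"]):
        sub = raw[raw["code"] == code]
        out[code] = ECDF(
            support=sub["support"].to_numpy(dtype=float),
            cum_prob=sub["cum_prob"].to_numpy(dtype=float),
        )
    return out
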