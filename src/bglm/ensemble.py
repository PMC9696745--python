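"""Ensemble rule: combine the distributional mapping with a text mapper.

Given a local code C with distribution-based candidate B (and its Z-score)
and external text-mapper candidate R: if B and R agree, or the Z-score of B
is below the ensemble cutoff (default -3.80), the ensemble chooses B;
otherwise it defers to R. Codes covered by only one source fall back to
that source's candidate, with the branch label preserving auditability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io_tables import CandidateMappingTable
from .mapping import MappingRecord

DEFAULT_ENSEMBLE_Z_CUTOFF = -3.80


class Branch(str, Enum):
    AGREE = "agree"
    BGLM_CONFIDENT = "bglm_confident"
    EXTERNAL_DEFAULT = "external_default"
    BGLM_ONLY = "bglm_only"
    EXTERNAL_ONLY = "external_only"


@dataclass
class EnsembleDecision:
    local_code_id: str
    bglm_candidate: str | None
    external_candidate: str | None
    chosen: str
    branch: Branch
    z_score: float


def ensemble_combine(
    bglm: Sequence[MappingRecord],
    external: CandidateMappingTable,
    z_cutoff: float = DEFAULT_ENSEMBLE_Z_CUTOFF,
) -> list[EnsembleDecision]:
    """Apply the ensemble decision rule per local code.

    Codes are decided in sorted order for deterministic output. A NaN
    Z-score (unmappable code) never counts as confident.
    """
    by_code = {r.local_code_id: r for r in bglm}
    decisions: list[EnsembleDecision] = []
    for code in sorted(set(by_code) | set(external.candidates)):
        rec = by_code.get(code)
        ext = external.get(code)
        if rec is None:
            decisions.append(
                EnsembleDecision(code, None, ext, ext, Branch.EXTERNAL_ONLY, math.nan)
            )
            continue
        if ext is None:
            decisions.append(
                EnsembleDecision(
                    code, rec.mapped_loinc, None, rec.mapped_loinc, Branch.BGLM_ONLY, rec.z_score
                )
            )
            continue
        if rec.mapped_loinc == ext:
            branch, chosen = Branch.AGREE, rec.mapped_loinc
        elif not math.isnan(rec.z_score) and rec.z_score < z_cutoff:
            branch, chosen = Branch.BGLM_CONFIDENT, rec.mapped_loinc
        else:
            branch, chosen = Branch.EXTERNAL_DEFAULT, ext
        decisions.append(
            EnsembleDecision(code, rec.mapped_loinc, ext, chosen, branch, rec.z_score)
        )
    return decisions


def write_ensemble_decisions(decisions: Sequence[EnsembleDecision], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "local_code_id": d.local_code_id,
                "chosen": d.chosen,
                "branch": d.branch.value,
                "bglm_candidate": d.bglm_candidate,
                "external_candidate": d.external_candidate,
                "z_score": d.z_score,
            }
            for d in decisions
        ]
    ).to_csv(path, index=False)
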