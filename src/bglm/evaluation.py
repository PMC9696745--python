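"""Evaluation harness: precision-vs-cutoff curves and Z-score separation.

Because sampling introduces randomness, the mapper is run repeatedly
(30 times by default) and the precision curve is averaged over runs. The
harness also tests whether Z-scores of correct mappings sit below those of
incorrect ones — the evidence that the Z-score is a usable confidence
signal — with a one-sided Wilcoxon rank-sum test (a Welch t-test variant
is available behind a flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ecdf import DEFAULT_SAMPLE_SIZE, derive_subseed
from .exceptions import ContractViolationError, EvaluationError, SeparationUndefinedError
from .io_tables import LabEventTable, TruthTable
from .mapping import MappingRecord
from .pipeline import run_mapping


@dataclass
class EvaluationReport:
    """Multi-run evaluation results.

    ``per_run`` holds one row per (run, cutoff); ``averaged`` the mean curve
    over runs; ``per_run_separation`` one (run_index, statistic, p_value)
    row per run; ``zscore_separation`` the test pooled over all runs.
    Precision is NaN wherever nothing was accepted.
    """

    per_run: pd.DataFrame
    averaged: pd.DataFrame
    per_run_separation: pd.DataFrame
    zscore_separation: tuple[float, float] | None
    n_runs: int


def precision_at_cutoff(
    records: Sequence[MappingRecord],
    truth: TruthTable,
    cutoff: float,
) -> tuple[float | None, int]:
    """Fraction of accepted mappings that are correct at the given cutoff.

    Returns ``(None, 0)`` when nothing is accepted — the ratio is undefined,
    not zero. A record whose code is absent from the truth table is an
    evaluation error.
    """
    n_accepted = 0
    n_correct = 0
    for r in records:
        if r.local_code_id not in truth:
            raise EvaluationError(f"code {r.local_code_id!r} missing from truth table")
        if not math.isnan(r.z_score) and r.z_score < cutoff:
            n_accepted += 1
            if r.mapped_loinc == truth[r.local_code_id]:
                n_correct += 1
    if n_accepted == 0:
        return None, 0
    return n_correct / n_accepted, n_accepted


def zscore_separation_test(
    records: Sequence[MappingRecord],
    truth: TruthTable,
    method: str = "ranksum",
) -> tuple[float, float]:
    """One-sided test that correct mappings carry lower Z-scores.

    ``method`` is ``"ranksum"`` (Wilcoxon/Mann-Whitney, default) or
    ``"ttest"`` (Welch). Both groups must be non-empty.
    """
    correct, incorrect = [], []
    for r in records:
        if r.local_code_id not in truth:
            raise EvaluationError(f"code {r.local_code_id!r} missing from truth table")
        if math.isnan(r.z_score):
            continue
        (correct if r.mapped_loinc == truth[r.local_code_id] else incorrect).append(r.z_score)
    if not correct or not incorrect:
        raise SeparationUndefinedError(
            f"need both groups non-empty (correct={len(correct)}, incorrect={len(incorrect)})"
        )
    if method == "ranksum":
        # exact null distribution where cheap and tie-free; asymptotic otherwise
        pooled = correct + incorrect
        mw_method = (
            "exact" if len(pooled) <= 60 and len(set(pooled)) == len(pooled) else "asymptotic"
        )
        res = stats.mannwhitneyu(correct, incorrect, alternative="less", method=mw_method)
    elif method == "ttest":
        res = stats.ttest_ind(correct, incorrect, equal_var=False, alternative="less")
    else:
        raise ContractViolationError(f"unknown separation test method {method!r}")
    return float(res.statistic), float(res.pvalue)


def run_repeated_evaluation(
    query: LabEventTable,
    reference: LabEventTable,
    truth: TruthTable,
    cutoff_grid: Sequence[float],
    n_runs: int = 30,
    master_seed: int = 0,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    separation_method: str = "ranksum",
) -> EvaluationReport:
    """Run the mapper *n_runs* times and average precision over the grid.

    Run r draws all its samples from a sub-seed derived from
    (master_seed, r), so the whole report is reproducible and runs are
    mutually independent.
    """
    if n_runs < 1:
        raise ContractViolationError("n_runs must be >= 1")
    cutoffs = [float(c) for c in cutoff_grid]
    per_run_rows = []
    sep_rows = []
    pooled: list[MappingRecord] = []
    for r in range(n_runs):
        run_seed = derive_subseed(master_seed, f"run:{r}")
        run = run_mapping(
            query, reference, sample_size=sample_size, master_seed=run_seed, cutoff=math.inf
        )
        pooled.extend(run.records)
        for c in cutoffs:
            prec, n_acc = precision_at_cutoff(run.records, truth, c)
            per_run_rows.append(
                {
                    "run_index": r,
                    "cutoff": c,
                    "precision": math.nan if prec is None else prec,
                    "n_accepted": n_acc,
                }
            )
        try:
            stat, p = zscore_separation_test(run.records, truth, method=separation_method)
        except SeparationUndefinedError:
            stat, p = math.nan, math.nan
        sep_rows.append({"run_index": r, "statistic": stat, "p_value": p})

    per_run = pd.DataFrame(per_run_rows)
    averaged = (
        per_run.groupby("cutoff", sort=True)
        .agg(mean_precision=("precision", "mean"), mean_n_accepted=("n_accepted", "mean"))
        .reset_index()
    )
    try:
        pooled_sep: tuple[float, float] | None = zscore_separation_test(
            pooled, truth, method=separation_method
        )
    except SeparationUndefinedError:
        pooled_sep = None
    return EvaluationReport(
        per_run=per_run,
        averaged=averaged,
        per_run_separation=pd.DataFrame(sep_rows),
        zscore_separation=pooled_sep,
        n_runs=n_runs,
    )


def plot_precision_curve(report: EvaluationReport, path) -> None:
    """Save the averaged precision / acceptance curve (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(6, 4))
    av = report.averaged.dropna(subset=["mean_precision"])
    ax1.plot(av["cutoff"], av["mean_precision"], "o-", color="tab:blue")
    ax1.set_xlabel("Z-score cutoff")
    ax1.set_ylabel("mean precision", color="tab:blue")
    ax1.set_ylim(0, 1.05)
    ax2 = ax1.twinx()
    ax2.plot(report.averaged["cutoff"], report.averaged["mean_n_accepted"], "s--",
             color="tab:orange")
    ax2.set_ylabel("mean accepted mappings", color="tab:orange")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
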