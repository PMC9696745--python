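"""Step I: per-code value sampling and empirical CDF construction.

For each lab code a fixed-size random sample of reading values is drawn
(1000 by default) and condensed into an empirical cumulative distribution
function — a right-continuous step function F(x) = #{values <= x} / n.
Ties collapse into a single support point carrying the pooled cumulative
probability, so integer-valued analytes are represented exactly.

Sampling is without replacement and driven by per-code sub-seeds derived
deterministically from (master seed, code id); adding or removing a code
never perturbs the samples drawn for other codes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import CodeNotFoundError, ContractViolationError
from .io_tables import LabEventTable

logger = logging.getLogger(__name__)

DEFAULT_SAMPLE_SIZE = 1000


def derive_subseed(master_seed: int, key: str) -> int:
    """Stable sub-seed in [0, 2^31) from a master seed and a string key."""
    digest = hashlib.blake2b(f"{master_seed}:{key}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass
class ValueSample:
    """A random draw of reading values for one code."""

    code_id: str
    values: np.ndarray
    sample_size_requested: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and not np.isfinite(self.values).all():
            raise ContractViolationError(f"sample for {self.code_id} has non-finite values")


@dataclass(frozen=True)
class ECDF:
    """Empirical CDF: strictly increasing support, cumulative probabilities.

    ``cum_prob[k]`` is the fraction of sample values <= ``support[k]``;
    the last element is exactly 1.
    """

    support: np.ndarray
    cum_prob: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", np.asarray(self.support, dtype=float))
        object.__setattr__(self, "cum_prob", np.asarray(self.cum_prob, dtype=float))
        if self.support.size == 0:
            raise ContractViolationError("ECDF needs at least one support point")
        if self.support.size != self.cum_prob.size:
            raise ContractViolationError("support and cum_prob lengths differ")
        if np.any(np.diff(self.support) <= 0):
            raise ContractViolationError("ECDF support must be strictly increasing")
        if np.any(np.diff(self.cum_prob) < 0) or self.cum_prob[-1] != 1.0:
            raise ContractViolationError("cum_prob must be non-decreasing and end at 1")

    def evaluate(self, x) -> np.ndarray | float:
        return ecdf_eval(self, x)


def draw_sample(
    table: LabEventTable,
    code_id: str,
    n: int = DEFAULT_SAMPLE_SIZE,
    seed: int = 0,
) -> ValueSample:
    """Draw up to *n* values for *code_id* uniformly without replacement.

    Codes holding fewer than *n* observations contribute everything they
    have (with a warning) rather than being excluded, so the tool degrades
    gracefully below the >1000-observation regime it is designed for.
    """
    if n < 1:
        raise ContractViolationError("sample size must be positive")
    values = table.values_for(code_id)
    if values.size == 0:
        raise CodeNotFoundError(f"code {code_id!r} not present in {table.source_label} table")
    rng = np.random.default_rng(derive_subseed(seed, code_id))
    if values.size > n:
        drawn = rng.choice(values, size=n, replace=False)
    else:
        if values.size < n:
            logger.warning(
                "code %s has only %d observations (< %d requested); using all",
                code_id,
                values.size,
                n,
            )
        drawn = values.copy()
    return ValueSample(code_id=code_id, values=drawn, sample_size_requested=n, seed=seed)


def build_ecdf(sample: ValueSample | np.ndarray) -> ECDF:
    """Build the empirical CDF of a sample; tied values share a support point."""
    values = sample.values if isinstance(sample, ValueSample) else np.asarray(sample, dtype=float)
    if values.size == 0:
        raise ContractViolationError("cannot build an ECDF from an empty sample")
    support, counts = np.unique(values, return_counts=True)
    cum_prob = np.cumsum(counts) / values.size
    cum_prob[-1] = 1.0  # guard against float round-off in the cumulative sum
    return ECDF(support=support, cum_prob=cum_prob)


def ecdf_eval(ecdf: ECDF, x) -> np.ndarray | float:
    """Evaluate F(x): right-continuous, 0 below the support, 1 above it."""
    x = np.asarray(x, dtype=float)
    idx = np.searchsorted(ecdf.support, x, side="right")
    padded = np.concatenate(([0.0], ecdf.cum_prob))
    out = padded[idx]
    return float(out) if out.ndim == 0 else out


def build_ecdfs_for_table(
    table: LabEventTable,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    master_seed: int = 0,
    code_ids: list[str] | None = None,
) -> dict[str, ECDF]:
    """Sample every code of *table* and return an ordered code → ECDF map."""
    codes = table.code_ids() if code_ids is None else code_ids
    return {
        code: build_ecdf(draw_sample(table, code, n=sample_size, seed=master_seed))
        for code in codes
    }
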