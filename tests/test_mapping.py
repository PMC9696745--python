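import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bglm import DistanceMatrix, acceptance_curve, apply_cutoff, map_and_score, zscore_row
from bglm.exceptions import ContractViolationError, DegenerateRowError


def matrix(rows, query_ids=None, reference_ids=None):
    rows = np.asarray(rows, dtype=float)
    query_ids = query_ids or [f"C{i}" for i in range(rows.shape[0])]
    reference_ids = reference_ids or [f"L{j}" for j in range(rows.shape[1])]
    return DistanceMatrix(values=rows, query_ids=query_ids, reference_ids=reference_ids)


class TestZscoreRow:
    def test_hand_case_with_sample_sd(self):
        # mean 0.5, sample sd 0.4 -> (-1, 0, 1)
        assert np.allclose(zscore_row(np.array([0.1, 0.5, 0.9])), [-1.0, 0.0, 1.0])

    def test_population_divisor_variant(self):
        z = zscore_row(np.array([0.1, 0.5, 0.9]), ddof=0)
        assert np.allclose(z, np.array([-1, 0, 1]) * math.sqrt(3 / 2))

    def test_constant_row_is_degenerate(self):
        with pytest.raises(DegenerateRowError):
            zscore_row(np.array([0.3, 0.3, 0.3]))

    def test_short_row_rejected(self):
        with pytest.raises(ContractViolationError):
            zscore_row(np.array([0.3]))

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=30
        ).filter(lambda r: np.asarray(r).std() > 1e-6)
    )
    def test_standardization_contract(self, row):
        z = zscore_row(np.array(row))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=1, allow_nan=False), min_size=2, max_size=20
        ).filter(lambda r: np.asarray(r).std() > 1e-6),
        st.floats(min_value=-5, max_value=5, allow_nan=False),
        st.floats(min_value=0.01, max_value=100, allow_nan=False),
    )
    def test_affine_invariance(self, row, shift, scale):
        base = zscore_row(np.array(row))
        transformed = zscore_row(np.array(row) * scale + shift)
        assert np.allclose(base, transformed, atol=1e-9)


class TestMapAndScore:
    def test_clear_outlier_row_accepted(self):
        recs = map_and_score(matrix([[0.05, 0.60, 0.62, 0.61]]), cutoff=-1.0)
        assert recs[0].mapped_loinc == "L0"
        assert recs[0].ks_distance == 0.05
        assert recs[0].z_score < -1.0 and recs[0].accepted

    def test_tie_breaks_to_lexicographically_smallest(self, caplog):
        D = matrix([[0.9, 0.1, 0.5, 0.4, 0.1]], reference_ids=["L9", "L5", "L3", "L4", "L2"])
        with caplog.at_level("WARNING"):
            recs = map_and_score(D, cutoff=0.0)
        assert recs[0].mapped_loinc == "L2"
        assert "tie" in caplog.text

    def test_infinite_cutoff_accepts_everything(self):
        recs = map_and_score(matrix([[0.2, 0.4, 0.9], [0.7, 0.8, 0.6]]), cutoff=math.inf)
        assert all(r.accepted for r in recs)

    def test_single_reference_rejected(self):
        with pytest.raises(ContractViolationError):
            map_and_score(matrix([[0.5]]))

    def test_constant_row_yields_nan_not_crash(self):
        recs = map_and_score(matrix([[0.5, 0.5, 0.5]]), cutoff=math.inf)
        assert math.isnan(recs[0].z_score) and not recs[0].accepted

    def test_argmin_property_brute_force(self, rng):
        vals = rng.uniform(0, 1, size=(8, 12))
        D = matrix(vals)
        for rec in map_and_score(D, cutoff=-5.0):
            i = D.query_ids.index(rec.local_code_id)
            j = D.reference_ids.index(rec.mapped_loinc)
            assert vals[i, j] == vals[i].min()
            assert (vals[i, j] <= vals[i]).all()

    def test_acceptance_monotone_in_cutoff(self, rng):
        D = matrix(rng.uniform(0, 1, size=(10, 15)))
        grid = [-3.0, -1.0, 0.0, 1.0]
        per_cutoff = [apply_cutoff(map_and_score(D, cutoff=math.inf), c) for c in grid]
        sets = [{r.local_code_id for r in recs if r.accepted} for recs in per_cutoff]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


class TestAcceptanceCurve:
    def test_counts_monotone_and_extremes(self, rng):
        D = matrix(rng.uniform(0, 1, size=(10, 15)))
        base = map_and_score(D, cutoff=math.inf)
        zs = [r.z_score for r in base]
        grid = [min(zs) - 1, (min(zs) + max(zs)) / 2, max(zs) + 1]
        curve = acceptance_curve(grid, [apply_cutoff(base, c) for c in grid])
        counts = curve["n_accepted"].tolist()
        assert counts == sorted(counts)
        assert counts[0] == 0
        assert counts[-1] == len(base)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ContractViolationError):
            acceptance_curve([0.0, 0.0], [[], []])
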