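from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from bglm import (
    CodeSpec,
    ScenarioConfig,
    add_mild_shift,
    build_distance_matrix,
    build_ecdf,
    generate_scenario,
    make_analyte_panel,
    make_confusable_panel,
    make_mixed_panel,
    run_mapping,
    scenario_from_yaml,
    scenario_to_yaml,
)
from bglm.exceptions import ConfigError


class TestCodeSpec:
    @pytest.mark.parametrize(
        "family,params",
        [
            ("normal", (0.0, -1.0)),
            ("gamma", (-2.0, 1.0)),
            ("uniform", (5.0, 1.0)),
            ("discrete", (0.0,)),
            ("mixture", (0.0, 1.0, 1.5, 0.0, 50.0)),
            ("weibull", (1.0, 1.0)),
        ],
    )
    def test_invalid_params_rejected(self, family, params):
        with pytest.raises(ConfigError):
            CodeSpec(loinc="X", family=family, params=params)

    def test_moments_match_simulation(self, rng):
        for spec in make_mixed_panel().specs:
            mean, sd = spec.nominal_moments()
            draws = spec.draw(200_000, rng)
            assert draws.mean() == pytest.approx(mean, rel=0.02, abs=0.05)
            assert draws.std() == pytest.approx(sd, rel=0.03)

    def test_discrete_family_produces_ties(self, rng):
        spec = CodeSpec(loinc="6690-2", family="discrete", params=(9.0,))
        draws = spec.draw(500, rng)
        assert np.unique(draws).size < 60  # integer-valued, heavy ties
        assert (draws == draws.round()).all()


class TestGenerateScenario:
    def test_truth_covers_every_query_code_exactly_once(self):
        q, _, truth = generate_scenario(make_confusable_panel(6, 0.2, seed=1))
        assert sorted(q.code_ids()) == sorted(truth.truth)

    def test_unmapped_fraction_counts(self):
        cfg = replace(make_confusable_panel(10, 0.0, seed=2), unmapped_fraction=0.3)
        _, reference, truth = generate_scenario(cfg)
        missing = set(truth.truth.values()) - set(reference.code_ids())
        assert len(missing) == 3

    def test_same_seed_is_byte_identical(self, tmp_path):
        from bglm import write_lab_events

        for name in ("a", "b"):
            q, r, _ = generate_scenario(make_confusable_panel(4, 0.5, seed=9))
            write_lab_events(q, tmp_path / f"q_{name}.csv")
            write_lab_events(r, tmp_path / f"r_{name}.csv")
        assert (tmp_path / "q_a.csv").read_bytes() == (tmp_path / "q_b.csv").read_bytes()
        assert (tmp_path / "r_a.csv").read_bytes() == (tmp_path / "r_b.csv").read_bytes()

    def test_reference_only_codes_absent_from_query(self):
        cfg = make_analyte_panel(5, n_reference_only=3, seed=4)
        q, r, truth = generate_scenario(cfg)
        assert len(truth) == 5
        assert len(r.code_ids()) == 8
        assert set(truth.truth.values()) <= set(r.code_ids())

    def test_confuser_pair_copies_params(self):
        cfg = make_confusable_panel(4, 0.0, seed=3)
        cfg = replace(cfg, confuser_pairs=[(cfg.specs[0].loinc, cfg.specs[3].loinc)])
        _, reference, _ = generate_scenario(cfg)
        a = reference.values_for(cfg.specs[0].loinc)
        b = reference.values_for(cfg.specs[3].loinc)
        assert abs(a.mean() - b.mean()) < 0.2  # near-identical locations

    def test_zero_shift_generator_self_consistency(self):
        """Query and reference draws per code come from the same distribution."""
        cfg = make_confusable_panel(20, 0.0, seed=5)
        query, reference, truth = generate_scenario(cfg)
        n_pass = 0
        for local, loinc in truth.truth.items():
            p = stats.ks_2samp(query.values_for(local), reference.values_for(loinc)).pvalue
            n_pass += p > 0.01
        assert n_pass >= 0.95 * len(truth)


class TestPanels:
    def test_zero_overlap_panel_is_well_separated(self):
        cfg = make_confusable_panel(5, 0.0, seed=6)
        _, reference, _ = generate_scenario(cfg)
        ecdfs = {
            c: build_ecdf(np.random.default_rng(0).choice(reference.values_for(c), 1000, False))
            for c in reference.code_ids()
        }
        D = build_distance_matrix(ecdfs, ecdfs)
        off_diag = D.values[~np.eye(len(ecdfs), dtype=bool)]
        assert off_diag.mean() > 0.9

    def test_full_overlap_panel_shares_params(self):
        cfg = make_confusable_panel(4, 1.0, seed=6)
        assert len({s.params for s in cfg.specs}) == 1

    def test_panel_size(self):
        assert len(make_confusable_panel(2, 0.5).specs) == 2

    def test_end_to_end_recovery_on_separated_panel(self):
        """Well-separated codes with no shift: mapping recovers the truth."""
        q, r, truth = generate_scenario(make_confusable_panel(10, 0.0, seed=11))
        run = run_mapping(q, r, master_seed=1)
        assert all(rec.mapped_loinc == truth[rec.local_code_id] for rec in run.records)

    def test_mild_shift_magnitudes_are_bounded(self):
        cfg = add_mild_shift(make_analyte_panel(5, 2, seed=8))
        for spec in cfg.specs:
            loc, scale = cfg.query_shift[spec.loinc]
            assert abs(loc) <= 0.05 * spec.shift_scale() + 1e-12
            assert 0.98 - 1e-12 <= scale <= 1.02 + 1e-12


def test_yaml_round_trip(tmp_path):
    cfg = add_mild_shift(
        replace(make_analyte_panel(4, 2, seed=12), unmapped_fraction=0.25)
    )
    cfg = replace(cfg, confuser_pairs=[(cfg.specs[0].loinc, cfg.specs[1].loinc)])
    scenario_to_yaml(cfg, tmp_path / "s.yaml")
    back = scenario_from_yaml(tmp_path / "s.yaml")
    assert back == cfg


def test_all_reference_only_rejected():
    specs = [CodeSpec(loinc="X-1", family="normal", params=(0.0, 1.0)),
             CodeSpec(loinc="Y-1", family="normal", params=(5.0, 1.0))]
    with pytest.raises(ConfigError):
        ScenarioConfig(specs=specs, reference_only=["X-1", "Y-1"])
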