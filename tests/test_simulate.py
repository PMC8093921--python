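"""Synthetic-data generator: determinism, planted structure, truth consistency."""

import dataclasses

import numpy as np
import pytest

from crossde import (
    SimulationConfig,
    SyntheticTruth,
    io,
    planted_de_genes,
    simulate_expression,
    simulate_go_annotation,
    simulate_human_de,
    simulate_ortholog_table,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_de": 1.5},
            {"frac_detected": -0.1},
            {"sign_concordance": 2.0},
            {"n_genes": 0},
            {"n_samples_per_group": 0},
            {"noise_sd": -1.0},
            {"n_planted_terms": 99},
        ],
    )
    def test_invalid_configs_rejected_with_parameter_name(self, kwargs):
        with pytest.raises(ValueError, match=next(iter(kwargs))):
            SimulationConfig(**kwargs)


class TestSimulateExpression:
    def test_no_de_when_frac_de_zero(self):
        cfg = SimulationConfig(seed=1, n_genes=100, frac_de=0.0, noise_sd=0.0)
        table, truth = simulate_expression(cfg, "young")
        diff = table.group_values("treated").mean(1) - table.group_values("control").mean(1)
        assert np.allclose(diff, 0.0)
        assert truth.planted_de_fly["young"] == {}

    def test_zero_noise_recovers_exact_effects(self):
        cfg = SimulationConfig(seed=2, n_genes=100, frac_de=0.1, noise_sd=0.0)
        table, truth = simulate_expression(cfg, "young")
        diff = dict(
            zip(
                table.gene_ids,
                table.group_values("treated").mean(1) - table.group_values("control").mean(1),
            )
        )
        planted = truth.planted_de_fly["young"]
        assert len(planted) == 10
        for g, sign in planted.items():
            assert diff[g] != 0 and np.sign(diff[g]) == sign
        for g in set(table.gene_ids) - set(planted):
            assert diff[g] == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_bytes_identical(self, tmp_path, small_config):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        t1, _ = simulate_expression(small_config, "old")
        t2, _ = simulate_expression(small_config, "old")
        io.write_expression(t1, p1)
        io.write_expression(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_ages_share_planted_set_by_default(self, small_config):
        _, truth = simulate_expression(small_config, "young")
        _, truth2 = simulate_expression(small_config, "old")
        assert truth.planted_de_fly["young"] == truth2.planted_de_fly["old"]

    def test_expression_roundtrip(self, tmp_path, small_config):
        table, _ = simulate_expression(small_config, "young")
        io.write_expression(table, tmp_path / "e.tsv")
        back = io.read_expression(tmp_path / "e.tsv")
        assert back.gene_ids == table.gene_ids
        assert np.allclose(back.values, table.values)
        assert (back.detected == table.detected).all()
        assert (back.group == table.group).all()


class TestSimulateOrthologTable:
    def test_bijection_without_multimapping(self):
        cfg = SimulationConfig(seed=3, n_genes=50, frac_one_to_many=0.0, frac_nonreciprocal=0.0)
        table = simulate_ortholog_table(cfg)
        assert len(table) == 50
        assert table["human_gene"].is_unique and table["fly_gene"].is_unique
        assert (table["best_forward"] == "yes").all() and (table["best_reverse"] == "yes").all()

    def test_fully_nonreciprocal_translates_to_nothing(self):
        from crossde import filter_reciprocal_best, translate

        cfg = SimulationConfig(seed=4, n_genes=50, frac_nonreciprocal=1.0)
        table = simulate_ortholog_table(cfg)
        recip = filter_reciprocal_best(table)
        assert translate(set(table["human_gene"]), recip).fly_genes == set()

    def test_shared_fly_ortholog_exists(self, small_config):
        """With one-to-many rows present, some fly gene has two human
        contributors (exercises the dedup rule)."""
        table = simulate_ortholog_table(small_config)
        assert table["fly_gene"].duplicated().any()

    def test_deterministic(self, small_config):
        t1 = simulate_ortholog_table(small_config)
        t2 = simulate_ortholog_table(small_config)
        assert t1.equals(t2)


class TestSimulateHumanDE:
    def test_zero_concordance_means_all_opposite(self, small_config):
        truth = SyntheticTruth()
        _, truth = simulate_expression(small_config, "old", truth)
        ortho = simulate_ortholog_table(small_config)
        simulate_human_de(small_config, truth, ortho)
        assert truth.conserved_pairs
        assert all(rel == "opposite" for _, _, rel in truth.conserved_pairs)

    def test_full_concordance_means_all_same(self, small_config):
        cfg = dataclasses.replace(small_config, sign_concordance=1.0)
        truth = SyntheticTruth()
        _, truth = simulate_expression(cfg, "old", truth)
        human = simulate_human_de(cfg, truth, simulate_ortholog_table(cfg))
        assert all(rel == "same" for _, _, rel in truth.conserved_pairs)
        # conserved human genes appear in the planted cell type's list
        planted_ct = truth.planted_celltype
        listed = set(human.loc[human["cell_type"] == planted_ct, "gene"])
        assert {h for h, _, _ in truth.conserved_pairs} <= listed

    def test_no_conservation_no_planted_celltype(self, small_config):
        cfg = dataclasses.replace(small_config, frac_conserved=0.0)
        truth = SyntheticTruth()
        _, truth = simulate_expression(cfg, "old", truth)
        simulate_human_de(cfg, truth, simulate_ortholog_table(cfg))
        assert truth.planted_celltype is None
        assert truth.conserved_pairs == []

    def test_celltype_count(self, small_config):
        cfg = dataclasses.replace(small_config, n_celltypes=6)
        truth = SyntheticTruth()
        _, truth = simulate_expression(cfg, "old", truth)
        human = simulate_human_de(cfg, truth, simulate_ortholog_table(cfg))
        assert human["cell_type"].nunique() == 6

    def test_truth_table_inconsistency_rejected(self, small_config):
        truth = SyntheticTruth()
        truth.planted_de_fly["old"] = {"not_a_gene": 1}
        with pytest.raises(ValueError, match="inconsistency"):
            simulate_human_de(small_config, truth, simulate_ortholog_table(small_config))


class TestSimulateGoAnnotation:
    def test_term_sizes_and_planted_directions(self, small_config):
        truth = SyntheticTruth()
        _, truth = simulate_expression(small_config, "old", truth)
        coll = simulate_go_annotation(small_config, truth)
        assert len(coll.sets) == small_config.n_go_terms
        assert all(len(m) == small_config.genes_per_term for m in coll.sets.values())
        assert len(truth.planted_enriched_terms) == small_config.n_planted_terms
        planted = truth.planted_de_fly["old"]
        for term, direction in truth.planted_enriched_terms.items():
            wanted = 1 if direction == "up" else -1
            members = coll.sets[term]
            n_match = sum(1 for g in members if planted.get(g) == wanted)
            assert n_match >= len(members) // 2

    def test_oversized_term_request_rejected(self, small_config):
        cfg = dataclasses.replace(small_config, genes_per_term=small_config.n_genes + 1)
        with pytest.raises(ValueError, match="genes_per_term"):
            simulate_go_annotation(cfg, SyntheticTruth())

    def test_no_planted_terms(self, small_config):
        cfg = dataclasses.replace(small_config, n_planted_terms=0)
        truth = SyntheticTruth()
        _, truth = simulate_expression(cfg, "old", truth)
        simulate_go_annotation(cfg, truth)
        assert truth.planted_enriched_terms == {}


class TestTruthConsistency:
    def test_every_truth_id_resolves_in_emitted_tables(self, small_config):
        truth = SyntheticTruth()
        tables = {}
        for age in ("young", "old"):
            tables[age], truth = simulate_expression(small_config, age, truth)
        ortho = simulate_ortholog_table(small_config)
        coll = simulate_go_annotation(small_config, truth)
        human = simulate_human_de(small_config, truth, ortho)

        for age, planted in truth.planted_de_fly.items():
            assert set(planted) <= set(tables[age].gene_ids)
        assert set(truth.planted_enriched_terms) <= set(coll.sets)
        humans_listed = set(human["gene"])
        for ct, de_map in truth.planted_human_de.items():
            assert set(de_map) <= humans_listed
        fly_planted = truth.fly_planted_union()
        human_planted_all = {g for m in truth.planted_human_de.values() for g in m}
        pair_rows = {(h, f) for h, f in zip(ortho["human_gene"], ortho["fly_gene"])}
        for h, f, rel in truth.conserved_pairs:
            assert f in fly_planted and h in human_planted_all
            assert (h, f) in pair_rows
            assert rel in ("same", "opposite")

    def test_truth_json_roundtrip(self, tmp_path, small_config):
        truth = SyntheticTruth()
        _, truth = simulate_expression(small_config, "old", truth)
        simulate_human_de(small_config, truth, simulate_ortholog_table(small_config))
        truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back == truth
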