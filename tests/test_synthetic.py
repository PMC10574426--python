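"""Synthetic-data generators: determinism, planted ground truth, validation."""

import numpy as np
import pytest

from herbnet.md import mmpbsa_totals
from herbnet.screen import merge_dedup, screen_swissadme, screen_tcmsp
from herbnet.synthetic import (
    EnergyParams,
    PlantedTerm,
    SyntheticSpec,
    SyntheticSpecError,
    TrajectoryParams,
    gen_annotations,
    gen_compound_table,
    gen_docking_poses,
    gen_energy_table,
    gen_ppi,
    gen_target_sets,
    gen_trajectory,
)
from herbnet.targets import TargetSet, intersect


class TestSpecValidation:
    def test_infeasible_overlap_names_field(self):
        with pytest.raises(SyntheticSpecError, match="planted_overlap"):
            SyntheticSpec(n_compound_targets=10, n_disease_targets=5, planted_overlap=6)

    def test_negative_count_names_field(self):
        with pytest.raises(SyntheticSpecError, match="n_terms"):
            SyntheticSpec(n_terms=-1)

    def test_negative_noise_rejected(self):
        with pytest.raises(SyntheticSpecError, match="noise_sd"):
            SyntheticSpec(trajectory_params=TrajectoryParams(noise_sd=-0.1))

    def test_bad_graph_model(self):
        with pytest.raises(SyntheticSpecError, match="graph_model"):
            gen_ppi(SyntheticSpec(graph_model="small_world"))


class TestDeterminism:
    def test_all_generators_repeat_identically(self):
        for make in (gen_compound_table, gen_target_sets, gen_ppi, gen_energy_table):
            a = make(SyntheticSpec(seed=42))
            b = make(SyntheticSpec(seed=42))
            if make is gen_ppi:
                assert sorted(a.edges) == sorted(b.edges)
                assert {e: a.edges[e]["score"] for e in a.edges} == {
                    e: b.edges[e]["score"] for e in b.edges
                }
            else:
                assert a == b

    def test_trajectory_repeats_identically(self):
        a = gen_trajectory(SyntheticSpec(seed=3))
        b = gen_trajectory(SyntheticSpec(seed=3))
        assert np.array_equal(a.times, b.times) and np.array_equal(a.values, b.values)

    def test_different_seeds_differ(self):
        a = gen_compound_table(SyntheticSpec(seed=1))
        b = gen_compound_table(SyntheticSpec(seed=2))
        assert a != b


class TestCompoundTable:
    def test_planted_duplicates_recovered_by_dedup(self):
        spec = SyntheticSpec(seed=5, n_compounds=30, n_duplicates=3)
        table = gen_compound_table(spec)
        assert len(table) == 30
        assert len(merge_dedup(table)) == 27

    def test_pass_fraction_zero_kills_screen(self):
        spec = SyntheticSpec(seed=5, tcmsp_pass_fraction=0.0,
                             swissadme_pass_fraction=0.0, n_duplicates=0)
        table = gen_compound_table(spec)
        assert screen_tcmsp(table) == []
        assert screen_swissadme(table) == []

    def test_pass_fractions_respected_exactly(self):
        spec = SyntheticSpec(seed=8, n_compounds=20, n_duplicates=0,
                             tcmsp_pass_fraction=0.5, swissadme_pass_fraction=0.25)
        table = gen_compound_table(spec)
        assert len(screen_tcmsp(table)) == 10
        assert len(screen_swissadme(table)) == 5


class TestTargetSets:
    @pytest.mark.parametrize("nc,nd,k", [(665, 593, 119), (10, 8, 0), (10, 8, 8)])
    def test_planted_overlap_exact(self, nc, nd, k):
        spec = SyntheticSpec(seed=1, n_compound_targets=nc, n_disease_targets=nd,
                             planted_overlap=k)
        compound, disease = gen_target_sets(spec)
        assert len(compound) == nc and len(disease) == nd
        _, counts = intersect(compound, disease)
        assert counts.common == k


class TestPpiGeneration:
    def test_empty_er_graph(self):
        g = gen_ppi(SyntheticSpec(graph_params={"n": 10, "p": 0.0}))
        assert g.number_of_nodes() == 10 and g.number_of_edges() == 0

    def test_complete_er_graph(self):
        g = gen_ppi(SyntheticSpec(graph_params={"n": 5, "p": 1.0}))
        assert g.number_of_edges() == 10

    def test_fixed_edge_list_passthrough(self):
        edges = [(0, 1), (1, 2)]
        g = gen_ppi(SyntheticSpec(graph_model="fixed_edge_list",
                                  graph_params={"edges": edges}))
        assert sorted(g.edges) == edges

    def test_no_self_loops_and_scores_in_range(self):
        g = gen_ppi(SyntheticSpec(seed=2, graph_params={"n": 30, "p": 0.2}))
        assert all(a != b for a, b in g.edges)
        assert all(0.9 < g.edges[e]["score"] <= 1.0 for e in g.edges)

    def test_node_relabelling(self):
        labels = [f"G{i}" for i in range(10)]
        g = gen_ppi(SyntheticSpec(graph_params={"n": 10, "p": 0.5}), nodes=labels)
        assert set(g.nodes) == set(labels)


class TestAnnotations:
    def setup_method(self):
        self.background = TargetSet.from_symbols([f"G{i:05d}" for i in range(300)])
        self.study = TargetSet.from_symbols([f"G{i:05d}" for i in range(40)])

    def test_study_outside_background_rejected(self):
        stray = TargetSet.from_symbols(["ZZZ"])
        with pytest.raises(ValueError, match="subset"):
            gen_annotations(SyntheticSpec(), stray, self.background)

    def test_effect_one_term_is_all_study_genes(self):
        spec = SyntheticSpec(
            seed=4, n_terms=5,
            planted_terms=[PlantedTerm("T0001", effect=1.0, size=60, category="BP")],
        )
        coll = gen_annotations(spec, self.study, self.background)
        term = next(t for t in coll.terms if t.term_id == "T0001")
        assert self.study.members <= term.members
        assert len(term.members) == 60

    def test_effect_zero_draws_from_whole_background(self):
        spec = SyntheticSpec(seed=4, n_terms=6)
        coll = gen_annotations(spec, self.study, self.background)
        assert all(t.members <= self.background.members for t in coll.terms)

    def test_seeded_repeat_identical(self):
        spec = SyntheticSpec(seed=9, n_terms=8)
        a = gen_annotations(spec, self.study, self.background)
        b = gen_annotations(spec, self.study, self.background)
        assert [(t.term_id, t.members) for t in a.terms] == [
            (t.term_id, t.members) for t in b.terms
        ]


class TestTrajectory:
    def test_noise_free_plateau_exact(self):
        spec = SyntheticSpec(trajectory_params=TrajectoryParams(
            equilibration_time=10.0, plateau_level=0.4, noise_sd=0.0,
            total_time=30.0, dt=0.5))
        s = gen_trajectory(spec)
        post = s.times >= 10.0
        assert np.all(s.values[post] == 0.4)
        assert np.all(s.values[~post] < 0.4)

    def test_zero_equilibration_time(self):
        spec = SyntheticSpec(trajectory_params=TrajectoryParams(
            equilibration_time=0.0, plateau_level=0.3, noise_sd=0.0))
        s = gen_trajectory(spec)
        assert np.all(s.values == 0.3)

    def test_plateau_noise_magnitude(self):
        spec = SyntheticSpec(seed=6, trajectory_params=TrajectoryParams(
            equilibration_time=5.0, plateau_level=1.0, noise_sd=0.05,
            total_time=55.0, dt=0.1))
        s = gen_trajectory(spec)
        post = s.values[s.times >= 5.0]
        assert np.std(post, ddof=1) == pytest.approx(0.05, rel=0.2)


class TestEnergyTable:
    def test_totals_reconstruct_by_plain_addition(self):
        rows = gen_energy_table(SyntheticSpec(seed=12))
        for row in mmpbsa_totals(rows):
            assert row.mm == pytest.approx(row.vdw + row.cou, abs=1e-12)
            assert row.delta_g == pytest.approx(
                row.vdw + row.cou + row.pb + row.sa + row.minus_t_delta_s, abs=1e-12
            )

    def test_zero_ranges_give_zero_totals(self):
        spec = SyntheticSpec(energy_params=EnergyParams(
            vdw_range=(0, 0), cou_range=(0, 0), pb_range=(0, 0),
            sa_range=(0, 0), minus_t_delta_s_range=(0, 0)))
        for row in mmpbsa_totals(gen_energy_table(spec)):
            assert row.delta_g == 0.0

    def test_components_within_ranges(self):
        spec = SyntheticSpec(seed=3)
        ep = spec.energy_params
        for row in gen_energy_table(spec):
            assert ep.vdw_range[0] <= row.vdw <= ep.vdw_range[1]
            assert ep.pb_range[0] <= row.pb <= ep.pb_range[1]


class TestDockingPoseGeneration:
    def test_pose_one_is_best_per_pair(self):
        poses = gen_docking_poses(SyntheticSpec(seed=2), ["L1", "L2"], ["R1", "R2"],
                                  n_poses=10)
        assert len(poses) == 40
        for lig in ("L1", "L2"):
            for rec in ("R1", "R2"):
                pair = [p for p in poses if p.ligand == lig and p.receptor == rec]
                best = min(pair, key=lambda p: p.affinity)
                assert best.pose_index == 1
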