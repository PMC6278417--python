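"""Elimination rules, per-run pre-selection, and screening invariants."""

import itertools

import pytest

import poserank as pr
from poserank.screening import ReasonCode, SimilarityEps


def make_pose(i=1, run=1, ligand="lig", dist=4.0, e_inter=-80.0,
              e_hbond=-2.0, residues=("Ser203",)):
    return pr.PoseRecord(ligand, run, f"run{run}_p{i}", dist, e_inter,
                         e_hbond, residues=residues)


SITE = {"Ser203", "His447", "Trp86"}


class TestEliminationRules:
    def test_positive_intermolecular_energy_removed(self):
        rep = pr.apply_elimination_rules([make_pose(e_inter=5.0)], SITE)
        assert rep.kept == []
        assert rep.removed[0][1] is ReasonCode.POSITIVE_E_INTER

    def test_positive_hbond_energy_removed(self):
        rep = pr.apply_elimination_rules([make_pose(e_hbond=0.3)], SITE)
        assert rep.removed[0][1] is ReasonCode.POSITIVE_E_HBOND

    def test_zero_energy_is_kept(self):
        # literal reading of "positive": exactly 0 survives rules 1-2
        rep = pr.apply_elimination_rules(
            [make_pose(e_inter=-1.0, e_hbond=0.0)], SITE)
        assert len(rep.kept) == 1

    def test_first_triggered_rule_recorded(self):
        rep = pr.apply_elimination_rules(
            [make_pose(e_inter=5.0, e_hbond=5.0)], SITE)
        assert rep.removed[0][1] is ReasonCode.POSITIVE_E_INTER

    def test_no_active_site_contact_removed(self):
        rep = pr.apply_elimination_rules(
            [make_pose(residues=("Pro232",))], SITE)
        assert rep.removed[0][1] is ReasonCode.NO_ACTIVE_SITE_CONTACT

    def test_residue_match_case_insensitive(self):
        rep = pr.apply_elimination_rules(
            [make_pose(residues=(" ser203 ",))], SITE)
        assert len(rep.kept) == 1

    def test_rule3_disabled_without_site(self):
        rep = pr.apply_elimination_rules([make_pose(residues=())], None)
        assert len(rep.kept) == 1

    def test_empty_active_site_is_config_error(self):
        with pytest.raises(pr.ConfigError):
            pr.apply_elimination_rules([make_pose()], set())

    def test_empty_input(self):
        rep = pr.apply_elimination_rules([], SITE)
        assert rep.kept == [] and rep.removed == []

    def test_duplicate_pair_keeps_first(self):
        a = make_pose(i=1)
        b = make_pose(i=2)  # identical criterion values
        rep = pr.apply_elimination_rules([a, b], SITE)
        assert rep.kept == [a]
        assert rep.removed == [(b, ReasonCode.SIMILAR_DUPLICATE)]

    def test_duplicates_match_brute_force_scan(self, rng):
        """Rule 4 agrees with an exhaustive pairwise duplicate scan."""
        eps = SimilarityEps(0.05, 0.5, 0.5, 0)
        poses = [make_pose(i=i,
                           dist=float(rng.choice([4.0, 4.02, 5.0])),
                           e_inter=float(rng.choice([-80.0, -80.2, -90.0])),
                           e_hbond=float(rng.choice([-2.0, -2.1])),
                           residues=("Ser203",) * int(rng.choice([1, 2])))
                 for i in range(12)]
        rep = pr.apply_elimination_rules(poses, SITE, eps)

        def similar(a, b):
            return all(abs(x - y) <= e for x, y, e in zip(
                a.criterion_values(), b.criterion_values(), eps.as_tuple()))

        expected_kept = []
        for p in poses:
            if not any(similar(k, p) for k in expected_kept):
                expected_kept.append(p)
        assert rep.kept == expected_kept

    def test_partition_is_exact(self, rng):
        spec = pr.PoseGenSpec(n_ligands=1, n_runs=3, poses_per_run=10,
                              seed=7)
        poses = pr.gen_pose_tables(spec)
        rep = pr.apply_elimination_rules(poses, SITE)
        assert rep.n_input == len(poses)
        kept_ids = {id(p) for p in rep.kept}
        removed_ids = {id(p) for p, _ in rep.removed}
        assert not kept_ids & removed_ids

    def test_screen_is_idempotent(self):
        spec = pr.PoseGenSpec(seed=11)
        poses = pr.gen_pose_tables(spec)
        first = pr.apply_elimination_rules(poses,
                                           pr.DEFAULT_ACTIVE_SITE)
        second = pr.apply_elimination_rules(first.kept,
                                            pr.DEFAULT_ACTIVE_SITE)
        assert second.kept == first.kept and second.removed == []


class TestSelectRunBest:
    def test_lexicographic_selection(self):
        poses = [make_pose(i=1, dist=5.19, e_inter=-81.0),
                 make_pose(i=2, dist=4.50, e_inter=-94.0),
                 make_pose(i=3, dist=4.50, e_inter=-78.0)]
        [best] = pr.select_run_best(poses)
        assert best.distance_OP == 4.50 and best.e_inter == -94.0

    def test_matches_brute_force(self, rng):
        poses = [make_pose(i=i, run=int(rng.integers(1, 4)),
                           dist=float(rng.uniform(3.5, 6.0)),
                           e_inter=float(rng.uniform(-130, -70)))
                 for i in range(40)]
        got = pr.select_run_best(poses)
        for run, group in itertools.groupby(
                sorted(poses, key=lambda p: p.run_id),
                key=lambda p: p.run_id):
            group = list(group)
            best = min(group, key=lambda p: (p.distance_OP, p.e_inter))
            [sel] = [p for p in got if p.run_id == run]
            assert sel == best

    def test_singleton_run(self):
        p = make_pose()
        assert pr.select_run_best([p]) == [p]

    def test_tie_broken_by_input_order(self):
        a = make_pose(i=1)
        b = make_pose(i=2)  # identical distance and energy
        assert pr.select_run_best([a, b]) == [a]

    def test_one_survivor_per_run_at_campaign_scale(self):
        spec = pr.PoseGenSpec(n_ligands=1, n_runs=10, poses_per_run=30,
                              fraction_fail_rule1=0, fraction_fail_rule2=0,
                              fraction_fail_rule3=0, fraction_duplicates=0,
                              seed=3)
        poses = pr.gen_pose_tables(spec)
        assert len(poses) == 300
        assert len(pr.select_run_best(poses)) == 10

    def test_output_ordered_by_run(self):
        poses = [make_pose(i=1, run=3), make_pose(i=2, run=1),
                 make_pose(i=3, run=2)]
        assert [p.run_id for p in pr.select_run_best(poses)] == [1, 2, 3]


class TestScreenPipeline:
    def test_orders_cover_same_runs(self):
        spec = pr.PoseGenSpec(n_ligands=2, n_runs=5, poses_per_run=8,
                              seed=5)
        poses = pr.gen_pose_tables(spec)
        for order in ("rules_then_best", "best_then_rules"):
            rep = pr.screen_poses(poses, pr.DEFAULT_ACTIVE_SITE,
                                  order=order)
            assert rep.n_input == len(poses)
            assert len(rep.kept) <= 2 * 5

    def test_unknown_order_rejected(self):
        with pytest.raises(pr.ConfigError):
            pr.screen_poses([], None, order="sideways")
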