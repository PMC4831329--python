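"""Airway-tree module: morphometry loading, generation, scaling, narrowing."""

import numpy as np
import pandas as pd
import pytest

import lungsim as ls
from lungsim.errors import (
    DomainError,
    FormatError,
    InfeasibleTreeError,
    LookupIdError,
    ValidationError,
)
from lungsim.morphometry import MorphometryTable

from conftest import make_tree


class TestMorphometry:
    def test_packaged_table_counts(self, morph26):
        assert morph26.n_generations == 26
        last = morph26.row(26)
        assert last["branches"] == 108
        assert last["terminal_branches"] == 108
        assert morph26.total_terminals == 32447

    def test_single_row_table_is_valid(self):
        t = MorphometryTable(
            pd.DataFrame(
                {
                    "generation": [1],
                    "branches": [1],
                    "terminal_branches": [1],
                    "d_mean": [14.12],
                    "d_max": [14.12],
                    "d_min": [14.12],
                    "d_std": [0.0],
                }
            )
        )
        assert t.total_branches == 1

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"generation": [1], "branches": [1]}).to_csv(path, index=False)
        with pytest.raises(FormatError):
            ls.load_morphometry(path)

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda f: f.assign(generation=[1, 3]),  # non-contiguous generations
            lambda f: f.assign(d_mean=[-1.0, 2.0]),  # negative diameter
            lambda f: f.assign(terminal_branches=[5, 2]),  # terminals > branches
            lambda f: f.assign(d_min=[5.0, 5.0]),  # d_min > d_mean
        ],
    )
    def test_invalid_tables_raise(self, mutate):
        base = pd.DataFrame(
            {
                "generation": [1, 2],
                "branches": [1, 2],
                "terminal_branches": [0, 2],
                "d_mean": [10.0, 2.0],
                "d_max": [10.0, 3.0],
                "d_min": [10.0, 1.0],
                "d_std": [0.0, 0.5],
            }
        )
        with pytest.raises(ValidationError):
            MorphometryTable(mutate(base))

    def test_csv_round_trip_with_unit_suffixes(self, tmp_path, morph26):
        path = tmp_path / "morph.csv"
        frame = morph26.frame.rename(columns={"d_mean": "d_mean_mm"})
        frame.to_csv(path, index=False)
        again = ls.load_morphometry(path)
        pd.testing.assert_frame_equal(again.frame, morph26.frame)


class TestGenerateTree:
    def test_fixture_tree_counts(self, fixture_tree, morph26):
        assert fixture_tree.n_terminals == 32447
        assert fixture_tree.n_branches == morph26.total_branches

    def test_single_branch_table(self):
        t = MorphometryTable(
            pd.DataFrame(
                {
                    "generation": [1],
                    "branches": [1],
                    "terminal_branches": [1],
                    "d_mean": [14.12],
                    "d_max": [14.12],
                    "d_min": [14.12],
                    "d_std": [0.0],
                }
            )
        )
        tree = ls.generate_tree(t, seed=0)
        assert tree.n_branches == 1
        assert tree.is_terminal[tree.root_id]

    def test_toy_table_exhaustive_traversal(self, toy_table):
        tree = ls.generate_tree(toy_table, seed=5)
        # brute-force traversal of the generated structure
        children = tree.children_lists()
        seen, leaves = [], []
        stack = [tree.root_id]
        while stack:
            b = stack.pop()
            seen.append(b)
            if not children[b]:
                leaves.append(b)
            stack.extend(children[b])
        assert len(seen) == 7
        assert len(leaves) == 4
        assert all(tree.generation[b] == 3 for b in leaves)

    def test_deterministic_under_seed(self, toy_table, morph26):
        a = ls.generate_tree(morph26, seed=11)
        b = ls.generate_tree(morph26, seed=11)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())
        c = ls.generate_tree(toy_table, seed=3)
        d = ls.generate_tree(toy_table, seed=4)
        assert not c.to_frame().equals(d.to_frame())

    def test_infeasible_counts_raise(self):
        bad = MorphometryTable(
            pd.DataFrame(
                {
                    "generation": [1, 2],
                    "branches": [1, 3],  # > 2 children of a single parent
                    "terminal_branches": [0, 3],
                    "d_mean": [10.0, 3.0],
                    "d_max": [10.0, 4.0],
                    "d_min": [10.0, 2.0],
                    "d_std": [0.0, 0.5],
                }
            )
        )
        with pytest.raises(InfeasibleTreeError):
            ls.generate_tree(bad, seed=0)

    def test_subtrees_are_spatially_compact(self, morph26):
        # the two generation-2 subtrees must occupy disjoint x half-spaces
        tree = ls.generate_tree(morph26, seed=1)
        kids = tree.children_lists()
        g2 = kids[tree.root_id]
        assert len(g2) == 2
        mids = tree.midpoints_mm
        sub_x = [mids[tree.descendants([b]), 0] for b in g2]
        hi0, lo1 = sub_x[0].max(), sub_x[1].min()
        assert hi0 <= lo1 or sub_x[1].max() <= sub_x[0].min()


class TestSummary:
    def test_round_trip_counts_and_means(self, fixture_tree, morph26):
        summary = ls.tree_summary(fixture_tree)
        np.testing.assert_array_equal(summary.branch_counts, morph26.branch_counts)
        np.testing.assert_array_equal(summary.terminal_counts, morph26.terminal_counts)
        # per-generation mean diameters within 2 standard errors of the draw
        for g in range(1, 27):
            row_in, row_out = morph26.row(g), summary.row(g)
            se = row_in["d_std"] / np.sqrt(row_in["branches"])
            assert abs(row_out["d_mean"] - row_in["d_mean"]) <= 2 * se + 1e-9

    def test_single_branch_summary(self):
        tree = make_tree([{"parent": None, "d": 10.0, "l": 50.0}])
        s = ls.tree_summary(tree)
        assert s.total_branches == 1 and s.total_terminals == 1

    def test_narrowing_reduces_generation_minimum(self, toy_table):
        tree = ls.generate_tree(toy_table, seed=2)
        target = int(np.flatnonzero(tree.generation == 3)[0])
        narrowed = ls.narrow_branches(tree, [target], 0.5)
        before = ls.tree_summary(tree).row(3)["d_min"]
        after = ls.tree_summary(narrowed).row(3)["d_min"]
        assert after < before


class TestScaleAndNarrow:
    def test_frc_scaling_volume_ratio(self, seven_branch_tree):
        scaled = ls.scale_to_frc(seven_branch_tree, 0.8)
        ratio = scaled.total_volume_mm3() / seven_branch_tree.total_volume_mm3()
        assert ratio == pytest.approx(0.512, rel=1e-12)
        assert round(ratio, 1) == 0.5

    def test_scale_identity_and_cube_law(self, seven_branch_tree):
        same = ls.scale_to_frc(seven_branch_tree, 1.0)
        np.testing.assert_allclose(same.diameter_mm, seven_branch_tree.diameter_mm)
        half = ls.scale_to_frc(seven_branch_tree, 0.5)
        assert half.total_volume_mm3() / seven_branch_tree.total_volume_mm3() == (
            pytest.approx(0.125, rel=1e-12)
        )

    @pytest.mark.parametrize("factor", [0.0, -0.5, 1.5])
    def test_scale_domain_errors(self, seven_branch_tree, factor):
        with pytest.raises(DomainError):
            ls.scale_to_frc(seven_branch_tree, factor)

    def test_narrow_poiseuille_factors(self, seven_branch_tree):
        tree = seven_branch_tree
        for factor, expected in [(0.1, 1e4), (0.5, 16.0)]:
            narrowed = ls.narrow_branches(tree, [3], factor)
            r0 = ls.poiseuille_resistance(tree.branch(3))
            r1 = ls.poiseuille_resistance(narrowed.branch(3))
            assert r1 / r0 == pytest.approx(expected, rel=1e-9)

    def test_narrow_identity_and_untouched_branches(self, seven_branch_tree):
        same = ls.narrow_branches(seven_branch_tree, [2], 1.0)
        np.testing.assert_allclose(same.diameter_mm, seven_branch_tree.diameter_mm)
        narrowed = ls.narrow_branches(seven_branch_tree, [2], 0.3)
        mask = np.ones(7, dtype=bool)
        mask[2] = False
        np.testing.assert_allclose(
            narrowed.diameter_mm[mask], seven_branch_tree.diameter_mm[mask]
        )

    def test_narrow_restore_round_trip(self, seven_branch_tree):
        factor = 0.37
        down = ls.narrow_branches(seven_branch_tree, [0, 4, 6], factor)
        # inverse factor > 1 is applied directly on the arrays
        up = down.copy()
        up.diameter_mm[[0, 4, 6]] /= factor
        np.testing.assert_allclose(
            up.diameter_mm, seven_branch_tree.diameter_mm, rtol=1e-12
        )

    def test_narrow_errors(self, seven_branch_tree):
        with pytest.raises(LookupIdError):
            ls.narrow_branches(seven_branch_tree, [99], 0.5)
        with pytest.raises(DomainError):
            ls.narrow_branches(seven_branch_tree, [1], 0.0)


class TestSerialisation:
    def test_csv_round_trip(self, tmp_path, toy_table):
        tree = ls.generate_tree(toy_table, seed=9)
        path = tmp_path / "tree.csv"
        tree.to_csv(path)
        again = ls.AirwayTree.from_csv(path)
        pd.testing.assert_frame_equal(tree.to_frame(), again.to_frame())

    def test_json_round_trip(self, tmp_path, seven_branch_tree):
        path = tmp_path / "tree.json"
        seven_branch_tree.to_json(path)
        again = ls.AirwayTree.from_json(path)
        np.testing.assert_allclose(again.diameter_mm, seven_branch_tree.diameter_mm)

    def test_validation_rejects_broken_structure(self, seven_branch_tree):
        broken = seven_branch_tree.copy()
        broken.generation[3] = 5  # child generation != parent + 1
        with pytest.raises(ValidationError):
            broken.validate()
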