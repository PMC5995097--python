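"""Generator geometry, noise, pruning operators and parameter recovery."""

import math

import numpy as np
import pytest

from allomtree import (SynthConfig, generate, metrics_table, prune,
                       read_branch_table, rma_fit, subtree_metrics,
                       wbe_geometry, write_synthetic)


def segment_fit(tree, y="mass", x="diameter"):
    m = metrics_table(tree, levels=("segment",))
    return rma_fit(m[x], m[y], y_variable=y, x_variable=x)


class TestGenerate:
    def test_full_binary_tree_counts_and_exact_geometry(self):
        cfg = SynthConfig(n_children=2, levels=3, root_diameter=8.0,
                          root_length=50.0, beta=0.7, gamma=0.6)
        tree, truth = generate(cfg)
        assert len(tree) == 7
        depth = tree.depth_map()
        for r in tree:
            assert r.diameter == pytest.approx(8.0 * 0.7 ** depth[r.branch_id])
            assert r.length == pytest.approx(50.0 * 0.6 ** depth[r.branch_id])
        assert truth["n_branches"] == 7

    @pytest.mark.parametrize("beta, gamma, expect", [
        (2 ** -0.5, 2 ** (-1 / 3), 2 / 3),
        (2 ** -0.5, 2 ** -0.5, 1.0),  # area-preserving, flow-like geometry
    ])
    def test_closed_form_exponent(self, beta, gamma, expect):
        cfg = SynthConfig(beta=beta, gamma=gamma)
        assert cfg.a_true == pytest.approx(expect, abs=1e-12)
        assert generate(cfg)[1]["a_true"] == pytest.approx(expect, abs=1e-12)

    def test_same_seed_same_records(self):
        cfg = SynthConfig(levels=5, noise_sigma=0.1, prune_fraction=0.2, seed=9)
        t1, _ = generate(cfg)
        t2, _ = generate(cfg)
        assert [(r.branch_id, r.diameter, r.length, r.mass) for r in t1] \
            == [(r.branch_id, r.diameter, r.length, r.mass) for r in t2]

    @pytest.mark.parametrize("bad", [
        {"beta": 1.0}, {"beta": 0.0}, {"gamma": 1.2}, {"levels": 1},
        {"prune_fraction": 1.0}, {"noise_sigma": -0.1},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            generate(SynthConfig(**bad))

    def test_mass_is_density_times_cylinder_volume_when_noiseless(self):
        tree, _ = generate(SynthConfig(levels=4, wood_density=0.55))
        for r in tree:
            vol = math.pi * (r.diameter / 2) ** 2 * r.length
            assert r.mass == pytest.approx(0.55 * vol, rel=1e-12)


class TestWbeGeometry:
    def test_noiseless_segment_slopes_exact(self):
        tree, _ = wbe_geometry(2, 8)
        assert len(tree) == 255
        assert segment_fit(tree, "mass", "diameter").a_hat \
            == pytest.approx(8 / 3, abs=1e-9)
        assert segment_fit(tree, "length", "diameter").a_hat \
            == pytest.approx(2 / 3, abs=1e-9)

    def test_root_subtree_mass_matches_brute_force_volumes(self):
        tree, _ = wbe_geometry(2, 6, wood_density=0.6)
        expect = 0.6 * sum(math.pi * (r.diameter / 2) ** 2 * r.length
                           for r in tree)
        sub = subtree_metrics(tree)
        assert sub.at[tree.root_id, "mass"] == pytest.approx(expect, rel=1e-12)

    def test_exponent_invariant_to_depth(self):
        for levels in (4, 6, 8):
            tree, _ = wbe_geometry(2, levels)
            assert segment_fit(tree).a_hat == pytest.approx(8 / 3, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_recovery_within_tolerance(self, seed):
        tree, truth = wbe_geometry(2, 8, noise_sigma=0.05, seed=seed)
        assert len(tree) >= 255
        assert segment_fit(tree, "mass", "diameter").a_hat \
            == pytest.approx(8 / 3, abs=0.05)
        assert segment_fit(tree, "length", "diameter").a_hat \
            == pytest.approx(2 / 3, abs=0.05)


class TestPrune:
    def test_noop_returns_identical_tree(self):
        tree, _ = generate(SynthConfig(levels=4))
        pruned, removed = prune(tree, prune_fraction=0.0, tip_trim=0.0, seed=0)
        assert removed == 0.0
        assert [(r.branch_id, r.length, r.mass) for r in pruned] \
            == [(r.branch_id, r.length, r.mass) for r in tree]

    def test_total_removal_leaves_only_root(self):
        tree, _ = generate(SynthConfig(n_children=3, levels=4))
        pruned, removed = prune(tree, prune_fraction=0.999999,
                                prune_min_depth=1, seed=1)
        assert len(pruned) == 1
        assert pruned.root_id == tree.root_id
        root_share = tree.root.mass / sum(r.mass for r in tree)
        assert removed == pytest.approx(1.0 - root_share, rel=1e-12)

    def test_tip_trim_removed_fraction_by_hand(self):
        from conftest import make_record
        from allomtree import TreeArchitecture
        tree = TreeArchitecture.from_records([
            make_record("r", None, mass=90.0, length=10.0),
            make_record("a", "r", mass=10.0, length=5.0),
        ])
        pruned, removed = prune(tree, tip_trim=0.5, seed=0)
        assert removed == pytest.approx(0.05, abs=1e-12)  # 5 g of 100 g
        assert pruned.record("a").length == pytest.approx(2.5)
        assert pruned.record("r").length == pytest.approx(10.0)

    def test_removed_fraction_linear_in_tip_trim(self):
        tree, _ = generate(SynthConfig(levels=5, noise_sigma=0.1, seed=4))
        base = prune(tree, tip_trim=0.1, seed=0)[1]
        for k in (2, 3, 5):
            assert prune(tree, tip_trim=0.1 * k / (1), seed=0)[1] \
                == pytest.approx(base * k, rel=1e-9)

    def test_removed_fraction_monotone_in_prune_fraction(self):
        tree, _ = generate(SynthConfig(levels=5, seed=2))
        seeds = range(50)
        means = []
        for pf in (0.1, 0.3, 0.5, 0.8):
            means.append(np.mean([prune(tree, prune_fraction=pf, seed=s)[1]
                                  for s in seeds]))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_prune_min_depth_protects_shallow_branches(self):
        tree, _ = generate(SynthConfig(n_children=2, levels=4))
        pruned, _ = prune(tree, prune_fraction=0.999999, prune_min_depth=2,
                          seed=3)
        assert set(pruned.branch_ids()) \
            == {b for b, d in tree.depth_map().items() if d < 2}


class TestRoundTrip:
    def test_written_table_reingests_identically(self, tmp_path):
        cfg = SynthConfig(levels=5, noise_sigma=0.08, seed=13)
        table = tmp_path / "synth.csv"
        truth_file = tmp_path / "truth.yml"
        tree, truth = write_synthetic(cfg, table, truth_path=truth_file)
        back = read_branch_table(table)
        assert len(back) == 1
        assert len(back[0]) == len(tree)
        assert back[0].parent_child_pairs() == tree.parent_child_pairs()
        import yaml
        stored = yaml.safe_load(truth_file.read_text())
        assert stored["a_true"] == pytest.approx(truth["a_true"])

    def test_noiseless_recovery_after_roundtrip(self, tmp_path):
        table = tmp_path / "synth.csv"
        write_synthetic(SynthConfig(levels=7), table)
        tree = read_branch_table(table)[0]
        assert segment_fit(tree, "length", "diameter").a_hat \
            == pytest.approx(SynthConfig().a_true, abs=1e-9)
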