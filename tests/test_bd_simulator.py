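"""Gillespie simulator: waiting times, conditioning, genealogies, Newick."""

import math

import numpy as np
import pytest
from scipy import stats

from bdcoal import bd_analytic as bda
from bdcoal import bd_simulator as sim
from bdcoal.params import BDParams
from conftest import ks_distance


class TestTrajectory:
    def test_pure_birth_never_shrinks(self):
        p = BDParams(0.5, 0.0, 8.0)
        traj = sim.simulate_trajectory(p, "survival", rng_seed=3)
        assert np.all(traj.event_deltas == 1)
        assert np.all(np.diff(traj.sizes()) == 1)

    def test_first_event_waiting_time(self):
        """From one individual the first event is Exp(lambda + mu)."""
        p = BDParams(0.5, 0.25, 20.0)
        firsts = []
        for k in range(4000):
            traj = sim.simulate_trajectory(p, "none", rng_seed=k)
            if len(traj.event_times):
                firsts.append(traj.event_times[0])
        res = stats.kstest(firsts, stats.expon(scale=1.0 / 0.75).cdf)
        assert res.pvalue > 0.001

    def test_birth_fraction(self):
        """Each event is a birth with probability lambda/(lambda+mu)."""
        p = BDParams(0.5, 0.25, 10.0)
        trajs, _ = sim.simulate_trajectories(p, 400, "none", rng_seed=11)
        deltas = np.concatenate([t.event_deltas for t in trajs])
        k = int(np.sum(deltas == 1))
        n = len(deltas)
        phat, pexp = k / n, 0.5 / 0.75
        assert abs(phat - pexp) < 3 * math.sqrt(pexp * (1 - pexp) / n)

    def test_survival_acceptance_rate(self, std_params):
        """Rejection acceptance fraction estimates 1 - p0(T)."""
        n = 2000
        _, attempts = sim.simulate_trajectories(std_params, n, "survival", rng_seed=5)
        pexp = 1.0 - bda.p0(std_params.origin_time, std_params)
        phat = n / attempts
        se = math.sqrt(pexp * (1 - pexp) / attempts)
        assert abs(phat - pexp) < 3 * se

    def test_conditioned_final_size_mean(self):
        p = BDParams(0.5, 0.45, 6.0)
        trajs, _ = sim.simulate_trajectories(p, 4000, "survival", rng_seed=17)
        finals = np.array([t.final_size for t in trajs], float)
        expected = bda.expected_popsize_conditioned(6.0, p)
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 3 * se

    def test_unconditioned_mean_counts_extinct_as_zero(self):
        p = BDParams(0.5, 0.3, 5.0)
        trajs, _ = sim.simulate_trajectories(p, 6000, "none", rng_seed=23)
        finals = np.array([t.final_size for t in trajs], float)
        expected = math.exp(0.2 * 5.0)
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 3 * se

    def test_condition_enforced(self, std_params):
        for k in range(50):
            traj = sim.simulate_trajectory(std_params, "at_least_two_at_T", k)
            assert traj.final_size >= 2
            assert np.all(traj.sizes() > 0)

    def test_size_at_and_tsv(self, std_params, tmp_path):
        traj = sim.simulate_trajectory(std_params, "survival", rng_seed=1)
        assert traj.size_at(0.0) == 1
        assert traj.size_at(std_params.origin_time) == traj.final_size
        path = tmp_path / "traj.tsv"
        traj.to_tsv(str(path))
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "time\tevent\tpopsize_after"
        assert len(lines) == len(traj.event_times) + 1

    def test_rejection_guard_validates_condition(self, std_params):
        with pytest.raises(ValueError):
            sim.simulate_trajectory(std_params, "bogus", 0)


class TestTree:
    def test_tip_count_matches_geometric_law(self, std_params):
        """Extant tip counts follow the survivor-count geometric, given >= 2."""
        counts = {}
        n = 3000
        for k in range(n):
            t = sim.simulate_tree(std_params, rng_seed=k)
            counts[t.n_extant] = counts.get(t.n_extant, 0) + 1
        b = bda.depth_cdf(std_params.origin_time, std_params)
        ks = np.arange(2, 200)
        probs = (1 - b) * b ** (ks - 2)  # geometric conditioned on >= 2
        probs /= probs.sum()
        # bin the tail so expected counts stay above 5
        edges = [2, 3, 4, 6, 9, 14, 22, 35, 60, 200]
        obs, exp = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            obs.append(sum(v for key, v in counts.items() if lo <= key < hi))
            exp.append(n * probs[(ks >= lo) & (ks < hi)].sum())
        res = stats.chisquare(obs, np.array(exp) * sum(obs) / sum(exp))
        assert res.pvalue > 0.001

    def test_yule_mean_tip_count(self):
        p = BDParams(0.5, 0.0, 4.0)
        tips = np.array(
            [sim.simulate_tree(p, "survival", rng_seed=k).n_extant for k in range(3000)],
            float,
        )
        se = tips.std(ddof=1) / math.sqrt(len(tips))
        assert abs(tips.mean() - math.exp(0.5 * 4.0)) < 3 * se

    def test_newick_round_trip(self, std_params):
        dendropy = pytest.importorskip("dendropy")
        tree = sim.simulate_tree(std_params, rng_seed=9)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_nodes() if leaf.taxon}
        assert taxa == {f"t{i+1}" for i in range(tree.n_extant)}
        # total branch length is preserved by serialization
        own_total = float(np.sum(tree.end_time - tree.birth_time))
        parsed_total = sum(
            e.length for e in parsed.preorder_edge_iter() if e.length is not None
        )
        assert parsed_total == pytest.approx(own_total, abs=1e-12 * len(tree.parent))
        # every extant tip sits at depth T from the root
        for leaf in parsed.leaf_nodes():
            if leaf.taxon:
                depth = leaf.distance_from_root()
                assert depth == pytest.approx(std_params.origin_time, abs=1e-9)

    def test_internal_nodes_are_binary(self, std_params):
        tree = sim.simulate_tree(std_params, rng_seed=21)
        kids = tree.children_lists()
        for lst in kids:
            assert len(lst) in (0, 2)

    def test_two_tip_tree_pair_time_is_deterministic(self):
        p = BDParams(0.5, 0.0, 0.5)
        for k in range(200):
            tree = sim.simulate_tree(p, rng_seed=k)
            if tree.n_extant != 2:
                continue
            tau = sim.sample_pair_coalescence(tree, rng_seed=k)
            # with exactly two tips, the pair split is the first (root) split
            first_split = np.min(tree.end_time[tree.end_time < 0.5])
            assert tau == pytest.approx(0.5 - first_split, abs=1e-12)

    def test_pair_sampling_needs_two_tips(self, std_params):
        tree = sim.simulate_tree(std_params, rng_seed=2)
        lone = sim.SimulatedTree(
            parent=np.array([-1]), birth_time=np.array([0.0]),
            end_time=np.array([10.0]), duration=10.0, extant=np.array([0]),
        )
        with pytest.raises(ValueError):
            sim.sample_pair_coalescence(lone, 0)
        assert tree.n_extant >= 2  # fixture tree usable


class TestPairOracle:
    def test_pair_times_match_analytic_cdf(self, std_params):
        """Moderate-n cross-check of the tree oracle against F_bd."""
        n = 4000
        taus = np.array(
            [
                sim.sample_pair_coalescence(
                    sim.simulate_tree(std_params, rng_seed=k), rng_seed=10_000_000 + k
                )
                for k in range(n)
            ]
        )
        d = ks_distance(taus, lambda x: bda.F_bd(x, std_params))
        assert d < 1.95 / math.sqrt(n)  # ~ KS 99.9% band

    def test_exchangeability_across_seeds(self, std_params):
        a = [
            sim.sample_pair_coalescence(sim.simulate_tree(std_params, rng_seed=k), k + 1)
            for k in range(1500)
        ]
        b = [
            sim.sample_pair_coalescence(
                sim.simulate_tree(std_params, rng_seed=50_000 + k), 60_000 + k
            )
            for k in range(1500)
        ]
        res = stats.ks_2samp(a, b)
        assert res.pvalue > 0.001
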