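import math

import numpy as np
import pytest

from ptpdelim import (
    Delimitation,
    MCMCConfig,
    SupportMap,
    all_singletons_delimitation,
    asddsv,
    asv,
    combine_runs,
    enumerate_delimitations,
    loglik_multi,
    ml_delimit,
    null_delimitation,
    parse_newick,
    random_delimitation,
    run_chain,
    simulate_dataset,
    SimulationConfig,
)
from ptpdelim.mcmc import _Chain, acceptance_probability, propose


def exact_posterior(tree, model="multi"):
    """Akaike-weight distribution over all delimitations, by enumeration."""
    from ptpdelim import score_delimitation

    weights = {}
    for d in enumerate_delimitations(tree):
        s = score_delimitation(tree, d, model)
        weights[d.coalescent_roots] = (
            0.0 if math.isinf(s.aicc) else math.exp(-s.aicc / 2.0)
        )
    z = sum(weights.values())
    return {k: v / z for k, v in weights.items()}


def exact_supports(tree, posterior):
    values = np.zeros(len(tree.nodes))
    for roots, prob in posterior.items():
        d = Delimitation(roots)
        for node in tree.nodes:
            if d.is_speciation_node(tree, node):
                values[node.id] += prob
    return values


class TestRandomDelimitation:
    def test_stop_probability_one_gives_null(self, six_tip_tree):
        d = random_delimitation(six_tip_tree, np.random.default_rng(0), p_stop=1.0)
        assert d.coalescent_roots == {six_tip_tree.root.id}

    def test_stop_probability_zero_gives_all_singletons(self, six_tip_tree):
        d = random_delimitation(six_tip_tree, np.random.default_rng(0), p_stop=0.0)
        assert d.coalescent_roots == all_singletons_delimitation(
            six_tip_tree
        ).coalescent_roots

    def test_deterministic_under_seed(self, six_tip_tree):
        a = random_delimitation(six_tip_tree, np.random.default_rng(7))
        b = random_delimitation(six_tip_tree, np.random.default_rng(7))
        assert a == b
        random_delimitation(six_tip_tree, np.random.default_rng(8)).validate(
            six_tip_tree
        )


class TestMoves:
    def test_null_state_candidates(self, worked_tree):
        chain = _Chain(worked_tree, null_delimitation(worked_tree))
        assert chain.split_cands == [worked_tree.root.id]
        assert chain.merge_cands == []

    def test_candidates_after_root_split(self, worked_tree):
        chain = _Chain(worked_tree, null_delimitation(worked_tree))
        chain.apply_split(worked_tree.root.id)
        assert sorted(chain.split_cands) == [2, 5]  # the two cherries
        assert chain.merge_cands == [worked_tree.root.id]
        chain.check_against_full_rescore()

    def test_all_singleton_state_has_no_splits(self, worked_tree):
        chain = _Chain(worked_tree, all_singletons_delimitation(worked_tree))
        assert chain.split_cands == []
        assert len(chain.merge_cands) == 2

    def test_split_then_merge_restores_state(self, six_tip_tree):
        chain = _Chain(six_tip_tree, null_delimitation(six_tip_tree))
        before = chain.score()
        chain.apply_split(six_tip_tree.root.id)
        chain.apply_merge(six_tip_tree.root.id)
        assert chain.delimitation() == null_delimitation(six_tip_tree)
        assert chain.score() == pytest.approx(before, abs=1e-12)
        chain.check_against_full_rescore()

    def test_propose_leaves_state_unchanged(self, six_tip_tree):
        rng = np.random.default_rng(1)
        chain = _Chain(six_tip_tree, null_delimitation(six_tip_tree))
        out = propose(chain, rng)
        assert chain.delimitation() == null_delimitation(six_tip_tree)
        if out is not None:
            cand, log_h = out
            cand.validate(six_tip_tree)
            assert math.isfinite(log_h)

    def test_move_graph_is_connected(self, six_tip_tree):
        # BFS over split moves reaches every delimitation from the null model
        tree = six_tip_tree
        seen = set()
        frontier = [frozenset({tree.root.id})]
        while frontier:
            roots = frontier.pop()
            if roots in seen:
                continue
            seen.add(roots)
            for rid in roots:
                node = tree.nodes[rid]
                if node.children:
                    split = (roots - {rid}) | {c.id for c in node.children}
                    frontier.append(split)
        assert seen == {d.coalescent_roots for d in enumerate_delimitations(tree)}


class TestAcceptance:
    def test_neutral_move_always_accepted(self):
        assert acceptance_probability(10.0, 10.0, 0.0) == 1.0

    def test_two_unit_aicc_penalty(self):
        assert acceptance_probability(10.0, 12.0, 0.0) == pytest.approx(
            math.exp(-1.0)
        )

    def test_inadmissible_candidate_never_accepted(self):
        assert acceptance_probability(10.0, math.inf, 0.0) == 0.0


class TestChain:
    def test_stationary_distribution_matches_enumeration(self, six_tip_tree):
        posterior = exact_posterior(six_tip_tree)
        supports = exact_supports(six_tip_tree, posterior)
        cfg = MCMCConfig(steps=200_000, burn_in=20_000, sample_every=1, seed=11)
        res = run_chain(six_tip_tree, cfg, "multi", track_delimitations=True)
        for roots, prob in posterior.items():
            assert res.delim_freqs.get(roots, 0.0) == pytest.approx(prob, abs=0.02)
        assert np.max(np.abs(res.support.values - supports)) < 0.02

    def test_incremental_score_equals_full_rescore_at_checkpoints(self, six_tip_tree):
        cfg = MCMCConfig(steps=20_000, burn_in=1_000, seed=4)
        # run_chain itself asserts at checkpoints and at the end
        run_chain(six_tip_tree, cfg, "multi", check_every=2_000)
        run_chain(six_tip_tree, cfg, "single", check_every=2_000)

    def test_single_sample_boundary(self, six_tip_tree):
        cfg = MCMCConfig(steps=11, burn_in=10, sample_every=1, seed=0)
        res = run_chain(six_tip_tree, cfg)
        assert res.support.n_samples == 1
        assert set(np.unique(res.support.values)) <= {0.0, 1.0}

    def test_identical_seeds_identical_supports(self, six_tip_tree):
        cfg = MCMCConfig(steps=5_000, burn_in=500, seed=21)
        a = run_chain(six_tip_tree, cfg)
        b = run_chain(six_tip_tree, cfg)
        assert np.array_equal(a.support.values, b.support.values)
        assert a.acceptance_rate == b.acceptance_rate


class TestDiagnostics:
    def test_asddsv_of_identical_maps_is_zero(self, six_tip_tree):
        m = SupportMap(np.full(len(six_tip_tree.nodes), 0.3), 10)
        assert asddsv([m, m], six_tip_tree) == 0.0

    def test_asddsv_hand_computed(self):
        t = parse_newick("(A:1,B:1);")
        a = SupportMap(np.array([0.0, 0.0, 0.4]), 10)
        b = SupportMap(np.array([0.0, 0.0, 0.6]), 10)
        # one inner node with f = 0.4 vs 0.6: sample sd = 0.1414...
        assert asddsv([a, b], t) == pytest.approx(math.sqrt(0.02), abs=1e-12)

    def test_asddsv_requires_two_runs(self, six_tip_tree):
        with pytest.raises(ValueError):
            asddsv([SupportMap(np.zeros(len(six_tip_tree.nodes)), 1)], six_tip_tree)

    def test_asv_perfect_agreement(self, six_tip_tree):
        ml = ml_delimit(six_tip_tree).best.delimitation
        values = np.zeros(len(six_tip_tree.nodes))
        for node in six_tip_tree.nodes:
            if ml.is_speciation_node(six_tip_tree, node):
                values[node.id] = 1.0
        assert asv(SupportMap(values, 1), ml, six_tip_tree) == 1.0

    def test_asv_half_supports(self, six_tip_tree):
        ml = ml_delimit(six_tip_tree).best.delimitation
        values = np.full(len(six_tip_tree.nodes), 0.5)
        assert asv(SupportMap(values, 1), ml, six_tip_tree) == pytest.approx(0.5)

    def test_asv_total_disagreement(self, six_tip_tree):
        ml = ml_delimit(six_tip_tree).best.delimitation
        values = np.zeros(len(six_tip_tree.nodes))
        for node in six_tip_tree.nodes:
            if not ml.is_speciation_node(six_tip_tree, node):
                values[node.id] = 1.0
        assert asv(SupportMap(values, 1), ml, six_tip_tree) == 0.0

    def test_asv_null_delimitation_uses_root_support(self):
        t = parse_newick("(A:1,B:1);")
        null = null_delimitation(t)
        values = np.array([0.0, 0.0, 0.25])
        assert asv(SupportMap(values, 1), null, t) == pytest.approx(0.75)


class TestCombineRuns:
    def test_single_run_mean_asv_is_that_run(self, six_tip_tree):
        cfg = MCMCConfig(steps=5_000, burn_in=500, runs=1, seed=3)
        report = combine_runs(six_tip_tree, cfg)
        assert report.mean_asv == pytest.approx(report.per_run_asv[0])
        assert report.asddsv_value is None

    def test_report_shape(self, six_tip_tree):
        cfg = MCMCConfig(steps=3_000, burn_in=300, runs=3, seed=9)
        report = combine_runs(six_tip_tree, cfg)
        assert len(report.per_run_asv) == 3
        assert len(report.acceptance_rates) == 3
        assert report.asddsv_value is not None
        assert report.annotated_newick.endswith(";")
        parse_newick(report.annotated_newick)  # still valid newick

    def test_deterministic_under_master_seed(self, six_tip_tree):
        cfg = MCMCConfig(steps=2_000, burn_in=200, runs=2, seed=5)
        a = combine_runs(six_tip_tree, cfg)
        b = combine_runs(six_tip_tree, cfg)
        assert a.per_run_asv == b.per_run_asv
        assert a.annotated_newick == b.annotated_newick
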