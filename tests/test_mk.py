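"""Mk model: transition probabilities, likelihood, reconstruction, origins."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import (
    balanced_tree,
    brute_force_likelihood,
    brute_force_marginals,
    random_tree,
)
from mimevo.mk import (
    MkModel,
    bayesian_ancestral,
    estimate_rate,
    log_likelihood,
    marginal_ancestral,
    origin_counts,
    origin_events,
    rate_interval,
    simulate_history,
    simulate_trait,
    transition_matrix,
)
from mimevo.trees import Phylogeny


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        m = MkModel.equal_rates(6, 0.7)
        assert np.allclose(transition_matrix(m, 0.0), np.eye(6))

    def test_two_state_closed_form(self):
        mu, t = 0.4, 1.3
        m = MkModel.equal_rates(2, mu)
        P = transition_matrix(m, t)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-2 * mu * t))

    def test_saturation_reaches_uniform(self):
        m = MkModel.equal_rates(6, 1.0)
        P = transition_matrix(m, 50.0)
        assert np.abs(P - 1 / 6).max() < 1e-9

    def test_matches_matrix_exponential(self):
        m = MkModel.equal_rates(4, 0.8)
        assert np.abs(transition_matrix(m, 0.9) - expm(m.Q * 0.9)).max() < 1e-12

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(MkModel.equal_rates(2, 1.0), -0.1)

    def test_malformed_q_rejected(self):
        with pytest.raises(ValueError):
            MkModel(k=2, Q=np.array([[0.0, 1.0], [1.0, 0.0]]))


class TestSimulation:
    def test_zero_rate_propagates_root_state(self):
        t = balanced_tree(16)
        traits = simulate_trait(t, MkModel.equal_rates(4, 0.0), seed=3)
        assert len(set(traits.values())) == 1

    def test_star_tree_saturates_to_uniform_frequencies(self):
        n = 10_000
        nwk = "(" + ",".join(f"t{i}:50.0" for i in range(n)) + ");"
        t = Phylogeny.from_newick(nwk)
        traits = simulate_trait(t, MkModel.equal_rates(4, 1.0), seed=11)
        counts = np.bincount([s - 1 for s in traits.values()], minlength=4)
        # binomial 3-sigma band around n/4
        sigma = math.sqrt(n * 0.25 * 0.75)
        assert np.abs(counts - n / 4).max() < 3 * sigma

    def test_seed_determinism(self):
        t = balanced_tree(32)
        m = MkModel.equal_rates(6, 0.8)
        assert simulate_trait(t, m, seed=7) == simulate_trait(t, m, seed=7)

    def test_history_replays_to_tip_states(self):
        """Replaying the recorded changes from the root state reproduces
        every tip state exactly."""
        t = balanced_tree(32)
        m = MkModel.equal_rates(6, 1.5)
        traits, changes, root_state = simulate_history(t, m, seed=5)
        assert len(changes) > 0
        idx = t.index()
        by_branch = {}
        for node, time, s_from, s_to in changes:
            by_branch.setdefault(node, []).append((time, s_from, s_to))
        states = {idx.root: root_state}
        stack = [idx.root]
        while stack:
            node = stack.pop()
            for child in idx.children[node]:
                s = states[node]
                for _, s_from, s_to in sorted(by_branch.get(child, [])):
                    assert s == s_from  # history is internally consistent
                    s = s_to
                states[child] = s
                stack.append(child)
        for lab, i in idx.tip_index.items():
            assert states[i] == traits[lab]

    def test_zero_rate_empty_history(self):
        t = balanced_tree(8)
        _, changes, _ = simulate_history(t, MkModel.equal_rates(3, 0.0), seed=1)
        assert changes == []


class TestLikelihood:
    def test_single_branch_closed_form(self):
        t = Phylogeny.from_newick("(A:0.7,B:0.7);")
        m = MkModel.equal_rates(2, 0.4)
        ll = log_likelihood(t, m, {"A": 1, "B": 2})
        P = transition_matrix(m, 0.7)
        expected = sum(
            0.5 * P[s, 0] * P[s, 1] for s in range(2)
        )
        assert ll == pytest.approx(math.log(expected), abs=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        """Pruning equals the exhaustive sum over internal assignments on
        50 random instances (trees ≤ 6 tips, k ≤ 3)."""
        for _ in range(50):
            n = int(rng.integers(2, 7))
            k = int(rng.integers(2, 4))
            t = random_tree(n, rng)
            mu = float(rng.uniform(0.05, 2.0))
            m = MkModel.equal_rates(k, mu)
            traits = {lab: int(rng.integers(1, k + 1)) for lab in t.tip_labels}
            if rng.uniform() < 0.3 and n > 2:  # sprinkle missing data
                traits.pop(t.tip_labels[0])
            ll = log_likelihood(t, m, traits)
            bf = brute_force_likelihood(t, m, traits)
            assert ll == pytest.approx(math.log(bf), abs=1e-10)

    def test_all_missing_gives_likelihood_one(self):
        t = balanced_tree(4)
        assert log_likelihood(t, MkModel.equal_rates(3, 0.5), {}) == pytest.approx(0.0)

    def test_unknown_tip_rejected(self):
        t = balanced_tree(4)
        with pytest.raises(ValueError, match="unknown"):
            log_likelihood(t, MkModel.equal_rates(2, 0.5), {"zz": 1})


class TestEstimateRate:
    def test_constant_trait_boundary(self):
        t = balanced_tree(8)
        with pytest.warns(UserWarning, match="boundary"):
            fit = estimate_rate(t, {lab: 2 for lab in t.tip_labels}, k=3)
        assert fit.rate == 0.0 and fit.boundary

    def test_doubling_lengths_halves_rate(self, rng):
        t = balanced_tree(64, height=1.0)
        traits = simulate_trait(t, MkModel.equal_rates(3, 0.8), seed=4)
        fit1 = estimate_rate(t, traits, k=3)
        t2 = balanced_tree(64, height=2.0)
        fit2 = estimate_rate(t2, traits, k=3)
        assert fit2.rate == pytest.approx(fit1.rate / 2, rel=1e-4)

    def test_interval_brackets_estimate(self):
        t = balanced_tree(64)
        traits = simulate_trait(t, MkModel.equal_rates(3, 0.6), seed=9)
        fit = estimate_rate(t, traits, k=3)
        lo, hi = rate_interval(t, traits, fit)
        assert lo < fit.rate < hi


class TestMarginalAncestral:
    def test_cherry_with_matching_tips(self):
        t = Phylogeny.from_newick("(A:0.5,B:0.5);")
        rec = marginal_ancestral(t, MkModel.equal_rates(3, 0.4), {"A": 2, "B": 2})
        assert rec.map_state[rec.tree_index.root] == 2

    def test_matches_brute_force_posteriors(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 6))
            k = int(rng.integers(2, 4))
            t = random_tree(n, rng)
            m = MkModel.equal_rates(k, float(rng.uniform(0.1, 1.5)))
            traits = {lab: int(rng.integers(1, k + 1)) for lab in t.tip_labels}
            rec = marginal_ancestral(t, m, traits)
            bf = brute_force_marginals(t, m, traits)
            idx = t.index()
            for node in idx.postorder:
                assert np.allclose(rec.node_probs[node], bf[node], atol=1e-10)

    def test_saturation_returns_root_prior(self):
        t = balanced_tree(8, height=1.0)
        prior = np.array([0.1, 0.2, 0.7])
        m = MkModel.equal_rates(3, 500.0, root_prior=prior)
        traits = {lab: 1 for lab in t.tip_labels}
        rec = marginal_ancestral(t, m, traits)
        assert np.allclose(rec.node_probs[rec.tree_index.root], prior, atol=1e-4)

    def test_invariant_to_tip_order_and_joint_rescaling(self, rng):
        t = random_tree(12, rng)
        traits = {lab: 1 + (i % 3) for i, lab in enumerate(t.tip_labels)}
        m = MkModel.equal_rates(3, 0.7)
        rec1 = marginal_ancestral(t, m, traits)
        # rescale lengths x2 and rate /2
        scaled = Phylogeny.from_newick(t.to_newick())
        for e in scaled._tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= 2
        rec2 = marginal_ancestral(scaled, MkModel.equal_rates(3, 0.35), traits)
        assert np.allclose(rec1.node_probs, rec2.node_probs, atol=1e-9)


class TestBayesianAncestral:
    def test_two_seeds_mostly_agree_on_map(self):
        t = balanced_tree(32)
        traits = simulate_trait(t, MkModel.equal_rates(3, 0.4), seed=21)
        kwargs = dict(k=3, generations=20_000, sample_every=20, burnin_fraction=0.25)
        r1 = bayesian_ancestral(t, traits, seed=1, **kwargs)
        r2 = bayesian_ancestral(t, traits, seed=2, **kwargs)
        idx = r1.tree_index
        internal = slice(idx.n_tips, idx.n_nodes)
        agree = (r1.map_state[internal] == r2.map_state[internal]).mean()
        assert agree >= 0.95

    def test_burnin_discards_first_quarter(self):
        t = balanced_tree(16)
        traits = simulate_trait(t, MkModel.equal_rates(2, 0.5), seed=2)
        r = bayesian_ancestral(
            t, traits, k=2, generations=1000, sample_every=10,
            burnin_fraction=0.25, seed=0,
        )
        assert len(r.rate_samples) == 75

    def test_identical_state_cherry_close_to_marginal(self):
        t = Phylogeny.from_newick("(A:0.4,B:0.4);")
        traits = {"A": 1, "B": 1}
        r = bayesian_ancestral(
            t, traits, k=2, generations=4000, sample_every=4, seed=3,
        )
        fit = estimate_rate(t, traits, k=2)
        ml = marginal_ancestral(t, MkModel.equal_rates(2, max(fit.rate, 0.05)), traits)
        root = r.tree_index.root
        assert r.node_probs[root, 0] >= ml.node_probs[root, 0] - 0.05

    def test_too_few_samples_rejected(self):
        t = balanced_tree(4)
        with pytest.raises(ValueError):
            bayesian_ancestral(t, {lab: 1 for lab in t.tip_labels},
                               generations=50, sample_every=10)


class TestOriginEvents:
    def test_constant_trait_no_events(self):
        t = balanced_tree(8).to_rtu()
        rec = marginal_ancestral(t, MkModel.equal_rates(2, 0.1),
                                 {lab: 1 for lab in t.tip_labels})
        assert origin_events(t, rec) == []

    def test_planted_single_transition_recovered(self):
        t = balanced_tree(8).to_rtu()
        # one clade of 4 tips carries state 2: single origin on its stem
        traits = {f"t{i}": (2 if i >= 4 else 1) for i in range(8)}
        fit = estimate_rate(t, traits, k=2)
        rec = marginal_ancestral(t, fit.model, traits)
        events = origin_events(t, rec)
        assert len(events) == 1
        e = events[0]
        assert e.state == 2 and e.parent_state == 1 and not e.is_reversal
        # the event node is the MRCA of the derived clade, at age 0.5
        assert e.rtu_age == pytest.approx(0.5, abs=1e-9)

    def test_two_gains_one_reversal_matches_parsimony(self):
        """Hand-built 16-tip tree: state 2 gained on two separate stems and
        lost again inside one of them; MAP origins match the unambiguous
        parsimony reading (2 gains + 1 reversal to state 1)."""
        t = balanced_tree(16).to_rtu()
        traits = {f"t{i}": 1 for i in range(16)}
        for i in (0, 1, 2):      # gain of 2 in the first quartet...
            traits[f"t{i}"] = 2
        traits["t3"] = 1         # ...with one tip reverted
        for i in (8, 9, 10, 11):  # second independent gain
            traits[f"t{i}"] = 2
        fit = estimate_rate(t, traits, k=2)
        rec = marginal_ancestral(t, fit.model, traits)
        events = origin_events(t, rec)
        gains = [e for e in events if e.state == 2]
        reversals = [e for e in events if e.is_reversal]
        assert len(gains) == 2
        assert len(reversals) == 1 and reversals[0].state == 1
        counts = origin_counts(events)
        assert counts[2] == 2 and counts[1] == 1

    def test_events_sorted_oldest_first(self):
        t = balanced_tree(16).to_rtu()
        traits = {f"t{i}": (2 if i >= 8 else 1) for i in range(16)}
        traits["t0"] = 2
        fit = estimate_rate(t, traits, k=2)
        rec = marginal_ancestral(t, fit.model, traits)
        events = origin_events(t, rec)
        ages = [e.rtu_age for e in events]
        assert ages == sorted(ages, reverse=True)
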