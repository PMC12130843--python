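"""MFPT transition statistics, mechanism graphs, lumping, rate-limiting step."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eccperm.mechgraph import (
    build_mechanism_graph,
    ion_count_class,
    lump_graph,
    pairwise_transition_stats,
    rate_limiting_step,
)
from eccperm.synth import CTMCSpec, demo_mechanism_ctmc_spec, simulate_ctmc

from conftest import mfpt_oracle, transition_count_oracle


class TestPairwiseStats:
    def test_alternating_trajectory(self):
        st_ = pairwise_transition_stats((1.0, list("ABABABAB")))
        assert st_.mfpt[("A", "B")] == pytest.approx(1.0)
        assert st_.rate("A", "B") == pytest.approx(1.0)
        assert st_.rate("B", "A") == pytest.approx(1.0)

    def test_censored_passages_excluded_not_zero(self):
        st_ = pairwise_transition_stats((1.0, list("AAABBB")))
        assert ("B", "A") not in st_.mfpt
        assert st_.rate("B", "A") is None
        assert st_.mfpt[("A", "B")] == pytest.approx(3.0)

    def test_random_trajectory_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        codes = [str(s) for s in rng.integers(0, 4, size=200)]
        stride = 0.2
        st_ = pairwise_transition_stats((stride, codes))
        oracle = mfpt_oracle(stride, codes)
        assert set(st_.mfpt) == set(oracle)
        for pair, t in oracle.items():
            assert st_.mfpt[pair] == pytest.approx(t, abs=1e-12)
        assert st_.counts == {
            k: v for k, v in transition_count_oracle(codes).items()
        }

    @given(
        labels=st.lists(st.integers(0, 5), min_size=2, max_size=500),
        stride=st.sampled_from([0.01, 0.1, 1.0]),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_oracle_equivalence_property(self, labels, stride):
        """MFPTs equal the brute-force scan for arbitrary small trajectories
        of up to 6 states and 500 frames."""
        codes = [chr(ord("A") + v) for v in labels]
        st_ = pairwise_transition_stats((stride, codes))
        oracle = mfpt_oracle(stride, codes)
        assert set(st_.mfpt) == set(oracle)
        for pair, t in oracle.items():
            assert st_.mfpt[pair] == pytest.approx(t, abs=1e-9)

    def test_exhaustive_short_two_state_trajectories(self):
        """Every trajectory of length <= 6 over two states matches the oracle."""
        for n in range(2, 7):
            for mask in range(2**n):
                codes = ["A" if (mask >> i) & 1 else "B" for i in range(n)]
                st_ = pairwise_transition_stats((1.0, codes))
                oracle = mfpt_oracle(1.0, codes)
                assert set(st_.mfpt) == set(oracle)
                for pair, t in oracle.items():
                    assert st_.mfpt[pair] == pytest.approx(t, abs=1e-12)

    def test_two_state_ctmc_mfpt_matches_analytic(self):
        """MFPT(A->B) = 1/k_AB = 2 ns for k = 0.5/ns, within 3 SEM over 10 seeds."""
        k = 0.5
        Q = np.array([[0.0, k], [k, 0.0]])
        vals = []
        for seed in range(10):
            spec = CTMCSpec(states=["A", "B"], rate_matrix=Q, stride=0.05,
                            duration=500.0, seed=seed)
            traj, _ = simulate_ctmc(spec)
            vals.append(pairwise_transition_stats(traj).mfpt[("A", "B")])
        mean = np.mean(vals)
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        # discrete observation adds ~stride/2 of bias; keep it well under 3 SEM
        assert abs(mean - 2.0) < 3 * sem + 0.05 / 2

    def test_replicas_pool_passage_times_not_rates(self):
        """Pooling two replicas averages the passage times themselves."""
        r1 = (1.0, list("ABB"))   # one passage of 1
        r2 = (1.0, list("AAAB"))  # one passage of 3
        pooled = pairwise_transition_stats([r1, r2])
        assert pooled.mfpt[("A", "B")] == pytest.approx(2.0)  # (1+3)/2
        # averaging the two rates instead would give (1/1 + 1/3)/2 = 0.667
        assert pooled.rate("A", "B") == pytest.approx(0.5)


class TestBuildGraph:
    def test_two_state_graph_shape(self):
        st_ = pairwise_transition_stats((1.0, list("ABABAB")))
        g = build_mechanism_graph(st_, {"A": 0.5, "B": 0.5})
        assert sorted(g.nodes()) == ["A", "B"]
        assert g.edge("A", "B")["rate"] == pytest.approx(1.0)
        assert len(g.graph.edges) == 2

    def test_ion_count_classes(self):
        assert ion_count_class("WKKK0K") == 4
        assert ion_count_class("WKK0KK") == 4
        assert ion_count_class("WKKK0K", window="s1_s4") == 3
        assert ion_count_class("WKKKK0", window="s1_s4") == 4

    def test_populations_pass_through(self):
        st_ = pairwise_transition_stats((1.0, list("ABAB")))
        pops = {"A": 0.3, "B": 0.7}
        g = build_mechanism_graph(st_, pops)
        assert g.population("A") == 0.3
        assert g.population("B") == 0.7


@pytest.fixture(scope="module")
def chain_traj():
    """3-state chain A<->B fast (10/ns), B<->C slow (0.1/ns)."""
    Q = np.array([[0, 10.0, 0], [10.0, 0, 0.1], [0, 0.1, 0]])
    spec = CTMCSpec(states=["A", "B", "C"], rate_matrix=Q, stride=0.01,
                    duration=600.0, seed=4)
    traj, _ = simulate_ctmc(spec)
    return traj


class TestLumping:
    def test_hand_traced_chain(self, chain_traj):
        g = lump_graph(chain_traj, cutoff=1.0)
        assert sorted(g.nodes()) == ["A+B", "C"]
        assert g.members("A+B") == ("A", "B")

    def test_cutoff_above_all_rates_means_no_lumping(self, chain_traj):
        g = lump_graph(chain_traj, cutoff=1e6)
        assert sorted(g.nodes()) == ["A", "B", "C"]

    def test_cutoff_below_all_rates_means_single_node(self, chain_traj):
        g = lump_graph(chain_traj, cutoff=1e-4)
        assert g.nodes() == ["A+B+C"]
        assert g.population("A+B+C") == pytest.approx(1.0)

    def test_lumping_monotone_in_cutoff(self, chain_traj):
        cutoffs = [1e6, 50.0, 1.0, 0.05, 1e-4]
        sizes = [len(lump_graph(chain_traj, cutoff=c).nodes()) for c in cutoffs]
        assert sizes == sorted(sizes, reverse=True)

    def test_lumped_population_is_sum_of_members(self, chain_traj):
        codes = list(chain_traj.codes)
        g = lump_graph(chain_traj, cutoff=1.0)
        n = len(codes)
        expected = (codes.count("A") + codes.count("B")) / n
        assert g.population("A+B") == pytest.approx(expected, abs=1e-12)


class TestRateLimitingStep:
    def test_designed_bottleneck_found_across_seeds(self):
        """The slow leg of a driven 3-state cycle is identified in 20/20 seeds."""
        hits = 0
        for seed in range(20):
            spec = demo_mechanism_ctmc_spec(seed=seed, duration=1500.0)
            traj, _ = simulate_ctmc(spec)
            st_ = pairwise_transition_stats(traj)
            pops = {c: traj.codes.count(c) / len(traj.codes) for c in set(traj.codes)}
            g = build_mechanism_graph(st_, pops)
            total = st_.net_flux("WKKK0K", "WKK0KK")  # cycle flux through the slow leg
            step = rate_limiting_step(g, total_flux=total)
            if {step.node_a, step.node_b} == {"WKKK0K", "WKK0KK"} and not step.warning:
                hits += 1
        assert hits == 20

    def test_unique_minimum_rate_edge(self):
        # linear cycle A->B->C->A where B->C is slow, all carry the full flux
        codes = []
        for _ in range(200):
            codes += ["A", "B"] + ["B"] * 8 + ["C"]
        st_ = pairwise_transition_stats((0.1, codes))
        pops = {c: codes.count(c) / len(codes) for c in "ABC"}
        g = build_mechanism_graph(st_, pops)
        step = rate_limiting_step(g, total_flux=200)
        assert {step.node_a, step.node_b} == {"B", "C"}
        assert not step.warning

    def test_zero_net_flux_takes_warning_path(self):
        st_ = pairwise_transition_stats((1.0, list("ABABAB")))
        g = build_mechanism_graph(st_, {"A": 0.5, "B": 0.5})
        step = rate_limiting_step(g, total_flux=0)
        assert step.warning

    def test_flux_conservation_at_each_node(self):
        """In a steady driven cycle, net flux in equals net flux out (+-1)."""
        spec = demo_mechanism_ctmc_spec(seed=8, duration=1500.0)
        traj, _ = simulate_ctmc(spec)
        st_ = pairwise_transition_stats(traj)
        pops = {c: traj.codes.count(c) / len(traj.codes) for c in set(traj.codes)}
        g = build_mechanism_graph(st_, pops)
        for node in g.nodes():
            assert abs(g.node_flux_imbalance(node)) <= 1
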