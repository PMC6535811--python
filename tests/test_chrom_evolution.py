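"""Chromosome-number CTMC: rate matrices, likelihood, fitting, reconstruction."""

import itertools

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from paleowgd import chrom_evolution as ce
from paleowgd import phylo_io as pio
from paleowgd import synthetic_data as synth


def brute_force_loglik(tree, counts, spec, root_prior="ml"):
    """Exhaustive sum over all internal-state assignments (small trees only)."""
    Q = ce.build_rate_matrix(spec)
    m = spec.n_states
    nodes = list(tree.postorder_node_iter())
    internals = [nd for nd in nodes if not nd.is_leaf()]
    P = {}
    for nd in nodes:
        if nd.parent_node is not None:
            P[id(nd)] = scipy.linalg.expm(Q * (nd.edge.length or 0.0))
    root = tree.seed_node
    per_root = []
    for root_state in range(m):
        total = 0.0
        others = [nd for nd in internals if nd is not root]
        for assign in itertools.product(range(m), repeat=len(others)):
            state = {id(root): root_state}
            state.update({id(nd): s for nd, s in zip(others, assign)})
            for nd in tree.leaf_node_iter():
                state[id(nd)] = int(counts.values[nd.taxon.label]) - spec.n_min
            prob = 1.0
            for nd in nodes:
                if nd.parent_node is not None:
                    prob *= P[id(nd)][state[id(nd.parent_node)], state[id(nd)]]
            total += prob
        per_root.append(total)
    agg = max(per_root) if root_prior == "ml" else np.mean(per_root)
    return np.log(agg) if agg > 0 else -np.inf


class TestRateMatrix:
    def test_gain_only_chain_with_absorbing_top(self):
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=4, gain=1.0, free=("gain",))
        Q = ce.build_rate_matrix(spec)
        expected = np.array([
            [-1, 1, 0, 0],
            [0, -1, 1, 0],
            [0, 0, -1, 1],
            [0, 0, 0, 0],
        ], dtype=float)
        assert np.allclose(Q, expected)

    def test_duplication_doubles_count(self):
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=8, dupl=0.5, free=("dupl",))
        Q = ce.build_rate_matrix(spec)
        assert Q[2, 5] == pytest.approx(0.5)  # state 3 -> 6

    def test_demiduplication_odd_count_splits(self):
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=10, demi=1.0, free=("demi",))
        Q = ce.build_rate_matrix(spec)
        # 1.5 * 5 = 7.5: half rate each to 7 and 8
        assert Q[4, 6] == pytest.approx(0.5)
        assert Q[4, 7] == pytest.approx(0.5)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_duplication_overflow_routed_to_boundary(self):
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=6, dupl=0.3, free=("dupl",))
        Q = ce.build_rate_matrix(spec)
        assert Q[4, 5] == pytest.approx(0.3)  # 5 -> 10 truncated to 6
        assert Q[5, 5] == pytest.approx(0.0)  # 6 -> 12 would be a self-move

    def test_linear_rates_clamped_at_zero(self):
        spec = ce.ChromosomeModelSpec(
            n_min=1, n_max=10, gain=0.5, gain_slope=-0.2,
            free=("gain", "gain_slope"),
        )
        Q = ce.build_rate_matrix(spec)
        assert Q[0, 1] == pytest.approx(0.5)
        assert Q[4, 5] == pytest.approx(0.0)  # 0.5 - 0.2*4 < 0 clamps

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        gain=st.floats(0, 5), loss=st.floats(0, 5),
        dupl=st.floats(0, 2), demi=st.floats(0, 2),
    )
    def test_generator_rows_always_sum_to_zero(self, gain, loss, dupl, demi):
        spec = ce.ChromosomeModelSpec(
            n_min=2, n_max=14, gain=gain, loss=loss, dupl=dupl, demi=demi
        )
        Q = ce.build_rate_matrix(spec)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-10)
        off = Q - np.diag(np.diag(Q))
        assert (off >= 0).all()

    def test_transition_matrix_rows_sum_to_one(self):
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=12, gain=0.8, loss=0.4, dupl=0.1)
        Q = ce.build_rate_matrix(spec)
        for t in (0.1, 1.0, 7.5):
            P = scipy.linalg.expm(Q * t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)


class TestLikelihood:
    def test_single_tip_zero_length_tree(self):
        tree = pio.read_newick("A:0.0;")
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=4, gain=1.0)
        counts = pio.TraitVector({"A": 2}, kind="chromosome_count_n")
        assert ce.likelihood(tree, counts, spec, "ml") == pytest.approx(0.0)

    def test_frozen_chain_limits(self):
        tree = pio.read_newick("((A:1,B:1):1,C:2);")
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=4)  # all rates zero
        same = pio.TraitVector({"A": 2, "B": 2, "C": 2}, kind="chromosome_count_n")
        diff = pio.TraitVector({"A": 2, "B": 3, "C": 2}, kind="chromosome_count_n")
        assert ce.likelihood(tree, same, spec, "ml") == pytest.approx(0.0)
        assert ce.likelihood(tree, diff, spec, "ml") == -np.inf

    def test_three_tip_enumeration_oracle(self):
        tree = pio.read_newick("((A:0.3,B:0.7)N2:0.4,C:1.1)N1;")
        rng = np.random.default_rng(5)
        for _ in range(10):
            spec = ce.ChromosomeModelSpec(
                n_min=1, n_max=4,
                gain=rng.uniform(0, 2), loss=rng.uniform(0, 2),
                dupl=rng.uniform(0, 1),
            )
            counts = pio.TraitVector(
                {s: int(rng.integers(1, 5)) for s in "ABC"},
                kind="chromosome_count_n",
            )
            for prior in ("ml", "uniform"):
                assert ce.likelihood(tree, counts, spec, prior) == pytest.approx(
                    brute_force_loglik(tree, counts, spec, prior), abs=1e-8
                )

    def test_count_outside_space_raises(self):
        tree = pio.read_newick("(A:1,B:1);")
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=4, gain=1.0)
        counts = pio.TraitVector({"A": 2, "B": 9}, kind="chromosome_count_n")
        with pytest.raises(ValueError, match="widen"):
            ce.likelihood(tree, counts, spec)


@pytest.fixture(scope="module")
def small_data():
    tree = synth.simulate_species_tree(60, 1.0, 0.0, seed=21)
    spec = ce.ChromosomeModelSpec(n_min=1, n_max=60, gain=0.6, loss=0.3)
    Q = ce.build_rate_matrix(spec)
    counts, _, _ = synth.simulate_chromosome_counts(tree, Q, root_count=8, seed=22)
    return tree, counts


class TestFit:

    def test_refit_same_seed_identical(self, small_data):
        tree, counts = small_data
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=30, free=("gain", "loss"))
        a = ce.fit_model(tree, counts, spec, n_starts=2, seed=5)
        b = ce.fit_model(tree, counts, spec, n_starts=2, seed=5)
        assert a.params == b.params and a.logL == b.logL

    def test_nested_model_likelihood_monotone(self, small_data):
        tree, counts = small_data
        const = ce.ChromosomeModelSpec(
            name="CONST", n_min=1, n_max=30, free=("gain", "loss")
        )
        linear = ce.ChromosomeModelSpec(
            name="LINEAR", n_min=1, n_max=30,
            free=("gain", "loss", "gain_slope", "loss_slope"),
        )
        f0 = ce.fit_model(tree, counts, const, n_starts=2, seed=1)
        f1 = ce.fit_model(tree, counts, linear, n_starts=2, seed=1)
        assert f1.logL >= f0.logL - 1e-6

    def test_aic_definition(self, small_data):
        tree, counts = small_data
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=30, free=("gain", "loss"))
        fit = ce.fit_model(tree, counts, spec, n_starts=1, seed=3)
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.logL)


class TestCompareModels:
    def _fake_fit(self, name, k, logL, fp=("x",)):
        spec = ce.ChromosomeModelSpec(name=name, n_min=1, n_max=5)
        return ce.ChromFit(
            spec=spec, params={}, logL=logL, k=k, aic=2 * k - 2 * logL,
            root_prior="ml", fingerprint=fp,
        )

    def test_single_model_weight_one(self):
        df = ce.compare_models([self._fake_fit("M", 2, -10.0)])
        assert df["akaike_weight"].iloc[0] == pytest.approx(1.0)

    def test_equal_aic_splits_evenly(self):
        df = ce.compare_models(
            [self._fake_fit("M1", 2, -10.0), self._fake_fit("M2", 2, -10.0)]
        )
        assert np.allclose(df["akaike_weight"], 0.5)

    def test_closed_form_weights_for_delta_0_2_4(self):
        fits = [
            self._fake_fit("M1", 1, -10.0),          # AIC 22
            self._fake_fit("M2", 2, -10.0),          # AIC 24
            self._fake_fit("M3", 3, -10.0),          # AIC 26
        ]
        df = ce.compare_models(fits).set_index("model")
        w = np.exp([0, -1, -2]); w = w / w.sum()
        assert df.loc["M1", "akaike_weight"] == pytest.approx(w[0], abs=1e-9)
        assert df.loc["M2", "akaike_weight"] == pytest.approx(w[1], abs=1e-9)
        assert df.loc["M3", "akaike_weight"] == pytest.approx(w[2], abs=1e-9)

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="different data"):
            ce.compare_models(
                [self._fake_fit("M1", 2, -10.0, fp=("a",)),
                 self._fake_fit("M2", 2, -10.0, fp=("b",))]
            )

    def test_default_battery_has_ten_models(self):
        batt = ce.default_model_battery(1, 20)
        assert len(batt) == 10
        assert len({s.name for s in batt}) == 10


class TestAncestralStates:
    def test_frozen_chain_reconstructs_tip_value_everywhere(self):
        tree = pio.read_newick("((A:1,B:1)N2:1,C:2)N1;")
        spec = ce.ChromosomeModelSpec(n_min=10, n_max=20)
        counts = pio.TraitVector({s: 16 for s in "ABC"}, kind="chromosome_count_n")
        fit = ce.ChromFit(spec=spec, params={}, logL=0.0, k=0, aic=0.0,
                          root_prior="ml", fingerprint=())
        post, ml = ce.ancestral_states(fit, tree, counts)
        assert (ml == 16).all()
        assert post.loc["N1", 16] == pytest.approx(1.0)

    def test_three_tip_marginals_match_enumeration(self):
        tree = pio.read_newick("((A:0.4,B:0.9)N2:0.6,C:1.2)N1;")
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=4, gain=0.9, loss=0.5, dupl=0.2)
        counts = pio.TraitVector({"A": 2, "B": 3, "C": 1}, kind="chromosome_count_n")
        fit = ce.ChromFit(spec=spec, params={}, logL=0.0, k=0, aic=0.0,
                          root_prior="uniform", fingerprint=())
        post, _ = ce.ancestral_states(fit, tree, counts)
        # enumeration with uniform root prior
        Q = ce.build_rate_matrix(spec)
        m = 4
        P = {t: scipy.linalg.expm(Q * t) for t in (0.4, 0.9, 0.6, 1.2)}
        joint = np.zeros((m, m))  # root x N2
        for r in range(m):
            for n2 in range(m):
                joint[r, n2] = (
                    P[0.6][r, n2] * P[0.4][n2, 1] * P[0.9][n2, 2] * P[1.2][r, 0]
                )
        assert np.allclose(post.loc["N1"], joint.sum(1) / joint.sum(), atol=1e-8)
        assert np.allclose(post.loc["N2"], joint.sum(0) / joint.sum(), atol=1e-8)

    def test_posteriors_sum_to_one(self):
        tree = synth.simulate_species_tree(25, 1.0, 0.0, seed=31)
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=20, gain=0.5, loss=0.2)
        Q = ce.build_rate_matrix(spec)
        counts, _, _ = synth.simulate_chromosome_counts(tree, Q, root_count=6, seed=32)
        fit = ce.ChromFit(spec=spec, params={}, logL=0.0, k=0, aic=0.0,
                          root_prior="uniform", fingerprint=())
        post, _ = ce.ancestral_states(fit, tree, counts)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-10)


class TestExpectedChanges:
    def test_zero_matrix_zero_changes(self):
        tree = pio.read_newick("((A:1,B:1)N2:1,C:2)N1;")
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=4)
        counts = pio.TraitVector({s: 2 for s in "ABC"}, kind="chromosome_count_n")
        fit = ce.ChromFit(spec=spec, params={}, logL=0.0, k=0, aic=0.0,
                          root_prior="ml", fingerprint=())
        df = ce.expected_changes(fit, tree, counts, n_mappings=10, seed=1)
        assert df.values.sum() == 0.0

    def test_gain_only_matches_simulated_event_log(self):
        tree = synth.simulate_species_tree(40, 1.0, 0.0, seed=41)
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=40, gain=0.6, free=("gain",))
        Q = ce.build_rate_matrix(spec)
        true_events, mapped = [], []
        for rep in range(30):
            counts, _, log = synth.simulate_chromosome_counts(
                tree, Q, root_count=3, seed=500 + rep
            )
            fit = ce.ChromFit(spec=spec, params={}, logL=0.0, k=0, aic=0.0,
                              root_prior="uniform", fingerprint=())
            df = ce.expected_changes(fit, tree, counts, n_mappings=20, seed=rep)
            true_events.append(len(log))
            mapped.append(df["gain"].sum())
        diff = np.array(mapped) - np.array(true_events)
        se = np.std(diff, ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) <= 3 * max(se, 0.5)

    def test_nonnegative_and_additive(self):
        tree = synth.simulate_species_tree(15, 1.0, 0.0, seed=51)
        spec = ce.ChromosomeModelSpec(n_min=1, n_max=15, gain=0.4, loss=0.2)
        Q = ce.build_rate_matrix(spec)
        counts, _, _ = synth.simulate_chromosome_counts(tree, Q, root_count=5, seed=52)
        fit = ce.ChromFit(spec=spec, params={}, logL=0.0, k=0, aic=0.0,
                          root_prior="uniform", fingerprint=())
        df = ce.expected_changes(fit, tree, counts, n_mappings=25, seed=3)
        assert (df.values >= 0).all()
        assert df.values.sum() == pytest.approx(df.sum(axis=1).sum())


class TestHaploidCounts:
    def test_conversion_and_exclusion(self):
        tv = pio.TraitVector(
            {"A": 32, "B": 28, "Voanioala_gerardii": 596},
            kind="chromosome_count_2n",
        )
        n = ce.haploid_counts(tv, exclude=["Voanioala_gerardii"])
        assert n.values == {"A": 16, "B": 14}

    def test_odd_diploid_count_rejected(self):
        tv = pio.TraitVector({"A": 31}, kind="chromosome_count_2n")
        with pytest.raises(ValueError, match="odd"):
            ce.haploid_counts(tv)

    def test_default_state_space_pads_max(self):
        tv = pio.TraitVector({"A": 16, "B": 12}, kind="chromosome_count_n")
        assert ce.default_state_space(tv) == (1, 26)
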