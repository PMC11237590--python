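import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from conftest import make_counts, make_metadata, make_taxonomy
from fermnet import association as assoc
from fermnet.association import MetricThresholds, decide_edge, weighted_mean_age


class TestMetrics:
    def test_jaccard_identity_and_disjoint(self):
        assert assoc.jaccard_distance([1, 1, 0], [1, 1, 0]) == 0.0
        assert assoc.jaccard_distance([1, 0], [0, 1]) == 1.0
        assert assoc.jaccard_distance([0, 0], [0, 0]) == 1.0

    def test_jaccard_worked_example(self):
        assert assoc.jaccard_distance([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(2 / 3)

    def test_pearson_linear_and_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert assoc.abundance_correlation(x, 2 * x) == pytest.approx(1.0)
        assert assoc.abundance_correlation(
            [1, 2, 3], [3, 1, 2]
        ) == pytest.approx(-0.5)

    def test_spearman_monotone_transform(self):
        x = np.array([0.1, 0.5, 0.2, 0.9])
        assert assoc.abundance_correlation(
            x, np.exp(x), method="spearman"
        ) == pytest.approx(1.0)

    def test_constant_vector_gives_nan(self):
        assert math.isnan(assoc.abundance_correlation([1, 1, 1], [1, 2, 3]))

    def test_phi_shift_and_example(self):
        cx = np.array([0.0, 1.0, 2.0])
        assert assoc.phi_proportionality(cx, cx + 3.0) == pytest.approx(0.0)
        assert assoc.phi_proportionality(cx, 2 * cx) == pytest.approx(1 / 9)

    def test_phi_antiproportional_undefined(self):
        cx = np.array([0.0, 1.0, 2.0])
        assert math.isnan(assoc.phi_proportionality(cx, -cx))

    def test_phi_symmetric_and_shift_invariant(self):
        rng = np.random.default_rng(0)
        cx, cy = rng.normal(size=(2, 8))
        assert assoc.phi_proportionality(cx, cy) == pytest.approx(
            assoc.phi_proportionality(cy, cx)
        )
        c = 1.234  # adding a common constant to both clr vectors is a no-op
        assert assoc.phi_proportionality(cx + c, cy + c) == pytest.approx(
            assoc.phi_proportionality(cx, cy)
        )

    @pytest.mark.parametrize("n_samples", [5, 10])
    def test_metrics_match_bruteforce_oracles(self, n_samples):
        rng = np.random.default_rng(123)
        for _ in range(200):
            x = rng.integers(0, 30, size=n_samples).astype(float)
            y = rng.integers(0, 30, size=n_samples).astype(float)
            assert assoc.jaccard_distance(x > 0, y > 0) == pytest.approx(
                oracles.jaccard_distance(x, y), abs=1e-10)
            if np.ptp(x) and np.ptp(y):
                assert assoc.abundance_correlation(x, y) == pytest.approx(
                    oracles.pearson(x, y), abs=1e-10)
                assert assoc.abundance_correlation(
                    x, y, method="spearman"
                ) == pytest.approx(oracles.spearman(x, y), abs=1e-10)
            if np.var(x + y):
                assert assoc.phi_proportionality(x, y) == pytest.approx(
                    oracles.phi(x, y), abs=1e-10)


class TestDecideEdge:
    def test_all_four_pass(self):
        out = decide_edge({"jaccard": 0.1, "pearson": 0.9,
                           "spearman": 0.8, "phi": 0.2})
        assert out == {"is_edge": True, "support": 4, "flags": {
            "jaccard": True, "pearson": True, "spearman": True, "phi": True}}

    def test_single_metric_suffices(self):
        out = decide_edge({"jaccard": 0.9, "pearson": 0.1,
                           "spearman": 0.6, "phi": 2.0})
        assert out["is_edge"] and out["support"] == 1

    def test_negative_correlation_not_an_edge_when_signed(self):
        out = decide_edge({"jaccard": 0.9, "pearson": -0.9,
                           "spearman": -0.9, "phi": 2.0})
        assert not out["is_edge"]
        out = decide_edge({"jaccard": 0.9, "pearson": -0.9,
                           "spearman": -0.9, "phi": 2.0},
                          MetricThresholds(signed_corr=False))
        assert out["support"] == 2

    def test_nan_metrics_count_as_failing(self):
        out = decide_edge({"jaccard": float("nan"), "pearson": float("nan"),
                           "spearman": float("nan"), "phi": float("nan")})
        assert not out["is_edge"]

    @given(
        jd=st.floats(0, 1), r1=st.floats(-1, 1), r2=st.floats(-1, 1),
        ph=st.floats(0, 5),
    )
    def test_edges_monotone_in_thresholds(self, jd, r1, r2, ph):
        """Loosening every threshold can never remove an edge."""
        metrics = {"jaccard": jd, "pearson": r1, "spearman": r2, "phi": ph}
        tight = decide_edge(metrics, MetricThresholds(0.3, 0.6, 0.4))
        loose = decide_edge(metrics, MetricThresholds(0.5, 0.4, 0.8))
        if tight["is_edge"]:
            assert loose["is_edge"]
        assert loose["support"] >= tight["support"]


class TestWMA:
    def test_single_sample(self):
        assert weighted_mean_age([0.0, 0.3], [2.0, 7.0]) == pytest.approx(7.0)

    def test_worked_example(self):
        assert weighted_mean_age([0.5, 0.25], [2.0, 10.0]) == pytest.approx(14 / 3)

    def test_symmetry(self):
        assert weighted_mean_age([0.2, 0.2], [0.0, 10.0]) == 5.0

    def test_absent_everywhere_is_error(self):
        with pytest.raises(ValueError):
            weighted_mean_age([0.0, 0.0], [1.0, 2.0])

    @given(st.lists(
        st.tuples(st.floats(0.001, 1), st.floats(0, 60)),
        min_size=1, max_size=10,
    ))
    def test_wma_bounded_by_presence_times(self, pairs):
        p, t = zip(*pairs)
        wma = weighted_mean_age(np.array(p), np.array(t))
        assert min(t) - 1e-9 <= wma <= max(t) + 1e-9


def _study_tables(values, times):
    counts = make_counts(values)
    tax = make_taxonomy({a: {"order": "Lactobacillales"}
                         for a in counts.asv_ids})
    meta = make_metadata(counts.sample_ids, times=times)
    return counts, tax, meta


class TestBuildNetwork:
    def test_identical_profiles_give_high_support_edge(self):
        # a background ASV makes the relative abundances of the identical
        # pair non-constant, so all abundance metrics saturate
        values = np.array([[10, 10, 100], [40, 40, 20],
                           [5, 5, 200], [20, 20, 30]])
        counts, tax, meta = _study_tables(values, [0, 2, 5, 9])
        net = assoc.build_association_network(counts, tax, meta)
        assert net.graph.edges["asv0", "asv1"]["support"] >= 3

    def test_disjoint_uncorrelated_profiles_give_no_edge(self):
        values = np.array([[50, 0], [40, 0], [30, 0],
                           [0, 10], [0, 90], [0, 40]])
        counts, tax, meta = _study_tables(values, [0, 1, 2, 3, 4, 5])
        net = assoc.build_association_network(counts, tax, meta)
        assert net.graph.number_of_edges() == 0

    def test_single_asv_is_error(self):
        counts = make_counts([[5], [6]])
        tax = make_taxonomy({"asv0": {}})
        meta = make_metadata(counts.sample_ids, times=[0, 1])
        with pytest.raises(ValueError):
            assoc.build_association_network(counts, tax, meta)

    def test_node_attributes(self):
        values = np.array([[10, 10], [40, 40], [5, 5], [20, 20]])
        counts, tax, meta = _study_tables(values, [0, 2, 5, 9])
        net = assoc.build_association_network(counts, tax, meta)
        node = net.graph.nodes["asv0"]
        assert node["order"] == "Lactobacillales"
        assert node["max_relabund"] == pytest.approx(0.5)
        assert 0 <= node["wma"] <= 9

    def test_succession_study_orders_guilds_by_wma(self, synthetic_study):
        from fermnet.pipeline import run_study_pipeline

        counts, tax, meta = synthetic_study
        net = run_study_pipeline(counts, tax, meta).network
        wma_by_order = {}
        for n, a in net.graph.nodes(data=True):
            wma_by_order.setdefault(a["order"], []).append(a["wma"])
        assert (np.mean(wma_by_order["Pseudomonadales"])
                < np.mean(wma_by_order["Enterobacterales"])
                < np.mean(wma_by_order["Lactobacillales"]))


class TestScaleWmaAndLayout:
    def _net_with_wmas(self, wmas):
        net = assoc.AssociationNetwork(study_id="x")
        for i, w in enumerate(wmas):
            net.graph.add_node(f"a{i}", wma=float(w))
        return net

    def test_z_scores(self):
        net = assoc.scale_wma(self._net_with_wmas([0, 5, 10]))
        zs = [net.graph.nodes[n]["scaled_wma"] for n in ["a0", "a1", "a2"]]
        assert zs == pytest.approx([-1.0, 0.0, 1.0])

    def test_all_equal_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            net = assoc.scale_wma(self._net_with_wmas([4, 4, 4]))
        assert all(net.graph.nodes[n]["scaled_wma"] == 0 for n in net.graph)

    def test_idempotent(self):
        net = assoc.scale_wma(self._net_with_wmas([1, 3, 8, 2]))
        first = [net.graph.nodes[n]["scaled_wma"] for n in net.graph]
        net = assoc.scale_wma(net)
        second = [net.graph.nodes[n]["scaled_wma"] for n in net.graph]
        assert first == second

    def test_layout_deterministic_and_x_is_wma(self):
        net = self._net_with_wmas([1, 5, 9])
        net.graph.add_edge("a0", "a1")
        pos1 = assoc.compute_layout(net, seed=4)
        pos2 = assoc.compute_layout(net, seed=4)
        assert pos1 == pos2
        for node, (x, y) in pos1.items():
            assert x == net.graph.nodes[node]["wma"]
            assert np.isfinite(y)
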