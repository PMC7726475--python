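"""Chain-graph layers, supra-adjacency assembly and comparison reports."""

import numpy as np
import pytest

from dcgnet import (
    ConnectivityEstimate,
    PenaltySpec,
    build_multilayer,
    compare_conditions,
    compare_methods,
    effective_edges,
    functional_edges,
    supra_adjacency,
    threshold_weak_links,
)
from dcgnet.networks import GraphLayer, MultilayerNetwork, edges_to_matrix


def estimate_from(gamma, omega, labels=None, method="var_ols"):
    m = gamma.shape[0]
    labels = labels or [f"ch{i}" for i in range(m)]
    return ConnectivityEstimate(
        gamma_hat=gamma,
        intercept_hat=np.zeros(m),
        sigma_hat=np.linalg.inv(omega),
        omega_hat=omega,
        method=method,
        penalty=PenaltySpec("none"),
        labels=labels,
    )


class TestEdgeExtraction:
    def test_identity_gamma_gives_self_loops(self):
        edges = effective_edges(np.eye(4))
        assert len(edges) == 4
        assert all(e.source == e.target and e.directed for e in edges)

    def test_zero_gamma_gives_no_edges(self):
        assert effective_edges(np.zeros((3, 3))) == []

    def test_tolerance_filters_small_entries(self):
        gamma = np.zeros((3, 3))
        gamma[0, 1], gamma[1, 2], gamma[2, 0] = 0.5, -0.3, 0.2
        gamma[0, 2], gamma[1, 0] = 1e-12, -1e-10
        assert len(effective_edges(gamma, tol=1e-8)) == 3

    def test_partial_correlation_weight(self):
        omega = np.array([[2.0, -1.0], [-1.0, 2.0]])
        edges = functional_edges(omega, ["a", "b"])
        assert len(edges) == 1
        assert edges[0].weight == pytest.approx(0.5)  # -(-1)/sqrt(2*2)
        assert not edges[0].directed

    def test_diagonal_omega_gives_no_edges(self):
        assert functional_edges(np.diag([1.0, 2.0, 3.0])) == []

    def test_asymmetric_omega_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            functional_edges(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_matrix_edge_round_trip_preserves_support(self):
        rng = np.random.default_rng(0)
        gamma = rng.standard_normal((4, 4)) * (rng.random((4, 4)) > 0.5)
        labels = [f"ch{i}" for i in range(4)]
        back = edges_to_matrix(effective_edges(gamma, labels), labels, directed=True)
        assert np.array_equal(back != 0, np.abs(gamma) > 1e-8)
        assert np.allclose(back[back != 0], gamma[np.abs(gamma) > 1e-8])


class TestMultilayer:
    def make_net(self, n_layers=2, m=3, coupling=0.0):
        rng = np.random.default_rng(1)
        ests = {}
        for k in range(n_layers):
            gamma = rng.standard_normal((m, m)) * 0.2
            a = rng.standard_normal((m, m)) * 0.2
            omega = np.eye(m) + (a + a.T) / 4
            ests[f"band{k}"] = estimate_from(gamma, omega)
        return build_multilayer(ests, interlayer_coupling=coupling)

    def test_single_layer_equals_its_graphlayer(self):
        net = self.make_net(n_layers=1)
        assert net.layer_names == ["band0"]
        mat, index = supra_adjacency(net, "functional")
        assert mat.shape == (3, 3)
        assert index == [("band0", ch) for ch in net.nodes]

    def test_mismatched_labels_rejected(self):
        a = estimate_from(np.zeros((2, 2)), np.eye(2), labels=["x", "y"])
        b = estimate_from(np.zeros((2, 2)), np.eye(2), labels=["x", "z"])
        with pytest.raises(ValueError, match="mismatched"):
            build_multilayer({"one": a, "two": b})

    def test_supra_dimension_is_nodes_times_layers(self):
        net = self.make_net(n_layers=5, m=7)
        mat, index = supra_adjacency(net, "functional")
        assert mat.shape == (35, 35)
        assert len(index) == 35

    def test_functional_supra_is_symmetric_and_block_diagonal(self):
        net = self.make_net(n_layers=3, m=4)
        mat, _ = supra_adjacency(net, "functional")
        assert np.allclose(mat, mat.T)
        # no couplings: off-diagonal blocks vanish
        assert np.allclose(mat[:4, 4:8], 0.0)

    def test_coupling_puts_identity_in_offdiagonal_blocks(self):
        net = self.make_net(n_layers=2, m=3, coupling=1.0)
        mat, _ = supra_adjacency(net, "effective")
        assert np.allclose(mat[:3, 3:], np.eye(3))
        assert np.allclose(mat[3:, :3], np.eye(3))

    def test_effective_supra_preserves_sign_and_direction(self):
        gamma = np.zeros((3, 3))
        gamma[2, 0] = -0.7  # ch0 -> ch2
        net = build_multilayer({"b": estimate_from(gamma, np.eye(3))})
        mat, _ = supra_adjacency(net, "effective")
        assert mat[2, 0] == -0.7
        assert mat[0, 2] == 0.0


class TestCompareMethods:
    def reference(self):
        gamma = np.zeros((3, 3))
        gamma[0, 1], gamma[1, 2] = 0.9, 0.6  # strong
        gamma[2, 0], gamma[0, 2] = 0.05, 0.02  # weak
        omega = np.eye(3)
        omega[0, 1] = omega[1, 0] = -0.5
        return estimate_from(gamma, omega)

    def test_candidate_equal_to_thresholded_reference(self):
        ref = self.reference()
        thr = threshold_weak_links(ref, 0.5)
        rep = compare_methods(ref, thr, {"ideal": thr, "raw": ref})
        e = rep.per_method["ideal"]["effective"]
        # the ideal candidate keeps every strong link and drops every weak one
        assert len(e["preserved_strong"]) == len(rep.strong["effective"])
        assert len(e["removed_weak"]) == len(rep.weak["effective"])
        assert e["created"] == []
        raw = rep.per_method["raw"]["effective"]
        assert len(raw["removed_weak"]) == 0  # unthresholded keeps its weak links
        assert raw["created"] == []

    def test_empty_candidate(self):
        ref = self.reference()
        thr = threshold_weak_links(ref, 0.5)
        empty = estimate_from(np.zeros((3, 3)), np.eye(3))
        rep = compare_methods(ref, thr, {"empty": empty})
        e = rep.per_method["empty"]["effective"]
        assert e["preserved_strong"] == []
        assert e["created"] == []
        assert len(e["removed_weak"]) == len(rep.weak["effective"])

    def test_injected_spurious_edge_reported_as_created(self):
        ref = self.reference()
        thr = threshold_weak_links(ref, 0.5)
        gamma = ref.gamma_hat.copy()
        gamma[2, 1] = 0.4  # a link absent from the reference support
        cand = estimate_from(gamma, np.eye(3))
        rep = compare_methods(ref, thr, {"cand": cand})
        assert rep.per_method["cand"]["effective"]["created"] == [("ch1", "ch2")]

    def test_conservation_preserved_plus_missing_equals_strong(self):
        ref = self.reference()
        thr = threshold_weak_links(ref, 0.5)
        partial = estimate_from(
            np.diag([0.0, 0.0, 0.0]) + np.where(ref.gamma_hat > 0.8, ref.gamma_hat, 0.0),
            np.eye(3),
        )
        rep = compare_methods(ref, thr, {"partial": partial})
        for kind in ("effective", "functional"):
            e = rep.per_method["partial"][kind]
            assert len(e["preserved_strong"]) + len(e["missing_strong"]) == len(
                rep.strong[kind]
            )


class TestCompareConditions:
    def single_layer_net(self, omega, name="gamma"):
        est = estimate_from(np.zeros((4, 4)), omega)
        return build_multilayer({name: est})

    def test_identical_networks_no_changes(self):
        omega = np.eye(4)
        omega[0, 1] = omega[1, 0] = -0.4
        a = self.single_layer_net(omega)
        b = self.single_layer_net(omega.copy())
        out = compare_conditions(a, b)
        entry = out["gamma"]["functional"]
        assert entry["gained"] == [] and entry["lost"] == []
        assert len(entry["shared"]) == 1

    def test_constructed_gains_counted_per_band(self):
        base_omega = np.eye(4)
        post_omega = np.eye(4)
        post_omega[0, 1] = post_omega[1, 0] = -0.4
        post_omega[2, 3] = post_omega[3, 2] = -0.3
        rng = np.random.default_rng(0)
        shared_gamma = rng.standard_normal((4, 4)) * 0.1
        base = build_multilayer(
            {
                "alpha": estimate_from(shared_gamma, np.eye(4)),
                "gamma": estimate_from(shared_gamma, base_omega),
            }
        )
        post = build_multilayer(
            {
                "alpha": estimate_from(shared_gamma, np.eye(4)),
                "gamma": estimate_from(shared_gamma, post_omega),
            }
        )
        out = compare_conditions(base, post)
        assert len(out["gamma"]["functional"]["gained"]) == 2
        assert len(out["alpha"]["functional"]["gained"]) == 0
        assert out["alpha"]["effective"]["gained"] == []

    def test_mismatched_layers_rejected(self):
        a = self.single_layer_net(np.eye(4), "alpha")
        b = self.single_layer_net(np.eye(4), "beta")
        with pytest.raises(ValueError, match="different layers"):
            compare_conditions(a, b)
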