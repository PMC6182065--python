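"""PCIT edge significance, group networks, differential hubbing, targets."""

import numpy as np
import pandas as pd
import pytest

from conftest import pcit_bruteforce
from tendernet import (
    ExpressionMatrix,
    GroupNetwork,
    differential_hubbing,
    group_network,
    hub_targets,
    partial_correlation,
    pcit_edges,
    pearson_matrix,
)
from tendernet.errors import ConfigError, DataError


def random_corr(rng, n, kind="random"):
    if kind == "rank1":
        v = rng.normal(size=(n, 1))
        M = v @ v.T + 0.05 * np.eye(n)
    elif kind == "block":
        data = np.zeros((n, 40))
        half = n // 2
        f1, f2 = rng.normal(size=40), rng.normal(size=40)
        data[:half] = 0.9 * f1 + 0.4 * rng.normal(size=(half, 40))
        data[half:] = 0.9 * f2 + 0.4 * rng.normal(size=(n - half, 40))
        M = np.cov(data)
    else:
        data = rng.normal(size=(n, 12))
        M = np.cov(data)
    d = np.sqrt(np.diag(M))
    R = M / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1, 1)


class TestPearson:
    def test_self_and_anticorrelation(self, rng):
        x = rng.normal(size=10)
        R = pearson_matrix(np.vstack([x, -x + 0.0]))
        assert R[0, 0] == pytest.approx(1.0)
        assert R[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_covariance_oracle(self, rng):
        X = rng.normal(size=(10, 13))
        R = pearson_matrix(X)
        # textbook two-pass: center, then normalized cross products
        C = (X - X.mean(axis=1, keepdims=True))
        S = C @ C.T / (X.shape[1] - 1)
        d = np.sqrt(np.diag(S))
        assert np.allclose(R, S / np.outer(d, d), atol=1e-12)

    def test_zero_variance_rejected(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DataError, match="zero-variance"):
            pearson_matrix(X)


class TestPartialCorrelation:
    def test_hand_case(self):
        assert partial_correlation(0.9, 0.9, 0.81) == pytest.approx(
            0.669, abs=5e-4
        )

    def test_conditioning_on_unrelated_is_identity(self):
        assert partial_correlation(0.7, 0.0, 0.0) == pytest.approx(0.7)

    def test_exact_mediation_vanishes(self):
        assert partial_correlation(0.72, 0.9, 0.8) == pytest.approx(0.0)

    def test_degenerate_conditioning_rejected(self):
        with pytest.raises(DataError):
            partial_correlation(0.5, 1.0, 0.3)

    def test_equals_residual_correlation_oracle(self, rng):
        """The formula equals correlating OLS residuals on the conditioner."""
        for _ in range(50):
            n = 200
            z = rng.normal(size=n)
            x = 0.6 * z + rng.normal(size=n)
            y = -0.4 * z + 0.3 * x + rng.normal(size=n)
            R = np.corrcoef(np.vstack([x, y, z]))
            got = partial_correlation(R[0, 1], R[0, 2], R[1, 2])
            rx = x - np.polyval(np.polyfit(z, x, 1), z)
            ry = y - np.polyval(np.polyfit(z, y, 1), z)
            expect = np.corrcoef(rx, ry)[0, 1]
            assert got == pytest.approx(expect, abs=1e-10)


class TestPCITEdges:
    def test_three_gene_hand_trio_survives(self):
        R = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, 0.81], [0.9, 0.81, 1.0]])
        # trio tolerance: mean of the three partial/direct ratios ~ 0.4956
        p1 = partial_correlation(0.9, 0.9, 0.81)
        p2 = partial_correlation(0.9, 0.9, 0.81)
        p3 = partial_correlation(0.81, 0.9, 0.9)
        eps = np.mean([p1 / 0.9, p2 / 0.9, p3 / 0.81])
        assert eps == pytest.approx(0.4956, abs=2e-3)
        mask = pcit_edges(R)
        assert mask[np.triu_indices(3, 1)].all()

    def test_diagonal_only_matrix_has_no_edges(self):
        # zero correlations are never significant edges
        mask = pcit_edges(np.eye(5))
        assert not mask.any()

    def test_matches_bruteforce_oracle(self, rng):
        for kind in ("random", "block", "rank1"):
            for n in (5, 10, 17):
                R = random_corr(rng, n, kind)
                assert np.array_equal(pcit_edges(R), pcit_bruteforce(R)), (
                    kind,
                    n,
                )

    def test_small_matrix_warns_and_survives(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        with pytest.warns(UserWarning):
            mask = pcit_edges(R)
        assert mask[0, 1]

    def test_node_guard(self):
        with pytest.raises(ConfigError):
            pcit_edges(np.eye(10), max_nodes=5)


def make_em(values, groups):
    m, n = values.shape
    cols = [f"s{j}" for j in range(n)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=[f"t{i}" for i in range(m)], columns=cols),
        groups=pd.Series(groups, index=cols),
        stage="residual_fpkm",
    )


class TestGroupNetwork:
    def test_threshold_validation(self, rng):
        em = make_em(rng.normal(size=(5, 8)), ["H"] * 4 + ["L"] * 4)
        with pytest.raises(ConfigError):
            group_network(em, "H", r_threshold=1.5)

    def test_full_threshold_empty_for_continuous_data(self, rng):
        em = make_em(rng.normal(size=(8, 10)), ["H"] * 5 + ["L"] * 5)
        net = group_network(em, "H", r_threshold=1.0)
        assert len(net.edges) == 0

    def test_edge_sets_nested_in_threshold(self, rng):
        em = make_em(rng.normal(size=(12, 14)), ["H"] * 7 + ["L"] * 7)
        loose = group_network(em, "H", r_threshold=0.3)
        tight = group_network(em, "H", r_threshold=0.6)
        as_set = lambda net: {
            tuple(sorted(e)) for e in net.edges[["node_a", "node_b"]].itertuples(
                index=False, name=None
            )
        }
        assert as_set(tight) <= as_set(loose)

    def test_zero_variance_transcripts_flagged_not_fatal(self, rng):
        v = rng.normal(size=(6, 10))
        v[2] = 3.0
        em = make_em(v, ["H"] * 5 + ["L"] * 5)
        with pytest.warns(UserWarning, match="zero-variance"):
            net = group_network(em, "H")
        assert "t2" in net.dropped_zero_variance
        assert "t2" in net.nodes  # still part of the universe, isolated


def star_network(group, edges):
    nodes = sorted({a for a, _, _ in edges} | {b for _, b, _ in edges})
    return GroupNetwork(
        group=group,
        nodes=nodes,
        edges=pd.DataFrame(edges, columns=["node_a", "node_b", "r"]),
    )


class TestDifferentialHubbing:
    def test_degree_difference(self):
        h = star_network("H", [("hub", f"x{i}", 0.95) for i in range(12)])
        l = star_network("L", [("hub", f"x{i}", 0.95) for i in range(5)])
        l.nodes = h.nodes
        dh = differential_hubbing(h, l).set_index("transcript")
        assert dh.loc["hub", "DH"] == 7

    def test_swap_negates(self, rng):
        em = make_em(rng.normal(size=(10, 12)), ["H"] * 6 + ["L"] * 6)
        net_h = group_network(em, "H", r_threshold=0.4)
        net_l = group_network(em, "L", r_threshold=0.4)
        d1 = differential_hubbing(net_h, net_l).set_index("transcript")["DH"]
        d2 = differential_hubbing(net_l, net_h).set_index("transcript")["DH"]
        assert (d1 + d2.reindex(d1.index) == 0).all()

    def test_l_only_module_gets_negative_dh(self):
        h = star_network("H", [("a", "b", 0.91)])
        edges = [("hub", f"m{i}", 0.95) for i in range(20)]
        l = star_network("L", edges)
        nodes = sorted(set(h.nodes) | set(l.nodes))
        h.nodes = l.nodes = nodes
        dh = differential_hubbing(h, l).set_index("transcript")
        assert dh.loc["hub", "DH"] == -20

    def test_node_mismatch_rejected(self):
        h = star_network("H", [("a", "b", 0.95)])
        l = star_network("L", [("c", "d", 0.95)])
        with pytest.raises(DataError):
            differential_hubbing(h, l)


class TestHubTargets:
    def test_sign_partition(self):
        net = star_network(
            "H",
            [("hub", "p1", 0.95), ("hub", "p2", 0.92), ("hub", "n1", -0.91)],
        )
        t = hub_targets(net, "hub")
        assert list(t["positive"]["target"]) == ["p1", "p2"]
        assert list(t["negative"]["target"]) == ["n1"]
        all_targets = set(t["positive"]["target"]) | set(t["negative"]["target"])
        assert all_targets == set(net.neighbors("hub")["target"])

    def test_isolated_node(self):
        net = star_network("H", [("a", "b", 0.95)])
        net.nodes = ["a", "b", "iso"]
        t = hub_targets(net, "iso")
        assert t["positive"].empty and t["negative"].empty

    def test_missing_hub_rejected(self):
        net = star_network("H", [("a", "b", 0.95)])
        with pytest.raises(DataError):
            hub_targets(net, "zz")
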