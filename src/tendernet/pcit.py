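"""PCIT co-expression networks, differential hubbing, and hub targets.

PCIT (partial correlation with information theory) scans every gene trio
(x, y, z). For a trio it computes the three first-order partial
correlations, e.g.

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)),

and a trio-specific tolerance eps = mean of the three partial/direct
ratios (ratios with an exactly zero direct correlation, or an undefined
partial, are skipped). The edge (x, y) is eliminated if for some third
gene z both |r_xy| <= |eps * r_xz| and |r_xy| <= |eps * r_yz| — i.e. the
association is fully explained through z at the trio's tolerance. Edges
surviving every trio are significant; group networks additionally require
|r| >= 0.90 on the direct correlation.

Differential hubbing (DH) is the difference in a transcript's number of
significant connections between the high and low phenotype groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .prep import ExpressionMatrix

#: refuse the O(n^3) trio scan above this size unless the caller overrides
DEFAULT_MAX_NODES = 5000


def pearson_matrix(values) -> np.ndarray:
    """Pearson correlation across samples (rows = transcripts).

    Zero-variance transcripts are an error: correlation is undefined for
    them and they must be removed (``group_network`` does so, with a
    warning) before calling.
    """
    if isinstance(values, pd.DataFrame):
        arr = values.to_numpy(dtype=float)
        ids = list(values.index)
    else:
        arr = np.asarray(values, dtype=float)
        ids = list(range(arr.shape[0]))
    if arr.shape[1] < 3:
        raise DataError("need >= 3 samples to estimate correlations")
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = [ids[i] for i in np.flatnonzero(sd == 0)[:10]]
        raise DataError(f"zero-variance transcripts present, e.g. {bad}")
    r = np.corrcoef(arr)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r_xy.z."""
    for r in (r_xy, r_xz, r_yz):
        if abs(r) > 1 + 1e-12:
            raise DataError("correlations must lie in [-1, 1]")
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        raise DataError("partial correlation undefined: a conditioning correlation is +-1")
    return (r_xy - r_xz * r_yz) / np.sqrt(denom)


def pcit_edges(R: np.ndarray, max_nodes: int = DEFAULT_MAX_NODES) -> np.ndarray:
    """Boolean significance mask over edges (True = edge survives PCIT).

    Vectorised over pairs with a Python loop over the conditioning gene
    only, so the O(n^3) trio scan stays inside numpy. The diagonal is
    False (no self-edges), and an exactly zero correlation is never a
    significant edge.
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n):
        raise DataError("correlation matrix must be square")
    if n > max_nodes:
        raise ConfigError(
            f"{n} nodes exceeds the trio-scan guard ({max_nodes}); "
            "pass a larger max_nodes explicitly to override"
        )
    mask = (R != 0)
    np.fill_diagonal(mask, False)
    if n < 3:
        warnings.warn("fewer than 3 transcripts: all edges trivially survive")
        return mask

    absR = np.abs(R)
    one_minus_R2 = np.clip(1.0 - R**2, 0.0, None)
    eliminated = np.zeros((n, n), dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(n):
            rz = R[:, z]
            dz = 1.0 - rz**2  # 1 - r_xz^2 per row
            # partials of the three trio edges, as (x, y) matrices
            p_xy = (R - np.outer(rz, rz)) / np.sqrt(np.outer(dz, dz))
            p_xz = (rz[:, None] - R * rz[None, :]) / np.sqrt(
                one_minus_R2 * dz[None, :]
            )
            p_yz = (rz[None, :] - R * rz[:, None]) / np.sqrt(
                one_minus_R2 * dz[:, None]
            )
            ratios = (
                p_xy / R,
                p_xz / rz[:, None],
                p_yz / rz[None, :],
            )
            ssum = np.zeros((n, n))
            cnt = np.zeros((n, n))
            for rat in ratios:
                ok = np.isfinite(rat)
                ssum += np.where(ok, rat, 0.0)
                cnt += ok
            eps = np.where(cnt > 0, ssum / np.maximum(cnt, 1), np.nan)
            with np.errstate(invalid="ignore"):
                cond = (absR <= np.abs(eps * rz[:, None])) & (
                    absR <= np.abs(eps * rz[None, :])
                )
            cond &= cnt > 0
            cond[z, :] = False
            cond[:, z] = False
            np.fill_diagonal(cond, False)
            eliminated |= cond
    mask &= ~eliminated
    return mask


@dataclass
class GroupNetwork:
    """Significant co-expression network of one phenotype group.

    ``nodes`` is the full transcript universe (including isolated nodes);
    ``edges`` has columns node_a, node_b, r with node_a < node_b.
    """

    group: str
    nodes: list
    edges: pd.DataFrame
    dropped_zero_variance: list = field(default_factory=list)

    def degree(self) -> pd.Series:
        deg = pd.Series(0, index=pd.Index(self.nodes, name="transcript"), dtype=int)
        if len(self.edges):
            counts = pd.concat(
                [self.edges["node_a"], self.edges["node_b"]]
            ).value_counts()
            deg.loc[counts.index] = counts.astype(int)
        return deg

    def neighbors(self, node) -> pd.DataFrame:
        if node not in set(self.nodes):
            raise DataError(f"transcript {node!r} not in network")
        e = self.edges
        a = e[e["node_a"] == node][["node_b", "r"]].rename(columns={"node_b": "target"})
        b = e[e["node_b"] == node][["node_a", "r"]].rename(columns={"node_a": "target"})
        return pd.concat([a, b], ignore_index=True)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            self.edges[["node_a", "node_b", "r"]].itertuples(index=False, name=None),
            weight="r",
        )
        return g


def group_network(
    em: ExpressionMatrix,
    group: str,
    r_threshold: float = 0.90,
    max_nodes: int = DEFAULT_MAX_NODES,
) -> GroupNetwork:
    """PCIT network of one group: PCIT-significant edges with |r| >= threshold."""
    if not 0.0 < r_threshold <= 1.0:
        raise ConfigError(f"r_threshold must be in (0, 1], got {r_threshold}")
    samples = em.group_samples(group)
    if len(samples) < 3:
        raise DataError(f"group {group!r} has {len(samples)} samples; need >= 3")
    sub = em.values[samples]
    sd = sub.std(axis=1, ddof=0)
    dropped = list(sub.index[sd == 0])
    if dropped:
        warnings.warn(
            f"{len(dropped)} zero-variance transcripts excluded from the "
            f"{group} network (first: {dropped[:5]})"
        )
        sub = sub.loc[sd > 0]
    R = pearson_matrix(sub)
    mask = pcit_edges(R, max_nodes=max_nodes)
    sig = mask & (np.abs(R) >= r_threshold)
    iu = np.triu_indices(len(sub), k=1)
    keep = sig[iu]
    ids = np.asarray(sub.index)
    edges = pd.DataFrame(
        {
            "node_a": ids[iu[0][keep]],
            "node_b": ids[iu[1][keep]],
            "r": R[iu][keep],
        }
    )
    return GroupNetwork(
        group=group,
        nodes=list(em.values.index),
        edges=edges,
        dropped_zero_variance=dropped,
    )


def differential_hubbing(net_h: GroupNetwork, net_l: GroupNetwork) -> pd.DataFrame:
    """Per-transcript DH = (connections in H) - (connections in L), ranked.

    Both networks must share the same node universe.
    """
    if set(net_h.nodes) != set(net_l.nodes):
        raise DataError("networks have different node universes")
    k_h = net_h.degree()
    k_l = net_l.degree().reindex(k_h.index)
    out = pd.DataFrame(
        {"transcript": k_h.index, "k_H": k_h.values, "k_L": k_l.values}
    )
    out["DH"] = out["k_H"] - out["k_L"]
    return out.sort_values(
        ["DH", "transcript"], ascending=[False, True]
    ).reset_index(drop=True)


def hub_targets(net: GroupNetwork, hub_id) -> dict:
    """Positively and negatively correlated targets of a hub transcript."""
    nbrs = net.neighbors(hub_id)
    pos = nbrs[nbrs["r"] > 0].sort_values("r", ascending=False).reset_index(drop=True)
    neg = nbrs[nbrs["r"] < 0].sort_values("r").reset_index(drop=True)
    return {"hub": hub_id, "positive": pos, "negative": neg}
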