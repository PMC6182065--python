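"""Phenotypic and regulatory impact factor scoring.

PIF prioritizes abundant, strongly changing transcripts:

    PIF_i = a_bar_i * d_i,  a_bar = (e_H + e_L)/2,  d = e_H - e_L,

where e_H, e_L are group means of residual FPKM. RIF scores every
transcript as a candidate regulator of the DE target set, using the
group-specific PCIT-masked correlations (r = 0 for pairs without a
significant |r| >= threshold edge in that group):

    RIF1_i = (1/n_DE) * sum_j PIF_j * (r_ij^H - r_ij^L)^2
    RIF2_i = (1/n_DE) * sum_j [ (e_j^H r_ij^H)^2 - (e_j^L r_ij^L)^2 ]

RIF1 accumulates PIF-weighted differential wiring; RIF2 the change in a
regulator's squared predicted contribution to each target's abundance.
Scores are z-standardized across the candidate population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import qvalues
from .errors import ConfigError, DataError
from .pcit import GroupNetwork
from .prep import ExpressionMatrix


def _zscore(x: np.ndarray, population: np.ndarray | None = None) -> np.ndarray:
    pop = x if population is None else population
    sd = pop.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - pop.mean()) / sd


def pif_scores(em: ExpressionMatrix) -> pd.DataFrame:
    """Group means, PIF, and its normal-approximation significance.

    PIF p-values come from z-scoring PIF over transcripts and a two-sided
    normal tail, BH-adjusted (a convention; the score itself is the
    quantity of interest).
    """
    if em.groups is None or not {"H", "L"} <= set(em.groups.dropna().unique()):
        raise DataError("expression matrix needs both H and L groups")
    h_cols = em.group_samples("H")
    l_cols = em.group_samples("L")
    if len(h_cols) < 3 or len(l_cols) < 3:
        raise DataError("each group needs >= 3 samples")
    e_h = em.values[h_cols].mean(axis=1)
    e_l = em.values[l_cols].mean(axis=1)
    a_bar = (e_h + e_l) / 2.0
    d = e_h - e_l
    pif = a_bar * d
    z = _zscore(pif.to_numpy())
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "e_H": e_h,
            "e_L": e_l,
            "a_bar": a_bar,
            "d": d,
            "PIF": pif,
            "PIF_z": z,
            "PIF_p": p,
            "PIF_fdr": qvalues(p, method="bh"),
        },
        index=em.values.index,
    )


def _masked_correlation_matrix(
    net: GroupNetwork, candidates: list, targets: list
) -> np.ndarray:
    """candidates x targets matrix of PCIT-masked correlations (0 if no edge)."""
    cpos = {t: i for i, t in enumerate(candidates)}
    tpos = {t: j for j, t in enumerate(targets)}
    r = np.zeros((len(candidates), len(targets)))
    for a, b, val in net.edges[["node_a", "node_b", "r"]].itertuples(index=False):
        if a in cpos and b in tpos:
            r[cpos[a], tpos[b]] = val
        if b in cpos and a in tpos:
            r[cpos[b], tpos[a]] = val
    return r


def rif_scores(
    pif: pd.DataFrame,
    de_ids: list,
    net_h: GroupNetwork,
    net_l: GroupNetwork,
    standardize_on: str = "all",
) -> pd.DataFrame:
    """RIF1/RIF2 for every transcript against the DE target set.

    ``standardize_on`` selects the z-score population: ``all`` scored
    transcripts (default) or ``nonzero`` raw scores only.
    """
    de_ids = [t for t in de_ids if t in pif.index]
    if not de_ids:
        raise DataError(
            "empty DE target set; relax the q threshold to obtain targets"
        )
    if standardize_on not in ("all", "nonzero"):
        raise ConfigError("standardize_on must be 'all' or 'nonzero'")
    candidates = list(pif.index)
    r_h = _masked_correlation_matrix(net_h, candidates, de_ids)
    r_l = _masked_correlation_matrix(net_l, candidates, de_ids)
    pif_t = pif.loc[de_ids, "PIF"].to_numpy()
    e_h_t = pif.loc[de_ids, "e_H"].to_numpy()
    e_l_t = pif.loc[de_ids, "e_L"].to_numpy()
    n_de = len(de_ids)

    rif1 = (pif_t[None, :] * (r_h - r_l) ** 2).sum(axis=1) / n_de
    rif2 = ((e_h_t[None, :] * r_h) ** 2 - (e_l_t[None, :] * r_l) ** 2).sum(axis=1) / n_de

    out = pif.copy()
    out["RIF1_raw"] = rif1
    out["RIF2_raw"] = rif2
    for col in ("RIF1", "RIF2"):
        raw = out[f"{col}_raw"].to_numpy()
        pop = raw[raw != 0] if standardize_on == "nonzero" else raw
        if pop.size == 0:
            pop = raw
        out[f"{col}_z"] = _zscore(raw, pop)
    return out


def rank_and_slice(scores: pd.Series, top_n: int = 3000) -> dict:
    """Top positive and top negative transcripts of one score column.

    Stable sort with transcript-ID tie-break; also tallies how many
    transcripts score negative, zero, and positive.
    """
    if top_n < 1:
        raise ConfigError("top_n must be >= 1")
    frame = scores.rename("score").rename_axis("transcript").reset_index()
    pos = (
        frame[frame["score"] > 0]
        .sort_values(["score", "transcript"], ascending=[False, True], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
    neg = (
        frame[frame["score"] < 0]
        .sort_values(["score", "transcript"], ascending=[True, True], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
    return {
        "top_positive": pos,
        "top_negative": neg,
        "n_positive": int((frame["score"] > 0).sum()),
        "n_negative": int((frame["score"] < 0).sum()),
        "n_zero": int((frame["score"] == 0).sum()),
    }
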