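"""Over-representation analysis with Benjamini-Hochberg control.

A generic replacement for web-service enrichment tools: each term in a
term-to-gene table is tested for over-representation in a query gene list
against a declared background with the hypergeometric upper tail
P(X >= k), where N = |background|, K = |term in background|, n = |query|,
k = |term in query|.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError

TERM_COLUMNS = ["term_id", "name", "category", "gene_id"]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_ora(query, background, terms: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query list.

    ``terms`` is long-format with columns term_id, name, category, gene_id.
    Term members absent from the background are dropped with a warning;
    terms with no background overlap are skipped.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise DataError("empty query set")
    stray = query - background
    if stray:
        raise DataError(
            f"query contains {len(stray)} genes outside the background, "
            f"e.g. {sorted(stray)[:5]}"
        )
    if set(TERM_COLUMNS) - set(terms.columns):
        raise DataError(f"term table needs columns {TERM_COLUMNS}")

    n_outside = (~terms["gene_id"].isin(background)).sum()
    if n_outside:
        warnings.warn(
            f"{n_outside} term-membership rows reference genes outside the "
            "background and are dropped"
        )
    terms = terms[terms["gene_id"].isin(background)]

    big_n, small_n = len(background), len(query)
    rows = []
    for (term_id, name, category), grp in terms.groupby(
        ["term_id", "name", "category"], sort=True
    ):
        members = set(grp["gene_id"])
        big_k = len(members)
        if big_k == 0:
            continue
        k = len(members & query)
        expected = small_n * big_k / big_n
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, small_n))
        # odds ratio of the 2x2 overlap table (0.5 continuity guard)
        a, b = k, big_k - k
        c, d = small_n - k, big_n - big_k - (small_n - k)
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            {
                "term_id": term_id,
                "name": name,
                "category": category,
                "k": k,
                "K": big_k,
                "n": small_n,
                "N": big_n,
                "expected": expected,
                "odds_ratio": odds,
                "p": p,
            }
        )
    if not rows:
        warnings.warn("no term overlaps the background; empty result")
        return pd.DataFrame(
            columns=["term_id", "name", "category", "k", "K", "n", "N",
                     "expected", "odds_ratio", "p", "p_adj"]
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "term_id"]).reset_index(drop=True)
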