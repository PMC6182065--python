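"""Count filtering, upper-quartile normalization, FPKM, and residualization.

This module turns a raw transcript x sample count table into the
residual-FPKM expression matrix consumed by the network stages:

1. ``filter_counts`` removes non-expressed and unreliably quantified
   transcripts (all-zero, total < 2 reads, too many zero samples).
2. ``uq_normalize`` computes per-sample upper-quartile (75th percentile)
   scale factors to absorb library-size differences.
3. ``compute_fpkm`` converts counts to fragments per kilobase of transcript
   per million mapped reads.
4. ``residualize`` regresses fixed-effect covariates out of each
   transcript's FPKM profile, leaving residual FPKM values whose pairwise
   correlations are not driven by known nuisance structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DesignError, NormalizationError


@dataclass
class CountMatrix:
    """Integer read counts (transcripts x samples) with metadata.

    ``lengths`` are transcript lengths in bp, ``totals`` per-sample total
    mapped reads, ``covariates`` a sample-indexed table of fixed-effect
    covariates (must include a ``group`` column with H/L labels for the
    network stages).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise DataError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()].tolist()[:5]
            raise DataError(f"missing transcript lengths, e.g. {missing}")
        if (self.lengths <= 0).any():
            raise DataError("transcript lengths must be positive")
        self.totals = self.totals.reindex(self.counts.columns)
        if self.totals.isna().any() or (self.totals <= 0).any():
            raise DataError("per-sample totals must be present and positive")
        if self.covariates is not None:
            self.covariates = self.covariates.reindex(self.counts.columns)

    @property
    def n_transcripts(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset(self, transcripts) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[transcripts],
            lengths=self.lengths.loc[transcripts],
            totals=self.totals,
            covariates=self.covariates,
        )


@dataclass
class ExpressionMatrix:
    """Real-valued expression (transcripts x samples) with group labels.

    ``stage`` records the transform applied: ``raw_fpkm`` or
    ``residual_fpkm``.
    """

    values: pd.DataFrame
    groups: Optional[pd.Series] = None
    stage: str = "raw_fpkm"

    def __post_init__(self):
        if not np.isfinite(self.values.values).all():
            raise DataError("expression values must be finite")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.columns)

    def group_samples(self, group: str) -> list:
        if self.groups is None:
            raise DataError("no group labels attached")
        return list(self.values.columns[self.groups == group])


def default_max_zero_samples(n_samples: int) -> int:
    """Zero-sample cutoff: drop a transcript with this many (or more) zeros.

    ceil(n/5) + 1 zeros; at n = 24 this is the six-or-more-zeros rule.
    """
    return ceil(n_samples / 5) + 1


def filter_counts(
    cm: CountMatrix,
    min_total: int = 2,
    max_zero_samples: Optional[int] = None,
) -> tuple[CountMatrix, dict]:
    """Apply the three expression filters; return survivors and removal tally.

    Rules (per-transcript predicates, order-independent):
      (a) all counts zero (non-expressed);
      (b) total reads < ``min_total`` (very low expression);
      (c) zero counts in >= ``max_zero_samples`` samples (unreliable
          quantification).

    The removal tally counts each rule independently, so a transcript may
    contribute to several rules; ``removed`` is the unique total.
    """
    if cm.n_transcripts == 0:
        raise DataError("empty count matrix")
    n = cm.n_samples
    if max_zero_samples is None:
        max_zero_samples = default_max_zero_samples(n)
    if max_zero_samples < 1:
        raise ConfigError("max_zero_samples must be >= 1")

    counts = cm.counts
    zeros = (counts == 0).sum(axis=1)
    totals = counts.sum(axis=1)
    rule_a = totals == 0
    rule_b = totals < min_total
    rule_c = zeros >= max_zero_samples
    drop = rule_a | rule_b | rule_c
    tally = {
        "all_zero": int(rule_a.sum()),
        "low_total": int(rule_b.sum()),
        "too_many_zero_samples": int(rule_c.sum()),
        "removed": int(drop.sum()),
        "kept": int((~drop).sum()),
    }
    return cm.subset(counts.index[~drop]), tally


def uq_normalize(cm: CountMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Upper-quartile normalization.

    The per-sample factor is the 75th percentile of that sample's non-zero
    counts (linear interpolation between order statistics) divided by the
    geometric mean of those percentiles across samples, so factors average
    to 1 on the log scale. Normalized value = count / factor, which
    equalizes the non-zero upper quartiles across samples.
    """
    counts = cm.counts
    uqs = {}
    for s in counts.columns:
        col = counts[s].values
        nz = col[col > 0]
        if nz.size == 0:
            raise NormalizationError(f"sample {s!r} has all-zero counts")
        if nz.size < 4:
            warnings.warn(
                f"sample {s!r} has only {nz.size} non-zero counts; "
                "upper quartile is poorly determined"
            )
        uqs[s] = float(np.percentile(nz, 75))
    uq = pd.Series(uqs)
    ref = float(np.exp(np.mean(np.log(uq))))
    factors = uq / ref
    normalized = counts.div(factors, axis=1)
    return normalized, factors


def compute_fpkm(cm: CountMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    fpkm = count * 1e9 / (length_bp * total_mapped_reads). Totals are the
    per-sample total mapped reads carried by the count matrix (not
    post-filter column sums).
    """
    if (cm.lengths <= 0).any() or (cm.totals <= 0).any():
        raise DataError("lengths and totals must be positive")
    denom = np.outer(cm.lengths.values, cm.totals.values)
    fpkm = cm.counts.values * 1e9 / denom
    groups = None
    if cm.covariates is not None and "group" in cm.covariates.columns:
        groups = cm.covariates["group"]
    return ExpressionMatrix(
        values=pd.DataFrame(fpkm, index=cm.counts.index, columns=cm.counts.columns),
        groups=groups,
        stage="raw_fpkm",
    )


def build_design(covariates: pd.DataFrame, drop_first: bool = True) -> pd.DataFrame:
    """Fixed-effect design matrix: intercept, dummy-coded categoricals
    (first level dropped), centered numeric covariates."""
    cols = {"intercept": np.ones(len(covariates))}
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=drop_first)
            for dname in dummies.columns:
                cols[dname] = dummies[dname].to_numpy(dtype=float)
        else:
            vals = col.to_numpy(dtype=float)
            cols[name] = vals - vals.mean()
    return pd.DataFrame(cols, index=covariates.index)


def _drop_redundant(X: pd.DataFrame) -> pd.DataFrame:
    """Drop linearly dependent columns (pivoted-QR rank detection)."""
    from scipy.linalg import qr

    A = X.to_numpy(dtype=float)
    _, r, piv = qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    return X.iloc[:, keep]


def residualize(
    em: ExpressionMatrix, covariates: Optional[pd.DataFrame] = None
) -> ExpressionMatrix:
    """OLS residuals of each transcript's expression on the covariate design.

    With no covariates the design is the intercept alone, so residuals are
    mean-centered values. Residuals are orthogonal to every design column.
    """
    if covariates is None:
        covariates = pd.DataFrame(index=em.values.columns)
    X = build_design(covariates.loc[em.values.columns])
    if X.shape[1] > X.shape[0]:
        raise DesignError(
            f"{X.shape[1]} design columns for {X.shape[0]} samples"
        )
    X = _drop_redundant(X)
    A = X.to_numpy(dtype=float)
    Y = em.values.to_numpy(dtype=float).T  # samples x transcripts
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ coef
    return ExpressionMatrix(
        values=pd.DataFrame(resid.T, index=em.values.index, columns=em.values.columns),
        groups=em.groups,
        stage="residual_fpkm",
    )
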