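"""Quasi-negative-binomial differential expression.

Counts are modelled per transcript with a log-linear negative-binomial GLM
(offset = log upper-quartile normalization factor), the tested covariate
(shear force, continuous) is dropped to form the reduced model, and the
deviance drop is referred to an F distribution after dividing by a
spline-shrunk quasi-dispersion:

    phi_g      = deviance_full_g / df_resid           (raw quasi-dispersion)
    trend      = cubic smoothing spline of log phi on log mean count
    phi_shrunk = (df_resid * phi_g + prior_df * trend_g) / (df_resid + prior_df)
    F_g        = (deviance_reduced - deviance_full) / df_test / phi_shrunk
    p_g        = upper tail of F(df_test, df_resid + prior_df)

Per-transcript NB dispersions (alpha in var = m + alpha m^2) are estimated
by moments from a Poisson working fit; the quasi layer absorbs the
remaining misspecification. FDR is controlled with q-values (Storey's pi0
estimate, with plain Benjamini-Hochberg as the ``bh`` option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .errors import DataError, DesignError

_MAX_IRLS = 50
_IRLS_TOL = 1e-8


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """Negative-binomial (Poisson if alpha ~ 0) residual deviance."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-12, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        yl = np.where(y > 0, y * np.log(y / mu), 0.0)
        if alpha < 1e-12:
            dev = 2.0 * np.sum(yl - (y - mu))
        else:
            k = 1.0 / alpha
            dev = 2.0 * np.sum(yl - (y + k) * np.log((y + k) / (mu + k)))
    return float(max(dev, 0.0))


def fit_gene_glm(
    y: np.ndarray,
    X: np.ndarray,
    offset: Optional[np.ndarray] = None,
    alpha: float = 0.0,
) -> dict:
    """Log-linear NB GLM by iteratively reweighted least squares.

    Fisher scoring with the NB working weight w = mu / (1 + alpha * mu).
    Returns coefficients, fitted means, deviance, and a convergence flag.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)

    eta = np.log(np.clip(y, 0.5, None)) - offset
    beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
    dev_old = np.inf
    converged = False
    for _ in range(_MAX_IRLS):
        eta = X @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            break
        beta = beta_new
        dev = nb_deviance(y, np.exp(np.clip(X @ beta + offset, -30, 30)), alpha)
        if abs(dev - dev_old) < _IRLS_TOL * (abs(dev) + 0.1):
            converged = True
            dev_old = dev
            break
        dev_old = dev
    mu = np.exp(np.clip(X @ beta + offset, -30.0, 30.0))
    return {
        "beta": beta,
        "mu": mu,
        "deviance": nb_deviance(y, mu, alpha),
        "converged": converged,
    }


def moment_dispersion(y: np.ndarray, mu: np.ndarray, p: int) -> float:
    """Moment estimate of the NB alpha from Poisson-fit residuals."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-12, None)
    n = len(y)
    denom = np.sum(mu**2)
    if denom <= 0 or n <= p:
        return 0.0
    # bias-adjust the squared residuals for the p fitted parameters
    num = np.sum((y - mu) ** 2) * n / max(n - p, 1) - np.sum(mu)
    return float(max(num / denom, 0.0))


def shrink_dispersions(
    phi: np.ndarray,
    mean_counts: np.ndarray,
    prior_df: float,
    df_resid: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Shrink raw quasi-dispersions toward a mean-dependent spline trend.

    Fits a cubic smoothing spline of log(phi) on log(mean) and combines
    each raw estimate with its trend value with weights
    df_resid : prior_df. ``prior_df = 0`` returns the raw estimates,
    ``prior_df = inf`` the trend. Returns (shrunk, trend).
    """
    phi = np.asarray(phi, dtype=float)
    mean_counts = np.asarray(mean_counts, dtype=float)
    m = len(phi)
    if m < 20:
        raise DataError(f"need >= 20 transcripts to fit a dispersion trend (got {m})")
    if np.all(phi <= 0):
        warnings.warn("all raw dispersions are zero; trend is zero")
        trend = np.zeros(m)
    else:
        floor = max(np.min(phi[phi > 0]) * 1e-3, 1e-8)
        x = np.log(np.clip(mean_counts, 1e-8, None))
        yv = np.log(np.clip(phi, floor, None))
        # smoothing splines need strictly increasing x: average duplicates
        order = np.argsort(x)
        xs, ys = x[order], yv[order]
        ux, inv = np.unique(xs, return_inverse=True)
        uy = np.bincount(inv, weights=ys) / np.bincount(inv)
        if len(ux) < 4:
            trend = np.full(m, float(np.exp(uy.mean())))
        else:
            spl = interpolate.UnivariateSpline(ux, uy, k=3, s=len(ux))
            trend = np.exp(spl(x))
    if np.isinf(prior_df):
        shrunk = trend.copy()
    elif prior_df <= 0:
        shrunk = phi.copy()
    else:
        shrunk = (df_resid * phi + prior_df * trend) / (df_resid + prior_df)
    return shrunk, trend


def ql_ftest(
    dev_full: np.ndarray,
    dev_reduced: np.ndarray,
    phi_shrunk: np.ndarray,
    df_test: int,
    df_resid: float,
    prior_df: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quasi-likelihood F test of the reduced-vs-full deviance drop.

    Returns (F, p, flagged) where flagged marks transcripts with a
    non-positive quasi-dispersion (assigned p = 1).
    """
    drop = np.clip(np.asarray(dev_reduced) - np.asarray(dev_full), 0.0, None)
    phi = np.asarray(phi_shrunk, dtype=float)
    flagged = phi <= 0
    F = np.zeros_like(drop)
    ok = ~flagged
    F[ok] = (drop[ok] / df_test) / phi[ok]
    df2 = df_resid + (0.0 if np.isinf(prior_df) else prior_df)
    if np.isinf(prior_df):
        p = stats.chi2.sf(F * df_test, df_test)
    else:
        p = stats.f.sf(F, df_test, df2)
    p = np.where(flagged, 1.0, p)
    return F, p, flagged


def _storey_pi0(p: np.ndarray) -> float:
    """Storey's pi0: spline-smoothed pi0(lambda) evaluated at max lambda."""
    lam = np.arange(0.05, 0.96, 0.05)
    m = len(p)
    pi0_lam = np.array([(p > la).sum() / (m * (1.0 - la)) for la in lam])
    if m < 100:  # spline on few points is unstable; use a conservative choice
        return float(np.clip(pi0_lam.min(), 1e-8, 1.0))
    spl = interpolate.UnivariateSpline(lam, pi0_lam, k=3, s=len(lam) / 2)
    return float(np.clip(spl(lam.max()), 1e-8, 1.0))


def qvalues(p, method: str = "storey") -> np.ndarray:
    """q-values for FDR control.

    ``bh`` is plain Benjamini-Hochberg step-up (pi0 = 1); ``storey``
    multiplies by the estimated null proportion pi0 <= 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    if method == "bh":
        return q
    if method == "storey":
        return np.clip(_storey_pi0(p) * q, 0.0, 1.0)
    raise DataError(f"unknown FDR method {method!r}")


class QuasiNB:
    """Quasi-negative-binomial DE model for a count matrix.

    Parameters
    ----------
    counts : DataFrame
        Filtered integer counts, transcripts x samples.
    design : DataFrame
        Full design matrix (samples x columns), including the tested
        covariate; typically from :func:`tendernet.prep.build_design`.
    test_col : str
        Column of ``design`` whose effect is tested (dropped in the
        reduced model), e.g. the shear-force phenotype.
    norm_factors : Series, optional
        Upper-quartile factors; the GLM offset is their log. Defaults to 1.
    """

    def __init__(self, counts, design, test_col, norm_factors=None):
        self.counts = counts
        if test_col not in design.columns:
            raise DesignError(f"test column {test_col!r} not in design")
        design = design.loc[counts.columns]
        if np.linalg.matrix_rank(design.to_numpy(dtype=float)) < design.shape[1]:
            raise DesignError("design matrix is rank deficient")
        self.design = design
        self.test_col = test_col
        if norm_factors is None:
            norm_factors = pd.Series(1.0, index=counts.columns)
        self.offset = np.log(norm_factors.loc[counts.columns].to_numpy(dtype=float))

    def fit(self, prior_df: float = 10.0, fdr_method: str = "storey") -> "QuasiNBResults":
        counts = self.counts.to_numpy(dtype=float)
        X_full = self.design.to_numpy(dtype=float)
        cols = list(self.design.columns)
        j = cols.index(self.test_col)
        X_red = np.delete(X_full, j, axis=1)
        n, p = X_full.shape
        df_resid = n - p
        if df_resid < 1:
            raise DesignError("no residual degrees of freedom")
        m = counts.shape[0]
        beta_sf = np.zeros(m)
        dev_full = np.zeros(m)
        dev_red = np.zeros(m)
        alphas = np.zeros(m)
        bad = np.zeros(m, dtype=bool)
        for g in range(m):
            y = counts[g]
            pois = fit_gene_glm(y, X_full, self.offset, alpha=0.0)
            a = moment_dispersion(y, pois["mu"], p)
            full = fit_gene_glm(y, X_full, self.offset, alpha=a)
            red = fit_gene_glm(y, X_red, self.offset, alpha=a)
            if not (full["converged"] and red["converged"]):
                bad[g] = True
            beta_sf[g] = full["beta"][j]
            dev_full[g] = full["deviance"]
            dev_red[g] = red["deviance"]
            alphas[g] = a

        norm_counts = counts / np.exp(self.offset)[None, :]
        mean_norm = norm_counts.mean(axis=1)
        phi_raw = dev_full / df_resid
        phi_shrunk, trend = shrink_dispersions(phi_raw, mean_norm, prior_df, df_resid)
        F, pvals, flagged = ql_ftest(
            dev_full, dev_red, phi_shrunk, 1, df_resid, prior_df
        )
        pvals = np.where(bad, 1.0, pvals)
        if bad.any():
            warnings.warn(f"{int(bad.sum())} transcripts failed to converge; p set to 1")
        q = qvalues(pvals, method=fdr_method)
        frame = pd.DataFrame(
            {
                "beta_sf": beta_sf,
                "F": F,
                "p": pvals,
                "q": q,
                "mean_norm": mean_norm,
                "dispersion_raw": phi_raw,
                "dispersion_shrunk": phi_shrunk,
                "nb_alpha": alphas,
                "flagged": bad | flagged,
            },
            index=self.counts.index,
        )
        return QuasiNBResults(model=self, frame=frame, prior_df=prior_df,
                              fdr_method=fdr_method, df_resid=df_resid)


@dataclass
class QuasiNBResults:
    """Per-transcript DE results with a statsmodels-flavoured summary."""

    model: QuasiNB
    frame: pd.DataFrame
    prior_df: float
    fdr_method: str
    df_resid: float

    def significant(self, q_threshold: float = 0.10) -> pd.DataFrame:
        """Transcripts called DE at the given q-value cutoff."""
        sig = self.frame[self.frame["q"] < q_threshold]
        return sig.sort_values("q")

    def summary(self, q_threshold: float = 0.10) -> str:
        sig = self.significant(q_threshold)
        lines = [
            "Quasi-Negative-Binomial DE Results",
            "=" * 44,
            f"transcripts tested:     {len(self.frame)}",
            f"tested covariate:       {self.model.test_col}",
            f"residual df:            {self.df_resid}",
            f"prior df (shrinkage):   {self.prior_df}",
            f"FDR method:             {self.fdr_method}",
            f"DE at q < {q_threshold:g}:          {len(sig)}",
        ]
        if len(sig):
            lines.append("-" * 44)
            lines.append("top transcripts (by q):")
            for tid, row in sig.head(10).iterrows():
                lines.append(
                    f"  {tid:<14s} b={row['beta_sf']:+.3f}  "
                    f"F={row['F']:8.2f}  q={row['q']:.3g}"
                )
        return "\n".join(lines)
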