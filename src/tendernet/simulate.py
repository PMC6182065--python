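"""Synthetic half-sib study generator with planted truth.

Generates (i) a half-sib pedigree with shear-force phenotypes under the
additive animal model y = Xb + Zu + e, and (ii) two-group negative-binomial
RNA-seq count matrices with planted differential expression, planted
group-specific hub modules, and planted regulators wired to DE targets in
one group only. The planted structure is returned as a ``SyntheticTruth``
record so every downstream stage can be tested for parameter recovery.

Expression model
----------------
Each transcript has a natural-log baseline mean drawn from N(3, 1.5^2)
(log-normal dynamic range typical of bulk RNA-seq). Planted-structure
transcripts (DE, hubs + modules, regulators) are given a higher baseline
(log-mean 7) and a capped NB dispersion (2e-3) so that the co-expression
signal planted on the log scale survives counting noise; background
transcripts use the configured dispersion. Co-expression is planted through
per-sample latent factors with log-scale loading tau = 0.5: a hub's module
members load rho*F_hub + sqrt(1-rho^2)*noise in the wired group only, and a
regulator's DE targets load on the regulator factor in group H only.
Counts are NB(mean * libsize_factor, alpha) with var = m + alpha*m^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigError, DataError
from .prep import CountMatrix

#: log-scale standard deviation of the planted latent factors
LATENT_SD = 0.5
#: natural-log baseline mean of planted-structure transcripts
PLANTED_LOG_MEAN = 7.0
#: NB dispersion cap for planted-structure transcripts
PLANTED_DISPERSION = 2e-3
#: nominal per-sample total mapped reads at library factor 1
NOMINAL_TOTAL = 1_000_000


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic run.

    ``hub_ids`` maps hub transcript -> group (H/L) in which its module is
    wired; ``regulator_targets`` maps regulator transcript -> list of the DE
    transcripts it drives (in group H only).
    """

    true_breeding_values: Optional[pd.Series] = None
    de_ids: list = field(default_factory=list)
    hub_ids: dict = field(default_factory=dict)
    hub_members: dict = field(default_factory=dict)
    regulator_targets: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = {
            "true_breeding_values": (
                None
                if self.true_breeding_values is None
                else {str(k): float(v) for k, v in self.true_breeding_values.items()}
            ),
            "de_ids": list(self.de_ids),
            "hub_ids": dict(self.hub_ids),
            "hub_members": {k: list(v) for k, v in self.hub_members.items()},
            "regulator_targets": {k: list(v) for k, v in self.regulator_targets.items()},
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        tbv = d.get("true_breeding_values")
        return cls(
            true_breeding_values=None if tbv is None else pd.Series(tbv),
            de_ids=d["de_ids"],
            hub_ids=d["hub_ids"],
            hub_members=d.get("hub_members", {}),
            regulator_targets=d["regulator_targets"],
        )


def simulate_pedigree_phenotypes(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Half-sib pedigree with additive-model phenotypes.

    Sires are unrelated founders with unknown parents; each has
    ``progeny_per_sire`` progeny out of unknown, unrelated dams. Breeding
    values follow u_sire ~ N(0, h2*sigma2_p) and
    u_progeny = u_sire/2 + m with Mendelian-sampling variance
    (3/4)*h2*sigma2_p (one unknown, non-inbred parent). Phenotypes (progeny
    only) are mu_sf + CG effect + age_slope*(age - 750) + u + e with
    e ~ N(0, (1-h2)*sigma2_p); ages uniform on [600, 900] days and
    contemporary groups assigned round-robin.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])

    sigma2_a = cfg.h2 * cfg.sigma2_p
    sigma2_e = (1.0 - cfg.h2) * cfg.sigma2_p

    sires = [f"S{i:03d}" for i in range(1, cfg.n_sires + 1)]
    progeny = [
        f"A{i:04d}" for i in range(1, cfg.n_sires * cfg.progeny_per_sire + 1)
    ]
    sire_of = {
        a: sires[i // cfg.progeny_per_sire] for i, a in enumerate(progeny)
    }

    if sigma2_a > 0:
        u_sire = rng.normal(0.0, np.sqrt(sigma2_a), size=cfg.n_sires)
        mend = rng.normal(0.0, np.sqrt(0.75 * sigma2_a), size=len(progeny))
    else:
        u_sire = np.zeros(cfg.n_sires)
        mend = np.zeros(len(progeny))
        rng.normal(size=cfg.n_sires + len(progeny))  # keep stream position stable
    u = dict(zip(sires, u_sire))
    for i, a in enumerate(progeny):
        u[a] = 0.5 * u[sire_of[a]] + mend[i]

    ped = pd.DataFrame(
        {
            "animal": sires + progeny,
            "sire": ["0"] * len(sires) + [sire_of[a] for a in progeny],
            "dam": ["0"] * (len(sires) + len(progeny)),
        }
    )

    cg_effects = rng.normal(0.0, 0.5, size=cfg.n_cg)
    ages = rng.integers(600, 901, size=len(progeny))
    cgs = np.arange(len(progeny)) % cfg.n_cg
    e = rng.normal(0.0, np.sqrt(sigma2_e), size=len(progeny))
    sf = (
        cfg.mu_sf
        + cg_effects[cgs]
        + cfg.age_slope * (ages - 750.0)
        + np.array([u[a] for a in progeny])
        + e
    )
    phen = pd.DataFrame(
        {"animal": progeny, "sf": sf, "cg": [f"CG{c + 1}" for c in cgs], "age": ages}
    )
    truth = SyntheticTruth(
        true_breeding_values=pd.Series(u, name="tbv").loc[sires + progeny]
    )
    return ped, phen, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, var = m + alpha m^2); Poisson in the alpha -> 0 limit."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / alpha
    # gamma-Poisson mixture keeps the parametrization explicit
    lam = rng.gamma(shape=size, scale=mean * alpha)
    return rng.poisson(lam)


def simulate_counts(
    cfg: SimulationConfig,
    group_labels: Optional[Sequence[str]] = None,
    sample_ids: Optional[Sequence[str]] = None,
    truth: Optional[SyntheticTruth] = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Two-group NB count matrix with planted DE, hubs, and regulators.

    ``group_labels`` assigns each sample to 'H' or 'L'; defaults to
    ``n_samples_per_group`` each. Planted transcript blocks are allocated
    deterministically and disjointly: DE first, then hub + module blocks
    (wired group alternating H, L), then regulators; DE targets are split
    round-robin among regulators. Returns the count matrix (with lengths,
    per-sample totals = column sums, and a ``group`` covariate column) and
    the truth record (extended in place if one is passed in).
    """
    cfg.validate()
    if group_labels is None:
        group_labels = ["H"] * cfg.n_samples_per_group + [
            "L"
        ] * cfg.n_samples_per_group
    group_labels = list(group_labels)
    if any(g not in ("H", "L") for g in group_labels):
        raise DataError("group labels must be 'H' or 'L'")
    n_h = group_labels.count("H")
    n_l = group_labels.count("L")
    if n_h < 3 or n_l < 3:
        raise DataError(
            f"degenerate group: need >= 3 samples per group (got H={n_h}, L={n_l})"
        )
    n = len(group_labels)
    if sample_ids is None:
        sample_ids = [f"smp{i:03d}" for i in range(1, n + 1)]
    sample_ids = list(sample_ids)

    rng = np.random.default_rng([cfg.seed, 1])
    m = cfg.n_transcripts
    tids = [f"T{i:05d}" for i in range(1, m + 1)]

    # ---- planted index blocks (disjoint) ----
    pos = 0
    de_idx = list(range(pos, pos + cfg.n_de))
    pos += cfg.n_de
    hub_idx, module_idx = [], {}
    for h in range(cfg.n_hubs):
        hub_idx.append(pos)
        module_idx[pos] = list(range(pos + 1, pos + 1 + cfg.hub_module_size))
        pos += 1 + cfg.hub_module_size
    reg_idx = list(range(pos, pos + cfg.n_regulators))
    pos += cfg.n_regulators

    planted = set(de_idx) | set(hub_idx) | set(reg_idx)
    for mem in module_idx.values():
        planted |= set(mem)

    # ---- baseline log-means and dispersions ----
    log_mu = rng.normal(3.0, 1.5, size=m)
    alpha = np.full(m, cfg.nb_dispersion)
    planted_arr = np.fromiter(planted, dtype=int)
    if planted_arr.size:
        log_mu[planted_arr] = PLANTED_LOG_MEAN
        alpha[planted_arr] = min(cfg.nb_dispersion, PLANTED_DISPERSION)

    is_h = np.array([g == "H" for g in group_labels])
    log_signal = np.tile(log_mu[:, None], (1, n))

    # ---- planted DE: symmetric +/- lfc/2 shift (log2), sign alternating ----
    shift = cfg.lfc * np.log(2.0) / 2.0
    de_sign = np.array([1 if k % 2 == 0 else -1 for k in range(cfg.n_de)])
    for k, i in enumerate(de_idx):
        log_signal[i, is_h] += de_sign[k] * shift
        log_signal[i, ~is_h] -= de_sign[k] * shift

    # ---- planted hub modules: shared latent factor in the wired group ----
    hub_groups = {}
    tau = LATENT_SD
    for h_ord, hi in enumerate(hub_idx):
        wired = "H" if h_ord % 2 == 0 else "L"
        hub_groups[hi] = wired
        in_wired = is_h if wired == "H" else ~is_h
        f_hub = rng.normal(size=n)
        log_signal[hi] += tau * f_hub
        # graded loadings: members attach to the hub with varying strength
        # (an equicorrelated module is a degenerate clique in which every
        # member is as connected as the hub; grading keeps member-member
        # correlations rho_i*rho_j below the hub-member ones)
        loadings = np.linspace(
            max(cfg.hub_corr - 0.1, 0.0), cfg.hub_corr, cfg.hub_module_size
        )
        for rho, mi in zip(loadings, module_idx[hi]):
            g_noise = rng.normal(size=n)
            member = np.where(
                in_wired,
                rho * f_hub + np.sqrt(1 - rho**2) * g_noise,
                g_noise,
            )
            log_signal[mi] += tau * member

    # ---- planted regulators: correlated with DE targets in group H only ----
    reg_targets = {}
    for r_ord, ri in enumerate(reg_idx):
        targets = [de_idx[k] for k in range(cfg.n_de) if k % cfg.n_regulators == r_ord]
        reg_targets[ri] = targets
        f_reg = rng.normal(size=n)
        log_signal[ri] += tau * f_reg
        rho = cfg.reg_corr
        for ti in targets:
            g_noise = rng.normal(size=n)
            target = np.where(
                is_h, rho * f_reg + np.sqrt(1 - rho**2) * g_noise, g_noise
            )
            log_signal[ti] += tau * target

    # ---- library sizes and NB sampling ----
    lo, hi = cfg.libsize_range
    lib = rng.uniform(lo, hi, size=n)
    means = np.exp(log_signal) * lib[None, :]
    counts = np.empty((m, n), dtype=np.int64)
    for i in range(m):
        counts[i] = _nb_draw(rng, means[i], float(alpha[i]))

    lengths = pd.Series(
        rng.integers(500, 5001, size=m), index=tids, name="length_bp"
    )
    counts_df = pd.DataFrame(counts, index=tids, columns=sample_ids)
    covars = pd.DataFrame({"group": group_labels}, index=sample_ids)
    # totals represent mapped reads to the *full* transcriptome, of which
    # the simulated transcripts are a subset; tying them to the library
    # factor (not the realised column sums) keeps FPKM from re-introducing
    # planted-module signal through the denominator
    totals = pd.Series(lib * NOMINAL_TOTAL, index=sample_ids, name="total")
    cm = CountMatrix(
        counts=counts_df,
        lengths=lengths,
        totals=totals,
        covariates=covars,
    )

    if truth is None:
        truth = SyntheticTruth()
    truth.de_ids = [tids[i] for i in de_idx]
    truth.hub_ids = {tids[hi]: g for hi, g in hub_groups.items()}
    truth.hub_members = {tids[hi]: [tids[j] for j in module_idx[hi]] for hi in hub_idx}
    truth.regulator_targets = {
        tids[ri]: [tids[t] for t in tg] for ri, tg in reg_targets.items()
    }
    return cm, truth


def write_tables(
    outdir,
    ped: Optional[pd.DataFrame] = None,
    phen: Optional[pd.DataFrame] = None,
    cm: Optional[CountMatrix] = None,
    truth: Optional[SyntheticTruth] = None,
) -> None:
    """Dump simulation outputs as plain-text tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if ped is not None:
        ped.to_csv(out / "pedigree.csv", index=False)
    if phen is not None:
        phen.to_csv(out / "phenotypes.csv", index=False)
    if cm is not None:
        cm.counts.to_csv(out / "counts.tsv", sep="\t")
        ann = pd.DataFrame(
            {
                "transcript_id": cm.counts.index,
                "length_bp": cm.lengths.values,
                "symbol": cm.counts.index,
            }
        )
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
        if cm.covariates is not None:
            cm.covariates.to_csv(out / "covariates.csv")
    if truth is not None:
        truth.to_json(out / "truth.json")
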