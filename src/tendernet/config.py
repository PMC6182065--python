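"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigError


@dataclass
class SimulationConfig:
    """Parameters of the synthetic half-sib + RNA-seq study.

    The defaults emulate the design of a progeny-test tenderness study:
    ~33 unrelated sires with half-sib progeny, Warner-Bratzler shear force
    (kgf/cm^2) with narrow-sense heritability ~0.3, and a two-group
    (high/low EBV) RNA-seq contrast with 11 and 13 animals per group.

    Attributes
    ----------
    n_sires, progeny_per_sire : int
        Half-sib family structure; sires are unrelated founders, dams unknown.
    h2 : float
        Narrow-sense heritability of shear force, in [0, 1].
    sigma2_p : float
        Phenotypic variance of shear force, (kgf/cm^2)^2.
    mu_sf : float
        Mean shear force, kgf/cm^2.
    n_cg : int
        Number of contemporary groups (fixed effect levels).
    age_slope : float
        Linear age effect on shear force, kgf/cm^2 per day.
    n_transcripts : int
        Transcriptome size of the simulated count matrix.
    n_samples_per_group : int
        Default per-group sample count when groups are not supplied.
    n_de : int
        Number of planted differentially expressed transcripts.
    lfc : float
        log2 fold change of planted DE transcripts between groups.
    nb_dispersion : float
        Negative-binomial dispersion alpha (var = m + alpha*m^2) of
        background transcripts; planted-structure transcripts use
        ``min(nb_dispersion, 2e-3)`` so that co-expression signal is not
        drowned by counting noise.
    libsize_range : tuple of float
        Uniform range of per-sample library-size factors.
    n_hubs, hub_module_size, hub_corr : int, int, float
        Planted hub structure: each hub drives a module of
        ``hub_module_size`` transcripts through a shared latent factor,
        wired in one group only (alternating H, L). Member loadings are
        graded over [hub_corr - 0.1, hub_corr]: an equicorrelated module
        is a degenerate clique in which every member is as connected as
        the hub, so grading is what makes the designated hub the
        best-connected module node.
    n_regulators, reg_corr : int, float
        Planted regulators: transcripts correlated (latent correlation
        ``reg_corr``) with their assigned DE targets in group H only, with
        no mean shift of their own.
    seed : int
        Master seed; all randomness flows from it through named streams.
    """

    n_sires: int = 33
    progeny_per_sire: int = 10
    h2: float = 0.3
    sigma2_p: float = 1.0
    mu_sf: float = 8.0
    n_cg: int = 4
    age_slope: float = 0.005
    n_transcripts: int = 300
    n_samples_per_group: int = 12
    n_de: int = 20
    lfc: float = 2.0
    nb_dispersion: float = 0.1
    libsize_range: tuple = (0.7, 1.3)
    n_hubs: int = 2
    hub_module_size: int = 30
    hub_corr: float = 0.97
    n_regulators: int = 2
    reg_corr: float = 0.90
    seed: int = 1234

    def validate(self) -> None:
        if self.n_sires < 2 or self.progeny_per_sire < 1:
            raise ConfigError(
                "invalid design: need n_sires >= 2 and progeny_per_sire >= 1 "
                f"(got {self.n_sires}, {self.progeny_per_sire})"
            )
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigError(f"h2 must be in [0, 1], got {self.h2}")
        if self.sigma2_p <= 0:
            raise ConfigError("sigma2_p must be positive")
        for name in ("n_cg", "n_transcripts", "n_samples_per_group"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_de > self.n_transcripts:
            raise ConfigError("n_de must not exceed n_transcripts")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ConfigError("libsize_range must be an increasing pair of positives")
        for name in ("hub_corr", "reg_corr"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        n_planted = (
            self.n_de
            + self.n_hubs * (1 + self.hub_module_size)
            + self.n_regulators
        )
        if n_planted > self.n_transcripts:
            raise ConfigError(
                f"planted structure needs {n_planted} transcripts but only "
                f"{self.n_transcripts} are simulated"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["libsize_range"] = list(self.libsize_range)
        return d


@dataclass
class PipelineConfig:
    """Full-pipeline configuration: thresholds, variance components, paths.

    Thresholds default to the analysis conventions of the study design:
    DE at q < 0.10, network edges at |r| >= 0.90 among PCIT-significant
    pairs, PIF significance at FDR < 0.05, enrichment at FDR < 0.10,
    top-3000 regulator lists, and extreme groups of 11 (H) and 13 (L).
    """

    outdir: str = "runs/default"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    q_de: float = 0.10
    r_threshold: float = 0.90
    pif_fdr: float = 0.05
    enrich_fdr: float = 0.10
    top_n: int = 3000
    n_high: int = 11
    n_low: int = 13
    # None, None -> estimate by EM-REML; otherwise used as given.
    sigma2_a: Optional[float] = None
    sigma2_e: Optional[float] = None
    prior_df: float = 10.0
    fdr_method: str = "storey"
    seed: int = 1234

    def validate(self) -> None:
        self.sim.validate()
        if not 0 < self.q_de <= 1:
            raise ConfigError("q_de must be in (0, 1]")
        if not 0 < self.r_threshold <= 1:
            raise ConfigError("r_threshold must be in (0, 1]")
        for name in ("pif_fdr", "enrich_fdr"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if self.n_high < 1 or self.n_low < 1:
            raise ConfigError("group sizes must be >= 1")
        if self.fdr_method not in ("storey", "bh"):
            raise ConfigError("fdr_method must be 'storey' or 'bh'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "libsize_range" in sim_raw:
            sim_raw["libsize_range"] = tuple(sim_raw["libsize_range"])
        known_sim = {f for f in SimulationConfig.__dataclass_fields__}
        known = {f for f in cls.__dataclass_fields__} - {"sim"}
        bad = (set(sim_raw) - known_sim) | (set(raw) - known)
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(sim=SimulationConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d
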