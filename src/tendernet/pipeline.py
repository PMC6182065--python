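"""Stage orchestration: file contracts, provenance manifest, full runs.

Stages communicate through plain-text tables in the run directory and can
be executed one at a time (``run_stage``) or end to end (``run_all``).
Every stage writes outputs atomically (temp file + rename) and appends a
provenance record (stage, config hash, input hashes, wall time) to
``manifest.jsonl``. On fully synthetic runs the final ``evaluate`` stage
scores recovery of the planted truth.

Stage order and file contract:

    simulate -> pedigree.csv, phenotypes.csv, truth.json
    ebv      -> ebv.tsv                       (EBVs, accuracies, H/L groups)
    assay    -> counts.tsv, annotation.tsv, covariates.csv  (selected animals)
    prep     -> filtered_counts.tsv, norm_factors.tsv, residual_fpkm.tsv
    de       -> de_results.tsv
    pcit     -> edges_H.tsv, edges_L.tsv, dh_table.tsv
    rifpif   -> scores.tsv, ranked lists
    enrich   -> enrichment_*.tsv              (needs terms.tsv; else skipped)
    evaluate -> evaluation.json
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .de import QuasiNB
from .ebv import AnimalModel
from .enrich import fisher_ora
from .errors import DataError
from .pcit import differential_hubbing, group_network
from .prep import (
    CountMatrix,
    compute_fpkm,
    filter_counts,
    residualize,
    uq_normalize,
)
from .rif import pif_scores, rank_and_slice, rif_scores
from .simulate import (
    SyntheticTruth,
    simulate_counts,
    simulate_pedigree_phenotypes,
)

log = logging.getLogger("tendernet")

#: produced-by map used in missing-input error messages
_PRODUCERS = {
    "pedigree.csv": "simulate",
    "phenotypes.csv": "simulate",
    "truth.json": "simulate",
    "ebv.tsv": "ebv",
    "counts.tsv": "assay",
    "annotation.tsv": "assay",
    "covariates.csv": "assay",
    "filtered_counts.tsv": "prep",
    "norm_factors.tsv": "prep",
    "residual_fpkm.tsv": "prep",
    "de_results.tsv": "de",
    "edges_H.tsv": "pcit",
    "edges_L.tsv": "pcit",
    "dh_table.tsv": "pcit",
    "scores.tsv": "rifpif",
}

STAGES = ("simulate", "ebv", "assay", "prep", "de", "pcit", "rifpif", "enrich", "evaluate")


def _require(outdir: Path, *names: str) -> list[Path]:
    paths = []
    for name in names:
        p = outdir / name
        if not p.exists():
            producer = _PRODUCERS.get(name, "an earlier stage")
            raise DataError(
                f"missing input {name!r}; run the {producer!r} stage first"
            )
        paths.append(p)
    return paths


def _atomic_write(path: Path, writer) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_table(path: Path, df: pd.DataFrame, index: bool = False) -> None:
    sep = "\t" if path.suffix == ".tsv" else ","
    _atomic_write(path, lambda tmp: df.to_csv(tmp, sep=sep, index=index))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest_append(outdir: Path, stage: str, cfg: PipelineConfig,
                     inputs: list[Path], outputs: list[Path], t0: float) -> None:
    rec = {
        "stage": stage,
        "version": __version__,
        "config_sha": hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "inputs": {p.name: _hash_file(p) for p in inputs},
        "outputs": {p.name: _hash_file(p) for p in outputs if p.exists()},
        "wall_s": round(time.time() - t0, 3),
    }
    with open(outdir / "manifest.jsonl", "a") as fh:
        fh.write(json.dumps(rec, sort_keys=True) + "\n")


# ---------------------------------------------------------------- stages


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    ped, phen, truth = simulate_pedigree_phenotypes(cfg.sim)
    _write_table(outdir / "pedigree.csv", ped)
    _write_table(outdir / "phenotypes.csv", phen)
    _atomic_write(outdir / "truth.json", truth.to_json)
    return [outdir / n for n in ("pedigree.csv", "phenotypes.csv", "truth.json")]


def _stage_ebv(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    ped_p, phen_p = _require(outdir, "pedigree.csv", "phenotypes.csv")
    ped = pd.read_csv(ped_p, dtype=str)
    phen = pd.read_csv(phen_p)
    model = AnimalModel.from_tables(ped, phen)
    res = model.fit(sigma2_a=cfg.sigma2_a, sigma2_e=cfg.sigma2_e)
    log.info("animal model: h2=%.3f (sigma2_a=%.4g, sigma2_e=%.4g)",
             res.h2, res.sigma2_a, res.sigma2_e)
    # only phenotyped animals are sampling candidates
    tab = res.select_extremes(cfg.n_high, cfg.n_low,
                              candidates=phen["animal"].tolist())
    fit_info = {
        "sigma2_a": res.sigma2_a, "sigma2_e": res.sigma2_e, "h2": res.h2,
        "reml": res.reml,
    }
    _atomic_write(outdir / "variance_components.json",
                  lambda tmp: Path(tmp).write_text(json.dumps(fit_info, indent=1)))
    _write_table(outdir / "ebv.tsv", tab)
    return [outdir / "ebv.tsv", outdir / "variance_components.json"]


def _stage_assay(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    ebv_p, phen_p = _require(outdir, "ebv.tsv", "phenotypes.csv")
    ebv = pd.read_csv(ebv_p, sep="\t", dtype={"animal": str})
    phen = pd.read_csv(phen_p, dtype={"animal": str}).set_index("animal")
    selected = ebv[ebv["group"].isin(["H", "L"])]
    truth = SyntheticTruth.from_json(outdir / "truth.json") \
        if (outdir / "truth.json").exists() else None
    cm, truth = simulate_counts(
        cfg.sim,
        group_labels=selected["group"].tolist(),
        sample_ids=selected["animal"].tolist(),
        truth=truth,
    )
    covars = cm.covariates
    covars["sf"] = phen.loc[covars.index, "sf"].values
    covars["cg"] = phen.loc[covars.index, "cg"].values
    covars["age"] = phen.loc[covars.index, "age"].values
    covars["lane"] = [f"lane{i % 2 + 1}" for i in range(len(covars))]
    _write_table(outdir / "counts.tsv", cm.counts, index=True)
    ann = pd.DataFrame(
        {"transcript_id": cm.counts.index, "length_bp": cm.lengths.values,
         "symbol": cm.counts.index}
    )
    _write_table(outdir / "annotation.tsv", ann)
    _write_table(outdir / "covariates.csv", covars, index=True)
    _atomic_write(outdir / "truth.json", truth.to_json)
    return [outdir / n for n in
            ("counts.tsv", "annotation.tsv", "covariates.csv", "truth.json")]


def _load_count_matrix(outdir: Path, counts_name: str) -> CountMatrix:
    counts_p, ann_p, cov_p = _require(
        outdir, counts_name, "annotation.tsv", "covariates.csv"
    )
    counts = pd.read_csv(counts_p, sep="\t", index_col=0)
    ann = pd.read_csv(ann_p, sep="\t").set_index("transcript_id")
    covars = pd.read_csv(cov_p, index_col=0)
    covars.index = covars.index.astype(str)
    counts.columns = counts.columns.astype(str)
    totals_p = outdir / "totals.tsv"
    if totals_p.exists():
        totals = pd.read_csv(totals_p, sep="\t", index_col=0).iloc[:, 0]
    else:
        totals = counts.sum(axis=0).astype(float)
    return CountMatrix(
        counts=counts,
        lengths=ann["length_bp"].reindex(counts.index),
        totals=totals,
        covariates=covars,
    )


RESIDUAL_COVARIATES = ["cg", "age", "lane"]


def _stage_prep(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    cm = _load_count_matrix(outdir, "counts.tsv")
    filtered, tally = filter_counts(cm)
    log.info("filtering: %s", tally)
    _, factors = uq_normalize(filtered)
    fpkm = compute_fpkm(filtered)
    covars = filtered.covariates[
        [c for c in RESIDUAL_COVARIATES if c in filtered.covariates.columns]
    ]
    resid = residualize(fpkm, covars)
    _write_table(outdir / "filtered_counts.tsv", filtered.counts, index=True)
    _write_table(outdir / "norm_factors.tsv",
                 factors.rename("factor").rename_axis("sample").reset_index())
    _write_table(outdir / "residual_fpkm.tsv", resid.values, index=True)
    _atomic_write(outdir / "filter_tally.json",
                  lambda tmp: Path(tmp).write_text(json.dumps(tally, indent=1)))
    return [outdir / n for n in
            ("filtered_counts.tsv", "norm_factors.tsv", "residual_fpkm.tsv")]


def _stage_de(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    cm = _load_count_matrix(outdir, "filtered_counts.tsv")
    (nf_p,) = _require(outdir, "norm_factors.tsv")
    factors = pd.read_csv(nf_p, sep="\t").set_index("sample")["factor"]
    factors.index = factors.index.astype(str)
    from .prep import build_design

    cov_cols = [c for c in ("cg", "age", "lane", "sf") if c in cm.covariates.columns]
    design = build_design(cm.covariates[cov_cols])
    model = QuasiNB(cm.counts, design, test_col="sf", norm_factors=factors)
    res = model.fit(prior_df=cfg.prior_df, fdr_method=cfg.fdr_method)
    log.info("DE: %d transcripts at q < %g", len(res.significant(cfg.q_de)), cfg.q_de)
    out = res.frame.rename_axis("transcript_id").reset_index()
    _write_table(outdir / "de_results.tsv", out)
    return [outdir / "de_results.tsv"]


def _load_expression(outdir: Path):
    from .prep import ExpressionMatrix

    resid_p, cov_p = _require(outdir, "residual_fpkm.tsv", "covariates.csv")
    values = pd.read_csv(resid_p, sep="\t", index_col=0)
    values.columns = values.columns.astype(str)
    covars = pd.read_csv(cov_p, index_col=0)
    covars.index = covars.index.astype(str)
    return ExpressionMatrix(values=values, groups=covars["group"],
                            stage="residual_fpkm")


def _stage_pcit(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    em = _load_expression(outdir)
    net_h = group_network(em, "H", r_threshold=cfg.r_threshold)
    net_l = group_network(em, "L", r_threshold=cfg.r_threshold)
    dh = differential_hubbing(net_h, net_l)
    log.info("PCIT: %d edges (H), %d edges (L)", len(net_h.edges), len(net_l.edges))
    _write_table(outdir / "edges_H.tsv", net_h.edges)
    _write_table(outdir / "edges_L.tsv", net_l.edges)
    _write_table(outdir / "dh_table.tsv", dh)
    return [outdir / n for n in ("edges_H.tsv", "edges_L.tsv", "dh_table.tsv")]


def _read_network(outdir: Path, group: str):
    from .pcit import GroupNetwork

    (edges_p,) = _require(outdir, f"edges_{group}.tsv")
    (resid_p,) = _require(outdir, "residual_fpkm.tsv")
    nodes = pd.read_csv(resid_p, sep="\t", index_col=0).index.tolist()
    edges = pd.read_csv(edges_p, sep="\t")
    if edges.empty:
        edges = pd.DataFrame(columns=["node_a", "node_b", "r"])
    return GroupNetwork(group=group, nodes=nodes, edges=edges)


def _stage_rifpif(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    em = _load_expression(outdir)
    (de_p,) = _require(outdir, "de_results.tsv")
    de = pd.read_csv(de_p, sep="\t").set_index("transcript_id")
    de_ids = de.index[de["q"] < cfg.q_de].tolist()
    net_h = _read_network(outdir, "H")
    net_l = _read_network(outdir, "L")
    pif = pif_scores(em)
    scores = rif_scores(pif, de_ids, net_h, net_l)
    out = scores.rename_axis("transcript_id").reset_index()
    _write_table(outdir / "scores.tsv", out)
    outputs = [outdir / "scores.tsv"]
    for col in ("PIF", "RIF1_z", "RIF2_z"):
        sliced = rank_and_slice(scores[col], top_n=cfg.top_n)
        for direction in ("top_positive", "top_negative"):
            p = outdir / f"ranked_{col}_{direction}.tsv"
            _write_table(p, sliced[direction])
            outputs.append(p)
    return outputs


def _stage_enrich(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    terms_p = outdir / "terms.tsv"
    if not terms_p.exists():
        log.info("no terms.tsv present; enrichment skipped")
        return []
    terms = pd.read_csv(terms_p, sep="\t")
    (scores_p,) = _require(outdir, "scores.tsv")
    scores = pd.read_csv(scores_p, sep="\t").set_index("transcript_id")
    background = set(scores.index)
    outputs = []
    queries = {
        "pif_significant": set(scores.index[scores["PIF_fdr"] < cfg.pif_fdr]),
        "rif1_top": set(
            rank_and_slice(scores["RIF1_z"], cfg.top_n)["top_positive"]["transcript"]
        )
        | set(rank_and_slice(scores["RIF1_z"], cfg.top_n)["top_negative"]["transcript"]),
    }
    dh_p = outdir / "dh_table.tsv"
    if dh_p.exists():
        dh = pd.read_csv(dh_p, sep="\t")
        top_hub = dh.iloc[dh["DH"].abs().idxmax()]["transcript"]
        net = _read_network(outdir, "H")
        try:
            nbrs = net.neighbors(top_hub)
            queries["top_hub_targets"] = set(nbrs["target"]) & background
        except DataError:
            pass
    for name, query in queries.items():
        if not query:
            continue
        res = fisher_ora(query & background, background, terms)
        p = outdir / f"enrichment_{name}.tsv"
        _write_table(p, res)
        outputs.append(p)
    return outputs


def _stage_evaluate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    (truth_p,) = _require(outdir, "truth.json")
    truth = SyntheticTruth.from_json(truth_p)
    report: dict = {}

    ebv_p = outdir / "ebv.tsv"
    if ebv_p.exists() and truth.true_breeding_values is not None:
        ebv = pd.read_csv(ebv_p, sep="\t", dtype={"animal": str})
        tbv = truth.true_breeding_values
        sel = ebv[ebv["group"].isin(["H", "L"])]
        means = sel.groupby("group")["animal"].apply(
            lambda ids: float(tbv.loc[list(ids)].mean())
        )
        report["ebv"] = {
            "mean_true_bv_H": means.get("H", float("nan")),
            "mean_true_bv_L": means.get("L", float("nan")),
            "separation": float(means.get("H", np.nan) - means.get("L", np.nan)),
        }

    de_p = outdir / "de_results.tsv"
    if de_p.exists():
        de = pd.read_csv(de_p, sep="\t").set_index("transcript_id")
        called = set(de.index[de["q"] < cfg.q_de])
        planted = set(truth.de_ids) & set(de.index)
        report["de"] = {
            "n_called": len(called),
            "n_planted_tested": len(planted),
            "recall": len(called & planted) / len(planted) if planted else None,
            "false_discoveries": len(called - set(truth.de_ids)),
        }

    dh_p = outdir / "dh_table.tsv"
    if dh_p.exists() and truth.hub_ids:
        dh = pd.read_csv(dh_p, sep="\t").set_index("transcript")
        # per wired direction: is the top DH position held by the hub's
        # planted module, and where does the designated hub itself rank?
        module_top = 0
        hub_ranks = {}
        sign_ok = 0
        for h, g in truth.hub_ids.items():
            col = dh["DH"] if g == "H" else -dh["DH"]
            module = {h} | set(truth.hub_members.get(h, []))
            top_id = col.idxmax()
            module_top += int(top_id in module and col[top_id] > 0)
            if h in dh.index:
                hub_ranks[h] = int((col > col[h]).sum()) + 1
                sign_ok += int(np.sign(dh.loc[h, "DH"]) == (1 if g == "H" else -1))
        report["dh"] = {
            "module_top_of_direction": module_top / len(truth.hub_ids),
            "hub_rank_in_direction": hub_ranks,
            "hub_sign_agreement": sign_ok / len(truth.hub_ids),
            "planted_dh": {h: int(dh.loc[h, "DH"]) for h in truth.hub_ids
                           if h in dh.index},
        }

    scores_p = outdir / "scores.tsv"
    if scores_p.exists() and truth.regulator_targets:
        scores = pd.read_csv(scores_p, sep="\t").set_index("transcript_id")
        absz = scores["RIF1_z"].abs()
        cut = absz.quantile(0.95)
        regs = [r for r in truth.regulator_targets if r in scores.index]
        in_top5 = sum(absz.loc[r] >= cut for r in regs)
        pif_abs = scores["PIF"].abs()
        pif_cut = pif_abs.quantile(0.99)
        report["rif"] = {
            "regulator_top5pct_rif1": in_top5 / len(regs) if regs else None,
            "regulator_rif1_z": {r: float(scores.loc[r, "RIF1_z"]) for r in regs},
            "regulators_in_pif_top1pct": int(
                sum(pif_abs.loc[r] >= pif_cut for r in regs)
            ),
        }

    _atomic_write(
        outdir / "evaluation.json",
        lambda tmp: Path(tmp).write_text(json.dumps(report, indent=1, sort_keys=True)),
    )
    return [outdir / "evaluation.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "ebv": _stage_ebv,
    "assay": _stage_assay,
    "prep": _stage_prep,
    "de": _stage_de,
    "pcit": _stage_pcit,
    "rifpif": _stage_rifpif,
    "enrich": _stage_enrich,
    "evaluate": _stage_evaluate,
}


def run_stage(name: str, cfg: PipelineConfig) -> list[Path]:
    """Run one pipeline stage; returns the paths it wrote."""
    if name not in _STAGE_FUNCS:
        raise DataError(f"unknown stage {name!r}; stages are {STAGES}")
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    outputs = _STAGE_FUNCS[name](cfg, outdir)
    inputs = [p for p in outdir.iterdir()
              if p.name in _PRODUCERS and p not in outputs]
    _manifest_append(outdir, name, cfg, inputs, outputs, t0)
    log.info("stage %s done (%.1fs)", name, time.time() - t0)
    return outputs


def run_all(cfg: PipelineConfig) -> dict:
    """Full synthetic chain; returns the evaluation report."""
    for stage in STAGES:
        run_stage(stage, cfg)
    report = json.loads((Path(cfg.outdir) / "evaluation.json").read_text())
    return report
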