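"""End-to-end pipeline: simulate -> preprocess -> factors -> enrichment ->
network -> survival -> drugs.

Each stage is a plain function taking the products of the previous ones, so
the pipeline is equally usable stage by stage from Python; ``run_pipeline``
chains them, writes every stage's outputs as TSV/JSON before the next stage
starts, and records a manifest (config hash, seed, timings, row counts).
Identical config + seed yields identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import drug_response, enrichment, factors, io, network, preprocess
from . import survival as surv
from . import synthetic
from .config import child_seed, config_hash, make_config

logger = logging.getLogger(__name__)


def simulate_stage(cfg: dict, seed: int):
    scfg = cfg["synthetic"]
    design = synthetic.TimeCourseDesign(
        n_features=dict(scfg["n_features"]), n_factors=scfg["n_factors"],
        effect_size=scfg["effect_size"], n_signature=scfg["n_signature"],
        seed=child_seed(seed, "timecourse"))
    dataset = synthetic.generate_timecourse(design)
    kb = synthetic.generate_knowledge_bases(
        dataset.truth,
        synthetic.KnowledgeParams(seed=child_seed(seed, "knowledge")))
    return dataset, kb


def preprocess_stage(dataset: synthetic.MultiOmicsDataset, cfg: dict, seed: int):
    pcfg = cfg["preprocess"]
    meta = dataset.sample_meta
    processed: dict[str, pd.DataFrame] = {}
    regulated: dict[str, list[str]] = {}
    diffs: dict[str, pd.DataFrame] = {}
    for view_name, mat in dataset.views.items():
        cond = meta.loc[mat.columns, "time"].astype(str)
        batch = meta.loc[mat.columns, "batch"]
        if view_name == "rna":
            sf = preprocess.size_factors(mat)
            x = preprocess.transform_counts(mat, sf)
            x = preprocess.remove_batch(x, batch, preserve=cond)
        else:
            x = preprocess.normalize_abundance(mat)
            x = preprocess.impute(
                x, cond, min_observed_frac=pcfg["min_observed_frac"],
                tail_shift=pcfg["tail_shift"],
                tail_sd_scale=pcfg["tail_sd_scale"],
                seed=child_seed(seed, f"impute:{view_name}"))
            x = preprocess.remove_batch(x, batch, preserve=cond)
        diff = preprocess.differential(x, meta)
        regulated[view_name] = preprocess.filter_regulated(
            diff, view_name, feature_meta=dataset.feature_meta[view_name],
            lfc_thresh=pcfg["lfc_thresh"], p_thresh=pcfg["p_thresh"])
        processed[view_name] = x
        diffs[view_name] = diff
    return processed, diffs, regulated


def factor_stage(processed: dict[str, pd.DataFrame],
                 regulated: dict[str, list[str]],
                 meta: pd.DataFrame, cfg: dict):
    tcfg = cfg["tfa"]
    views = {v: processed[v].loc[regulated[v]] for v in processed
             if regulated[v]}
    scaled = factors.scale_views(views)
    time_cov = meta["time"].astype(float)
    k_cap = min(tcfg["k_max"], min(m.shape[0] for m in scaled.values()))
    model, vd = factors.select_model(
        scaled, time_cov, k_max=k_cap, k_min=tcfg["k_min"],
        lam=tcfg["lam"], tol=tcfg["tol"], max_iter=tcfg["max_iter"])
    kept = factors.select_factors(vd)
    waves = factors.assign_waves(model, vd, factors=kept,
                                 exclusion_z=tcfg["exclusion_z"])
    selected = {}
    for k in kept:
        for v in scaled:
            if v in waves.excluded_views.get(k, []):
                continue
            selected[(v, k)] = factors.select_features(
                model, v, k, z_thresh=tcfg["z_thresh"])
    return {"model": model, "variance": vd, "kept": kept, "waves": waves,
            "selected": selected, "scaled": scaled}


def _meki_direction(model: factors.FactorModel, factor: str,
                    wave_time: float) -> int:
    """Sign of the factor trajectory's move from baseline at its wave."""
    z = model.Z[factor]
    t = model.time
    base = z[t == t.min()].mean()
    after = z[t >= wave_time].mean()
    return int(np.sign(after - base)) or 1


def effector_table(fit: dict, feature_meta: dict[str, pd.DataFrame],
                   tf_hits: pd.DataFrame | None = None,
                   kinase_hits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wave-annotated effector genes from the factor, TFEA and kinase analyses.

    Feature direction upon MEK inhibition is the product of its weight sign
    and the factor trajectory's activation direction; phosphosites map to
    their parent gene.  Returns (gene, layer, wave, direction_upon_meki,
    source).
    """
    model: factors.FactorModel = fit["model"]
    waves: factors.WaveAssignment = fit["waves"]
    rows = []
    for (view, factor), table in fit["selected"].items():
        if factor not in waves.wave_time:
            continue
        wtime = waves.wave_time[factor]
        traj_dir = _meki_direction(model, factor, wtime)
        genes = feature_meta[view]["gene"]
        for _, r in table.iterrows():
            rows.append({"gene": genes.get(r["feature"], r["feature"]),
                         "layer": view, "wave": wtime,
                         "direction_upon_meki": int(r["direction"]) * traj_dir,
                         "source": "factor"})
    if tf_hits is not None:
        for _, r in tf_hits.iterrows():
            rows.append({"gene": r["tf"], "layer": "rna", "wave": 60.0,
                         "direction_upon_meki": int(r["direction"]) or 1,
                         "source": "tfea"})
    if kinase_hits is not None:
        for _, r in kinase_hits.iterrows():
            rows.append({"gene": r["kinase"], "layer": "phospho",
                         "wave": 15.0,
                         "direction_upon_meki": int(r["direction"]) or 1,
                         "source": "kinase"})
    return pd.DataFrame(rows)


def enrichment_stage(processed, diffs, fit, kb, cfg: dict, seed: int):
    ecfg = cfg["enrichment"]
    # ssGSEA scorecards per layer on the gene sets measurable in that layer
    cards = {}
    for view_name, mat in processed.items():
        usable = {}
        for name, members in kb.gene_sets.items():
            if 0 < len(set(members) & set(mat.index)) < mat.shape[0]:
                usable[name] = members
        if usable:
            cards[view_name] = enrichment.ssgsea(mat, usable,
                                                 alpha=ecfg["alpha"])
    consistent = enrichment.consistency_filter(
        {v: c.sub(c.mean(axis=1), axis=0).div(
            c.std(axis=1, ddof=0).replace(0, np.nan), axis=0).fillna(0.0)
         for v, c in cards.items()},
        min_effect=ecfg["min_effect"]) if len(cards) >= 2 else []
    # TFEA on the 6 h differentially regulated genes (target-gene wave)
    rna_diff = diffs["rna"]
    at6h = rna_diff[rna_diff["time"] == 360.0]
    hits = at6h[(at6h["log2FC"].abs() > 1.0) & (at6h["p"] < 0.05)]
    universe = rna_diff["feature"].unique().tolist()
    tf_hits = pd.DataFrame()
    if not hits.empty:
        directions = dict(zip(hits["feature"],
                              np.sign(hits["log2FC"]).astype(int)))
        tf_res = enrichment.tfea(hits["feature"].unique().tolist(),
                                 kb.tf_target, universe,
                                 query_directions=directions)
        if not tf_res.empty:
            tf_hits = tf_res[tf_res["p_adj"] < 0.05]
    # KSEA on the late (24 h) phosphosite fold changes
    ph = diffs["phospho"]
    late = ph[ph["time"] == ph["time"].max()].set_index("feature")["log2FC"]
    ksea_res = enrichment.ksea(late, kb.kinase_substrate,
                               p_cut=ecfg["ksea_p_cut"],
                               m_min=ecfg["ksea_m_min"])
    return {"scorecards": cards, "consistent_sets": consistent,
            "tf_hits": tf_hits, "ksea": ksea_res}


def network_stage(fit, enrich, kb, dataset, cfg: dict, seed: int):
    ncfg = cfg["network"]
    sene = network.senequest_filter(kb.senescence_evidence,
                                    min_refs=ncfg["min_refs"])
    kin_hits = enrich["ksea"][enrich["ksea"]["reported"]] \
        if not enrich["ksea"].empty else None
    kinase_nodes = None
    phos_selected = [t.assign(view="phospho") for (v, k), t
                     in fit["selected"].items() if v == "phospho"]
    if phos_selected:
        sites = pd.concat(phos_selected, ignore_index=True)
        kinase_nodes = network.infer_kinases(sites, kb.kinase_substrate)
    effectors = effector_table(
        fit, dataset.feature_meta,
        tf_hits=enrich["tf_hits"] if len(enrich["tf_hits"]) else None,
        kinase_hits=kinase_nodes if kinase_nodes is not None
        and len(kinase_nodes) else None)
    signatures = network.assemble_signature(effectors, sene)
    nets = {name: network.build_wave_network(
        nodes, kb.interactions, edge_min_refs=ncfg["edge_min_refs"])
        for name, nodes in signatures.items() if len(nodes)}
    nulls = {}
    universe = sene["gene"].tolist()
    for name, nodes in signatures.items():
        if len(nodes) and len(universe) > len(nodes):
            nulls[name] = network.connectivity_null(
                nodes["gene"].tolist(), universe, kb.ppi,
                B=ncfg["null_B"], seed=child_seed(seed, f"null:{name}"))
    return {"senescence": sene, "signatures": signatures,
            "networks": nets, "nulls": nulls}


def survival_stage(cfg: dict, seed: int):
    vcfg = cfg["survival"]
    spec = synthetic.SurvivalCohortSpec(
        n_patients=vcfg["n_patients"],
        true_hazard_ratio=vcfg["true_hazard_ratio"],
        censoring_rate=vcfg["censoring_rate"],
        seed=child_seed(seed, "cohort"))
    cohort = synthetic.generate_cohort(spec)
    scan = surv.scan_cutoff(cohort["score"], cohort["time"], cohort["event"],
                            min_group_frac=vcfg["min_group_frac"])
    cohort = cohort.assign(high_score=(cohort["score"]
                                       > scan.best_cutoff).astype(int))
    uni = surv.cox_fit(cohort, ["high_score", "site", "resection",
                                "alteration"], mode="univariate")
    multi = surv.cox_fit(cohort, ["high_score", "site", "resection",
                                  "alteration"], mode="multivariate")
    return {"cohort": cohort, "scan": scan, "cox_uni": uni,
            "cox_multi": multi}


def drugs_stage(cfg: dict, seed: int):
    dcfg = cfg["drugs"]
    spec = synthetic.DrugPlateSpec(replicate_noise_sd=dcfg["replicate_noise_sd"],
                                   seed=child_seed(seed, "plate"))
    data = synthetic.generate_dose_response(spec)
    plate, screen, truth = data["plate"], data["screen"], data["truth"]
    fits = []
    for (drug, condition), grp in plate.groupby(["drug", "condition"]):
        fit = drug_response.fit_4pl(grp["dose"], grp["response"])
        fits.append({"drug": drug, "condition": condition, "ic50": fit.ic50,
                     "top": fit.top, "bottom": fit.bottom, "hill": fit.hill,
                     "converged": fit.converged})
    fits = pd.DataFrame(fits)
    calls = screen.assign(
        called_class=[drug_response.classify_drug(a, t, delta=dcfg["delta"])
                      for a, t in zip(screen["A"], screen["T"])])
    calls = calls.merge(truth[["drug", "true_class"]], on="drug")
    return {"plate": plate, "fits": fits, "calls": calls, "truth": truth}


def run_pipeline(cfg: dict | None = None, outdir: str | Path = "pipeline_out",
                 stages=("simulate", "preprocess", "tfa", "enrichment",
                         "network", "survival", "drugs")) -> dict:
    """Run the full pipeline and write per-stage outputs plus a manifest.

    Returns the in-memory products of every stage (``manifest`` included).
    """
    cfg = make_config(cfg if isinstance(cfg, dict) else None) \
        if not _is_complete(cfg) else cfg
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash(cfg), "seed": seed,
                "stages": {}, "version": "0.1.0"}
    products: dict = {"config": cfg}

    def record(name, t0, counts):
        manifest["stages"][name] = {"seconds": round(_time.time() - t0, 3),
                                    "counts": counts}

    t0 = _time.time()
    dataset, kb = simulate_stage(cfg, seed)
    products.update(dataset=dataset, kb=kb)
    for v, m in dataset.views.items():
        io.write_matrix(m, outdir / f"view_{v}.tsv")
    dataset.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t")
    io.write_gmt(kb.gene_sets, outdir / "gene_sets.gmt")
    io.write_table(kb.senescence_evidence, outdir / "senescence_evidence.tsv")
    record("simulate", t0, {v: m.shape[0] for v, m in dataset.views.items()})

    if "preprocess" in stages:
        t0 = _time.time()
        processed, diffs, regulated = preprocess_stage(dataset, cfg, seed)
        products.update(processed=processed, diffs=diffs, regulated=regulated)
        for v, d in diffs.items():
            io.write_table(d, outdir / f"differential_{v}.tsv")
        record("preprocess", t0, {v: len(r) for v, r in regulated.items()})

    if "tfa" in stages:
        t0 = _time.time()
        fit = factor_stage(products["processed"], products["regulated"],
                           dataset.sample_meta, cfg)
        products["fit"] = fit
        fit["model"].Z.to_csv(outdir / "factor_scores.tsv", sep="\t")
        fit["variance"].per_view_factor.to_csv(outdir / "variance_r2.tsv",
                                               sep="\t")
        record("tfa", t0, {"K": fit["model"].K, "kept": len(fit["kept"])})

    if "enrichment" in stages:
        t0 = _time.time()
        enrich = enrichment_stage(products["processed"], products["diffs"],
                                  products["fit"], kb, cfg, seed)
        products["enrich"] = enrich
        if not enrich["ksea"].empty:
            io.write_table(enrich["ksea"], outdir / "ksea.tsv")
        record("enrichment", t0,
               {"consistent_sets": len(enrich["consistent_sets"]),
                "tf_hits": len(enrich["tf_hits"])})

    if "network" in stages:
        t0 = _time.time()
        net = network_stage(products["fit"], products["enrich"], kb,
                            dataset, cfg, seed)
        products["net"] = net
        for name, nodes in net["signatures"].items():
            io.write_table(nodes, outdir / f"signature_{name}.tsv")
        for name, n in net["networks"].items():
            network.export_sif(n, outdir / f"network_{name}.sif")
            io.write_table(n.edges, outdir / f"edges_{name}.tsv")
        record("network", t0, {name: len(nodes) for name, nodes
                               in net["signatures"].items()})

    if "survival" in stages:
        t0 = _time.time()
        sv = survival_stage(cfg, seed)
        products["survival"] = sv
        sv["cohort"].to_csv(outdir / "cohort.tsv", sep="\t")
        io.write_table(sv["cox_multi"].table, outdir / "cox_multivariate.tsv")
        record("survival", t0,
               {"n": len(sv["cohort"]), "cutoffs": sv["scan"].n_tested})

    if "drugs" in stages:
        t0 = _time.time()
        dr = drugs_stage(cfg, seed)
        products["drugs"] = dr
        io.write_table(dr["fits"], outdir / "drug_fits.tsv")
        io.write_table(dr["calls"], outdir / "drug_calls.tsv")
        record("drugs", t0, {"drugs": dr["calls"]["drug"].nunique()})

    products["manifest"] = manifest
    tmp = outdir / ".manifest.json.tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2)
    os.replace(tmp, outdir / "manifest.json")  # atomic at run end
    return products


def _is_complete(cfg) -> bool:
    from .config import DEFAULTS
    return isinstance(cfg, dict) and set(DEFAULTS) <= set(cfg)
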