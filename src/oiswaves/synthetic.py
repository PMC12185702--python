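"""Synthetic multi-omics study generator with known ground truth.

Emulates a MEK-inhibitor time course in senescent MAPK-driven glioma cells:
RNA counts, protein and phosphopeptide log-abundances are driven by latent
temporal factors, one per "wave" of MAPK pathway activity (direct substrate
phosphorylation ~15 min, immediate-early genes ~1 h, target genes ~6 h, late
remodelling ~24 h).  Companion generators produce the prior-knowledge tables
(senescence evidence, signed interactions, PPI, kinase-substrate, TF-target,
gene sets), a survival cohort under a proportional-hazards model, and
dose-response plates, so that every downstream stage of the pipeline can be
exercised against a planted truth.

Design choices
--------------
* Factor trajectories are sigmoidal wave pulses in log-time: a factor switches
  on at its wave's time point and off at the next wave's time point (the last
  wave stays on).  Trajectories are centred and orthogonalised across samples
  so that planted factors are identifiable and largely uncorrelated.
* Each factor loads on a disjoint block of genes, half of them down upon MEK
  inhibition (i.e. up in the senescent baseline, "OIS_UP") and half up upon
  MEK inhibition ("OIS_DN").
* Proteomic missingness is missing-not-at-random: the dropout probability is
  a logistic function of latent abundance, mimicking low-intensity dropout in
  LC-MS data.
* RNA counts are negative-binomial around ``exp(baseline + W Z)`` with fixed
  dispersion; setting a view's ``noise_sd`` to zero switches the view to its
  noiseless limit (counts become the rounded mean).
* All randomness flows from a single integer seed through one
  ``numpy.random.Generator`` per artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VIEWS = ("rna", "protein", "phospho")

# relative per-factor scale taper: later-ranked factors carry less signal,
# which keeps the planted factors separable by variance (as ranked factor
# models display in practice)
_FACTOR_TAPER = 0.9


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed) % (2**31))


@dataclass
class TimeCourseDesign:
    """Design of the MEKi time-course experiment.

    Parameters
    ----------
    time_points : ordered durations in minutes; must start at 0 (control).
    replicates : biological replicates per view (3 RNA, 4 protein/phospho
        by default, matching the emulated experiment).
    n_features : features per view.
    n_factors : number of latent wave factors (``K_true``).
    wave_of_factor : map factor index (0-based) -> wave index 1..4, where
        wave ``w`` activates at ``time_points[w]``.
    effect_size : per-factor loading scale; a scalar is tapered by 0.9 per
        rank so planted factors remain distinguishable.
    noise_sd : per-view observation noise (log-scale for RNA); 0 gives the
        noiseless limit.
    baseline_sd : per-view spread of feature baselines.
    batch_sd : per-view additive batch-offset scale (log-scale for RNA).
    missing_rate : MNAR dropout fraction for protein/phospho; must be 0
        for the RNA view.
    n_signature : planted signature genes per factor (split across layers).
    dispersion : negative-binomial dispersion for RNA counts.
    """

    time_points: tuple[float, ...] = (0.0, 15.0, 60.0, 360.0, 1440.0)
    replicates: Mapping[str, int] = field(
        default_factory=lambda: {"rna": 3, "protein": 4, "phospho": 4})
    n_features: Mapping[str, int] = field(
        default_factory=lambda: {"rna": 2000, "protein": 800, "phospho": 600})
    n_factors: int = 4
    wave_of_factor: Mapping[int, int] | None = None
    effect_size: float | Sequence[float] = 2.0
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"rna": 0.3, "protein": 0.5, "phospho": 0.6})
    baseline_sd: Mapping[str, float] = field(
        default_factory=lambda: {"rna": 1.0, "protein": 1.5, "phospho": 1.5})
    batch_sd: Mapping[str, float] = field(
        default_factory=lambda: {"rna": 0.2, "protein": 0.3, "phospho": 0.3})
    missing_rate: Mapping[str, float] = field(
        default_factory=lambda: {"rna": 0.0, "protein": 0.20, "phospho": 0.25})
    n_batches: int = 2
    n_signature: int = 30
    dispersion: float = 0.1
    rna_baseline_log_mean: float = math.log(100.0)
    seed: int = 0

    def waves(self) -> dict[int, int]:
        if self.wave_of_factor is not None:
            return dict(self.wave_of_factor)
        return {k: k + 1 for k in range(self.n_factors)}

    def effect_sizes(self) -> np.ndarray:
        if np.isscalar(self.effect_size):
            return float(self.effect_size) * _FACTOR_TAPER ** np.arange(self.n_factors)
        arr = np.asarray(self.effect_size, dtype=float)
        if arr.shape != (self.n_factors,):
            raise ValueError("effect_size sequence must have one entry per factor")
        return arr

    def validate(self) -> None:
        tp = np.asarray(self.time_points, dtype=float)
        if tp[0] != 0.0:
            raise ValueError("time 0 (control) must be the first time point")
        if np.any(np.diff(tp) <= 0) or np.any(tp < 0):
            raise ValueError("time points must be non-negative and strictly increasing")
        for v in VIEWS:
            if self.replicates[v] < 1 or self.n_features[v] < 1:
                raise ValueError("replicates and n_features must be positive")
            if not 0.0 <= self.missing_rate.get(v, 0.0) < 1.0:
                raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_rate.get("rna", 0.0) != 0.0:
            raise ValueError("RNA view must have missing_rate 0")
        if self.n_factors > min(self.n_features.values()):
            raise ValueError("K_true exceeds the smallest view's feature count")
        for k, w in self.waves().items():
            if not 1 <= w < len(tp):
                raise ValueError(f"factor {k}: wave index {w} has no time point > 0")


@dataclass
class MultiOmicsDataset:
    """Aligned per-view matrices plus sample metadata and optional truth.

    All views index their columns into a single global sample table
    (``sample_meta``); a view with fewer replicates simply omits the extra
    samples but preserves the global ordering.
    """

    views: dict[str, pd.DataFrame]
    sample_meta: pd.DataFrame  # index: sample id; columns: time, batch, replicate
    feature_meta: dict[str, pd.DataFrame]
    truth: dict | None = None

    def validate(self) -> None:
        order = list(self.sample_meta.index)
        pos = {s: i for i, s in enumerate(order)}
        for name, mat in self.views.items():
            cols = list(mat.columns)
            if not set(cols) <= set(order):
                raise ValueError(f"view {name}: samples missing from metadata")
            if [pos[c] for c in cols] != sorted(pos[c] for c in cols):
                raise ValueError(f"view {name}: sample ordering differs from metadata")
            if mat.index.duplicated().any():
                raise ValueError(f"view {name}: duplicate feature identifiers")
        rna = self.views.get("rna")
        if rna is not None:
            vals = rna.to_numpy()
            if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
                raise ValueError("RNA view must hold non-negative integer counts")


def _switch(t: np.ndarray, center_log1p: float, sharpness: float = 0.35) -> np.ndarray:
    """Sigmoidal on-switch in log1p-time."""
    return 1.0 / (1.0 + np.exp(-(np.log1p(t) - center_log1p) / sharpness))


def true_trajectories(design: TimeCourseDesign, t: np.ndarray) -> np.ndarray:
    """Centred, orthogonalised, unit-sd wave trajectories (samples x K).

    A wave-``w`` factor switches on between the grid time preceding its wave
    and the wave's own time point (log-midpoint centre), and off again before
    the next wave's time point, so it is near-fully active exactly at its
    wave and near-silent elsewhere; the last sampled wave stays on.
    """
    tp = np.asarray(design.time_points, dtype=float)
    ltp = np.log1p(tp)
    waves = design.waves()
    cols = []
    for k in range(design.n_factors):
        w = waves[k]
        on = _switch(t, (ltp[w - 1] + ltp[w]) / 2.0)
        if w + 1 < len(tp):
            on = on - _switch(t, (ltp[w] + ltp[w + 1]) / 2.0)
        cols.append(on)
    Z = np.column_stack(cols)
    Z = Z - Z.mean(axis=0)
    # symmetric (Loewdin) orthogonalisation spreads the small pulse overlaps
    # evenly, so every factor keeps its peak at its own wave and the factors
    # end up exactly uncorrelated
    G = Z.T @ Z
    evals, evecs = np.linalg.eigh(G)
    if np.any(evals < 1e-10):
        raise ValueError("degenerate wave trajectories (duplicate waves?)")
    Z = Z @ evecs @ np.diag(evals ** -0.5) @ evecs.T
    return Z / Z.std(axis=0, ddof=0)


# relative loading strength per view for each wave: the 15-min wave lives on
# the phospho (and some protein) level, the 1-h immediate-early and 6-h
# target-gene waves are transcriptional, and the 24-h remodelling wave is
# proteomic/phosphoproteomic (RNA silent on the first and last)
_WAVE_VIEW_PATTERN = {
    1: {"rna": 0.0, "protein": 0.4, "phospho": 1.0},
    2: {"rna": 1.0, "protein": 0.3, "phospho": 0.0},
    3: {"rna": 1.0, "protein": 0.7, "phospho": 0.6},
    4: {"rna": 0.0, "protein": 1.0, "phospho": 1.0},
}


def _plant_signature(design: TimeCourseDesign, rng: np.random.Generator):
    """Assign disjoint gene blocks (and their protein/phospho homologs) to factors.

    Loadings follow a wave-specific view pattern (see ``_WAVE_VIEW_PATTERN``);
    a factor's signature members are the features it actually loads on.
    Returns per-view loading matrices W and a truth table of signature
    members with their direction upon MEK inhibition (-1 = down upon MEKi,
    i.e. up in the senescent baseline).
    """
    n_rna = design.n_features["rna"]
    n_prot = design.n_features["protein"]
    n_phos = design.n_features["phospho"]
    genes = [f"G{i + 1:04d}" for i in range(n_rna)]
    # protein view covers the first genes; phospho sites sit on those proteins
    prot_genes = genes[:n_prot]
    phos_positions = rng.integers(2, 999, size=n_phos)
    phos_residues = rng.choice(list("STY"), size=n_phos)
    phos_parent = [prot_genes[i % n_prot] for i in range(n_phos)]
    phos_sites = [f"{g}_{r}{p}" for g, r, p in
                  zip(phos_parent, phos_residues, phos_positions)]

    eff = design.effect_sizes()
    K = design.n_factors
    W = {"rna": np.zeros((n_rna, K)),
         "protein": np.zeros((n_prot, K)),
         "phospho": np.zeros((n_phos, K))}
    members = []  # (view, feature, gene, factor, direction_upon_meki)
    n_sig = design.n_signature
    limit = min(n_prot, n_rna)
    if n_sig * K > limit:
        raise ValueError("signature blocks exceed the protein-covered gene range")
    site_by_gene: dict[str, list[int]] = {}
    for i, g in enumerate(phos_parent):
        site_by_gene.setdefault(g, []).append(i)
    waves = design.waves()
    for k in range(K):
        pattern = _WAVE_VIEW_PATTERN.get(waves[k],
                                         {"rna": 1.0, "protein": 1.0,
                                          "phospho": 1.0})
        block = range(k * n_sig, (k + 1) * n_sig)
        for rank, gi in enumerate(block):
            gene = genes[gi]
            # half the block is up in OIS (down upon MEKi), half the converse
            direction = -1 if rank < n_sig // 2 else 1
            mag = eff[k] * rng.uniform(0.8, 1.2)
            if pattern["rna"] > 0:
                W["rna"][gi, k] = direction * mag * pattern["rna"]
                members.append(("rna", gene, gene, k, direction))
            if pattern["protein"] > 0:
                W["protein"][gi, k] = direction * mag * pattern["protein"]
                members.append(("protein", gene, gene, k, direction))
            if pattern["phospho"] > 0:
                for si in site_by_gene.get(gene, [])[:1]:
                    W["phospho"][si, k] = (direction * eff[k]
                                           * pattern["phospho"]
                                           * rng.uniform(0.8, 1.2))
                    members.append(("phospho", phos_sites[si], gene, k,
                                    direction))
    truth_members = pd.DataFrame(
        members, columns=["view", "feature", "gene", "factor", "direction_upon_meki"])
    names = {"rna": genes, "protein": list(prot_genes), "phospho": phos_sites}
    return W, truth_members, names


def generate_timecourse(design: TimeCourseDesign) -> MultiOmicsDataset:
    """Generate the multi-omics MEKi time course with recorded ground truth."""
    design.validate()
    rng = _rng(design.seed)

    tp = np.asarray(design.time_points, dtype=float)
    max_rep = max(design.replicates.values())
    rows = []
    for t in tp:
        for r in range(max_rep):
            rows.append((f"t{int(t)}_r{r + 1}", t, r + 1, (r % design.n_batches) + 1))
    sample_meta = pd.DataFrame(
        rows, columns=["sample", "time", "replicate", "batch"]).set_index("sample")

    t_all = sample_meta["time"].to_numpy(dtype=float)
    Z = true_trajectories(design, t_all)

    W, truth_members, names = _plant_signature(design, rng)

    views: dict[str, pd.DataFrame] = {}
    feature_meta: dict[str, pd.DataFrame] = {}
    batch_idx = sample_meta["batch"].to_numpy() - 1
    for view in VIEWS:
        keep = sample_meta["replicate"] <= design.replicates[view]
        cols = sample_meta.index[keep]
        col_mask = keep.to_numpy()
        n_feat = design.n_features[view]
        signal = W[view] @ Z[col_mask].T
        noise_sd = design.noise_sd[view]
        base_sd = design.baseline_sd[view]
        batch_sd = design.batch_sd[view]
        baseline = rng.normal(0.0, base_sd, size=n_feat)
        batch_off = rng.normal(0.0, batch_sd, size=(n_feat, design.n_batches)) \
            if batch_sd > 0 else np.zeros((n_feat, design.n_batches))
        boff = batch_off[:, batch_idx[col_mask]]
        if view == "rna":
            log_mu = design.rna_baseline_log_mean + baseline[:, None] + signal + boff
            if noise_sd > 0:
                log_mu = log_mu + rng.normal(0.0, noise_sd, size=log_mu.shape)
                mu = np.exp(log_mu)
                n_nb = 1.0 / design.dispersion
                counts = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))
            else:
                counts = np.round(np.exp(log_mu))
            mat = pd.DataFrame(counts.astype(np.int64), index=names[view], columns=cols)
        else:
            latent = baseline[:, None] + signal
            x = latent + boff
            if noise_sd > 0:
                x = x + rng.normal(0.0, noise_sd, size=x.shape)
            rate = design.missing_rate[view]
            if rate > 0:
                # MNAR: dropout odds increase as latent abundance falls
                sd = latent.std() or 1.0
                pivot = np.quantile(latent, 0.4)
                u = 1.0 / (1.0 + np.exp(-(pivot - latent) / (0.5 * sd)))
                p = np.clip(rate * u / u.mean(), 0.0, 0.95)
                x = np.where(rng.uniform(size=x.shape) < p, np.nan, x)
            mat = pd.DataFrame(x, index=names[view], columns=cols)
        views[view] = mat
        feature_meta[view] = pd.DataFrame(
            {"feature": names[view],
             "gene": names[view] if view != "phospho"
             else [f.split("_")[0] for f in names[view]],
             "is_coding": True}).set_index("feature")

    truth = {
        "Z": pd.DataFrame(Z, index=sample_meta.index,
                          columns=[f"factor{k + 1}" for k in range(design.n_factors)]),
        "W": {v: pd.DataFrame(W[v], index=names[v],
                              columns=[f"factor{k + 1}" for k in range(design.n_factors)])
              for v in VIEWS},
        "members": truth_members,
        "wave_of_factor": design.waves(),
        "wave_time": {k: design.time_points[w] for k, w in design.waves().items()},
        "ois_up_genes": sorted(set(
            truth_members.loc[truth_members.direction_upon_meki == -1, "gene"])),
        "ois_dn_genes": sorted(set(
            truth_members.loc[truth_members.direction_upon_meki == 1, "gene"])),
        "design": design,
    }
    ds = MultiOmicsDataset(views=views, sample_meta=sample_meta,
                           feature_meta=feature_meta, truth=truth)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# knowledge bases
# ---------------------------------------------------------------------------

@dataclass
class KnowledgeParams:
    """Parameters for the synthetic prior-knowledge tables."""
    n_universe: int = 300
    p_in: float = 0.6       # planted-module PPI edge density
    p_out: float = 0.05     # background PPI edge density
    n_decoy_tfs: int = 15
    n_decoy_kinases: int = 10
    targets_per_tf: int = 12
    sites_per_kinase: int = 6
    interaction_refs_low: int = 1   # background interactions: 1..3 references
    allow_unseparable: bool = False
    seed: int = 0


@dataclass
class KnowledgeBases:
    senescence_evidence: pd.DataFrame  # gene, n_up_publications, n_down_publications
    interactions: pd.DataFrame         # source, target, sign, n_references, interaction_type
    ppi: pd.DataFrame                  # a, b (undirected, no self-loops/duplicates)
    kinase_substrate: pd.DataFrame     # kinase, phosphosite
    tf_target: pd.DataFrame            # tf, target
    gene_sets: dict[str, list[str]]

    def validate(self) -> None:
        ev = self.senescence_evidence
        if (ev[["n_up_publications", "n_down_publications"]] < 0).any().any():
            raise ValueError("publication counts must be non-negative")
        if (self.interactions["n_references"] < 0).any():
            raise ValueError("reference counts must be non-negative")
        pairs = {frozenset((a, b)) for a, b in zip(self.ppi["a"], self.ppi["b"])}
        if any(len(p) != 2 for p in pairs):
            raise ValueError("PPI contains self-loops")
        if len(pairs) != len(self.ppi):
            raise ValueError("PPI contains duplicate undirected edges")


def generate_knowledge_bases(truth: dict,
                             params: KnowledgeParams | None = None) -> KnowledgeBases:
    """Build senescence/interaction/PPI/kinase/TF tables around a planted truth.

    True signature genes receive >= 3 concordant senescence publications, form
    a PPI module of density ``p_in`` against a ``p_out`` background, and are
    linked across consecutive waves by interactions with > 3 references.
    """
    params = params or KnowledgeParams()
    if params.p_in <= params.p_out and not params.allow_unseparable:
        raise ValueError("p_in <= p_out: planted module would not be separable "
                         "(set allow_unseparable=True to override)")
    rng = _rng(params.seed)
    members = truth["members"]
    sig_genes = sorted(set(members["gene"]))
    up_genes = set(truth["ois_up_genes"])
    design: TimeCourseDesign = truth["design"]
    all_genes = [f"G{i + 1:04d}" for i in range(design.n_features["rna"])]
    decoys = [g for g in all_genes if g not in set(sig_genes)]
    n_decoy = max(params.n_universe - len(sig_genes), 0)
    decoys = list(rng.choice(decoys, size=min(n_decoy, len(decoys)), replace=False))
    universe = sig_genes + decoys

    # senescence evidence: true genes strongly concordant, decoys noisy
    rows = []
    for g in sig_genes:
        win = 3 + rng.poisson(3)
        lose = rng.integers(0, 2)
        if g in up_genes:
            rows.append((g, win, lose))
        else:
            rows.append((g, lose, win))
    for g in decoys:
        rows.append((g, rng.poisson(2), rng.poisson(2)))
    evidence = pd.DataFrame(rows, columns=["gene", "n_up_publications",
                                           "n_down_publications"])

    # PPI: one planted module per signature direction, sparse background
    modules = [sorted(up_genes), sorted(truth["ois_dn_genes"])]
    edges = set()
    in_same_module = set()
    for module in modules:
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                in_same_module.add(frozenset((module[i], module[j])))
                if rng.uniform() < params.p_in:
                    edges.add((module[i], module[j]))
    for i in range(len(universe)):
        for j in range(i + 1, len(universe)):
            a, b = universe[i], universe[j]
            if frozenset((a, b)) in in_same_module:
                continue
            if rng.uniform() < params.p_out:
                edges.add((a, b))
    ppi = pd.DataFrame(sorted(edges), columns=["a", "b"])

    # signed interactions: consecutive-wave effectors with > 3 references
    wave_time = truth["wave_time"]
    by_factor = {k: sorted(set(members.loc[members.factor == k, "gene"]))
                 for k in wave_time}
    factors_by_time = sorted(wave_time, key=lambda k: wave_time[k])
    irows = []
    for ka, kb in zip(factors_by_time[:-1], factors_by_time[1:]):
        for a in by_factor[ka]:
            for b in rng.choice(by_factor[kb], size=min(3, len(by_factor[kb])),
                                replace=False):
                irows.append((a, b, int(rng.choice([1, -1], p=[0.7, 0.3])),
                              4 + rng.poisson(2), "post_translational"))
    # within-wave support and low-evidence background
    for k in factors_by_time:
        genes_k = by_factor[k]
        for _ in range(len(genes_k)):
            a, b = rng.choice(genes_k, size=2, replace=False)
            irows.append((a, b, 1, 4 + rng.poisson(1), "post_translational"))
    for _ in range(3 * len(universe)):
        a, b = rng.choice(universe, size=2, replace=False)
        irows.append((a, b, int(rng.choice([1, -1])),
                      int(rng.integers(params.interaction_refs_low, 4)),
                      "transcriptional"))
    interactions = pd.DataFrame(
        irows, columns=["source", "target", "sign", "n_references",
                        "interaction_type"]).drop_duplicates(["source", "target"])

    # kinase -> substrate map: planted kinases cover true phospho sites
    phos = members.loc[members.view == "phospho", "feature"].unique().tolist()
    krows = []
    kid = 0
    for start in range(0, len(phos), params.sites_per_kinase):
        kid += 1
        for site in phos[start:start + params.sites_per_kinase]:
            krows.append((f"KIN{kid:02d}", site))
    for d in range(params.n_decoy_kinases):
        n_prot = design.n_features["protein"]
        for _ in range(params.sites_per_kinase):
            g = all_genes[int(rng.integers(0, n_prot))]
            krows.append((f"DKIN{d + 1:02d}", f"{g}_S{rng.integers(2, 999)}"))
    kinase_substrate = pd.DataFrame(krows, columns=["kinase", "phosphosite"])

    # TF -> target map: planted TFs target the wave-3 (target-gene) signature
    target_wave_factor = factors_by_time[min(2, len(factors_by_time) - 1)]
    wave3_genes = by_factor[target_wave_factor]
    trows = []
    for i in range(3):
        picks = rng.choice(wave3_genes, size=min(params.targets_per_tf,
                                                 len(wave3_genes)), replace=False)
        for g in picks:
            trows.append((f"TF{i + 1:02d}", g))
    for d in range(params.n_decoy_tfs):
        picks = rng.choice(universe, size=params.targets_per_tf, replace=False)
        for g in picks:
            trows.append((f"DTF{d + 1:02d}", g))
    tf_target = pd.DataFrame(trows, columns=["tf", "target"]).drop_duplicates()

    gene_sets = {
        "OIS_UP_TRUE": sorted(up_genes),
        "OIS_DN_TRUE": sorted(truth["ois_dn_genes"]),
    }
    for i in range(8):
        gene_sets[f"RANDOM_{i + 1}"] = sorted(
            rng.choice(universe, size=25, replace=False))

    kb = KnowledgeBases(senescence_evidence=evidence, interactions=interactions,
                        ppi=ppi, kinase_substrate=kinase_substrate,
                        tf_target=tf_target, gene_sets=gene_sets)
    kb.validate()
    return kb


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCohortSpec:
    """Proportional-hazards cohort with a high/low signature-score split."""
    n_patients: int = 160
    true_hazard_ratio: float = 0.25   # hazard in the high-score group
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.02     # events per month in the low group
    score_separation: float = 3.0     # score gap between groups, in sd units
    covariates: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: {
        "site": {"cerebellum": 0.5, "supratentorial": 0.3, "brainstem": 0.2},
        "resection": {"complete": 0.45, "partial": 0.4, "biopsy": 0.15},
        "alteration": {"fusion": 0.7, "point_mutation": 0.3},
    })
    seed: int = 0

    def validate(self) -> None:
        if self.true_hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        for name, freqs in self.covariates.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"covariate {name}: frequencies must sum to 1")


def generate_cohort(spec: SurvivalCohortSpec) -> pd.DataFrame:
    """Sample a survival cohort: time (months), event, score and covariates."""
    spec.validate()
    rng = _rng(spec.seed)
    n = spec.n_patients
    high = rng.permutation(n) < n // 2
    score = rng.normal(0.0, 1.0, size=n) + spec.score_separation * high
    hazard = spec.baseline_hazard * np.where(high, spec.true_hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        # independent exponential censoring tuned to the target marginal rate
        c = spec.censoring_rate
        cens_rate = c / (1.0 - c) * hazard.mean()
        cens_time = rng.exponential(1.0 / cens_rate, size=n)
    else:
        cens_time = np.full(n, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    cov_cols = {}
    for name, freqs in spec.covariates.items():
        levels = list(freqs)
        cov_cols[name] = rng.choice(levels, size=n, p=[freqs[l] for l in levels])
    df = pd.DataFrame({"time": time, "event": event, "score": score,
                       "high_score_true": high.astype(int), **cov_cols})
    df.index = [f"P{i + 1:03d}" for i in range(n)]
    return df


# ---------------------------------------------------------------------------
# dose-response plates
# ---------------------------------------------------------------------------

@dataclass
class DrugSpec:
    name: str
    true_class: str   # one of drug_response.CLASSES
    ic50: float       # single-agent IC50 / EC50 (nM)
    hill: float = 1.2
    top: float = 1.0
    bottom: float = 0.1
    pretreat_ic50_fold: float = 1.0  # IC50 multiplier after MEKi pre-treatment


def default_drug_panel() -> list[DrugSpec]:
    """A screen panel mirroring the emulated study's effective-drug classes."""
    return [
        # senolytics lose potency in MEKi-released (non-senescent) cells
        DrugSpec("navitoclax", "MAPK-dependent cytotoxic", 120.0,
                 pretreat_ic50_fold=3.62),
        DrugSpec("LCS-1", "MAPK-dependent cytotoxic", 400.0,
                 pretreat_ic50_fold=1.09),
        DrugSpec("flavopiridol", "MAPK-independent cytotoxic", 150.0,
                 pretreat_ic50_fold=1.05),
        DrugSpec("NT157", "MAPK-independent cytotoxic", 900.0,
                 pretreat_ic50_fold=1.1),
        DrugSpec("silmitasertib", "MAPK-independent cytotoxic", 2000.0,
                 pretreat_ic50_fold=0.95),
        # growth promoters: responses rise above control with dose
        DrugSpec("2-D08", "MAPK-independent growth-promoting", 500.0,
                 hill=-1.2, top=1.6, bottom=1.0, pretreat_ic50_fold=1.0),
        DrugSpec("MRTX0902", "MAPK-dependent growth-promoting", 400.0,
                 hill=-1.2, top=1.6, bottom=1.0, pretreat_ic50_fold=50.0),
        DrugSpec("palbociclib", "MAPK-dependent growth-promoting", 600.0,
                 hill=-1.2, top=1.5, bottom=1.0, pretreat_ic50_fold=40.0),
        DrugSpec("inert-A", "ineffective", 1e7, top=1.0, bottom=0.9),
        DrugSpec("inert-B", "ineffective", 1e7, top=1.05, bottom=0.95),
    ]


# single-dose relative metabolic activity archetypes per class:
# (A = drug alone, T = after 24 h MEKi pre-treatment), control = 1
_SCREEN_ARCHETYPE = {
    "ineffective": (1.0, 1.0),
    "MAPK-independent growth-promoting": (1.5, 1.55),
    "MAPK-dependent growth-promoting": (1.5, 1.0),
    "MAPK-dependent cytotoxic": (0.4, 0.95),
    "MAPK-independent cytotoxic": (0.4, 0.38),
}


@dataclass
class DrugPlateSpec:
    drugs: list[DrugSpec] = field(default_factory=default_drug_panel)
    dose_grid: tuple[float, ...] = tuple(float(x) for x in
                                         np.geomspace(1.0, 10000.0, 8))
    n_replicates: int = 2
    replicate_noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if len(self.dose_grid) == 0:
            raise ValueError("dose grid must be non-empty")
        if any(d <= 0 for d in self.dose_grid):
            raise ValueError("doses must be positive")
        lo, hi = min(self.dose_grid), max(self.dose_grid)
        for d in self.drugs:
            if d.top <= d.bottom and d.hill > 0:
                raise ValueError(f"{d.name}: top must exceed bottom")
            if "cytotoxic" in d.true_class and not lo <= d.ic50 <= hi:
                raise ValueError(f"{d.name}: IC50 outside the dose-grid span")


def four_pl(x: np.ndarray, top: float, bottom: float, ic50: float,
            hill: float) -> np.ndarray:
    """Four-parameter logistic: top at low dose, bottom at high dose (hill > 0)."""
    return bottom + (top - bottom) / (1.0 + (np.asarray(x, float) / ic50) ** hill)


def generate_dose_response(spec: DrugPlateSpec) -> dict:
    """Simulate paired single-agent / MEKi-pre-treated dose-response plates.

    Returns a dict with ``plate`` (long table: drug, condition, dose,
    replicate, response), ``screen`` (per-drug single-dose relative activity:
    A alone and T after MEKi pre-treatment, each drug screened at its own
    relevant dose) and ``truth``.
    """
    spec.validate()
    rng = _rng(spec.seed)
    rows = []
    screen_rows = []
    for d in spec.drugs:
        for condition, fold in (("single", 1.0), ("pretreat", d.pretreat_ic50_fold)):
            ic50 = d.ic50 * fold
            for dose in spec.dose_grid:
                mu = four_pl(dose, d.top, d.bottom, ic50, d.hill)
                for rep in range(1, spec.n_replicates + 1):
                    y = mu + (rng.normal(0.0, spec.replicate_noise_sd)
                              if spec.replicate_noise_sd > 0 else 0.0)
                    rows.append((d.name, condition, dose, rep, max(float(y), 0.0)))
        # single-dose screen at each drug's own relevant dose: class archetype
        A, T = _SCREEN_ARCHETYPE[d.true_class]
        if spec.replicate_noise_sd > 0:
            A += float(rng.normal(0, spec.replicate_noise_sd / np.sqrt(spec.n_replicates)))
            T += float(rng.normal(0, spec.replicate_noise_sd / np.sqrt(spec.n_replicates)))
        screen_rows.append((d.name, max(A, 0.0), max(T, 0.0)))
    plate = pd.DataFrame(rows, columns=["drug", "condition", "dose",
                                        "replicate", "response"])
    screen = pd.DataFrame(screen_rows, columns=["drug", "A", "T"])
    truth = pd.DataFrame(
        [(d.name, d.true_class, d.ic50, d.ic50 * d.pretreat_ic50_fold, d.hill,
          d.top, d.bottom) for d in spec.drugs],
        columns=["drug", "true_class", "ic50_single", "ic50_pretreat",
                 "hill", "top", "bottom"])
    return {"plate": plate, "screen": screen, "truth": truth}
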