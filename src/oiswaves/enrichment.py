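"""Gene-set, kinase and transcription-factor enrichment scoring.

Implements single-sample GSEA (rank-weighted integrated ECDF difference),
two-group GSEA with a gene-set permutation null, kinase-substrate enrichment
(normalised mean-difference z statistic), hypergeometric TF enrichment with
Benjamini-Hochberg adjustment, z-sum signature scores, whole-trajectory
k-means clustering and a cross-omics consistency filter.

Ties in expression are broken by stable feature-name order so every score is
reproducible across runs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def _ranked(values: pd.Series) -> pd.Series:
    """Sort descending by value, ties broken by feature name (ascending)."""
    df = pd.DataFrame({"v": values})
    df["name"] = df.index
    df = df.sort_values(["v", "name"], ascending=[False, True], kind="stable")
    return df["v"]


def ssgsea_sample(values: pd.Series, gene_set: set[str],
                  alpha: float = 0.75) -> float:
    """Single-sample enrichment score for one expression profile.

    Features are ranked by expression (descending); the score is the sum over
    ranks of the difference between the |value|^alpha-weighted in-set ECDF and
    the count-based out-of-set ECDF.  No normalisation is applied — scores
    are in arbitrary units.
    """
    ranked = _ranked(values)
    in_set = ranked.index.isin(gene_set)
    m = int(in_set.sum())
    if m == 0 or m == len(ranked):
        raise ValueError("gene set must overlap the universe and its complement")
    w = np.abs(ranked.to_numpy()) ** alpha
    w_in = np.where(in_set, w, 0.0)
    denom = w_in.sum()
    p_in = np.cumsum(w_in) / denom if denom > 0 else np.cumsum(in_set) / m
    p_out = np.cumsum(~in_set) / (len(ranked) - m)
    return float(np.sum(p_in - p_out))


def ssgsea(expr: pd.DataFrame, sets: dict[str, list[str]],
           alpha: float = 0.75, zscore: bool = False) -> pd.DataFrame:
    """ssGSEA scorecard: gene sets in rows, samples in columns.

    With ``zscore=True`` each set's scores are standardised across samples.
    """
    universe = set(expr.index)
    rows = {}
    for name, members in sets.items():
        memb = set(members) & universe
        if not memb or len(memb) == len(universe):
            raise ValueError(f"set {name!r}: empty overlap or covers the universe")
        rows[name] = [ssgsea_sample(expr[c], memb, alpha) for c in expr.columns]
    card = pd.DataFrame(rows, index=expr.columns).T
    if zscore:
        card = card.sub(card.mean(axis=1), axis=0).div(
            card.std(axis=1, ddof=0), axis=0)
    return card


def zsum_signature_score(expr: pd.DataFrame, signature: list[str]) -> pd.Series:
    """Sum of per-feature z-scores (across samples) over signature features."""
    present = [f for f in signature if f in expr.index]
    missing = sorted(set(signature) - set(present))
    if not present:
        raise ValueError(f"no signature feature present; missing: {missing}")
    if missing:
        logger.info("zsum_signature_score: %d features absent", len(missing))
    sub = expr.loc[present].to_numpy(dtype=float)
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=0,
                                                          keepdims=True)
    return pd.Series(z.sum(axis=0), index=expr.columns, name="zsum")


# ---------------------------------------------------------------------------
# two-group GSEA
# ---------------------------------------------------------------------------

def _signal_to_noise(expr: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    m1, m2 = expr[:, g1].mean(axis=1), expr[:, g2].mean(axis=1)
    s1, s2 = expr[:, g1].std(axis=1, ddof=1), expr[:, g2].std(axis=1, ddof=1)
    denom = s1 + s2
    denom[denom == 0] = 1e-12
    return (m1 - m2) / denom


def _es_weighted_ks(ranked_scores: np.ndarray, in_set: np.ndarray) -> float:
    """Classic weighted Kolmogorov-Smirnov enrichment score (weight = |s|)."""
    w = np.abs(ranked_scores) * in_set
    denom = w.sum()
    if denom == 0:
        return 0.0
    p_hit = np.cumsum(w) / denom
    p_miss = np.cumsum(~in_set) / max((~in_set).sum(), 1)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def gsea_twogroup(expr: pd.DataFrame, group_labels, sets: dict[str, list[str]],
                  n_perm: int = 1000, seed: int = 0,
                  min_size: int = 3) -> pd.DataFrame:
    """Two-group GSEA: signal-to-noise ranking, weighted-KS ES, gene-set
    permutation null, NES and FDR q by signed pooling.

    Returns a table (set, size, ES, NES, p, q) sorted by NES.
    """
    labels = pd.Series(np.asarray(group_labels), index=expr.columns)
    lev = labels.unique()
    if len(lev) != 2:
        raise ValueError("exactly 2 groups required")
    g1 = np.flatnonzero((labels == lev[0]).to_numpy())
    g2 = np.flatnonzero((labels == lev[1]).to_numpy())
    if min(len(g1), len(g2)) < 2:
        raise ValueError("need >= 2 samples per group")
    if n_perm < 100:
        logger.warning("gsea_twogroup: n_perm < 100 gives coarse p-values")
    rng = np.random.default_rng(int(seed) % (2**31))
    s2n = pd.Series(_signal_to_noise(expr.to_numpy(dtype=float), g1, g2),
                    index=expr.index)
    ranked = _ranked(s2n)
    scores = ranked.to_numpy()
    names = ranked.index
    universe = set(names)

    results = []
    null_pool_pos, null_pool_neg = [], []
    obs = {}
    for name, members in sets.items():
        memb = set(members) & universe
        if len(memb) < min_size:
            logger.info("gsea_twogroup: set %s below min_size, skipped", name)
            continue
        in_set = names.isin(memb)
        obs[name] = (len(memb), _es_weighted_ks(scores, in_set))
    for name, (size, _) in obs.items():
        nulls = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(len(names), size=size, replace=False)
            mask = np.zeros(len(names), dtype=bool)
            mask[idx] = True
            nulls[b] = _es_weighted_ks(scores, mask)
        es = obs[name][1]
        same = nulls[nulls * es >= 0] if es != 0 else nulls
        denom = np.abs(same).mean() if same.size else np.abs(nulls).mean()
        nes = es / denom if denom > 0 else 0.0
        null_nes = nulls / denom if denom > 0 else nulls
        p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + max(same.size, 1))
        (null_pool_pos if es >= 0 else null_pool_neg).extend(
            null_nes[null_nes * np.sign(es if es != 0 else 1) >= 0])
        results.append({"set": name, "size": size, "ES": es, "NES": nes, "p": p})
    res = pd.DataFrame(results)
    if res.empty:
        return res
    # FDR q: fraction of pooled same-sign null NES at least as extreme,
    # over the fraction of observed NES at least as extreme
    qs = []
    pos_null = np.asarray(null_pool_pos)
    neg_null = np.asarray(null_pool_neg)
    for _, row in res.iterrows():
        nes = row["NES"]
        if nes >= 0:
            null_frac = np.mean(pos_null >= nes) if pos_null.size else 1.0
            obs_frac = np.mean(res["NES"] >= nes)
        else:
            null_frac = np.mean(neg_null <= nes) if neg_null.size else 1.0
            obs_frac = np.mean(res["NES"] <= nes)
        qs.append(min(1.0, null_frac / max(obs_frac, 1e-12)))
    res["q"] = qs
    return res.sort_values("NES", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# KSEA / TFEA
# ---------------------------------------------------------------------------

def ksea(site_log2fc: pd.Series, kinase_substrate: pd.DataFrame,
         p_cut: float = 0.05, m_min: int = 5) -> pd.DataFrame:
    """Kinase-substrate enrichment z statistic per kinase.

    ``z = (mean(FC_substrates) - mean(FC_all)) * sqrt(m) / sd(FC_all)`` with a
    two-sided normal p-value.  Returns all kinases with >= 1 mapped substrate
    (column ``reported`` flags those passing ``m >= m_min`` and ``p < p_cut``).
    """
    if site_log2fc.empty:
        raise ValueError("fold-change table is empty")
    fc_all = site_log2fc.to_numpy(dtype=float)
    sd_all = fc_all.std(ddof=1)
    if sd_all == 0:
        raise ValueError("all fold changes identical: sd is zero")
    mean_all = fc_all.mean()
    rows = []
    for kin, grp in kinase_substrate.groupby("kinase"):
        subs = [s for s in grp["phosphosite"] if s in site_log2fc.index]
        m = len(subs)
        if m == 0:
            continue
        mean_sub = site_log2fc.loc[subs].mean()
        z = (mean_sub - mean_all) * np.sqrt(m) / sd_all
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"kinase": kin, "z": z, "m": m, "p": p,
                     "reported": bool(m >= m_min and p < p_cut)})
    return pd.DataFrame(rows).sort_values("z", ascending=False,
                                          ignore_index=True)


def tfea(query_genes: list[str], tf_target: pd.DataFrame,
         universe: list[str],
         query_directions: dict[str, int] | None = None) -> pd.DataFrame:
    """One-sided hypergeometric TF-target over-representation.

    ``query_directions`` (gene -> +1/-1) sets each TF's direction as the
    majority sign of its overlapping query genes.  p-values are BH-adjusted.
    """
    query = set(query_genes)
    if not query:
        raise ValueError("query gene list is empty")
    uni = set(universe)
    if not query <= uni:
        raise ValueError("query must be a subset of the universe")
    M, N = len(uni), len(query)
    rows = []
    for tf, grp in tf_target.groupby("tf"):
        targets = set(grp["target"]) & uni
        if not targets:
            continue
        overlap = sorted(targets & query)
        k = len(overlap)
        p = stats.hypergeom.sf(k - 1, M, len(targets), N) if k > 0 else 1.0
        direction = 0
        if query_directions and overlap:
            signs = [query_directions.get(g, 0) for g in overlap]
            direction = int(np.sign(sum(signs)))
        rows.append({"tf": tf, "overlap": k, "set_size": len(targets),
                     "universe": M, "p": min(p, 1.0), "direction": direction})
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["p_adj"] = multipletests(res["p"], method="fdr_bh")[1]
    return res.sort_values("p", ignore_index=True)


# ---------------------------------------------------------------------------
# trajectory clustering & consistency
# ---------------------------------------------------------------------------

def cluster_trajectories(trajectories: pd.DataFrame, k: int,
                         seed: int = 0, n_init: int = 10):
    """Whole-trajectory k-means (Euclidean on time-ordered score vectors).

    Rows are trajectories, columns time-ordered scores.  Returns
    (labels Series, centroid DataFrame).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > trajectories.shape[0]:
        raise ValueError("k exceeds the number of trajectories")
    X = trajectories.to_numpy(dtype=float)
    if np.unique(X, axis=0).shape[0] < k:
        logger.warning("cluster_trajectories: fewer distinct trajectories "
                       "than clusters; some clusters will be empty")
    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=int(seed) % (2**31)).fit(X)
    labels = pd.Series(km.labels_, index=trajectories.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=trajectories.columns)
    return labels, centroids


def consistency_filter(layer_scores: dict[str, pd.DataFrame],
                       min_effect: float = 0.5) -> list[str]:
    """Keep signatures whose end-vs-start change agrees in sign across all
    layers measuring them, with |change| > min_effect in each.

    ``layer_scores``: per layer, a set x time-ordered-sample score matrix.
    Signatures present in fewer than 2 layers are ignored.
    """
    changes: dict[str, list[float]] = {}
    for layer, card in layer_scores.items():
        delta = card.iloc[:, -1] - card.iloc[:, 0]
        for sig, d in delta.items():
            changes.setdefault(sig, []).append(float(d))
    kept = []
    for sig, deltas in changes.items():
        if len(deltas) < 2:
            continue
        signs = {np.sign(d) for d in deltas}
        if len(signs) == 1 and 0 not in signs and \
                all(abs(d) > min_effect for d in deltas):
            kept.append(sig)
    logger.info("consistency_filter: %d of %d signatures kept",
                len(kept), len(changes))
    return sorted(kept)
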