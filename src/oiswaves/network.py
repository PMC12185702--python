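"""Senescence-evidence filtering, signature assembly and wave-network construction.

The senescence-evidence filter keeps genes with at least ``min_refs`` total
supporting publications (>= 3 by default) and assigns each the direction with
the larger publication count; edges of the signature network instead require
strictly more than three supporting references — the two thresholds are
intentionally different.  A permutation connectivity null benchmarks the
assembled signature's protein-protein interaction density against random gene
lists of the same size drawn from the prefiltered senescence universe.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def senequest_filter(evidence: pd.DataFrame, min_refs: int = 3,
                     include_ambiguous: bool = False) -> pd.DataFrame:
    """Filter senescence evidence to supported genes with a unique direction.

    Keeps genes whose total publication support (up + down) is >= ``min_refs``;
    direction is the better-supported one.  Ties are flagged ambiguous and
    excluded unless ``include_ambiguous`` (then emitted once per direction).
    Returns a table (gene, direction, n_supporting).
    """
    ev = evidence.copy()
    if (ev[["n_up_publications", "n_down_publications"]] < 0).any().any():
        raise ValueError("publication counts must be non-negative")
    total = ev["n_up_publications"] + ev["n_down_publications"]
    ev = ev[total >= min_refs]
    rows = []
    n_ambiguous = 0
    for _, r in ev.iterrows():
        up, dn = int(r["n_up_publications"]), int(r["n_down_publications"])
        if up > dn:
            rows.append((r["gene"], "up", up))
        elif dn > up:
            rows.append((r["gene"], "down", dn))
        else:
            n_ambiguous += 1
            if include_ambiguous:
                rows.append((r["gene"], "up", up))
                rows.append((r["gene"], "down", dn))
    if n_ambiguous:
        logger.info("senequest_filter: %d genes with tied direction %s",
                    n_ambiguous,
                    "included as both" if include_ambiguous else "excluded")
    return pd.DataFrame(rows, columns=["gene", "direction", "n_supporting"])


_SITE_RE = re.compile(r"^(?P<protein>[A-Za-z0-9.\-]+)_(?P<residue>[STY])"
                      r"(?P<position>\d+)$")


def parse_site(site: str):
    """Split a phosphosite id ``PROT_S123`` into (protein, residue, position)."""
    m = _SITE_RE.match(site)
    if m is None:
        return None
    return m.group("protein"), m.group("residue"), int(m.group("position"))


def infer_kinases(selected_sites: pd.DataFrame,
                  kinase_substrate: pd.DataFrame) -> pd.DataFrame:
    """Upstream kinases of the selected phosphosites.

    ``selected_sites``: table (feature, direction) of phosphosite ids with
    their regulation sign.  A kinase is reported when >= 1 selected substrate
    maps to it; its direction is the majority sign of its substrates.
    Unparseable site ids are logged and skipped.
    """
    parsed = {}
    for _, r in selected_sites.iterrows():
        if parse_site(str(r["feature"])) is None:
            logger.warning("infer_kinases: unparseable site id %r skipped",
                           r["feature"])
            continue
        parsed[r["feature"]] = int(r["direction"])
    rows = []
    for kin, grp in kinase_substrate.groupby("kinase"):
        subs = [s for s in grp["phosphosite"] if s in parsed]
        if not subs:
            continue
        total = sum(parsed[s] for s in subs)
        direction = int(np.sign(total)) if total != 0 else 0
        rows.append({"kinase": kin, "n_substrates": len(subs),
                     "direction": direction})
    if not rows:
        logger.warning("infer_kinases: no selected site maps to any kinase")
    return pd.DataFrame(rows, columns=["kinase", "n_substrates", "direction"])


def assemble_signature(effectors: pd.DataFrame,
                       senescence_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Intersect wave-annotated effectors with the senescence gene table.

    ``effectors``: table (gene, layer, wave, direction_upon_meki, source)
    from the factor, TFEA and kinase analyses.  Effectors down upon MEK
    inhibition (direction -1) are up in the senescent baseline and form
    OIS_UP; the converse forms OIS_DN.  Genes found in several layers are
    de-duplicated into one node with layer provenance retained.

    Returns ``{"OIS_UP": nodes, "OIS_DN": nodes}`` where nodes is a table
    (gene, wave, layers, sources, direction_upon_meki).
    """
    senescent = set(senescence_table["gene"])
    hit = effectors[effectors["gene"].isin(senescent)]
    if hit.empty:
        logger.warning("assemble_signature: no effector overlaps the "
                       "senescence table")
    out = {}
    for name, sign in (("OIS_UP", -1), ("OIS_DN", 1)):
        sub = hit[hit["direction_upon_meki"] == sign]
        nodes = (sub.groupby("gene")
                 .agg(wave=("wave", "min"),
                      layers=("layer", lambda s: ",".join(sorted(set(s)))),
                      sources=("source", lambda s: ",".join(sorted(set(s)))),
                      direction_upon_meki=("direction_upon_meki", "first"))
                 .reset_index())
        out[name] = nodes
    logger.info("assemble_signature: %d up / %d down molecules",
                len(out["OIS_UP"]), len(out["OIS_DN"]))
    return out


@dataclass
class SignatureNetwork:
    nodes: pd.DataFrame   # gene, wave, layers, sources, direction_upon_meki
    edges: pd.DataFrame   # source, target, sign, n_references, within_wave

    def validate(self) -> None:
        genes = set(self.nodes["gene"])
        for col in ("source", "target"):
            if not set(self.edges[col]) <= genes:
                raise ValueError("edge endpoint missing from node table")


def build_wave_network(nodes: pd.DataFrame, interactions: pd.DataFrame,
                       edge_min_refs: int = 3) -> SignatureNetwork:
    """Connect signature nodes using interactions with > edge_min_refs
    references (strictly more than three by default).

    Edges are flagged within- or between-wave; disconnected nodes are kept.
    Output is invariant to the row order of both inputs.
    """
    if "n_references" not in interactions.columns:
        raise ValueError("interaction table lacks an n_references column")
    wave = dict(zip(nodes["gene"], nodes["wave"]))
    rows = []
    for _, r in interactions.iterrows():
        a, b = r["source"], r["target"]
        if a in wave and b in wave and a != b and \
                int(r["n_references"]) > edge_min_refs:
            rows.append((a, b, int(r.get("sign", 1)), int(r["n_references"]),
                         bool(wave[a] == wave[b])))
    edges = (pd.DataFrame(rows, columns=["source", "target", "sign",
                                         "n_references", "within_wave"])
             .sort_values(["source", "target"], ignore_index=True))
    net = SignatureNetwork(nodes=nodes.sort_values("gene", ignore_index=True),
                           edges=edges)
    net.validate()
    return net


def export_sif(net: SignatureNetwork, path) -> None:
    """Write the network as a SIF file (source<TAB>relation<TAB>target)."""
    with open(path, "w") as fh:
        linked = set()
        for _, e in net.edges.iterrows():
            rel = "activates" if e["sign"] > 0 else "inhibits"
            fh.write(f"{e['source']}\t{rel}\t{e['target']}\n")
            linked.update((e["source"], e["target"]))
        for g in net.nodes["gene"]:
            if g not in linked:
                fh.write(f"{g}\n")


@dataclass
class ConnectivityStats:
    n_edges: int
    avg_degree: float
    avg_clustering: float
    n_listed: int
    n_mapped: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.n_edges, self.avg_degree, self.avg_clustering)


def connectivity_stats(gene_list, ppi: pd.DataFrame) -> ConnectivityStats:
    """Edge count, mean degree and mean local clustering of the induced
    PPI subgraph.

    Unmapped genes count toward ``n_listed`` but are excluded from averages;
    nodes of degree < 2 contribute a clustering coefficient of 0.
    """
    genes = list(dict.fromkeys(gene_list))
    if not genes:
        logger.warning("connectivity_stats: empty gene list")
        return ConnectivityStats(0, 0.0, 0.0, 0, 0)
    G = nx.Graph()
    G.add_edges_from(zip(ppi["a"], ppi["b"]))
    mapped = [g for g in genes if g in G]
    sub = G.subgraph(mapped)
    n_edges = sub.number_of_edges()
    if mapped:
        avg_deg = float(np.mean([d for _, d in sub.degree()]))
        avg_clu = float(np.mean(list(nx.clustering(sub).values())))
    else:
        avg_deg = avg_clu = 0.0
    return ConnectivityStats(n_edges=n_edges, avg_degree=avg_deg,
                             avg_clustering=avg_clu, n_listed=len(genes),
                             n_mapped=len(mapped))


@dataclass
class ConnectivityNullResult:
    observed: ConnectivityStats
    null: list[ConnectivityStats]
    rank: dict[str, int]          # 1 = best among observed + null
    empirical_p: dict[str, float]  # (1 + #null >= observed) / (B + 1)


_METRICS = ("n_edges", "avg_degree", "avg_clustering")


def connectivity_null(observed_list, universe, ppi: pd.DataFrame,
                      B: int = 100, seed: int = 0) -> ConnectivityNullResult:
    """Benchmark a gene list's connectivity against B random same-size lists
    drawn without replacement from the (prefiltered senescence) universe.

    Per metric: rank of the observed statistic among observed + null draws
    (ties share the best rank) and the add-one empirical p-value
    ``(1 + #null >= observed) / (B + 1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    universe = list(dict.fromkeys(universe))
    observed_list = list(dict.fromkeys(observed_list))
    if len(universe) < len(observed_list):
        raise ValueError("universe smaller than the observed list")
    rng = np.random.default_rng(int(seed) % (2**31))
    obs = connectivity_stats(observed_list, ppi)
    null = []
    for _ in range(B):
        draw = rng.choice(universe, size=len(observed_list), replace=False)
        null.append(connectivity_stats(draw, ppi))
    rank, emp_p = {}, {}
    for metric in _METRICS:
        ov = getattr(obs, metric)
        nv = np.array([getattr(s, metric) for s in null])
        rank[metric] = int(1 + np.sum(nv > ov))
        emp_p[metric] = float((1 + np.sum(nv >= ov)) / (B + 1))
    return ConnectivityNullResult(observed=obs, null=null, rank=rank,
                                  empirical_p=emp_p)
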