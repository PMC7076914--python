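"""Causal-graph synthesis and benchmarking of edge rankings.

Per-experiment graphs connect attributed drivers to their targets (direct
edges, weighted by psi) and the induced gene to every differentially
expressed gene (indirect edges). Experiment graphs union into a meta-graph
with per-edge support counts. Edge rankings are scored against reference
networks by ROC/AUC with a degree-preserving permutation null, and target
sets are linked to gene sets by hypergeometric overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .attribution import AttributionRecord, PSI_DRIVER_CUTOFF


# --------------------------------------------------------------------------
# graph construction
# --------------------------------------------------------------------------

def build_experiment_graph(
    records: list[AttributionRecord],
    de_genes: list,
    induced_gene,
    experiment,
    psi_cutoff: float = PSI_DRIVER_CUTOFF,
) -> nx.MultiDiGraph:
    """Causal graph of one induction experiment.

    Direct edges run from each passing driver (psi > cutoff on a response
    that passed the predictive filter) to its target, weighted by psi.
    Indirect edges run from the induced gene to every differentially
    expressed gene (those surviving hard-thresholding), regardless of
    whether a direct explanation exists. The strongest driver of each
    response is annotated on its edge.
    """
    g = nx.MultiDiGraph(experiment=experiment, induced_gene=induced_gene)
    g.add_node(induced_gene, induced=True)
    for gene in de_genes:
        if gene != induced_gene:
            g.add_edge(induced_gene, gene, type="indirect", weight=np.nan,
                       experiment=experiment)
    direct: dict[tuple, dict] = {}
    for rec in records:
        if not rec.passed_predictive_filter or rec.degenerate:
            continue
        strongest = rec.strongest_driver
        for reg in rec.drivers(psi_cutoff):
            attrs = {
                "type": "direct",
                "weight": float(rec.psi[reg]),
                "kind": rec.interval.kind,
                "experiment": experiment,
                "strongest": (reg == strongest),
            }
            key = (reg, rec.target)
            # one direct edge per (source, target, experiment); a target with
            # both a rise and a fall event keeps the stronger attribution
            if key not in direct or abs(attrs["weight"]) > abs(direct[key]["weight"]):
                direct[key] = attrs
    for (reg, target), attrs in direct.items():
        g.add_edge(reg, target, **attrs)
        g.nodes[reg]["predicted_regulator"] = True
    return g


def synthesize_meta_graph(graphs: list[nx.MultiDiGraph]) -> nx.DiGraph:
    """Union of experiment graphs with per-edge support counts.

    Edge attributes: ``support`` (number of experiments contributing the
    edge with that type), ``experiments``, and mean ``weight`` over
    supporting direct edges. Node attribute ``hub_score`` counts distinct
    direct targets across experiments.
    """
    if not graphs:
        raise ValueError("at least one experiment graph is required")
    meta = nx.DiGraph()
    weights: dict = {}
    for g in graphs:
        for u, v, data in g.edges(data=True):
            key = (u, v, data["type"])
            weights.setdefault(key, []).append((data.get("experiment"), data.get("weight")))
    for (u, v, etype), contribs in weights.items():
        exps = sorted({e for e, _ in contribs})
        ws = [w for _, w in contribs if w == w]  # drop NaN (indirect edges)
        meta.add_edge(
            u,
            v,
            type=etype,
            support=len(contribs),
            experiments=exps,
            weight=float(np.mean(ws)) if ws else np.nan,
        )
    for node in meta.nodes:
        targets = {v for _, v, d in meta.out_edges(node, data=True) if d["type"] == "direct"}
        meta.nodes[node]["hub_score"] = len(targets)
    return meta


def meta_graph_to_frame(meta: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "type": d["type"], "weight": d.get("weight"),
         "support": d["support"], "experiments": ",".join(map(str, d["experiments"]))}
        for u, v, d in meta.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["source", "target", "type", "weight",
                                       "support", "experiments"])


# --------------------------------------------------------------------------
# ROC evaluation
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    edges: pd.DataFrame  # source, target, score, label -- descending by score
    auc: float
    permutation_aucs: np.ndarray

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.permutation_aucs))


def _undirected(pairs) -> set:
    return {frozenset((a, b)) for a, b in pairs}


def evaluate_roc(
    edge_scores: pd.DataFrame,
    reference_edges,
    n_perm: int = 25,
    seed: int = 0,
) -> RocResult:
    """AUC of a scored edge list against an undirected reference network.

    Positives are scored pairs present in the reference (matching either
    orientation); negatives are all remaining scored pairs. Ties in the
    scores are handled by mid-rank averaging. The permutation null redraws
    the source/target pairing while preserving each source's out-count and
    each target's in-count (degree-preserving), recomputing the AUC
    ``n_perm`` times.
    """
    required = {"source", "target", "score"}
    if not required <= set(edge_scores.columns):
        # netmodel edge tables use regulator/target naming
        edge_scores = edge_scores.rename(columns={"regulator": "source"})
    ref = _undirected(reference_edges)
    edges = edge_scores[["source", "target", "score"]].copy()
    edges["label"] = [
        frozenset((s, t)) in ref for s, t in zip(edges["source"], edges["target"])
    ]
    n_pos = int(edges["label"].sum())
    if n_pos == 0 or n_pos == len(edges):
        raise ValueError("reference leaves no positives or no negatives among scored pairs")
    auc = float(roc_auc_score(edges["label"], edges["score"]))
    rng = np.random.default_rng(seed)
    perm_aucs = []
    targets = edges["target"].to_numpy()
    for _ in range(n_perm):
        perm_t = targets[rng.permutation(len(targets))]
        labels = np.fromiter(
            (frozenset((s, t)) in ref for s, t in zip(edges["source"], perm_t)),
            dtype=bool,
            count=len(edges),
        )
        if labels.all() or not labels.any():
            perm_aucs.append(0.5)
        else:
            perm_aucs.append(float(roc_auc_score(labels, edges["score"])))
    edges = edges.sort_values(["score", "source", "target"],
                              ascending=[False, True, True]).reset_index(drop=True)
    return RocResult(edges=edges, auc=auc, permutation_aucs=np.asarray(perm_aucs))


def rank_by_rise_time(kinetic_fits: pd.DataFrame, induced_map: dict) -> pd.DataFrame:
    """Score candidate (induced gene -> responder) edges by response onset.

    Earlier t_rise ranks higher (score = -t_rise); ties resolve by gene
    identifier for reproducibility."""
    rows = []
    for _, row in kinetic_fits.iterrows():
        exp = row["experiment"]
        induced = induced_map[exp]
        if row["gene"] == induced:
            continue
        rows.append(
            {"source": induced, "target": row["gene"], "experiment": exp,
             "t_rise": row["t_rise"], "score": -float(row["t_rise"])}
        )
    out = pd.DataFrame(rows, columns=["source", "target", "experiment", "t_rise", "score"])
    return out.sort_values(["t_rise", "target"], kind="stable", ignore_index=True)


# --------------------------------------------------------------------------
# gene-set overlap enrichment
# --------------------------------------------------------------------------

def enrich_overlap(
    target_set,
    gene_sets: dict,
    universe,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail overlap of a target set with gene sets.

    ``p = P(overlap >= k)`` under sampling |target_set| genes from the
    universe without replacement; Benjamini-Hochberg across sets."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = set(target_set) & universe
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        if not members:
            continue
        k = len(targets & members)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(members), len(targets)))
        rows.append({"gene_set": name, "overlap": k, "set_size": len(members),
                     "n_targets": len(targets), "pvalue": p})
    table = pd.DataFrame(rows, columns=["gene_set", "overlap", "set_size",
                                        "n_targets", "pvalue"])
    if len(table):
        reject, qvals, _, _ = multipletests(table["pvalue"], alpha=fdr_q, method="fdr_bh")
        table["qvalue"] = qvals
        table["linked"] = reject
    else:
        table["qvalue"] = []
        table["linked"] = []
    return table.sort_values("pvalue", ignore_index=True)
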