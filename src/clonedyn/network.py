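"""Gene functional categories, co-occurrence networks and fitness contrasts.

Driver genes are grouped into five functional categories (epigenetic
regulation, RNA splicing, signal transduction, transcription factors,
chromatin structure).  Variants sharing a clone in any participant are
connected in a co-occurrence network, and the log fitness of mutations
occurring alone in a clone is contrasted with co-occurring ones by the
Brunner-Munzel test under Benjamini-Yekutieli correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import brunnermunzel
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GENE_CATEGORIES",
    "assign_gene_category",
    "build_network",
    "compare_isolated_vs_cooccurring",
]

GENE_CATEGORIES: dict[str, str] = {}
# Epigenetic Regulation: DNA methylation, histone modification, other
for g in ("DNMT3A", "TET2", "ASXL1", "EZH2", "CREBBP", "KDM6A", "PHF6", "IDH1", "IDH2"):
    GENE_CATEGORIES[g] = "ER"
# RNA Splicing and Processing
for g in ("SF3B1", "SRSF2", "U2AF1", "U2AF2", "ZRSR2", "LUC7L2", "PRPF40B", "SF3A1"):
    GENE_CATEGORIES[g] = "RS"
# Signal Transduction
for g in (
    "JAK2", "BRAF", "KRAS", "NRAS", "PPM1D", "PTPN11", "CBL", "NOTCH1",
    "GNAS", "GNB1", "SH2B3", "NF1", "MPL", "PTEN", "CALR",
):
    GENE_CATEGORIES[g] = "ST"
# Transcription Factors
for g in (
    "TP53", "BCORL1", "WT1", "ZNF318", "CUX1", "CEBPA", "RUNX1", "ZBTB33",
    "ETV6", "GATA2",
):
    GENE_CATEGORIES[g] = "TF"
# Chromatin Structure / cohesion
for g in ("BRCC3", "STAG2", "RAD21", "SMC1A", "SMC3", "CTCF"):
    GENE_CATEGORIES[g] = "CS"


def assign_gene_category(gene: str) -> str:
    """Functional category of a driver gene; 'uncategorized' if unknown."""
    return GENE_CATEGORIES.get(gene, "uncategorized")


@dataclass
class NetworkSummary:
    graph: nx.Graph
    nodes: pd.DataFrame
    edges: pd.DataFrame


def _variant_records(estimates, log_s_floor: float) -> pd.DataFrame:
    """One row per (participant, variant): gene, category, log fitness, context."""
    rows = []
    for est in estimates:
        if est is None:
            continue
        for clone in est.clones:
            for lab in clone.variants:
                gene = lab.split(":", 1)[0]
                rows.append(
                    {
                        "participant_id": est.participant_id,
                        "variant": lab,
                        "gene": gene,
                        "category": assign_gene_category(gene),
                        "log_fitness": math.log(max(clone.map_s, log_s_floor)),
                        "co_occurring": len(clone.variants) > 1,
                        "block": tuple(sorted(clone.variants)),
                    }
                )
    return pd.DataFrame(rows)


def build_network(
    estimates,
    level: str = "gene",
    log_s_floor: float = 0.0025,
) -> NetworkSummary:
    """Co-occurrence network over genes (or categories, or variants).

    Nodes carry a count, its log as a size attribute, the mean log MAP
    fitness, and a color value linearly rescaled to [0, 1] between the
    cohort's min and max node mean log fitness (0.5 when degenerate).
    An edge joins two labels whenever their variants share a clone in any
    participant; its weight is the number of such participant-blocks.
    Fitness at the grid minimum is floored at ``log_s_floor`` before
    logging.
    """
    if level not in ("gene", "category", "variant"):
        raise ValueError(f"unknown level {level!r}")
    rec = _variant_records(estimates, log_s_floor)
    G = nx.Graph()
    if rec.empty:
        return NetworkSummary(G, pd.DataFrame(), pd.DataFrame())
    key = {"gene": "gene", "category": "category", "variant": "variant"}[level]

    grouped = rec.groupby(key)["log_fitness"].agg(["count", "mean"])
    lo, hi = grouped["mean"].min(), grouped["mean"].max()
    for label, row in grouped.iterrows():
        color = 0.5 if hi == lo else (row["mean"] - lo) / (hi - lo)
        G.add_node(
            label,
            count=int(row["count"]),
            size=math.log(row["count"]),
            mean_log_fitness=float(row["mean"]),
            color=float(color),
        )

    edge_weight: dict[tuple, int] = {}
    for (_, block), sub in rec.groupby(["participant_id", "block"]):
        labels = sorted(set(sub[key]))
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                edge_weight[(labels[i], labels[j])] = edge_weight.get((labels[i], labels[j]), 0) + 1
    for (a, b), w in sorted(edge_weight.items()):
        G.add_edge(
            a,
            b,
            weight=w,
            mean_log_fitness=float(
                (G.nodes[a]["mean_log_fitness"] + G.nodes[b]["mean_log_fitness"]) / 2
            ),
        )

    nodes = pd.DataFrame(
        [{"label": n, **d} for n, d in G.nodes(data=True)]
    ).sort_values("label").reset_index(drop=True)
    edges = pd.DataFrame(
        [{"source": a, "target": b, **d} for a, b, d in G.edges(data=True)]
    )
    if not edges.empty:
        edges = edges.sort_values(["source", "target"]).reset_index(drop=True)
    return NetworkSummary(G, nodes, edges)


def export_network(summary: NetworkSummary, graphml_path=None, json_path=None) -> None:
    if graphml_path is not None:
        nx.write_graphml(summary.graph, graphml_path)
    if json_path is not None:
        doc = nx.adjacency_data(summary.graph)
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)


@dataclass
class FitnessContrast:
    """Isolated vs co-occurring log-fitness contrast for one group."""

    group: str
    partner: str | None
    n_alone: int
    n_cooccurring: int
    statistic: float | None
    effect: float | None  # mean(co) - mean(alone) log fitness
    p_raw: float | None
    p_adjusted: float | None = None
    flag: str | None = None


def compare_isolated_vs_cooccurring(
    estimates,
    grouping: str = "gene",
    min_n: int = 2,
    log_s_floor: float = 0.0025,
):
    """Brunner-Munzel contrasts of log fitness, alone vs co-occurring.

    Per group (and per co-partner category pairing when grouping is
    ``category``), tests whether mutations occurring alone in a clone
    differ in log fitness from co-occurring ones.  Groups with fewer than
    ``min_n`` observations (or < 2 on either side) are flagged
    'insufficient' and excluded from the Benjamini-Yekutieli correction
    but still reported descriptively.
    """
    if grouping not in ("gene", "category"):
        raise ValueError(f"unknown grouping {grouping!r}")
    rec = _variant_records(estimates, log_s_floor)
    results: list[FitnessContrast] = []
    if rec.empty:
        return results

    def _contrast(group, alone, co, partner=None):
        n_a, n_c = len(alone), len(co)
        if min(n_a, n_c) < max(min_n, 2):
            return FitnessContrast(group, partner, n_a, n_c, None, None, None, flag="insufficient")
        with np.errstate(all="ignore"):
            stat, p = brunnermunzel(alone, co)
        flag = None
        if not np.isfinite(p):
            # complete separation: the BM variance estimate degenerates;
            # report the exact two-sided permutation floor of a rank test
            from scipy.special import comb

            p = min(2.0 / comb(n_a + n_c, n_a, exact=True), 1.0)
            flag = "complete-separation"
        return FitnessContrast(
            group, partner, n_a, n_c,
            float(stat), float(np.mean(co) - np.mean(alone)), float(p), flag=flag,
        )

    for group, sub in rec.groupby(grouping):
        alone = sub.loc[~sub["co_occurring"], "log_fitness"].to_numpy()
        co = sub.loc[sub["co_occurring"], "log_fitness"].to_numpy()
        results.append(_contrast(group, alone, co))

    if grouping == "category":
        # partner-specific contrasts: group members co-occurring with a
        # partner of each other category vs members alone in a clone
        cat_of = {lab: c for lab, c in zip(rec["variant"], rec["category"])}
        for group, sub in rec.groupby(grouping):
            alone = sub.loc[~sub["co_occurring"], "log_fitness"].to_numpy()
            for partner in sorted(rec["category"].unique()):
                mask = []
                for _, r in sub.iterrows():
                    partners = {cat_of[v] for v in r["block"] if v != r["variant"]}
                    mask.append(r["co_occurring"] and partner in partners)
                co = sub.loc[mask, "log_fitness"].to_numpy()
                if len(co) == 0:
                    continue
                results.append(_contrast(group, alone, co, partner=partner))

    tested = [r for r in results if r.p_raw is not None]
    if tested:
        adj = multipletests([r.p_raw for r in tested], method="fdr_by")[1]
        for r, p in zip(tested, adj):
            r.p_adjusted = float(p)
    return results
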