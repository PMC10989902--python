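"""Cross-kingdom Spearman co-occurrence networks and derived features.

Edges join taxon pairs (within and across kingdoms) whose Spearman rank
correlation over samples exceeds the magnitude threshold at the required
significance (no multiplicity correction, matching common practice for
these networks).  Per-sample subnetworks induced on the taxa detected in a
sample yield the biotic features used downstream: average degree (AD), the
proportion of negative edges (Neg) and the proportion of bacterium-fungus
edges (Int).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community import CountTable
from .exceptions import (
    DegenerateInputError,
    InvalidArgumentError,
    LabelMismatchError,
)


def build_cooccurrence(
    bacteria: CountTable,
    fungi: CountTable,
    rho_threshold: float = 0.6,
    p_threshold: float = 0.001,
) -> nx.Graph:
    """Spearman co-occurrence network over the merged bacteria+fungi table.

    An edge is kept iff |rho| > ``rho_threshold`` AND p < ``p_threshold``
    (two-sided t-approximation with average ranks).  Isolated nodes are
    removed.  Nodes carry ``kingdom`` and ``degree``; edges carry ``rho``,
    ``p`` and ``sign``.
    """
    if set(bacteria.sample_ids) != set(fungi.sample_ids):
        raise LabelMismatchError("bacteria and fungi tables have different samples")
    if bacteria.n_samples < 5:
        raise InvalidArgumentError("need >= 5 samples for the Spearman p-value")
    merged = bacteria.merge(fungi)
    X = merged.data.to_numpy(dtype=float)
    taxa = merged.taxon_ids
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield NaN rho
        rho, p = stats.spearmanr(X)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    keep = (np.abs(rho) > rho_threshold) & (p < p_threshold)
    keep &= np.isfinite(rho)
    np.fill_diagonal(keep, False)

    graph = nx.Graph()
    ii, jj = np.where(np.triu(keep, k=1))
    for i, j in zip(ii, jj):
        graph.add_edge(
            taxa[i],
            taxa[j],
            rho=float(rho[i, j]),
            p=float(p[i, j]),
            sign="pos" if rho[i, j] > 0 else "neg",
        )
    for node in graph.nodes:
        graph.nodes[node]["kingdom"] = merged.kingdom[node]
    degrees = dict(graph.degree())
    nx.set_node_attributes(graph, degrees, "degree")
    return graph


def niche_preference(
    table: CountTable, env: pd.DataFrame, variable: str
) -> pd.Series:
    """Abundance-weighted environmental preference per taxon.

    pref_i = sum over samples where taxon i is detected of w_is * x_s with
    w_is the taxon's relative abundance across its occupied samples.
    """
    if variable not in env.columns:
        raise InvalidArgumentError(f"variable {variable!r} not in env")
    x = env[variable].reindex(table.data.index).astype(float)
    if x.isna().any():
        raise LabelMismatchError("environment missing for some samples")
    counts = table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    detected = totals > 0
    if not detected.all():
        warnings.warn("taxa detected nowhere were excluded")
    weights = counts[:, detected] / totals[detected]
    prefs = weights.T @ x.to_numpy()
    return pd.Series(
        prefs, index=np.array(table.taxon_ids)[detected], name=variable
    )


def degree_preference_correlation(
    net: nx.Graph, prefs: pd.Series, variable: str | None = None
) -> dict:
    """Pearson correlation between node degree and niche preference.

    Returns ``{"r", "p", "slope", "n"}`` where slope is the OLS slope of
    degree on preference.
    """
    nodes = [n for n in net.nodes if n in prefs.index]
    if len(nodes) < 3:
        raise InvalidArgumentError("need >= 3 network nodes with a preference")
    degree = np.array([net.degree(n) for n in nodes], dtype=float)
    pref = prefs.loc[nodes].to_numpy(dtype=float)
    if degree.std() == 0 or pref.std() == 0:
        raise DegenerateInputError("zero variance in degree or preference")
    r, p = stats.pearsonr(pref, degree)
    slope = stats.linregress(pref, degree).slope
    return {"r": float(r), "p": float(p), "slope": float(slope), "n": len(nodes)}


def sample_subnetwork_features(net: nx.Graph, table: CountTable) -> pd.DataFrame:
    """AD / Neg / Int features of each sample's induced subnetwork.

    For every sample the subgraph induced on its detected taxa is taken
    from the global network; AD = 2E/N, Neg = negative edges / E and
    Int = cross-kingdom edges / E.  Samples with no edges get zeros and
    ``flagged=True`` so downstream regressions keep their alignment.
    """
    rows = []
    nodes = set(net.nodes)
    for sample in table.sample_ids:
        present = set(table.data.columns[table.data.loc[sample] > 0]) & nodes
        sub = net.subgraph(present)
        n_nodes, n_edges = sub.number_of_nodes(), sub.number_of_edges()
        if n_edges == 0:
            rows.append(
                {
                    "sample": sample,
                    "AD": 0.0,
                    "Neg": 0.0,
                    "Int": 0.0,
                    "n_nodes": n_nodes,
                    "n_edges": 0,
                    "flagged": True,
                }
            )
            continue
        neg = sum(1 for _, _, d in sub.edges(data=True) if d["sign"] == "neg")
        cross = sum(
            1
            for u, v in sub.edges()
            if net.nodes[u]["kingdom"] != net.nodes[v]["kingdom"]
        )
        rows.append(
            {
                "sample": sample,
                "AD": 2.0 * n_edges / n_nodes,
                "Neg": neg / n_edges,
                "Int": cross / n_edges,
                "n_nodes": n_nodes,
                "n_edges": n_edges,
                "flagged": False,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def edge_table(net: nx.Graph) -> pd.DataFrame:
    """Edge list with rho, p, sign and endpoint kingdoms."""
    rows = [
        {
            "taxonA": u,
            "taxonB": v,
            "rho": d["rho"],
            "p": d["p"],
            "sign": d["sign"],
            "kingdomA": net.nodes[u]["kingdom"],
            "kingdomB": net.nodes[v]["kingdom"],
        }
        for u, v, d in net.edges(data=True)
    ]
    return pd.DataFrame(
        rows, columns=["taxonA", "taxonB", "rho", "p", "sign", "kingdomA", "kingdomB"]
    )
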