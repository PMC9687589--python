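"""Weighted-graph measures, asymmetry ratios and the 784-feature vector.

Sixteen connectivity matrices per subject (IMCOH/PLV/PDC in five bands, MI
in the global band) feed four feature blocks:

* band power (40), * group-summarized connectivity (128),
* graph measures (468), * left/right asymmetry ratios (148);

784 in total, in a fixed canonical order shared by every subject.  Node-level
measures (strength, clustering, betweenness) are computed on the full
18-channel graph and then summarized per scalp group; in/out-degree maxima
and efficiency are computed on the 5-node group subgraphs.
"""

from __future__ import annotations

import logging
from collections import OrderedDict

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix
from .montage import GROUP_ORDER, MontageLayout

logger = logging.getLogger(__name__)

ESTIMATORS = ("imcoh", "plv", "mi", "pdc")
FIVE_BANDS = ("delta", "theta", "alpha", "beta", "global")
ASYM_CAP = 1e6
ASYM_EPSILON = 1e-12
#: (label, (left group, right group)) hemisphere comparisons
ASYM_PAIRS = (("anterior", ("AL", "AR")), ("posterior", ("PL", "PR")))


def estimator_bands() -> list[tuple[str, str]]:
    """The 16 (estimator, band) combinations, in canonical order."""
    combos = []
    for est in ESTIMATORS:
        bands = ("global",) if est == "mi" else FIVE_BANDS
        combos.extend((est, b) for b in bands)
    return combos


# ---------------------------------------------------------------------------
# graph measures

def node_strength(adjacency: np.ndarray, directed: bool) -> np.ndarray:
    """Sum of incident weights; directed graphs use in- plus out-strength."""
    adjacency = np.asarray(adjacency, dtype=float)
    if directed:
        return adjacency.sum(axis=0) + adjacency.sum(axis=1)
    return adjacency.sum(axis=1)


def in_out_degree_max(adjacency: np.ndarray, directed: bool,
                      group_idx: np.ndarray) -> tuple[float, float]:
    """Max in-strength (column sums) and out-strength (row sums) of a group."""
    if not directed:
        raise ValueError("in/out degrees are defined for directed graphs only")
    sub = np.asarray(adjacency, dtype=float)[np.ix_(group_idx, group_idx)]
    return float(sub.sum(axis=0).max()), float(sub.sum(axis=1).max())


def clustering_coefficient(adjacency: np.ndarray, directed: bool) -> np.ndarray:
    """Onnela weighted clustering per node.

    Weights are normalized by the graph's maximum; directed graphs are
    symmetrized as (W + W^T)/2 first.  Nodes with binary degree < 2 get 0.
    """
    W = np.asarray(adjacency, dtype=float).copy()
    if directed:
        W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    wmax = W.max()
    if wmax <= 0:
        return np.zeros(W.shape[0])
    Wn = W / wmax
    W3 = np.cbrt(Wn)
    num = np.diagonal(W3 @ W3 @ W3)
    k = (Wn > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    return C


def betweenness_centrality(adjacency: np.ndarray, directed: bool) -> np.ndarray:
    """Brandes betweenness on 1/weight edge lengths, pair-count normalized."""
    W = np.asarray(adjacency, dtype=float)
    n = W.shape[0]
    G = nx.DiGraph() if directed else nx.Graph()
    G.add_nodes_from(range(n))
    rows, cols = np.nonzero(W)
    for i, j in zip(rows, cols):
        if i == j:
            continue
        if not directed and i > j:
            continue
        G.add_edge(int(i), int(j), length=1.0 / W[i, j])
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(n)])


def global_efficiency(adjacency: np.ndarray, directed: bool) -> float:
    """Mean over ordered node pairs of 1/shortest-path-length (1/w lengths)."""
    W = np.asarray(adjacency, dtype=float)
    n = W.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    D = shortest_path(lengths, method="D", directed=directed)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(D)
    finite = np.isfinite(D) & (D > 0)
    inv[finite] = 1.0 / D[finite]
    return float(inv[off].mean())


def asymmetry_ratio(left: float, right: float) -> float:
    """max/min ratio, >= 1; non-positive inputs hit the documented cap."""
    hi, lo = max(left, right), min(left, right)
    if lo <= 0:
        logger.debug("non-positive asymmetry input (%g, %g); ratio capped",
                     left, right)
        return min((hi + ASYM_EPSILON) / ASYM_EPSILON, ASYM_CAP)
    return hi / lo


# ---------------------------------------------------------------------------
# canonical taxonomy

def feature_names() -> list[str]:
    """The canonical ordered names of all 784 features."""
    names: list[str] = []
    combos = estimator_bands()
    # band power block (40)
    for band in ("delta", "theta", "alpha", "beta"):
        for group in GROUP_ORDER:
            names += [f"bp_{band}_{group}_median", f"bp_{band}_{group}_std"]
    for group in GROUP_ORDER:
        names += [f"tap_{group}_median", f"tap_{group}_std"]
    # connectivity group summaries (128)
    for est, band in combos:
        for group in GROUP_ORDER:
            names += [f"conn_{est}_{band}_{group}_mean",
                      f"conn_{est}_{band}_{group}_std"]
    # graph block (468)
    for band in FIVE_BANDS:  # in/out degree maxima, PDC only (40)
        for group in GROUP_ORDER:
            names += [f"indeg_pdc_{band}_{group}_max",
                      f"outdeg_pdc_{band}_{group}_max"]
    for est, band in combos:  # node strength (108; PDC mean-only)
        for group in GROUP_ORDER:
            names.append(f"strength_{est}_{band}_{group}_mean")
            if est != "pdc":
                names.append(f"strength_{est}_{band}_{group}_std")
    for est, band in combos:  # clustering (128)
        for group in GROUP_ORDER:
            names += [f"clust_{est}_{band}_{group}_mean",
                      f"clust_{est}_{band}_{group}_std"]
    for est, band in combos:  # betweenness (128)
        for group in GROUP_ORDER:
            names += [f"btw_{est}_{band}_{group}_mean",
                      f"btw_{est}_{band}_{group}_std"]
    for est, band in combos:  # efficiency (64)
        for group in GROUP_ORDER:
            names.append(f"eff_{est}_{band}_{group}_value")
    # asymmetry block (148)
    for measure in ("strength", "clust", "btw"):
        for est, band in combos:
            for label, _ in ASYM_PAIRS:
                names.append(f"asym_{measure}_{est}_{band}_{label}")
    for band in FIVE_BANDS:
        for direction in ("indeg", "outdeg"):
            for label, _ in ASYM_PAIRS:
                names.append(f"asym_{direction}_pdc_{band}_{label}")
    for est, band in combos:
        for label, _ in ASYM_PAIRS:
            names.append(f"asym_eff_{est}_{band}_{label}")
    return names


def graph_features(
    matrices: dict[tuple[str, str], ConnectivityMatrix],
    layout: MontageLayout,
) -> dict[str, float]:
    """Graph-measure and asymmetry features from the 16 connectivity matrices."""
    feats: dict[str, float] = {}
    group_idx = {g: layout.group_indices(g) for g in GROUP_ORDER}
    # per-(est, band) group summaries reused by the asymmetry block
    summaries: dict[tuple[str, str, str, str], float] = {}

    for band in FIVE_BANDS:
        cm = matrices[("pdc", band)]
        for group in GROUP_ORDER:
            din, dout = in_out_degree_max(cm.values, cm.directed,
                                          group_idx[group])
            feats[f"indeg_pdc_{band}_{group}_max"] = din
            feats[f"outdeg_pdc_{band}_{group}_max"] = dout
            summaries[("indeg", band, "pdc", group)] = din
            summaries[("outdeg", band, "pdc", group)] = dout

    for est, band in estimator_bands():
        cm = matrices[(est, band)]
        strength = node_strength(cm.values, cm.directed)
        clust = clustering_coefficient(cm.values, cm.directed)
        btw = betweenness_centrality(cm.values, cm.directed)
        for group in GROUP_ORDER:
            gi = group_idx[group]
            s_mean = float(strength[gi].mean())
            feats[f"strength_{est}_{band}_{group}_mean"] = s_mean
            if est != "pdc":
                feats[f"strength_{est}_{band}_{group}_std"] = float(
                    strength[gi].std())
            c_mean = float(clust[gi].mean())
            feats[f"clust_{est}_{band}_{group}_mean"] = c_mean
            feats[f"clust_{est}_{band}_{group}_std"] = float(clust[gi].std())
            b_mean = float(btw[gi].mean())
            feats[f"btw_{est}_{band}_{group}_mean"] = b_mean
            feats[f"btw_{est}_{band}_{group}_std"] = float(btw[gi].std())
            eff = global_efficiency(cm.values[np.ix_(gi, gi)], cm.directed)
            feats[f"eff_{est}_{band}_{group}_value"] = eff
            summaries[("strength", band, est, group)] = s_mean
            summaries[("clust", band, est, group)] = c_mean
            summaries[("btw", band, est, group)] = b_mean
            summaries[("eff", band, est, group)] = eff

    for measure in ("strength", "clust", "btw"):
        for est, band in estimator_bands():
            for label, (lg, rg) in ASYM_PAIRS:
                feats[f"asym_{measure}_{est}_{band}_{label}"] = asymmetry_ratio(
                    summaries[(measure, band, est, lg)],
                    summaries[(measure, band, est, rg)])
    for band in FIVE_BANDS:
        for direction in ("indeg", "outdeg"):
            for label, (lg, rg) in ASYM_PAIRS:
                feats[f"asym_{direction}_pdc_{band}_{label}"] = asymmetry_ratio(
                    summaries[(direction, band, "pdc", lg)],
                    summaries[(direction, band, "pdc", rg)])
    for est, band in estimator_bands():
        for label, (lg, rg) in ASYM_PAIRS:
            feats[f"asym_eff_{est}_{band}_{label}"] = asymmetry_ratio(
                summaries[("eff", band, est, lg)],
                summaries[("eff", band, est, rg)])
    n_capped = sum(1 for k, v in feats.items()
                   if k.startswith("asym_") and v >= ASYM_CAP)
    if n_capped:
        logger.warning("%d asymmetry ratio(s) capped at %g "
                       "(a zero group summary on one side)", n_capped, ASYM_CAP)
    return feats


def connectivity_features(
    matrices: dict[tuple[str, str], ConnectivityMatrix],
    layout: MontageLayout,
) -> dict[str, float]:
    """The 128 group-summarized connectivity features."""
    from .connectivity import summarize_groups

    feats: dict[str, float] = {}
    for est, band in estimator_bands():
        summary = summarize_groups(matrices[(est, band)], layout)
        for group in GROUP_ORDER:
            mean, std = summary[group]
            feats[f"conn_{est}_{band}_{group}_mean"] = mean
            feats[f"conn_{est}_{band}_{group}_std"] = std
    return feats


def assemble_features(*blocks: dict[str, float]) -> "OrderedDict[str, float]":
    """Merge feature blocks into the canonical 784-entry ordered vector."""
    merged: dict[str, float] = {}
    for block in blocks:
        merged.update(block)
    names = feature_names()
    missing = [n for n in names if n not in merged]
    if missing:
        raise ValueError(
            f"{len(missing)} features missing from assembly, e.g. {missing[:5]}"
        )
    extra = set(merged) - set(names)
    if extra:
        raise ValueError(f"unknown feature names produced: {sorted(extra)[:5]}")
    return OrderedDict((n, float(merged[n])) for n in names)
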