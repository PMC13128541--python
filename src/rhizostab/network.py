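"""Signed co-occurrence network construction from abundance tables.

Networks follow the field's thresholded-correlation recipe: rare zOTUs
(mean relative abundance <= 0.01%) are removed, all pairwise Spearman
correlations are computed, p-values are Benjamini-Hochberg adjusted over
the pairs actually tested within the network, and an edge is kept when
|rho| > 0.8 and the adjusted p-value is below 0.05.  One network is
built per analysis dataset (one compartment x treatment, pooling growth
stages and replicates).
"""

from __future__ import annotations

import itertools
import logging
import math
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, RelAbundTable, filter_by_mean_rel_abund, relative_abundance

logger = logging.getLogger("rhizostab")

EXACT_P_MAX_N = 8  # full rank-permutation enumeration is practical up to 8!
MC_P_MAX_N = 30  # Monte-Carlo permutation null used up to this sample size
MC_NULL_DRAWS = 2_000_000
_MC_NULL_SEED = 916_351_477  # fixed: the null table is a deterministic constant


# ---------------------------------------------------------------------------
# Correlation and FDR primitives
# ---------------------------------------------------------------------------

def spearman_matrix(
    abund: RelAbundTable | pd.DataFrame, method: str = "auto"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p over a taxa x samples table.

    Ties are handled by average ranks.  P-value methods:

    - ``"exact"``: full enumeration of the tie-free permutation null
      (n <= 8 samples only);
    - ``"mc"``: a large shared Monte-Carlo permutation null (the exact
      null is universal for tie-free data given n); accurate deep into
      the tail, where the t approximation is several-fold
      anti-conservative at these sample sizes;
    - ``"t"``: the classical t-distribution approximation;
    - ``"auto"`` (default): exact for n <= 8, Monte-Carlo up to n = 30,
      t beyond.

    Constant taxa produce NaN rho/p for their pairs; such pairs are
    never promoted to edges.
    """
    values = abund.values if isinstance(abund, RelAbundTable) else abund
    n_samples = values.shape[1]
    if n_samples < 4:
        raise ValueError(
            f"need >= 4 samples for Spearman correlation, got {n_samples}"
        )
    data = values.to_numpy(dtype=float)
    constant = np.all(data == data[:, :1], axis=1)
    if constant.any():
        logger.warning(
            "spearman_matrix: %d constant taxa; their correlations are NaN",
            int(constant.sum()),
        )
    ranks = pd.DataFrame(data.T).rank(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    if method == "auto":
        if n_samples <= EXACT_P_MAX_N:
            method = "exact"
        elif n_samples <= MC_P_MAX_N:
            method = "mc"
        else:
            method = "t"
    if method == "t":
        p = _p_from_t(rho, n_samples)
    elif method == "mc":
        p = _p_mc(rho, n_samples)
    elif method == "exact":
        p = _p_exact(ranks, rho)
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    np.fill_diagonal(p, 0.0)
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    taxa = values.index
    return (
        pd.DataFrame(rho, index=taxa, columns=taxa),
        pd.DataFrame(p, index=taxa, columns=taxa),
    )


def _p_from_t(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return p


@lru_cache(maxsize=4)
def _mc_null(n: int) -> np.ndarray:
    """Sorted |rho| over a large Monte-Carlo sample of the tie-free
    permutation null (universal for a given n)."""
    rng = np.random.default_rng(_MC_NULL_SEED)
    base = np.tile(np.arange(n, dtype=np.int16), (MC_NULL_DRAWS, 1))
    perm = rng.permuted(base, axis=1)
    d2 = ((perm - np.arange(n, dtype=np.int16)) ** 2).sum(
        axis=1, dtype=np.int64
    )
    rho = np.abs(1.0 - 6.0 * d2 / (n * (n * n - 1.0)))
    rho.sort()
    return rho


def _p_mc(rho: np.ndarray, n: int) -> np.ndarray:
    null = _mc_null(n)
    total = null.size
    k = np.searchsorted(null, np.abs(rho) - 1e-12, side="left")
    # add-one correction keeps p > 0
    return (total - k + 1.0) / (total + 1.0)


@lru_cache(maxsize=8)
def _exact_null(n: int) -> np.ndarray:
    """Sorted |rho| values over all n! permutations of tie-free ranks."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n**2 - 1) / 6.0
    out = np.empty(math.factorial(n))
    for k, perm in enumerate(itertools.permutations(base)):
        d2 = float(((base - np.asarray(perm)) ** 2).sum())
        out[k] = abs(1.0 - d2 / denom)
    out.sort()
    return out


def _p_exact(ranks: np.ndarray, rho: np.ndarray) -> np.ndarray:
    n, m = ranks.shape
    if n > EXACT_P_MAX_N:
        raise ValueError(
            f"exact permutation p-values supported for n <= {EXACT_P_MAX_N} "
            f"samples, got {n}"
        )
    tied = [len(np.unique(ranks[:, j])) < n for j in range(m)]
    if any(tied):
        logger.warning(
            "exact Spearman p-values assume tie-free data; %d taxa have "
            "ties, falling back to the t approximation for their pairs",
            sum(tied),
        )
    null = _exact_null(n)
    total = null.size
    p = np.empty_like(rho)
    p_t = _p_from_t(rho, n)
    for i in range(m):
        for j in range(m):
            if tied[i] or tied[j]:
                p[i, j] = p_t[i, j]
            elif np.isnan(rho[i, j]):
                p[i, j] = np.nan
            else:
                # P(|rho_null| >= |rho_obs|), small tolerance for float noise
                k = np.searchsorted(null, abs(rho[i, j]) - 1e-12, side="left")
                p[i, j] = (total - k) / total
    return p


def fdr_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def build_network(
    table: CountTable,
    rho_threshold: float = 0.8,
    alpha: float = 0.05,
    min_rel_abund: float = 1e-4,
    dataset: str = "",
    p_method: str = "auto",
    keep_isolated: bool = False,
) -> nx.Graph:
    """Build one signed co-occurrence network from a count table.

    ``table`` should already be restricted to one analysis dataset
    (compartment x treatment, stages and replicates pooled).  Edges
    satisfy |rho| > ``rho_threshold`` and BH-adjusted p < ``alpha``; the
    adjustment runs over all pairs with defined rho in this network.
    Nodes are the retained zOTUs participating in at least one edge
    unless ``keep_isolated`` is set (the isolated-node policy is
    logged).  Node attribute ``kingdom`` and edge attributes ``rho``,
    ``p_raw``, ``p_fdr`` and ``sign`` are attached.
    """
    if len(table.samples) < 4:
        raise ValueError(
            f"refusing to build a network from {len(table.samples)} samples; "
            ">= 4 are required for Spearman correlation"
        )
    filtered = filter_by_mean_rel_abund(table, min_rel_abund)
    abund = relative_abundance(filtered)
    rho_df, p_df = spearman_matrix(abund, method=p_method)
    rho = rho_df.to_numpy()
    p = p_df.to_numpy()
    taxa = list(rho_df.index)
    iu = np.triu_indices(len(taxa), k=1)
    raw = p[iu]
    tested = ~np.isnan(raw)
    adj = np.full(raw.shape, np.nan)
    adj[tested] = fdr_adjust(raw[tested])

    g = nx.Graph(
        dataset=dataset,
        rho_threshold=float(rho_threshold),
        alpha=float(alpha),
        min_rel_abund=float(min_rel_abund),
        n_samples=int(len(table.samples)),
        n_tested_pairs=int(tested.sum()),
    )
    kingdoms = filtered.taxon_meta["kingdom"]
    if keep_isolated:
        for t in taxa:
            g.add_node(t, kingdom=str(kingdoms.loc[t]))
    keep = tested & (np.abs(rho[iu]) > rho_threshold) & (adj < alpha)
    for k in np.where(keep)[0]:
        i, j = iu[0][k], iu[1][k]
        a, b = taxa[i], taxa[j]
        for t in (a, b):
            if t not in g:
                g.add_node(t, kingdom=str(kingdoms.loc[t]))
        g.add_edge(
            a, b,
            rho=float(rho[i, j]),
            p_raw=float(raw[k]),
            p_fdr=float(adj[k]),
            sign="positive" if rho[i, j] > 0 else "negative",
        )
    logger.info(
        "build_network[%s]: %d nodes, %d edges from %d retained zOTUs "
        "(isolated nodes %s)",
        dataset, g.number_of_nodes(), g.number_of_edges(), len(taxa),
        "kept" if keep_isolated else "excluded",
    )
    return g


def build_treatment_networks(
    table: CountTable,
    compartments: list[str] | None = None,
    treatments: list[str] | None = None,
    **kwargs,
) -> dict[tuple[str, str], nx.Graph]:
    """One network per (compartment, treatment), pooling stages/replicates."""
    meta = table.sample_meta
    comps = compartments or sorted(meta["compartment"].unique())
    trts = treatments or sorted(meta["treatment"].unique())
    out: dict[tuple[str, str], nx.Graph] = {}
    for comp in comps:
        for trt in trts:
            sub = table.select(compartment=comp, treatment=trt)
            if len(sub.samples) == 0:
                continue
            out[(comp, trt)] = build_network(
                sub, dataset=f"{comp}:{trt}", **kwargs
            )
    return out


# ---------------------------------------------------------------------------
# Edge summaries
# ---------------------------------------------------------------------------

def edge_kingdom_summary(net: nx.Graph) -> dict:
    """Intra-/inter-kingdom edge counts and per-kingdom node counts."""
    for node, data in net.nodes(data=True):
        if "kingdom" not in data:
            raise ValueError(f"node {node!r} lacks a kingdom label")
    intra: dict[str, int] = {}
    inter: dict[tuple[str, str], int] = {}
    for a, b in net.edges():
        ka, kb = net.nodes[a]["kingdom"], net.nodes[b]["kingdom"]
        if ka == kb:
            intra[ka] = intra.get(ka, 0) + 1
        else:
            key = tuple(sorted((ka, kb)))
            inter[key] = inter.get(key, 0) + 1
    nodes: dict[str, int] = {}
    for _, data in net.nodes(data=True):
        nodes[data["kingdom"]] = nodes.get(data["kingdom"], 0) + 1
    return {"intra": intra, "inter": inter, "nodes": nodes}


def edge_sign_summary(net: nx.Graph) -> tuple[int, int]:
    """(number of positive edges, number of negative edges)."""
    pos = sum(1 for _, _, d in net.edges(data=True) if d["sign"] == "positive")
    return pos, net.number_of_edges() - pos


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    rows = [
        (a, b, d["rho"], d["p_raw"], d["p_fdr"], d["sign"])
        for a, b, d in net.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "rho", "p_raw", "p_fdr", "sign"]
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(
    path: str | Path, kingdoms: pd.Series | None = None
) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(
            row.source, row.target,
            rho=float(row.rho), p_raw=float(row.p_raw),
            p_fdr=float(row.p_fdr), sign=str(row.sign),
        )
    if kingdoms is not None:
        for node in g.nodes():
            g.nodes[node]["kingdom"] = str(kingdoms.loc[node])
    return g


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
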