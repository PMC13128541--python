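"""Network stability battery: natural connectivity, robustness under
random node removal, cohesion, average variation degree and vulnerability.

Natural connectivity is the log-average of exponentiated adjacency
eigenvalues, lambda_bar = ln((1/N) sum_i exp(lambda_i)); it measures the
weighted abundance of closed walks and hence the redundancy of
alternative paths.  Robustness tracks how it (and average degree) decay
as random fractions of nodes are deleted.  Cohesion summarises, per
sample, how strongly the community's realised abundances engage the
network's significant positive and negative correlations.  AVD measures
replicate-to-replicate dispersion of taxon abundances (higher = less
stable), and vulnerability is the worst single-node loss of global
efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from pathlib import Path
from scipy.special import logsumexp

from .tables import RelAbundTable

logger = logging.getLogger("rhizostab")


# ---------------------------------------------------------------------------
# Natural connectivity and robustness
# ---------------------------------------------------------------------------

def natural_connectivity(net: nx.Graph) -> float:
    """lambda_bar = ln((1/N) sum_i e^{lambda_i}) of the unweighted adjacency.

    Computed with a log-sum-exp so large eigenvalues cannot overflow.
    An edgeless graph (all eigenvalues zero) gives exactly 0.
    """
    n = net.number_of_nodes()
    if n < 1:
        raise ValueError("natural connectivity needs at least one node")
    if net.number_of_edges() == 0:
        return 0.0
    a = nx.to_numpy_array(net, weight=None)
    eig = np.linalg.eigvalsh(a)
    return float(logsumexp(eig) - np.log(n))


@dataclass
class RobustnessCurve:
    """Mean +/- sd of natural connectivity and average degree under random
    node removal, per removal fraction."""

    fractions: np.ndarray
    nc_mean: np.ndarray
    nc_sd: np.ndarray
    avg_degree_mean: np.ndarray
    avg_degree_sd: np.ndarray
    n_repetitions: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "mean_nc": self.nc_mean,
                "sd_nc": self.nc_sd,
                "mean_avg_degree": self.avg_degree_mean,
                "sd_avg_degree": self.avg_degree_sd,
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def robustness_curve(
    net: nx.Graph,
    fractions: np.ndarray | None = None,
    n_rep: int = 100,
    seed: int = 0,
) -> RobustnessCurve:
    """Randomly remove node fractions and track connectivity decay.

    For each fraction f, round(f * N) nodes are removed uniformly at
    random and the induced subgraph's natural connectivity and average
    degree recorded; repeated ``n_rep`` times.  Fraction 0 reproduces
    the intact network exactly (sd 0).
    """
    if net.number_of_nodes() < 2:
        raise ValueError("robustness needs >= 2 nodes")
    if fractions is None:
        fractions = np.arange(0.0, 0.8001, 0.05)
    fractions = np.asarray(fractions, dtype=float)
    if (fractions >= 1.0).any() or (fractions < 0).any():
        raise ValueError("removal fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    nodes = np.array(sorted(net.nodes()), dtype=object)
    n = len(nodes)
    a_full = nx.to_numpy_array(net, nodelist=list(nodes), weight=None)
    nc_mean, nc_sd, ad_mean, ad_sd = [], [], [], []
    for f in fractions:
        n_remove = int(round(f * n))
        ncs = np.empty(n_rep)
        ads = np.empty(n_rep)
        for r in range(n_rep):
            keep = np.ones(n, dtype=bool)
            if n_remove:
                keep[rng.choice(n, size=n_remove, replace=False)] = False
            sub = a_full[np.ix_(keep, keep)]
            m = keep.sum()
            if m == 0:
                ncs[r] = np.nan
                ads[r] = np.nan
                continue
            if sub.sum() == 0:
                ncs[r] = 0.0
            else:
                eig = np.linalg.eigvalsh(sub)
                ncs[r] = logsumexp(eig) - np.log(m)
            ads[r] = sub.sum() / m  # = 2E'/N'
        nc_mean.append(np.nanmean(ncs))
        nc_sd.append(np.nanstd(ncs, ddof=1) if n_rep > 1 else 0.0)
        ad_mean.append(np.nanmean(ads))
        ad_sd.append(np.nanstd(ads, ddof=1) if n_rep > 1 else 0.0)
    return RobustnessCurve(
        fractions=fractions,
        nc_mean=np.array(nc_mean),
        nc_sd=np.array(nc_sd),
        avg_degree_mean=np.array(ad_mean),
        avg_degree_sd=np.array(ad_sd),
        n_repetitions=n_rep,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cohesion
# ---------------------------------------------------------------------------

def connectedness(net: nx.Graph, agg: str = "mean") -> pd.DataFrame:
    """Per-taxon positive and negative connectedness from network edges.

    Positive connectedness of taxon i is the mean (or, with
    ``agg="sum"``, the sum) of rho over i's significant positive edges,
    0 if it has none; likewise for negative edges (values <= 0).
    """
    if agg not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation {agg!r}")
    rows = {}
    for node in net.nodes():
        pos = [d["rho"] for _, _, d in net.edges(node, data=True) if d["rho"] > 0]
        neg = [d["rho"] for _, _, d in net.edges(node, data=True) if d["rho"] < 0]
        f = np.mean if agg == "mean" else np.sum
        rows[node] = (
            float(f(pos)) if pos else 0.0,
            float(f(neg)) if neg else 0.0,
        )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["positive", "negative"]
    )


@dataclass
class CohesionResult:
    """Per-taxon connectedness and per-sample cohesion values."""

    connectedness: pd.DataFrame
    samples: pd.DataFrame  # positive, negative, total, neg_pos_ratio per sample

    def write(self, path: str | Path) -> None:
        self.samples.to_csv(path, sep="\t", index_label="sample_id")


def cohesion(
    abund: RelAbundTable | pd.DataFrame,
    conn: pd.DataFrame,
    renormalize: bool = False,
) -> CohesionResult:
    """Per-sample cohesion = sum_i abundance_i x connectedness_i.

    By default abundances are the community-wide relative abundances, so
    taxa outside the network implicitly contribute zero and cohesion
    scales with how much of the community the network engages (the
    behaviour of the index's source method).  With ``renormalize=True``
    the abundances are instead renormalised over the network's taxa
    within each sample, making cohesion a pure mean-correlation summary
    independent of network coverage.  Positive cohesion >= 0, negative
    <= 0, total = positive + |negative|, and the |negative|/positive
    ratio is NaN where positive is 0.
    """
    values = abund.values if isinstance(abund, RelAbundTable) else abund
    taxa = [t for t in conn.index if t in values.index]
    missing = set(conn.index) - set(values.index)
    if missing:
        raise ValueError(
            f"abundance table lacks network taxa: {sorted(missing)[:5]} ..."
        )
    sub = values.loc[taxa]
    totals = sub.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        logger.warning(
            "cohesion: sample(s) with zero abundance on network taxa "
            "(cohesion set to 0): %s", empty
        )
    weights = (
        sub.div(totals.replace(0, 1.0), axis=1) if renormalize else sub
    )
    pos = weights.mul(conn.loc[taxa, "positive"], axis=0).sum(axis=0)
    neg = weights.mul(conn.loc[taxa, "negative"], axis=0).sum(axis=0)
    total = pos + neg.abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = neg.abs() / pos
    ratio[pos == 0] = np.nan
    samples = pd.DataFrame(
        {
            "positive": pos,
            "negative": neg,
            "total": total,
            "neg_pos_ratio": ratio,
        }
    )
    return CohesionResult(connectedness=conn, samples=samples)


# ---------------------------------------------------------------------------
# Average variation degree
# ---------------------------------------------------------------------------

def avd(abund: RelAbundTable | pd.DataFrame, group: list[str]) -> float:
    """Average variation degree over one replicate group.

    For zOTU i and replicate k, a_ik = |x_ik - mean_i| / sd_i (sample sd,
    n-1 denominator, across the group's replicates); AVD is the grand
    mean sum_ik a_ik / (k * n).  zOTUs with zero sd (including taxa
    absent from the whole group) contribute 0.  Higher AVD means lower
    community stability.
    """
    values = abund.values if isinstance(abund, RelAbundTable) else abund
    x = values[list(group)].to_numpy(dtype=float)
    k = x.shape[1]
    if k < 2:
        raise ValueError("AVD needs >= 2 replicate samples in the group")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    # identical replicates must contribute exactly 0; compare the values
    # themselves so float rounding in mean/sd cannot leak through
    constant = (x == x[:, :1]).all(axis=1) | (sd.ravel() == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.abs(x - mean) / sd
    a[constant, :] = 0.0
    return float(a.sum() / (k * x.shape[0]))


def avd_by_treatment(
    abund: RelAbundTable, compartment: str | None = None
) -> pd.Series:
    """AVD per treatment, pooling all stages' replicates within a treatment."""
    meta = abund.sample_meta
    mask = pd.Series(True, index=meta.index)
    if compartment is not None:
        mask &= meta["compartment"] == compartment
    out = {}
    for trt in sorted(meta.loc[mask, "treatment"].unique()):
        group = meta.index[mask & (meta["treatment"] == trt)].tolist()
        out[trt] = avd(abund, group)
    return pd.Series(out, name="avd")


# ---------------------------------------------------------------------------
# Vulnerability
# ---------------------------------------------------------------------------

def global_efficiency(net: nx.Graph) -> float:
    """E = (1/(N(N-1))) sum_{u != v} 1/d(u, v); unreachable pairs add 0."""
    return nx.global_efficiency(net)


def vulnerability(net: nx.Graph) -> tuple[float, pd.Series]:
    """Maximum relative drop in global efficiency on single-node removal.

    V_i = (E - E_-i)/E for each node i (E_-i on the induced subgraph
    without i); V = max_i V_i.  Requires >= 3 nodes and at least one
    edge (E > 0).
    """
    n = net.number_of_nodes()
    if n < 3:
        raise ValueError("vulnerability needs >= 3 nodes")
    e_full = nx.global_efficiency(net)
    if e_full == 0:
        raise ValueError("global efficiency is 0 (edgeless graph); "
                         "vulnerability undefined")
    out = {}
    for node in net.nodes():
        sub = net.subgraph(n2 for n2 in net.nodes() if n2 != node)
        out[node] = (e_full - nx.global_efficiency(sub)) / e_full
    series = pd.Series(out, name="vulnerability")
    return float(series.max()), series


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """All stability indices for one network / dataset."""

    natural_connectivity: float
    robustness: RobustnessCurve | None = None
    cohesion: CohesionResult | None = None
    avd: pd.Series | None = None
    vulnerability: float | None = None
    node_vulnerability: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        row = {
            "natural_connectivity": self.natural_connectivity,
            "vulnerability": self.vulnerability,
        }
        if self.avd is not None:
            for trt, v in self.avd.items():
                row[f"avd_{trt}"] = v
        row.update(self.extras)
        return pd.DataFrame([row])

    def write(
        self,
        summary_path: str | Path,
        robustness_path: str | Path | None = None,
        cohesion_path: str | Path | None = None,
    ) -> None:
        self.summary().to_csv(summary_path, sep="\t", index=False)
        if robustness_path is not None and self.robustness is not None:
            self.robustness.write(robustness_path)
        if cohesion_path is not None and self.cohesion is not None:
            self.cohesion.write(cohesion_path)


def stability_report(
    net: nx.Graph,
    abund: RelAbundTable | None = None,
    n_rep: int = 100,
    seed: int = 0,
    with_robustness: bool = True,
) -> StabilityReport:
    """Compute the full stability battery for one network."""
    nc = natural_connectivity(net)
    rob = (
        robustness_curve(net, n_rep=n_rep, seed=seed)
        if with_robustness and net.number_of_nodes() >= 2
        else None
    )
    coh = None
    avd_series = None
    if abund is not None:
        coh = cohesion(abund, connectedness(net))
        avd_series = avd_by_treatment(abund)
    v = v_nodes = None
    if net.number_of_nodes() >= 3 and net.number_of_edges() > 0:
        v, v_nodes = vulnerability(net)
    return StabilityReport(
        natural_connectivity=nc,
        robustness=rob,
        cohesion=coh,
        avd=avd_series,
        vulnerability=v,
        node_vulnerability=v_nodes,
    )
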