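"""Core-taxa identification: Zi-Pi keystones, SPEC-OCCU specialists,
shared-taxa intersection, and abundance-stability correlation.

A "core taxon" is a zOTU that is simultaneously (i) a network keystone
(non-peripheral in the Zi-Pi plane), (ii) a habitat specialist
(specificity and occupancy both > 0.7 among a habitat's 500 most
abundant zOTUs, treating treatments as habitats), and (iii) detected in
every treatment group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable, RelAbundTable, filter_by_mean_rel_abund, relative_abundance

logger = logging.getLogger("rhizostab")

ROLES = ("peripheral", "connector", "module hub", "network hub")


# ---------------------------------------------------------------------------
# Zi-Pi keystone classification
# ---------------------------------------------------------------------------

def zi_pi(net: nx.Graph, modules: dict) -> pd.DataFrame:
    """Within-module degree z-score (Zi), participation coefficient (Pi)
    and topological role per node.

    Zi = (k_is - mean_s) / sd_s where k_is counts i's links inside its
    own module s and mean/sd run over that module's members (sample sd;
    sd = 0 gives Zi = 0).  Pi = 1 - sum_t (k_it / k_i)^2 over all
    modules t (Pi = 0 for degree-0 nodes, flagged).  Role thresholds:
    network hub (Zi >= 2.5 and Pi >= 0.62) takes precedence, then
    module hub (Zi > 2.5, Pi <= 0.62), then connector (Zi <= 2.5,
    Pi > 0.62); everything else is peripheral.
    """
    missing = [n for n in net.nodes() if n not in modules]
    if missing:
        raise ValueError(f"nodes without module assignment: {missing[:5]} ...")
    nodes = list(net.nodes())
    module_ids = sorted({modules[n] for n in nodes})
    # per-node links into each module
    k_to: dict = {n: {} for n in nodes}
    for a, b in net.edges():
        k_to[a][modules[b]] = k_to[a].get(modules[b], 0) + 1
        k_to[b][modules[a]] = k_to[b].get(modules[a], 0) + 1
    within = {n: k_to[n].get(modules[n], 0) for n in nodes}
    zi = {}
    for m in module_ids:
        members = [n for n in nodes if modules[n] == m]
        vals = np.array([within[n] for n in members], dtype=float)
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        mean = vals.mean()
        for n in members:
            zi[n] = 0.0 if sd == 0 else (within[n] - mean) / sd
    pi = {}
    for n in nodes:
        k = net.degree(n)
        if k == 0:
            logger.warning("zi_pi: node %r has degree 0; Pi set to 0", n)
            pi[n] = 0.0
        else:
            pi[n] = 1.0 - sum((kt / k) ** 2 for kt in k_to[n].values())
    roles = {}
    for n in nodes:
        z, p = zi[n], pi[n]
        if z >= 2.5 and p >= 0.62:
            roles[n] = "network hub"
        elif z > 2.5 and p <= 0.62:
            roles[n] = "module hub"
        elif z <= 2.5 and p > 0.62:
            roles[n] = "connector"
        else:
            roles[n] = "peripheral"
    return pd.DataFrame(
        {
            "Zi": pd.Series(zi),
            "Pi": pd.Series(pi),
            "module": pd.Series({n: modules[n] for n in nodes}),
            "role": pd.Series(roles),
        }
    ).loc[nodes]


def keystones(role_table: pd.DataFrame) -> set[str]:
    """Keystone taxa: connectors, module hubs and network hubs."""
    return set(role_table.index[role_table["role"] != "peripheral"])


# ---------------------------------------------------------------------------
# SPEC-OCCU specialists
# ---------------------------------------------------------------------------

def spec_occu(
    abund: RelAbundTable,
    habitats: pd.Series | None = None,
    top_n: int = 500,
    spec_min: float = 0.7,
    occu_min: float = 0.7,
) -> pd.DataFrame:
    """Per-(zOTU, habitat) specificity, occupancy and specialist flags.

    Habitats default to the treatment labels of the sample metadata.
    Specificity of zOTU i in habitat h is its mean relative abundance in
    h divided by the sum of its mean relative abundances across all
    habitats (rows sum to 1 for any zOTU observed anywhere); occupancy
    is the fraction of h's samples containing i.  A specialist has
    specificity > 0.7 and occupancy > 0.7 (strict) and ranks among the
    habitat's ``top_n`` most abundant zOTUs by mean relative abundance.
    """
    if habitats is None:
        habitats = abund.sample_meta["treatment"]
    habitats = habitats.loc[abund.samples]
    levels = sorted(habitats.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 habitats for a SPEC-OCCU analysis")
    mean_ra = {}
    occu = {}
    for h in levels:
        cols = habitats.index[habitats == h]
        if len(cols) == 0:
            raise ValueError(f"habitat {h!r} has no samples")
        mean_ra[h] = abund.values[cols].mean(axis=1)
        occu[h] = (abund.values[cols] > 0).sum(axis=1) / len(cols)
    mean_df = pd.DataFrame(mean_ra)
    occu_df = pd.DataFrame(occu)
    denom = mean_df.sum(axis=1)
    spec_df = mean_df.div(denom.replace(0, np.nan), axis=0)
    rows = []
    for h in levels:
        rank = mean_df[h].rank(ascending=False, method="min")
        for taxon in abund.taxa:
            s = spec_df.loc[taxon, h]
            o = occu_df.loc[taxon, h]
            r = rank.loc[taxon]
            rows.append(
                {
                    "zotu_id": taxon,
                    "habitat": h,
                    "specificity": s,
                    "occupancy": o,
                    "abundance_rank": int(r),
                    "specialist": bool(
                        (s > spec_min) and (o > occu_min) and (r <= top_n)
                    )
                    if not np.isnan(s)
                    else False,
                }
            )
    return pd.DataFrame(rows).set_index(["zotu_id", "habitat"])


def specialists(table: pd.DataFrame) -> set[str]:
    """zOTUs flagged as specialist in at least one habitat."""
    flagged = table.index[table["specialist"]]
    return {z for z, _ in flagged}


# ---------------------------------------------------------------------------
# Shared taxa (Venn intersection)
# ---------------------------------------------------------------------------

def shared_taxa(
    table: CountTable,
    treatments: list[str] | None = None,
    min_rel_abund: float = 1e-4,
) -> tuple[set[str], dict[frozenset, int]]:
    """zOTUs detected in every treatment group, plus Venn-region counts.

    A zOTU counts as detected in a group when it survives the
    network-level abundance filter for that group and has a total count
    > 0 there.  Venn regions are keyed by the exact set of treatments a
    zOTU is detected in; region counts sum to the size of the union.
    """
    meta = table.sample_meta
    trts = treatments or sorted(meta["treatment"].unique())
    if len(trts) < 2:
        raise ValueError("need >= 2 treatment groups")
    detected: dict[str, set[str]] = {}
    for trt in trts:
        sub = table.subset_samples(meta.index[meta["treatment"] == trt])
        try:
            filt = filter_by_mean_rel_abund(sub, min_rel_abund)
        except ValueError:
            detected[trt] = set()
            continue
        totals = filt.counts.sum(axis=1)
        detected[trt] = set(totals.index[totals > 0])
    union = set().union(*detected.values())
    regions: dict[frozenset, int] = {}
    for z in union:
        key = frozenset(t for t in trts if z in detected[t])
        regions[key] = regions.get(key, 0) + 1
    shared = set.intersection(*(detected[t] for t in trts))
    return shared, regions


# ---------------------------------------------------------------------------
# Core screen and abundance-stability correlation
# ---------------------------------------------------------------------------

@dataclass
class CoreTaxaResult:
    shared: set[str]
    specialists: set[str]
    keystones: set[str]
    core: set[str]
    abundance: pd.DataFrame | None = None  # per core taxon x (treatment, stage)

    def write(self, path: str | Path) -> None:
        rows = []
        for z in sorted(self.shared | self.specialists | self.keystones):
            rows.append(
                {
                    "zotu_id": z,
                    "shared": z in self.shared,
                    "specialist": z in self.specialists,
                    "keystone": z in self.keystones,
                    "core": z in self.core,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def core_taxa(
    shared: set[str],
    specialist_set: set[str],
    keystone_set: set[str],
    abund: RelAbundTable | None = None,
) -> CoreTaxaResult:
    """Three-way intersection of shared, specialist and keystone zOTUs.

    If an abundance table is given, each core taxon's mean relative
    abundance per treatment x stage is attached.  An empty intersection
    is a valid result (logged as a warning).
    """
    core = shared & specialist_set & keystone_set
    if not core:
        logger.warning("core_taxa: empty intersection (no core taxa found)")
    abundance = None
    if abund is not None and core:
        meta = abund.sample_meta
        cells = []
        for (trt, stage), cols in meta.groupby(
            ["treatment", "stage"], sort=True
        ).groups.items():
            mean = abund.values.loc[sorted(core), list(cols)].mean(axis=1)
            for z, v in mean.items():
                cells.append({"zotu_id": z, "treatment": trt, "stage": stage,
                              "mean_rel_abund": v})
        abundance = pd.DataFrame(cells).set_index(["zotu_id", "treatment", "stage"])
    return CoreTaxaResult(
        shared=set(shared),
        specialists=set(specialist_set),
        keystones=set(keystone_set),
        core=core,
        abundance=abundance,
    )


def abundance_stability_correlation(
    core_abund: pd.DataFrame, stability: pd.Series
) -> pd.DataFrame:
    """Pearson r and two-sided p of each core taxon's abundance against a
    per-sample stability statistic (e.g. |negative cohesion|).

    ``core_abund`` is taxa x samples; pairs are aligned by sample id.
    Taxa (or statistics) with zero variance are reported as NaN.
    """
    common = [s for s in core_abund.columns if s in stability.index]
    if len(common) < 4:
        raise ValueError(
            f"need >= 4 paired observations, got {len(common)}"
        )
    y = stability.loc[common].to_numpy(dtype=float)
    rows = []
    for taxon in core_abund.index:
        x = core_abund.loc[taxon, common].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning(
                "abundance_stability_correlation: zero variance for %r", taxon
            )
            rows.append({"zotu_id": taxon, "r": np.nan, "p": np.nan,
                         "n": len(common)})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"zotu_id": taxon, "r": float(r), "p": float(p),
                     "n": len(common)})
    return pd.DataFrame(rows).set_index("zotu_id")
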