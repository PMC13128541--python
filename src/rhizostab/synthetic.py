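"""Synthetic multi-kingdom zOTU community generator with planted structure.

Every downstream stage of the pipeline (network inference, stability
indices, core-taxa screens) is validated against data whose ground truth
is known by construction.  The generator emulates the study design of a
glasshouse drought experiment: three kingdoms (prokaryotes, fungi,
protists), three watering treatments (CK/MD/SD), three growth stages,
five replicates, compositional sequencing counts at realistic depth.

Latent model (Gaussian copula over log-normal abundances)
---------------------------------------------------------
Each taxon i has a latent standard-normal score

    z_i = sum_b L[i, b] * f_b  +  sqrt(psi_i) * eps_i,

where the f_b are block factors with correlation matrix Phi and
psi_i = 1 - (L Phi L^T)_ii.  Members of a positive block load
sqrt(rho) on the block's factor, giving every within-block pair latent
Pearson correlation rho; anti-correlated pairs carry loadings of
opposite sign.  "Attachment" taxa (planted hubs / connectors) load
evenly on several factors.  Log abundance is

    log a_is = mu_i + log(fold_i) * 1[treatment enriched] + sd_t * z_is,

and counts are drawn multinomially per sample at a log-normally drawn
library depth, so the data are compositional and rarefaction is
exercised.  Because counts are a monotone (per-sample) transform of the
latent scores, the latent Spearman correlation of a pair follows the
Gaussian-copula identity rho_s = (6/pi) * asin(r/2); pairs whose latent
rho_s exceeds the network threshold are recorded as planted edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import CountTable

logger = logging.getLogger("rhizostab")

KINGDOMS = ("prokaryote", "fungus", "protist")

#: Gaussian-copula conversion from latent Pearson r to population Spearman rho.
def copula_spearman(r: np.ndarray | float) -> np.ndarray | float:
    return (6.0 / np.pi) * np.arcsin(np.asarray(r) / 2.0)


# ---------------------------------------------------------------------------
# Design specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """A planted correlated block of taxa.

    ``rho`` is the target pairwise latent correlation between members.
    ``sign`` "negative" plants an anti-correlated pair (exactly two
    members); arbitrary all-negative blocks of size > 2 cannot form a
    positive-semi-definite correlation matrix.  ``treatments`` limits the
    block to some treatments (None = active everywhere).
    """

    name: str
    members: tuple[str, ...]
    rho: float
    sign: str = "positive"
    treatments: tuple[str, ...] | None = None


@dataclass(frozen=True)
class AttachmentSpec:
    """A taxon correlated evenly with several block factors (planted hub)."""

    taxon: str
    blocks: tuple[str, ...]
    corr: float
    treatments: tuple[str, ...] | None = None


@dataclass(frozen=True)
class CoreSpec:
    """A taxon enriched ``fold``-times in one treatment (planted specialist)."""

    taxon: str
    treatment: str
    fold: float
    prevalence: float = 1.0


@dataclass
class SyntheticDesign:
    """Full description of one synthetic community experiment."""

    n_taxa_per_kingdom: Mapping[str, int] = field(
        default_factory=lambda: {"prokaryote": 60, "fungus": 30, "protist": 30}
    )
    treatments: tuple[str, ...] = ("CK", "MD", "SD")
    n_stages: int = 3
    n_replicates: int = 5
    compartments: tuple[str, ...] = ("root",)
    depth_mean: int = 50_000
    depth_sigma: float = 0.2
    blocks: tuple[BlockSpec, ...] = ()
    factor_corr: Mapping[tuple[str, str], float] = field(default_factory=dict)
    attachments: tuple[AttachmentSpec, ...] = ()
    cores: tuple[CoreSpec, ...] = ()
    noise_sd: float | Mapping[str, float] = 1.0
    base_log_mean: float = 0.0
    base_log_sd: float = 1.5
    #: planted taxa (block members, attachments, cores) draw their base
    #: log-abundance from N(planted_log_abund, planted_log_sd): high enough
    #: that count noise cannot swamp the planted correlations, low enough
    #: that the correlated guild stays a small share of the community
    #: (a dominant co-fluctuating guild would distort every taxon's
    #: relative abundance through compositional closure).  Unplanted taxa
    #: keep the wide community abundance distribution, including a rare
    #: tail.
    planted_log_abund: float = -1.0
    planted_log_sd: float = 0.3
    #: conditionally rare taxa (CRT): a large pool of taxa far below the
    #: rare-taxon filter that occasionally bloom to moderate abundance.
    #: Replicate instability (``noise_sd``) scales both the log-scale
    #: dispersion of the persistent community and the per-cell bloom
    #: probability ``bloom_rate * noise_sd``; sporadic CRT blooms are the
    #: dominant contribution to the average variation degree, so less
    #: stable (noisier) communities score a higher AVD, as the index is
    #: meant to behave.  CRT never pass the network abundance filter and
    #: therefore leave co-occurrence inference untouched.
    n_rare_per_kingdom: Mapping[str, int] = field(
        default_factory=lambda: {"prokaryote": 150, "fungus": 75, "protist": 75}
    )
    rare_log_mean: float = -12.0
    rare_log_sd: float = 1.0
    bloom_rate: float = 0.1
    bloom_log_abund: float = -2.7
    bloom_log_sd: float = 0.7
    #: explicit per-taxon base log-abundance overrides (applied last);
    #: used e.g. to plant abundant anti-correlated competitor pairs whose
    #: negative correlations carry real cohesion weight
    log_abund_overrides: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    # -- derived ----------------------------------------------------------

    def stages(self) -> tuple[str, ...]:
        names = ("tillering", "jointing", "ripening")
        if self.n_stages <= 3:
            return names[: self.n_stages]
        return names + tuple(f"stage{i}" for i in range(4, self.n_stages + 1))

    def noise_sd_for(self, treatment: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd[treatment])
        return float(self.noise_sd)

    def all_taxa(self) -> list[str]:
        prefix = {"prokaryote": "pro", "fungus": "fun", "protist": "prot"}
        taxa: list[str] = []
        for k in self.n_taxa_per_kingdom:
            if k not in KINGDOMS:
                raise ValueError(f"unknown kingdom {k!r}")
            taxa.extend(
                f"{prefix[k]}_zOTU{i + 1}"
                for i in range(self.n_taxa_per_kingdom[k])
            )
        return taxa

    def rare_taxa(self) -> list[str]:
        prefix = {"prokaryote": "pro", "fungus": "fun", "protist": "prot"}
        taxa: list[str] = []
        for k in self.n_rare_per_kingdom:
            if k not in KINGDOMS:
                raise ValueError(f"unknown kingdom {k!r}")
            taxa.extend(
                f"{prefix[k]}_rare{i + 1}"
                for i in range(self.n_rare_per_kingdom[k])
            )
        return taxa

    def validate(self) -> None:
        if self.n_replicates < 3:
            raise ValueError(
                "n_replicates must be >= 3 (Spearman p-values are degenerate "
                "below that)"
            )
        if self.depth_mean <= 0:
            raise ValueError(f"depth_mean must be positive, got {self.depth_mean}")
        taxa = set(self.all_taxa())
        seen: set[str] = set()
        for b in self.blocks:
            if not -1.0 <= b.rho <= 1.0:
                raise ValueError(f"block {b.name!r}: rho {b.rho} outside [-1, 1]")
            if b.sign not in ("positive", "negative"):
                raise ValueError(f"block {b.name!r}: unknown sign {b.sign!r}")
            if b.sign == "negative" and len(b.members) != 2:
                raise ValueError(
                    f"block {b.name!r}: negative blocks must be pairs "
                    "(larger all-negative blocks are not positive semi-definite)"
                )
            overlap = seen & set(b.members)
            if overlap:
                raise ValueError(
                    f"block {b.name!r}: members {sorted(overlap)} already "
                    "belong to another block"
                )
            missing = set(b.members) - taxa
            if missing:
                raise ValueError(f"block {b.name!r}: unknown taxa {sorted(missing)}")
            seen |= set(b.members)
        block_names = {b.name for b in self.blocks}
        for a in self.attachments:
            if a.taxon in seen:
                raise ValueError(f"attachment {a.taxon!r} is also a block member")
            unknown = set(a.blocks) - block_names
            if unknown:
                raise ValueError(
                    f"attachment {a.taxon!r}: unknown blocks {sorted(unknown)}"
                )
        for c in self.cores:
            if c.treatment not in self.treatments:
                raise ValueError(
                    f"core {c.taxon!r}: unknown treatment {c.treatment!r}"
                )
            if c.fold <= 0:
                raise ValueError(f"core {c.taxon!r}: fold must be > 0")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic community.

    ``planted_edges`` maps each treatment to the set of signed taxon
    pairs whose latent Spearman correlation exceeds the network
    threshold; ``planted_core`` is the subset of hubs that are also
    planted habitat specialists (the three-way core-taxa screen's
    ground truth).
    """

    planted_edges: dict[str, set[tuple[str, str, str]]]
    planted_hubs: set[str]
    planted_specialists: dict[str, str]
    planted_core: set[str]
    #: wider reference set: pairs with a genuinely planted (non-null) latent
    #: correlation (|latent Spearman| > 0.5).  Pairs in this set but not in
    #: ``planted_edges`` sit near the detection threshold and are found
    #: with probability ~1/2 by construction; edge-recovery precision is
    #: judged against this set, recall against the strict one.
    planted_correlated: dict[str, set[tuple[str, str]]] = field(
        default_factory=dict
    )

    def edges_for(self, treatment: str) -> set[tuple[str, str, str]]:
        return self.planted_edges[treatment]

    def all_edges(self) -> set[tuple[str, str, str]]:
        out: set[tuple[str, str, str]] = set()
        for s in self.planted_edges.values():
            out |= s
        return out


def edge_recovery(
    net, truth: "GroundTruth", treatment: str
) -> tuple[float, float]:
    """(precision, recall) of a network's edges against the ground truth.

    Recall counts how many strictly supra-threshold planted edges were
    found; precision counts how many found edges carry any planted
    latent correlation (the wider set, which includes near-threshold
    pairs whose detection is a coin flip by construction).
    """
    found = {tuple(sorted(e)) for e in net.edges()}
    strict = {(a, b) for a, b, _ in truth.planted_edges[treatment]}
    wide = truth.planted_correlated.get(treatment, strict)
    recall = len(found & strict) / len(strict) if strict else float("nan")
    precision = (
        len(found & wide) / len(found) if found else float("nan")
    )
    return precision, recall


# ---------------------------------------------------------------------------
# Latent correlation machinery
# ---------------------------------------------------------------------------

def _active(spec_treatments: tuple[str, ...] | None, treatment: str) -> bool:
    return spec_treatments is None or treatment in spec_treatments


def _latent_structure(
    design: SyntheticDesign, treatment: str, taxa: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Loading matrix L, factor correlation Phi and residual variances psi."""
    blocks = [b for b in design.blocks if _active(b.treatments, treatment)]
    attach = [a for a in design.attachments if _active(a.treatments, treatment)]
    idx = {t: i for i, t in enumerate(taxa)}
    names = [b.name for b in blocks]
    fpos = {n: j for j, n in enumerate(names)}
    n, m = len(taxa), len(blocks)
    L = np.zeros((n, m))
    phi = np.eye(m)
    for (a_name, b_name), r in design.factor_corr.items():
        if a_name in fpos and b_name in fpos:
            phi[fpos[a_name], fpos[b_name]] = r
            phi[fpos[b_name], fpos[a_name]] = r
    for b in blocks:
        j = fpos[b.name]
        load = np.sqrt(abs(b.rho))
        if b.sign == "positive":
            for t in b.members:
                L[idx[t], j] = load
        else:
            L[idx[b.members[0]], j] = load
            L[idx[b.members[1]], j] = -load
    for a in attach:
        cols = [fpos[b] for b in a.blocks if b in fpos]
        if not cols:
            continue
        # even loading alpha solving corr(taxon, f_b) = alpha * sum_j Phi[j, b]
        row_sums = phi[np.ix_(cols, cols)].sum(axis=0)
        alpha = a.corr / row_sums
        L[idx[a.taxon], cols] = alpha
    communality = np.einsum("ib,bc,ic->i", L, phi, L)
    psi = 1.0 - communality
    bad = psi < -1e-9
    if bad.any():
        offenders = [taxa[i] for i in np.where(bad)[0]]
        raise ValueError(
            f"latent correlation for treatment {treatment!r} is not positive "
            f"semi-definite (communality > 1) for taxa {offenders}; reduce "
            "block/attachment correlations or factor_corr"
        )
    return L, phi, np.clip(psi, 0.0, None)


def latent_correlation(
    design: SyntheticDesign, treatment: str
) -> pd.DataFrame:
    """Exact latent Pearson correlation matrix for one treatment."""
    taxa = design.all_taxa()
    L, phi, psi = _latent_structure(design, treatment, taxa)
    sigma = L @ phi @ L.T
    np.fill_diagonal(sigma, 1.0)
    return pd.DataFrame(sigma, index=taxa, columns=taxa)


def ground_truth(
    design: SyntheticDesign,
    rho_threshold: float = 0.8,
    margin: float = 0.05,
    wide_threshold: float = 0.5,
) -> GroundTruth:
    """Planted edges / hubs / specialists / cores implied by the design.

    The strict planted-edge set contains pairs whose population Spearman
    correlation clearly exceeds the detection threshold (by ``margin``);
    pairs inside the decision band (``wide_threshold`` .. threshold +
    margin) carry genuine planted correlation but are detected with
    non-trivial miss probability at the study's sample size, so they
    enter only the wide ``planted_correlated`` set.  This is the usual
    indeterminate-band treatment when scoring a thresholded detector.
    """
    taxa = design.all_taxa()
    edges: dict[str, set[tuple[str, str, str]]] = {}
    correlated: dict[str, set[tuple[str, str]]] = {}
    for trt in design.treatments:
        sigma = latent_correlation(design, trt).to_numpy()
        rho_s = copula_spearman(sigma)
        np.fill_diagonal(rho_s, 0.0)
        hit = np.argwhere(
            np.triu(np.abs(rho_s) > rho_threshold + margin, k=1)
        )
        edges[trt] = {
            tuple(sorted((taxa[i], taxa[j])))
            + (("positive" if rho_s[i, j] > 0 else "negative"),)
            for i, j in hit
        }
        wide = np.argwhere(np.triu(np.abs(rho_s) > wide_threshold, k=1))
        correlated[trt] = {
            tuple(sorted((taxa[i], taxa[j]))) for i, j in wide
        }
    hubs = {
        a.taxon
        for a in design.attachments
        if len(a.blocks) >= 2
    }
    n_trt = len(design.treatments)
    specialists = {
        c.taxon: c.treatment
        for c in design.cores
        if c.fold / (c.fold + (n_trt - 1)) > 0.7 and c.prevalence > 0.7
    }
    core = hubs & set(specialists)
    return GroundTruth(edges, hubs, specialists, core, correlated)


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------

def generate_counts(design: SyntheticDesign) -> tuple[CountTable, GroundTruth]:
    """Draw a count table (and its ground truth) from a synthetic design.

    Fully reproducible from ``design.seed``; separate RNG streams are
    used for base abundances, latent scores, library depths and count
    draws so partial reruns stay reproducible.
    """
    design.validate()
    taxa = design.all_taxa()
    rare = design.rare_taxa()
    n = len(taxa)
    n_rare = len(rare)
    ss = np.random.SeedSequence(design.seed)
    rng_base, rng_latent, rng_depth, rng_counts, rng_bloom = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    mu = rng_base.normal(design.base_log_mean, design.base_log_sd, size=n)
    mu_rare = rng_base.normal(design.rare_log_mean, design.rare_log_sd, n_rare)
    idx = {t: i for i, t in enumerate(taxa)}
    planted: list[str] = []
    for b in design.blocks:
        planted.extend(b.members)
    planted.extend(a.taxon for a in design.attachments)
    planted.extend(c.taxon for c in design.cores)
    for t in dict.fromkeys(planted):  # stable order, no duplicates
        mu[idx[t]] = rng_base.normal(
            design.planted_log_abund, design.planted_log_sd
        )
    # enriched taxa share the planted baseline: it is low enough that
    # even a 30-fold enrichment leaves them at a few percent of the
    # community (heavy compositional distortion would corrupt every
    # other taxon's ranks), yet high enough that count noise does not
    # drown their correlations in the unenriched treatments
    for c in design.cores:
        mu[idx[c.taxon]] = design.planted_log_abund
    for taxon, value in design.log_abund_overrides.items():
        mu[idx[taxon]] = float(value)

    enrich = {trt: np.zeros(n) for trt in design.treatments}
    for c in design.cores:
        enrich[c.treatment][idx[c.taxon]] += np.log(c.fold)

    stages = design.stages()
    columns: list[str] = []
    meta_rows: list[tuple[str, str, str, int]] = []
    count_cols: list[np.ndarray] = []
    for comp in design.compartments:
        for trt in design.treatments:
            L, phi, psi = _latent_structure(design, trt, taxa)
            n_samples = design.n_stages * design.n_replicates
            try:
                chol = np.linalg.cholesky(phi + 1e-12 * np.eye(phi.shape[0]))
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"factor correlation matrix for treatment {trt!r} is not "
                    f"positive semi-definite: {dict(design.factor_corr)}"
                ) from exc
            f = chol @ rng_latent.standard_normal((phi.shape[0], n_samples))
            eps = rng_latent.standard_normal((n, n_samples))
            z = L @ f + np.sqrt(psi)[:, None] * eps
            sd_t = design.noise_sd_for(trt)
            log_a = mu[:, None] + enrich[trt][:, None] + sd_t * z
            # conditionally rare taxa: independent latent noise plus
            # sporadic blooms whose rate scales with replicate instability
            log_rare = mu_rare[:, None] + sd_t * rng_bloom.standard_normal(
                (n_rare, n_samples)
            )
            if n_rare:
                p_bloom = min(1.0, design.bloom_rate * sd_t)
                mask = rng_bloom.random((n_rare, n_samples)) < p_bloom
                log_rare[mask] = (
                    design.bloom_log_abund
                    + design.bloom_log_sd
                    * rng_bloom.standard_normal(int(mask.sum()))
                )
            log_all = np.vstack([log_a, log_rare])
            p = np.exp(log_all - log_all.max(axis=0))
            p /= p.sum(axis=0)
            s = 0
            for stage in stages:
                for rep in range(1, design.n_replicates + 1):
                    depth = max(
                        1,
                        int(
                            round(
                                design.depth_mean
                                * np.exp(
                                    rng_depth.normal(0.0, design.depth_sigma)
                                )
                            )
                        ),
                    )
                    count_cols.append(rng_counts.multinomial(depth, p[:, s]))
                    columns.append(f"{comp}_{trt}_{stage}_r{rep}")
                    meta_rows.append((comp, trt, stage, rep))
                    s += 1

    all_ids = taxa + rare
    counts = pd.DataFrame(
        np.column_stack(count_cols).astype(np.int64),
        index=all_ids,
        columns=columns,
    )
    sample_meta = pd.DataFrame(
        meta_rows, index=columns,
        columns=["compartment", "treatment", "stage", "replicate"],
    )
    kcol = [
        {"pro": "prokaryote", "fun": "fungus", "prot": "protist"}[
            t.split("_")[0]
        ]
        for t in all_ids
    ]
    taxon_meta = pd.DataFrame(
        {
            "kingdom": kcol,
            "taxonomy": [f"k__{k}; g__synthetic" for k in kcol],
        },
        index=all_ids,
    )
    table = CountTable(counts, sample_meta, taxon_meta)
    return table, ground_truth(design)


# ---------------------------------------------------------------------------
# Random phylogeny
# ---------------------------------------------------------------------------

def generate_tree(taxa: Sequence[str], seed: int = 0) -> str:
    """Random rooted bifurcating tree over ``taxa`` as a newick string.

    Built by repeatedly joining two uniformly chosen subtrees with
    positive exponential branch lengths; n tips, n-1 internal nodes.
    """
    if len(taxa) < 2:
        raise ValueError(f"need at least 2 taxa for a tree, got {len(taxa)}")
    rng = np.random.default_rng(seed)
    nodes = [str(t) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        bl, br = rng.exponential(0.5, size=2) + 0.05
        nodes.append(f"({left}:{bl:.6f},{right}:{br:.6f})")
    return nodes[0] + ";"


# ---------------------------------------------------------------------------
# Reference designs
# ---------------------------------------------------------------------------

def default_design(seed: int = 0, **overrides) -> SyntheticDesign:
    """The standard study-condition design with planted core taxa.

    A "core cluster" of four mutually correlated prokaryote sub-blocks
    (factor correlation 0.7) hosts two core taxa and one hub-only
    distractor as connector attachments; independent positive blocks in
    every kingdom and two anti-correlated pairs complete the planted
    structure.  Core taxa are 30-fold enriched under severe drought,
    abundant enough to occur in every sample, and attached to all four
    sub-block factors, so they are simultaneously shared, specialists
    and network keystones.  Two specialist-only distractors are enriched
    but unconnected.
    """
    n_sub, sub_size = 8, 6
    n_cluster = 2 * n_sub * sub_size  # one 4-block cluster per core taxon
    pro = [f"pro_zOTU{i + 1}" for i in range(n_cluster + 14)]
    fun = [f"fun_zOTU{i + 1}" for i in range(30)]
    prot = [f"prot_zOTU{i + 1}" for i in range(30)]
    clusters = [
        [
            tuple(
                pro[
                    c * n_sub * sub_size + sub_size * k :
                    c * n_sub * sub_size + sub_size * (k + 1)
                ]
            )
            for k in range(n_sub)
        ]
        for c in range(2)
    ]
    cores = (pro[n_cluster], pro[n_cluster + 1])
    spec_only = (pro[n_cluster + 2], pro[n_cluster + 3])
    blockA = tuple(pro[n_cluster + 4 : n_cluster + 9])
    neg1 = (pro[n_cluster + 9], pro[n_cluster + 10])
    neg2 = (pro[n_cluster + 11], pro[n_cluster + 12])
    blockF = tuple(fun[0:5])
    blockP = tuple(prot[0:5])

    blocks = []
    factor_corr: dict[tuple[str, str], float] = {}
    attachments = []
    for c, core in enumerate(cores):
        names = [f"hub{c}_block{k}" for k in range(n_sub)]
        blocks += [
            BlockSpec(names[k], clusters[c][k], 0.95) for k in range(n_sub)
        ]
        # Factor correlation 0.72 keeps cross-block pairs below the
        # detection threshold, so the eight blocks stay separate
        # modules, while leaving room for a strong even attachment.
        factor_corr.update(
            {
                (names[a], names[b]): 0.72
                for a in range(n_sub)
                for b in range(a + 1, n_sub)
            }
        )
        # Connector keystone: an even, moderately strong correlation to
        # all four block factors.  Each 15-sample network realises a
        # handful of supra-threshold edges into several modules -- the
        # Zi-Pi signature of a connector.  Detection is stochastic per
        # network, so the core screen unions keystone calls over all
        # compartment x treatment networks (as the study's screen spans
        # all its networks); each core owns its own cluster so the two
        # cores' outcomes are independent.
        attachments.append(AttachmentSpec(core, tuple(names), 0.865))
    blocks += [
        BlockSpec("proA", blockA, 0.95),
        BlockSpec("neg1", neg1, 0.9, sign="negative"),
        BlockSpec("neg2", neg2, 0.9, sign="negative"),
        BlockSpec("funA", blockF, 0.95),
        BlockSpec("protA", blockP, 0.95),
    ]
    blocks = tuple(blocks)
    attachments = tuple(attachments)
    core_spec = tuple(
        [CoreSpec(t, "SD", 30.0) for t in cores]
        + [CoreSpec(spec_only[0], "MD", 30.0), CoreSpec(spec_only[1], "SD", 30.0)]
    )
    kwargs = dict(
        n_taxa_per_kingdom={
            "prokaryote": n_cluster + 14, "fungus": 30, "protist": 30
        },
        compartments=("bulk", "rhizosphere", "root"),
        blocks=blocks,
        factor_corr=factor_corr,
        attachments=attachments,
        cores=core_spec,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticDesign(**kwargs)


def null_design(seed: int = 0) -> SyntheticDesign:
    """A structure-free community for false-positive control.

    No planted blocks, cores or conditionally-rare taxa; abundances are
    even (no hyperdominant taxon) and replicate dynamics calm, so that
    relative abundances carry no compositional closure structure: a
    hyperdominant taxon (> ~30% of reads) induces genuine negative
    correlations with, and positive correlations among, the taxa it
    suppresses, which a correlation network rightly detects.  One
    treatment, one compartment, 15 samples.
    """
    return SyntheticDesign(
        n_taxa_per_kingdom={"prokaryote": 100, "fungus": 25, "protist": 25},
        n_rare_per_kingdom={},
        base_log_sd=0.6,
        noise_sd=0.6,
        compartments=("root",),
        treatments=("CK",),
        seed=seed,
    )


_SCENARIO_LEVELS = {
    # per intensity level: (block_size, rho, bridges_per_junction,
    #                       closing_bridges, n_neg_pairs, noise_sd,
    #                       neg_log_abund)
    # closing_bridges span the b0-b2 junction, turning the chain of
    # blocks into a redundant ring at higher connectivity levels (ring
    # redundancy is what pushes vulnerability down)
    0: (5, 0.93, 1, 0, 1, 1.3, None),
    1: (6, 0.93, 2, 1, 4, 1.0, 0.3),
    2: (8, 0.96, 4, 4, 8, 0.7, 0.9),
}


def scenario_design(kind: str, seed: int = 0) -> SyntheticDesign:
    """Directional scenarios mirroring the study's niche contrast.

    ``kind="root"``: planted connectivity (block size, correlation
    strength, bridge redundancy, negative-pair count) increases and
    replicate noise decreases across CK -> MD -> SD, so every stability
    index should improve with drought.  ``kind="rhizosphere"``: the same
    levels assigned in reverse, so stability should degrade.  Each
    treatment has its own disjoint planted taxa; three blocks per
    treatment are chained by bridge taxa so that redundancy (parallel
    bridges) controls vulnerability.
    """
    if kind not in ("root", "rhizosphere"):
        raise ValueError(f"unknown scenario kind {kind!r}")
    treatments = ("CK", "MD", "SD")
    order = (0, 1, 2) if kind == "root" else (2, 1, 0)

    counters = {"prokaryote": 0, "fungus": 0, "protist": 0}

    def take(kingdom: str, n: int) -> tuple[str, ...]:
        p = {"prokaryote": "pro", "fungus": "fun", "protist": "prot"}[kingdom]
        start = counters[kingdom]
        counters[kingdom] += n
        return tuple(f"{p}_zOTU{i + 1}" for i in range(start, start + n))

    blocks: list[BlockSpec] = []
    attachments: list[AttachmentSpec] = []
    factor_corr: dict[tuple[str, str], float] = {}
    noise_sd: dict[str, float] = {}
    overrides: dict[str, float] = {}
    block_kingdoms = ("prokaryote", "fungus", "protist")
    for trt, level in zip(treatments, order):
        size, rho, n_bridge, n_close, n_neg, sd, neg_mu = _SCENARIO_LEVELS[level]
        noise_sd[trt] = sd
        names = []
        for k in range(3):
            kingdom = block_kingdoms[k]
            name = f"{trt}_b{k}"
            blocks.append(
                BlockSpec(name, take(kingdom, size), rho, treatments=(trt,))
            )
            names.append(name)
        for a, b2 in ((0, 1), (1, 2), (0, 2)):
            factor_corr[(names[a], names[b2])] = 0.6
        for a, b2 in ((0, 1), (1, 2)):
            for _ in range(n_bridge):
                (taxon,) = take("prokaryote", 1)
                attachments.append(
                    AttachmentSpec(
                        taxon, (names[a], names[b2]), 0.86, treatments=(trt,)
                    )
                )
        for _ in range(n_close):
            (taxon,) = take("prokaryote", 1)
            attachments.append(
                AttachmentSpec(
                    taxon, (names[0], names[2]), 0.86, treatments=(trt,)
                )
            )
        # abundant anti-correlated competitor pairs: their negative
        # correlations carry real abundance weight in cohesion, and the
        # pair sums are stable so they add no compositional distortion
        for b in range(n_neg):
            pair = take("prokaryote", 2)
            blocks.append(
                BlockSpec(
                    f"{trt}_neg{b}", pair, 0.95, sign="negative", treatments=(trt,)
                )
            )
            if neg_mu is not None:
                for t in pair:
                    overrides[t] = neg_mu
    # round up per-kingdom totals with noise taxa
    n_per = {
        "prokaryote": counters["prokaryote"] + 20,
        "fungus": counters["fungus"] + 10,
        "protist": counters["protist"] + 10,
    }
    return SyntheticDesign(
        n_taxa_per_kingdom=n_per,
        blocks=tuple(blocks),
        factor_corr=factor_corr,
        attachments=tuple(attachments),
        noise_sd=noise_sd,
        log_abund_overrides=overrides,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ground-truth manifest I/O
# ---------------------------------------------------------------------------

def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Plain-text key-value manifest of the planted structure."""
    lines = []
    for trt in sorted(gt.planted_edges):
        for a, b, sign in sorted(gt.planted_edges[trt]):
            lines.append(f"edge\t{trt}\t{a}\t{b}\t{sign}")
    for t in sorted(gt.planted_hubs):
        lines.append(f"hub\t{t}")
    for t, trt in sorted(gt.planted_specialists.items()):
        lines.append(f"specialist\t{t}\t{trt}")
    for t in sorted(gt.planted_core):
        lines.append(f"core\t{t}")
    Path(path).write_text("\n".join(lines) + "\n")
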