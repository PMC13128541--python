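"""End-to-end pipeline orchestration with a plain-text configuration.

Sequences the full analysis: read (or simulate) a multi-kingdom zOTU
table, rarefy per kingdom, filter rare taxa, build one signed
co-occurrence network per compartment x treatment, compute topology and
the stability battery, run the Zi-Pi / SPEC-OCCU / shared-taxa core
screen, optionally compute per-sample NTI, and write tab-separated
reports plus a run manifest.  Every random stage is seeded from the
config's global seed, so re-running with the same config and inputs
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coretaxa import (
    abundance_stability_correlation,
    core_taxa,
    keystones,
    spec_occu,
    specialists,
    shared_taxa,
    zi_pi,
)
from .network import (
    build_treatment_networks,
    edge_kingdom_summary,
    edge_sign_summary,
    write_edge_list,
    write_graphml,
)
from .phylo import nti_per_sample, patristic_distances, read_distance_matrix
from .stability import avd_by_treatment, stability_report
from .synthetic import default_design, generate_counts, generate_tree, scenario_design, write_ground_truth
from .tables import (
    CountTable,
    rarefy,
    read_count_table,
    relative_abundance,
    write_count_table,
)
from .topology import detect_modules, topology_report

logger = logging.getLogger("rhizostab")

#: the study's per-kingdom rarefaction depths (reads per sample)
RAREFACTION_DEPTHS = {"prokaryote": 26_533, "fungus": 7_992, "protist": 6_869}


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips through a key=value file."""

    input_matrix: str | None = None
    input_sample_meta: str | None = None
    input_taxon_meta: str | None = None
    input_tree: str | None = None
    input_distances: str | None = None
    synthetic: str | None = None  # "default", "root" or "rhizosphere"
    outdir: str = "rhizostab_out"
    # "auto" rarefies each kingdom to its shallowest sample
    depths: dict[str, float | str] = field(
        default_factory=lambda: {k: "auto" for k in RAREFACTION_DEPTHS}
    )
    min_rel_abund: float = 1e-4
    rho_threshold: float = 0.8
    alpha: float = 0.05
    n_rep: int = 100
    rm_random: int = 100
    with_relative_modularity: bool = False
    closeness_min: float = 0.25
    degree_min: float = 40.0
    spec_min: float = 0.7
    occu_min: float = 0.7
    top_n: int = 500
    n_null: int = 999
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.rho_threshold <= 1:
            raise ValueError(
                f"rho_threshold must be in (0, 1], got {self.rho_threshold}"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 <= self.min_rel_abund < 1:
            raise ValueError(
                f"min_rel_abund must be in [0, 1), got {self.min_rel_abund}"
            )
        for name in ("spec_min", "occu_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_rep", "rm_random", "top_n", "n_null"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.synthetic not in (None, "default", "root", "rhizosphere"):
            raise ValueError(f"unknown synthetic design {self.synthetic!r}")
        if self.synthetic is None and self.input_matrix is None:
            raise ValueError("either an input matrix or a synthetic design "
                             "must be given")

    # -- config file round-trip ------------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "depths":
                for k, d in v.items():
                    lines.append(f"depth_{k} = {d}")
            else:
                lines.append(f"{f.name} = {v if v is not None else ''}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        depths: dict[str, float | str] = {}
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key.startswith("depth_"):
                depths[key[len("depth_"):]] = (
                    value if value == "auto" else float(value)
                )
                continue
            if key not in field_types:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = _parse_value(value)
        if depths:
            kwargs["depths"] = depths
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def sha256(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _parse_value(value: str):
    if value == "" or value == "None":
        return None
    if value in ("True", "true"):
        return True
    if value in ("False", "false"):
        return False
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        pass
    return value


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def load_inputs(config: PipelineConfig):
    """Count table (and optional ground truth / tree) per the config."""
    truth = None
    tree = None
    if config.synthetic is not None:
        design = (
            default_design(seed=config.seed)
            if config.synthetic == "default"
            else scenario_design(config.synthetic, seed=config.seed)
        )
        table, truth = generate_counts(design)
        tree = generate_tree(
            [t for t in table.taxa if t.startswith("pro_")],
            seed=config.seed + 1,
        )
    else:
        table = read_count_table(
            config.input_matrix,
            config.input_sample_meta,
            config.input_taxon_meta,
        )
        if config.input_tree:
            tree = Path(config.input_tree).read_text()
    return table, truth, tree


def rarefy_per_kingdom(
    table: CountTable, depths: dict[str, float | str], seed: int
) -> tuple[CountTable, dict[str, list[str]]]:
    """Rarefy each kingdom's sub-table to its own depth, keeping only
    samples retained by every kingdom present."""
    kingdoms = sorted(table.taxon_meta["kingdom"].unique())
    parts = []
    dropped: dict[str, list[str]] = {}
    for k in kingdoms:
        taxa = table.taxon_meta.index[table.taxon_meta["kingdom"] == k]
        taxa = [t for t in table.taxa if t in set(taxa)]
        sub = CountTable(
            table.counts.loc[taxa], table.sample_meta, table.taxon_meta.loc[taxa]
        )
        depth = depths.get(k, "auto")
        if depth == "auto":
            depth = int(sub.counts.sum(axis=0).min())
            depth = max(depth, 1)
            logger.info("rarefy_per_kingdom: %s auto depth = %d", k, depth)
        result = rarefy(sub, int(depth), seed=seed)
        parts.append(result.table)
        dropped[k] = result.dropped
    kept = set(parts[0].samples)
    for p in parts[1:]:
        kept &= set(p.samples)
    order = [s for s in table.samples if s in kept]
    if not order:
        raise ValueError("no sample survived rarefaction in every kingdom")
    counts = pd.concat([p.counts[order] for p in parts], axis=0)
    return (
        CountTable(counts, table.sample_meta.loc[order], table.taxon_meta.loc[counts.index]),
        dropped,
    )


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Returns a dict of in-memory results keyed by stage.  Any stage
    failure raises with the stage name attached.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": config}
    stage = "load"
    try:
        table, truth, tree = load_inputs(config)
        results["raw_table"] = table
        if truth is not None:
            write_ground_truth(truth, outdir / "ground_truth.tsv")
            results["ground_truth"] = truth
        write_count_table(
            table,
            outdir / "counts_raw.tsv",
            outdir / "sample_metadata.tsv",
            outdir / "taxon_metadata.tsv",
        )

        stage = "preprocess"
        rarefied, dropped = rarefy_per_kingdom(table, config.depths, config.seed)
        results["table"] = rarefied
        results["dropped_samples"] = dropped
        write_count_table(rarefied, outdir / "counts_rarefied.tsv")
        abund_all = relative_abundance(rarefied)

        stage = "network"
        networks = build_treatment_networks(
            rarefied,
            rho_threshold=config.rho_threshold,
            alpha=config.alpha,
            min_rel_abund=config.min_rel_abund,
        )
        results["networks"] = networks
        net_summaries = []
        for (comp, trt), net in networks.items():
            write_edge_list(net, outdir / f"edges_{comp}_{trt}.tsv")
            write_graphml(net, outdir / f"network_{comp}_{trt}.graphml")
            pos, neg = edge_sign_summary(net)
            row = {
                "compartment": comp, "treatment": trt,
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "n_positive": pos, "n_negative": neg,
            }
            if net.number_of_nodes():
                ks = edge_kingdom_summary(net)
                for k, v in ks["intra"].items():
                    row[f"intra_{k}"] = v
                for (k1, k2), v in ks["inter"].items():
                    row[f"inter_{k1}_{k2}"] = v
            net_summaries.append(row)
        pd.DataFrame(net_summaries).to_csv(
            outdir / "network_summary.tsv", sep="\t", index=False
        )

        stage = "topology"
        topo: dict = {}
        for key, net in networks.items():
            if net.number_of_edges() == 0:
                logger.warning("topology: %s has no edges; skipped", key)
                continue
            rep = topology_report(
                net,
                seed=config.seed,
                n_random=config.rm_random,
                closeness_min=config.closeness_min,
                degree_min=config.degree_min,
                with_relative_modularity=config.with_relative_modularity,
            )
            comp, trt = key
            rep.write(
                outdir / f"topology_nodes_{comp}_{trt}.tsv",
                outdir / f"topology_summary_{comp}_{trt}.tsv",
            )
            topo[key] = rep
        results["topology"] = topo

        stage = "stability"
        stab: dict = {}
        for key, net in networks.items():
            comp, trt = key
            if net.number_of_edges() == 0:
                logger.warning("stability: %s has no edges; skipped", key)
                continue
            sub = rarefied.select(compartment=comp, treatment=trt)
            abund = relative_abundance(sub)
            rep = stability_report(
                net, abund, n_rep=config.n_rep, seed=config.seed
            )
            rep.write(
                outdir / f"stability_{comp}_{trt}.tsv",
                outdir / f"robustness_{comp}_{trt}.tsv",
                outdir / f"cohesion_{comp}_{trt}.tsv",
            )
            stab[key] = rep
        results["stability"] = stab
        avd_rows = []
        for comp in sorted(rarefied.sample_meta["compartment"].unique()):
            series = avd_by_treatment(abund_all, compartment=comp)
            for trt, v in series.items():
                avd_rows.append(
                    {"compartment": comp, "treatment": trt, "avd": v}
                )
        pd.DataFrame(avd_rows).to_csv(
            outdir / "avd.tsv", sep="\t", index=False
        )
        results["avd"] = avd_rows

        stage = "coretaxa"
        core_results: dict = {}
        for comp in sorted(rarefied.sample_meta["compartment"].unique()):
            comp_table = rarefied.select(compartment=comp)
            comp_abund = relative_abundance(comp_table)
            keystone_set: set[str] = set()
            role_frames = []
            for (c, trt), net in networks.items():
                if c != comp or net.number_of_edges() == 0:
                    continue
                modules, _ = detect_modules(net, seed=config.seed)
                roles = zi_pi(net, modules)
                roles["compartment"] = c
                roles["treatment"] = trt
                role_frames.append(roles)
                keystone_set |= keystones(roles)
            if role_frames:
                pd.concat(role_frames).to_csv(
                    outdir / f"node_roles_{comp}.tsv", sep="\t",
                    index_label="node",
                )
            so = spec_occu(
                comp_abund,
                top_n=config.top_n,
                spec_min=config.spec_min,
                occu_min=config.occu_min,
            )
            so.to_csv(outdir / f"spec_occu_{comp}.tsv", sep="\t")
            spec_set = specialists(so)
            shared, regions = shared_taxa(
                comp_table, min_rel_abund=config.min_rel_abund
            )
            pd.DataFrame(
                [
                    {"treatments": "&".join(sorted(k)), "n_zotus": v}
                    for k, v in sorted(
                        regions.items(), key=lambda kv: "&".join(sorted(kv[0]))
                    )
                ]
            ).to_csv(outdir / f"venn_{comp}.tsv", sep="\t", index=False)
            result = core_taxa(shared, spec_set, keystone_set, comp_abund)
            result.write(outdir / f"core_taxa_{comp}.tsv")
            # relate core abundance to |negative cohesion| across samples
            if result.core:
                neg = []
                for (c, trt), rep in stab.items():
                    if c == comp and rep.cohesion is not None:
                        neg.append(rep.cohesion.samples["negative"].abs())
                if neg:
                    neg_series = pd.concat(neg)
                    corr = abundance_stability_correlation(
                        comp_abund.values.loc[sorted(result.core)], neg_series
                    )
                    corr.to_csv(
                        outdir / f"core_cohesion_corr_{comp}.tsv", sep="\t"
                    )
                    result.abundance_cohesion_corr = corr
            core_results[comp] = result
        results["core"] = core_results

        stage = "nti"
        dist = None
        if config.input_distances:
            dist = read_distance_matrix(config.input_distances)
        elif tree is not None:
            dist = patristic_distances(tree)
        if dist is None:
            logger.warning("nti: no tree or distance matrix given; stage skipped")
        else:
            on_tree = [t for t in rarefied.taxa if t in set(dist.index)]
            series = nti_per_sample(
                rarefied.counts.loc[on_tree], dist,
                n_null=config.n_null, seed=config.seed,
            )
            series.to_frame().to_csv(
                outdir / "nti.tsv", sep="\t", index_label="sample_id"
            )
            results["nti"] = series

        stage = "manifest"
        manifest = {
            "software": f"rhizostab {__version__}",
            "config_sha256": config.sha256(),
            "seed": config.seed,
            "design_flags": {
                "spearman_p": "t-approximation",
                "fdr": "benjamini-hochberg per network",
                "connectedness": "mean of significant correlations per taxon",
                "cohesion_null_correction": "off",
                "closeness": "component-scaled (Wasserman-Faust)",
                "modularity": "louvain, seeded, sorted node order",
                "rarefaction": "without replacement, shallow samples dropped",
                "abundance_filter": "mean relative abundance, strict >",
                "isolated_nodes": "excluded from networks",
            },
        }
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results
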