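"""Count-table containers, I/O, rarefaction, filtering and alpha diversity.

The universal input of the pipeline is a zOTU count table: a non-negative
integer matrix (taxa x samples) with per-sample metadata (compartment,
treatment, growth stage, replicate) and per-taxon metadata (kingdom,
taxonomy string).  All readers/writers use plain tab-separated text and
round-trip bit-exactly for integer tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger("rhizostab")

SAMPLE_META_COLUMNS = ("compartment", "treatment", "stage", "replicate")
TAXON_META_COLUMNS = ("kingdom", "taxonomy")


@dataclass
class CountTable:
    """Integer zOTU x sample count matrix plus sample and taxon metadata.

    ``counts`` is indexed by zOTU id (rows) and sample id (columns);
    ``sample_meta`` is indexed by sample id and carries at least
    compartment / treatment / stage / replicate; ``taxon_meta`` is indexed
    by zOTU id and carries at least kingdom and taxonomy.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxon_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate zOTU ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count matrix contains non-numeric cells")
        bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"count matrix cell ({counts.index[i]!r}, {counts.columns[j]!r}) "
                f"= {values[i, j]!r} is not a non-negative integer"
            )
        missing_samples = counts.columns.difference(self.sample_meta.index)
        if len(missing_samples):
            raise ValueError(
                f"sample metadata missing ids: {sorted(missing_samples)}"
            )
        missing_taxa = counts.index.difference(self.taxon_meta.index)
        if len(missing_taxa):
            raise ValueError(f"taxon metadata missing ids: {sorted(missing_taxa)}")

    # -- convenience -------------------------------------------------------

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = [s for s in self.samples if s in set(sample_ids)]
        return CountTable(
            self.counts[ids], self.sample_meta.loc[ids], self.taxon_meta
        )

    def select(
        self,
        compartment: str | None = None,
        treatment: str | None = None,
        stage: str | None = None,
    ) -> "CountTable":
        """Restrict to one analysis dataset (e.g. one compartment x treatment)."""
        meta = self.sample_meta
        mask = pd.Series(True, index=meta.index)
        for col, val in (
            ("compartment", compartment),
            ("treatment", treatment),
            ("stage", stage),
        ):
            if val is not None:
                mask &= meta[col] == val
        return self.subset_samples(meta.index[mask])


@dataclass
class RelAbundTable:
    """Real matrix of per-sample relative abundances; columns sum to 1 or 0."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    taxon_meta: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.values.sum(axis=0).to_numpy()
        ok = (np.abs(sums - 1.0) < 1e-9) | (np.abs(sums) < 1e-9)
        if not ok.all():
            bad = self.values.columns[~ok].tolist()
            raise ValueError(f"columns do not sum to 0 or 1: {bad}")

    @property
    def taxa(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


class RarefactionResult(NamedTuple):
    table: CountTable
    dropped: list[str]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_table(
    matrix_path: str | Path,
    sample_meta_path: str | Path,
    taxon_meta_path: str | Path,
) -> CountTable:
    """Read a tab-separated taxa x samples matrix plus the two metadata TSVs.

    The matrix has a header row of sample ids and a first column of zOTU
    ids.  Row and column order are preserved.  Non-integer or negative
    cells and unmatched ids are rejected with the offending coordinates.
    """
    counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sample_meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0)
    taxon_meta = pd.read_csv(taxon_meta_path, sep="\t", index_col=0)
    table = CountTable(counts.astype("int64", errors="ignore"), sample_meta, taxon_meta)
    return table


def write_count_table(
    table: CountTable,
    matrix_path: str | Path,
    sample_meta_path: str | Path | None = None,
    taxon_meta_path: str | Path | None = None,
) -> None:
    table.counts.to_csv(matrix_path, sep="\t", index_label="zotu_id")
    if sample_meta_path is not None:
        table.sample_meta.to_csv(sample_meta_path, sep="\t", index_label="sample_id")
    if taxon_meta_path is not None:
        table.taxon_meta.to_csv(taxon_meta_path, sep="\t", index_label="zotu_id")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: CountTable, depth: int, seed: int = 0) -> RarefactionResult:
    """Subsample every sample to ``depth`` reads without replacement.

    Subsampling is multivariate hypergeometric (the without-replacement
    scheme of vegan's ``rrarefy``), so rarefying a sample to its exact
    total leaves its counts unchanged.  Samples shallower than ``depth``
    are dropped and listed in the result.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    keep = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if not keep:
        raise ValueError(
            f"all {len(dropped)} samples have fewer than {depth} reads"
        )
    if dropped:
        logger.warning(
            "rarefy: dropped %d sample(s) below depth %d: %s",
            len(dropped), depth, dropped,
        )
    out = np.empty((table.counts.shape[0], len(keep)), dtype=np.int64)
    for j, sample in enumerate(keep):
        col = table.counts[sample].to_numpy(dtype=np.int64)
        out[:, j] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    counts = pd.DataFrame(out, index=table.taxa, columns=keep)
    return RarefactionResult(
        CountTable(counts, table.sample_meta.loc[keep], table.taxon_meta), dropped
    )


# ---------------------------------------------------------------------------
# Relative abundance / filtering / diversity
# ---------------------------------------------------------------------------

def relative_abundance(table: CountTable) -> RelAbundTable:
    """Column-normalise counts to relative abundances; empty samples stay zero."""
    totals = table.counts.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        logger.warning("relative_abundance: all-zero sample(s): %s", empty)
    safe = totals.replace(0, 1)
    values = table.counts.div(safe, axis=1).astype(float)
    return RelAbundTable(values, table.sample_meta, table.taxon_meta)


def filter_by_mean_rel_abund(
    table: CountTable, threshold: float = 1e-4
) -> CountTable:
    """Retain zOTUs whose mean relative abundance exceeds ``threshold``.

    The mean is taken across the table's samples (one analysis dataset);
    the default 1e-4 corresponds to the 0.01% rare-taxon screen applied
    before network construction.  Strictly-greater comparison.
    """
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    rel = relative_abundance(table)
    mean_ra = rel.values.mean(axis=1)
    keep = mean_ra.index[mean_ra > threshold]
    if len(keep) == 0:
        raise ValueError(
            f"no zOTU exceeds mean relative abundance {threshold}; "
            "review the filter threshold"
        )
    logger.info(
        "filter_by_mean_rel_abund: retained %d of %d zOTUs at threshold %g "
        "(mean relative abundance across %d samples)",
        len(keep), len(table.taxa), threshold, len(table.samples),
    )
    return CountTable(
        table.counts.loc[keep], table.sample_meta, table.taxon_meta.loc[keep]
    )


def shannon(table: CountTable) -> pd.Series:
    """Shannon diversity H = -sum p_i ln p_i per sample (natural log).

    Empty samples are undefined and reported as NaN.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    out = np.full(counts.shape[1], np.nan)
    for j in range(counts.shape[1]):
        if totals[j] == 0:
            logger.warning(
                "shannon: sample %r is empty; diversity undefined",
                table.samples[j],
            )
            continue
        p = counts[:, j][counts[:, j] > 0] / totals[j]
        out[j] = float(-(p * np.log(p)).sum())
    return pd.Series(out, index=table.samples, name="shannon")
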