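"""Community phylogenetic structure: mean nearest taxon distance and the
nearest taxon index (NTI).

NTI is the negated standardised effect size of MNTD against a
label-shuffling null (the ``taxa.labels`` model: taxon names are
permuted on the distance matrix, equivalently random same-size subsets
of the pool are drawn).  NTI > 2 is conventionally read as significant
phylogenetic clustering.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("rhizostab")


def patristic_distances(tree: str | Path | TreeNode) -> pd.DataFrame:
    """Tip-to-tip (patristic) distance matrix from a newick tree.

    Accepts a newick string, a path to a newick file, or a parsed tree.
    """
    if isinstance(tree, TreeNode):
        t = tree
    else:
        text = str(tree)
        if "(" not in text:  # a path, not a newick string
            text = Path(tree).read_text()
        # keep underscores verbatim (newick convention would turn them
        # into spaces, breaking zOTU id matching)
        t = TreeNode.read(io.StringIO(text), convert_underscores=False)
    dm = t.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    """Square patristic distance matrix from a TSV (taxa in first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix rows and columns disagree")
    arr = df.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix is not symmetric")
    return df


def mntd(community: set[str] | list[str], dist: pd.DataFrame) -> float:
    """Mean nearest taxon distance of a presence set.

    Mean over present taxa of the minimum distance to any other present
    taxon; undefined (error) for fewer than two present taxa.
    """
    present = [t for t in dist.index if t in set(community)]
    if len(present) < 2:
        raise ValueError(
            f"MNTD needs >= 2 present taxa, got {len(present)}"
        )
    sub = dist.loc[present, present].to_numpy(dtype=float).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def nti(
    community: set[str] | list[str],
    dist: pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
) -> float:
    """Nearest taxon index against the taxa-labels null.

    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null) with the null
    built from ``n_null`` random same-size draws from the matrix's taxon
    pool (equivalent to shuffling taxon labels).  When the null sd is 0
    (e.g. the community is the whole pool) NTI is 0, with a log flag.
    """
    pool = list(dist.index)
    present = [t for t in pool if t in set(community)]
    unknown = set(community) - set(pool)
    if unknown:
        raise ValueError(
            f"community taxa absent from the distance matrix: {sorted(unknown)[:5]}"
        )
    obs = mntd(present, dist)
    k = len(present)
    rng = np.random.default_rng(seed)
    arr = dist.to_numpy(dtype=float)
    n = arr.shape[0]
    null = np.empty(n_null)
    for r in range(n_null):
        idx = rng.choice(n, size=k, replace=False)
        sub = arr[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        null[r] = sub.min(axis=1).mean()
    sd = null.std(ddof=1)
    # guard against a numerically degenerate null (e.g. community = whole
    # pool, where every shuffle yields the same MNTD up to float noise)
    if sd <= 1e-9 * max(1.0, abs(null.mean())):
        logger.warning(
            "nti: null distribution is degenerate (sd = 0); NTI set to 0"
        )
        return 0.0
    return float(-(obs - null.mean()) / sd)


def nti_per_sample(
    counts: pd.DataFrame, dist: pd.DataFrame, n_null: int = 999, seed: int = 0
) -> pd.Series:
    """NTI of each sample's presence set (count > 0), skipping samples
    with fewer than two present taxa."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(counts.shape[1])
    out = {}
    for j, sample in enumerate(counts.columns):
        present = counts.index[counts[sample] > 0]
        present = [t for t in present if t in dist.index]
        if len(present) < 2:
            logger.warning("nti_per_sample: sample %r has < 2 taxa on the "
                           "tree; skipped", sample)
            out[sample] = np.nan
            continue
        out[sample] = nti(present, dist, n_null=n_null,
                          seed=int(seeds[j] % (2**31 - 1)))
    return pd.Series(out, name="nti")
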