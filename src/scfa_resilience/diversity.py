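"""Per-sample resilience metrics: richness, Hill numbers, Gini-Simpson,
and Faith's phylogenetic diversity.

Hill numbers express diversity as an "effective number of taxa" at order q:
q = 0 counts taxa (richness), q = 1 is exp of the Shannon entropy (effective
number of common taxa), q = 2 is the inverse Simpson concentration (effective
number of dominant taxa).  The Gini-Simpson index 1 − Σp² is the probability
that two random reads originate from different taxa.  Faith's PD sums the
branch lengths of the tree subtending the observed taxa, here typically a
16S rRNA proxy phylogeny supplied as newick.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Optional, Set, Union

import numpy as np
import pandas as pd
import skbio

from .groups import GeneGroupMatrix

logger = logging.getLogger(__name__)

PhyloTree = skbio.TreeNode

HILL_ORDERS = (0, 1, 2)


def load_tree(source: Union[str, Path]) -> PhyloTree:
    """Load a rooted newick tree with branch lengths.

    ``source`` may be a file path or a newick string.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        tree = skbio.TreeNode.read(str(source), convert_underscores=False)
    else:
        tree = skbio.TreeNode.read(_io.StringIO(source), convert_underscores=False)
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("tree leaf labels are not unique")
    for node in tree.traverse():
        if node.length is not None and (
            not np.isfinite(node.length) or node.length < 0
        ):
            raise ValueError(f"invalid branch length on node {node.name!r}")
    return tree


def normalize_taxon_name(name: str) -> str:
    """Fold case and whitespace/underscore differences for leaf matching."""
    return name.strip().casefold().replace(" ", "_")


def _proportions(values: np.ndarray) -> Optional[np.ndarray]:
    values = np.asarray(values, dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        return None
    return positive / positive.sum()


def richness(values: Iterable[float]) -> int:
    """Number of taxa with abundance strictly greater than zero."""
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    return int(np.count_nonzero(values > 0))


def hill_number(values: Iterable[float], q: int) -> float:
    """Hill number of order q ∈ {0, 1, 2}; NaN for an all-zero vector.

    q=0: richness; q=1: exp(−Σ p ln p); q=2: 1/Σ p².  Sums run over
    positive-abundance taxa only; the result is invariant to rescaling.
    """
    if q not in HILL_ORDERS:
        raise ValueError(f"unsupported Hill order {q!r}; use one of {HILL_ORDERS}")
    values = np.asarray(
        list(values) if not isinstance(values, np.ndarray) else values, dtype=float
    )
    p = _proportions(values)
    if p is None:
        return float("nan")
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(1.0 / np.sum(p * p))


def gini_simpson(values: Iterable[float]) -> float:
    """Gini-Simpson index 1 − Σ p²; NaN for an all-zero vector."""
    values = np.asarray(
        list(values) if not isinstance(values, np.ndarray) else values, dtype=float
    )
    p = _proportions(values)
    if p is None:
        return float("nan")
    return float(1.0 - np.sum(p * p))


def faith_pd(
    present_taxa: Iterable[str],
    tree: PhyloTree,
    convention: str = "rooted",
) -> float:
    """Faith's phylogenetic diversity of a set of present taxa.

    ``rooted`` (default) sums the branch lengths of the minimal subtree
    connecting the present leaves *to the root* — a single present leaf has
    PD equal to its root-path length.  ``crown`` restricts to the subtree
    spanned below the most recent common ancestor of the present leaves.
    An empty taxon set returns 0.
    """
    if convention not in ("rooted", "crown"):
        raise ValueError(f"unknown PD convention {convention!r}")
    wanted = {normalize_taxon_name(t) for t in present_taxa}
    if not wanted:
        return 0.0
    tips = [t for t in tree.tips() if normalize_taxon_name(t.name) in wanted]
    found = {normalize_taxon_name(t.name) for t in tips}
    missing = wanted - found
    if missing:
        raise KeyError(
            f"taxa absent from the tree: {sorted(missing)}"
        )
    if not tips:
        return 0.0
    stop = tree if convention == "rooted" else tree.lca(tips)
    total = 0.0
    seen = set()
    for tip in tips:
        node = tip
        while node is not stop and node is not None:
            nid = id(node)
            if nid in seen:
                break
            seen.add(nid)
            total += node.length or 0.0
            node = node.parent
    return total


def diversity_profile(
    matrix: GeneGroupMatrix,
    tree: Optional[PhyloTree] = None,
    pd_convention: str = "rooted",
) -> pd.DataFrame:
    """All metrics for every sample of a gene-group matrix at one level.

    The unclassified-at-level bucket never counts as a taxon.  Samples with
    zero classified abundance are flagged missing (metrics NaN) rather than
    assigned zero diversity.  Taxa absent from the tree are excluded from PD
    only, with a logged count.
    """
    classified = matrix.classified()
    taxa = np.array(classified.index)
    values = classified.to_numpy()

    tree_leaves: Optional[Set[str]] = None
    if tree is not None:
        tree_leaves = {normalize_taxon_name(t.name) for t in tree.tips()}
        absent = [t for t in taxa if normalize_taxon_name(t) not in tree_leaves]
        if absent:
            logger.info(
                "group %s level %s: %d taxa absent from tree, excluded from PD",
                matrix.group_name,
                matrix.level,
                len(absent),
            )

    records = []
    for j, sample in enumerate(classified.columns):
        col = values[:, j]
        total = col.sum()
        missing = not (col > 0).any()
        rec = {
            "sample_id": sample,
            "group_name": matrix.group_name,
            "level": matrix.level,
            "missing": missing,
        }
        if missing:
            rec.update(
                richness=0,
                hill_q0=np.nan,
                hill_q1=np.nan,
                hill_q2=np.nan,
                gini_simpson=np.nan,
                pd=np.nan,
            )
        else:
            rec.update(
                richness=richness(col),
                hill_q0=hill_number(col, 0),
                hill_q1=hill_number(col, 1),
                hill_q2=hill_number(col, 2),
                gini_simpson=gini_simpson(col),
            )
            if tree is None:
                rec["pd"] = np.nan
            else:
                present = [
                    t
                    for t, v in zip(taxa, col)
                    if v > 0 and normalize_taxon_name(t) in tree_leaves
                ]
                rec["pd"] = faith_pd(present, tree, pd_convention)
        records.append(rec)
    return pd.DataFrame.from_records(records)
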