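"""Normalization, SCFA gene-group extraction, and taxonomic collapsing.

The three short-chain fatty acids are identified by the annotation names of
their terminal synthesis genes: acetate kinase (*ackA*) for acetate; butyrate
kinase (*buk*) and butyryl-CoA:acetate CoA transferase (*but*), combined, for
butyrate; and methylmalonyl-CoA decarboxylase (*mmdA*), lactoyl-CoA
dehydratase (*lcdA*) and CoA-dependent propionaldehyde dehydrogenase (*pduP*),
combined, for propionate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dialect import RANKS
from .io import FeatureKey, StratifiedGeneTable, Stratum, TableValidationError

logger = logging.getLogger(__name__)

#: Scale of the copies-per-million normalization.
CPM_TOTAL = 1_000_000.0

#: Bucket receiving abundance that carries no taxon name at the collapse level.
UNCLASSIFIED_AT_LEVEL = "UNCLASSIFIED_AT_LEVEL"

#: Pseudo-level for whole-community (taxon-agnostic) aggregation.
COMMUNITY_LEVEL = "community"


class NormalizationError(ValueError):
    pass


def _normalize_name(name: str) -> str:
    return " ".join(name.casefold().split())


@dataclass(frozen=True)
class GeneGroupDefinition:
    """A named SCFA group and the annotation names of its member genes."""

    group_name: str
    member_gene_names: Tuple[str, ...]
    regex: bool = False  # escape hatch: treat members as regex patterns

    def __post_init__(self) -> None:
        if not self.member_gene_names:
            raise ValueError(f"group {self.group_name!r} has no member genes")

    def matches(self, gene_name: str) -> bool:
        if self.regex:
            return any(
                re.search(p, gene_name, flags=re.IGNORECASE)
                for p in self.member_gene_names
            )
        target = _normalize_name(gene_name)
        return any(_normalize_name(m) == target for m in self.member_gene_names)


DEFAULT_GENE_GROUPS: Tuple[GeneGroupDefinition, ...] = (
    GeneGroupDefinition("acetate", ("acetate kinase",)),
    GeneGroupDefinition(
        "butyrate",
        ("butyrate kinase", "butyryl-CoA: acetate CoA transferase"),
    ),
    GeneGroupDefinition(
        "propionate",
        (
            "methylmalonyl-CoA decarboxylase",
            "lactoyl-CoA dehydratase",
            "CoA-dependent propionaldehyde dehydrogenase",
        ),
    ),
)

#: Short marker symbols for the default genes.
GENE_SYMBOLS: Mapping[str, str] = {
    "acetate kinase": "ackA",
    "butyrate kinase": "buk",
    "butyryl-CoA: acetate CoA transferase": "but",
    "methylmalonyl-CoA decarboxylase": "mmdA",
    "lactoyl-CoA dehydratase": "lcdA",
    "CoA-dependent propionaldehyde dehydrogenase": "pduP",
}


def normalize_to_cpm(table: StratifiedGeneTable) -> StratifiedGeneTable:
    """Rescale each sample so its grand total (including UNMAPPED, excluding
    redundant community-total rows) equals one million.

    Relative proportions within a sample are unchanged, and the operation is
    idempotent.
    """
    totals = table.grand_totals()
    zero = totals[totals <= 0]
    if len(zero):
        raise NormalizationError(
            f"sample(s) with zero total abundance: {list(zero.index)}"
        )
    factors = CPM_TOTAL / totals
    out = table.copy()
    out.data = out.data.mul(factors, axis=1)
    return out


def mapped_fraction(table: StratifiedGeneTable) -> pd.Series:
    """Per-sample fraction of abundance mapped to any gene: (total − UNMAPPED)/total."""
    unmapped = table.unmapped_values
    if unmapped is None:
        raise TableValidationError(
            "mapped_fraction is undefined without an UNMAPPED row"
        )
    totals = table.grand_totals()
    if (totals <= 0).any():
        raise NormalizationError(
            f"sample(s) with zero total: {list(totals.index[totals <= 0])}"
        )
    frac = (totals - unmapped) / totals
    frac.name = "mapped_fraction"
    return frac


def extract_gene_group(
    table: StratifiedGeneTable, definition: GeneGroupDefinition
) -> StratifiedGeneTable:
    """Retain exactly the rows whose annotation name matches a member gene.

    Matching is exact on the case-folded, whitespace-normalized annotation
    name (regex matching available via the definition).  The UNMAPPED row is
    dropped; all samples are preserved even when all-zero in the group.
    """
    keep = [
        i
        for i, k in enumerate(table.features)
        if k.stratum is not Stratum.UNMAPPED and definition.matches(k.gene_name)
    ]
    out = StratifiedGeneTable(
        table.data.iloc[keep].copy(),
        [table.features[i] for i in keep],
        table.dialect,
    )
    if not keep:
        logger.warning(
            "gene group %r matched no features", definition.group_name
        )
    return out


@dataclass
class GeneGroupMatrix:
    """Sample × taxon abundance of one SCFA group at one taxonomic level."""

    group_name: str
    level: str
    data: pd.DataFrame  # taxa × samples

    @property
    def taxa(self) -> List[str]:
        return list(self.data.index)

    @property
    def samples(self) -> List[str]:
        return list(self.data.columns)

    def classified(self) -> pd.DataFrame:
        """Taxon rows only, without the unclassified-at-level bucket."""
        return self.data.loc[self.data.index != UNCLASSIFIED_AT_LEVEL]

    def group_totals(self) -> pd.Series:
        return self.data.sum(axis=0)


def collapse_to_level(
    table: StratifiedGeneTable,
    level: str,
    group_name: str = "",
) -> GeneGroupMatrix:
    """Collapse taxon strata to a taxonomic rank (or the whole community).

    Strata naming a taxon at ``level`` contribute to that name (summed across
    member genes and deeper strata); strata lacking a name at ``level`` —
    including per-gene unclassified remainders — accrue to the
    ``UNCLASSIFIED_AT_LEVEL`` bucket.  Community-total and UNMAPPED rows are
    skipped (they duplicate mass).  Per-sample mass over stratified rows is
    conserved exactly.
    """
    if level != COMMUNITY_LEVEL and level not in RANKS:
        raise ValueError(f"unknown taxonomic rank {level!r}")
    labels: Dict[str, np.ndarray] = {}
    order: List[str] = []
    unclassified = np.zeros(table.n_samples)
    values = table.data.to_numpy()
    for i, key in enumerate(table.features):
        if key.stratum in (Stratum.UNMAPPED, Stratum.COMMUNITY_TOTAL):
            continue
        if level == COMMUNITY_LEVEL:
            label: Optional[str] = "COMMUNITY"
        elif key.stratum is Stratum.TAXON:
            label = key.rank_name(level)
        else:
            label = None
        if label is None:
            unclassified += values[i]
            continue
        if label not in labels:
            labels[label] = np.zeros(table.n_samples)
            order.append(label)
        labels[label] += values[i]
    rows = {name: labels[name] for name in order}
    if unclassified.any() or level != COMMUNITY_LEVEL:
        rows[UNCLASSIFIED_AT_LEVEL] = unclassified
    data = pd.DataFrame.from_dict(rows, orient="index", columns=table.samples)
    return GeneGroupMatrix(group_name=group_name, level=level, data=data)


def scfa_relative_abundance(groups: Sequence[GeneGroupMatrix]) -> pd.DataFrame:
    """Per-sample composition over SCFA groups (rows sum to 1).

    Samples with zero total SCFA abundance get NaN and are listed in the
    result's ``attrs["missing_samples"]``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two gene groups for a composition")
    samples = groups[0].samples
    for g in groups[1:]:
        if g.samples != samples:
            raise ValueError("gene-group matrices disagree on samples")
    totals = pd.DataFrame(
        {g.group_name: g.group_totals() for g in groups}
    )  # samples × groups
    denom = totals.sum(axis=1)
    shares = totals.div(denom, axis=0)
    missing = list(denom.index[denom <= 0])
    shares.loc[missing] = np.nan
    if missing:
        logger.warning("samples with zero SCFA abundance: %s", missing)
    shares.attrs["missing_samples"] = missing
    return shares
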