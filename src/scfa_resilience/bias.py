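"""Annotation/database bias statistics.

Reference databases under-represent taxa common in non-industrial gut
microbiomes, so the share of gene abundance that can be attributed to a taxon
falls with taxonomic depth — and falls faster in poorly represented
communities.  Two per-sample statistics quantify this: the classified
fraction at each rank, and the genus:species relative mapping index
(species-attributed abundance over genus-attributed abundance; values above
1 arise from strata annotated at species level with a missing genus).
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .dialect import RANKS
from .io import StratifiedGeneTable, Stratum

logger = logging.getLogger(__name__)

BIAS_RANKS = ("phylum", "family", "genus", "species")


def _gene_abundance_total(table: StratifiedGeneTable) -> pd.Series:
    """Per-sample total gene abundance: every gene row (taxon-stratified and
    unclassified, plus community rows of strata-less genes), UNMAPPED excluded."""
    mask = table.gene_total_mask() & ~table.stratum_mask(Stratum.UNMAPPED)
    return table.data.loc[mask].sum(axis=0)


def _rank_mapped_sum(table: StratifiedGeneTable, rank: str) -> pd.Series:
    """Per-sample abundance of strata whose lineage names a taxon at ``rank``
    (regardless of gaps at other ranks)."""
    mask = np.array(
        [
            k.stratum is Stratum.TAXON and k.rank_name(rank) is not None
            for k in table.features
        ],
        dtype=bool,
    )
    return table.data.loc[mask].sum(axis=0)


def classified_fraction(table: StratifiedGeneTable, rank: str) -> pd.Series:
    """Per-sample fraction of gene abundance classified to a taxon at ``rank``.

    The denominator is the sample's total gene abundance (UNMAPPED excluded,
    unclassified included).  Zero denominator yields NaN (flagged missing).
    The ratio is invariant to CPM normalization.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown taxonomic rank {rank!r}")
    denom = _gene_abundance_total(table)
    num = _rank_mapped_sum(table, rank)
    frac = num / denom.where(denom > 0)
    if frac.isna().any():
        logger.warning(
            "classified_fraction(%s): %d sample(s) with zero gene abundance",
            rank,
            int(frac.isna().sum()),
        )
    frac.name = f"classified_{rank}"
    return frac


def genus_species_mapping_index(table: StratifiedGeneTable) -> pd.Series:
    """Species-attributed over genus-attributed abundance, per sample.

    May exceed 1 when strata carry a species name but no genus name.  Samples
    with zero genus-attributed abundance yield NaN (flagged missing).
    """
    genus = _rank_mapped_sum(table, "genus")
    species = _rank_mapped_sum(table, "species")
    index = species / genus.where(genus > 0)
    if index.isna().any():
        logger.warning(
            "genus_species_mapping_index: %d sample(s) with zero genus-mapped "
            "abundance",
            int(index.isna().sum()),
        )
    index.name = "genus_species_index"
    return index


def bias_report(
    tables: Mapping[str, StratifiedGeneTable],
    metadata: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Classified fractions and mapping index for each scope.

    ``tables`` maps a scope label (e.g. ``all``, ``acetate``...) to its table;
    per-SCFA scopes use the group's own abundance as denominator.  Returns a
    tidy fractions table (sample, scope, rank, fraction) and an index table
    (sample, scope, index), optionally joined with lifestyle metadata.
    """
    frac_rows = []
    index_rows = []
    for scope, table in tables.items():
        for rank in BIAS_RANKS:
            frac = classified_fraction(table, rank)
            for sample, value in frac.items():
                frac_rows.append(
                    {"sample_id": sample, "scope": scope, "rank": rank,
                     "fraction": value}
                )
        idx = genus_species_mapping_index(table)
        for sample, value in idx.items():
            index_rows.append(
                {"sample_id": sample, "scope": scope, "index": value}
            )
    fractions = pd.DataFrame.from_records(frac_rows)
    indices = pd.DataFrame.from_records(index_rows)
    if metadata is not None:
        meta = metadata[["sample_id", "lifestyle_group"]]
        fractions = fractions.merge(meta, on="sample_id", how="left")
        indices = indices.merge(meta, on="sample_id", how="left")
    return fractions, indices
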