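"""Naming dialect of stratified gene-family tables.

The default values match the HUMAnN2/MetaPhlAn convention: a feature row is
``<gene_id>: <gene name>`` optionally followed by ``|`` and a taxon lineage
whose rank-prefixed segments (``g__``, ``s__``, ...) are joined by ``.``;
the literal token ``unclassified`` marks gene abundance not attributed to any
taxon, and a special ``UNMAPPED`` row carries reads matching no gene at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Tuple

#: Taxonomic ranks in increasing depth.
RANKS: Tuple[str, ...] = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_DEPTH: Mapping[str, int] = {rank: i for i, rank in enumerate(RANKS)}

_DEFAULT_PREFIXES: Mapping[str, str] = {
    "k__": "kingdom",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}


@dataclass(frozen=True)
class TableDialect:
    """Configurable spelling of the stratified-table feature identifiers."""

    strat_delimiter: str = "|"
    lineage_separator: str = "."
    gene_name_separator: str = ": "
    rank_prefixes: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_PREFIXES)
    )
    unclassified_token: str = "unclassified"
    # UNMAPPED recognized case-insensitively; the second spelling is a variant
    # seen in the wild.
    unmapped_labels: Tuple[str, ...] = ("UNMAPPED", "UNAMAPPED")

    def prefix_for(self, rank: str) -> str:
        for prefix, r in self.rank_prefixes.items():
            if r == rank:
                return prefix
        raise KeyError(f"no prefix configured for rank {rank!r}")

    def is_unmapped_label(self, label: str) -> bool:
        folded = label.strip().casefold()
        return any(folded == u.casefold() for u in self.unmapped_labels)


DEFAULT_DIALECT = TableDialect()
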