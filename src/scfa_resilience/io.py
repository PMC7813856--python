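"""Reading, writing, validating and merging stratified gene-family tables.

A stratified table holds one row per *feature* — a gene family, optionally
stratified by the contributing taxon — and one column per sample, with
non-negative RPK (reads per kilobase) abundances.  Three kinds of rows exist
besides plain taxon strata: a per-gene community total, a per-gene
``unclassified`` remainder, and a single table-wide ``UNMAPPED`` row for reads
matched to no gene.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dialect import DEFAULT_DIALECT, RANK_DEPTH, RANKS, TableDialect

logger = logging.getLogger(__name__)

UNMAPPED_ID = "UNMAPPED"


class TableError(ValueError):
    """Base class for stratified-table parse/validation failures."""


class FeatureParseError(TableError):
    pass


class TableValidationError(TableError):
    pass


class Stratum(enum.Enum):
    COMMUNITY_TOTAL = "community_total"
    TAXON = "taxon"
    UNCLASSIFIED = "unclassified"
    UNMAPPED = "unmapped"


Lineage = Tuple[Tuple[str, str], ...]


@dataclass(frozen=True)
class FeatureKey:
    """Parsed identity of one table row."""

    gene_id: str
    gene_name: str = ""
    stratum: Stratum = Stratum.COMMUNITY_TOTAL
    lineage: Lineage = ()

    def __post_init__(self) -> None:
        if self.stratum is Stratum.TAXON and not self.lineage:
            raise FeatureParseError("TAXON stratum requires a non-empty lineage")
        if self.stratum is not Stratum.TAXON and self.lineage:
            raise FeatureParseError("only TAXON strata carry a lineage")
        depths = [RANK_DEPTH[rank] for rank, _ in self.lineage]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise FeatureParseError(
                f"lineage ranks must strictly increase in depth: {self.lineage!r}"
            )

    def rank_name(self, rank: str) -> Optional[str]:
        """Taxon name at ``rank``, or None if the rank is absent."""
        for r, name in self.lineage:
            if r == rank:
                return name
        return None

    @property
    def is_unmapped(self) -> bool:
        return self.stratum is Stratum.UNMAPPED


def parse_feature_id(raw: str, dialect: TableDialect = DEFAULT_DIALECT) -> FeatureKey:
    """Parse a raw feature identifier string into a :class:`FeatureKey`.

    Missing ranks in the lineage are preserved as-is (a stratum may name a
    species without naming its genus); they are never imputed.
    """
    if not raw or not raw.strip():
        raise FeatureParseError("empty feature identifier")
    raw = raw.strip()
    if dialect.is_unmapped_label(raw):
        return FeatureKey(gene_id=UNMAPPED_ID, stratum=Stratum.UNMAPPED)

    gene_part, delim, taxon_part = raw.partition(dialect.strat_delimiter)
    gene_id, _, gene_name = gene_part.partition(dialect.gene_name_separator)
    gene_id = gene_id.strip()
    gene_name = gene_name.strip()
    if not gene_id:
        raise FeatureParseError(f"feature {raw!r} has an empty gene identifier")

    if not delim:
        return FeatureKey(gene_id, gene_name, Stratum.COMMUNITY_TOTAL)
    taxon_part = taxon_part.strip()
    if taxon_part.casefold() == dialect.unclassified_token.casefold():
        return FeatureKey(gene_id, gene_name, Stratum.UNCLASSIFIED)

    lineage = []
    for segment in taxon_part.split(dialect.lineage_separator):
        for prefix, rank in dialect.rank_prefixes.items():
            if segment.startswith(prefix):
                lineage.append((rank, segment[len(prefix):]))
                break
        else:
            raise FeatureParseError(
                f"unrecognized rank prefix in lineage segment {segment!r} "
                f"of feature {raw!r}"
            )
    return FeatureKey(gene_id, gene_name, Stratum.TAXON, tuple(lineage))


def format_feature_id(key: FeatureKey, dialect: TableDialect = DEFAULT_DIALECT) -> str:
    """Inverse of :func:`parse_feature_id` on every key it can produce."""
    if key.stratum is Stratum.UNMAPPED:
        return dialect.unmapped_labels[0]
    gene = key.gene_id
    if key.gene_name:
        gene = f"{gene}{dialect.gene_name_separator}{key.gene_name}"
    if key.stratum is Stratum.COMMUNITY_TOTAL:
        return gene
    if key.stratum is Stratum.UNCLASSIFIED:
        return f"{gene}{dialect.strat_delimiter}{dialect.unclassified_token}"
    segments = [
        f"{dialect.prefix_for(rank)}{name}" for rank, name in key.lineage
    ]
    return f"{gene}{dialect.strat_delimiter}{dialect.lineage_separator.join(segments)}"


@dataclass
class StratifiedGeneTable:
    """Features × samples abundance matrix with parsed feature keys.

    ``data`` is a dense pandas DataFrame indexed by the raw feature-identifier
    strings; ``features`` is the parallel list of parsed keys.
    """

    data: pd.DataFrame
    features: Sequence[FeatureKey]
    dialect: TableDialect = field(default_factory=lambda: DEFAULT_DIALECT)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.data.index):
            raise TableValidationError(
                "features list and data rows are not aligned"
            )
        self.features = list(self.features)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_data(
        cls, data: pd.DataFrame, dialect: TableDialect = DEFAULT_DIALECT
    ) -> "StratifiedGeneTable":
        keys = [parse_feature_id(str(ix), dialect) for ix in data.index]
        return cls(data.astype(float), keys, dialect)

    def copy(self) -> "StratifiedGeneTable":
        return StratifiedGeneTable(self.data.copy(), list(self.features), self.dialect)

    # -- basic accessors ---------------------------------------------------

    @property
    def samples(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def stratum_mask(self, *strata: Stratum) -> np.ndarray:
        wanted = set(strata)
        return np.array([k.stratum in wanted for k in self.features], dtype=bool)

    @property
    def unmapped_values(self) -> Optional[pd.Series]:
        """The UNMAPPED row as a per-sample Series, or None."""
        mask = self.stratum_mask(Stratum.UNMAPPED)
        if not mask.any():
            return None
        return self.data.iloc[np.flatnonzero(mask)[0]]

    def gene_total_mask(self) -> np.ndarray:
        """Rows that together give each sample's grand total without double
        counting: all stratified rows plus UNMAPPED, plus community-total rows
        only for genes that have no stratified rows."""
        stratified_genes = {
            k.gene_id
            for k in self.features
            if k.stratum in (Stratum.TAXON, Stratum.UNCLASSIFIED)
        }
        mask = np.zeros(self.n_features, dtype=bool)
        for i, k in enumerate(self.features):
            if k.stratum in (Stratum.TAXON, Stratum.UNCLASSIFIED, Stratum.UNMAPPED):
                mask[i] = True
            elif k.stratum is Stratum.COMMUNITY_TOTAL:
                mask[i] = k.gene_id not in stratified_genes
        return mask

    def grand_totals(self) -> pd.Series:
        """Per-sample grand total including UNMAPPED (no double counting)."""
        return self.data.loc[self.gene_total_mask()].sum(axis=0)

    # -- validation --------------------------------------------------------

    def validate(self, strict: bool = True, rtol: float = 1e-6) -> None:
        """Check structural invariants.

        ``strict`` additionally requires that every gene's community-total row
        equals the sum of its taxon + unclassified strata (relative tolerance
        ``rtol``); turn it off for foreign files with rounding drift.
        """
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise TableValidationError(
                f"non-finite abundance at feature {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise TableValidationError(
                f"negative abundance at feature {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TableValidationError(f"duplicate feature identifier {dup!r}")
        if self.stratum_mask(Stratum.UNMAPPED).sum() > 1:
            raise TableValidationError("more than one UNMAPPED feature")
        if strict:
            self._check_totals(rtol)

    def _check_totals(self, rtol: float) -> None:
        totals: dict = {}
        strata_sums: dict = {}
        for i, k in enumerate(self.features):
            if k.stratum is Stratum.COMMUNITY_TOTAL:
                totals[k.gene_id] = self.data.iloc[i].to_numpy()
            elif k.stratum in (Stratum.TAXON, Stratum.UNCLASSIFIED):
                acc = strata_sums.setdefault(
                    k.gene_id, np.zeros(self.n_samples)
                )
                acc += self.data.iloc[i].to_numpy()
        for gene_id, total in totals.items():
            if gene_id not in strata_sums:
                continue
            s = strata_sums[gene_id]
            if not np.allclose(total, s, rtol=rtol, atol=rtol):
                j = int(np.argmax(np.abs(total - s)))
                raise TableValidationError(
                    f"gene {gene_id!r}: community total "
                    f"{total[j]:g} != stratum sum {s[j]:g} in sample "
                    f"{self.data.columns[j]!r}"
                )


def read_stratified_table(
    path: Union[str, Path],
    dialect: TableDialect = DEFAULT_DIALECT,
    strict: Optional[bool] = None,
) -> StratifiedGeneTable:
    """Read a tab-separated stratified gene-family table.

    First column holds feature identifiers, remaining columns one numeric
    value per sample.  ``strict=None`` validates structure but not
    total-vs-strata consistency (appropriate for foreign files).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FeatureParseError(
            f"malformed numeric cell {raw.iat[r, c]!r} at feature "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FeatureParseError(
            f"missing value at feature {raw.index[r]!r}, sample "
            f"{raw.columns[c]!r} in {path}"
        )
    numeric.index.name = None
    numeric.columns.name = None
    table = StratifiedGeneTable.from_data(numeric.astype(float), dialect)
    table.validate(strict=bool(strict))
    return table


def write_stratified_table(
    table: StratifiedGeneTable,
    path: Union[str, Path],
    sig_digits: Optional[int] = None,
    index_label: str = "# Gene Family",
) -> None:
    """Write a table as TSV.  Default writes full precision so that
    ``read(write(T))`` reproduces T exactly; pass ``sig_digits`` for compact
    human-readable output."""
    fmt = f"%.{sig_digits}g" if sig_digits else None
    table.data.to_csv(path, sep="\t", float_format=fmt, index_label=index_label)


def merge_samples(tables: Iterable[StratifiedGeneTable]) -> StratifiedGeneTable:
    """Column-wise merge of tables over the union of their features.

    Sample identifiers must be pairwise disjoint; a feature absent from a
    table contributes 0 for that table's samples.  Per-sample totals are
    preserved exactly (merging only re-indexes, never adds).
    """
    tables = list(tables)
    if not tables:
        raise TableValidationError("nothing to merge")
    seen_samples: set = set()
    for t in tables:
        overlap = seen_samples.intersection(t.samples)
        if overlap:
            raise TableValidationError(
                f"duplicate sample identifier(s) across tables: {sorted(overlap)}"
            )
        seen_samples.update(t.samples)

    order: list = []
    keys: dict = {}
    for t in tables:
        for raw, key in zip(t.data.index, t.features):
            if raw not in keys:
                keys[raw] = key
                order.append(raw)
    frames = [t.data.reindex(order).fillna(0.0) for t in tables]
    data = pd.concat(frames, axis=1)
    return StratifiedGeneTable(data, [keys[r] for r in order], tables[0].dialect)


# -- sample metadata -------------------------------------------------------

METADATA_COLUMNS = ("sample_id", "lifestyle_group", "dataset_label")


def read_sample_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Read sample metadata (TSV with sample_id, lifestyle_group[, dataset_label])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "lifestyle_group"} - set(df.columns)
    if missing:
        raise TableValidationError(f"metadata lacks column(s): {sorted(missing)}")
    if "dataset_label" not in df.columns:
        df["dataset_label"] = ""
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TableValidationError(f"duplicate sample_id {dup!r} in metadata")
    return df[list(METADATA_COLUMNS)]


def write_sample_metadata(metadata: pd.DataFrame, path: Union[str, Path]) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def check_metadata_covers(table: StratifiedGeneTable, metadata: pd.DataFrame) -> None:
    """Every analyzed sample must have exactly one metadata row."""
    ids = set(metadata["sample_id"])
    missing = [s for s in table.samples if s not in ids]
    if missing:
        raise TableValidationError(
            f"samples without metadata: {missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
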