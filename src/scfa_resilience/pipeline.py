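"""End-to-end orchestration: normalize → extract → collapse → metrics →
bias → group statistics, with tidy TSV outputs and a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import __version__
from .bias import bias_report
from .diversity import PhyloTree, diversity_profile, load_tree
from .groups import (
    DEFAULT_GENE_GROUPS,
    GeneGroupDefinition,
    GeneGroupMatrix,
    COMMUNITY_LEVEL,
    collapse_to_level,
    extract_gene_group,
    mapped_fraction,
    normalize_to_cpm,
    scfa_relative_abundance,
)
from .io import (
    StratifiedGeneTable,
    check_metadata_covers,
    read_sample_metadata,
    read_stratified_table,
)
from .stats import ComparisonResult, compare_lifestyles, comparison_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""


@dataclass
class PipelineConfig:
    """Everything a run needs; all thresholds live here, not in stage logic."""

    table: Union[str, Path, StratifiedGeneTable]
    metadata: Union[str, Path, pd.DataFrame]
    tree: Union[str, Path, PhyloTree, None] = None
    gene_groups: Sequence[GeneGroupDefinition] = DEFAULT_GENE_GROUPS
    levels: Tuple[str, ...] = ("genus", "species")
    pd_convention: str = "rooted"
    fdr_scope: str = "per-metric"
    alpha: float = 0.05
    strict: bool = False
    out_dir: Union[str, Path, None] = None
    seed: int = 0


@dataclass
class PipelineResult:
    """In-memory output bundle of one pipeline run."""

    config: PipelineConfig
    normalized: StratifiedGeneTable
    mapped: pd.Series
    matrices: Dict[Tuple[str, str], GeneGroupMatrix]
    scfa_shares: pd.DataFrame
    diversity: pd.DataFrame           # long: one row per sample × group × level
    bias_fractions: pd.DataFrame
    bias_index: pd.DataFrame
    comparisons: List[ComparisonResult]
    manifest: dict = field(default_factory=dict)

    def comparison_frame(self) -> pd.DataFrame:
        return comparison_table(self.comparisons)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _load_inputs(config: PipelineConfig):
    table = config.table
    if not isinstance(table, StratifiedGeneTable):
        table = read_stratified_table(table, strict=config.strict)
    metadata = config.metadata
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_sample_metadata(metadata)
    tree = config.tree
    if tree is not None and not isinstance(tree, PhyloTree):
        tree = load_tree(tree)
    check_metadata_covers(table, metadata)
    return table, metadata, tree


def _diversity_metrics_long(diversity: pd.DataFrame) -> pd.DataFrame:
    value_cols = ["richness", "hill_q0", "hill_q1", "hill_q2", "gini_simpson", "pd"]
    long = diversity.melt(
        id_vars=["sample_id", "group_name", "level"],
        value_vars=value_cols,
        var_name="metric",
        value_name="value",
    )
    return long.dropna(subset=["value"])


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and (optionally) write the output bundle."""
    table, metadata, tree = _stage("load")(_load_inputs)(config)
    normalized = _stage("normalize")(normalize_to_cpm)(table)
    mapped = (
        _stage("mapped_fraction")(mapped_fraction)(normalized)
        if normalized.unmapped_values is not None
        else pd.Series(np.nan, index=normalized.samples, name="mapped_fraction")
    )

    matrices: Dict[Tuple[str, str], GeneGroupMatrix] = {}
    group_tables: Dict[str, StratifiedGeneTable] = {}
    diversity_frames: List[pd.DataFrame] = []
    community_matrices: List[GeneGroupMatrix] = []
    for definition in config.gene_groups:
        sub = _stage("extract")(extract_gene_group)(normalized, definition)
        group_tables[definition.group_name] = sub
        community = _stage("collapse")(collapse_to_level)(
            sub, COMMUNITY_LEVEL, definition.group_name
        )
        community_matrices.append(community)
        matrices[(definition.group_name, COMMUNITY_LEVEL)] = community
        for level in config.levels:
            m = _stage("collapse")(collapse_to_level)(sub, level, definition.group_name)
            matrices[(definition.group_name, level)] = m
            diversity_frames.append(
                _stage("diversity")(diversity_profile)(
                    m, tree=tree, pd_convention=config.pd_convention
                )
            )
    scfa_shares = _stage("scfa_shares")(scfa_relative_abundance)(community_matrices)
    diversity = pd.concat(diversity_frames, ignore_index=True)

    scopes = {"all": normalized, **group_tables}
    bias_fractions, bias_index = _stage("bias")(bias_report)(scopes, metadata)

    metrics_long = _diversity_metrics_long(diversity)
    extra = []
    for group in scfa_shares.columns:
        for sample, value in scfa_shares[group].dropna().items():
            extra.append(
                {
                    "sample_id": sample,
                    "group_name": group,
                    "level": COMMUNITY_LEVEL,
                    "metric": "scfa_share",
                    "value": value,
                }
            )
    for scope, sub in bias_index.groupby("scope"):
        for _, row in sub.dropna(subset=["index"]).iterrows():
            extra.append(
                {
                    "sample_id": row["sample_id"],
                    "group_name": scope,
                    "level": "genus_species",
                    "metric": "genus_species_index",
                    "value": row["index"],
                }
            )
    metrics_long = pd.concat(
        [metrics_long, pd.DataFrame.from_records(extra)], ignore_index=True
    )
    comparisons = _stage("group_stats")(compare_lifestyles)(
        metrics_long, metadata, fdr_scope=config.fdr_scope
    )

    manifest = {
        "package_version": __version__,
        "levels": list(config.levels),
        "gene_groups": [d.group_name for d in config.gene_groups],
        "pd_convention": config.pd_convention,
        "fdr_scope": config.fdr_scope,
        "alpha": config.alpha,
        "seed": config.seed,
        "n_samples": table.n_samples,
        "n_features": table.n_features,
        "per_stage_samples": {
            "input": table.n_samples,
            "scfa_shares_missing": scfa_shares.attrs.get("missing_samples", []),
            "per_test_n": {
                f"{r.group_name}/{r.level}/{r.metric}": r.per_group_n
                for r in comparisons
            },
        },
        "complete": True,
    }
    result = PipelineResult(
        config=config,
        normalized=normalized,
        mapped=mapped,
        matrices=matrices,
        scfa_shares=scfa_shares,
        diversity=diversity,
        bias_fractions=bias_fractions,
        bias_index=bias_index,
        comparisons=comparisons,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_bundle(result, config.out_dir)
    return result


def write_bundle(result: PipelineResult, out_dir: Union[str, Path]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (group, level), m in result.matrices.items():
        m.data.to_csv(out / f"matrix_{group}_{level}.tsv", sep="\t",
                      index_label="taxon")
        sidecar = {
            "group_name": group,
            "level": level,
            "normalization": "CPM-RPK",
        }
        (out / f"matrix_{group}_{level}.json").write_text(
            json.dumps(sidecar, indent=2)
        )
    result.diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
    result.scfa_shares.to_csv(out / "scfa_relative_abundance.tsv", sep="\t",
                              index_label="sample_id")
    result.mapped.to_frame().to_csv(out / "mapped_fraction.tsv", sep="\t",
                                    index_label="sample_id")
    result.bias_fractions.to_csv(out / "bias_fractions.tsv", sep="\t", index=False)
    result.bias_index.to_csv(out / "bias_index.tsv", sep="\t", index=False)
    result.comparison_frame().to_csv(out / "comparisons.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def make_figures(
    result: PipelineResult,
    metadata: Optional[pd.DataFrame] = None,
    out_dir: Union[str, Path] = ".",
) -> List[Path]:
    """Boxplot panels: Hill numbers per level × SCFA × order, SCFA shares,
    and the genus:species mapping index with its 1.0 reference line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if metadata is None:
        metadata = (
            result.config.metadata
            if isinstance(result.config.metadata, pd.DataFrame)
            else read_sample_metadata(result.config.metadata)
        )
    meta = metadata.set_index("sample_id")["lifestyle_group"]
    written: List[Path] = []

    div = result.diversity.merge(
        metadata[["sample_id", "lifestyle_group"]], on="sample_id"
    )
    levels = [l for l in result.config.levels]
    groups = sorted(div["group_name"].unique())
    orders = ["hill_q0", "hill_q1", "hill_q2"]
    for level in levels:
        sub_level = div[div["level"] == level]
        if sub_level.empty:
            logger.info("no diversity rows at level %s; panel omitted", level)
            continue
        fig, axes = plt.subplots(
            len(groups), len(orders),
            figsize=(3.2 * len(orders), 2.6 * len(groups)),
            squeeze=False,
        )
        for i, group in enumerate(groups):
            for j, order in enumerate(orders):
                ax = axes[i][j]
                sub = sub_level[sub_level["group_name"] == group].dropna(
                    subset=[order]
                )
                if sub.empty:
                    ax.set_visible(False)
                    logger.info("empty panel %s/%s/%s omitted", level, group, order)
                    continue
                data = [
                    g[order].to_numpy()
                    for _, g in sub.groupby("lifestyle_group", sort=True)
                ]
                labels = sorted(sub["lifestyle_group"].unique())
                ax.boxplot(data, tick_labels=labels)
                ax.set_title(f"{group} — {order}", fontsize=9)
                ax.tick_params(axis="x", rotation=45, labelsize=7)
        fig.suptitle(f"Hill numbers at {level} level")
        fig.tight_layout()
        p = out / f"hill_numbers_{level}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    shares = result.scfa_shares.dropna()
    if not shares.empty:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.boxplot(
            [shares[c].to_numpy() for c in shares.columns],
            tick_labels=list(shares.columns),
        )
        ax.set_ylabel("share of SCFA gene abundance")
        fig.tight_layout()
        p = out / "scfa_relative_abundance.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    idx = result.bias_index.dropna(subset=["index"])
    if not idx.empty:
        scopes = sorted(idx["scope"].unique())
        fig, axes = plt.subplots(
            1, len(scopes), figsize=(2.8 * len(scopes), 3.2), squeeze=False
        )
        for j, scope in enumerate(scopes):
            ax = axes[0][j]
            sub = idx[idx["scope"] == scope].copy()
            sub["lifestyle_group"] = sub["sample_id"].map(meta)
            data = [
                g["index"].to_numpy()
                for _, g in sub.groupby("lifestyle_group", sort=True)
            ]
            labels = sorted(sub["lifestyle_group"].unique())
            ax.boxplot(data, tick_labels=labels)
            ax.axhline(1.0, color="grey", linestyle="--", linewidth=1)
            ax.set_title(scope, fontsize=9)
            ax.tick_params(axis="x", rotation=45, labelsize=7)
        fig.suptitle("genus:species relative mapping index")
        fig.tight_layout()
        p = out / "mapping_index.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
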