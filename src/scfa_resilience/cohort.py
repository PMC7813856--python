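"""Synthetic stratified-table cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
population-specific taxon pools, per-sample taxon proportions drawn from a
symmetric Dirichlet whose concentration α controls evenness, lognormal
per-sample gene-group totals, a controlled unmapped fraction, and
rank-specific annotation dropout (masking) emulating reference-database
bias.  Simulation begins at the stratified-table level — no reads, k-mers
or mapping are simulated.

All randomness flows from one explicit seed through spawned NumPy
``SeedSequence`` children, so identical (specs, seed) always yield
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .dialect import DEFAULT_DIALECT, TableDialect
from .groups import DEFAULT_GENE_GROUPS, GENE_SYMBOLS
from .io import (
    UNMAPPED_ID,
    FeatureKey,
    StratifiedGeneTable,
    Stratum,
    format_feature_id,
    merge_samples,
)

TaxonPool = Tuple[Tuple[str, Optional[str]], ...]


@dataclass(frozen=True)
class GroupEcology:
    """Generative parameters of one SCFA gene group in one population.

    ``taxon_pool`` lists (genus, species) pairs; species may be None to
    emulate genus-only reference entries.  ``alpha`` is the symmetric
    Dirichlet concentration over the pool (large α → even community).
    ``mean_total`` is the arithmetic mean of the lognormal per-sample group
    total on the CPM-RPK scale, with log-scale dispersion ``sigma_log``.
    ``gene_split`` apportions the group total between member genes.
    """

    taxon_pool: TaxonPool
    alpha: float = 1.0
    mean_total: float = 5000.0
    sigma_log: float = 0.4
    gene_split: Optional[Mapping[str, float]] = None


@dataclass(frozen=True)
class PopulationSpec:
    """Generative parameters of one population (lifestyle group)."""

    name: str
    n_samples: int
    groups: Mapping[str, GroupEcology]
    unmapped_fraction: float = 0.25
    m_species: float = 0.0  # P(species rank erased) per stratum × sample cell
    m_genus: float = 0.0    # P(whole lineage erased) per stratum × sample cell
    dataset_label: str = ""


@dataclass
class CohortTruth:
    """Ground truth sufficient to recompute every expected metric."""

    seed: int
    populations: Dict[str, "PopulationTruth"] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        out = {"seed": self.seed, "populations": {}}
        for name, pt in self.populations.items():
            out["populations"][name] = {
                "spec": _spec_to_dict(pt.spec),
                "sample_ids": pt.sample_ids,
                "proportions": {g: v.tolist() for g, v in pt.proportions.items()},
                "totals": {g: v.tolist() for g, v in pt.totals.items()},
                "mapped_totals": pt.mapped_totals.tolist(),
                "masking_events": pt.masking_events,
            }
        return out


@dataclass
class PopulationTruth:
    spec: PopulationSpec
    sample_ids: List[str]
    proportions: Dict[str, np.ndarray]  # group -> n_samples × pool
    totals: Dict[str, np.ndarray]       # group -> n_samples
    mapped_totals: np.ndarray
    masking_events: Dict[str, Dict[str, List[bool]]]


class CohortSpecError(ValueError):
    pass


def _default_gene_split(group_name: str) -> Dict[str, float]:
    for d in DEFAULT_GENE_GROUPS:
        if d.group_name == group_name:
            w = 1.0 / len(d.member_gene_names)
            return {g: w for g in d.member_gene_names}
    return {group_name: 1.0}


def _gene_id(gene_name: str) -> str:
    return GENE_SYMBOLS.get(gene_name) or re.sub(r"\W+", "_", gene_name)[:16]


def validate_spec(spec: PopulationSpec) -> None:
    if spec.n_samples < 1:
        raise CohortSpecError(f"{spec.name}: n_samples must be >= 1")
    if not spec.groups:
        raise CohortSpecError(f"{spec.name}: no gene groups")
    if not (0.0 <= spec.unmapped_fraction < 1.0):
        raise CohortSpecError(f"{spec.name}: unmapped_fraction must be in [0, 1)")
    for rate, label in ((spec.m_species, "m_species"), (spec.m_genus, "m_genus")):
        if not (0.0 <= rate <= 1.0):
            raise CohortSpecError(f"{spec.name}: {label} must be in [0, 1]")
    for gname, eco in spec.groups.items():
        if not eco.taxon_pool:
            raise CohortSpecError(f"{spec.name}/{gname}: empty taxon pool")
        if eco.alpha <= 0:
            raise CohortSpecError(f"{spec.name}/{gname}: alpha must be > 0")
        if eco.mean_total <= 0:
            raise CohortSpecError(f"{spec.name}/{gname}: mean_total must be > 0")
        if eco.sigma_log < 0:
            raise CohortSpecError(f"{spec.name}/{gname}: sigma_log must be >= 0")
        split = eco.gene_split or _default_gene_split(gname)
        if abs(sum(split.values()) - 1.0) > 1e-9:
            raise CohortSpecError(f"{spec.name}/{gname}: gene_split must sum to 1")


def apply_classification_masking(
    table: StratifiedGeneTable,
    m_species: float,
    m_genus: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[StratifiedGeneTable, Dict[str, Dict[str, List[bool]]]]:
    """Randomly erase taxon annotations, conserving abundance exactly.

    Independently for every taxon-stratum × sample cell: with probability
    ``m_genus`` the whole lineage is erased (the cell's abundance moves to the
    gene's unclassified stratum); otherwise, with probability ``m_species``
    the species rank is erased (the cell moves to the genus-truncated
    stratum, or to unclassified when nothing else is named).  Returns the
    masked table and the realized per-row masking events.
    """
    for rate, label in ((m_species, "m_species"), (m_genus, "m_genus")):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{label} must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = table.n_samples
    acc: Dict[str, np.ndarray] = {}
    keymap: Dict[str, FeatureKey] = {}
    order: List[str] = []

    def add(key: FeatureKey, vec: np.ndarray) -> None:
        raw = format_feature_id(key, table.dialect)
        if raw not in acc:
            acc[raw] = np.zeros(n)
            keymap[raw] = key
            order.append(raw)
        acc[raw] += vec

    events: Dict[str, Dict[str, List[bool]]] = {}
    values = table.data.to_numpy()
    for i, key in enumerate(table.features):
        vec = values[i]
        if key.stratum is not Stratum.TAXON:
            add(key, vec.copy())
            continue
        genus_mask = rng.random(n) < m_genus
        has_species = key.rank_name("species") is not None
        if has_species:
            species_mask = (rng.random(n) < m_species) & ~genus_mask
        else:
            species_mask = np.zeros(n, dtype=bool)
        keep = ~genus_mask & ~species_mask
        add(key, vec * keep)
        unclassified_key = FeatureKey(
            key.gene_id, key.gene_name, Stratum.UNCLASSIFIED
        )
        if species_mask.any():
            reduced = tuple(
                (r, nm) for r, nm in key.lineage if r != "species"
            )
            if reduced:
                dest = FeatureKey(key.gene_id, key.gene_name, Stratum.TAXON, reduced)
            else:
                dest = unclassified_key
            add(dest, vec * species_mask)
        if genus_mask.any():
            add(unclassified_key, vec * genus_mask)
        events[str(table.data.index[i])] = {
            "genus_masked": genus_mask.tolist(),
            "species_masked": species_mask.tolist(),
        }
    data = pd.DataFrame(
        np.vstack([acc[r] for r in order]) if order else np.empty((0, n)),
        index=order,
        columns=table.samples,
    )
    return StratifiedGeneTable(data, [keymap[r] for r in order], table.dialect), events


def _population_table(
    spec: PopulationSpec,
    rng: np.random.Generator,
    dialect: TableDialect,
) -> Tuple[StratifiedGeneTable, PopulationTruth]:
    n = spec.n_samples
    sample_ids = [f"{spec.name}_s{i + 1:03d}" for i in range(n)]
    raws: List[str] = []
    keys: List[FeatureKey] = []
    rows: List[np.ndarray] = []
    proportions: Dict[str, np.ndarray] = {}
    totals: Dict[str, np.ndarray] = {}
    for gname, eco in spec.groups.items():
        pool = eco.taxon_pool
        p = rng.dirichlet(np.full(len(pool), eco.alpha), size=n)  # n × S
        mu = np.log(eco.mean_total) - eco.sigma_log**2 / 2.0
        tot = rng.lognormal(mean=mu, sigma=eco.sigma_log, size=n)
        proportions[gname] = p
        totals[gname] = tot
        split = eco.gene_split or _default_gene_split(gname)
        for gene_name, w in split.items():
            gid = _gene_id(gene_name)
            for t, (genus, species) in enumerate(pool):
                lineage: List[Tuple[str, str]] = []
                if genus is not None:
                    lineage.append(("genus", genus))
                if species is not None:
                    lineage.append(("species", species))
                key = FeatureKey(gid, gene_name, Stratum.TAXON, tuple(lineage))
                raws.append(format_feature_id(key, dialect))
                keys.append(key)
                rows.append(tot * w * p[:, t])
    data = pd.DataFrame(np.vstack(rows), index=raws, columns=sample_ids)
    table = StratifiedGeneTable(data, keys, dialect)
    table, events = apply_classification_masking(
        table, spec.m_species, spec.m_genus, rng=rng
    )
    mapped = table.data.sum(axis=0).to_numpy()
    u = spec.unmapped_fraction
    unmapped = u / (1.0 - u) * mapped
    unmapped_key = FeatureKey(UNMAPPED_ID, stratum=Stratum.UNMAPPED)
    data = pd.concat(
        [
            table.data,
            pd.DataFrame(
                [unmapped],
                index=[format_feature_id(unmapped_key, dialect)],
                columns=sample_ids,
            ),
        ]
    )
    table = StratifiedGeneTable(data, list(table.features) + [unmapped_key], dialect)
    truth = PopulationTruth(
        spec=spec,
        sample_ids=sample_ids,
        proportions=proportions,
        totals=totals,
        mapped_totals=mapped,
        masking_events=events,
    )
    return table, truth


def generate_cohort(
    specs: Sequence[PopulationSpec],
    seed: int,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> Tuple[StratifiedGeneTable, pd.DataFrame, CohortTruth]:
    """Generate a merged stratified table, sample metadata, and ground truth.

    The emitted table holds species-level strata (post-masking: species-,
    genus- or unclassified strata) plus one UNMAPPED row per construction
    such that the unmapped share of each sample equals the population's
    ``unmapped_fraction`` exactly.  It passes strict validation.
    """
    specs = list(specs)
    if not specs:
        raise CohortSpecError("no population specs given")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise CohortSpecError("population names must be unique")
    for spec in specs:
        validate_spec(spec)

    children = np.random.SeedSequence(seed).spawn(len(specs))
    tables = []
    truth = CohortTruth(seed=seed)
    meta_rows = []
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(child)
        table, pop_truth = _population_table(spec, rng, dialect)
        tables.append(table)
        truth.populations[spec.name] = pop_truth
        for sid in pop_truth.sample_ids:
            meta_rows.append(
                {
                    "sample_id": sid,
                    "lifestyle_group": spec.name,
                    "dataset_label": spec.dataset_label or spec.name,
                }
            )
    merged = merge_samples(tables)
    merged.validate(strict=True)
    metadata = pd.DataFrame.from_records(meta_rows)
    return merged, metadata, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_GENERA = (
    "Bacteroides", "Clostridium", "Prevotella", "Faecalibacterium",
    "Phascolarctobacterium", "Roseburia", "Blautia", "Eubacterium",
    "Ruminococcus", "Coprococcus", "Dialister", "Megasphaera",
    "Veillonella", "Akkermansia", "Bifidobacterium", "Lachnospira",
    "Dorea", "Anaerostipes", "Butyrivibrio", "Succinivibrio",
    "Treponema", "Oscillibacter", "Alistipes", "Parabacteroides",
)


def _pool(genera: Sequence[str], species_per_genus: int = 1) -> TaxonPool:
    return tuple(
        (g, f"{g}_sp{i + 1}")
        for g in genera
        for i in range(species_per_genus)
    )


#: Mean gene-group totals (CPM-RPK) giving the observed acetate-dominant
#: composition of gut metagenomes (roughly 60:21.5:18.5 overall).
_SCFA_MEANS = {"acetate": 18000.0, "butyrate": 6450.0, "propionate": 5520.0}


def _standard_groups(
    alpha: float,
    pools: Optional[Mapping[str, TaxonPool]] = None,
    means: Optional[Mapping[str, float]] = None,
    sigma_log: float = 0.4,
) -> Dict[str, GroupEcology]:
    if pools is None:
        pools = {
            "acetate": _pool(_GENERA[:15]),
            "butyrate": _pool(_GENERA[:12]),
            "propionate": _pool(_GENERA[:10]),
        }
    means = means or _SCFA_MEANS
    return {
        g: GroupEcology(
            taxon_pool=pools[g],
            alpha=alpha,
            mean_total=means.get(g, 5000.0),
            sigma_log=sigma_log,
        )
        for g in pools
    }


@dataclass(frozen=True)
class CohortPreset:
    name: str
    specs: Tuple[PopulationSpec, ...]
    tree: Optional[str] = None  # newick
    description: str = ""


def _congeneric_tree() -> str:
    """Newick tree for the congeneric-species preset: congeners sit on short
    terminal branches inside genus clades, dispersed species on long separate
    branches, so many congeners add little phylogenetic diversity."""
    clades = []
    for g in _GENERA[:4]:
        tips = ",".join(f"{g}_sp{i + 1}:0.02" for i in range(6))
        clades.append(f"({tips}):0.49")
    singles = [f"{g}_sp1:0.51" for g in _GENERA[4:16]]
    return "(" + ",".join(clades + singles) + ");"


def preset_cohorts() -> Dict[str, CohortPreset]:
    """Named spec bundles covering the contrasts the pipeline must detect."""
    presets: Dict[str, CohortPreset] = {}

    base = dict(unmapped_fraction=0.30, m_species=0.3, m_genus=0.2)
    presets["null"] = CohortPreset(
        name="null",
        specs=(
            PopulationSpec("pop_A", 50, _standard_groups(alpha=1.0), **base),
            PopulationSpec("pop_B", 50, _standard_groups(alpha=1.0), **base),
        ),
        description="Two populations with identical generative parameters; "
        "any detected difference is a false positive.",
    )

    even_pools = {
        g: _pool(_GENERA[:20]) for g in ("acetate", "butyrate", "propionate")
    }
    presets["evenness-shift"] = CohortPreset(
        name="evenness-shift",
        specs=(
            PopulationSpec(
                "even", 50, _standard_groups(alpha=5.0, pools=even_pools),
                unmapped_fraction=0.25,
            ),
            PopulationSpec(
                "uneven", 50, _standard_groups(alpha=0.2, pools=even_pools),
                unmapped_fraction=0.25,
            ),
        ),
        description="Same 20-genus pools; Dirichlet α = 5 vs 0.2 shifts "
        "evenness (Hill orders 1–2) without changing richness.",
    )

    presets["bias-shift"] = CohortPreset(
        name="bias-shift",
        specs=(
            PopulationSpec(
                "low_bias", 50, _standard_groups(alpha=1.0),
                unmapped_fraction=0.30, m_species=0.1, m_genus=0.0,
            ),
            PopulationSpec(
                "high_bias", 50, _standard_groups(alpha=1.0),
                unmapped_fraction=0.30, m_species=0.6, m_genus=0.0,
            ),
        ),
        description="Identical ecology; only the species-annotation dropout "
        "rate differs, emulating reference-database bias.",
    )

    congeneric_pool = _pool(_GENERA[:4], species_per_genus=6)   # 4 genera, 24 sp
    dispersed_pool = _pool(_GENERA[4:16], species_per_genus=1)  # 12 genera, 12 sp
    presets["congeneric-species"] = CohortPreset(
        name="congeneric-species",
        specs=(
            PopulationSpec(
                "congeneric", 50,
                _standard_groups(
                    alpha=1.0,
                    pools={g: congeneric_pool for g in _SCFA_MEANS},
                ),
                unmapped_fraction=0.25,
            ),
            PopulationSpec(
                "dispersed", 50,
                _standard_groups(
                    alpha=1.0,
                    pools={g: dispersed_pool for g in _SCFA_MEANS},
                ),
                unmapped_fraction=0.25,
            ),
        ),
        tree=_congeneric_tree(),
        description="Few genera with many closely related species vs many "
        "genera with one species each: species richness dissociates from "
        "phylogenetic diversity.",
    )

    presets["lifestyle"] = CohortPreset(
        name="lifestyle",
        specs=_lifestyle_specs(),
        description="Five lifestyle groups with industrial-style congeneric "
        "pools, low evenness and mild annotation dropout vs non-industrial "
        "dispersed pools, high evenness and strong dropout.",
    )
    return presets


def _lifestyle_specs() -> Tuple[PopulationSpec, ...]:
    industrial_pool = _pool(("Bacteroides",), 6) + _pool(("Clostridium",), 5) + _pool(
        ("Blautia", "Ruminococcus", "Veillonella", "Bifidobacterium")
    )
    nonindustrial_pool = _pool(
        (
            "Prevotella", "Faecalibacterium", "Phascolarctobacterium",
            "Roseburia", "Butyrivibrio", "Succinivibrio", "Treponema",
            "Eubacterium", "Coprococcus", "Lachnospira", "Dialister",
            "Megasphaera", "Oscillibacter", "Alistipes",
        )
    )
    industrial_means = {"acetate": 16000.0, "butyrate": 5400.0, "propionate": 5800.0}
    nonindustrial_means = {"acetate": 20000.0, "butyrate": 7500.0, "propionate": 5200.0}

    def groups(pool: TaxonPool, alpha: float, means: Mapping[str, float]):
        return _standard_groups(
            alpha=alpha,
            pools={g: pool for g in _SCFA_MEANS},
            means=means,
            sigma_log=0.35,
        )

    return (
        PopulationSpec(
            "industrial_EU_NA", 114,
            groups(industrial_pool, 0.3, industrial_means),
            unmapped_fraction=0.25, m_species=0.06, m_genus=0.2,
        ),
        PopulationSpec(
            "industrial_C_E_Asia", 96,
            groups(industrial_pool, 0.3, industrial_means),
            unmapped_fraction=0.25, m_species=0.06, m_genus=0.2,
        ),
        PopulationSpec(
            "pastoral", 50,
            groups(nonindustrial_pool, 1.0, nonindustrial_means),
            unmapped_fraction=0.33, m_species=0.3, m_genus=0.3,
        ),
        PopulationSpec(
            "rural_agricultural", 140,
            groups(nonindustrial_pool, 2.0, nonindustrial_means),
            unmapped_fraction=0.35, m_species=0.5, m_genus=0.4,
        ),
        PopulationSpec(
            "hunter_gatherer", 51,
            groups(nonindustrial_pool, 2.5, nonindustrial_means),
            unmapped_fraction=0.35, m_species=0.5, m_genus=0.45,
        ),
    )


# ---------------------------------------------------------------------------
# Spec (de)serialization — one human-editable YAML file per cohort
# ---------------------------------------------------------------------------


def _spec_to_dict(spec: PopulationSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["groups"] = {
        g: {
            "taxon_pool": [list(t) for t in eco["taxon_pool"]],
            "alpha": eco["alpha"],
            "mean_total": eco["mean_total"],
            "sigma_log": eco["sigma_log"],
            "gene_split": dict(eco["gene_split"]) if eco["gene_split"] else None,
        }
        for g, eco in d["groups"].items()
    }
    return d


def save_population_specs(specs: Sequence[PopulationSpec], path) -> None:
    payload = {"populations": [_spec_to_dict(s) for s in specs]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_population_specs(path) -> List[PopulationSpec]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    specs = []
    for d in payload["populations"]:
        groups = {
            g: GroupEcology(
                taxon_pool=tuple((p[0], p[1]) for p in eco["taxon_pool"]),
                alpha=eco.get("alpha", 1.0),
                mean_total=eco.get("mean_total", 5000.0),
                sigma_log=eco.get("sigma_log", 0.4),
                gene_split=eco.get("gene_split"),
            )
            for g, eco in d["groups"].items()
        }
        specs.append(
            PopulationSpec(
                name=d["name"],
                n_samples=int(d["n_samples"]),
                groups=groups,
                unmapped_fraction=float(d.get("unmapped_fraction", 0.25)),
                m_species=float(d.get("m_species", 0.0)),
                m_genus=float(d.get("m_genus", 0.0)),
                dataset_label=d.get("dataset_label", ""),
            )
        )
    for spec in specs:
        validate_spec(spec)
    return specs
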