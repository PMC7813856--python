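"""Nonparametric comparison of per-sample metrics across lifestyle groups.

Omnibus differences are tested with the Kruskal–Wallis H test (chi-squared
approximation with k−1 degrees of freedom, mid-ranks with tie correction;
an exact-permutation variant is available for tiny designs).  Pairwise
contrasts use Dunn's test on the pooled ranking with tie-corrected standard
errors, and p-values are adjusted with the Benjamini–Hochberg step-up within
a declared family scope.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FDR_SCOPES = ("per-metric", "global")


def _as_groups(groups: Sequence[Iterable[float]]) -> List[np.ndarray]:
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
        if not np.isfinite(a).all():
            raise ValueError(f"group {i} contains non-finite values")
    return arrays


def _tie_term(pooled: np.ndarray) -> float:
    """Σ (t³ − t) over tie groups of the pooled data."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _h_statistic(arrays: List[np.ndarray]) -> float:
    """Tie-corrected Kruskal–Wallis H on mid-ranks."""
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    start = 0
    h = 0.0
    for a in arrays:
        r = ranks[start : start + a.size]
        start += a.size
        h += r.sum() ** 2 / a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    correction = 1.0 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:  # all observations identical
        return 0.0
    return h / correction


def kruskal_wallis(
    groups: Sequence[Iterable[float]], method: str = "chi2"
) -> Tuple[float, float]:
    """Kruskal–Wallis H test; returns (H, p).

    ``method="chi2"`` uses the chi-squared approximation (k−1 df);
    ``method="exact"`` enumerates every assignment of the pooled observations
    to the group sizes (suitable for total n up to ~10) and returns
    P(H ≥ H_obs) under the permutation null.
    """
    arrays = _as_groups(groups)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if method == "chi2":
        h, p = scipy.stats.kruskal(*arrays)
        return float(h), float(p)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    n = pooled.size
    if n > 12:
        raise ValueError("exact permutation method limited to total n <= 12")
    h_obs = _h_statistic(arrays)
    sizes = [a.size for a in arrays]
    count = 0
    at_least = 0
    for perm in _distinct_assignments(n, sizes):
        parts = [pooled[list(idx)] for idx in perm]
        count += 1
        if _h_statistic(parts) >= h_obs - 1e-12:
            at_least += 1
    return h_obs, at_least / count


def _distinct_assignments(n: int, sizes: List[int]):
    """Yield tuples of index-sets partitioning range(n) into the given sizes."""
    indices = set(range(n))

    def rec(remaining: frozenset, k: int):
        if k == len(sizes) - 1:
            yield (tuple(sorted(remaining)),)
            return
        for combo in itertools.combinations(sorted(remaining), sizes[k]):
            rest = remaining - set(combo)
            for tail in rec(rest, k + 1):
                yield (combo,) + tail

    yield from rec(frozenset(indices), 0)


def dunn_posthoc(
    groups: Sequence[Iterable[float]],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on the pooled ranking.

    For each unordered pair, z is the difference in mean ranks divided by the
    tie-corrected standard error sqrt((N(N+1)/12 − ΣT/(12(N−1)))(1/n_i+1/n_j));
    two-sided p from the standard normal.  Identical pooled data gives z = 0,
    p = 1.
    """
    arrays = _as_groups(groups)
    if labels is None:
        labels = [f"group_{i}" for i in range(len(arrays))]
    if len(labels) != len(arrays):
        raise ValueError("labels do not match groups")
    pooled = np.concatenate(arrays)
    n = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    variance = n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1))
    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se2 = variance * (1.0 / arrays[i].size + 1.0 / arrays[j].size)
        if se2 <= 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "n_a": arrays[i].size,
                "n_b": arrays[j].size,
                "z": float(z),
                "p_raw": float(min(p, 1.0)),
            }
        )
    return pd.DataFrame.from_records(rows)


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """Omnibus + pairwise comparison of one metric across lifestyle groups."""

    metric: str
    group_name: str
    level: str
    h_statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame  # group_a, group_b, n_a, n_b, z, p_raw, p_adj
    n_total: int
    per_group_n: Dict[str, int]
    fdr_scope: str = "per-metric"

    def to_frame(self) -> pd.DataFrame:
        df = self.pairwise.copy()
        df.insert(0, "metric", self.metric)
        df.insert(1, "gene_group", self.group_name)
        df.insert(2, "level", self.level)
        df["h_statistic"] = self.h_statistic
        df["p_omnibus"] = self.p_omnibus
        df["n_total"] = self.n_total
        df["fdr_scope"] = self.fdr_scope
        return df


def compare_lifestyles(
    metrics: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr_scope: str = "per-metric",
) -> List[ComparisonResult]:
    """Kruskal–Wallis + Dunn + BH for every metric family in a long table.

    ``metrics`` must have columns sample_id, group_name, level, metric, value;
    ``metadata`` assigns each sample a lifestyle_group.  Missing values are
    dropped listwise per metric and per-group n is reported.  BH is applied
    within each (gene group, level, metric) family by default, or across all
    pairwise tests with ``fdr_scope="global"``.
    """
    if fdr_scope not in FDR_SCOPES:
        raise ValueError(f"fdr_scope must be one of {FDR_SCOPES}")
    required = {"sample_id", "group_name", "level", "metric", "value"}
    missing_cols = required - set(metrics.columns)
    if missing_cols:
        raise ValueError(f"metrics table lacks column(s): {sorted(missing_cols)}")
    merged = metrics.merge(
        metadata[["sample_id", "lifestyle_group"]], on="sample_id", how="left"
    )
    if merged["lifestyle_group"].isna().any():
        orphan = merged.loc[merged["lifestyle_group"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"sample {orphan!r} has no lifestyle metadata")

    results: List[ComparisonResult] = []
    for (gname, level, metric), block in merged.groupby(
        ["group_name", "level", "metric"], sort=False
    ):
        block = block.dropna(subset=["value"])
        grouped = {
            lg: sub["value"].to_numpy()
            for lg, sub in block.groupby("lifestyle_group", sort=False)
            if len(sub) > 0
        }
        if len(grouped) < 2:
            logger.warning(
                "metric %s/%s/%s: fewer than two non-empty lifestyle groups, "
                "skipped",
                gname,
                level,
                metric,
            )
            continue
        labels = list(grouped)
        arrays = [grouped[l] for l in labels]
        h, p = kruskal_wallis(arrays)
        pairwise = dunn_posthoc(arrays, labels)
        results.append(
            ComparisonResult(
                metric=metric,
                group_name=gname,
                level=level,
                h_statistic=h,
                p_omnibus=p,
                pairwise=pairwise,
                n_total=int(sum(a.size for a in arrays)),
                per_group_n={l: int(a.size) for l, a in zip(labels, arrays)},
                fdr_scope=fdr_scope,
            )
        )

    if fdr_scope == "per-metric":
        for res in results:
            res.pairwise["p_adj"] = bh_adjust(res.pairwise["p_raw"])
    else:
        all_p = np.concatenate([r.pairwise["p_raw"].to_numpy() for r in results])
        adj = bh_adjust(all_p)
        start = 0
        for res in results:
            k = len(res.pairwise)
            res.pairwise["p_adj"] = adj[start : start + k]
            start += k
    return results


def comparison_table(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Tidy concatenation of pairwise results across all metric families."""
    if not results:
        return pd.DataFrame(
            columns=[
                "metric", "gene_group", "level", "group_a", "group_b",
                "n_a", "n_b", "z", "p_raw", "p_adj", "h_statistic",
                "p_omnibus", "n_total", "fdr_scope",
            ]
        )
    return pd.concat([r.to_frame() for r in results], ignore_index=True)
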