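"""Pairwise coexpression, dual gene orderings and per-mode correlation
distributions.

Coexpression is the Pearson correlation of two genes' expression profiles
across all samples pooled.  Two orderings of the same gene set are
produced for heat-map display: average-linkage hierarchical clustering on
the distance 1 - r, and the left-to-right tip order of a phylogeny.
Correlation distributions are stratified by duplication mode and compared
against a random-pair baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from kinodup.io import ValidationError

HIST_BINS = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)


@dataclass
class CoexpressionResult:
    """Symmetric Pearson correlation matrix with undefined entries flagged."""

    correlations: pd.DataFrame
    undefined: set[str] = field(default_factory=set)  # zero-variance genes
    clustering_order: list[str] | None = None
    phylogeny_order: list[str] | None = None


@dataclass
class ModeCorrelationDistribution:
    """Per-mode correlation values plus a fixed-bin histogram summary."""

    values: dict[str, list[float]]  # mode (incl. "random") -> r values

    def summary(self) -> pd.DataFrame:
        rows = []
        for mode, vals in sorted(self.values.items()):
            arr = np.asarray(vals, float)
            hist = (
                np.histogram(arr, bins=HIST_BINS)[0].tolist() if arr.size else []
            )
            rows.append(
                (
                    mode,
                    len(arr),
                    float(arr.mean()) if arr.size else np.nan,
                    float(np.median(arr)) if arr.size else np.nan,
                    hist,
                )
            )
        return pd.DataFrame(rows, columns=["mode", "n", "mean", "median", "hist"])


def pairwise_correlation(
    expr: pd.DataFrame, genes: Sequence[str] | None = None
) -> CoexpressionResult:
    """Pearson correlation across all samples for every gene pair.

    Genes with zero expression variance get undefined (NaN) correlations
    and are flagged for downstream exclusion.  Requires >= 3 samples.
    """
    if expr.shape[1] < 3:
        raise ValidationError("need >= 3 expression samples")
    if genes is not None:
        missing = [g for g in genes if g not in expr.index]
        if missing:
            raise ValidationError(f"genes absent from expression matrix: {missing[:5]}")
        expr = expr.loc[list(genes)]
    mat = expr.to_numpy(float)
    sd = mat.std(axis=1)
    undefined = set(expr.index[sd == 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    cdf = pd.DataFrame(corr, index=expr.index, columns=expr.index)
    return CoexpressionResult(correlations=cdf, undefined=undefined)


def order_genes(
    result: CoexpressionResult, tree: dendropy.Tree
) -> tuple[list[str], list[str]]:
    """Clustering and phylogeny orderings of the correlation gene set.

    The clustering order comes from average-linkage agglomerative
    clustering on 1 - r over genes with defined correlations (genes sorted
    lexicographically first, so merge tie-breaks are deterministic); the
    phylogeny order is the tree's left-to-right tip order.  Every tree tip
    must be present in the correlation matrix.
    """
    corr = result.correlations
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in corr.index]
    if missing:
        raise ValidationError(f"tree tips absent from correlations: {missing}")
    genes = sorted(g for g in corr.index if g not in result.undefined)
    if len(genes) < 2:
        raise ValidationError("need >= 2 genes with defined correlations")
    sub = corr.loc[genes, genes].to_numpy(float)
    dist = np.clip(1.0 - sub, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaf_order = hierarchy.leaves_list(link)
    clustering_order = [genes[i] for i in leaf_order]
    result.clustering_order = clustering_order
    result.phylogeny_order = tips
    return clustering_order, tips


def correlation_by_mode(
    result: CoexpressionResult,
    pairs: Sequence[tuple[str, str, str]],
    n_random: int = 1000,
    seed: int = 0,
) -> ModeCorrelationDistribution:
    """Correlation distributions per duplication mode with a random-pair
    baseline.

    ``pairs`` are typed duplicate pairs ``(a, b, mode)``.  The baseline is
    ``n_random`` uniformly sampled unordered gene pairs excluding the true
    duplicate pairs; pairs touching a zero-variance gene are skipped.
    """
    corr = result.correlations
    values: dict[str, list[float]] = {}
    true_pairs = set()
    for a, b, mode in pairs:
        true_pairs.add(frozenset((a, b)))
        values.setdefault(mode, [])
        if a in result.undefined or b in result.undefined:
            continue
        if a not in corr.index or b not in corr.index:
            raise ValidationError(f"pair gene missing from correlations: {a}/{b}")
        values[mode].append(float(corr.loc[a, b]))

    rng = np.random.default_rng(seed)
    genes = [g for g in corr.index if g not in result.undefined]
    random_vals: list[float] = []
    if n_random > 0 and len(genes) >= 2:
        capacity = len(genes) * (len(genes) - 1) // 2 - len(true_pairs)
        n_random = min(n_random, max(capacity, 0))
        seen: set[frozenset] = set()
        while len(random_vals) < n_random:
            i, j = rng.choice(len(genes), size=2, replace=False)
            key = frozenset((genes[int(i)], genes[int(j)]))
            if key in true_pairs or key in seen:
                continue
            seen.add(key)
            random_vals.append(float(corr.loc[genes[int(i)], genes[int(j)]]))
    values["random"] = random_vals
    return ModeCorrelationDistribution(values=values)


def fisher_z_mean(correlations: Sequence[float]) -> float:
    """Average correlations on the Fisher z scale (per-set combination)."""
    z = np.arctanh(np.clip(np.asarray(correlations, float), -0.999999, 0.999999))
    return float(np.tanh(z.mean()))
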