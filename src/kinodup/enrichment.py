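"""Null-model expectations and family-level enrichment statistics.

Tandem null model
    The expected number of tandem gene pairs in a family of size *N* is
    estimated by Monte Carlo: place *N* genes of size 1 kb uniformly in an
    idealised genome of ~100,000 kb and count unordered pairs whose starts
    lie within a 50 kb window; average over replicates.  The family-size
    grid runs 10..300 in steps of 10 with 1000 replicates per size, and
    off-grid sizes are served by linear interpolation.  The closed form
    ``C(N,2) * (2w/L' - (w/L')^2)`` with ``L' = genome_length - gene_size``
    is provided as an independent check.

Segmental null model
    Roughly 75% of an extensively duplicated plant genome lies in at least
    one segmentally duplicated block, so under unbiased retention a family
    of size *N* expects ``0.75 * N`` segmentally duplicated members.

Enrichment
    Each (family, mode) cell is tested with a two-sided Fisher's exact
    test of the 2x2 collapse [family vs all other families] x [mode vs all
    other modes], Benjamini-Hochberg corrected across all cells jointly;
    Pearson residuals (O - E)/sqrt(E) give direction and strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from kinodup.classify import FamilyCounts
from kinodup.io import ValidationError

RATIO_BANDS = ("below-2SD", "-2SD..-1SD", "box", "+1SD..+2SD", "above+2SD")


@dataclass
class TandemNullConfig:
    """Geometry and replication of the tandem-count null simulation.

    Lengths are in kb.  The defaults are the idealised-genome conditions:
    1 kb genes in a 100,000 kb genome, a 50 kb window, family sizes 10..300
    in steps of 10, 1000 replicates.
    """

    genome_length: float = 100_000.0
    gene_size: float = 1.0
    window: float = 50.0
    family_sizes: tuple[int, ...] = tuple(range(10, 301, 10))
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window < self.genome_length:
            raise ValidationError("window must be smaller than the genome")
        if self.replicates < 1:
            raise ValidationError("need >= 1 replicate")


@dataclass
class EnrichmentResult:
    family: str
    mode: str
    observed: int
    expected: float
    p_value: float
    p_adjusted: float
    pearson_residual: float
    direction: str
    degenerate: bool = False


@dataclass
class RatioClassification:
    """Observed/expected ratios with median +- SD band assignments."""

    table: pd.DataFrame  # family, tandem_ratio, segmental_ratio, bands
    tandem_median: float
    tandem_sd: float
    segmental_median: float
    segmental_sd: float
    excluded: list[str] = field(default_factory=list)


def analytic_expected_tandem(
    N: int,
    genome_length: float = 100_000.0,
    gene_size: float = 1.0,
    window: float = 50.0,
) -> float:
    """Closed-form expected within-window pair count for N uniform genes.

    Two starts uniform on [0, L'] with L' = genome_length - gene_size fall
    within ``window`` of each other with probability 2w/L' - (w/L')^2 (the
    band area around the diagonal of the L' x L' square); the expectation
    over C(N,2) exchangeable pairs follows by linearity.
    """
    if N < 2:
        return 0.0
    lp = genome_length - gene_size
    w = min(window, lp)
    p = 2 * w / lp - (w / lp) ** 2
    return math.comb(N, 2) * p


def simulate_expected_tandem(
    config: TandemNullConfig | None = None,
) -> dict[int, tuple[float, float]]:
    """Monte Carlo expected tandem pair counts per family size.

    Returns ``{N: (mean pair count, standard error of the mean)}`` over
    ``config.replicates`` replicates; deterministic under ``config.seed``.
    """
    config = config or TandemNullConfig()
    rng = np.random.default_rng(config.seed)
    lp = config.genome_length - config.gene_size
    out: dict[int, tuple[float, float]] = {}
    for N in config.family_sizes:
        if N < 2:
            out[int(N)] = (0.0, 0.0)
            continue
        counts = np.empty(config.replicates)
        for r in range(config.replicates):
            starts = np.sort(rng.uniform(0.0, lp, size=N))
            # two-pointer pair count: for each gene, partners within window
            upper = np.searchsorted(starts, starts + config.window, side="right")
            counts[r] = int(np.sum(upper - np.arange(1, N + 1)))
        mean = float(counts.mean())
        se = float(counts.std(ddof=1) / np.sqrt(config.replicates))
        out[int(N)] = (mean, se)
    return out


def interpolate_expected(
    expectations: Mapping[int, tuple[float, float]], N: int
) -> float:
    """Expected tandem count for an off-grid family size, by linear
    interpolation on the simulated grid (clamped at the grid ends)."""
    grid = sorted(expectations)
    means = [expectations[n][0] for n in grid]
    return float(np.interp(N, grid, means))


def expected_segmental(N: int) -> float:
    """Expected segmentally duplicated gene count: 0.75 * N."""
    if N < 0:
        raise ValidationError("family size must be >= 0")
    return 0.75 * N


# ---------------------------------------------------------------------------
# ratio bands
# ---------------------------------------------------------------------------

def _band(ratio: float, median: float, sd: float) -> str:
    """Assign a ratio to a median +- SD band.

    A boundary value belongs to the band farther from the median: the box
    is the open interval (median-1SD, median+1SD) and a ratio exactly at
    median+-2SD falls in the beyond-2SD band.  With sd == 0 every ratio at
    the median is "box" and anything else is beyond 2 SD.
    """
    if sd == 0:
        if ratio == median:
            return "box"
        return "above+2SD" if ratio > median else "below-2SD"
    z = (ratio - median) / sd
    if z >= 2:
        return "above+2SD"
    if z >= 1:
        return "+1SD..+2SD"
    if z > -1:
        return "box"
    if z > -2:
        return "-2SD..-1SD"
    return "below-2SD"


def classify_ratios(families: Sequence[FamilyCounts]) -> RatioClassification:
    """Observed/expected ratio per family for tandem and segmental counts,
    with per-axis median +- 1/2 SD band assignment.

    Families whose expectation is 0 on an axis are excluded from that
    axis's statistics and listed in ``excluded``.  The SD is the sample
    standard deviation (n-1) of the per-family ratios.  Input order does
    not affect the result.
    """
    if len(families) < 2:
        raise ValidationError("need >= 2 families to classify ratios")
    rows = []
    excluded = []
    for fc in sorted(families, key=lambda f: f.family):
        ok_t = fc.expected_tandem > 0
        ok_s = fc.expected_segmental > 0
        if not (ok_t and ok_s):
            excluded.append(fc.family)
        obs_tandem = (
            fc.observed_tandem_pairs
            if fc.observed_tandem_pairs is not None
            else fc.observed.get("tandem", 0)
        )
        rows.append(
            (
                fc.family,
                obs_tandem / fc.expected_tandem if ok_t else np.nan,
                fc.observed.get("wgd_segmental", 0) / fc.expected_segmental if ok_s else np.nan,
            )
        )
    df = pd.DataFrame(rows, columns=["family", "tandem_ratio", "segmental_ratio"])
    if df["tandem_ratio"].isna().all() and df["segmental_ratio"].isna().all():
        raise ValidationError("all families have zero expectations")
    stats_ = {}
    for axis in ("tandem", "segmental"):
        vals = df[f"{axis}_ratio"].dropna()
        med = float(vals.median())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        stats_[axis] = (med, sd)
        df[f"{axis}_band"] = [
            _band(r, med, sd) if not np.isnan(r) else "excluded"
            for r in df[f"{axis}_ratio"]
        ]
    return RatioClassification(
        table=df,
        tandem_median=stats_["tandem"][0], tandem_sd=stats_["tandem"][1],
        segmental_median=stats_["segmental"][0], segmental_sd=stats_["segmental"][1],
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def fisher_enrichment(observed: pd.DataFrame) -> list[EnrichmentResult]:
    """Two-sided Fisher's exact test for every family x mode cell.

    ``observed`` is a family (rows) x mode (columns) matrix of gene
    counts.  For each cell the 2x2 table is [[n(f,m), n(f,not m)],
    [n(not f,m), n(not f,not m)]], where "not f" aggregates the other
    families in the matrix.  P-values are BH-adjusted across all cells
    jointly; the Pearson residual (O-E)/sqrt(E) with E = row x col /
    grand total gives direction.  Cells on a zero row or column margin
    are flagged degenerate with p = 1 and residual 0.
    """
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValidationError("need >= 2 families and >= 2 modes")
    counts = observed.to_numpy()
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.number):
        raise ValidationError("counts must be non-negative numbers")
    counts = counts.astype(np.int64)
    grand = counts.sum()
    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    results: list[EnrichmentResult] = []
    raw_p: list[float] = []
    for i, fam in enumerate(observed.index):
        for j, mode in enumerate(observed.columns):
            o = int(counts[i, j])
            degenerate = row_tot[i] == 0 or col_tot[j] == 0
            if degenerate:
                p, resid, e = 1.0, 0.0, 0.0
            else:
                a = o
                b = int(row_tot[i] - o)
                c = int(col_tot[j] - o)
                d = int(grand - a - b - c)
                p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
                e = row_tot[i] * col_tot[j] / grand
                resid = (o - e) / math.sqrt(e)
            raw_p.append(p)
            results.append(
                EnrichmentResult(
                    family=str(fam), mode=str(mode), observed=o,
                    expected=float(e), p_value=p, p_adjusted=np.nan,
                    pearson_residual=float(resid),
                    direction="enriched" if resid > 0 else "depleted",
                    degenerate=bool(degenerate),
                )
            )
    adjusted = benjamini_hochberg(raw_p)
    for res, padj in zip(results, adjusted):
        res.p_adjusted = float(max(padj, res.p_value))
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.family, r.mode, r.observed, r.expected, r.p_value,
             r.p_adjusted, r.pearson_residual, r.direction, r.degenerate)
            for r in results
        ],
        columns=["family", "mode", "observed", "expected", "p", "p_adj",
                 "residual", "direction", "degenerate"],
    )


def phenotype_enrichment(
    phenotype_of: Mapping[str, str], focal: set[str]
) -> list[EnrichmentResult]:
    """Per-class Fisher enrichment of the focal gene set vs the background.

    For each phenotype class c the 2x2 table is [[|focal in c|,
    |focal not in c|], [|background in c|, |background not in c|]];
    BH correction is applied across classes.
    """
    if not focal:
        raise ValidationError("empty focal set")
    focal = {g for g in focal if g in phenotype_of}
    if not focal:
        raise ValidationError("focal set disjoint from phenotype table")
    classes = sorted(set(phenotype_of.values()))
    n_focal = len(focal)
    n_bg = len(phenotype_of) - n_focal
    results: list[EnrichmentResult] = []
    raw_p = []
    for cls in classes:
        in_cls = {g for g, c in phenotype_of.items() if c == cls}
        a = len(focal & in_cls)
        b = n_focal - a
        c = len(in_cls) - a
        d = n_bg - c
        if n_bg == 0 or len(in_cls) in (0, len(phenotype_of)):
            p, resid, e = 1.0, 0.0, float(a)
            degenerate = True
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
            e = n_focal * len(in_cls) / len(phenotype_of)
            resid = (a - e) / math.sqrt(e) if e > 0 else 0.0
            degenerate = False
        raw_p.append(p)
        results.append(
            EnrichmentResult(
                family="focal", mode=cls, observed=a, expected=float(e),
                p_value=p, p_adjusted=np.nan, pearson_residual=float(resid),
                direction="enriched" if resid > 0 else "depleted",
                degenerate=degenerate,
            )
        )
    for res, padj in zip(results, benjamini_hochberg(raw_p)):
        res.p_adjusted = float(max(padj, res.p_value))
    return results


def attach_expectations(
    families: Sequence[FamilyCounts],
    expectations: Mapping[int, tuple[float, float]],
) -> list[FamilyCounts]:
    """Fill each family's tandem (interpolated null grid) and segmental
    (0.75N) expectations in place and return the list."""
    for fc in families:
        fc.expected_tandem = interpolate_expected(expectations, fc.N)
        fc.expected_segmental = expected_segmental(fc.N)
    return list(families)
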