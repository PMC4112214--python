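"""Duplication-mode classification and summary tabulation.

Every gene receives exactly one of six modes — whole-genome/segmental
(``wgd_segmental``), ``tandem``, ``proximal``, ``transposed``,
``dispersed`` or ``singleton`` — following the MCScanX /
MCScanX-transposed semantics:

1. a gene with no retained homology hit and no collinear-block anchor is
   a singleton;
2. a gene anchored in at least one within-genome collinear block is
   wgd_segmental;
3. homolog pairs on one chromosome at rank distance 1 are tandem; runs of
   adjacent homologs link transitively into tandem arrays;
4. remaining same-chromosome pairs within the proximal window (rank
   distance 2..20 by default) are proximal;
5. pairs where exactly one member sits at an outgroup-supported ancestral
   locus mark the *other* member as transposed;
6. every other duplicated gene is dispersed.

A gene touched by several pair types takes the highest-precedence mode
(wgd_segmental > tandem > proximal > transposed > dispersed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import pandas as pd

from kinodup.io import CollinearBlock, GenomeTable, HomologyHit, ValidationError

#: all six per-gene modes, in precedence order (singleton last).
MODES = ("wgd_segmental", "tandem", "proximal", "transposed", "dispersed", "singleton")
#: the five duplicate (non-singleton) modes.
DUPLICATE_MODES = MODES[:-1]


@dataclass
class ClassificationParams:
    """Tunable rule parameters.

    proximal_max_rank_distance
        Largest same-chromosome rank distance still called proximal
        (default 20, i.e. up to 19 intervening genes in the <=20-gene
        window; configurable because conventions differ between tools).
    """

    proximal_max_rank_distance: int = 20
    tandem_rank_distance: int = 1
    precedence: tuple[str, ...] = DUPLICATE_MODES

    def __post_init__(self) -> None:
        if self.proximal_max_rank_distance <= self.tandem_rank_distance:
            raise ValueError("proximal window must exceed the tandem distance")
        if sorted(self.precedence) != sorted(DUPLICATE_MODES):
            raise ValueError("precedence must be a permutation of the duplicate modes")


@dataclass
class DuplicationLabeling:
    """Per-gene mode assignment plus typed duplicate pairs.

    ``pairs`` holds one entry per classified homolog pair ``(a, b, mode)``;
    transposed pairs are directional ``(ancestral, transposed, mode)`` and
    the ancestral locus of each transposed gene is in ``ancestral_of``.
    """

    mode_of: dict[str, str]
    pairs: list[tuple[str, str, str]]
    ancestral_of: dict[str, str] = field(default_factory=dict)

    def genes_with_mode(self, mode: str) -> list[str]:
        return sorted(g for g, m in self.mode_of.items() if m == mode)

    def counts(self) -> dict[str, int]:
        out = {m: 0 for m in MODES}
        for m in self.mode_of.values():
            out[m] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        partners: dict[str, set[str]] = {}
        for a, b, _ in self.pairs:
            partners.setdefault(a, set()).add(b)
            partners.setdefault(b, set()).add(a)
        rows = [
            (g, m, ",".join(sorted(partners.get(g, ()))))
            for g, m in sorted(self.mode_of.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "mode", "partners"])


@dataclass
class FamilyCounts:
    """Observed per-mode gene counts for one family, plus null expectations.

    ``observed`` is in genes (summary-table units); ``observed_tandem_pairs``
    additionally counts within-family tandem pairs, the unit system of the
    tandem null simulation, and is preferred for observed/expected ratios
    when available.
    """

    family: str
    N: int
    observed: dict[str, int]
    expected_tandem: float = 0.0
    expected_segmental: float = 0.0
    observed_tandem_pairs: int | None = None

    def __post_init__(self) -> None:
        if sum(self.observed.values()) != self.N:
            raise ValidationError(
                f"family {self.family}: observed counts sum to "
                f"{sum(self.observed.values())}, not N={self.N}"
            )


def classify_duplications(
    genome: GenomeTable,
    hits: Sequence[HomologyHit],
    blocks: Sequence[CollinearBlock],
    outgroup_anchored: set[str] | None = None,
    params: ClassificationParams | None = None,
) -> DuplicationLabeling:
    """Assign every gene in ``genome`` a duplication mode.

    ``hits`` must already have passed :func:`kinodup.io.filter_hits`.
    ``outgroup_anchored`` is the set of genes whose locus is supported as
    ancestral by outgroup collinearity; without it, the transposed rule is
    skipped and such pairs remain dispersed.

    Raises :class:`ValidationError` if a hit or block references a gene
    absent from the genome table.
    """
    params = params or ClassificationParams()
    anchored = outgroup_anchored or set()

    for h in hits:
        for g in (h.query, h.subject):
            if g not in genome:
                raise ValidationError(f"hit gene {g} absent from genome table")
    block_genes: dict[str, set[str]] = {}
    for blk in blocks:
        for g in blk.anchor_genes:
            if g not in genome:
                raise ValidationError(f"block anchor {g} absent from genome table")
            block_genes.setdefault(g, set()).add(blk.block_id)

    # undirected unique homolog pairs
    pair_set: set[tuple[str, str]] = set()
    for h in hits:
        pair_set.add((min(h.query, h.subject), max(h.query, h.subject)))
    # anchor pairs are homolog pairs even if the hit list omits them
    for blk in blocks:
        for a, b in blk.anchor_pairs:
            if a != b:
                pair_set.add((min(a, b), max(a, b)))

    prec = {m: i for i, m in enumerate(params.precedence)}
    mode_of: dict[str, str] = {}
    pairs: list[tuple[str, str, str]] = []
    ancestral_of: dict[str, str] = {}

    def propose(gene: str, mode: str) -> None:
        cur = mode_of.get(gene)
        if cur is None or prec[mode] < prec[cur]:
            mode_of[gene] = mode

    for g in block_genes:
        propose(g, "wgd_segmental")

    for a, b in sorted(pair_set):
        if a in block_genes and b in block_genes and block_genes[a] & block_genes[b]:
            pairs.append((a, b, "wgd_segmental"))
            continue
        d = genome.rank_distance(a, b)
        if d is not None and d == params.tandem_rank_distance:
            mode = "tandem"
        elif d is not None and d <= params.proximal_max_rank_distance:
            mode = "proximal"
        elif (a in anchored) != (b in anchored):
            mode = "transposed"
            anc, tr = (a, b) if a in anchored else (b, a)
            ancestral_of[tr] = anc
            pairs.append((anc, tr, mode))
            propose(tr, "transposed")
            propose(anc, "dispersed")
            continue
        else:
            mode = "dispersed"
        pairs.append((a, b, mode))
        propose(a, mode)
        propose(b, mode)

    for g in genome:
        mode_of.setdefault(g.gene_id, "singleton")
    return DuplicationLabeling(mode_of=mode_of, pairs=pairs, ancestral_of=ancestral_of)


def compute_duplication_depth(
    genome: GenomeTable, blocks: Sequence[CollinearBlock]
) -> tuple[dict[str, int], float | None, int | None]:
    """Duplication depth per gene: number of distinct collinear blocks in
    which the gene is an anchor.

    Returns ``(depth_of, median, maximum)`` where the median is taken over
    genes with depth >= 1; both summary values are ``None`` when no gene is
    anchored.
    """
    depth: dict[str, int] = {g.gene_id: 0 for g in genome}
    for blk in blocks:
        for g in blk.anchor_genes:
            depth[g] = depth.get(g, 0) + 1
    support = sorted(d for d in depth.values() if d >= 1)
    if not support:
        return depth, None, None
    n = len(support)
    med = (
        float(support[n // 2])
        if n % 2
        else (support[n // 2 - 1] + support[n // 2]) / 2.0
    )
    return depth, med, support[-1]


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def tabulate_summary(
    labeling: DuplicationLabeling,
    family_of: Mapping[str, str] | None = None,
    focal_families: set[str] | None = None,
    counts: Mapping[str, int] | None = None,
    focal_counts: Mapping[str, int] | None = None,
) -> dict:
    """Tabulate genome-wide and focal-set mode counts with percentages.

    Percentages use the respective column total as denominator and are
    rounded half-away-from-zero to 1 decimal; the headline "fraction
    duplicated" (100 x (1 - singleton/total)) is rounded to the nearest
    integer.  Pre-computed ``counts`` / ``focal_counts`` mappings may be
    supplied instead of a labeling (e.g. to re-derive a published summary
    table); otherwise counts come from ``labeling`` and the focal set is
    the union of ``focal_families`` members under ``family_of``.
    """
    if counts is None:
        if not labeling.mode_of:
            raise ValidationError("empty labeling")
        counts = labeling.counts()
    counts = {m: int(counts.get(m, 0)) for m in MODES}
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("empty labeling")

    def table(c: Mapping[str, int]) -> dict[str, dict]:
        tot = sum(c.values())
        return {
            m: {
                "count": c.get(m, 0),
                "percent": _round_half_up(100.0 * c.get(m, 0) / tot, 1) if tot else 0.0,
            }
            for m in MODES
        }

    result: dict = {
        "all": table(counts),
        "fraction_duplicated": _round_half_up(
            100.0 * (1.0 - counts["singleton"] / total), 0
        ),
    }

    if focal_counts is None and family_of is not None and focal_families is not None:
        focal_genes = {g for g, f in family_of.items() if f in focal_families}
        fc = {m: 0 for m in MODES}
        for g in focal_genes:
            fc[labeling.mode_of[g]] += 1
        focal_counts = fc
    if focal_counts is not None:
        focal_counts = {m: int(focal_counts.get(m, 0)) for m in MODES}
        result["focal"] = table(focal_counts)

    fams: list[FamilyCounts] = []
    if family_of is not None:
        by_family: dict[str, dict[str, int]] = {}
        for g, fam in family_of.items():
            if g in labeling.mode_of:
                by_family.setdefault(fam, {m: 0 for m in MODES})
                by_family[fam][labeling.mode_of[g]] += 1
        tandem_pairs: dict[str, int] = {}
        for a, b, mode in labeling.pairs:
            if mode == "tandem" and family_of.get(a) == family_of.get(b) \
                    and family_of.get(a) is not None:
                tandem_pairs[family_of[a]] = tandem_pairs.get(family_of[a], 0) + 1
        for fam in sorted(by_family):
            obs = by_family[fam]
            fams.append(
                FamilyCounts(
                    family=fam, N=sum(obs.values()), observed=obs,
                    observed_tandem_pairs=tandem_pairs.get(fam, 0),
                )
            )
    result["families"] = fams
    return result
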