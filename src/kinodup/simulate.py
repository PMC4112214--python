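"""Synthetic genomes with planted duplication histories and full ground truth.

The generator builds a multi-chromosome gene order, applies a configured
number of duplication events of each mode, and records the complete truth:
per-gene modes, typed duplicate pairs, the collinear blocks implied by
segmental events, family membership and the event log.  Downstream
generators derive homology hits, per-family phylogenies, expression
profiles, phenotype labels and interaction edges from that truth, so every
pipeline stage can be tested against a known answer.

Event semantics (mirroring the classifier's rules):

* ``tandem`` — the copy is inserted at rank distance 1 from its source;
* ``proximal`` — the copy lands 2..20 ranks away on the same chromosome;
* ``wgd_segmental`` — a run of ``block_length`` consecutive genes is copied
  to another location preserving order, emitting a collinear block;
* ``transposed`` — the copy moves to a different chromosome; the source
  stays at the (outgroup-supported) ancestral locus and is itself recorded
  as dispersed, matching the classifier's fall-through;
* ``dispersed`` — the copy lands at least 21 ranks from its source (or on
  another chromosome) with no block evidence.

Each gene participates in at most one event, so the planted mode of every
gene is unambiguous.  All generators are pure functions of (config, seed):
per-generator random substreams are derived deterministically from the one
seed in the config.

Gene length is fixed at 1 kb and coordinates are re-spaced uniformly after
all events, mirroring the idealised-genome geometry of the tandem null
model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from kinodup.io import CollinearBlock, GeneRecord, GenomeTable, HomologyHit, ValidationError

GENE_LENGTH_BP = 1000
GENE_SPACING_BP = 2000

_SUBSTREAM = {
    "genome": 0, "hits": 1, "expression": 2,
    "trees": 3, "phenotypes": 4, "interactions": 5,
}

PHENOTYPE_CLASSES = (
    "conditional", "morphological", "essential", "cellular_biochemical", "none",
)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _SUBSTREAM[stream]])


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults model a 3000-gene genome carrying 50 duplication events of
    every mode: 2550 ancestral genes on 5 chromosomes plus 250 genes copied
    by 50 segmental blocks of length 5 and 50 single-gene copies of each of
    the four remaining modes.  Default per-mode expression correlations
    follow the qualitative ordering seen in real duplicate pairs —
    strongest conservation for segmental duplicates, weakest for
    transposed ones.  Phenotype class frequencies approximate a genome
    where roughly 8.5% of genes have a detectable loss-of-function
    phenotype, distributed over conditional > morphological > essential >
    cellular/biochemical classes.
    """

    n_chromosomes: int = 5
    genome_length: int = 30_000_000
    n_ancestral_genes: int = 2550
    family_size_spec: dict[str, int] = field(
        default_factory=lambda: {f"fam{i:02d}": 30 for i in range(1, 21)}
    )
    event_counts: dict[str, int] = field(
        default_factory=lambda: {
            "wgd_segmental": 50, "tandem": 50, "proximal": 50,
            "transposed": 50, "dispersed": 50,
        }
    )
    block_length: int = 5
    expression_samples: int = 500
    rho_by_mode: dict[str, float] = field(
        default_factory=lambda: {
            "wgd_segmental": 0.7, "tandem": 0.4, "proximal": 0.1,
            "transposed": 0.0, "dispersed": 0.0,
        }
    )
    phenotype_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "conditional": 0.038, "morphological": 0.025, "essential": 0.015,
            "cellular_biochemical": 0.007, "none": 0.915,
        }
    )
    #: source-sampling weight multipliers per family for tandem events,
    #: used to plant family-level tandem enrichment.
    tandem_boost_by_family: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        total_p = sum(self.phenotype_class_probs.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ValidationError(f"phenotype class probabilities sum to {total_p}, not 1")
        for mode, rho in self.rho_by_mode.items():
            if not -1.0 <= rho <= 1.0:
                raise ValidationError(f"rho_by_mode[{mode}]={rho} outside [-1, 1]")
        if any(c < 0 for c in self.event_counts.values()):
            raise ValidationError("event counts must be >= 0")


@dataclass
class GroundTruth:
    """The planted-event record: the oracle for every downstream stage."""

    true_mode: dict[str, str]
    true_pairs: list[tuple[str, str, str, str | None]]
    planted_blocks: list[CollinearBlock]
    family_of: dict[str, str]
    event_log: list[dict]
    seed: int = 0

    @property
    def outgroup_anchored(self) -> set[str]:
        """Ancestral loci of transposed events (outgroup-supported)."""
        return {anc for _, _, mode, anc in self.true_pairs
                if mode == "transposed" and anc is not None}

    def pairs_by_mode(self, mode: str) -> list[tuple[str, str]]:
        return [(a, b) for a, b, m, _ in self.true_pairs if m == mode]


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(config: SyntheticConfig) -> tuple[GenomeTable, GroundTruth]:
    """Build the synthetic genome and its ground truth.

    Deterministic under ``config.seed``.  Raises :class:`ValidationError`
    when the requested events exceed placeable capacity (too few ancestral
    genes, or transposed events on a single-chromosome genome).
    """
    rng = _rng(config.seed, "genome")
    ev = {m: int(config.event_counts.get(m, 0)) for m in
          ("wgd_segmental", "tandem", "proximal", "transposed", "dispersed")}
    n_seg_src = ev["wgd_segmental"] * config.block_length
    n_single_src = ev["tandem"] + ev["proximal"] + ev["transposed"] + ev["dispersed"]
    if n_seg_src + n_single_src > config.n_ancestral_genes:
        raise ValidationError(
            f"{n_seg_src + n_single_src} event source genes requested but only "
            f"{config.n_ancestral_genes} ancestral genes available"
        )
    if ev["transposed"] > 0 and config.n_chromosomes < 2:
        raise ValidationError("transposed events need >= 2 chromosomes")

    n = config.n_ancestral_genes
    width = max(4, len(str(n + n_seg_src + n_single_src)))
    anc_ids = [f"g{i:0{width}d}" for i in range(n)]
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    # contiguous even split of ancestral genes over chromosomes
    bounds = np.linspace(0, n, config.n_chromosomes + 1).astype(int)
    order: dict[str, list[str]] = {
        c: anc_ids[bounds[i]:bounds[i + 1]] for i, c in enumerate(chrom_names)
    }

    # family assignment: random genes per family, remainder in "bg";
    # copies inherit their source's family
    family_of: dict[str, str] = {g: "bg" for g in anc_ids}
    fam_total = sum(config.family_size_spec.values())
    if fam_total > n:
        raise ValidationError("family sizes exceed ancestral gene count")
    assigned = rng.choice(n, size=fam_total, replace=False)
    cursor = 0
    for fam in sorted(config.family_size_spec):
        size = config.family_size_spec[fam]
        for idx in assigned[cursor:cursor + size]:
            family_of[anc_ids[idx]] = fam
        cursor += size

    used: set[str] = set()
    true_mode: dict[str, str] = {}
    true_pairs: list[tuple[str, str, str, str | None]] = []
    planted_blocks: list[CollinearBlock] = []
    event_log: list[dict] = []
    copy_counter = itertools.count()

    def new_copy_id() -> str:
        return f"c{next(copy_counter):0{width}d}"

    def chrom_of(gene: str) -> str:
        for c, genes in order.items():
            if gene in genes:
                return c
        raise KeyError(gene)

    def splits_critical_pair(chrom: str, slot: int) -> bool:
        """Would inserting at ``slot`` break a planted tandem pair or push a
        proximal pair past the 20-rank window?"""
        genes = order[chrom]
        pos = {g: i for i, g in enumerate(genes)}
        for a, b, mode, _ in true_pairs:
            if mode == "tandem":
                if a in pos and b in pos:
                    lo, hi = sorted((pos[a], pos[b]))
                    if lo < slot <= hi:
                        return True
            elif mode == "proximal":
                if a in pos and b in pos:
                    lo, hi = sorted((pos[a], pos[b]))
                    if hi - lo >= 20 and lo < slot <= hi:
                        return True
        return False

    # --- segmental: reserve disjoint source runs on the initial layout ----
    run_starts: list[tuple[str, int]] = []
    reserved: set[str] = set()
    candidates = [
        (c, i)
        for c in chrom_names
        for i in range(len(order[c]) - config.block_length + 1)
    ]
    rng.shuffle(candidates)
    for c, i in candidates:
        if len(run_starts) == ev["wgd_segmental"]:
            break
        run = order[c][i:i + config.block_length]
        if any(g in reserved for g in run):
            continue
        run_starts.append((c, i))
        reserved.update(run)
    if len(run_starts) < ev["wgd_segmental"]:
        raise ValidationError("cannot place the requested segmental source runs")
    run_genes = [
        order[c][i:i + config.block_length] for c, i in run_starts
    ]
    for k, (src_run, (src_chrom, _)) in enumerate(zip(run_genes, run_starts)):
        copies = [new_copy_id() for _ in src_run]
        dst_chrom = chrom_names[rng.integers(len(chrom_names))]
        slot = int(rng.integers(len(order[dst_chrom]) + 1))
        order[dst_chrom][slot:slot] = copies
        anchor_pairs = list(zip(src_run, copies))
        planted_blocks.append(
            CollinearBlock(
                block_id=str(k), anchor_pairs=anchor_pairs,
                chrom_pair=(src_chrom, dst_chrom),
            )
        )
        for s, c_ in anchor_pairs:
            used.update((s, c_))
            true_mode[s] = true_mode[c_] = "wgd_segmental"
            family_of[c_] = family_of[s]
            true_pairs.append((s, c_, "wgd_segmental", None))
        event_log.append({"mode": "wgd_segmental", "source": list(src_run),
                          "copy": copies, "block_id": str(k)})

    free = [g for g in anc_ids if g not in used]

    def take_source(weights: Mapping[str, float] | None = None) -> str:
        if not free:
            raise ValidationError("ran out of ancestral source genes")
        if weights:
            w = np.array([weights.get(family_of[g], 1.0) for g in free], float)
            idx = rng.choice(len(free), p=w / w.sum())
        else:
            idx = rng.integers(len(free))
        return free.pop(int(idx))

    # --- transposed -------------------------------------------------------
    for _ in range(ev["transposed"]):
        src = take_source()
        src_chrom = chrom_of(src)
        others = [c for c in chrom_names if c != src_chrom]
        dst = others[rng.integers(len(others))]
        slot = int(rng.integers(len(order[dst]) + 1))
        copy = new_copy_id()
        order[dst][slot:slot] = [copy]
        used.update((src, copy))
        true_mode[src] = "dispersed"     # ancestral locus; see classifier rule 6
        true_mode[copy] = "transposed"
        family_of[copy] = family_of[src]
        true_pairs.append((src, copy, "transposed", src))
        event_log.append({"mode": "transposed", "source": src, "copy": copy})

    # --- dispersed --------------------------------------------------------
    for _ in range(ev["dispersed"]):
        src = take_source()
        src_chrom = chrom_of(src)
        copy = new_copy_id()
        slots: list[tuple[str, int]] = []
        for c in chrom_names:
            if c == src_chrom:
                i = order[c].index(src)
                for s in range(len(order[c]) + 1):
                    d = s - i if s > i else i + 1 - s
                    if d >= 21:
                        slots.append((c, s))
            else:
                slots.extend((c, s) for s in range(len(order[c]) + 1))
        if not slots:
            raise ValidationError("no placement >= 21 ranks away for dispersed copy")
        c, s = slots[rng.integers(len(slots))]
        order[c][s:s] = [copy]
        used.update((src, copy))
        true_mode[src] = true_mode[copy] = "dispersed"
        family_of[copy] = family_of[src]
        true_pairs.append((src, copy, "dispersed", None))
        event_log.append({"mode": "dispersed", "source": src, "copy": copy})

    # --- proximal ---------------------------------------------------------
    for _ in range(ev["proximal"]):
        placed = False
        for _attempt in range(200):
            src = take_source()
            c = chrom_of(src)
            i = order[c].index(src)
            d = int(rng.integers(2, 21))
            options = []
            if i + d <= len(order[c]):
                options.append(i + d)
            if i + 1 - d >= 0:
                options.append(i + 1 - d)
            rng.shuffle(options)
            slot = next(
                (s for s in options if not splits_critical_pair(c, s)), None
            )
            if slot is None:
                free.append(src)  # put back, retry with another source
                continue
            copy = new_copy_id()
            order[c][slot:slot] = [copy]
            used.update((src, copy))
            true_mode[src] = true_mode[copy] = "proximal"
            family_of[copy] = family_of[src]
            true_pairs.append((src, copy, "proximal", None))
            event_log.append({"mode": "proximal", "source": src, "copy": copy})
            placed = True
            break
        if not placed:
            raise ValidationError("could not place a proximal event")

    # --- tandem (last: nothing may later split an adjacent pair) ----------
    for _ in range(ev["tandem"]):
        placed = False
        for _attempt in range(200):
            src = take_source(config.tandem_boost_by_family or None)
            c = chrom_of(src)
            slot = order[c].index(src) + 1
            if splits_critical_pair(c, slot):
                free.append(src)
                continue
            copy = new_copy_id()
            order[c][slot:slot] = [copy]
            used.update((src, copy))
            true_mode[src] = true_mode[copy] = "tandem"
            family_of[copy] = family_of[src]
            true_pairs.append((src, copy, "tandem", None))
            event_log.append({"mode": "tandem", "source": src, "copy": copy})
            placed = True
            break
        if not placed:
            raise ValidationError("could not place a tandem event")

    # --- finalize: singletons, uniform coordinate re-spacing --------------
    records: list[GeneRecord] = []
    for c in chrom_names:
        for i, g in enumerate(order[c]):
            true_mode.setdefault(g, "singleton")
            start = 1 + i * GENE_SPACING_BP
            records.append(
                GeneRecord(g, c, start, start + GENE_LENGTH_BP - 1, "+")
            )
    genome = GenomeTable(
        records,
        chromosome_lengths={c: config.genome_length for c in chrom_names},
    )
    truth = GroundTruth(
        true_mode=true_mode, true_pairs=true_pairs,
        planted_blocks=planted_blocks, family_of=family_of,
        event_log=event_log, seed=config.seed,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# derived data generators
# ---------------------------------------------------------------------------

def generate_hits(
    truth: GroundTruth, noise: float = 0.0, seed: int | None = None
) -> list[HomologyHit]:
    """Homology hits: a reciprocal below-cutoff hit per true pair, plus
    ``noise``-rate spurious hits between random unrelated genes with
    E-values straddling the 1e-5 cutoff (log-uniform over 1e-8..1e-3).
    """
    if not 0 <= noise < 1:
        raise ValidationError("noise must be in [0, 1)")
    rng = _rng(truth.seed if seed is None else seed, "hits")
    hits: list[HomologyHit] = []
    for a, b, _, _ in truth.true_pairs:
        e = 10.0 ** rng.uniform(-50, -10)
        hits.append(HomologyHit(a, b, e))
        hits.append(HomologyHit(b, a, e))
    genes = sorted(truth.true_mode)
    paired = {frozenset((a, b)) for a, b, _, _ in truth.true_pairs}
    n_spurious = int(noise * 2 * len(truth.true_pairs))
    made = 0
    while made < n_spurious:
        a, b = rng.choice(len(genes), size=2, replace=False)
        ga, gb = genes[int(a)], genes[int(b)]
        if frozenset((ga, gb)) in paired:
            continue
        e = 10.0 ** rng.uniform(-8, -3)
        hits.append(HomologyHit(ga, gb, e))
        made += 1
    return hits


def generate_expression(
    truth: GroundTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Expression profiles whose pairwise correlation encodes duplication mode.

    Ancestral genes get independent standard-normal profiles; each copy's
    profile is ``rho * source + sqrt(1 - rho^2) * noise`` with ``rho``
    taken from ``config.rho_by_mode`` for the pair's mode, so the expected
    sample Pearson correlation of a planted pair equals ``rho``.
    """
    s = config.expression_samples
    if s < 3:
        raise ValidationError("need >= 3 expression samples")
    rng = _rng(config.seed, "expression")
    genes = sorted(truth.true_mode)
    profiles: dict[str, np.ndarray] = {}
    copy_of = {b: (a, m) for a, b, m, _ in truth.true_pairs}
    for g in genes:
        if g not in copy_of:
            profiles[g] = rng.standard_normal(s)
    for g in genes:
        if g in copy_of:
            src, mode = copy_of[g]
            rho = float(config.rho_by_mode.get(mode, 0.0))
            profiles[g] = rho * profiles[src] + np.sqrt(1 - rho**2) * rng.standard_normal(s)
    arr = np.vstack([profiles[g] for g in genes])
    return pd.DataFrame(arr, index=genes, columns=[f"s{j:03d}" for j in range(s)])


def generate_family_tree(truth: GroundTruth, family: str) -> dendropy.Tree:
    """Phylogeny of one family encoding the planted event order.

    Ancestral members start as children of the root; each event replaces
    its source leaf with a cherry ``(source, copy)``, so the MRCA of every
    planted pair is exactly the node created by its event.
    """
    members = sorted(g for g, f in truth.family_of.items() if f == family)
    if not members:
        raise ValidationError(f"family {family!r} has no members")
    member_set = set(members)
    copies = set()
    for entry in truth.event_log:
        cs = entry["copy"] if isinstance(entry["copy"], list) else [entry["copy"]]
        copies.update(cs)
    founders = [g for g in members if g not in copies]

    taxa = dendropy.TaxonNamespace(members)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    leaf_of: dict[str, dendropy.Node] = {}
    for g in founders:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(g)
        tree.seed_node.add_child(node)
        leaf_of[g] = node
    for entry in truth.event_log:
        srcs = entry["source"] if isinstance(entry["source"], list) else [entry["source"]]
        cs = entry["copy"] if isinstance(entry["copy"], list) else [entry["copy"]]
        for s_, c_ in zip(srcs, cs):
            if s_ not in member_set:
                continue
            old = leaf_of[s_]
            old.taxon = None
            for g2, tax in ((s_, taxa.get_taxon(s_)), (c_, taxa.get_taxon(c_))):
                child = dendropy.Node()
                child.taxon = tax
                old.add_child(child)
                leaf_of[g2] = child
    return tree


def generate_phenotypes(
    truth: GroundTruth,
    config: SyntheticConfig,
    focal: set[str] | None = None,
    boost_class: str | None = None,
    boost: float = 0.0,
) -> dict[str, str]:
    """Phenotype class labels with an optional planted focal-set enrichment.

    Background genes draw their class from ``config.phenotype_class_probs``.
    A focal gene is assigned ``boost_class`` directly with probability
    ``boost`` and otherwise drawn from the background distribution, so
    ``boost = 1`` labels the whole focal set with the boosted class.
    """
    rng = _rng(config.seed, "phenotypes")
    classes = list(config.phenotype_class_probs)
    probs = np.array([config.phenotype_class_probs[c] for c in classes])
    focal = focal or set()
    out: dict[str, str] = {}
    for g in sorted(truth.true_mode):
        if g in focal and boost_class is not None and rng.random() < boost:
            out[g] = boost_class
        else:
            out[g] = classes[int(rng.choice(len(classes), p=probs))]
    return out


def generate_interactions(
    truth: GroundTruth,
    config: SyntheticConfig,
    mean_degree: float = 4.7,
    n_hubs: int = 0,
    hub_degree: int = 25,
    focal: set[str] | None = None,
) -> list[tuple[str, str]]:
    """Undirected interaction edges with Poisson focal degrees and optional hubs.

    Each focal gene is wired to a Poisson(``mean_degree``) number of
    distinct partners drawn from the non-focal background (emulating a
    bait-centred interactome, where most partners of the focal set lie
    outside it), so the focal-set mean degree equals ``mean_degree`` in
    expectation.  When the focal set spans (almost) the whole gene set the
    partner pool falls back to all other genes.  Planted hubs are wired to
    exactly ``hub_degree`` distinct partners.
    """
    rng = _rng(config.seed, "interactions")
    genes = sorted(truth.true_mode)
    focal_genes = sorted(focal) if focal else genes
    focal_set = set(focal_genes)
    hubs = list(rng.choice(focal_genes, size=n_hubs, replace=False)) if n_hubs else []
    hub_set = set(hubs)
    background = [g for g in genes if g not in focal_set and g not in hub_set]
    edges: set[frozenset[str]] = set()

    def pool_for(g: str, need: int) -> list[str]:
        pool = background if len(background) >= need else \
            [x for x in genes if x not in hub_set]
        return [x for x in pool if x != g]

    for h in hubs:
        partners = rng.choice(pool_for(h, hub_degree), size=hub_degree, replace=False)
        for p in partners:
            edges.add(frozenset((h, p)))
    for g in focal_genes:
        if g in hub_set:
            continue
        d = int(rng.poisson(mean_degree))
        if d == 0:
            continue
        pool = pool_for(g, d)
        partners = rng.choice(pool, size=min(d, len(pool)), replace=False)
        for p in partners:
            edges.add(frozenset((g, p)))
    return sorted(tuple(sorted(str(x) for x in e)) for e in edges)


#: class frequencies among genes with a detectable loss-of-function
#: phenotype (conditional > morphological > essential > biochemical).
PHENOTYPED_CLASS_PROBS = {
    "conditional": 0.45, "morphological": 0.29,
    "essential": 0.18, "cellular_biochemical": 0.08,
}


def odds_boosted_prob(base_prob: float, odds_ratio: float) -> float:
    """Probability whose odds are ``odds_ratio`` times the base odds."""
    odds = base_prob / (1.0 - base_prob) * odds_ratio
    return odds / (1.0 + odds)


def sample_phenotypes(
    n_genes: int,
    n_focal: int,
    class_probs: Mapping[str, float] | None = None,
    boost_class: str | None = None,
    odds_ratio: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, str], set[str]]:
    """Sample phenotype labels with an optional odds-ratio enrichment of
    one class among the first ``n_focal`` genes.

    Returns ``(phenotype_of, focal_set)`` — the substrate for enrichment
    power and null calibration studies.
    """
    probs = dict(class_probs or PHENOTYPED_CLASS_PROBS)
    classes = list(probs)
    p = np.array([probs[c] for c in classes], float)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    phen: dict[str, str] = {}
    focal = {f"g{i:05d}" for i in range(n_focal)}
    if boost_class is not None:
        pe = odds_boosted_prob(probs[boost_class], odds_ratio)
        q = p.copy()
        q[classes.index(boost_class)] = 0.0
        q = q / q.sum()
    for i in range(n_genes):
        g = f"g{i:05d}"
        if g in focal and boost_class is not None:
            if rng.random() < pe:
                phen[g] = boost_class
            else:
                phen[g] = classes[int(rng.choice(len(classes), p=q))]
        else:
            phen[g] = classes[int(rng.choice(len(classes), p=p))]
    return phen, focal


def sample_mode_counts(
    family_sizes: Mapping[str, int],
    base_probs: Mapping[str, float],
    boost: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a family x mode count matrix gene-by-gene from per-mode
    probabilities — the lightweight substrate for enrichment power and
    false-positive-rate studies.

    A ``boost`` entry ``(family, mode): b`` sets that family's rate for the
    mode to exactly ``b`` times the background rate (capped at 1); the
    remaining modes share the leftover probability proportionally.
    """
    rng = np.random.default_rng(seed)
    boost = boost or {}
    modes = list(base_probs)
    base = np.array([base_probs[m] for m in modes], float)
    base = base / base.sum()
    rows = {}
    for fam in sorted(family_sizes):
        p = base.copy()
        boosted = [j for j, m in enumerate(modes) if (fam, m) in boost]
        if boosted:
            for j in boosted:
                p[j] = min(base[j] * boost[(fam, modes[j])], 1.0)
            rest = [j for j in range(len(modes)) if j not in boosted]
            spare = 1.0 - p[boosted].sum()
            if spare < 0:
                raise ValidationError(f"boosted rates for {fam} exceed 1")
            p[rest] = base[rest] * (spare / base[rest].sum())
        counts = rng.multinomial(family_sizes[fam], p)
        rows[fam] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=modes)
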