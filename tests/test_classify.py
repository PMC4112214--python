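"""Classifier unit tests, the brute-force rule oracle, and summary arithmetic."""

import pytest

from conftest import small_config
from kinodup.classify import (
    ClassificationParams,
    DuplicationLabeling,
    classify_duplications,
    compute_duplication_depth,
    tabulate_summary,
)
from kinodup.io import (
    CollinearBlock,
    GeneRecord,
    GenomeTable,
    HomologyHit,
    ValidationError,
    filter_hits,
)
from kinodup.simulate import generate_genome, generate_hits

PRECEDENCE = ("wgd_segmental", "tandem", "proximal", "transposed", "dispersed")


def chain_genome(n, chrom="chr1"):
    return GenomeTable(
        [GeneRecord(f"g{i}", chrom, 1 + i * 1000, 500 + i * 1000) for i in range(n)]
    )


def hits_for(*pairs):
    out = []
    for a, b in pairs:
        out.append(HomologyHit(a, b, 1e-20))
        out.append(HomologyHit(b, a, 1e-20))
    return out


def brute_force_modes(genome, hits, blocks, anchored=None, max_prox=20):
    """Independent rule evaluation by exhaustive pair enumeration.

    Recomputes gene order from raw coordinates and applies the six rules
    pair by pair without any of the library's data structures.
    """
    anchored = anchored or set()
    genes = sorted(
        [(g.gene_id, g.chromosome, g.start) for g in genome],
        key=lambda t: (t[1], t[2], t[0]),
    )
    pos = {}
    for chrom in {c for _, c, _ in genes}:
        on = [gid for gid, c, _ in genes if c == chrom]
        for i, gid in enumerate(on):
            pos[gid] = (chrom, i)
    in_block = {}
    for blk in blocks:
        for a, b in blk.anchor_pairs:
            in_block.setdefault(a, set()).add(blk.block_id)
            in_block.setdefault(b, set()).add(blk.block_id)
    pairs = set()
    for h in hits:
        pairs.add(tuple(sorted((h.query, h.subject))))
    for blk in blocks:
        for a, b in blk.anchor_pairs:
            pairs.add(tuple(sorted((a, b))))
    rank = {m: i for i, m in enumerate(PRECEDENCE)}
    mode = {}

    def vote(g, m):
        if g not in mode or rank[m] < rank[mode[g]]:
            mode[g] = m

    for g in in_block:
        vote(g, "wgd_segmental")
    for a, b in sorted(pairs):
        if in_block.get(a, set()) & in_block.get(b, set()):
            continue
        ca, ia = pos[a]
        cb, ib = pos[b]
        if ca == cb and abs(ia - ib) == 1:
            vote(a, "tandem"); vote(b, "tandem")
        elif ca == cb and abs(ia - ib) <= max_prox:
            vote(a, "proximal"); vote(b, "proximal")
        elif (a in anchored) != (b in anchored):
            anc, tr = (a, b) if a in anchored else (b, a)
            vote(tr, "transposed"); vote(anc, "dispersed")
        else:
            vote(a, "dispersed"); vote(b, "dispersed")
    return {g.gene_id: mode.get(g.gene_id, "singleton") for g in genome}


class TestRules:
    def test_adjacent_homologs_are_tandem(self):
        lab = classify_duplications(chain_genome(10), hits_for(("g4", "g5")), [])
        assert lab.mode_of["g4"] == lab.mode_of["g5"] == "tandem"

    def test_near_homologs_are_proximal(self):
        lab = classify_duplications(chain_genome(12), hits_for(("g4", "g10")), [])
        assert lab.mode_of["g4"] == lab.mode_of["g10"] == "proximal"

    def test_beyond_window_is_dispersed(self):
        lab = classify_duplications(chain_genome(30), hits_for(("g0", "g25")), [])
        assert lab.mode_of["g0"] == lab.mode_of["g25"] == "dispersed"

    def test_no_evidence_is_singleton(self):
        lab = classify_duplications(chain_genome(3), [], [])
        assert set(lab.mode_of.values()) == {"singleton"}

    def test_block_precedence_beats_adjacency(self):
        blocks = [CollinearBlock("0", [("g4", "g5"), ("g6", "g7")], ("chr1", "chr1"))]
        lab = classify_duplications(chain_genome(10), hits_for(("g4", "g5")), blocks)
        assert lab.mode_of["g4"] == lab.mode_of["g5"] == "wgd_segmental"

    def test_transposed_requires_anchored_set(self):
        genome = GenomeTable(
            [GeneRecord("a", "chr1", 1, 500), GeneRecord("b", "chr2", 1, 500)]
        )
        lab = classify_duplications(genome, hits_for(("a", "b")), [])
        assert lab.mode_of["a"] == lab.mode_of["b"] == "dispersed"
        lab = classify_duplications(genome, hits_for(("a", "b")), [],
                                    outgroup_anchored={"a"})
        assert lab.mode_of["b"] == "transposed"
        assert lab.mode_of["a"] == "dispersed"
        assert lab.ancestral_of == {"b": "a"}

    def test_tandem_array_transitivity(self):
        genome = chain_genome(8)
        lab = classify_duplications(
            genome, hits_for(("g2", "g3"), ("g3", "g4"), ("g2", "g4")), []
        )
        assert all(lab.mode_of[g] == "tandem" for g in ("g2", "g3", "g4"))

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValidationError, match="absent"):
            classify_duplications(chain_genome(3), hits_for(("g0", "nope")), [])

    def test_exhaustive_and_exclusive(self, study_genome):
        _, genome, truth = study_genome
        hits = filter_hits(generate_hits(truth))
        lab = classify_duplications(genome, hits, truth.planted_blocks,
                                    truth.outgroup_anchored)
        assert set(lab.mode_of) == {g.gene_id for g in genome}
        assert sum(lab.counts().values()) == len(genome)

    def test_precedence_monotone_under_added_block(self):
        genome = chain_genome(10)
        hits = hits_for(("g4", "g5"))
        before = classify_duplications(genome, hits, []).mode_of
        blocks = [CollinearBlock("0", [("g4", "g5"), ("g8", "g9")], ("chr1", "chr1"))]
        after = classify_duplications(genome, hits, blocks).mode_of
        rank = {m: i for i, m in enumerate(PRECEDENCE + ("singleton",))}
        for g in ("g4", "g5", "g8", "g9"):
            assert rank[after[g]] <= rank[before[g]]


class TestGroundTruthRecovery:
    def test_noise_free_recovery_is_exact(self):
        cfg = small_config(seed=21)
        genome, truth = generate_genome(cfg)
        hits = filter_hits(generate_hits(truth, noise=0.0))
        lab = classify_duplications(genome, hits, truth.planted_blocks,
                                    truth.outgroup_anchored)
        assert lab.mode_of == truth.true_mode

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        cfg = small_config(
            seed=seed, n_ancestral_genes=160,
            event_counts={"wgd_segmental": 3, "tandem": 4, "proximal": 4,
                          "transposed": 3, "dispersed": 3},
        )
        genome, truth = generate_genome(cfg)
        hits = filter_hits(generate_hits(truth, noise=0.1))
        lab = classify_duplications(genome, hits, truth.planted_blocks,
                                    truth.outgroup_anchored)
        oracle = brute_force_modes(genome, hits, truth.planted_blocks,
                                   truth.outgroup_anchored)
        assert lab.mode_of == oracle


class TestDuplicationDepth:
    def test_gene_in_two_blocks_has_depth_two(self):
        genome = chain_genome(10)
        blocks = [
            CollinearBlock("0", [("g1", "g5"), ("g2", "g6")], ("chr1", "chr1")),
            CollinearBlock("1", [("g1", "g8"), ("g2", "g9")], ("chr1", "chr1")),
        ]
        depth, med, mx = compute_duplication_depth(genome, blocks)
        assert depth["g1"] == 2 and mx == 2

    def test_all_depth_one(self):
        genome = chain_genome(6)
        blocks = [CollinearBlock("0", [("g0", "g3"), ("g1", "g4")], ("chr1", "chr1"))]
        _, med, mx = compute_duplication_depth(genome, blocks)
        assert med == 1 and mx == 1

    def test_no_blocks_undefined(self):
        _, med, mx = compute_duplication_depth(chain_genome(3), [])
        assert med is None and mx is None


class TestSummaryArithmetic:
    ALL = {"wgd_segmental": 7496, "dispersed": 11779, "proximal": 1323,
           "tandem": 2875, "singleton": 5233}
    FOCAL = {"wgd_segmental": 335, "dispersed": 444, "proximal": 67,
             "tandem": 89, "singleton": 2}

    def summary(self):
        lab = DuplicationLabeling(mode_of={"g": "tandem"}, pairs=[])
        return tabulate_summary(lab, counts=self.ALL, focal_counts=self.FOCAL)

    def test_genome_wide_percentages(self):
        s = self.summary()
        assert s["all"]["wgd_segmental"]["percent"] == 26.1
        assert s["all"]["dispersed"]["percent"] == 41.0
        assert s["all"]["proximal"]["percent"] == 4.6
        assert s["all"]["tandem"]["percent"] == 10.0
        assert s["all"]["singleton"]["percent"] == 18.2

    def test_focal_percentages(self):
        s = self.summary()
        assert s["focal"]["tandem"]["percent"] == 9.5
        assert s["focal"]["dispersed"]["percent"] == 47.4
        assert s["focal"]["proximal"]["percent"] == 7.2
        assert s["focal"]["singleton"]["percent"] == 0.2

    def test_fraction_duplicated_headline(self):
        assert self.summary()["fraction_duplicated"] == 82

    def test_uniform_counts(self):
        lab = DuplicationLabeling(mode_of={"g": "tandem"}, pairs=[])
        s = tabulate_summary(
            lab, counts={m: 1 for m in ("wgd_segmental", "dispersed", "proximal",
                                        "tandem", "singleton")}
        )
        assert all(s["all"][m]["percent"] == 20.0 for m in s["all"]
                   if s["all"][m]["count"])

    def test_empty_labeling_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            tabulate_summary(DuplicationLabeling(mode_of={}, pairs=[]))
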