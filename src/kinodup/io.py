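"""Readers, writers and filters for the external file formats.

Everything downstream of this module consumes only the in-memory types
defined here: :class:`GenomeTable` (the gene-order backbone),
:class:`CollinearBlock` (within-genome syntenic blocks in the MCScanX
``.collinearity`` dialect), :class:`HomologyHit` (tabular BLAST-style
hits), :class:`ProfileAlignment` (a profile-HMM alignment with a
match-column mask) and plain pandas / dendropy containers for expression
matrices and trees.

Coordinates follow the GFF convention: 1-based, inclusive.  Gene-order
ranks are 0-based per chromosome, assigned by start coordinate (ties
broken by end, then gene id).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file violated its format; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a content invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One gene with 1-based inclusive coordinates and its order rank."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "?"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval {self.start}..{self.end}"
            )


class GenomeTable:
    """Ordered genes per chromosome; the coordinate backbone for classification.

    Parameters
    ----------
    genes
        Gene records; ranks are (re)assigned here from start coordinates,
        so the input order does not matter.
    chromosome_lengths
        Optional chromosome sizes in base pairs.
    """

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        chromosome_lengths: Mapping[str, int] | None = None,
    ) -> None:
        records = list(genes)
        if not records:
            raise ValidationError("no gene records")
        ids = [g.gene_id for g in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate gene_id(s): {', '.join(dup[:5])}")
        records.sort(key=lambda g: (g.chromosome, g.start, g.end, g.gene_id))
        self._by_chrom: dict[str, list[GeneRecord]] = {}
        for g in records:
            self._by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, gs in self._by_chrom.items():
            self._by_chrom[chrom] = [
                GeneRecord(g.gene_id, g.chromosome, g.start, g.end, g.strand, i)
                for i, g in enumerate(gs)
            ]
        self._by_id: dict[str, GeneRecord] = {
            g.gene_id: g for gs in self._by_chrom.values() for g in gs
        }
        self.chromosome_lengths = dict(chromosome_lengths or {})

    # -- access ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes_on(self, chromosome: str) -> list[GeneRecord]:
        """Genes on one chromosome in rank order."""
        return list(self._by_chrom.get(chromosome, []))

    def __iter__(self):
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def rank_distance(self, a: str, b: str) -> int | None:
        """Rank distance between two genes, or None if on different chromosomes."""
        ga, gb = self._by_id[a], self._by_id[b]
        if ga.chromosome != gb.chromosome:
            return None
        return abs(ga.rank - gb.rank)

    # -- I/O ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (g.gene_id, g.chromosome, g.start, g.end, g.strand, g.rank)
                for g in self
            ],
            columns=["gene_id", "chromosome", "start", "end", "strand", "rank"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().drop(columns="rank").to_csv(path, sep="\t", index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeTable):
            return NotImplemented
        return list(self) == list(other)


@dataclass
class CollinearBlock:
    """One within-genome collinear (syntenic) block of anchor gene pairs."""

    block_id: str
    anchor_pairs: list[tuple[str, str]]
    chrom_pair: tuple[str, str] = ("", "")
    score: float | None = None
    e_value: float | None = None

    def __post_init__(self) -> None:
        if len(self.anchor_pairs) < 2:
            raise ValidationError(
                f"block {self.block_id}: needs >= 2 anchor pairs, "
                f"got {len(self.anchor_pairs)}"
            )

    @property
    def anchor_genes(self) -> set[str]:
        return {g for pair in self.anchor_pairs for g in pair}


@dataclass(frozen=True)
class HomologyHit:
    """One directed homology hit (query, subject, E-value)."""

    query: str
    subject: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(f"negative e_value for {self.query}->{self.subject}")


@dataclass
class ProfileAlignment:
    """Aligned sequences plus a boolean mask of profile-HMM match columns."""

    sequences: dict[str, str]
    match_mask: Sequence[bool]

    def __post_init__(self) -> None:
        ncol = len(self.match_mask)
        for sid, seq in self.sequences.items():
            if len(seq) != ncol:
                raise ValidationError(
                    f"sequence {sid}: length {len(seq)} != mask length {ncol}"
                )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_gene_table(path: str | Path, format: str = "tsv") -> GenomeTable:
    """Read gene positions from GFF3 (``gene`` features) or 5-column TSV.

    The TSV dialect is ``gene_id  chromosome  start  end  strand`` with a
    header line.  Returns a :class:`GenomeTable` with ranks assigned.
    """
    path = Path(path)
    if format == "gff3":
        return _read_gff3(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    records: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValidationError("no gene records")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            gid, chrom, start, end, strand = parts
            try:
                records.append(GeneRecord(gid, chrom, int(start), int(end), strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return GenomeTable(records)


def _read_gff3(path: Path) -> GenomeTable:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            gid = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gid = kv[3:]
            if gid is None:
                raise ParseError(f"{path}:{lineno}: gene feature without ID attribute")
            try:
                records.append(GeneRecord(gid, chrom, int(start), int(end), strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return GenomeTable(records)


def read_collinearity(path: str | Path) -> list[CollinearBlock]:
    """Parse an MCScanX ``.collinearity`` file into blocks.

    Grammar: ``#`` comment header, then per block one
    ``## Alignment k: score=S e_value=E N=n chrA&chrB orient`` line followed
    by ``k-i: geneA geneB e`` anchor lines.  A mismatch between the header
    ``N`` and the anchor count is logged as a warning, not an error.
    """
    path = Path(path)
    blocks: list[CollinearBlock] = []
    header: dict | None = None
    pairs: list[tuple[str, str]] = []

    def flush() -> None:
        nonlocal header, pairs
        if header is None:
            return
        if header["n"] is not None and header["n"] != len(pairs):
            log.warning(
                "%s: block %s header N=%s but %d anchor lines",
                path, header["id"], header["n"], len(pairs),
            )
        blocks.append(
            CollinearBlock(
                block_id=header["id"],
                anchor_pairs=pairs,
                chrom_pair=header["chroms"],
                score=header["score"],
                e_value=header["e"],
            )
        )
        header, pairs = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("## Alignment"):
                flush()
                header = _parse_block_header(line, path, lineno)
                pairs = []
            elif line.startswith("#"):
                continue
            else:
                if header is None:
                    raise ParseError(f"{path}:{lineno}: anchor line before any '## Alignment' header")
                fields = line.split()
                # "k-i: geneA geneB e" — the leading index token may be split
                # by whitespace ("k- i:") in some MCScanX builds.
                if fields and fields[0].endswith("-") and len(fields) >= 2:
                    fields = [fields[0] + fields[1]] + fields[2:]
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: expected 'index: geneA geneB [e]'")
                pairs.append((fields[1], fields[2]))
    flush()
    return blocks


def _parse_block_header(line: str, path: Path, lineno: int) -> dict:
    # ## Alignment 0: score=450.0 e_value=1e-20 N=9 at1&at3 plus
    body = line[len("## Alignment"):].strip()
    try:
        idx, rest = body.split(":", 1)
        kv = {"score": None, "e": None, "n": None, "chroms": ("", "")}
        for tok in rest.split():
            if tok.startswith("score="):
                kv["score"] = float(tok[6:])
            elif tok.startswith("e_value="):
                kv["e"] = float(tok[8:])
            elif tok.startswith("N="):
                kv["n"] = int(tok[2:])
            elif "&" in tok:
                a, b = tok.split("&", 1)
                kv["chroms"] = (a, b)
        kv["id"] = idx.strip()
        return kv
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed block header") from exc


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick tree with gene ids as tip labels."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            preserve_underscores=True, suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ParseError(f"{path}: not parseable as newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"{path}: duplicate tip labels")
    return tree


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV expression matrix (gene ids in column 0)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicated gene ids in expression matrix")
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: expression matrix has no sample columns")
    if df.isna().all(axis=0).any():
        bad = df.columns[df.isna().all(axis=0)].tolist()
        raise ValidationError(f"{path}: sample column(s) entirely missing: {bad}")
    return df


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping gene_id -> label (family, phenotype, ...)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            gid, label = parts
            if gid in out and out[gid] != label:
                raise ValidationError(
                    f"{path}:{lineno}: conflicting labels for {gid}: "
                    f"{out[gid]!r} vs {label!r}"
                )
            out[gid] = label
    return out


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column TSV of undirected interaction edges."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            edges.append((parts[0], parts[1]))
    return edges


def read_hits(path: str | Path) -> list[HomologyHit]:
    """Read a 3-column TSV of homology hits (query, subject, e_value)."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                hits.append(HomologyHit(parts[0], parts[1], float(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.query}\t{h.subject}\t{h.e_value:g}\n")


def write_collinearity(blocks: Iterable[CollinearBlock], path: str | Path) -> None:
    """Write blocks in the MCScanX ``.collinearity`` dialect."""
    with open(path, "w") as fh:
        fh.write("############### Parameters ###############\n")
        for blk in blocks:
            score = f"score={blk.score:g}" if blk.score is not None else "score=0"
            ev = f"e_value={blk.e_value:g}" if blk.e_value is not None else "e_value=0"
            fh.write(
                f"## Alignment {blk.block_id}: {score} {ev} "
                f"N={len(blk.anchor_pairs)} {blk.chrom_pair[0]}&{blk.chrom_pair[1]} plus\n"
            )
            for i, (a, b) in enumerate(blk.anchor_pairs):
                fh.write(f"{blk.block_id}-{i}: {a} {b} 0\n")


def read_profile_alignment(fasta_path: str | Path, mask_path: str | Path) -> ProfileAlignment:
    """Read a FASTA alignment plus a sidecar mask file (one 0/1 per column)."""
    seqs: dict[str, str] = {}
    sid = None
    chunks: list[str] = []
    with open(fasta_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if sid is not None:
                    seqs[sid] = "".join(chunks)
                sid = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if sid is not None:
        seqs[sid] = "".join(chunks)
    mask_text = Path(mask_path).read_text().split()
    mask = [bool(int(tok)) for tok in "".join(mask_text)]
    return ProfileAlignment(seqs, mask)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Sequence[HomologyHit], max_e: float = 1e-5, top_k: int = 5
) -> list[HomologyHit]:
    """Apply the hit filter: drop self-hits, keep per-query hits with
    ``e_value <= max_e``, sorted ascending by E-value and truncated to the
    ``top_k`` best.  Ties at the boundary are broken by subject id so the
    output is deterministic.  Idempotent.
    """
    if max_e <= 0:
        raise ValueError("max_e must be > 0")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    per_query: dict[str, list[HomologyHit]] = {}
    order: list[str] = []
    for h in hits:
        if h.query == h.subject:
            continue
        if h.e_value > max_e:
            continue
        if h.query not in per_query:
            order.append(h.query)
        per_query.setdefault(h.query, []).append(h)
    out: list[HomologyHit] = []
    for q in order:
        kept = sorted(per_query[q], key=lambda h: (h.e_value, h.subject))
        out.extend(kept[:top_k])
    return out


def filter_alignment_coverage(
    aln: ProfileAlignment, threshold: float = 0.70
) -> tuple[ProfileAlignment, dict[str, float]]:
    """Remove sequences covering less than ``threshold`` of the profile
    match columns.

    Coverage of a sequence is the fraction of match columns where it has a
    non-gap residue.  Sequences with coverage strictly below the threshold
    are removed; a sequence exactly at the threshold is retained.  Returns
    the retained alignment and a coverage report over all input sequences.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    match_cols = [i for i, m in enumerate(aln.match_mask) if m]
    if not match_cols:
        raise ValidationError("alignment has zero match columns")
    report: dict[str, float] = {}
    kept: dict[str, str] = {}
    for sid, seq in aln.sequences.items():
        cov = sum(1 for i in match_cols if seq[i] != "-") / len(match_cols)
        report[sid] = cov
        if cov >= threshold:
            kept[sid] = seq
    return ProfileAlignment(kept, list(aln.match_mask)), report
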