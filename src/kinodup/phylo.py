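"""Clade-based annotation of unlabeled genes and MRCA mapping of duplicate
pairs on a phylogeny."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import pandas as pd

from kinodup.io import ValidationError

log = logging.getLogger(__name__)


@dataclass
class AnnotationProposal:
    """Proposed family for one unlabeled tip, with its evidence.

    ``evidence`` is "sister-clade unanimity" when the tip's sister clade is
    unanimously labeled, "clade majority" when the smallest enclosing
    labeled clade has a >50% majority, and "ambiguous" otherwise.
    ``support`` carries the deciding node's support value if present.
    """

    gene_id: str
    proposed_family: str
    evidence: str
    majority_fraction: float
    support: float | None = None


@dataclass
class AnnotationConflict:
    """A labeled tip whose sister clade unanimously carries another family.

    Mirrors expert re-annotation candidates; conflicts are reported, never
    applied automatically.
    """

    gene_id: str
    current_family: str
    sister_family: str


def _labeled_tips(node: dendropy.Node, known: dict[str, str]) -> list[str]:
    """Family labels of the labeled tips under ``node``."""
    return [
        known[leaf.taxon.label]
        for leaf in node.leaf_iter()
        if leaf.taxon is not None and leaf.taxon.label in known
    ]


def _node_support(node: dendropy.Node) -> float | None:
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def annotate_by_clade(
    tree: dendropy.Tree, known: dict[str, str]
) -> tuple[list[AnnotationProposal], list[AnnotationConflict]]:
    """Propose a family for every unlabeled tip from its clade context.

    For each unlabeled tip: if the labeled tips of its sister clade (the
    rest of its parent's subtree) are unanimous, propose that family;
    otherwise ascend to the smallest enclosing clade containing at least
    one labeled tip and propose the majority family if it exceeds 50%,
    else "ambiguous".  Existing labels are never changed; a labeled tip
    whose sister clade unanimously disagrees is reported as a conflict.
    """
    if not known:
        raise ValidationError("no labeled tips")
    proposals: list[AnnotationProposal] = []
    conflicts: list[AnnotationConflict] = []
    for leaf in tree.leaf_node_iter():
        gid = leaf.taxon.label
        parent = leaf.parent_node
        sister_labels: list[str] = []
        if parent is not None:
            for sib in parent.child_nodes():
                if sib is not leaf:
                    sister_labels.extend(_labeled_tips(sib, known))
        if gid in known:
            if sister_labels and len(set(sister_labels)) == 1 \
                    and sister_labels[0] != known[gid]:
                conflicts.append(
                    AnnotationConflict(gid, known[gid], sister_labels[0])
                )
            continue
        if sister_labels and len(set(sister_labels)) == 1:
            proposals.append(
                AnnotationProposal(
                    gene_id=gid, proposed_family=sister_labels[0],
                    evidence="sister-clade unanimity", majority_fraction=1.0,
                    support=_node_support(parent) if parent else None,
                )
            )
            continue
        # ascend to the smallest enclosing clade with labeled tips
        node = parent
        labels: list[str] = sister_labels
        while node is not None and not labels:
            node = node.parent_node
            labels = _labeled_tips(node, known) if node is not None else []
        if not labels:
            proposals.append(
                AnnotationProposal(gid, "ambiguous", "clade majority", 0.0)
            )
            continue
        counts = pd.Series(labels).value_counts()
        frac = counts.iloc[0] / len(labels)
        tied = (counts == counts.iloc[0]).sum() > 1
        if frac > 0.5 and not tied:
            proposals.append(
                AnnotationProposal(
                    gene_id=gid, proposed_family=str(counts.index[0]),
                    evidence="clade majority", majority_fraction=float(frac),
                    support=_node_support(node),
                )
            )
        else:
            proposals.append(
                AnnotationProposal(gid, "ambiguous", "clade majority", float(frac)),
            )
    return proposals, conflicts


def map_duplications_to_tree(
    tree: dendropy.Tree, pairs: list[tuple[str, str, str]]
) -> dict[dendropy.Node, list[tuple[tuple[str, str], str]]]:
    """Map each typed duplicate pair to the MRCA node of its two tips.

    Returns ``{node: [((gene_a, gene_b), mode), ...]}``; several pairs may
    share a node.  Raises with the full list of missing tips if any pair
    member is absent from the tree.
    """
    taxa = {leaf.taxon.label: leaf.taxon for leaf in tree.leaf_node_iter()}
    missing = sorted(
        {g for a, b, _ in pairs for g in (a, b) if g not in taxa}
    )
    if missing:
        raise ValidationError(f"pair genes absent from tree: {missing}")
    marking: dict[dendropy.Node, list[tuple[tuple[str, str], str]]] = {}
    for a, b, mode in pairs:
        node = tree.mrca(taxa=[taxa[a], taxa[b]])
        marking.setdefault(node, []).append(((a, b), mode))
    return marking


def midpoint_root_if_unrooted(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a tree whose seed node has more than two children.

    Input trees without an explicit root are midpoint-rooted with a logged
    warning (only meaningful when branch lengths are present).
    """
    if len(tree.seed_node.child_nodes()) > 2 and any(
        e.length for e in tree.preorder_edge_iter() if e.length
    ):
        log.warning("tree appears unrooted; applying midpoint rooting")
        tree.reroot_at_midpoint(update_bipartitions=True)
    return tree
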