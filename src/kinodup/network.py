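"""Degree statistics and hub identification on an interaction network,
stratified by duplication mode."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from kinodup.classify import DuplicationLabeling
from kinodup.io import ValidationError

log = logging.getLogger(__name__)


@dataclass
class DegreeReport:
    """Per-gene degrees over the focal set, hubs, and per-mode means.

    Degrees count all distinct interaction partners of a focal gene,
    whether or not the partner is itself focal.  Hubs are focal genes with
    degree >= ``hub_threshold`` (inclusive, so a gene with exactly the
    threshold degree counts as a hub).
    """

    degree_of: dict[str, int]
    mean_degree: float
    hubs: list[str]
    hub_threshold: int
    mean_degree_by_mode: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.degree_of.items()), columns=["gene_id", "degree"]
        )


def degree_stats(
    edges: Sequence[tuple[str, str]],
    focal: set[str],
    labeling: DuplicationLabeling | None = None,
    hub_threshold: int = 20,
) -> DegreeReport:
    """Compute the degree report for a focal gene set.

    Edges are undirected; self-loops are dropped and duplicate entries are
    collapsed with a warning.  Per-mode mean degrees use ``labeling`` when
    given (modes absent from the focal set are omitted).
    """
    if not focal:
        raise ValidationError("empty focal set")
    graph = nx.Graph()
    graph.add_nodes_from(focal)
    n_self = n_dup = 0
    for a, b in edges:
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_dup:
        log.warning("collapsed %d duplicate edge entries", n_dup)
    if n_self:
        log.warning("dropped %d self-loops", n_self)
    degree_of = {g: (graph.degree(g) if g in graph else 0) for g in sorted(focal)}
    mean = sum(degree_of.values()) / len(degree_of)
    hubs = sorted(g for g, d in degree_of.items() if d >= hub_threshold)
    by_mode: dict[str, float] = {}
    if labeling is not None:
        buckets: dict[str, list[int]] = {}
        for g, d in degree_of.items():
            mode = labeling.mode_of.get(g)
            if mode is not None:
                buckets.setdefault(mode, []).append(d)
        by_mode = {m: sum(v) / len(v) for m, v in sorted(buckets.items())}
    return DegreeReport(
        degree_of=degree_of, mean_degree=mean, hubs=hubs,
        hub_threshold=hub_threshold, mean_degree_by_mode=by_mode,
    )
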