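"""Level-1/2/3 interaction counts from candidate genes to a pathway set.

On an undirected protein–protein interaction graph, a candidate's level-k
count is the number of pathway genes at shortest-path distance exactly k
(k = 1: direct partner, k = 2: one intermediate, k = 3: two
intermediates).  Each target is counted once, at its shortest level, so
the three counts partition the reachable targets.  Candidates are ranked
by the sum of the three counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .containers import InputError

LEVEL_COLUMNS = ["gene", "level1", "level2", "level3", "total", "rank"]


@dataclass
class LevelCountRecord:
    gene: str
    level1: int
    level2: int
    level3: int
    rank: int | None = None

    @property
    def total(self) -> int:
        return self.level1 + self.level2 + self.level3


def shortest_levels(
    g: nx.Graph, source: str, targets: set[str], max_level: int = 3
) -> LevelCountRecord:
    """BFS level counts from ``source`` to ``targets`` up to ``max_level``.

    The source's own membership in the target set is ignored.  Targets
    entirely absent from the graph give all-zero counts with a warning.
    """
    if source not in g:
        raise InputError(f"source gene {source!r} not in the graph")
    targets = set(targets) - {source}
    if not targets:
        raise InputError("target set is empty")
    if not targets & set(g.nodes):
        warnings.warn("no target gene is present in the graph", stacklevel=2)
        return LevelCountRecord(gene=source, level1=0, level2=0, level3=0)
    dist = nx.single_source_shortest_path_length(g, source, cutoff=max_level)
    counts = [0] * max_level
    for t in targets:
        d = dist.get(t)
        if d is not None and 1 <= d <= max_level:
            counts[d - 1] += 1
    c = counts + [0] * (3 - len(counts))
    return LevelCountRecord(gene=source, level1=c[0], level2=c[1], level3=c[2])


def count_simple_paths(
    g: nx.Graph, source: str, targets: set[str], max_level: int = 3
) -> LevelCountRecord:
    """Sensitivity-analysis variant: count simple paths per level.

    Instead of classifying each target once at its shortest distance,
    counts every simple path of length k from the candidate to any
    target, for k = 1..max_level.
    """
    if source not in g:
        raise InputError(f"source gene {source!r} not in the graph")
    targets = set(targets) - {source}
    counts = [0] * max_level
    present = [t for t in targets if t in g]
    for t in present:
        for path in nx.all_simple_paths(g, source, t, cutoff=max_level):
            counts[len(path) - 2] += 1
    c = counts + [0] * (3 - len(counts))
    return LevelCountRecord(gene=source, level1=c[0], level2=c[1], level3=c[2])


def rank_candidates(
    g: nx.Graph,
    candidates: list[str],
    targets: set[str],
    max_level: int = 3,
    count_paths: bool = False,
) -> pd.DataFrame:
    """Rank candidates by total level-1..3 count toward the target set.

    Sorting is by total descending, then (level1, level2, level3)
    descending, then gene symbol ascending; ranks run 1..n.  Candidates
    absent from the graph score zero; duplicate candidate symbols are
    dropped with a warning.
    """
    if not candidates:
        raise InputError("candidate list is empty")
    seen: list[str] = []
    for c in candidates:
        if c in seen:
            warnings.warn(f"duplicate candidate {c!r} dropped", stacklevel=2)
        else:
            seen.append(c)
    scorer = count_simple_paths if count_paths else shortest_levels
    records = []
    for c in seen:
        if c in g:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rec = scorer(g, c, targets, max_level=max_level)
        else:
            rec = LevelCountRecord(gene=c, level1=0, level2=0, level3=0)
        records.append(rec)
    records.sort(
        key=lambda r: (-r.total, -r.level1, -r.level2, -r.level3, r.gene)
    )
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "level1": r.level1, "level2": r.level2,
                "level3": r.level3, "total": r.total, "rank": i,
            }
            for i, r in enumerate(records, start=1)
        ],
        columns=LEVEL_COLUMNS,
    )


def direct_partners(g: nx.Graph, gene: str) -> list[str]:
    """Sorted level-1 neighborhood of a gene, for contact-map reporting."""
    if gene not in g:
        raise InputError(f"gene {gene!r} not in the graph")
    return sorted(g.neighbors(gene))
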