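"""Largest-connected-component significance of a compound's target set.

If a compound's targets form a larger connected subgraph than expected
for a degree-matched random node set, they occupy a coherent interactome
neighbourhood ("disease-module" behaviour) rather than being scattered —
evidence that the compound perturbs one biological process.  The default
significance screen keeps compounds with |z| > 1.70.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .interactome import Interactome, largest_connected_component
from .null_models import DegreeBins, NullDistribution, sample_degree_matched_many
from .similarity import TargetSet

__all__ = ["LCCResult", "lcc_zscore", "screen_significant"]

Z_THRESHOLD_DEFAULT = 1.70


@dataclass
class LCCResult:
    compound: str
    n_targets_mapped: int
    lcc_size: int
    null: NullDistribution | None
    z: float
    significant: bool
    flag: str | None = None  # "not_evaluated" | "degenerate_null" | None


def _lcc_size_within(graph_adj, nodes: Iterable[str]) -> int:
    """Size of the largest connected component of the subgraph induced on
    ``nodes`` (adjacency looked up in the parent graph)."""
    pool = set(nodes)
    seen: set[str] = set()
    best = 0
    for start in pool:
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for v in graph_adj[u]:
                if v in pool and v not in seen:
                    seen.add(v)
                    stack.append(v)
        if size > best:
            best = size
    return best


def lcc_zscore(
    g: Interactome,
    targets: TargetSet,
    bins: DegreeBins,
    n_reps: int = 1000,
    z_threshold: float = Z_THRESHOLD_DEFAULT,
    seed: int = 0,
    min_targets: int = 2,
) -> LCCResult:
    """LCC size of the mapped targets versus a degree-matched null.

    z = (lcc_size − μ_null)/σ_null.  Fewer than ``min_targets`` mapped
    targets yields a ``not_evaluated`` result (an LCC needs two nodes to
    be meaningful; the cutoff is configurable).  A zero-variance null is
    flagged ``degenerate_null``: z is 0 when the observation equals the
    null mean, ±inf otherwise.
    """
    mapped = set(targets.members) & set(g.graph.nodes)
    if len(mapped) < min_targets:
        return LCCResult(
            compound=targets.name,
            n_targets_mapped=len(mapped),
            lcc_size=len(mapped),
            null=None,
            z=math.nan,
            significant=False,
            flag="not_evaluated",
        )
    obs = largest_connected_component(g, restrict_to=mapped).size
    samples = sample_degree_matched_many(mapped, bins, n_reps, np.random.default_rng(seed))
    adj = g.graph.adj
    sizes = np.array([_lcc_size_within(adj, row) for row in samples], dtype=float)
    null = NullDistribution.from_values(sizes, seed=seed)
    flag = None
    if null.sigma == 0:
        flag = "degenerate_null"
        z = 0.0 if obs == null.mu else math.copysign(math.inf, obs - null.mu)
    else:
        z = (obs - null.mu) / null.sigma
    return LCCResult(
        compound=targets.name,
        n_targets_mapped=len(mapped),
        lcc_size=obs,
        null=null,
        z=z,
        significant=abs(z) > z_threshold,
        flag=flag,
    )


def screen_significant(results: Sequence[LCCResult]) -> list[str]:
    """Names of significant compounds, sorted by |z| descending."""
    keep = [r for r in results if r.significant and r.flag != "not_evaluated"]
    keep.sort(key=lambda r: (-abs(r.z), r.compound))
    return [r.compound for r in keep]
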