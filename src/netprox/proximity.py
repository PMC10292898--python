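"""Network proximity between compound targets and disease proteins.

Two distance summaries between a target set S and a disease protein set T
on the interactome:

* closest distance  d_c(S,T) = (1/|T|) Σ_{t∈T} min_{s∈S} d(s,t)
* shortest distance d_s(S,T) = (1/(|S||T|)) Σ_{s,t} d(s,t)

Raw distances confound node degree (hubs are close to everything), so
each is standardized against a degree-matched null in which S is replaced
by random node sets with the same degree profile, T held fixed:
z = (d_obs − μ_null)/σ_null.  Negative z_closest means the compound's
targets sit closer to the disease module than chance — the repurposing
signal.  Run on a connected analysis component (see
``interactome.restrict_to_lcc``) so all distances are finite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .interactome import Interactome, shortest_path_lengths_from
from .null_models import DegreeBins, NullDistribution, sample_degree_matched_many
from .similarity import TargetSet

__all__ = [
    "ProximityResult",
    "distance_matrix",
    "distance_closest",
    "distance_shortest",
    "proximity_zscore",
    "proximity_profile",
    "rank_compounds",
]


@dataclass
class ProximityResult:
    compound: str
    n_S: int
    n_T: int
    d_closest: float | None = None
    z_closest: float | None = None
    null_closest: NullDistribution | None = None
    d_shortest: float | None = None
    z_shortest: float | None = None
    null_shortest: NullDistribution | None = None
    flag: str | None = None


def _map_set(ts: TargetSet, g: Interactome, role: str) -> set[str]:
    mapped = set(ts.members) & set(g.graph.nodes)
    dropped = len(ts.members) - len(mapped)
    if dropped:
        warnings.warn(
            f"{role} set {ts.name!r}: {dropped} member(s) not in the analysis component; dropped",
            stacklevel=3,
        )
    if not mapped:
        raise ValueError(f"{role} set {ts.name!r} has no members in the interactome")
    return mapped


def distance_matrix(
    g: Interactome, T_nodes: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Hop-distance matrix from each disease node (rows, sorted) to every
    graph node (columns, sorted); np.inf where unreachable.

    One BFS per disease node; the matrix is reused across the observed
    statistic and all null replicates, and across compounds sharing T.
    """
    node_order = sorted(g.graph.nodes)
    pos = {n: i for i, n in enumerate(node_order)}
    rows = sorted(T_nodes)
    dmat = np.full((len(rows), len(node_order)), np.inf)
    for i, t in enumerate(rows):
        for node, d in shortest_path_lengths_from(g, {t}).items():
            dmat[i, pos[node]] = d
    return dmat, node_order, pos


def distance_closest(g: Interactome, S: TargetSet, T: TargetSet) -> float:
    """Mean over disease proteins of the distance to the nearest target.

    Disease proteins unreachable from every target are excluded with a
    warning; if none is reachable the sets are disconnected and an error
    is raised.  Zero iff T ⊆ S (every disease protein is itself a target).
    """
    S_m = _map_set(S, g, "compound")
    T_m = _map_set(T, g, "disease")
    dist = shortest_path_lengths_from(g, S_m)  # multi-source BFS = min over S
    reachable = [dist[t] for t in T_m if t in dist]
    n_unreached = len(T_m) - len(reachable)
    if not reachable:
        raise ValueError(f"disconnected sets: {S.name!r} vs {T.name!r}")
    if n_unreached:
        warnings.warn(
            f"{n_unreached} disease protein(s) unreachable from {S.name!r}; excluded",
            stacklevel=2,
        )
    return float(np.mean(reachable))


def distance_shortest(g: Interactome, S: TargetSet, T: TargetSet) -> float:
    """Mean hop distance over all (target, disease-protein) pairs."""
    S_m = _map_set(S, g, "compound")
    T_m = sorted(_map_set(T, g, "disease"))
    total = 0.0
    n_pairs = 0
    n_unreached = 0
    for s in S_m:
        dist = shortest_path_lengths_from(g, {s})
        for t in T_m:
            if t in dist:
                total += dist[t]
                n_pairs += 1
            else:
                n_unreached += 1
    if n_pairs == 0:
        raise ValueError(f"disconnected sets: {S.name!r} vs {T.name!r}")
    if n_unreached:
        warnings.warn(f"{n_unreached} unreachable pair(s) excluded", stacklevel=2)
    return total / n_pairs


def _closest_from_cols(dmat: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """d_closest for a batch of column-index sets: cols (R, k) → (R,)."""
    sub = dmat[:, cols]  # (|T|, R, k)
    return sub.min(axis=2).mean(axis=0)


def _shortest_from_cols(dmat: np.ndarray, cols: np.ndarray) -> np.ndarray:
    sub = dmat[:, cols]
    return sub.mean(axis=(0, 2))


def proximity_zscore(
    g: Interactome,
    S: TargetSet,
    T: TargetSet,
    bins: DegreeBins,
    metric: str = "closest",
    n_reps: int = 1000,
    seed: int = 0,
    _dmat: tuple | None = None,
) -> ProximityResult:
    """Proximity z-score for one metric; see ``proximity_profile`` for both."""
    return _proximity(g, S, T, bins, (metric,), n_reps, seed, _dmat)


def proximity_profile(
    g: Interactome,
    S: TargetSet,
    T: TargetSet,
    bins: DegreeBins,
    n_reps: int = 1000,
    seed: int = 0,
    _dmat: tuple | None = None,
) -> ProximityResult:
    """Closest and shortest proximity z-scores, sharing the null samples."""
    return _proximity(g, S, T, bins, ("closest", "shortest"), n_reps, seed, _dmat)


def _proximity(g, S, T, bins, metrics, n_reps, seed, dmat_cache):
    for m in metrics:
        if m not in ("closest", "shortest"):
            raise ValueError(f"unknown metric {m!r}")
    S_m = sorted(_map_set(S, g, "compound"))
    T_m = sorted(_map_set(T, g, "disease"))
    if dmat_cache is None:
        dmat, node_order, pos = distance_matrix(g, T_m)
    else:
        dmat, node_order, pos = dmat_cache
    finite_rows = np.isfinite(dmat).all(axis=1)
    if not finite_rows.all():
        warnings.warn(
            f"{int((~finite_rows).sum())} disease protein(s) not in the connected "
            "analysis component; excluded from proximity",
            stacklevel=3,
        )
        dmat = dmat[finite_rows]
        if dmat.shape[0] == 0:
            raise ValueError(f"disconnected sets: {S.name!r} vs {T.name!r}")
    S_cols = np.array([pos[s] for s in S_m])
    samples = sample_degree_matched_many(S_m, bins, n_reps, np.random.default_rng(seed))
    sample_cols = np.array([[pos[n] for n in row] for row in samples])
    result = ProximityResult(compound=S.name, n_S=len(S_m), n_T=int(dmat.shape[0]))
    for metric in metrics:
        fn = _closest_from_cols if metric == "closest" else _shortest_from_cols
        d_obs = float(fn(dmat, S_cols[None, :])[0])
        null = NullDistribution.from_values(fn(dmat, sample_cols), seed=seed)
        if null.sigma == 0:
            z = 0.0 if d_obs == null.mu else math.copysign(math.inf, d_obs - null.mu)
            result.flag = "degenerate_null"
        else:
            z = (d_obs - null.mu) / null.sigma
        if metric == "closest":
            result.d_closest, result.z_closest, result.null_closest = d_obs, z, null
        else:
            result.d_shortest, result.z_shortest, result.null_shortest = d_obs, z, null
    return result


def rank_compounds(results: Sequence[ProximityResult], k: int = 8) -> list[ProximityResult]:
    """Top-k most proximal compounds: ascending z_closest (most negative
    first), ties by d_closest ascending, then name."""
    if k > len(results):
        warnings.warn(
            f"k={k} exceeds the {len(results)} scored compounds; returning all",
            stacklevel=2,
        )
        k = len(results)

    def key(r: ProximityResult):
        z = r.z_closest if r.z_closest is not None and not math.isnan(r.z_closest) else math.inf
        d = r.d_closest if r.d_closest is not None else math.inf
        return (z, d, r.compound)

    return sorted(results, key=key)[:k]
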