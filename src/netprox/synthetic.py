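"""Synthetic inputs with the statistical structure the screens assume.

The generator builds a miniature of the whole study so that every stage
of the pipeline can be exercised, and its operating characteristics
(power, false-positive behaviour, ranking recovery) measured, without any
external database:

* a scale-free interactome (preferential attachment — connected by
  construction, heavy-tailed degrees like a real PPI network);
* a connected planted "disease module" grown by BFS;
* compound target sets: *signal* compounds draw a stated fraction of
  their targets inside or adjacent to the module, *null* compounds are
  degree-matched random sets with the same degree profile as a signal
  draw, so the screens cannot separate the classes on degree alone;
* a compound–disease association benchmark (therapeutic disease sets
  overlap a compound's target neighbourhood; negatives are degree-matched
  random sets);
* a two-group log2 expression matrix with a planted fraction of shifted
  genes, some of them compound targets so the DEG×target intersection is
  non-trivial.

Every draw flows from one integer seed through NumPy's PCG64 generator;
the ``truth`` record of each object suffices to compute the expected
output of every downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import Interactome, build_interactome, write_edge_tsv
from .null_models import DegreeBins, make_degree_bins, sample_degree_matched
from .similarity import TargetSet, write_gmt
from .validation import AssociationTable
from .deg_analysis import ExpressionMatrix

__all__ = [
    "SyntheticScenario",
    "SyntheticBundle",
    "generate_interactome",
    "plant_disease_module",
    "plant_compounds",
    "generate_expression",
    "generate_associations",
    "generate_bundle",
    "write_bundle",
]


@dataclass
class SyntheticScenario:
    """Study-shaped defaults: ~30 compounds (3 carrying signal), a 30-node
    disease module in a 2000-node scale-free graph, and a 26 vs 26 sample
    expression design with 10% of 1000 genes shifted by ±2 log2 units."""

    seed: int = 0
    n_nodes: int = 2000
    attachment: int = 2
    disease_module_size: int = 30
    n_signal_compounds: int = 3
    n_null_compounds: int = 27
    targets_per_compound: int = 10
    signal_overlap_fraction: float = 0.7
    n_genes: int = 1000
    n_per_group: int = 26
    de_fraction: float = 0.1
    effect_logfc: float = 2.0
    noise_sd: float = 0.5
    n_overlap_genes: int = 12  # planted DE genes that are also compound targets
    n_diseases: int = 20
    disease_set_size: int = 10
    min_bin_size: int = 100

    def __post_init__(self) -> None:
        for name in (
            "n_nodes", "attachment", "disease_module_size", "n_signal_compounds",
            "n_null_compounds", "targets_per_compound", "n_genes", "n_per_group",
            "n_diseases", "disease_set_size", "min_bin_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("signal_overlap_fraction", "de_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")


@dataclass
class SyntheticBundle:
    scenario: SyntheticScenario
    interactome: Interactome
    bins: DegreeBins
    disease: TargetSet
    compounds: list[TargetSet]
    associations: AssociationTable
    disease_sets: dict[str, TargetSet]
    expression: ExpressionMatrix
    truth: dict


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["graph", "module", "compounds", "expression", "associations"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _node_name(i: int) -> str:
    return f"G{i:05d}"


def generate_interactome(scenario: SyntheticScenario, rng: np.random.Generator | None = None) -> Interactome:
    """Preferential-attachment graph: connected, heavy-tailed degrees."""
    if rng is None:
        rng = _stage_rngs(scenario.seed)["graph"]
    nx_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(scenario.n_nodes, scenario.attachment, seed=nx_seed)
    records = [(_node_name(u), _node_name(v), "synthetic") for u, v in sorted(g.edges())]
    return build_interactome(records)


def plant_disease_module(
    g: Interactome, scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> TargetSet:
    """Connected node set of ``disease_module_size`` grown by seeded BFS
    (neighbours visited in sorted order) from a random start node."""
    if rng is None:
        rng = _stage_rngs(scenario.seed)["module"]
    nodes = sorted(g.graph.nodes)
    start = nodes[int(rng.integers(0, len(nodes)))]
    visited = [start]
    seen = {start}
    frontier = [start]
    while frontier and len(visited) < scenario.disease_module_size:
        nxt = []
        for u in frontier:
            for v in sorted(g.graph.adj[u]):
                if v not in seen:
                    seen.add(v)
                    visited.append(v)
                    nxt.append(v)
                    if len(visited) == scenario.disease_module_size:
                        break
            if len(visited) == scenario.disease_module_size:
                break
        frontier = nxt
    module = visited[: scenario.disease_module_size]
    assert nx.is_connected(g.graph.subgraph(module))
    return TargetSet.from_iterable("disease", module)


def _neighbourhood_pool(g: Interactome, nodes: Sequence[str]) -> list[str]:
    pool = set(nodes)
    for n in nodes:
        pool.update(g.graph.adj[n])
    return sorted(pool)


def _draw_near(
    g: Interactome,
    core: Sequence[str],
    k: int,
    rng: np.random.Generator,
    inside_fraction: float = 0.5,
) -> list[str]:
    """Draw ``k`` distinct nodes from ``core`` ∪ its neighbours, half of
    them (by default) from the core itself.

    Weighting the core equally with its (far more numerous) neighbours
    mirrors how real drug targets are often disease proteins themselves,
    and keeps the planted proximity signal a genuine signal rather than a
    diluted one.
    """
    core = sorted(set(core))
    adjacent = sorted(set(_neighbourhood_pool(g, core)) - set(core))
    n_inside = min(len(core), round(inside_fraction * k))
    n_adj = min(len(adjacent), k - n_inside)
    picks = list(rng.choice(np.asarray(core, dtype=object), size=n_inside, replace=False))
    picks += list(rng.choice(np.asarray(adjacent, dtype=object), size=n_adj, replace=False))
    if len(picks) < k:  # tiny graphs: top up from whatever remains
        rest = sorted((set(core) | set(adjacent)) - set(picks))
        picks += list(rng.choice(np.asarray(rest, dtype=object), size=k - len(picks), replace=False))
    return picks


def _grow_connected(
    g: Interactome,
    core: set[str],
    pool: set[str],
    start: str,
    k: int,
    rng: np.random.Generator,
) -> list[str]:
    """Grow a connected node set of size ``k`` from ``start`` by randomly
    expanding the current set's frontier, preferring ``core`` (module)
    nodes, then ``pool`` (module neighbourhood) nodes, spilling outside
    only when stuck.

    Connected, module-covering target clusters are what make a planted
    compound both form a significant LCC and sit proximal to the whole
    disease module — scattered single targets would do neither.
    """
    chosen = [start]
    members = {start}
    while len(chosen) < k:
        neigh = {v for u in chosen for v in g.graph.adj[u] if v not in members}
        frontier = sorted(neigh & core) or sorted(neigh & pool) or sorted(neigh)
        if not frontier:
            break
        nxt = frontier[int(rng.integers(0, len(frontier)))]
        chosen.append(nxt)
        members.add(nxt)
    return chosen


def _degree_matched_replacement(
    template: Sequence[str], keep: set[str], bins: DegreeBins, rng: np.random.Generator, max_tries: int = 100
) -> set[str]:
    """Degree-matched sample for ``template`` avoiding collisions with ``keep``."""
    for _ in range(max_tries):
        cand = sample_degree_matched(set(template), bins, rng)
        if not (cand & keep):
            return cand
    raise RuntimeError("could not draw a collision-free degree-matched sample")


def plant_compounds(
    g: Interactome,
    module: TargetSet,
    scenario: SyntheticScenario,
    bins: DegreeBins | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[TargetSet], dict]:
    """Signal and null compound target sets plus truth labels.

    Every compound starts from a template drawn from the module ∪ its
    neighbours; signal compounds keep ``round(signal_overlap_fraction ·
    targets_per_compound)`` template nodes and replace the rest with
    degree-matched random nodes, null compounds replace all of them.
    Signal and null sets therefore share a degree profile and differ only
    in placement.
    """
    if rng is None:
        rng = _stage_rngs(scenario.seed)["compounds"]
    if bins is None:
        bins = make_degree_bins(g, scenario.min_bin_size)
    module_nodes = sorted(module.members)
    tpc = scenario.targets_per_compound
    if len(_neighbourhood_pool(g, module_nodes)) < tpc:
        raise ValueError("module neighbourhood smaller than targets_per_compound")
    n_in = round(scenario.signal_overlap_fraction * tpc)
    compounds: list[TargetSet] = []
    truth: dict[str, dict] = {}
    n_total = scenario.n_signal_compounds + scenario.n_null_compounds
    pool = set(_neighbourhood_pool(g, module_nodes))
    for i in range(n_total):
        name = f"C{i:02d}"
        is_signal = i < scenario.n_signal_compounds
        start = module_nodes[int(rng.integers(0, len(module_nodes)))]
        near = _grow_connected(g, set(module_nodes), pool, start, n_in, rng)
        far_template = list(
            _degree_matched_replacement(
                _draw_near(g, module_nodes, tpc - n_in, rng), set(near), bins, rng
            )
        ) if tpc > n_in else []
        template = near + far_template
        if is_signal:
            kept = set(near)
            members = set(template)
        else:
            kept = set()
            members = _degree_matched_replacement(template, kept, bins, rng)
        assert len(members) == tpc
        compounds.append(TargetSet.from_iterable(name, members))
        truth[name] = {
            "label": "signal" if is_signal else "null",
            "n_module_neighbourhood_targets": len(kept),
        }
    return compounds, truth


def generate_expression(
    g: Interactome,
    scenario: SyntheticScenario,
    compounds: Sequence[TargetSet],
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """Two-group log2 expression matrix with planted shifts.

    Gene universe: all compound targets first (guaranteeing DEG×target
    overlap is possible), padded with other graph nodes up to ``n_genes``.
    A ``de_fraction`` of genes is shifted by ±``effect_logfc`` in the case
    group, including ``n_overlap_genes`` drawn from the compound targets;
    noise is i.i.d. Gaussian with sd ``noise_sd`` on a uniform(6, 12)
    per-gene baseline.
    """
    if rng is None:
        rng = _stage_rngs(scenario.seed)["expression"]
    target_genes = sorted(set().union(*(c.members for c in compounds)))
    others = sorted(set(g.graph.nodes) - set(target_genes))
    genes = (target_genes + others)[: scenario.n_genes]
    if len(genes) < scenario.n_genes:
        genes = genes + [f"X{i:05d}" for i in range(scenario.n_genes - len(genes))]
    genes = sorted(genes)
    n_de = round(scenario.de_fraction * scenario.n_genes)
    target_in_universe = sorted(set(target_genes) & set(genes))
    n_overlap = min(scenario.n_overlap_genes, n_de, len(target_in_universe))
    overlap_de = list(
        rng.choice(np.asarray(target_in_universe, dtype=object), size=n_overlap, replace=False)
    )
    rest_pool = sorted(set(genes) - set(target_in_universe))
    need = n_de - n_overlap
    if len(rest_pool) < need:  # tiny universes: spill into remaining target genes
        rest_pool = sorted(set(genes) - set(overlap_de))
    fill = list(rng.choice(np.asarray(rest_pool, dtype=object), size=need, replace=False))
    de_genes = sorted(overlap_de + fill)
    signs = {gene: int(s) for gene, s in zip(de_genes, rng.choice([-1, 1], size=len(de_genes)))}
    n = scenario.n_per_group
    samples = [f"case_{i+1:02d}" for i in range(n)] + [f"ctrl_{i+1:02d}" for i in range(n)]
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples)
    baseline = rng.uniform(6.0, 12.0, size=len(genes))
    mat = rng.normal(0.0, scenario.noise_sd, size=(len(genes), 2 * n)) + baseline[:, None]
    gene_pos = {gene: i for i, gene in enumerate(genes)}
    for gene in de_genes:
        mat[gene_pos[gene], :n] += signs[gene] * scenario.effect_logfc
    expr = ExpressionMatrix(values=pd.DataFrame(mat, index=genes, columns=samples), groups=groups)
    truth = {
        "de_genes": {gene: ("up" if signs[gene] > 0 else "down") for gene in de_genes},
        "overlap_de_genes": sorted(set(de_genes) & set(target_in_universe)),
        "n_de": len(de_genes),
    }
    return expr, truth


def generate_associations(
    g: Interactome,
    compounds: Sequence[TargetSet],
    compound_truth: dict,
    scenario: SyntheticScenario,
    bins: DegreeBins | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[AssociationTable, dict[str, TargetSet], dict]:
    """Labelled compound–disease benchmark.

    Diseases are assigned round-robin to the signal compounds; even-index
    diseases are therapeutic (their protein set is drawn from the
    compound's target neighbourhood), odd-index ones are degree-matched
    random sets of the same size.
    """
    if rng is None:
        rng = _stage_rngs(scenario.seed)["associations"]
    if bins is None:
        bins = make_degree_bins(g, scenario.min_bin_size)
    signal = [c for c in compounds if compound_truth[c.name]["label"] == "signal"]
    if not signal:
        raise ValueError("no signal compounds to build associations for")
    rows: list[tuple[str, str, str]] = []
    disease_sets: dict[str, TargetSet] = {}
    truth: dict[str, str] = {}
    for d in range(scenario.n_diseases):
        compound = signal[d % len(signal)]
        name = f"D{d:02d}"
        therapeutic = d % 2 == 0
        template = _draw_near(g, sorted(compound.members), scenario.disease_set_size, rng)
        if therapeutic:
            members = set(template)
        else:
            members = _degree_matched_replacement(template, set(), bins, rng)
        disease_sets[name] = TargetSet.from_iterable(name, members)
        label = "therapeutic" if therapeutic else "non_therapeutic"
        rows.append((compound.name, name, label))
        truth[name] = label
    return AssociationTable(rows=rows), disease_sets, truth


def generate_bundle(scenario: SyntheticScenario) -> SyntheticBundle:
    """All pipeline inputs plus the planted truth, from one seed."""
    rngs = _stage_rngs(scenario.seed)
    g = generate_interactome(scenario, rngs["graph"])
    bins = make_degree_bins(g, scenario.min_bin_size)
    module = plant_disease_module(g, scenario, rngs["module"])
    compounds, compound_truth = plant_compounds(g, module, scenario, bins, rngs["compounds"])
    expr, expr_truth = generate_expression(g, scenario, compounds, rngs["expression"])
    assoc, disease_sets, assoc_truth = generate_associations(
        g, compounds, compound_truth, scenario, bins, rngs["associations"]
    )
    truth = {
        "scenario": asdict(scenario),
        "disease_module": sorted(module.members),
        "compounds": compound_truth,
        "expression": expr_truth,
        "associations": assoc_truth,
    }
    return SyntheticBundle(
        scenario=scenario,
        interactome=g,
        bins=bins,
        disease=module,
        compounds=compounds,
        associations=assoc,
        disease_sets=disease_sets,
        expression=expr,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, str]:
    """Write the complete input bundle as plain-text files; returns the
    file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "edges": "edges.tsv",
        "targets": "compound_targets.gmt",
        "disease": "disease_proteins.txt",
        "associations": "associations.tsv",
        "disease_sets": "disease_sets.gmt",
        "expression": "expression.tsv",
        "samples": "samples.tsv",
        "truth": "truth.json",
    }
    write_edge_tsv(bundle.interactome, outdir / files["edges"])
    write_gmt(bundle.compounds, outdir / files["targets"])
    (outdir / files["disease"]).write_text("\n".join(sorted(bundle.disease.members)) + "\n")
    bundle.associations.to_frame().to_csv(outdir / files["associations"], sep="\t", index=False)
    write_gmt(sorted(bundle.disease_sets.values(), key=lambda s: s.name), outdir / files["disease_sets"])
    bundle.expression.values.round(6).to_csv(outdir / files["expression"], sep="\t", index_label="gene")
    pd.DataFrame(
        {"sample": bundle.expression.groups.index, "group": bundle.expression.groups.values}
    ).to_csv(outdir / files["samples"], sep="\t", index=False)
    (outdir / files["truth"]).write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
    return {k: str(outdir / v) for k, v in files.items()}
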