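"""Batch orchestration: run the whole repurposing screen from input files.

Stage order mirrors the analysis: interactome build → target-set Jaccard
similarity → per-compound LCC significance screen → proximity z-scores →
top-k ranking → ROC validation against known indications → DEG calling →
DEG×target intersection → hub-target ranking → per-gene diagnostic ROC.
Every stage writes a TSV/JSON artifact (seed recorded in each JSON) and
the run ends with a manifest.  Any stage can be skipped via config; a
stage failure aborts the run naming the stage, retaining earlier outputs.
"""

from __future__ import annotations

import json
import math
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .interactome import (
    Interactome,
    read_edge_tsv,
    read_node_set,
    restrict_to_lcc,
)
from .similarity import TargetSet, pairwise_jaccard, read_gmt
from .null_models import make_degree_bins
from .module_significance import lcc_zscore, screen_significant
from .proximity import proximity_profile, rank_compounds
from .validation import read_association_tsv, roc_auc, score_pairs
from .deg_analysis import (
    ExpressionMatrix,
    call_degs,
    diagnostic_roc,
    hub_targets,
    intersect_targets,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "STAGES"]

STAGES = ["build", "ji", "lcc", "prox", "rank", "validate", "deg", "intersect", "hubs", "diag"]

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage."""


@dataclass
class RunConfig:
    """Paths to the input bundle plus all tunable thresholds."""

    edges: str = ""
    targets: str = ""  # compound target sets, GMT
    disease: str = ""  # disease protein set, one ID per line
    associations: str = ""  # compound/disease/label TSV
    disease_sets: str = ""  # disease target sets, GMT
    expression: str = ""
    samples: str = ""
    subnet_edges: str = ""  # hub subnetwork; defaults to the interactome
    output_dir: str = "netprox_out"
    n_reps: int = 1000
    min_bin_size: int = 100
    z_threshold: float = 1.70
    lfc_thresh: float = 0.5
    alpha: float = 0.05
    k_top_compounds: int = 8
    k_hubs: int = 12
    min_targets: int = 2
    lcc_scope: str = "full"  # "full" graph or "disease"-induced subgraph
    seed: int = 0
    skip_stages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("n_reps", "min_bin_size", "k_top_compounds", "k_hubs", "min_targets"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("z_threshold", "lfc_thresh", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lcc_scope not in ("full", "disease"):
            raise ValueError("lcc_scope must be 'full' or 'disease'")
        unknown = set(self.skip_stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages to skip: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if isinstance(data.get("skip_stages"), str):
            data["skip_stages"] = [s.strip() for s in data["skip_stages"].split(",") if s.strip()]
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _dump_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True) + "\n")


def _fin(x: float) -> float | str:
    """JSON-safe float (inf/nan become strings)."""
    if x is None or (isinstance(x, float) and math.isfinite(x)):
        return x
    return str(x)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all (non-skipped) stages; returns and writes the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "netprox_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "metadata": {
            "analysis_component": "interactome LCC",
            "randomized_set": "compound targets (disease set held fixed)",
            "logFC_orientation": "case - control",
        },
        "stages": {},
        "counts": {},
    }
    state: dict = {}
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGES, seed_seq.spawn(len(STAGES)))
    }

    def run_stage(name, fn):
        entry = {"status": "skipped", "outputs": [], "seconds": 0.0}
        manifest["stages"][name] = entry
        if name in config.skip_stages:
            return
        t0 = time.perf_counter()
        try:
            entry["outputs"] = fn() or []
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            entry["status"] = "failed"
            entry["seconds"] = round(time.perf_counter() - t0, 3)
            _dump_json(out / "manifest.json", manifest)
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        entry["status"] = "complete"
        entry["seconds"] = round(time.perf_counter() - t0, 3)

    # ---- build -----------------------------------------------------------
    def stage_build():
        g_full = read_edge_tsv(config.edges)
        manifest["counts"]["interactome_nodes"] = g_full.n_nodes
        manifest["counts"]["interactome_edges"] = g_full.n_edges
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state["g"] = restrict_to_lcc(g_full)
        manifest["counts"]["analysis_component_nodes"] = state["g"].n_nodes
        state["compounds"] = read_gmt(config.targets)
        state["disease"] = TargetSet.from_iterable("disease", read_node_set(config.disease))
        state["bins"] = make_degree_bins(state["g"], config.min_bin_size)
        report = out / "load_report.json"
        _dump_json(report, json.loads(g_full.load_report.to_json()))
        return [report.name]

    run_stage("build", stage_build)
    if "g" not in state:
        raise PipelineError("stage 'build' cannot be skipped")
    g, bins = state["g"], state["bins"]
    compounds, disease = state["compounds"], state["disease"]

    # ---- ji --------------------------------------------------------------
    def stage_ji():
        sim = pairwise_jaccard(compounds)
        sim.to_frame().to_csv(out / "ji_matrix.tsv", sep="\t", float_format=FLOAT_FMT)
        _dump_json(
            out / "ji_summary.json",
            {"mean_offdiag": sim.mean_offdiag, "n_sets": len(sim.names), "seed": config.seed},
        )
        manifest["counts"]["mean_offdiag_ji"] = sim.mean_offdiag
        return ["ji_matrix.tsv", "ji_summary.json"]

    run_stage("ji", stage_ji)

    # ---- lcc -------------------------------------------------------------
    def stage_lcc():
        if config.lcc_scope == "disease":
            g_lcc = g.induced(disease.members)
            bins_lcc = make_degree_bins(g_lcc, config.min_bin_size)
        else:
            g_lcc, bins_lcc = g, bins
        results = [
            lcc_zscore(
                g_lcc, ts, bins_lcc,
                n_reps=config.n_reps, z_threshold=config.z_threshold,
                seed=stage_seeds["lcc"] + i, min_targets=config.min_targets,
            )
            for i, ts in enumerate(compounds)
        ]
        state["lcc_results"] = results
        rows = [
            {
                "compound": r.compound,
                "n_targets": r.n_targets_mapped,
                "lcc_size": r.lcc_size,
                "mu": r.null.mu if r.null else math.nan,
                "sigma": r.null.sigma if r.null else math.nan,
                "z": r.z,
                "significant": r.significant,
                "flag": r.flag or "",
            }
            for r in results
        ]
        pd.DataFrame(rows).to_csv(out / "lcc_results.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        passing = screen_significant(results)
        manifest["counts"]["lcc_significant"] = len(passing)
        return ["lcc_results.tsv"]

    run_stage("lcc", stage_lcc)

    # ---- prox ------------------------------------------------------------
    def stage_prox():
        from .proximity import distance_matrix

        T_m = sorted(set(disease.members) & set(g.graph.nodes))
        dmat = distance_matrix(g, T_m)
        results = [
            proximity_profile(
                g, ts, disease, bins,
                n_reps=config.n_reps, seed=stage_seeds["prox"] + i, _dmat=dmat,
            )
            for i, ts in enumerate(compounds)
        ]
        state["prox_results"] = results
        rows = [
            {
                "compound": r.compound,
                "n_S": r.n_S,
                "n_T": r.n_T,
                "d_closest": r.d_closest,
                "z_closest": r.z_closest,
                "abs_z_closest": abs(r.z_closest),
                "d_shortest": r.d_shortest,
                "z_shortest": r.z_shortest,
                "mu_closest": r.null_closest.mu,
                "sigma_closest": r.null_closest.sigma,
                "n_reps": config.n_reps,
                "seed": r.null_closest.seed,
            }
            for r in results
        ]
        pd.DataFrame(rows).to_csv(out / "proximity.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        return ["proximity.tsv"]

    run_stage("prox", stage_prox)

    # ---- rank ------------------------------------------------------------
    def stage_rank():
        top = rank_compounds(state["prox_results"], k=config.k_top_compounds)
        state["top_compounds"] = [r.compound for r in top]
        pd.DataFrame(
            {
                "rank": np.arange(1, len(top) + 1),
                "compound": [r.compound for r in top],
                "z_closest": [r.z_closest for r in top],
                "d_closest": [r.d_closest for r in top],
            }
        ).to_csv(out / "top_compounds.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        manifest["counts"]["top_compounds"] = state["top_compounds"]
        return ["top_compounds.tsv"]

    run_stage("rank", stage_rank)

    # ---- validate --------------------------------------------------------
    def stage_validate():
        table = read_association_tsv(config.associations)
        disease_sets = {s.name: s for s in read_gmt(config.disease_sets)}
        compound_sets = {c.name: c for c in compounds}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = score_pairs(
                g, compound_sets, disease_sets, table, bins,
                n_reps=config.n_reps, seed=stage_seeds["validate"],
            )
        labelled = [
            (scores[(c, d)], label == "therapeutic")
            for c, d, label in table.rows
            if (c, d) in scores
        ]
        roc = roc_auc([s for s, _ in labelled], [l for _, l in labelled])
        state["validation_auc"] = roc.auc
        pd.DataFrame(roc.curve_points, columns=["fpr", "tpr"]).to_csv(
            out / "validation_roc.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        _dump_json(
            out / "validation_summary.json",
            {
                "auc": roc.auc,
                "n_pos": roc.n_pos,
                "n_neg": roc.n_neg,
                "auc_screen_passed": roc.auc > 0.75,
                "seed": config.seed,
            },
        )
        manifest["counts"]["validation_auc"] = roc.auc
        return ["validation_roc.tsv", "validation_summary.json"]

    run_stage("validate", stage_validate)

    # ---- deg -------------------------------------------------------------
    def stage_deg():
        expr = ExpressionMatrix.from_tsv(config.expression, config.samples)
        state["expr"] = expr
        degs = call_degs(expr, lfc_thresh=config.lfc_thresh, alpha=config.alpha)
        state["degs"] = degs
        degs.to_csv(out / "degs.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        n_up = int((degs["direction"] == "up").sum())
        n_down = int((degs["direction"] == "down").sum())
        manifest["counts"]["degs_up"] = n_up
        manifest["counts"]["degs_down"] = n_down
        return ["degs.tsv"]

    run_stage("deg", stage_deg)

    # ---- intersect -------------------------------------------------------
    def stage_intersect():
        if "degs" not in state:
            raise RuntimeError("requires the 'deg' stage")
        inter = intersect_targets(state["degs"], compounds)
        state["intersection"] = inter
        inter.to_csv(out / "intersection.tsv", sep="\t", index=False)
        manifest["counts"]["intersection_genes"] = int(len(inter))
        return ["intersection.tsv"]

    run_stage("intersect", stage_intersect)

    # ---- hubs ------------------------------------------------------------
    def stage_hubs():
        if "intersection" not in state:
            raise RuntimeError("requires the 'intersect' stage")
        subnet = read_edge_tsv(config.subnet_edges) if config.subnet_edges else g
        genes = set(state["intersection"]["gene"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = hub_targets(subnet, genes, k=config.k_hubs)
        state["hubs"] = report.selected
        report.table.to_csv(out / "hubs.tsv", sep="\t", index=False)
        manifest["counts"]["hub_targets"] = report.selected
        return ["hubs.tsv"]

    run_stage("hubs", stage_hubs)

    # ---- diag ------------------------------------------------------------
    def stage_diag():
        if "expr" not in state or "hubs" not in state:
            raise RuntimeError("requires the 'deg' and 'hubs' stages")
        results = {}
        for gene in state["hubs"]:
            if gene not in state["expr"].values.index:
                continue
            r = diagnostic_roc(state["expr"], gene)
            results[gene] = {
                "auc": r.auc,
                "cutoff": _fin(r.cutoff),
                "sens_at_cutoff": _fin(r.sens_at_cutoff),
                "spec_at_cutoff": _fin(r.spec_at_cutoff),
                "high_accuracy": r.high_accuracy,
                "direction": r.direction,
                "flag": r.flag,
            }
        _dump_json(out / "diagnostics.json", {"genes": results, "seed": config.seed})
        manifest["counts"]["high_accuracy_markers"] = sorted(
            gene for gene, r in results.items() if r["high_accuracy"]
        )
        return ["diagnostics.json"]

    run_stage("diag", stage_diag)

    _dump_json(out / "manifest.json", manifest)
    return manifest
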