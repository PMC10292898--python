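"""Differential expression, target intersection, hub ranking, diagnostic ROC.

Downstream of the network screen: call differentially expressed genes
(DEGs) between case and control skin samples, intersect them with the
screened compounds' targets (with up/down direction), rank the
intersection genes by degree in a PPI subnetwork to nominate hub targets,
and evaluate each hub as a diagnostic biomarker by per-gene ROC with a
Youden-index cutoff.

DEG calling uses a per-gene Welch two-sample t-test on log2 expression
with Benjamini–Hochberg adjustment, thresholded at |logFC| > 0.5 (strict)
and adjusted P < 0.05.  logFC is case − control mean difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .interactome import Interactome
from .similarity import TargetSet
from .validation import roc_auc

__all__ = [
    "ExpressionMatrix",
    "HubReport",
    "DiagnosticResult",
    "call_degs",
    "intersect_targets",
    "hub_targets",
    "diagnostic_roc",
]

GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """Genes × samples log2 expression with a two-group sample sheet."""

    values: pd.DataFrame  # index: gene IDs, columns: sample IDs
    groups: pd.Series  # sample ID -> "case" | "control"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene IDs")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group: {sorted(missing)[:5]}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"groups must be in {GROUPS}; got {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @classmethod
    def from_tsv(cls, expr_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        """Expression TSV (first column gene ID, header = samples) plus a
        sample sheet TSV with columns ``sample``, ``group``."""
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
        if not {"sample", "group"}.issubset(sheet.columns):
            raise ValueError("sample sheet needs columns: sample, group")
        groups = sheet.set_index("sample")["group"]
        return cls(values=values, groups=groups)

    def sample_ids(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass
class HubReport:
    table: pd.DataFrame  # columns: gene, degree_in_subnet, rank
    selected: list[str]


@dataclass
class DiagnosticResult:
    gene: str
    auc: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    high_accuracy: bool  # auc > 0.9
    direction: str  # "up": case-high, classify positive at value >= cutoff
    flag: str | None = None


def call_degs(expr: ExpressionMatrix, lfc_thresh: float = 0.5, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t-test with BH adjustment.

    Returns a DEG table with columns gene, logFC, p_raw, p_adj, direction
    (up/down/ns).  Direction is "up" iff logFC > lfc_thresh AND
    p_adj < alpha (both strict), symmetrically "down".  A gene constant
    in both groups with equal means gets p = 1.
    """
    case_ids = expr.sample_ids("case")
    ctrl_ids = expr.sample_ids("control")
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    case = expr.values[case_ids].to_numpy()
    ctrl = expr.values[ctrl_ids].to_numpy()
    logfc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant genes trip scipy's precision-loss warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p_raw = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    # zero variance in both groups: the test statistic is undefined;
    # identical means carry no evidence (p=1), distinct means are separated
    # with certainty at any sample size (p=0)
    p_raw = np.where(np.isnan(p_raw), np.where(logfc == 0.0, 1.0, 0.0), p_raw)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    direction = np.where(
        (logfc > lfc_thresh) & (p_adj < alpha),
        "up",
        np.where((logfc < -lfc_thresh) & (p_adj < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": expr.values.index,
            "logFC": logfc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": direction,
        }
    ).reset_index(drop=True)


def intersect_targets(degs: pd.DataFrame, compound_sets: Sequence[TargetSet]) -> pd.DataFrame:
    """Directional DEGs that are also targets of ≥1 compound.

    Returns rows (gene, direction, compounds) with compounds as a sorted
    ';'-joined list; only up/down genes qualify.
    """
    membership: dict[str, list[str]] = {}
    for ts in compound_sets:
        for gene in ts.members:
            membership.setdefault(gene, []).append(ts.name)
    rows = []
    sig = degs[degs["direction"].isin(["up", "down"])]
    for gene, direction in zip(sig["gene"], sig["direction"]):
        if gene in membership:
            rows.append((gene, direction, ";".join(sorted(membership[gene]))))
    return pd.DataFrame(rows, columns=["gene", "direction", "compounds"])


def hub_targets(subnet: Interactome, genes: Iterable[str], k: int = 12) -> HubReport:
    """Rank genes by degree in the subgraph they induce; select the top k.

    Ties are broken alphabetically.  Genes absent from the subnetwork are
    dropped with a warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    genes = set(genes)
    mapped = genes & set(subnet.graph.nodes)
    if len(mapped) < len(genes):
        warnings.warn(f"{len(genes) - len(mapped)} gene(s) absent from the subnetwork; dropped", stacklevel=2)
    sub = subnet.graph.subgraph(mapped)
    deg = dict(sub.degree())
    order = sorted(deg, key=lambda n: (-deg[n], n))
    table = pd.DataFrame(
        {
            "gene": order,
            "degree_in_subnet": [deg[n] for n in order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return HubReport(table=table, selected=order[:k])


def diagnostic_roc(expr: ExpressionMatrix, gene: str, positive_group: str = "case") -> DiagnosticResult:
    """Single-gene diagnostic ROC with a Youden-index cutoff.

    Expression values are the classifier scores.  Orientation is chosen
    so AUC ≥ 0.5 and recorded: direction "up" classifies positive at
    value ≥ cutoff, "down" at value ≤ cutoff.  The cutoff maximizes
    J = sensitivity + specificity − 1 over observed expression values;
    ties prefer higher specificity.  Constant expression yields AUC 0.5
    and an undefined cutoff flag.
    """
    if gene not in expr.values.index:
        raise ValueError(f"gene {gene!r} not in the expression matrix")
    if positive_group not in GROUPS:
        raise ValueError(f"positive_group must be one of {GROUPS}")
    x = expr.values.loc[gene].to_numpy(dtype=float)
    labels = (expr.groups[expr.values.columns] == positive_group).to_numpy()
    if not labels.any() or labels.all():
        raise ValueError("both groups must be non-empty")
    if np.ptp(x) == 0:
        return DiagnosticResult(
            gene=gene, auc=0.5, cutoff=math.nan, sens_at_cutoff=math.nan,
            spec_at_cutoff=math.nan, high_accuracy=False, direction="up",
            flag="cutoff_undefined",
        )
    raw_auc = roc_auc(x, labels).auc
    direction = "up" if raw_auc >= 0.5 else "down"
    scores = x if direction == "up" else -x
    auc = max(raw_auc, 1 - raw_auc)
    pos = scores[labels]
    neg = scores[~labels]
    best = None  # (J, spec, -threshold) maximized lexicographically
    for thr in np.unique(scores):
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        j = sens + spec - 1
        key = (j, spec, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    _, thr, sens, spec = best
    cutoff = float(thr if direction == "up" else -thr)
    return DiagnosticResult(
        gene=gene,
        auc=float(auc),
        cutoff=cutoff,
        sens_at_cutoff=sens,
        spec_at_cutoff=spec,
        high_accuracy=auc > 0.9,
        direction=direction,
    )
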