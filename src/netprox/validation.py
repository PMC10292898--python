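"""ROC validation of proximity against known compound–disease indications.

Each known (compound, disease) association is scored by −z_closest of the
compound's targets against that disease's protein set; pairs with no
therapeutic annotation serve as negatives.  If proximity captures
therapeutic relevance, the score separates the two classes — the screen
keeps predictors with AUC > 0.75.  AUCs of two score sets are compared
with a stratified bootstrap (positives and negatives resampled
independently).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score, roc_curve

from .interactome import Interactome
from .null_models import DegreeBins
from .proximity import distance_matrix, proximity_zscore
from .similarity import TargetSet

__all__ = [
    "AssociationTable",
    "ROCResult",
    "read_association_tsv",
    "score_pairs",
    "roc_auc",
    "compare_auc",
]

LABELS = ("therapeutic", "non_therapeutic")


@dataclass
class AssociationTable:
    """Rows of (compound, disease, label); duplicates are rejected."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for compound, disease, label in self.rows:
            if label not in LABELS:
                raise ValueError(f"label must be one of {LABELS}; got {label!r}")
            key = (compound, disease)
            if key in seen:
                raise ValueError(f"duplicate association pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["compound", "disease", "label"])


@dataclass
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int
    curve_points: list[tuple[float, float]]
    compare_p: float | None = None


def read_association_tsv(path: str | Path) -> AssociationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"compound", "disease", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"association TSV needs columns {sorted(required)}")
    return AssociationTable(rows=[tuple(r) for r in df[["compound", "disease", "label"]].itertuples(index=False)])


def score_pairs(
    g: Interactome,
    compound_sets: Mapping[str, TargetSet],
    disease_sets: Mapping[str, TargetSet],
    table: AssociationTable,
    bins: DegreeBins,
    n_reps: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Score every association pair by −z_closest (higher = more likely
    therapeutic).  Pairs whose compound or disease set is unknown or
    unmappable are excluded with a warning.  The disease distance matrix
    is cached so all compounds against one disease share the BFS work.
    """
    scores: dict[tuple[str, str], float] = {}
    dmat_cache: dict[str, tuple] = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = {
        (c, d): int(s.generate_state(1)[0] % (2**31))
        for (c, d, _), s in zip(table.rows, ss.spawn(len(table.rows)))
    }
    for compound, disease, _label in table.rows:
        if compound not in compound_sets or disease not in disease_sets:
            warnings.warn(f"pair ({compound}, {disease}) has no target sets; excluded", stacklevel=2)
            continue
        if disease not in dmat_cache:
            T_m = sorted(set(disease_sets[disease].members) & set(g.graph.nodes))
            if not T_m:
                warnings.warn(f"disease {disease!r} unmappable; pairs excluded", stacklevel=2)
                dmat_cache[disease] = None
            else:
                dmat_cache[disease] = distance_matrix(g, T_m)
        if dmat_cache[disease] is None:
            continue
        try:
            res = proximity_zscore(
                g,
                compound_sets[compound],
                disease_sets[disease],
                bins,
                metric="closest",
                n_reps=n_reps,
                seed=child_seeds[(compound, disease)],
                _dmat=dmat_cache[disease],
            )
        except ValueError as exc:
            warnings.warn(f"pair ({compound}, {disease}) excluded: {exc}", stacklevel=2)
            continue
        scores[(compound, disease)] = -res.z_closest
    return scores


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC of scores against boolean labels.

    The AUC equals the Mann–Whitney pair statistic (ties count 0.5); the
    curve is the full threshold sweep over observed scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(auc=auc, n_pos=n_pos, n_neg=n_neg, curve_points=list(zip(fpr.tolist(), tpr.tolist())))


def _bootstrap_aucs(scores: np.ndarray, labels: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """AUC of ``n_boot`` stratified resamples, computed via the rank
    identity AUC = (R_pos − n_pos(n_pos+1)/2)/(n_pos·n_neg) per row."""
    pos = scores[labels]
    neg = scores[~labels]
    n_pos, n_neg = pos.size, neg.size
    pos_b = pos[rng.integers(0, n_pos, size=(n_boot, n_pos))]
    neg_b = neg[rng.integers(0, n_neg, size=(n_boot, n_neg))]
    both = np.concatenate([pos_b, neg_b], axis=1)
    ranks = rankdata(both, axis=1)
    r_pos = ranks[:, :n_pos].sum(axis=1)
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def compare_auc(
    scores_a: Sequence[float],
    labels_a: Sequence[bool],
    scores_b: Sequence[float],
    labels_b: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for AUC_A − AUC_B by stratified bootstrap.

    Positives and negatives of each score set are resampled independently
    ``n_boot`` times; the p-value is the (add-one smoothed) two-sided
    percentile of 0 in the bootstrap difference distribution.
    """
    a = np.asarray(scores_a, dtype=float)
    la = np.asarray(labels_a, dtype=bool)
    b = np.asarray(scores_b, dtype=float)
    lb = np.asarray(labels_b, dtype=bool)
    roc_auc(a, la)  # validates both inputs
    roc_auc(b, lb)
    rng = np.random.default_rng(seed)
    auc_a = _bootstrap_aucs(a, la, n_boot, rng)
    auc_b = _bootstrap_aucs(b, lb, n_boot, rng)
    delta = auc_a - auc_b
    p_lo = (1 + int((delta <= 0).sum())) / (n_boot + 1)
    p_hi = (1 + int((delta >= 0).sum())) / (n_boot + 1)
    return float(min(1.0, 2 * min(p_lo, p_hi)))
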