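"""Target-set containers and Jaccard overlap between compound target sets.

Compounds of a multi-component natural product typically hit largely
disjoint target sets; the pairwise Jaccard index quantifies that overlap.
A tiny mean off-diagonal JI says the compounds act through distinct
proteins even when those proteins cluster in the same interactome
neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .interactome import canonical_id

__all__ = [
    "TargetSet",
    "SimilarityMatrix",
    "jaccard_index",
    "pairwise_jaccard",
    "read_gmt",
    "write_gmt",
    "read_membership_tsv",
]


@dataclass(frozen=True)
class TargetSet:
    """A named set of canonical protein IDs (one compound's targets, or a
    disease protein set)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValueError("target set needs a non-empty name")
        if not self.members:
            raise ValueError(f"target set {self.name!r} is empty")

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[object]) -> "TargetSet":
        return cls(name=str(name).strip(), members=frozenset(canonical_id(m) for m in members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SimilarityMatrix:
    names: list[str]
    values: np.ndarray  # symmetric, diagonal 1, entries in [0, 1]
    mean_offdiag: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.names, columns=self.names)


def jaccard_index(a: TargetSet, b: TargetSet) -> float:
    """|a∩b| / |a∪b| of two non-empty target sets."""
    inter = len(a.members & b.members)
    union = len(a.members | b.members)
    return inter / union


def pairwise_jaccard(sets: Sequence[TargetSet]) -> SimilarityMatrix:
    """All-pairs JI matrix; ``mean_offdiag`` averages the strict upper
    triangle (self-pairs excluded — they would dominate a small mean)."""
    if len(sets) < 2:
        raise ValueError("need at least two target sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate target set names: {dupes}")
    n = len(sets)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = jaccard_index(sets[i], sets[j])
    iu = np.triu_indices(n, k=1)
    return SimilarityMatrix(names=names, values=values, mean_offdiag=float(values[iu].mean()))


def read_gmt(path: str | Path) -> list[TargetSet]:
    """GMT: ``name<TAB>description<TAB>member...`` per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line needs name, description, >=1 member: {line[:60]!r}")
        out.append(TargetSet.from_iterable(fields[0], fields[2:]))
    return out


def write_gmt(sets: Sequence[TargetSet], path: str | Path) -> None:
    lines = [
        "\t".join([s.name, "na"] + sorted(s.members)) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_membership_tsv(path: str | Path) -> list[TargetSet]:
    """Two-column TSV ``set_name<TAB>member`` (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("membership TSV needs two columns: set_name, member")
    name_col, member_col = df.columns[:2]
    out = []
    for name, grp in df.groupby(name_col, sort=True):
        out.append(TargetSet.from_iterable(str(name), grp[member_col]))
    return out
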