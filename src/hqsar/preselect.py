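"""Heuristic descriptor preselection applied before the subset search.

Three rules, in order, all computed on training compounds only so that
test compounds can never influence selection:

1. drop descriptors with any missing value (``drop_incomplete``),
2. drop descriptors that do not vary (``drop_invariant``),
3. collapse groups of near-duplicate descriptors (pairwise |Pearson r|
   above ``r_dup``, default 0.99), keeping the member best correlated
   with the response (``collapse_duplicates``).

The companion cap of 0.8 on the intercorrelation of descriptors that
co-occur inside one model is enforced downstream by the subset search,
not here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import DescriptorMatrix

__all__ = [
    "PreselectReport",
    "drop_incomplete",
    "drop_invariant",
    "collapse_duplicates",
    "correlation_matrix",
    "preselect",
]


@dataclass
class PreselectReport:
    dropped_incomplete: list[str] = field(default_factory=list)
    dropped_invariant: list[str] = field(default_factory=list)
    collapsed_duplicates: list[tuple[str, str]] = field(default_factory=list)
    survivors: list[str] = field(default_factory=list)

    @property
    def dropped(self) -> list[str]:
        return (
            self.dropped_incomplete
            + self.dropped_invariant
            + [d for _, d in self.collapsed_duplicates]
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def drop_incomplete(matrix: DescriptorMatrix) -> tuple[DescriptorMatrix, list[str]]:
    """Remove descriptors with >= 1 missing value among training compounds."""
    train = matrix.training_values()
    dropped = [c for c in train.columns if train[c].isna().any()]
    keep = [c for c in train.columns if c not in dropped]
    return matrix.select_descriptors(keep), dropped


def drop_invariant(
    matrix: DescriptorMatrix, tol: float = 1e-12
) -> tuple[DescriptorMatrix, list[str]]:
    """Remove descriptors whose training range (max - min) is <= tol."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    train = matrix.training_values()
    rng = train.max(axis=0) - train.min(axis=0)
    dropped = [c for c in train.columns if not rng[c] > tol]
    keep = [c for c in train.columns if c not in dropped]
    return matrix.select_descriptors(keep), dropped


def correlation_matrix(matrix: DescriptorMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between descriptors over training compounds.

    Exactly symmetric with a unit diagonal; raises on zero-variance
    columns (those must be removed by :func:`drop_invariant` first).
    """
    train = (
        matrix.training_values() if isinstance(matrix, DescriptorMatrix) else matrix
    )
    arr = train.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        bad = [c for c, s in zip(train.columns, sd) if s == 0]
        raise ValueError(f"zero-variance descriptors: {bad}")
    corr = np.corrcoef(arr, rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=train.columns, columns=train.columns)


def collapse_duplicates(
    matrix: DescriptorMatrix,
    y: pd.Series | np.ndarray,
    r_dup: float = 0.99,
) -> tuple[DescriptorMatrix, list[tuple[str, str]]]:
    """Collapse groups of near-duplicate descriptors.

    Descriptors are grouped by connecting every pair with training
    |Pearson r| > ``r_dup``; within each group the member with the
    largest |correlation with y| is kept (ties break to the earlier
    descriptor in matrix order).  Returns the reduced matrix and the
    (kept, dropped) pairs.
    """
    if not (0 < r_dup <= 1):
        raise ValueError("r_dup must be in (0, 1]")
    train = matrix.training_values()
    yv = np.asarray(y, dtype=float)
    if yv.shape[0] != train.shape[0]:
        raise ValueError("y must align with training compounds")

    corr = correlation_matrix(matrix).to_numpy()
    names = list(train.columns)
    n = len(names)
    # connected components of the |r| > r_dup graph (union-find)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr[i, j]) > r_dup:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    sd = train.to_numpy().std(axis=0)
    yc = yv - yv.mean()
    ysd = yc.std()
    with np.errstate(invalid="ignore"):
        ry = np.abs(
            (train.to_numpy() - train.to_numpy().mean(axis=0)).T @ yc
        ) / (train.shape[0] * sd * (ysd if ysd > 0 else 1.0))

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    pairs: list[tuple[str, str]] = []
    drop: set[str] = set()
    for members in groups.values():
        if len(members) == 1:
            continue
        # max |corr with y|; ties -> earliest in matrix order
        kept = max(members, key=lambda i: (ry[i], -i))
        for i in members:
            if i != kept:
                pairs.append((names[kept], names[i]))
                drop.add(names[i])
    keep = [c for c in names if c not in drop]
    return matrix.select_descriptors(keep), pairs


def preselect(
    matrix: DescriptorMatrix,
    y: pd.Series | np.ndarray,
    r_dup: float = 0.99,
    invariant_tol: float = 1e-12,
) -> tuple[DescriptorMatrix, PreselectReport]:
    """Run the full preselection pipeline and assemble the report.

    ``y`` must align with the matrix's training compounds.
    """
    m1, inc = drop_incomplete(matrix)
    m2, inv = drop_invariant(m1, tol=invariant_tol)
    m3, dup = collapse_duplicates(m2, y, r_dup=r_dup)
    report = PreselectReport(
        dropped_incomplete=inc,
        dropped_invariant=inv,
        collapsed_duplicates=dup,
        survivors=m3.descriptor_names,
    )
    return m3, report
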