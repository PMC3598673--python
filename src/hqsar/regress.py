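"""Ordinary least squares with the statistics a descriptor-model listing
prints — coefficient X, standard error DX, t = |X|/DX per term, and the
header statistics N, R2, s2, F and the leave-one-out Q2.

Fits use a QR decomposition of the design matrix (intercept always
included).  Conventions for degenerate inputs:

* TSS = 0 (constant response): R2 = 0, Q2 = 0, all coefficients 0, with a
  warning — this keeps subset searches NaN-free.
* Perfect fit (RSS = 0): s2 = 0, every DX = 0 and t = +inf, F = +inf.

Q2 = 1 - PRESS/TSS is computed through the hat-matrix identity
e_loo_i = e_i / (1 - h_ii); when any leverage approaches 1 the
implementation falls back to explicit leave-one-out refits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Term", "LinearModel", "CollinearityError", "fit_ols", "loo_q2", "predict"]

_RANK_TOL = 1e-10


class CollinearityError(ValueError):
    """Design matrix is rank deficient; carries the offending columns."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear design columns: {columns}")


@dataclass(frozen=True)
class Term:
    name: str
    coef: float  # X
    se: float  # DX
    t: float  # |X| / DX


@dataclass
class LinearModel:
    """An intercept plus selected descriptor terms with fit statistics."""

    intercept: float
    intercept_se: float
    intercept_t: float
    terms: list[Term]
    n: int
    r2: float
    s2: float
    f_stat: float
    q2: float

    @property
    def size(self) -> int:
        return len(self.terms)

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def coefs(self) -> np.ndarray:
        return np.array([t.coef for t in self.terms])

    def to_dict(self) -> dict:
        """JSON layout mirroring a model listing: row 0 is the intercept,
        rows 1..k the descriptor terms, plus the header statistics."""
        rows = [
            {"row": 0, "X": self.intercept, "DX": self.intercept_se,
             "t": self.intercept_t, "name": "Intercept"}
        ]
        rows += [
            {"row": i + 1, "X": t.coef, "DX": t.se, "t": t.t, "name": t.name}
            for i, t in enumerate(self.terms)
        ]
        return {
            "N": self.n,
            "R2": self.r2,
            "F": self.f_stat,
            "s2": self.s2,
            "Q2": self.q2,
            "size": self.size,
            "rows": rows,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        rows = d["rows"]
        ic = rows[0]
        return cls(
            intercept=ic["X"],
            intercept_se=ic["DX"],
            intercept_t=ic["t"],
            terms=[Term(r["name"], r["X"], r["DX"], r["t"]) for r in rows[1:]],
            n=d["N"],
            r2=d["R2"],
            s2=d["s2"],
            f_stat=d["F"],
            q2=d["Q2"],
        )


def _as_design(
    X: pd.DataFrame | np.ndarray, names: Sequence[str] | None
) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if names is None:
        names = [f"x{j}" for j in range(arr.shape[1])]
    return arr, list(names)


def fit_ols(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    names: Sequence[str] | None = None,
    compute_q2: bool = True,
) -> LinearModel:
    """Least-squares fit of y on the given descriptors plus an intercept.

    Requires n >= k + 2 and a full-rank design.  Returns the fitted
    :class:`LinearModel` with R2, s2 = RSS/(n-k-1), the overall
    F = (R2/k)/((1-R2)/(n-k-1)), per-term DX = sqrt(s2 [(X'X)^-1]_jj) and
    t = |X|/DX, and (when n >= k + 3) the leave-one-out Q2.
    """
    Xa, names = _as_design(X, names)
    yv = np.asarray(y, dtype=float).ravel()
    n, k = Xa.shape
    if yv.shape[0] != n:
        raise ValueError("X and y lengths differ")
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 compounds (n={n}, k={k})")

    A = np.column_stack([np.ones(n), Xa])
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    if diag.min() <= _RANK_TOL * max(diag.max(), 1.0):
        bad = [
            (["Intercept"] + names)[j]
            for j in range(k + 1)
            if diag[j] <= _RANK_TOL * max(diag.max(), 1.0)
        ]
        raise CollinearityError(bad)

    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss <= 1e-30 * max(1.0, float(np.sum(yv**2))):
        warnings.warn("response has zero variance; R2 and Q2 defined as 0")
        zero_terms = [Term(nm, 0.0, 0.0, 0.0) for nm in names]
        return LinearModel(
            intercept=float(yv.mean()), intercept_se=0.0, intercept_t=0.0,
            terms=zero_terms, n=n, r2=0.0, s2=0.0, f_stat=0.0, q2=0.0,
        )

    from scipy.linalg import solve_triangular

    b = solve_triangular(R, Q.T @ yv)
    resid = yv - A @ b
    rss = max(float(resid @ resid), 0.0)
    if rss <= 1e-24 * tss:  # numerically perfect fit
        rss = 0.0
        resid = np.zeros_like(resid)
    r2 = 1.0 - rss / tss
    dof = n - k - 1
    s2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = float((r2 / k) / ((1.0 - r2) / dof)) if r2 < 1.0 else float("inf")

    Rinv = solve_triangular(R, np.eye(k + 1))
    xtx_inv_diag = np.sum(Rinv**2, axis=1)
    se = np.sqrt(np.maximum(s2 * xtx_inv_diag, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, np.abs(b) / se, np.inf)

    q2 = float("nan")
    if compute_q2 and n >= k + 3:
        h = np.sum(Q**2, axis=1)
        if np.any(h > 1.0 - 1e-8):
            q2 = _loo_q2_refit(A, yv, tss)
        else:
            press = float(np.sum((resid / (1.0 - h)) ** 2))
            q2 = 1.0 - press / tss

    terms = [
        Term(nm, float(b[j + 1]), float(se[j + 1]), float(tvals[j + 1]))
        for j, nm in enumerate(names)
    ]
    return LinearModel(
        intercept=float(b[0]), intercept_se=float(se[0]),
        intercept_t=float(tvals[0]), terms=terms, n=n, r2=r2, s2=s2,
        f_stat=f_stat, q2=q2,
    )


def _loo_q2_refit(A: np.ndarray, y: np.ndarray, tss: float) -> float:
    """Explicit leave-one-out refits (fallback for leverage ~ 1)."""
    n = A.shape[0]
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        bi, *_ = np.linalg.lstsq(A[keep], y[keep], rcond=None)
        press += float((y[i] - A[i] @ bi) ** 2)
    return 1.0 - press / tss


def loo_q2(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    names: Sequence[str] | None = None,
) -> float:
    """Leave-one-out cross-validated Q2 = 1 - PRESS/TSS.

    Uses the hat-matrix shortcut e_loo = e / (1 - h); falls back to
    explicit refits when a leverage approaches 1.  Requires n >= k + 3.
    """
    Xa, names = _as_design(X, names)
    n, k = Xa.shape
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 for leave-one-out (n={n}, k={k})")
    model = fit_ols(Xa, y, names=names, compute_q2=True)
    return model.q2


def predict(
    model: LinearModel, rows: pd.DataFrame | Mapping | np.ndarray
) -> np.ndarray:
    """Predict responses: intercept + sum of coef * descriptor value.

    ``rows`` may be a DataFrame (columns looked up by term name), a mapping
    of name -> vector, or a plain array whose columns already follow the
    model's term order.  A missing term raises, naming the descriptor.
    """
    names = model.term_names
    if isinstance(rows, pd.DataFrame):
        missing = [nm for nm in names if nm not in rows.columns]
        if missing:
            raise KeyError(f"missing descriptor values for: {missing}")
        mat = rows[names].to_numpy(dtype=float)
        if np.isnan(mat).any():
            bad = [nm for nm in names if rows[nm].isna().any()]
            raise ValueError(f"NaN descriptor values for: {bad}")
    elif isinstance(rows, Mapping):
        missing = [nm for nm in names if nm not in rows]
        if missing:
            raise KeyError(f"missing descriptor values for: {missing}")
        mat = np.column_stack([np.asarray(rows[nm], dtype=float) for nm in names])
    else:
        mat = np.asarray(rows, dtype=float)
        if mat.ndim == 1:
            mat = mat[None, :] if model.size > 1 else mat[:, None]
        if mat.shape[1] != model.size:
            raise ValueError(
                f"expected {model.size} descriptor columns, got {mat.shape[1]}"
            )
    return model.intercept + mat @ model.coefs
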