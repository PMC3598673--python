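"""Heuristic best-subset search for the best linear descriptor model.

The search grows models one descriptor at a time, CODESSA-HM style:

* size-1 stage: fit every preselected descriptor, rank by R2, keep the
  top ``beam_width`` subsets;
* size-k stage: extend every kept subset by every descriptor whose
  training |Pearson r| with each included descriptor is <= ``r_pair``
  (default 0.8, guarding against over-optimistic collinear fits), refit,
  discard candidates with an insignificant term (t below the two-sided
  critical value at alpha = 0.05 unless ``t_min`` is fixed), rank the
  survivors by R2 and keep the top ``beam_width``;
* stop at ``max_size`` (default: floor(N/3), mirroring the rule that a
  final model carries fewer descriptors than a third of the molecules)
  or when no candidate survives;
* a backward-refinement sweep then revisits each per-size winner: if
  deleting one term from the size-(k+1) winner beats the size-k winner,
  the better subset replaces it (greedy growth can carry the good subset
  only inside a superset; deletion recovers it).

Final-model choice.  Because R2 can only grow with size, picking the
highest-R2 (or highest-F) ladder entry would routinely absorb one
spuriously significant extra descriptor: the best size-(k+1) candidate
is a maximum over ~d extensions, so its weakest t statistic is an
extreme order statistic, not an ordinary t.  The choice rule therefore
demands selection-level significance: a ladder size is eligible only if
its model passes Q2 >= ``q2_min`` and every descriptor term's t exceeds
the two-sided critical value at ``alpha_enter`` Bonferroni-corrected for
the number of candidate descriptors times the number of growth steps.
Among eligible sizes the model with the highest overall F is chosen
(ties break to the smaller size), matching the practice of ranking
final models by F and t.  The full ladder is always returned so other
choice rules can be applied post hoc.

Candidate screening runs on a precomputed Gram matrix for speed; every
model that leaves this module is refit with the QR-based
:func:`hqsar.regress.fit_ols`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DescriptorMatrix
from .preselect import correlation_matrix
from .regress import LinearModel, fit_ols

__all__ = ["SearchConfig", "ModelLadder", "heuristic_search", "rank_report"]


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds of the heuristic search.

    r_pair
        cap on |Pearson r| between descriptors co-occurring in one model.
    max_size
        largest model size, or "auto" for floor(N/3).
    beam_width
        subsets kept per stage; set >= C(d, k) for exhaustive search.
    t_min
        per-term significance gate; "auto" recomputes the two-sided
        critical value at ``alpha`` with N - k - 1 df at each size;
        a number fixes the gate (0 disables it).
    q2_min
        leave-one-out acceptability gate on the chosen model (0.5, the
        usual CoMFA-style criterion).
    alpha
        significance level behind the "auto" t gate.
    alpha_enter
        family-wise level of the Bonferroni-corrected selection t gate
        used when choosing the final model size.
    seed
        recorded in serialized artifacts; the search itself is
        deterministic.
    """

    r_pair: float = 0.8
    max_size: int | str = "auto"
    beam_width: int = 50
    t_min: float | str = "auto"
    q2_min: float = 0.5
    alpha: float = 0.05
    alpha_enter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_pair <= 1):
            raise ValueError("r_pair must be in (0, 1]")
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.max_size != "auto" and int(self.max_size) < 1:
            raise ValueError("max_size must be >= 1 or 'auto'")

    def resolve_max_size(self, n: int, d: int) -> int:
        k = n // 3 if self.max_size == "auto" else int(self.max_size)
        # fits need n >= k + 2; Q2 needs n >= k + 3
        return max(1, min(k, d, n - 3))

    def t_crit(self, n: int, k: int) -> float:
        if self.t_min != "auto":
            return float(self.t_min)
        df = n - k - 1
        return float(stats.t.ppf(1.0 - self.alpha / 2.0, df)) if df > 0 else np.inf

    def to_dict(self) -> dict:
        return {
            "r_pair": self.r_pair,
            "max_size": self.max_size,
            "beam_width": self.beam_width,
            "t_min": self.t_min,
            "q2_min": self.q2_min,
            "alpha": self.alpha,
            "alpha_enter": self.alpha_enter,
            "seed": self.seed,
        }


@dataclass
class ModelLadder:
    """Best model per size, the chosen final model, and a search audit."""

    best_per_size: dict[int, LinearModel]
    chosen_size: int
    audit: dict
    config: SearchConfig

    @property
    def chosen(self) -> LinearModel:
        return self.best_per_size[self.chosen_size]

    @property
    def sizes(self) -> list[int]:
        return sorted(self.best_per_size)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "chosen_size": self.chosen_size,
            "best_per_size": {
                str(k): m.to_dict() for k, m in sorted(self.best_per_size.items())
            },
            "audit": self.audit,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


class _GramFitter:
    """Candidate screening on the precomputed Gram matrix.

    Returns (rss, coefs, min descriptor |t|) per subset; used only to
    rank and filter candidates — reported models are refit by QR.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        n = X.shape[0]
        A = np.column_stack([np.ones(n), X])
        self.n = n
        self.G = A.T @ A
        self.Ay = A.T @ y
        self.yy = float(y @ y)
        self.tss = float(np.sum((y - y.mean()) ** 2))

    def fit(self, subset: tuple[int, ...]):
        ia = np.array((0,) + tuple(j + 1 for j in subset))
        Gs = self.G[np.ix_(ia, ia)]
        try:
            Li = np.linalg.inv(Gs)
        except np.linalg.LinAlgError:
            return None
        ay = self.Ay[ia]
        b = Li @ ay
        rss = max(self.yy - float(b @ ay), 0.0)
        k = len(subset)
        dof = self.n - k - 1
        s2 = rss / dof
        var = s2 * np.diag(Li)[1:]
        if np.any(var < -1e-9):  # numerically broken inverse
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            tmin = float(
                np.min(np.where(var > 0, np.abs(b[1:]) / np.sqrt(np.abs(var)), np.inf))
            )
        return rss, b, tmin


def heuristic_search(
    matrix: DescriptorMatrix | pd.DataFrame,
    y: pd.Series | np.ndarray,
    config: SearchConfig | None = None,
) -> ModelLadder:
    """Run the staged beam search and choose the final model.

    ``matrix`` should already be preselected (complete, varying,
    de-duplicated descriptors); ``y`` aligns with its training compounds.
    Deterministic for fixed inputs and config.
    """
    config = config or SearchConfig()
    if isinstance(matrix, DescriptorMatrix):
        train = matrix.training_values()
    else:
        train = matrix
    names = list(train.columns)
    X = train.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if d < 1:
        raise ValueError("matrix has no descriptors")
    if yv.shape[0] != n:
        raise ValueError("y must align with training compounds")

    max_size = config.resolve_max_size(n, d)
    abscorr = np.abs(correlation_matrix(train).to_numpy())
    compatible = abscorr <= config.r_pair
    np.fill_diagonal(compatible, False)

    fitter = _GramFitter(X, yv)
    audit: dict = {"stages": {}}
    best_subset: dict[int, tuple[int, ...]] = {}
    best_rss: dict[int, float] = {}

    # stage 1: every single descriptor, no t gate
    scored = []
    for j in range(d):
        res = fitter.fit((j,))
        if res is not None:
            scored.append((res[0], (j,)))
    if not scored:
        raise RuntimeError(f"no size-1 model could be fitted; audit={audit}")
    scored.sort(key=lambda s: (s[0], s[1]))
    beam = [sub for _, sub in scored[: config.beam_width]]
    best_subset[1], best_rss[1] = beam[0], scored[0][0]
    audit["stages"][1] = {
        "evaluated": len(scored), "rejected_t": 0, "kept": len(beam)
    }

    for k in range(2, max_size + 1):
        t_gate = config.t_crit(n, k)
        seen: set[tuple[int, ...]] = set()
        scored = []
        n_eval = n_reject_t = 0
        for sub in beam:
            ok = compatible[sub[0]].copy()
            for j in sub[1:]:
                ok &= compatible[j]
            for j in np.nonzero(ok)[0]:
                cand = tuple(sorted(sub + (int(j),)))
                if cand in seen:
                    continue
                seen.add(cand)
                res = fitter.fit(cand)
                if res is None:
                    continue
                n_eval += 1
                rss, _, tmin = res
                if tmin < t_gate:
                    n_reject_t += 1
                    continue
                scored.append((rss, cand))
        audit["stages"][k] = {
            "evaluated": n_eval, "rejected_t": n_reject_t, "kept": 0
        }
        if not scored:
            break
        scored.sort(key=lambda s: (s[0], s[1]))
        beam = [sub for _, sub in scored[: config.beam_width]]
        audit["stages"][k]["kept"] = len(beam)
        best_subset[k], best_rss[k] = beam[0], scored[0][0]

    # backward refinement: deleting one term from a larger winner can beat
    # the greedy winner one size down (the beam may have carried the good
    # subset only inside a superset); sweep top-down until stable
    n_refined = 0
    for _ in range(len(best_subset)):
        changed = False
        for k in sorted(best_subset, reverse=True):
            if k - 1 not in best_subset:
                continue
            t_gate = config.t_crit(n, k - 1)
            sub = best_subset[k]
            for drop in sub:
                cand = tuple(j for j in sub if j != drop)
                res = fitter.fit(cand)
                if res is None:
                    continue
                rss, _, tmin = res
                if rss < best_rss[k - 1] * (1.0 - 1e-12) and (
                    k - 1 == 1 or tmin >= t_gate
                ):
                    best_subset[k - 1], best_rss[k - 1] = cand, rss
                    changed = True
                    n_refined += 1
        if not changed:
            break
    audit["backward_refinements"] = n_refined

    # refit the per-size winners exactly (QR) with Q2
    best_per_size = {
        k: fit_ols(X[:, list(sub)], yv, names=[names[j] for j in sub])
        for k, sub in best_subset.items()
    }

    chosen_size, gate_audit = _choose(best_per_size, config, n, d)
    audit["choice"] = gate_audit
    return ModelLadder(
        best_per_size=best_per_size,
        chosen_size=chosen_size,
        audit=audit,
        config=config,
    )


def _choose(
    best_per_size: dict[int, LinearModel],
    config: SearchConfig,
    n: int,
    d: int,
) -> tuple[int, dict]:
    sizes = sorted(best_per_size)
    n_steps = max(len(sizes) - 1, 1)
    n_tests = max(d * n_steps, 1)

    def t_select(k: int) -> float:
        # a fixed t_min is taken at face value; "auto" applies the
        # selection-level Bonferroni correction on top of alpha_enter
        if config.t_min != "auto":
            return float(config.t_min)
        df = n - k - 1
        if df <= 0:
            return np.inf
        return float(stats.t.ppf(1.0 - config.alpha_enter / (2.0 * n_tests), df))

    def eligible(k: int) -> bool:
        m = best_per_size[k]
        gate = t_select(k)
        tmin = min((t.t for t in m.terms), default=np.inf)
        return (not np.isnan(m.q2)) and m.q2 >= config.q2_min and tmin >= gate

    candidates = [k for k in sizes if eligible(k)]
    gate_audit = {
        "eligible_sizes": candidates,
        "gates_met": bool(candidates),
        "n_selection_tests": n_tests,
        "selection_t_crit": {k: t_select(k) for k in sizes},
    }
    if candidates:
        # highest overall F; ties -> smaller size
        chosen = max(candidates, key=lambda k: (best_per_size[k].f_stat, -k))
    else:
        # nothing passes the gates: fall back to the most stable model
        chosen = max(
            best_per_size,
            key=lambda k: (
                -np.inf if np.isnan(best_per_size[k].q2) else best_per_size[k].q2,
                -k,
            ),
        )
    return chosen, gate_audit


def rank_report(ladder: ModelLadder) -> pd.DataFrame:
    """Per-size summary table: R2, Q2, F, s2, terms and the chosen flag."""
    if not ladder.best_per_size:
        raise ValueError("empty ladder")
    rows = []
    for k in ladder.sizes:
        m = ladder.best_per_size[k]
        rows.append(
            {
                "size": k,
                "R2": m.r2,
                "Q2": m.q2,
                "F": m.f_stat,
                "s2": m.s2,
                "terms": "; ".join(m.term_names),
                "chosen": k == ladder.chosen_size,
            }
        )
    return pd.DataFrame(rows).set_index("size")
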