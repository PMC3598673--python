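"""External validation of a fitted descriptor model.

The headline statistic is the absolute relative error (ARE),
|actual - predicted| / |actual|, computed per test compound, with an
overall pass when every ARE is within a threshold (default 10%).  The
module also provides the per-descriptor odds-ratio screen and the full
two-fold cross-validation scheme: split by role, categorize descriptors
by class, screen by odds ratio, fit on the training set, and select the
ladder candidate with the lowest mean test ARE.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DescriptorMatrix, split_train_test
from .hmsearch import ModelLadder, SearchConfig, heuristic_search
from .preselect import PreselectReport, preselect
from .regress import LinearModel, predict

__all__ = [
    "ValidationReport",
    "SchemeReport",
    "absolute_relative_error",
    "external_validation",
    "descriptor_odds_ratio",
    "crossvalidate_scheme",
]


def absolute_relative_error(actual: float, predicted: float) -> float:
    """ARE = |actual - predicted| / |actual|; undefined for actual = 0."""
    if actual == 0:
        raise ValueError("ARE is undefined for actual = 0")
    return abs(actual - predicted) / abs(actual)


@dataclass
class ValidationReport:
    """Experimental vs predicted values on the test set, with per-compound
    ARE, the squared experimental/predicted correlation (test_r2), the
    test-set Q2 analogue 1 - sum((e-p)^2)/sum((e-mean(e))^2), and pass
    flags against the ARE threshold."""

    per_compound: pd.DataFrame  # experimental, predicted, are, passed
    threshold: float
    test_r2: float
    test_q2_analog: float
    n_pass: int
    overall_pass: bool

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "test_R2": self.test_r2,
            "test_Q2_analog": self.test_q2_analog,
            "n_pass": self.n_pass,
            "overall_pass": self.overall_pass,
            "per_compound": self.per_compound.reset_index().to_dict("records"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def external_validation(
    model: LinearModel,
    test_matrix: DescriptorMatrix | pd.DataFrame,
    y_test: pd.Series | np.ndarray,
    threshold: float = 0.10,
) -> ValidationReport:
    """Predict the test set with ``model`` and score the AREs.

    ``overall_pass`` is True iff every compound's ARE <= threshold.
    """
    if isinstance(test_matrix, DescriptorMatrix):
        rows = test_matrix.values
    else:
        rows = test_matrix
    yv = np.asarray(y_test, dtype=float).ravel()
    if yv.shape[0] != rows.shape[0]:
        raise ValueError("y_test must align with the test matrix rows")
    pred = predict(model, rows)
    are = np.array([absolute_relative_error(a, p) for a, p in zip(yv, pred)])
    passed = are <= threshold
    table = pd.DataFrame(
        {
            "experimental": yv,
            "predicted": pred,
            "are": are,
            "passed": passed,
        },
        index=rows.index if hasattr(rows, "index") else None,
    )
    resid2 = float(np.sum((yv - pred) ** 2))
    tss = float(np.sum((yv - yv.mean()) ** 2))
    if tss > 0:
        q2a = 1.0 - resid2 / tss
        sp = float(np.std(pred))
        r = float(np.corrcoef(yv, pred)[0, 1]) if sp > 0 else 0.0
        r2 = r * r
    else:
        q2a = 0.0
        r2 = 1.0 if resid2 == 0 else 0.0
    if resid2 == 0:
        r2 = 1.0
    return ValidationReport(
        per_compound=table,
        threshold=threshold,
        test_r2=r2,
        test_q2_analog=q2a,
        n_pass=int(passed.sum()),
        overall_pass=bool(passed.all()),
    )


def descriptor_odds_ratio(
    matrix: DescriptorMatrix | pd.DataFrame, y: pd.Series | np.ndarray
) -> pd.Series:
    """Median-split odds ratio of each descriptor against the response.

    Both the descriptor and the response are dichotomized at their
    medians ("high" = strictly above); the 2x2 cell counts get the
    Haldane–Anscombe +0.5 correction and the ratio (a*d)/(b*c) is
    returned per descriptor.  A screening statistic only: it never gates
    the subset search.
    """
    if isinstance(matrix, DescriptorMatrix):
        vals = matrix.training_values()
    else:
        vals = matrix
    yv = np.asarray(y, dtype=float).ravel()
    if vals.shape[0] != yv.shape[0]:
        raise ValueError("y must align with the matrix rows")
    if vals.shape[0] < 4:
        raise ValueError("need >= 4 compounds for the odds-ratio screen")
    y_hi = yv > np.median(yv)
    out = {}
    for name in vals.columns:
        x = vals[name].to_numpy(dtype=float)
        med = np.median(x)
        x_hi = x > med
        if not x_hi.any() and (x == med).all():
            raise ValueError(
                f"descriptor {name!r} is constant at its median; "
                "run drop_invariant first"
            )
        a = np.sum(x_hi & y_hi) + 0.5
        b = np.sum(x_hi & ~y_hi) + 0.5
        c = np.sum(~x_hi & y_hi) + 0.5
        d = np.sum(~x_hi & ~y_hi) + 0.5
        out[name] = (a * d) / (b * c)
    return pd.Series(out, name="odds_ratio")


@dataclass
class SchemeReport:
    """Outcome of the two-fold cross-validation scheme."""

    preselect_report: PreselectReport
    class_counts: dict[str, int]
    odds_ratios: pd.Series
    descriptor_numbers: dict[str, int]
    ladder: ModelLadder
    candidate_scores: pd.DataFrame  # size, mean test ARE, max ARE
    selected_size: int
    validation: ValidationReport
    model_p_value: float
    seed: int

    @property
    def selected(self) -> LinearModel:
        return self.ladder.best_per_size[self.selected_size]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "class_counts": self.class_counts,
            "preselect": json.loads(self.preselect_report.to_json()),
            "odds_ratios": self.odds_ratios.round(6).to_dict(),
            "descriptor_numbers": self.descriptor_numbers,
            "candidate_scores": self.candidate_scores.reset_index().to_dict("records"),
            "selected_size": self.selected_size,
            "selected_model": self.selected.to_dict(),
            "model_p_value": self.model_p_value,
            "validation": self.validation.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def crossvalidate_scheme(
    matrix: DescriptorMatrix,
    y: Mapping[str, float] | pd.Series,
    roles: Mapping[str, str] | None = None,
    config: SearchConfig | None = None,
    threshold: float = 0.10,
) -> SchemeReport:
    """Run the full validation scheme on one response.

    1. Split the compounds into the training and test subsets by role.
    2. Categorize the descriptors by class (counts reported).
    3. Screen each training descriptor by its median-split odds ratio.
    4. Fit the ladder on the training subset only, score every per-size
       candidate by its mean test-set ARE, and select the candidate with
       the lowest mean ARE; model consistency is summarized by the
       overall-F p-value of the selected model on the training set.

    Descriptor numbering uses the seeded generator from ``config`` (a
    reproducible stand-in for drawing numbers from an external random
    source); it is recorded in the report and does not affect fitting.
    """
    config = config or SearchConfig()
    if roles is not None:
        compounds = [c for c in matrix.compounds]
        matrix = DescriptorMatrix(
            compounds=[
                type(c)(c.id, c.name, roles[c.id], c.pharm_class) for c in compounds
            ],
            descriptors=list(matrix.descriptors),
            values=matrix.values.copy(),
        )
    train_m, test_m = split_train_test(matrix)
    y = pd.Series(y)
    y_train = y.loc[train_m.values.index].to_numpy(dtype=float)
    y_test = y.loc[test_m.values.index].to_numpy(dtype=float)

    class_counts: dict[str, int] = {}
    for d in matrix.descriptors:
        class_counts[d.dclass] = class_counts.get(d.dclass, 0) + 1

    pre_m, pre_report = preselect(train_m, y_train)
    odds = descriptor_odds_ratio(pre_m, y_train)

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(pre_m.descriptor_names))
    numbers = {
        name: int(order[i]) + 1 for i, name in enumerate(pre_m.descriptor_names)
    }

    ladder = heuristic_search(pre_m, y_train, config)

    scores = []
    for k in ladder.sizes:
        m = ladder.best_per_size[k]
        rep = external_validation(
            m, test_m.values[m.term_names], y_test, threshold=threshold
        )
        scores.append(
            {
                "size": k,
                "mean_are": float(rep.per_compound["are"].mean()),
                "max_are": float(rep.per_compound["are"].max()),
                "test_R2": rep.test_r2,
            }
        )
    score_df = pd.DataFrame(scores).set_index("size")
    selected_size = int(score_df["mean_are"].idxmin())
    selected = ladder.best_per_size[selected_size]
    validation = external_validation(
        selected, test_m.values[selected.term_names], y_test, threshold=threshold
    )

    n, k = selected.n, selected.size
    if math.isinf(selected.f_stat):
        p_value = 0.0
    else:
        p_value = float(stats.f.sf(selected.f_stat, k, n - k - 1))

    return SchemeReport(
        preselect_report=pre_report,
        class_counts=class_counts,
        odds_ratios=odds,
        descriptor_numbers=numbers,
        ladder=ladder,
        candidate_scores=score_df,
        selected_size=selected_size,
        validation=validation,
        model_p_value=p_value,
        seed=config.seed,
    )
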