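"""Synthetic descriptor matrices with the structure the analysis assumes.

The generator emulates a class-labelled molecular-descriptor table for a
small compound panel (default 18 training + 7 test compounds, ~40
descriptors across the six descriptor classes) together with a sparse
linear response

    y = intercept + sum_j beta_j * x_j + Gaussian noise.

Descriptor columns are standard normal with within-class equicorrelation
``block_rho`` (classes are independent of each other); this mimics the
tendency of same-class descriptors to covary without attempting any
quantum-chemical physics.  Pathologies the preselection stage must
handle are planted on demand: near-duplicate columns (|r| > 0.99 with
their source), constant columns, and columns with a missing training
cell.  Everything is reproducible from the seed, and the ground truth
(support, coefficients, noiseless response, noise draw) is returned
alongside the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .data_model import (
    DESCRIPTOR_CLASSES,
    CompoundRecord,
    DescriptorMatrix,
    DescriptorMeta,
)
from .hmsearch import SearchConfig, heuristic_search
from .preselect import preselect
from .validate import external_validation

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "recovery_experiment",
           "RecoverySummary"]

_CLASS_ABBREV = {
    "constitutional": "const",
    "topological": "topo",
    "geometrical": "geom",
    "electrostatic": "elec",
    "thermodynamic": "thermo",
    "quantum_chemical": "qc",
}

#: Default class sizes, ~40 descriptors spread over the six classes.
_DEFAULT_CLASS_SIZES = {
    "constitutional": 8,
    "topological": 6,
    "geometrical": 5,
    "electrostatic": 5,
    "thermodynamic": 4,
    "quantum_chemical": 12,
}

#: Default 4-term support: one dominant positive effect, one negative,
#: two smaller positives — echoing the magnitude pattern of small fitted
#: uptake models without reusing any particular coefficients.
_DEFAULT_SUPPORT = ((2, 6.0), (12, 2.5), (25, -3.0), (33, 1.5))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-shaped generator settings.

    noise_sd and noise_frac are mutually exclusive: noise_frac scales the
    noise to the given fraction of the standard deviation of the
    noiseless signal (default 0.05, i.e. 5% noise).
    """

    n_train: int = 18
    n_test: int = 7
    class_sizes: tuple[tuple[str, int], ...] = tuple(_DEFAULT_CLASS_SIZES.items())
    block_rho: float = 0.3
    support: tuple[tuple[int, float], ...] = _DEFAULT_SUPPORT
    intercept: float = 200.0
    noise_sd: float | None = None
    noise_frac: float | None = 0.05
    n_dup: int = 2
    n_missing: int = 2
    n_const: int = 2
    scale_mix: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = dict(self.class_sizes)
        unknown = set(sizes) - set(DESCRIPTOR_CLASSES)
        if unknown:
            raise ValueError(f"unknown descriptor classes: {sorted(unknown)}")
        if any(v < 0 for v in sizes.values()):
            raise ValueError("class sizes must be non-negative")
        if not (0 <= self.block_rho < 1):
            raise ValueError("block_rho must be in [0, 1)")
        d = sum(sizes.values())
        idx = [i for i, _ in self.support]
        if len(set(idx)) != len(idx):
            raise ValueError("support indices must be distinct")
        if any(not (0 <= i < d) for i in idx):
            raise ValueError(f"support indices must be in [0, {d})")
        if (self.noise_sd is None) == (self.noise_frac is None):
            raise ValueError("give exactly one of noise_sd or noise_frac")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.n_dup, self.n_missing, self.n_const) < 0:
            raise ValueError("planted counts must be non-negative")
        if self.n_train < 3 * len(self.support) + 2:
            raise ValueError(
                f"n_train must be >= 3*|support| + 2 "
                f"(= {3 * len(self.support) + 2})"
            )
        if d - len(idx) < self.n_dup + self.n_missing + self.n_const:
            raise ValueError("not enough non-support columns for the plants")

    @property
    def n_descriptors(self) -> int:
        return sum(v for _, v in self.class_sizes)


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    support_indices: tuple[int, ...]
    support_names: tuple[str, ...]
    beta: tuple[float, ...]
    intercept: float
    noise_sd: float
    noiseless_y: np.ndarray
    noise: np.ndarray
    dup_pairs: list[tuple[str, str]]  # (source, duplicate)
    const_names: list[str]
    missing_names: list[str]


def generate(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, pd.Series, GroundTruth]:
    """Draw one synthetic (descriptor matrix, response, ground truth)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_train + spec.n_test
    sizes = dict(spec.class_sizes)
    d = spec.n_descriptors

    # class-blocked equicorrelated standard-normal descriptors
    cols = np.empty((n, d))
    classes: list[str] = []
    names: list[str] = []
    j = 0
    for dclass in DESCRIPTOR_CLASSES:
        m = sizes.get(dclass, 0)
        if m == 0:
            continue
        z = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, m))
        cols[:, j : j + m] = (
            np.sqrt(spec.block_rho) * z + np.sqrt(1.0 - spec.block_rho) * eps
        )
        for i in range(m):
            names.append(f"{_CLASS_ABBREV[dclass]}_{i + 1:02d}")
            classes.append(dclass)
        j += m

    support_idx = tuple(i for i, _ in spec.support)
    beta = tuple(b for _, b in spec.support)

    # plant pathologies on non-support columns (deterministic draw)
    free = np.array([i for i in range(d) if i not in support_idx])
    n_plant = spec.n_const + spec.n_missing + spec.n_dup
    plant_cols = rng.choice(free, size=n_plant, replace=False)
    const_cols = plant_cols[: spec.n_const]
    missing_cols = plant_cols[spec.n_const : spec.n_const + spec.n_missing]
    dup_cols = plant_cols[spec.n_const + spec.n_missing :]

    for c in const_cols:
        cols[:, c] = 1.37

    dup_pairs: list[tuple[str, str]] = []
    forbidden = set(plant_cols) | set(support_idx)
    dup_sources = rng.choice(
        np.array([i for i in range(d) if i not in forbidden]),
        size=spec.n_dup,
        replace=False,
    )
    for src, dst in zip(dup_sources, dup_cols):
        cols[:, dst] = cols[:, src] + 0.03 * rng.standard_normal(n)
        dup_pairs.append((names[src], names[dst]))

    # response before missingness (missing cells never hit the support)
    signal = spec.intercept + cols[:, list(support_idx)] @ np.array(beta)
    sig_sd = float(np.std(signal))
    if spec.noise_sd is not None:
        noise_sd = float(spec.noise_sd)
    else:
        noise_sd = float(spec.noise_frac) * sig_sd
    noise = noise_sd * rng.standard_normal(n)
    y = signal + noise

    missing_names = []
    for c in missing_cols:
        row = int(rng.integers(0, spec.n_train))  # a training cell
        cols[row, c] = np.nan
        missing_names.append(names[c])

    if spec.scale_mix:
        scales = 10.0 ** rng.uniform(-3, 3, size=d)
        cols = cols * scales

    compounds = [
        CompoundRecord(
            id=f"c{i + 1:02d}",
            name=f"compound {i + 1}",
            role="training" if i < spec.n_train else "test",
        )
        for i in range(n)
    ]
    descriptors = [
        DescriptorMeta(name=nm, dclass=cl) for nm, cl in zip(names, classes)
    ]
    matrix = DescriptorMatrix(
        compounds=compounds,
        descriptors=descriptors,
        values=pd.DataFrame(
            cols, index=[c.id for c in compounds], columns=names
        ),
    )
    truth = GroundTruth(
        support_indices=support_idx,
        support_names=tuple(names[i] for i in support_idx),
        beta=beta,
        intercept=spec.intercept,
        noise_sd=noise_sd,
        noiseless_y=signal,
        noise=noise,
        dup_pairs=dup_pairs,
        const_names=[names[c] for c in const_cols],
        missing_names=missing_names,
    )
    y_series = pd.Series(y, index=matrix.values.index, name="response")
    return matrix, y_series, truth


@dataclass
class RecoverySummary:
    """Aggregates of a support-recovery simulation."""

    n_reps: int
    recovery_rate: float
    mean_coef_rmse: float  # over replicates with exact recovery
    mean_test_are: float
    mean_r2_q2_gap: float
    q2_le_r2_violations: int
    per_rep: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "per_rep"}
        d["per_rep"] = self.per_rep
        return json.dumps(d, indent=1)


def recovery_experiment(
    spec: SyntheticSpec,
    config: SearchConfig | None = None,
    n_reps: int = 100,
) -> RecoverySummary:
    """Generate -> preselect -> search -> validate, n_reps times.

    Replicate r uses seed = spec.seed + r.  Reports the exact-support
    recovery rate (chosen terms == planted support), the coefficient
    RMSE on recovered fits, the mean test-set ARE, the mean R2 - Q2 gap,
    and the count of fits violating Q2 <= R2.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    config = config or SearchConfig()
    per_rep = []
    violations = 0
    for rep in range(n_reps):
        m, y, truth = generate(replace(spec, seed=spec.seed + rep))
        train_m = m  # preselect/search read training rows internally
        y_train = y.loc[train_m.training_values().index].to_numpy()
        pre_m, _ = preselect(train_m, y_train)
        ladder = heuristic_search(pre_m, y_train, config)
        chosen = ladder.chosen
        recovered = set(chosen.term_names) == set(truth.support_names)
        gaps = [
            m_.r2 - m_.q2
            for m_ in ladder.best_per_size.values()
            if not np.isnan(m_.q2)
        ]
        violations += sum(1 for g in gaps if g < -1e-10)

        test_ids = [c.id for c in m.compounds if c.role == "test"]
        rep_val = external_validation(
            chosen,
            m.values.loc[test_ids, chosen.term_names],
            y.loc[test_ids].to_numpy(),
        )
        rmse = np.nan
        if recovered:
            order = {nm: b for nm, b in zip(truth.support_names, truth.beta)}
            err = [t.coef - order[t.name] for t in chosen.terms]
            rmse = float(np.sqrt(np.mean(np.square(err))))
        per_rep.append(
            {
                "rep": rep,
                "seed": spec.seed + rep,
                "recovered": bool(recovered),
                "chosen_size": chosen.size,
                "coef_rmse": rmse,
                "mean_test_are": float(rep_val.per_compound["are"].mean()),
                "r2_q2_gap": float(chosen.r2 - chosen.q2),
            }
        )
    rec = [r for r in per_rep if r["recovered"]]
    return RecoverySummary(
        n_reps=n_reps,
        recovery_rate=len(rec) / n_reps,
        mean_coef_rmse=(
            float(np.mean([r["coef_rmse"] for r in rec])) if rec else float("nan")
        ),
        mean_test_are=float(np.mean([r["mean_test_are"] for r in per_rep])),
        mean_r2_q2_gap=float(np.mean([r["r2_q2_gap"] for r in per_rep])),
        q2_le_r2_violations=violations,
        per_rep=per_rep,
    )
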