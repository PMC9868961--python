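"""TOPSIS multi-criteria ranking of classifier configurations.

Alternatives (models) are scored by their relative closeness to an
ideal point in weighted, normalized criterion space (Hwang-Yoon):

1. normalize each criterion column;
2. weight the normalized columns (weights sum to 1);
3. form the ideal A+ (per-column best: max for benefit criteria, min
   for cost criteria) and anti-ideal A-;
4. Euclidean distances S+ and S- of each alternative to A+ and A-;
5. closeness C = S- / (S+ + S-), ranked descending.

Three normalizations are available:

* ``vector`` (classical default): x / ||x||_2 per column;
* ``minmax``: (x - min) / (max - min);
* ``rank``: replace each column by within-column ranks (direction
  aware, best = m, average ties), after which every criterion is a
  benefit. Rank transformation makes the result invariant to any
  monotone rescaling of a criterion and reproduces the published
  ranking of the eleven-model benchmark, which the continuous variants
  do not (see the methods note).

The default criteria are the eight evaluation metrics with FPR as the
single cost criterion and equal weights 1/8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .metrics import METRIC_NAMES

NORMALIZATIONS = ("vector", "minmax", "rank")


@dataclass(frozen=True)
class Criterion:
    name: str
    direction: str = "benefit"  # "benefit" | "cost"
    weight: float = 1.0

    def __post_init__(self):
        if self.direction not in ("benefit", "cost"):
            raise ValueError(f"direction {self.direction!r}")
        if self.weight < 0:
            raise ValueError("criterion weight must be >= 0")


def default_criteria(fpr_direction: str = "cost") -> list:
    return [
        Criterion(m, "cost" if (m == "fpr" and fpr_direction == "cost") else "benefit", 1.0)
        for m in METRIC_NAMES
    ]


@dataclass
class DecisionMatrix:
    alternatives: list
    criteria: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if m != len(self.alternatives) or n != len(self.criteria):
            raise ValueError("matrix shape does not match alternatives x criteria")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("decision matrix values must be finite")
        total = sum(c.weight for c in self.criteria)
        if total <= 0:
            raise ValueError("criterion weights must not all be zero")
        self.criteria = [
            Criterion(c.name, c.direction, c.weight / total) for c in self.criteria
        ]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.criteria])


@dataclass(frozen=True)
class TopsisResult:
    model_id: str
    closeness: float
    rank: int


def build_decision_matrix(reports, criteria: Optional[list] = None) -> DecisionMatrix:
    """Assemble the models x metrics matrix from evaluation reports.

    Values enter on the percentage scale, exactly as reported.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to rank")
    criteria = criteria or default_criteria()
    rows = []
    for r in reports:
        row = []
        for c in criteria:
            v = getattr(r, c.name, None)
            if v is None:
                raise ValueError(f"report for {r.model_id!r} is missing metric {c.name!r}")
            row.append(v)
        rows.append(row)
    return DecisionMatrix(
        alternatives=[r.model_id for r in reports], criteria=criteria, values=np.array(rows)
    )


def _normalize(matrix: DecisionMatrix, normalization: str) -> tuple:
    """Returns (normalized values, effective cost mask)."""
    X = matrix.values
    cost = np.array([c.direction == "cost" for c in matrix.criteria])
    if normalization == "vector":
        norms = np.linalg.norm(X, axis=0)
        if np.any(norms == 0):
            raise ValueError("all-zero criterion column under vector normalization")
        return X / norms, cost
    if normalization == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        rng = np.where(hi > lo, hi - lo, 1.0)
        return (X - lo) / rng, cost
    if normalization == "rank":
        # classical TOPSIS applied to the per-criterion rank matrix:
        # best alternative gets rank 1 (dense ties), so every rank
        # column is a cost criterion
        R = np.empty_like(X)
        for j in range(X.shape[1]):
            col = X[:, j] if cost[j] else -X[:, j]
            R[:, j] = rankdata(col, method="dense")
        return R / np.linalg.norm(R, axis=0), np.ones_like(cost)
    raise ValueError(f"unknown normalization {normalization!r}; choose from {NORMALIZATIONS}")


def topsis_scores(matrix: DecisionMatrix, normalization: str = "vector") -> list:
    """Closeness coefficient per alternative, ranked descending.

    An alternative coinciding with the ideal point gets closeness 1,
    with the anti-ideal 0. Ties in closeness are broken by model_id.
    """
    if len(matrix.alternatives) < 2:
        raise ValueError("TOPSIS needs at least 2 alternatives")
    R, cost = _normalize(matrix, normalization)
    V = R * matrix.weights
    ideal = np.where(cost, V.min(axis=0), V.max(axis=0))
    anti = np.where(cost, V.max(axis=0), V.min(axis=0))
    s_plus = np.linalg.norm(V - ideal, axis=1)
    s_minus = np.linalg.norm(V - anti, axis=1)
    denom = s_plus + s_minus
    if np.any(denom == 0):  # all alternatives identical in every criterion
        raise ValueError("degenerate decision matrix: an alternative is both ideal and anti-ideal")
    closeness = s_minus / denom
    order = sorted(
        range(len(closeness)), key=lambda i: (-closeness[i], matrix.alternatives[i])
    )
    results = [None] * len(closeness)
    for rank0, i in enumerate(order):
        results[i] = TopsisResult(matrix.alternatives[i], float(closeness[i]), rank0 + 1)
    return results


def rank_table(results) -> pd.DataFrame:
    """Ordered (model, score, rank) table, best first."""
    df = pd.DataFrame(
        [(r.model_id, r.closeness, r.rank) for r in results],
        columns=["model", "score", "rank"],
    )
    return df.sort_values("rank").reset_index(drop=True)


def load_reference_benchmark() -> dict:
    """The published 11-model x 8-metric matrix and its reported closeness scores."""
    with resources.files("cleavesite.data").joinpath("reference_benchmark.json").open() as fh:
        return json.load(fh)


def reference_decision_matrix(fpr_direction: str = "cost") -> DecisionMatrix:
    ref = load_reference_benchmark()
    models = list(ref["models"])
    values = np.array([ref["models"][m] for m in models])
    crit = default_criteria(fpr_direction)
    assert [c.name for c in crit] == ref["metric_names"]
    return DecisionMatrix(alternatives=models, criteria=crit, values=values)
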