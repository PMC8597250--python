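"""Cross-validation protocols and ranking metrics.

Three blinding schemes are supported, matching the standard chemogenomic
evaluation settings:

* **CVS1** — random drug-target *pairs* are blinded.  Only cells whose
  drug has at least 2 known targets and whose target has at least 2 known
  drugs are eligible; the eligible cells (interacting and non-interacting
  alike) are partitioned across folds.
* **CVS2** — whole drug rows are blinded (new-drug setting).
* **CVS3** — whole target columns are blinded (new-target setting).

Metrics are AUC (probability that a random true interaction outranks a
random non-interaction, ties counted 1/2) and AUPR (average-precision step
rule), with AUPR the more demanding measure because true interactions are
rare.  The experiment runner performs repeated ten-fold CV, recomputing
the interaction-profile similarities from the *training-masked* matrix
inside every fold so no information leaks through the similarity channel.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import model as _model
from .data_io import InteractionData
from .similarity import combine_similarities

__all__ = [
    "CVFoldPlan",
    "MetricReport",
    "eligible_pairs_cvs1",
    "make_cv_folds",
    "training_copy",
    "auc_score",
    "aupr_score",
    "run_experiment",
    "format_mean_std",
]

Scheme = Literal["CVS1", "CVS2", "CVS3"]


@dataclasses.dataclass
class CVFoldPlan:
    """Test-unit partition for one repetition of cross-validation.

    ``folds`` holds matrix cells (i, j) for CVS1, drug row indices for
    CVS2 and target column indices for CVS3.
    """

    scheme: Scheme
    folds: list[list]
    n_folds: int
    seed: int


def eligible_pairs_cvs1(data: InteractionData) -> set[tuple[int, int]]:
    """Cells whose drug has ≥ 2 known targets and target ≥ 2 known drugs.

    All such cells — ones and zeros — are eligible: the folds partition
    prediction cells, not just positives.
    """
    Y = data.values
    row_deg = Y.sum(axis=1)
    col_deg = Y.sum(axis=0)
    rows = np.flatnonzero(row_deg >= 2)
    cols = np.flatnonzero(col_deg >= 2)
    return {(int(i), int(j)) for i in rows for j in cols}


def make_cv_folds(data: InteractionData, scheme: Scheme, n_folds: int = 10,
                  seed: int = 0) -> CVFoldPlan:
    """Randomly partition the scheme's eligible units into near-equal folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    rng = np.random.default_rng(seed)
    if scheme == "CVS1":
        units: list = sorted(eligible_pairs_cvs1(data))
    elif scheme == "CVS2":
        units = list(range(data.shape[0]))
    elif scheme == "CVS3":
        units = list(range(data.shape[1]))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if len(units) < n_folds:
        raise ValueError(
            f"{scheme}: only {len(units)} eligible units for {n_folds} folds")
    order = rng.permutation(len(units))
    folds: list[list] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(units[idx])
    return CVFoldPlan(scheme=scheme, folds=[sorted(f) for f in folds],
                      n_folds=n_folds, seed=seed)


def training_copy(data: InteractionData, plan: CVFoldPlan,
                  fold: int) -> tuple[InteractionData, list[tuple[int, int]]]:
    """Blind one fold: zero its mask entries (and Y entries in the training
    copy) and return the training data plus the test cells to score."""
    train = data.copy()
    test_units = plan.folds[fold]
    if plan.scheme == "CVS1":
        cells = [tuple(c) for c in test_units]
        for i, j in cells:
            train.mask[i, j] = 0.0
            train.values[i, j] = 0.0
    elif plan.scheme == "CVS2":
        cells = [(int(i), j) for i in test_units
                 for j in range(data.shape[1])]
        for i in test_units:
            train.mask[i, :] = 0.0
            train.values[i, :] = 0.0
    else:  # CVS3
        cells = [(i, int(j)) for j in test_units
                 for i in range(data.shape[0])]
        for j in test_units:
            train.mask[:, j] = 0.0
            train.values[:, j] = 0.0
    return train, cells


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("labels must contain both classes")


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def aupr_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve via the average-precision
    step rule Σ_n (R_n − R_{n−1})·P_n."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_two_classes(labels)
    return float(average_precision_score(labels, scores))


def format_mean_std(values: Sequence[float]) -> str:
    """Benchmark-table cell style: "mean (sample std)" to 4 decimals."""
    v = np.asarray(values, dtype=float)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return f"{v.mean():.4f} ({sd:.4f})"


@dataclasses.dataclass
class MetricReport:
    """Per-(repetition, fold) AUC/AUPR with aggregate summaries."""

    scheme: str
    rows: list[dict]
    rep_seeds: list[int]

    @property
    def auc_values(self) -> np.ndarray:
        return np.array([r["auc"] for r in self.rows])

    @property
    def aupr_values(self) -> np.ndarray:
        return np.array([r["aupr"] for r in self.rows])

    def summary(self) -> dict[str, str]:
        return {"auc": format_mean_std(self.auc_values),
                "aupr": format_mean_std(self.aupr_values)}

    def to_table(self) -> str:
        lines = [f"# scheme={self.scheme} rep_seeds={self.rep_seeds}",
                 "rep\tfold\tauc\taupr"]
        for r in self.rows:
            lines.append(f"{r['rep']}\t{r['fold']}\t{r['auc']:.6f}"
                         f"\t{r['aupr']:.6f}")
        s = self.summary()
        lines.append(f"summary\t-\t{s['auc']}\t{s['aupr']}")
        return "\n".join(lines) + "\n"


Predictor = Callable[
    [InteractionData, Optional[np.ndarray], Optional[np.ndarray],
     "_model.GRNNBFParams"],
    np.ndarray,
]


def _default_predictor(train: InteractionData,
                       drug_sim: Optional[np.ndarray],
                       target_sim: Optional[np.ndarray],
                       params: "_model.GRNNBFParams") -> np.ndarray:
    """Fit the full model on the training copy; similarities derived from
    the training-masked Y only."""
    p = min(params.p_nn, min(train.shape) - 1)
    dset = combine_similarities(drug_sim, train.values, "drug", p_nn=p)
    tset = combine_similarities(target_sim, train.values, "target", p_nn=p)
    result = _model.fit(train, dset, tset, params)
    return result.scores.scores


def run_experiment(
    data: InteractionData,
    drug_sim: Optional[np.ndarray],
    target_sim: Optional[np.ndarray],
    params: "_model.GRNNBFParams",
    scheme: Scheme = "CVS1",
    n_reps: int = 5,
    n_folds: int = 10,
    base_seed: int = 0,
    predictor: Optional[Predictor] = None,
) -> MetricReport:
    """Repeated n-fold cross-validated evaluation.

    Repetition r uses fold seed base_seed + r.  For each fold the training
    copy is fitted (profile similarities recomputed from the masked Y),
    the blinded cells are scored, and AUC/AUPR are computed against the
    true labels pooled over the fold's cells.
    """
    if predictor is None:
        predictor = _default_predictor
    rows: list[dict] = []
    rep_seeds = [base_seed + rep for rep in range(n_reps)]
    for rep, seed in enumerate(rep_seeds):
        plan = make_cv_folds(data, scheme, n_folds=n_folds, seed=seed)
        for fold in range(n_folds):
            train, cells = training_copy(data, plan, fold)
            Z = predictor(train, drug_sim, target_sim, params)
            idx = tuple(np.array(cells).T)
            scores = Z[idx]
            labels = data.values[idx]
            rows.append({
                "rep": rep, "fold": fold,
                "auc": auc_score(scores, labels),
                "aupr": aupr_score(scores, labels),
            })
    return MetricReport(scheme=scheme, rows=rows, rep_seeds=rep_seeds)
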