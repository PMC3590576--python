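"""Evaluation protocol: chain-level sevenfold CV, hyperparameter tuning and
the incremental prototype-count search.

Cross-validation splits at the *chain* level — all residues of a chain share
a fold — so no residue of a test chain ever contributes a training row, and
each fold keeps the naturally occurring turn/non-turn proportion (no
stratification).  Per fold the feature selector is fitted on the training
residues only, an FS-KLR model is trained, the held-out chains are scored
(optionally after rule smoothing), and the final figures are the arithmetic
mean over the folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .features import (
    DEFAULT_K_FEATURES,
    DEFAULT_WINDOW,
    FeatureMatrix,
    encode_dataset,
    rank_features,
    select_features,
)
from .formats import Dataset
from .fsklr import fs_klr_predict, fs_klr_train
from .klr import Hyperparams
from .metrics import (
    MetricReport,
    average_reports,
    compute_metrics,
    confusion,
    roc_auc,
)
from .rules import apply_state_rules


@dataclass
class FoldPlan:
    """Chain → fold assignment; folds partition the chains, sizes within 1."""

    assignments: Dict[str, int]
    k: int
    seed: int

    def chains_in_fold(self, fold: int) -> List[str]:
        return [cid for cid, f in self.assignments.items() if f == fold]


@dataclass
class FoldResult:
    fold: int
    raw: MetricReport
    smoothed: MetricReport
    auc: float
    n_residues: int


@dataclass
class CVResult:
    plan: FoldPlan
    folds: List[FoldResult]
    mean_raw: MetricReport
    mean_smoothed: MetricReport

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))


@dataclass
class TuningResult:
    grid: List[dict] = field(default_factory=list)
    best: Optional[dict] = None
    m_search: List[dict] = field(default_factory=list)


def make_folds(chain_ids: Sequence[str], k: int = 7, seed: int = 0) -> FoldPlan:
    """Seeded shuffle + round-robin assignment of chains to ``k`` folds."""
    chain_ids = sorted(chain_ids)  # invariant to caller's ordering
    if len(chain_ids) < k:
        raise ValueError(f"need at least {k} chains, got {len(chain_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chain_ids))
    assignments = {chain_ids[int(idx)]: i % k for i, idx in enumerate(order)}
    return FoldPlan(assignments=assignments, k=k, seed=seed)


def _fold_seed(seed: int, fold: int) -> int:
    return int((seed + 1000003 * (fold + 1)) % (2**31))


def cross_validate(
    dataset: Dataset,
    hyper: Hyperparams,
    m: int,
    seed: int,
    n_folds: int = 7,
    window: int = DEFAULT_WINDOW,
    k_features: int = DEFAULT_K_FEATURES,
    apply_rules: bool = True,
    global_selection: bool = False,
    encoded: Optional[FeatureMatrix] = None,
    plan: Optional[FoldPlan] = None,
) -> CVResult:
    """Chain-level k-fold cross-validation of the full pipeline.

    ``encoded`` may carry a pre-encoded feature matrix (encoding is
    label-independent, so sharing it across calls leaks nothing);
    ``global_selection`` fits the feature selector once on all residues
    instead of per training fold.
    """
    fm = encoded if encoded is not None else encode_dataset(dataset, window=window)
    assert fm.y is not None
    if plan is None:
        plan = make_folds([c.chain_id for c in dataset.chains], k=n_folds, seed=seed)

    chain_rows: Dict[str, np.ndarray] = {}
    for i, (cid, _) in enumerate(fm.provenance):
        chain_rows.setdefault(cid, [])
        chain_rows[cid].append(i)
    chain_rows = {cid: np.array(rows) for cid, rows in chain_rows.items()}

    global_selector = (
        rank_features(fm.X, fm.y, k=k_features) if global_selection else None
    )

    labels_by_chain = {cid: lab.labels for cid, lab in dataset.labels.items()}
    fold_results: List[FoldResult] = []
    for fold in range(plan.k):
        test_chains = plan.chains_in_fold(fold)
        train_chains = [c for c in plan.assignments if plan.assignments[c] != fold]
        train_idx = np.concatenate([chain_rows[c] for c in train_chains])
        y_train = fm.y[train_idx]
        if (y_train > 0).all() or (y_train < 0).all():
            raise ValueError(f"fold {fold}: training set contains a single class")

        selector = (
            global_selector
            if global_selector is not None
            else rank_features(fm.X[train_idx], y_train, k=k_features)
        )
        X_train = select_features(selector, fm.X[train_idx], k=k_features)
        model = fs_klr_train(
            X_train,
            y_train,
            hyper,
            m=min(m, len(train_idx)),
            seed=_fold_seed(seed, fold),
            selector=selector,
            window=window,
        )

        raw_pred_parts: List[str] = []
        smooth_pred_parts: List[str] = []
        truth_parts: List[str] = []
        prob_parts: List[np.ndarray] = []
        for cid in test_chains:
            rows = chain_rows[cid]
            X_test = select_features(selector, fm.X[rows], k=k_features)
            probs, labels = fs_klr_predict(model, X_test)
            raw = "".join(labels)
            smoothed = apply_state_rules(raw, probs) if apply_rules else raw
            raw_pred_parts.append(raw)
            smooth_pred_parts.append(smoothed)
            truth_parts.append(labels_by_chain[cid])
            prob_parts.append(probs)

        truth = "".join(truth_parts)
        probs_all = np.concatenate(prob_parts)
        raw_report = compute_metrics(confusion("".join(raw_pred_parts), truth))
        smooth_report = compute_metrics(confusion("".join(smooth_pred_parts), truth))
        _, fold_auc = roc_auc(probs_all, truth)
        raw_report.auc = fold_auc
        fold_results.append(
            FoldResult(
                fold=fold,
                raw=raw_report,
                smoothed=smooth_report,
                auc=fold_auc,
                n_residues=len(truth),
            )
        )

    return CVResult(
        plan=plan,
        folds=fold_results,
        mean_raw=average_reports([f.raw for f in fold_results]),
        mean_smoothed=average_reports([f.smoothed for f in fold_results]),
    )


def _mcc_or_neg_inf(report: MetricReport) -> float:
    return -np.inf if report.mcc is None else report.mcc


def tune_hyperparams(
    dataset: Dataset,
    lambda_grid: Sequence[float] = tuple(2.0**k for k in range(-6, 7, 2)),
    gamma_grid: Sequence[float] = tuple(2.0**k for k in range(-8, 3, 2)),
    m: int = 60,
    seed: int = 0,
    **cv_kwargs,
) -> TuningResult:
    """Exhaustive (λ, γ) grid search maximising mean CV MCC of the smoothed
    predictions; ties broken by higher Q_total, then smaller γ, then larger λ.
    """
    lambda_grid = list(lambda_grid)
    gamma_grid = list(gamma_grid)
    if not lambda_grid or not gamma_grid:
        raise ValueError("hyperparameter grids must be nonempty")
    encoded = cv_kwargs.pop("encoded", None)
    if encoded is None:
        encoded = encode_dataset(dataset, window=cv_kwargs.get("window", DEFAULT_WINDOW))
    result = TuningResult()
    for lam in lambda_grid:
        for gamma in gamma_grid:
            hyper = Hyperparams(lam=lam, gamma=gamma)
            cv = cross_validate(
                dataset, hyper, m=m, seed=seed, encoded=encoded, **cv_kwargs
            )
            cell = {
                "lambda": lam,
                "gamma": gamma,
                "mcc": cv.mean_smoothed.mcc,
                "q_total": cv.mean_smoothed.q_total,
                "auc": cv.mean_auc,
            }
            result.grid.append(cell)

    def sort_key(cell: dict):
        return (
            -(cell["mcc"] if cell["mcc"] is not None else -np.inf),
            -(cell["q_total"] if cell["q_total"] is not None else -np.inf),
            cell["gamma"],
            -cell["lambda"],
        )

    result.best = sorted(result.grid, key=sort_key)[0]
    return result


def search_m(
    dataset: Dataset,
    hyper: Hyperparams,
    m_start: int = 20,
    m_step: int = 10,
    tol: float = 0.005,
    seed: int = 0,
    max_evals: int = 30,
    **cv_kwargs,
) -> List[dict]:
    """Grow the prototype count until CV MCC stops improving.

    Evaluates m = m_start, m_start + m_step, …; stops once the mean CV MCC
    has failed to improve on the best seen by more than ``tol`` for two
    consecutive steps, or when m would exceed the training-set size.
    Returns the full trace of (m, MCC, Q_total) dicts.
    """
    if m_start < 1:
        raise ValueError("m_start must be at least 1")
    encoded = cv_kwargs.pop("encoded", None)
    if encoded is None:
        encoded = encode_dataset(dataset, window=cv_kwargs.get("window", DEFAULT_WINDOW))
    n_total = encoded.X.shape[0]
    n_folds = cv_kwargs.get("n_folds", 7)
    n_train_min = n_total - max(1, n_total // n_folds) * 2  # conservative floor

    trace: List[dict] = []
    best = -np.inf
    stall = 0
    m = m_start
    for _ in range(max_evals):
        if m > n_train_min:
            break
        cv = cross_validate(
            dataset, hyper, m=m, seed=seed, encoded=encoded, **cv_kwargs
        )
        mcc = _mcc_or_neg_inf(cv.mean_smoothed)
        trace.append(
            {
                "m": m,
                "mcc": cv.mean_smoothed.mcc,
                "q_total": cv.mean_smoothed.q_total,
                "auc": cv.mean_auc,
            }
        )
        if mcc > best + tol:
            best = mcc
            stall = 0
        else:
            stall += 1
            if stall >= 2:
                break
        m += m_step
    return trace
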