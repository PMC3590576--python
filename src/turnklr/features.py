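"""Per-residue feature encoding and filter-based feature selection.

Each residue is described by 216 features at the default window of 7:

* 140 PSSM features — the logistic-scaled 20-column profile rows of the
  residue and its 3 neighbours on each side (off-chain positions contribute
  zeros);
* 76 secondary-structure features from four external 3-state predictors,
  in four blocks: (a) 12 one-hot states of the central residue, (b) 4
  confidence digits ÷ 10, (c) 48 local-pattern indicators (SSS, SSX, XSS,
  XSX over the central residue and its two neighbours, per state and
  source), (d) 12 within-window state ratios.

The 216 features are then reduced to 90 by ranking with information gain
and the chi-squared statistic (10 equal-width bins on [0, 1]) and fusing
the two rankings by average rank position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import json
import numpy as np
from scipy.special import expit

from .formats import Dataset, PSSMProfile, SSPrediction

SS_STATE_ORDER = "HEC"
#: Local 3-residue patterns: S = the state under test, X = any other state.
PATTERNS = ("SSS", "SSX", "XSS", "XSX")

#: SS-feature block width: 12 one-hot + 4 confidence + 48 pattern + 12 ratio.
SS_BLOCK_WIDTH = 76
SS_ONEHOT_WIDTH = 12
SS_CONFIDENCE_WIDTH = 4
SS_PATTERN_WIDTH = 48
SS_RATIO_WIDTH = 12

DEFAULT_WINDOW = 7
DEFAULT_K_FEATURES = 90


def feature_width(window: int = DEFAULT_WINDOW) -> int:
    """Total encoded width: 20·window PSSM features + 76 SS features."""
    return 20 * window + SS_BLOCK_WIDTH


@dataclass
class FeatureMatrix:
    """Encoded dataset: N×d matrix, ±1 targets and per-row provenance."""

    X: np.ndarray
    y: Optional[np.ndarray]  # +1 = turn, −1 = non-turn; None when unlabelled
    provenance: List[Tuple[str, int]]  # (chain_id, 0-based position)

    def rows_for_chain(self, chain_id: str) -> np.ndarray:
        return np.array(
            [i for i, (cid, _) in enumerate(self.provenance) if cid == chain_id],
            dtype=int,
        )


# ---------------------------------------------------------------------------
# PSSM block
# ---------------------------------------------------------------------------


def scale_pssm(raw: np.ndarray) -> np.ndarray:
    """Squash raw log-odds scores into [0, 1] with the elementwise logistic.

    s = 1 / (1 + exp(−raw)); monotone in the raw score and independent of the
    rest of the dataset (no leakage across chains or folds).
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("PSSM contains non-finite entries")
    return expit(raw)


def encode_pssm_window(
    scaled: np.ndarray, pos: int, window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Concatenate the scaled profile rows in a window centred on ``pos``.

    Off-chain positions contribute 20 zeros each; the result has length
    ``20 * window``.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    scaled = np.asarray(scaled, dtype=float)
    L = scaled.shape[0]
    if not (0 <= pos < L):
        raise IndexError(f"position {pos} outside chain of length {L}")
    half = window // 2
    out = np.zeros(window * 20)
    for k, p in enumerate(range(pos - half, pos + half + 1)):
        if 0 <= p < L:
            out[20 * k : 20 * (k + 1)] = scaled[p]
    return out


# ---------------------------------------------------------------------------
# secondary-structure block
# ---------------------------------------------------------------------------


def encode_ss_block(
    predictions: Sequence[SSPrediction], pos: int, window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Encode the 76 secondary-structure features for one residue.

    ``predictions`` must contain exactly four sources in the configured,
    fixed order (the block layout depends on it).
    """
    if len(predictions) != 4:
        raise ValueError(f"expected exactly 4 SS sources, got {len(predictions)}")
    L = predictions[0].length
    if not (0 <= pos < L):
        raise IndexError(f"position {pos} outside chain of length {L}")
    half = window // 2

    onehot = np.zeros(SS_ONEHOT_WIDTH)
    confidence = np.zeros(SS_CONFIDENCE_WIDTH)
    patterns = np.zeros(SS_PATTERN_WIDTH)
    ratios = np.zeros(SS_RATIO_WIDTH)

    for s_idx, pred in enumerate(predictions):
        states = pred.states
        # (a) one-hot of the central residue, order H, E, C
        onehot[3 * s_idx + SS_STATE_ORDER.index(states[pos])] = 1.0
        # (b) central confidence digit scaled to [0, 0.9]
        confidence[s_idx] = pred.confidence[pos] / 10.0
        # (c) 3-residue patterns; fire only when both neighbours exist
        if 0 <= pos - 1 and pos + 1 < L:
            triple = states[pos - 1 : pos + 2]
            for st_idx, S in enumerate(SS_STATE_ORDER):
                is_s = [c == S for c in triple]
                fired = {
                    "SSS": is_s[0] and is_s[1] and is_s[2],
                    "SSX": is_s[0] and is_s[1] and not is_s[2],
                    "XSS": (not is_s[0]) and is_s[1] and is_s[2],
                    "XSX": (not is_s[0]) and is_s[1] and not is_s[2],
                }
                for p_idx, pat in enumerate(PATTERNS):
                    if fired[pat]:
                        patterns[12 * s_idx + 4 * st_idx + p_idx] = 1.0
        # (d) state ratio within the window; off-chain counts as no state
        lo, hi = max(0, pos - half), min(L, pos + half + 1)
        segment = states[lo:hi]
        for st_idx, S in enumerate(SS_STATE_ORDER):
            ratios[3 * s_idx + st_idx] = segment.count(S) / window
    return np.concatenate([onehot, confidence, patterns, ratios])


# ---------------------------------------------------------------------------
# dataset encoding
# ---------------------------------------------------------------------------


def encode_dataset(
    dataset: Dataset, window: int = DEFAULT_WINDOW, require_labels: bool = True
) -> FeatureMatrix:
    """Encode every residue of every chain into one feature matrix.

    One row per residue in chain order; ``y`` is +1 where the label is ``t``
    (None when the dataset is unlabelled and ``require_labels`` is False).
    """
    dataset.validate(require_labels=require_labels)
    rows: List[np.ndarray] = []
    ys: List[int] = []
    provenance: List[Tuple[str, int]] = []
    labelled = bool(dataset.labels) or require_labels
    for chain in dataset.chains:
        cid = chain.chain_id
        pssm = dataset.pssms[cid]
        scaled = pssm.scaled if pssm.scaled is not None else scale_pssm(pssm.raw)
        preds = [dataset.ss[cid][src] for src in dataset.source_order]
        lab = dataset.labels.get(cid) if labelled else None
        if require_labels and lab is None:
            raise ValueError(f"chain {cid!r}: missing labels")
        for pos in range(chain.length):
            rows.append(
                np.concatenate(
                    [
                        encode_pssm_window(scaled, pos, window),
                        encode_ss_block(preds, pos, window),
                    ]
                )
            )
            provenance.append((cid, pos))
            if lab is not None:
                ys.append(+1 if lab.labels[pos] == "t" else -1)
    X = np.array(rows) if rows else np.zeros((0, feature_width(window)))
    y = np.array(ys) if ys and len(ys) == len(rows) else None
    return FeatureMatrix(X=X, y=y, provenance=provenance)


# ---------------------------------------------------------------------------
# filter feature selection: information gain + chi-squared
# ---------------------------------------------------------------------------


@dataclass
class FeatureSelector:
    """Average-rank fusion of information-gain and chi-squared rankings.

    ``ranked_indices`` lists all features best-first; ``k`` is the retained
    count.  Selection keeps the top-``k`` features in original column order,
    so downstream matrices stay aligned with the encoder layout.
    """

    ranked_indices: np.ndarray
    info_gain: np.ndarray
    chi_squared: np.ndarray
    k: int = DEFAULT_K_FEATURES

    def selected_indices(self, k: Optional[int] = None) -> np.ndarray:
        k = self.k if k is None else k
        if k > len(self.ranked_indices):
            raise ValueError(f"k={k} exceeds feature count {len(self.ranked_indices)}")
        return np.sort(self.ranked_indices[:k])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "ranked_indices": self.ranked_indices.tolist(),
                    "info_gain": self.info_gain.tolist(),
                    "chi_squared": self.chi_squared.tolist(),
                    "k": int(self.k),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "FeatureSelector":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            ranked_indices=np.array(d["ranked_indices"], dtype=int),
            info_gain=np.array(d["info_gain"], dtype=float),
            chi_squared=np.array(d["chi_squared"], dtype=float),
            k=int(d["k"]),
        )


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def rank_features(
    X: np.ndarray, y: np.ndarray, n_bins: int = 10, k: int = DEFAULT_K_FEATURES
) -> FeatureSelector:
    """Rank features by information gain and chi-squared over binned values.

    Each feature is discretised into ``n_bins`` equal-width bins on [0, 1];
    IG(f) = H(y) − H(y | bin(f)) and the chi-squared statistic of the
    bin×class table are computed; features are ordered by the average of the
    two rank positions, ties broken by lower feature index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows to rank features")
    pos = y > 0
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present to rank features")

    t = pos.astype(int)
    class_counts = np.array([np.sum(t == 0), np.sum(t == 1)], dtype=float)
    h_y = _entropy(class_counts)

    bins = np.clip((X * n_bins).astype(int), 0, n_bins - 1)
    ig = np.zeros(d)
    chi2 = np.zeros(d)
    for j in range(d):
        # bin × class contingency table
        table = np.zeros((n_bins, 2))
        np.add.at(table, (bins[:, j], t), 1.0)
        # conditional entropy
        bin_totals = table.sum(axis=1)
        h_cond = 0.0
        for b in range(n_bins):
            if bin_totals[b] > 0:
                h_cond += (bin_totals[b] / n) * _entropy(table[b])
        ig[j] = h_y - h_cond
        # chi-squared over cells with positive expectation
        expected = np.outer(bin_totals, class_counts) / n
        mask = expected > 0
        chi2[j] = float(((table[mask] - expected[mask]) ** 2 / expected[mask]).sum())

    def rank_positions(scores: np.ndarray) -> np.ndarray:
        order = np.argsort(-scores, kind="stable")  # ties → lower index first
        positions = np.empty(d)
        positions[order] = np.arange(d)
        return positions

    avg_rank = 0.5 * (rank_positions(ig) + rank_positions(chi2))
    ranked = np.lexsort((np.arange(d), avg_rank))
    return FeatureSelector(
        ranked_indices=ranked, info_gain=ig, chi_squared=chi2, k=min(k, d)
    )


def select_features(
    selector: FeatureSelector, X: np.ndarray, k: Optional[int] = None
) -> np.ndarray:
    """Keep the selector's top-``k`` columns, in original column order."""
    X = np.asarray(X)
    k = selector.k if k is None else k
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds matrix width {X.shape[1]}")
    return X[:, selector.selected_indices(k)]
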