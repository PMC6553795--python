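"""Evaluation statistics for ranked drug-pair predictions.

Provides rank-based AUROC (Mann–Whitney with average ranks on ties),
step-based AUPR (average precision over distinct score thresholds),
precision@k, approximate curve averaging over many hold-out runs on a
fixed 1,001-point grid, the two-sided permutation test on the difference
of sample means used to compare feature distributions between interacting
and non-interacting pairs, and the maximum-averaged-F1 probability cutoff
used to flag novel interaction predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

GRID_SIZE = 1001  # every thousandth of a point on the x axis


def _check_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return s, y.astype(int)


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outranks a random negative.

    Computed from average ranks (Mann–Whitney form), so ties contribute 1/2.
    Requires both classes present.
    """
    s, y = _check_scores_labels(scores, labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Step-based average precision.

    Sum over distinct score thresholds of (recall increment) x (precision at
    that threshold) — the step-function area under the precision-recall
    curve, with no linear interpolation.  Requires at least one positive.
    """
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("AUPR needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last entry of each tied-score block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp_d, fp_d = tp[distinct], fp[distinct]
    precision = tp_d / (tp_d + fp_d)
    recall = tp_d / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(d_recall * precision))


def precision_at_k(ranked: pd.DataFrame, k: int) -> float:
    """Fraction of true interactions among the top-k ranked predictions."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k={k} out of range 1..{len(ranked)}")
    top = ranked.iloc[:k]
    if top["label"].isna().any():
        raise ValueError("unknown labels within the top k")
    return float(top["label"].astype(float).mean())


def rank_predictions(
    pairs: Sequence[tuple[str, str]],
    probabilities: Sequence[float],
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Deterministically ranked predictions.

    Sorted by descending probability with ties broken by the lexicographic
    pair key, so tabular outputs are reproducible.
    """
    probs = np.asarray(probabilities, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    frame = pd.DataFrame(
        {
            "drug_a": [p[0] for p in pairs],
            "drug_b": [p[1] for p in pairs],
            "probability": probs,
            "label": labels if labels is not None else np.nan,
        }
    )
    frame = frame.sort_values(
        ["probability", "drug_a", "drug_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return frame


@dataclass(frozen=True)
class AveragedCurve:
    """Pointwise mean of many step curves on a fixed x grid."""

    grid: np.ndarray
    mean_y: np.ndarray
    n_runs: int
    kind: str

    def to_frame(self) -> pd.DataFrame:
        x_name = "fpr" if self.kind == "ROC" else "recall"
        y_name = "tpr" if self.kind == "ROC" else "precision"
        return pd.DataFrame({x_name: self.grid, y_name: self.mean_y})


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) step points including the (0,0) and (1,1) anchors."""
    s, y = _check_scores_labels(scores, labels)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    fpr = np.r_[0.0, fp[distinct] / n0]
    tpr = np.r_[0.0, tp[distinct] / n1]
    return fpr, tpr


def pr_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) step points, anchored at (0, 1)."""
    s, y = _check_scores_labels(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PR curve needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    recall = np.r_[0.0, tp[distinct] / n_pos]
    precision = np.r_[1.0, tp[distinct] / (tp[distinct] + fp[distinct])]
    return recall, precision


def average_curves(
    runs: Iterable[tuple[np.ndarray, np.ndarray]], kind: str
) -> AveragedCurve:
    """Average per-run step curves at every thousandth of the x axis.

    ROC curves are linearly interpolated onto the grid; PR curves use
    previous-point (step) interpolation, since linear interpolation between
    PR points is biased.
    """
    if kind not in ("ROC", "PR"):
        raise ValueError("kind must be 'ROC' or 'PR'")
    grid = np.linspace(0.0, 1.0, GRID_SIZE)
    total = np.zeros(GRID_SIZE)
    n_runs = 0
    for x, y in runs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) == 0:
            raise ValueError("empty run")
        if kind == "ROC":
            total += np.interp(grid, x, y)
        else:
            idx = np.searchsorted(x, grid, side="right") - 1
            idx = np.clip(idx, 0, len(x) - 1)
            total += y[idx]
        n_runs += 1
    if n_runs == 0:
        raise ValueError("no runs to average")
    return AveragedCurve(grid=grid, mean_y=total / n_runs, n_runs=n_runs, kind=kind)


def permutation_test_mean(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_perm: int = 100_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation test on the difference of sample means.

    When the number of distinct group assignments C(n_a+n_b, n_a) does not
    exceed ``n_perm``, all assignments are enumerated and the p-value is the
    exact fraction with |difference| at least as large as observed.
    Otherwise ``n_perm`` random permutations are drawn and the add-one
    estimator ``(1 + hits) / (1 + n_perm)`` is returned, which never reports
    an exact zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pooled = np.concatenate([a, b])
    n_a, n_tot = len(a), len(pooled)
    obs = abs(a.mean() - b.mean())
    eps = 1e-12 * max(1.0, obs)
    total_sum = pooled.sum()

    if comb(n_tot, n_a) <= n_perm:
        hits = 0
        n_parts = 0
        for idx in combinations(range(n_tot), n_a):
            sum_a = pooled[list(idx)].sum()
            delta = abs(sum_a / n_a - (total_sum - sum_a) / (n_tot - n_a))
            hits += delta >= obs - eps
            n_parts += 1
        return hits / n_parts

    rng = np.random.default_rng(seed)
    hits = 0
    block = 2048
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        mats = np.tile(pooled, (m, 1))
        perms = rng.permuted(mats, axis=1)
        sums_a = perms[:, :n_a].sum(axis=1)
        deltas = np.abs(sums_a / n_a - (total_sum - sums_a) / (n_tot - n_a))
        hits += int(np.sum(deltas >= obs - eps))
        done += m
    return (1 + hits) / (1 + n_perm)


def f1_score_at(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> float:
    pred = scores >= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def max_f1_threshold(
    holdout_results: Iterable[tuple[Sequence[float], Sequence[int]]],
    grid: Sequence[float] | None = None,
) -> float:
    """Probability cutoff maximizing the across-run mean F1 score.

    Candidate cutoffs form a 0.01-spaced grid on [0, 1] by default; ties are
    broken toward the larger cutoff (the more conservative prediction set).
    """
    cuts = (
        np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
        if grid is None
        else np.asarray(sorted(grid), dtype=float)
    )
    totals = np.zeros(len(cuts))
    n_runs = 0
    any_pos = False
    for scores, labels in holdout_results:
        s, y = _check_scores_labels(scores, labels)
        any_pos = any_pos or bool(y.sum())
        totals += [f1_score_at(s, y, c) for c in cuts]
        n_runs += 1
    if n_runs == 0:
        raise ValueError("no hold-out runs supplied")
    if not any_pos:
        raise ValueError("no positives in any hold-out run")
    mean_f1 = totals / n_runs
    best = np.flatnonzero(mean_f1 >= mean_f1.max() - 1e-12)[-1]
    return float(cuts[best])


def predict_novel(
    model,
    candidate_pairs: Sequence[tuple[str, str]],
    features: pd.DataFrame,
    cutoff: float,
    feature_names: Sequence[str],
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Score candidate pairs and flag those at or above the F1-optimal cutoff.

    Candidates with any unavailable feature cannot be scored and are
    returned separately.  The flagged set shrinks monotonically as the
    cutoff rises.
    """
    scorable: list[tuple[str, str]] = []
    missing: list[tuple[str, str]] = []
    rows = []
    for pair in candidate_pairs:
        try:
            row = features.loc[pair, list(feature_names)]
        except KeyError:
            missing.append(pair)
            continue
        if row.isna().any():
            missing.append(pair)
        else:
            scorable.append(pair)
            rows.append(row.to_numpy(dtype=float))
    if scorable:
        probs = model.predict_proba(np.vstack(rows))[:, 1]
    else:
        probs = np.array([])
    ranked = rank_predictions(scorable, probs)
    ranked["flagged"] = ranked["probability"] >= cutoff
    return ranked, missing
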