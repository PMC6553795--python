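"""Group minimax-concave-penalty (MCP) feature-group selection.

The 16 pair features fall into 4 natural groups (indication, side-effect,
target-similarity and genetic-interaction).  To keep the downstream
classifier interpretable, whole groups — and individual features within
retained groups — are selected with MCP-penalized logistic regression:
MCP applies full soft-thresholding-strength shrinkage near zero but tapers
to no shrinkage beyond ``gamma * lambda``, giving nearly unbiased estimates
of large coefficients while still setting small ones exactly to zero.  The
group form penalizes the Euclidean norm of each group's coefficient block,
scaled by the square root of the group size.

The solver is proximal gradient descent on the (standardized) design with a
group firm-thresholding prox, run along a decreasing lambda path with warm
starts.  ``lambda`` is chosen by held-out deviance over repeated drug-based
splits of the rows (random row splits when no drug information is given),
so the selection step respects the same pair-input leakage rules as the
rest of the pipeline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pairs import LabeledPairSet, canonical_pair, drug_split


def mcp_penalty(t: float, lam: float, gamma: float) -> float:
    """The scalar MCP penalty value at ``t``.

    ``lam * |t| - t^2 / (2 gamma)`` for ``|t| <= gamma * lam``, then flat at
    ``gamma * lam^2 / 2``.  Non-negative and non-decreasing in ``|t|``.
    """
    if gamma <= 1:
        raise ValueError("MCP requires gamma > 1")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    a = abs(t)
    if a <= gamma * lam:
        return lam * a - a * a / (2.0 * gamma)
    return gamma * lam * lam / 2.0


def firm_threshold(z: float, lam: float, gamma: float) -> float:
    """Closed-form MCP solution under an orthonormal design.

    0 inside the threshold, linearly inflated soft-thresholding in the
    middle regime, and the unshrunk ``z`` beyond ``gamma * lambda``.
    """
    if gamma <= 1:
        raise ValueError("firm thresholding requires gamma > 1")
    a = abs(z)
    if a <= lam:
        return 0.0
    if a <= gamma * lam:
        return math.copysign((a - lam) / (1.0 - 1.0 / gamma), z)
    return z


def _prox_norm(z: float, lam: float, gamma: float, v: float) -> float:
    """Minimize v/2 (b - z)^2 + MCP(b; lam, gamma) over b >= 0, z >= 0.

    For ``gamma * v > 1`` this is the firm threshold with curvature ``v``.
    Otherwise the majorized objective is concave between the endpoints and
    the minimum is at 0 or at ``z`` itself (hard-threshold regime).
    """
    if gamma * v > 1.0:
        thr = lam / v
        if z <= thr:
            return 0.0
        if z <= gamma * lam:
            return (z - thr) / (1.0 - 1.0 / (gamma * v))
        return z
    return z if z > lam * math.sqrt(gamma / v) else 0.0


@dataclass
class SelectionConfig:
    """Configuration for :func:`group_mcp_select`.

    ``groups`` maps each feature name to its group label and must cover
    every column.  ``lambda_path`` overrides the auto-generated path
    (``n_lambda`` log-spaced values from the data-driven lambda_max down to
    ``lambda_min_ratio * lambda_max``).
    """

    groups: Mapping[str, str]
    gamma: float = 3.0
    lambda_path: Sequence[float] | None = None
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    cv_trials: int = 5
    loss: str = "logistic"
    standardize: bool = True
    fit_intercept: bool = True
    tol: float = 1e-7
    max_iter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 1:
            raise ValueError("gamma must be > 1")
        if self.loss not in ("logistic", "squared"):
            raise ValueError("loss must be 'logistic' or 'squared'")


@dataclass
class SelectionResult:
    selected: tuple[str, ...]
    lambda_path: np.ndarray
    coef_path: np.ndarray  # (n_features, n_lambda), standardized scale
    intercept_path: np.ndarray
    lambda_index: int
    cv_deviance: np.ndarray | None
    feature_names: tuple[str, ...]
    group_labels: tuple[str, ...]

    @property
    def selected_groups(self) -> tuple[str, ...]:
        sel = set(self.selected)
        seen = []
        for name, grp in zip(self.feature_names, self.group_labels):
            if name in sel and grp not in seen:
                seen.append(grp)
        return tuple(seen)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _fit_path(
    X: np.ndarray,
    y: np.ndarray,
    group_idx: list[np.ndarray],
    multipliers: np.ndarray,
    lambda_path: np.ndarray,
    gamma: float,
    loss: str,
    tol: float,
    max_iter: int,
    fit_intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Proximal-gradient path fit with warm starts; returns (coefs, intercepts)."""
    n, p = X.shape
    gram_scale = float(np.linalg.eigvalsh(X.T @ X / n).max()) if p else 1.0
    lip = gram_scale * (0.25 if loss == "logistic" else 1.0)
    lip = max(lip, 1e-12)
    step = 1.0 / lip
    beta = np.zeros(p)
    if not fit_intercept:
        b0 = 0.0
    elif loss == "logistic":
        pbar = np.clip(y.mean(), 1e-8, 1 - 1e-8)
        b0 = math.log(pbar / (1 - pbar))
    else:
        b0 = float(y.mean())
    coefs = np.zeros((p, len(lambda_path)))
    intercepts = np.zeros(len(lambda_path))
    for li, lam in enumerate(lambda_path):
        for _ in range(max_iter):
            eta = X @ beta + b0
            if loss == "logistic":
                prob = _sigmoid(eta)
                grad = X.T @ (prob - y) / n
            else:
                grad = X.T @ (eta - y) / n
            u = beta - step * grad
            new = np.empty_like(beta)
            for idx, m in zip(group_idx, multipliers):
                block = u[idx]
                norm = float(np.linalg.norm(block))
                if norm == 0.0:
                    new[idx] = 0.0
                    continue
                shrunk = _prox_norm(norm, lam * m, gamma, lip)
                new[idx] = block * (shrunk / norm)
            # unpenalized intercept
            if fit_intercept:
                if loss == "logistic":
                    prob = _sigmoid(X @ new + b0)
                    denom = float(np.sum(prob * (1 - prob)))
                    if denom > 1e-10:
                        b0 += float(np.sum(y - prob)) / denom
                else:
                    b0 = float(np.mean(y - X @ new))
            delta = float(np.max(np.abs(new - beta))) if p else 0.0
            beta = new
            if delta < tol:
                break
        coefs[:, li] = beta
        intercepts[li] = b0
    return coefs, intercepts


def _deviance(eta: np.ndarray, y: np.ndarray, loss: str) -> float:
    if loss == "logistic":
        prob = np.clip(_sigmoid(eta), 1e-10, 1 - 1e-10)
        return float(-2.0 * np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    return float(np.sum((y - eta) ** 2))


def _lambda_max(
    X: np.ndarray,
    y: np.ndarray,
    group_idx: list[np.ndarray],
    multipliers: np.ndarray,
    loss: str,
    gamma: float,
) -> float:
    n = X.shape[0]
    resid = y - y.mean()
    grads = np.array(
        [np.linalg.norm(X[:, idx].T @ resid / n) / m for idx, m in zip(group_idx, multipliers)]
    )
    gram_scale = float(np.linalg.eigvalsh(X.T @ X / n).max())
    lip = gram_scale * (0.25 if loss == "logistic" else 1.0)
    # in the hard-threshold prox regime the entry point is inflated
    safety = max(1.0, math.sqrt(1.0 / (gamma * lip))) if gamma * lip <= 1 else 1.0
    return float(grads.max() * safety) if len(grads) else 1.0


def group_mcp_select(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    cfg: SelectionConfig,
    *,
    feature_names: Sequence[str] | None = None,
    pair_drugs: Sequence[tuple[str, str]] | None = None,
) -> SelectionResult:
    """Select features by group-MCP-penalized regression along a lambda path.

    Features are standardized internally (constant columns dropped with a
    warning).  ``lambda`` is picked by mean held-out deviance over
    ``cfg.cv_trials`` splits — drug-based 2:1 splits of the rows when
    ``pair_drugs`` (one ``(drug_a, drug_b)`` per row) is given, otherwise
    random 2:1 row splits.  Selected features are the columns with nonzero
    coefficients at the chosen lambda in the full-data fit.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(map(str, X.columns))
        Xmat = X.to_numpy(dtype=float)
    else:
        Xmat = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = tuple(f"x{i}" for i in range(Xmat.shape[1]))
        feature_names = tuple(feature_names)
    yvec = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(Xmat)) or not np.all(np.isfinite(yvec)):
        raise ValueError("non-finite values in X or y")
    missing = [f for f in feature_names if f not in cfg.groups]
    if missing:
        raise ValueError(f"features without a group assignment: {missing}")
    group_labels = tuple(str(cfg.groups[f]) for f in feature_names)

    # drop constant columns
    sd = Xmat.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(feature_names, keep) if not k]
        warnings.warn(f"dropping constant feature columns: {dropped}")
    kept_names = tuple(f for f, k in zip(feature_names, keep) if k)
    kept_groups = tuple(g for g, k in zip(group_labels, keep) if k)
    Xk = Xmat[:, keep]
    if cfg.standardize:
        Xk = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)

    labels_order: list[str] = []
    for g in kept_groups:
        if g not in labels_order:
            labels_order.append(g)
    group_idx = [
        np.array([j for j, g in enumerate(kept_groups) if g == lab]) for lab in labels_order
    ]
    multipliers = np.array([math.sqrt(len(idx)) for idx in group_idx])

    if cfg.lambda_path is not None:
        lambda_path = np.asarray(list(cfg.lambda_path), dtype=float)
    else:
        lmax = _lambda_max(Xk, yvec, group_idx, multipliers, cfg.loss, cfg.gamma)
        lambda_path = np.geomspace(lmax, lmax * cfg.lambda_min_ratio, cfg.n_lambda)

    coefs, intercepts = _fit_path(
        Xk,
        yvec,
        group_idx,
        multipliers,
        lambda_path,
        cfg.gamma,
        cfg.loss,
        cfg.tol,
        cfg.max_iter,
        cfg.fit_intercept,
    )

    cv_dev = None
    if len(lambda_path) > 1 and cfg.cv_trials > 0:
        cv_dev = np.zeros(len(lambda_path))
        n = Xk.shape[0]
        for trial in range(cfg.cv_trials):
            rng = np.random.default_rng([cfg.seed, trial])
            if pair_drugs is not None:
                fit_rows, val_rows = _drug_based_rows(pair_drugs, yvec, rng)
            else:
                perm = rng.permutation(n)
                cut = max(1, min(n - 1, round(n * 2 / 3)))
                fit_rows, val_rows = perm[:cut], perm[cut:]
            c_tr, i_tr = _fit_path(
                Xk[fit_rows],
                yvec[fit_rows],
                group_idx,
                multipliers,
                lambda_path,
                cfg.gamma,
                cfg.loss,
                cfg.tol,
                cfg.max_iter,
                cfg.fit_intercept,
            )
            eta_val = Xk[val_rows] @ c_tr + i_tr[None, :]
            for li in range(len(lambda_path)):
                cv_dev[li] += _deviance(eta_val[:, li], yvec[val_rows], cfg.loss)
        cv_dev /= cfg.cv_trials
        lambda_index = int(np.argmin(cv_dev))
    else:
        lambda_index = len(lambda_path) - 1

    nonzero = np.abs(coefs[:, lambda_index]) > 1e-12
    selected = tuple(f for f, nz in zip(kept_names, nonzero) if nz)

    # re-embed dropped constant columns as zero rows for a full-width path
    full_coefs = np.zeros((len(feature_names), len(lambda_path)))
    full_coefs[np.flatnonzero(keep), :] = coefs
    return SelectionResult(
        selected=selected,
        lambda_path=lambda_path,
        coef_path=full_coefs,
        intercept_path=intercepts,
        lambda_index=lambda_index,
        cv_deviance=cv_dev,
        feature_names=feature_names,
        group_labels=group_labels,
    )


def _drug_based_rows(
    pair_drugs: Sequence[tuple[str, str]], y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """2:1 drug-based row split for lambda cross-validation."""
    pairs = tuple(
        (*canonical_pair(a, b), int(lab)) for (a, b), lab in zip(pair_drugs, y)
    )
    drugs = frozenset(d for a, b, _ in pairs for d in (a, b))
    pair_set = LabeledPairSet(pairs, drugs)
    seed = int(rng.integers(0, 2**31 - 1))
    plan = drug_split(pair_set, ratio=(2, 1), balance_tol=0.5, seed=seed)
    index = {(a, b): i for i, (a, b, _) in enumerate(pairs)}
    fit_rows = np.array([index[(a, b)] for a, b, _ in plan.train_pairs])
    val_rows = np.array([index[(a, b)] for a, b, _ in plan.test_pairs])
    return fit_rows, val_rows
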