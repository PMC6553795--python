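"""Labeled drug-pair assembly and leakage-free drug-based splitting.

Pair-input prediction has a well-known leakage mode: if the same drug
appears in both training and test pairs, the model can exploit that drug's
interaction propensity and report inflated performance.  The remedy used
here partitions *drugs*, not pairs: drugs are randomly split into "training
drugs" and "test drugs" (default ratio 2:1), the training set keeps only
pairs whose both members are training drugs, the test set only pairs whose
both members are test drugs, and cross pairs are dropped entirely.  On a
complete pair graph a 2:1 drug split therefore discards about
2 * (2/3) * (1/3) = 4/9 of the pairs.

The same scheme is reapplied *within* the training drugs to produce
independent hold-out validation trials (fit on training-drugs_i pairs,
validate on validation-drugs_i pairs), so hyperparameter tuning never sees
a drug it is evaluated on either.

Splits are resampled (bounded attempts, derived seeds) until the positive
prevalence of the two sides is fairly balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BalanceError

Pair = tuple[str, str]


def canonical_pair(drug_a: str, drug_b: str) -> Pair:
    """Unordered pair key: lexicographically sorted drug ids."""
    if drug_a == drug_b:
        raise ValueError(f"a drug cannot pair with itself: {drug_a!r}")
    return (drug_a, drug_b) if drug_a <= drug_b else (drug_b, drug_a)


@dataclass(frozen=True)
class LabeledPairSet:
    """Unordered drug pairs with binary labels over a drug universe."""

    pairs: tuple[tuple[str, str, int], ...]
    drugs: frozenset[str]

    def __post_init__(self) -> None:
        seen: set[Pair] = set()
        for a, b, label in self.pairs:
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"pair ({a!r}, {b!r}) not in canonical order")
            if (a, b) in seen:
                raise ValueError(f"duplicate pair ({a!r}, {b!r})")
            if label not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {label!r}")
            if a not in self.drugs or b not in self.drugs:
                raise ValueError(f"pair ({a!r}, {b!r}) references drug outside universe")
            seen.add((a, b))

    @property
    def positives(self) -> tuple[Pair, ...]:
        return tuple((a, b) for a, b, y in self.pairs if y == 1)

    @property
    def prevalence(self) -> float:
        if not self.pairs:
            return float("nan")
        return sum(y for _, _, y in self.pairs) / len(self.pairs)

    def restrict(self, drugs: Iterable[str]) -> "LabeledPairSet":
        """Keep only pairs whose both drugs are in ``drugs``."""
        keep = frozenset(drugs)
        return LabeledPairSet(
            tuple(p for p in self.pairs if p[0] in keep and p[1] in keep),
            frozenset(self.drugs & keep),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["drug_a", "drug_b", "label"])


@dataclass(frozen=True)
class SplitPlan:
    """A drug-based split: disjoint drug sets and the derived pair routing."""

    train_drugs: frozenset[str]
    test_drugs: frozenset[str]
    train_pairs: tuple[tuple[str, str, int], ...]
    test_pairs: tuple[tuple[str, str, int], ...]
    dropped_pairs: tuple[tuple[str, str, int], ...]
    seed: int
    ratio: tuple[int, int]
    attempts: int = 1

    def __post_init__(self) -> None:
        if self.train_drugs & self.test_drugs:
            raise ValueError("train and test drug sets overlap")
        for a, b, _ in self.train_pairs:
            if a not in self.train_drugs or b not in self.train_drugs:
                raise ValueError(f"train pair ({a}, {b}) uses a non-training drug")
        for a, b, _ in self.test_pairs:
            if a not in self.test_drugs or b not in self.test_drugs:
                raise ValueError(f"test pair ({a}, {b}) uses a non-test drug")

    def summary(self) -> dict:
        def _prev(pairs):
            return (sum(y for *_, y in pairs) / len(pairs)) if pairs else None

        return {
            "seed": self.seed,
            "ratio": list(self.ratio),
            "n_train_drugs": len(self.train_drugs),
            "n_test_drugs": len(self.test_drugs),
            "n_train_pairs": len(self.train_pairs),
            "n_test_pairs": len(self.test_pairs),
            "n_dropped_pairs": len(self.dropped_pairs),
            "train_prevalence": _prev(self.train_pairs),
            "test_prevalence": _prev(self.test_pairs),
            "attempts": self.attempts,
        }

    def to_dict(self) -> dict:
        d = self.summary()
        d["train_drugs"] = sorted(self.train_drugs)
        d["test_drugs"] = sorted(self.test_drugs)
        return d


def assemble_pairs(
    positives: Iterable[tuple[str, str]],
    drug_universe: Iterable[str],
    exclusions: Iterable[tuple[str, str]] = (),
) -> LabeledPairSet:
    """Build the labeled pair set from positives and an exclusion list.

    Positives are labeled interacting; every other unordered drug
    combination over the universe is labeled non-interacting unless listed
    in ``exclusions`` (pairs with interaction evidence too weak to call
    positive but too strong to trust as negative), in which case it is
    omitted.  A positive listed among the exclusions stays positive.
    """
    universe = sorted(set(drug_universe))
    universe_set = frozenset(universe)
    pos = {canonical_pair(a, b) for a, b in positives}
    excl = {canonical_pair(a, b) for a, b in exclusions}
    for a, b in pos | excl:
        if a not in universe_set or b not in universe_set:
            raise ValueError(f"pair ({a!r}, {b!r}) references drug outside universe")
    pairs = []
    for i, a in enumerate(universe):
        for b in universe[i + 1 :]:
            key = (a, b)
            if key in pos:
                pairs.append((a, b, 1))
            elif key not in excl:
                pairs.append((a, b, 0))
    return LabeledPairSet(tuple(pairs), universe_set)


def filter_complete(pairs: LabeledPairSet, features: pd.DataFrame) -> LabeledPairSet:
    """Keep only pairs whose 16 features are all available (non-NaN).

    ``features`` is indexed by canonical (drug_a, drug_b) with one column
    per feature; NaN marks an unavailable feature.  Every pair must be
    present in the table.
    """
    kept = []
    for a, b, y in pairs.pairs:
        try:
            row = features.loc[(a, b)]
        except KeyError:
            raise KeyError(f"pair ({a!r}, {b!r}) missing from feature table") from None
        if not row.isna().any():
            kept.append((a, b, y))
    drugs = frozenset(d for a, b, _ in kept for d in (a, b))
    return LabeledPairSet(tuple(kept), drugs)


def _split_counts(n_drugs: int, ratio: tuple[int, int]) -> tuple[int, int]:
    r_train, r_test = ratio
    if r_train <= 0 or r_test <= 0:
        raise ValueError("ratio parts must be positive")
    n_test = round(n_drugs * r_test / (r_train + r_test))
    n_test = min(max(n_test, 1), n_drugs - 1)
    return n_drugs - n_test, n_test


def _route(pairs, train_drugs, test_drugs):
    train, test, dropped = [], [], []
    for p in pairs:
        a, b, _ = p
        if a in train_drugs and b in train_drugs:
            train.append(p)
        elif a in test_drugs and b in test_drugs:
            test.append(p)
        else:
            dropped.append(p)
    return tuple(train), tuple(test), tuple(dropped)


def drug_split(
    pairs: LabeledPairSet,
    ratio: tuple[int, int] = (2, 1),
    balance_tol: float = 0.25,
    seed: int = 0,
    *,
    max_attempts: int = 1000,
) -> SplitPlan:
    """Randomly split drugs and route pairs, resampling until balanced.

    Drugs are partitioned at ``ratio`` (test count rounded to nearest,
    training keeps the remainder).  The split is accepted when the positive
    prevalence of the two sides satisfies
    ``|prev_train - prev_test| / prev_all <= balance_tol``; otherwise a new
    split is drawn from a deterministically derived seed, up to
    ``max_attempts`` times.
    """
    drugs = sorted(pairs.drugs)
    if len(drugs) < 2:
        raise ValueError("need at least 2 drugs to split")
    n_train, n_test = _split_counts(len(drugs), ratio)
    prev_all = pairs.prevalence
    best_imbalance = float("inf")
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        perm = rng.permutation(len(drugs))
        test_drugs = frozenset(drugs[i] for i in perm[:n_test])
        train_drugs = frozenset(drugs[i] for i in perm[n_test:])
        train, test, dropped = _route(pairs.pairs, train_drugs, test_drugs)
        if not train or not test or not (prev_all > 0):
            imbalance = float("inf")
        else:
            prev_train = sum(y for *_, y in train) / len(train)
            prev_test = sum(y for *_, y in test) / len(test)
            imbalance = abs(prev_train - prev_test) / prev_all
        best_imbalance = min(best_imbalance, imbalance)
        if imbalance <= balance_tol:
            return SplitPlan(
                train_drugs=train_drugs,
                test_drugs=test_drugs,
                train_pairs=train,
                test_pairs=test,
                dropped_pairs=dropped,
                seed=seed,
                ratio=ratio,
                attempts=attempt + 1,
            )
    raise BalanceError(
        f"no drug split reached balance tolerance {balance_tol} in "
        f"{max_attempts} attempts (best relative imbalance {best_imbalance:.3f})",
        best_imbalance,
    )


def holdout_splits(
    train_plan: SplitPlan,
    n_trials: int,
    ratio: tuple[int, int] = (2, 1),
    balance_tol: float = 0.25,
    seed: int = 0,
    *,
    max_attempts: int = 1000,
) -> list[SplitPlan]:
    """Independent drug-based re-splits of the training drugs.

    Trial ``i`` is reproducible from ``(seed, i)``; each trial routes the
    training pairs into fit/validation partitions with the same rules as
    the outer split.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    inner = LabeledPairSet(train_plan.train_pairs, train_plan.train_drugs)
    plans = []
    for i in range(n_trials):
        trial_seed = int(np.random.default_rng([seed, i]).integers(0, 2**31 - 1))
        plans.append(
            drug_split(
                inner,
                ratio=ratio,
                balance_tol=balance_tol,
                seed=trial_seed,
                max_attempts=max_attempts,
            )
        )
    return plans
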