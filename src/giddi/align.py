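"""Target-sequence similarity features.

A drug pair's target similarity is computed from protein sequences: every
cross pair of targets (one from each drug) is locally aligned with the
Smith–Waterman algorithm, the raw score is normalized by the geometric mean
of the two self-alignment scores (so identical sequences score 1), and the
resulting set of pairwise similarities is summarized with four functions —
minimum, mean, median and maximum — giving the features ``ts_min``,
``ts_mean``, ``ts_median`` and ``ts_max``.

Alignment uses an affine gap model: a gap of length ``L`` costs
``gap_open + (L - 1) * gap_extend`` (the first gapped residue is charged
``gap_open``); ``gap_extend == gap_open`` reduces to a linear model.  The
default scoring scheme is BLOSUM62 with gap open 11 / extend 1, the
conventional protein-search defaults; both matrix and penalties are
configurable and should be recorded alongside any persisted features, since
normalized scores are scheme-dependent.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import FeatureUnavailable

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

TARGET_FEATURES = ("ts_min", "ts_mean", "ts_median", "ts_max")

_AGG_FUNCS = {
    "min": min,
    "mean": lambda v: sum(v) / len(v),
    "median": statistics.median,
    "max": max,
}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores and affine gap penalties for local alignment.

    ``substitution`` is either the name of a protein substitution matrix
    (e.g. ``"blosum62"``) or a ``(match, mismatch)`` integer pair.  Gap
    penalties are non-negative and applied subtractively.
    """

    substitution: str | tuple[int, int] = "blosum62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    def describe(self) -> dict:
        sub = (
            self.substitution
            if isinstance(self.substitution, str)
            else list(self.substitution)
        )
        return {
            "substitution": sub,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
        }


@dataclass(frozen=True)
class TargetSet:
    """A drug's protein targets: gene id -> amino-acid sequence."""

    drug_id: str
    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            _validate_sequence(seq, context=f"{self.drug_id}/{gene}")


def _validate_sequence(seq: str, *, context: str = "") -> None:
    if not seq:
        raise ValueError(f"empty protein sequence ({context})")
    bad = set(seq.upper()) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(
            f"non-amino-acid residues {sorted(bad)} in sequence ({context}); "
            "nucleotide or malformed input?"
        )


@lru_cache(maxsize=8)
def _aligner(substitution, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if isinstance(substitution, str):
        aligner.substitution_matrix = substitution_matrices.load(substitution.upper())
    else:
        match, mismatch = substitution
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    # Biopython charges open_gap_score on the first gapped residue.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman_score(
    seq_a: str, seq_b: str, scheme: ScoringScheme | None = None
) -> float:
    """Optimal local-alignment score of two protein sequences (>= 0)."""
    scheme = scheme or ScoringScheme()
    _validate_sequence(seq_a, context="seq_a")
    _validate_sequence(seq_b, context="seq_b")
    aligner = _aligner(scheme.substitution, scheme.gap_open, scheme.gap_extend)
    return float(aligner.score(seq_a.upper(), seq_b.upper()))


def normalized_similarity(
    seq_a: str, seq_b: str, scheme: ScoringScheme | None = None
) -> float:
    """SW(a,b) / sqrt(SW(a,a) * SW(b,b)) — symmetric, 1 for identical sequences."""
    scheme = scheme or ScoringScheme()
    self_a = smith_waterman_score(seq_a, seq_a, scheme)
    self_b = smith_waterman_score(seq_b, seq_b, scheme)
    if self_a <= 0 or self_b <= 0:
        raise ValueError("degenerate sequence: non-positive self-alignment score")
    return smith_waterman_score(seq_a, seq_b, scheme) / (self_a * self_b) ** 0.5


def aggregate(values: Iterable[float], fn: str) -> float:
    """Summarize a non-empty collection with min, mean, median or max.

    Median of an even count is the midpoint of the two central values.
    """
    values = list(values)
    if not values:
        raise FeatureUnavailable("cannot aggregate an empty collection")
    try:
        func = _AGG_FUNCS[fn]
    except KeyError:
        raise ValueError(f"unknown aggregation {fn!r}; expected one of {sorted(_AGG_FUNCS)}")
    return float(func(values))


def target_features(
    a: TargetSet,
    b: TargetSet,
    scheme: ScoringScheme | None = None,
    *,
    similarity_cache: dict[tuple[str, str], float] | None = None,
) -> dict[str, float | None]:
    """The 4 target-similarity features of a drug pair.

    Aggregates normalized Smith–Waterman similarity over every cross pair of
    targets, one from each drug.  A shared target contributes a self pair
    with similarity 1.0 — drugs hitting the same protein are maximally
    target-similar (the dosage-effect scenario).  ``similarity_cache`` maps a
    lexicographically sorted gene-id pair to a precomputed similarity and is
    filled in as new pairs are aligned.
    """
    scheme = scheme or ScoringScheme()
    if not a.sequences or not b.sequences:
        return {name: None for name in TARGET_FEATURES}
    sims: list[float] = []
    for ga, seq_a in a.sequences.items():
        for gb, seq_b in b.sequences.items():
            key = (ga, gb) if ga <= gb else (gb, ga)
            if similarity_cache is not None and key in similarity_cache:
                sims.append(similarity_cache[key])
                continue
            sim = 1.0 if ga == gb else normalized_similarity(seq_a, seq_b, scheme)
            if similarity_cache is not None:
                similarity_cache[key] = sim
            sims.append(sim)
    return {
        "ts_min": aggregate(sims, "min"),
        "ts_mean": aggregate(sims, "mean"),
        "ts_median": aggregate(sims, "median"),
        "ts_max": aggregate(sims, "max"),
    }
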