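"""Genetic-interaction features for drug pairs.

A genetic-interaction (GI) score measures how much a double mutant's
fitness deviates from the product expectation of the two single mutants:
negative scores are synergistic (the double mutant is sicker than expected),
positive scores are buffering.  Systematic GI screens in yeast report
allele-level measurements with significance values.

The pipeline collapses the allele-level table to one score per unordered
gene pair (mean over measurements passing the p-value filter, default
p < 0.05), maps each human drug-target pair onto yeast gene pairs through a
many-to-many homology table, averages over the scored homolog pairs, and
finally aggregates over all cross target pairs of a drug pair into the four
features ``gi_min``, ``gi_mean``, ``gi_median`` and ``gi_max``.

A human GI table can be used directly by passing an identity homology map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .align import TargetSet, aggregate
from .errors import FeatureUnavailable

GI_FEATURES = ("gi_min", "gi_mean", "gi_median", "gi_max")

GenePair = tuple[str, str]


def pair_key(gene_a: str, gene_b: str) -> GenePair:
    """Canonical unordered gene-pair key (lexicographic)."""
    return (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)


@dataclass(frozen=True)
class GiMeasurement:
    """One allele-level GI measurement."""

    gene_a: str
    gene_b: str
    score: float
    p_value: float
    allele_a: str = ""
    allele_b: str = ""

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair GI measurement for gene {self.gene_a!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def collapse_allele_scores(
    measurements: Iterable[GiMeasurement],
    p_cutoff: float = 0.05,
    *,
    strict_inequality: bool = True,
) -> dict[GenePair, float]:
    """Filter by p-value and average allele combinations per gene pair.

    Keeps measurements with ``p_value < p_cutoff`` (strict by default,
    configurable) and returns the arithmetic mean score per unordered gene
    pair; pairs with no passing measurement are absent from the map.
    """
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must lie in (0, 1]")
    sums: dict[GenePair, float] = {}
    counts: dict[GenePair, int] = {}
    for m in measurements:
        passes = m.p_value < p_cutoff if strict_inequality else m.p_value <= p_cutoff
        if not passes:
            continue
        key = pair_key(m.gene_a, m.gene_b)
        sums[key] = sums.get(key, 0.0) + m.score
        counts[key] = counts.get(key, 0) + 1
    return {key: sums[key] / counts[key] for key in sums}


def measurements_from_frame(frame: pd.DataFrame) -> list[GiMeasurement]:
    """Parse a GI table with columns gene_a, gene_b, allele_a, allele_b, score, p_value."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            GiMeasurement(
                gene_a=str(row.gene_a),
                gene_b=str(row.gene_b),
                score=float(row.score),
                p_value=float(row.p_value),
                allele_a=str(getattr(row, "allele_a", "") or ""),
                allele_b=str(getattr(row, "allele_b", "") or ""),
            )
        )
    return out


def identity_homology(genes: Iterable[str]) -> dict[str, frozenset[str]]:
    """Homology map for using a same-species GI table directly."""
    return {g: frozenset((g,)) for g in genes}


def human_pair_score(
    gene_a: str,
    gene_b: str,
    hmap: Mapping[str, frozenset[str]],
    gmap: Mapping[GenePair, float],
) -> float | None:
    """GI score of a human gene pair via its homologs, or None.

    Averages the collapsed GI score over all cross-homolog pairs (x, y) with
    x != y that are present in the score map; candidate homolog pairs that
    were never measured (or never passed the p-filter) are simply left out
    of the average.  Returns ``None`` when no homolog pair is scored.
    """
    if gene_a == gene_b:
        raise ValueError("human_pair_score requires two distinct genes")
    homs_a = hmap.get(gene_a, frozenset())
    homs_b = hmap.get(gene_b, frozenset())
    scores = []
    for x in homs_a:
        for y in homs_b:
            if x == y:
                continue
            score = gmap.get(pair_key(x, y))
            if score is not None:
                scores.append(score)
    if not scores:
        return None
    return sum(scores) / len(scores)


def gi_features(
    a: TargetSet,
    b: TargetSet,
    hmap: Mapping[str, frozenset[str]],
    gmap: Mapping[GenePair, float],
    *,
    score_cache: dict[GenePair, float | None] | None = None,
) -> dict[str, float | None]:
    """The 4 GI features of a drug pair, or all-None when unscorable.

    Aggregates :func:`human_pair_score` over all cross target pairs with
    distinct genes.  Same-gene cross pairs are excluded — a gene has no
    genetic interaction with itself in the source network — so two drugs
    sharing their only target have no GI features.
    """
    scores: list[float] = []
    for ga in a.sequences:
        for gb in b.sequences:
            if ga == gb:
                continue
            key = pair_key(ga, gb)
            if score_cache is not None and key in score_cache:
                s = score_cache[key]
            else:
                s = human_pair_score(key[0], key[1], hmap, gmap)
                if score_cache is not None:
                    score_cache[key] = s
            if s is not None:
                scores.append(s)
    if not scores:
        return {name: None for name in GI_FEATURES}
    return {
        "gi_min": aggregate(scores, "min"),
        "gi_mean": aggregate(scores, "mean"),
        "gi_median": aggregate(scores, "median"),
        "gi_max": aggregate(scores, "max"),
    }
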