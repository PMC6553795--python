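"""MedDRA-level annotation similarity features.

Drug indications and side effects arrive as sets of MedDRA preferred-term
(PT) identifiers.  The MedDRA terminology is multi-axial: a PT may sit under
several high-level terms (HLT), which roll up into high-level group terms
(HLGT) and system organ classes (SOC).  Similarity between two drugs'
annotation profiles is the Jaccard index of their term sets after mapping
every PT to a chosen level of the hierarchy, giving four indication and four
side-effect features per drug pair (one per level).

Multi-parent PTs contribute the union of their ancestors over all paths.
Empty term sets make the corresponding features *unavailable* rather than
zero: a drug without recorded side effects carries no evidence either way,
and pairs with any unavailable feature are later dropped from modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import FeatureUnavailable, UnknownTermError

LEVELS = ("PT", "HLT", "HLGT", "SOC")

#: feature-name templates for the two annotation groups
INDICATION_FEATURES = tuple(f"ind_{lv.lower()}" for lv in LEVELS)
SIDE_EFFECT_FEATURES = tuple(f"se_{lv.lower()}" for lv in LEVELS)


@dataclass(frozen=True)
class MeddraHierarchy:
    """PT -> (HLT, HLGT, SOC) ancestry, possibly multi-parent.

    Parameters
    ----------
    paths
        One ``(pt_id, hlt_id, hlgt_id, soc_id)`` tuple per hierarchy path.
        A PT appearing in several rows has several parents (multi-axial
        placement); its ancestors at any level are the union over rows.
    """

    paths: tuple[tuple[str, str, str, str], ...]
    _index: dict[str, dict[str, frozenset[str]]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        index: dict[str, dict[str, set[str]]] = {}
        for pt, hlt, hlgt, soc in self.paths:
            anc = index.setdefault(pt, {lv: set() for lv in LEVELS})
            anc["PT"].add(pt)
            anc["HLT"].add(hlt)
            anc["HLGT"].add(hlgt)
            anc["SOC"].add(soc)
        frozen = {
            pt: {lv: frozenset(s) for lv, s in anc.items()} for pt, anc in index.items()
        }
        object.__setattr__(self, "_index", frozen)

    def __contains__(self, pt_id: str) -> bool:
        return pt_id in self._index

    def ancestors(self, pt_id: str, level: str) -> frozenset[str]:
        if level not in LEVELS:
            raise ValueError(f"unknown MedDRA level {level!r}; expected one of {LEVELS}")
        try:
            return self._index[pt_id][level]
        except KeyError:
            raise UnknownTermError(f"PT term {pt_id!r} not found in hierarchy") from None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MeddraHierarchy":
        """Build from a table with columns pt_id, hlt_id, hlgt_id, soc_id."""
        cols = ["pt_id", "hlt_id", "hlgt_id", "soc_id"]
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValueError(f"hierarchy table missing columns {sorted(missing)}")
        rows = tuple(
            tuple(str(v) for v in row) for row in frame[cols].itertuples(index=False)
        )
        return cls(rows)


@dataclass(frozen=True)
class AnnotationProfile:
    """A drug's indication and side-effect PT term sets."""

    drug_id: str
    indication_terms: frozenset[str] = frozenset()
    side_effect_terms: frozenset[str] = frozenset()


def map_terms_to_level(
    terms: Iterable[str],
    hierarchy: MeddraHierarchy,
    level: str,
    *,
    on_unknown: str = "error",
) -> frozenset[str]:
    """Map PT terms to the union of their ancestors at ``level``.

    At level ``PT`` this is the identity on known terms.  ``on_unknown``
    is ``"error"`` (default) or ``"skip"``.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown MedDRA level {level!r}; expected one of {LEVELS}")
    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    mapped: set[str] = set()
    for term in terms:
        if term not in hierarchy:
            if on_unknown == "skip":
                continue
            raise UnknownTermError(f"PT term {term!r} not found in hierarchy")
        mapped |= hierarchy.ancestors(term, level)
    return frozenset(mapped)


def jaccard_similarity(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Jaccard index |A∩B| / |A∪B| of two non-empty term sets.

    Raises :class:`FeatureUnavailable` if either set is empty — absent
    annotations are missing evidence, not zero similarity.
    """
    a, b = frozenset(set_a), frozenset(set_b)
    if not a or not b:
        raise FeatureUnavailable("Jaccard similarity undefined for empty term sets")
    return len(a & b) / len(a | b)


def annotation_features(
    a: AnnotationProfile,
    b: AnnotationProfile,
    hierarchy: MeddraHierarchy,
    *,
    on_unknown: str = "error",
) -> dict[str, float | None]:
    """The 8 annotation features of a drug pair, ``None`` where unavailable.

    For each MedDRA level, the indication (resp. side-effect) feature is the
    Jaccard index of the two drugs' level-mapped term sets; it is unavailable
    when either drug's PT set is empty.
    """
    out: dict[str, float | None] = {}
    for kind, name_tmpl in (("indication_terms", "ind_{}"), ("side_effect_terms", "se_{}")):
        terms_a: frozenset[str] = getattr(a, kind)
        terms_b: frozenset[str] = getattr(b, kind)
        for level in LEVELS:
            name = name_tmpl.format(level.lower())
            if not terms_a or not terms_b:
                out[name] = None
                continue
            mapped_a = map_terms_to_level(terms_a, hierarchy, level, on_unknown=on_unknown)
            mapped_b = map_terms_to_level(terms_b, hierarchy, level, on_unknown=on_unknown)
            if not mapped_a or not mapped_b:  # possible if all terms skipped
                out[name] = None
            else:
                out[name] = jaccard_similarity(mapped_a, mapped_b)
    return out


def profiles_from_frames(
    indications: pd.DataFrame, side_effects: pd.DataFrame
) -> dict[str, AnnotationProfile]:
    """Assemble profiles from long-format (drug_id, pt_id) tables."""
    ind: Mapping[str, set[str]] = {}
    se: Mapping[str, set[str]] = {}
    for frame, store in ((indications, ind), (side_effects, se)):
        for drug, pt in frame[["drug_id", "pt_id"]].itertuples(index=False):
            store.setdefault(str(drug), set()).add(str(pt))
    drugs = sorted(set(ind) | set(se))
    return {
        d: AnnotationProfile(
            d,
            frozenset(ind.get(d, ())),
            frozenset(se.get(d, ())),
        )
        for d in drugs
    }
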