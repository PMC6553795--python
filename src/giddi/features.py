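"""Assembly of the 16-feature table for drug pairs.

Each unordered drug pair gets 16 features in 4 groups:

* 4 indication-similarity features (Jaccard at MedDRA PT/HLT/HLGT/SOC),
* 4 side-effect-similarity features (same levels),
* 4 target-sequence-similarity features (normalized Smith–Waterman,
  aggregated by min/mean/median/max over cross target pairs),
* 4 genetic-interaction features (homology-mapped GI scores, same four
  aggregations).

Unavailable features are NaN in the table; only pairs with all 16
available enter modeling.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .align import TARGET_FEATURES, ScoringScheme, TargetSet, target_features
from .gi import GI_FEATURES, gi_features
from .meddra import (
    INDICATION_FEATURES,
    SIDE_EFFECT_FEATURES,
    AnnotationProfile,
    MeddraHierarchy,
    annotation_features,
)
from .pairs import canonical_pair

FEATURE_NAMES: tuple[str, ...] = (
    *INDICATION_FEATURES,
    *SIDE_EFFECT_FEATURES,
    *TARGET_FEATURES,
    *GI_FEATURES,
)

FEATURE_GROUPS: dict[str, str] = {
    **{f: "indication" for f in INDICATION_FEATURES},
    **{f: "side_effect" for f in SIDE_EFFECT_FEATURES},
    **{f: "target" for f in TARGET_FEATURES},
    **{f: "gi" for f in GI_FEATURES},
}

GROUP_ORDER = ("indication", "side_effect", "target", "gi")


def pair_features(
    drug_a: str,
    drug_b: str,
    profiles: Mapping[str, AnnotationProfile],
    hierarchy: MeddraHierarchy,
    targets: Mapping[str, TargetSet],
    hmap: Mapping[str, frozenset[str]],
    gmap: Mapping[tuple[str, str], float],
    scheme: ScoringScheme | None = None,
    *,
    similarity_cache: dict | None = None,
    gi_cache: dict | None = None,
) -> dict[str, float | None]:
    """All 16 features for one unordered drug pair (None = unavailable)."""
    a, b = canonical_pair(drug_a, drug_b)
    empty = AnnotationProfile(drug_id="")
    feats = annotation_features(profiles.get(a, empty), profiles.get(b, empty), hierarchy)
    no_targets = TargetSet(drug_id="", sequences={})
    ta = targets.get(a, no_targets)
    tb = targets.get(b, no_targets)
    feats.update(target_features(ta, tb, scheme, similarity_cache=similarity_cache))
    feats.update(gi_features(ta, tb, hmap, gmap, score_cache=gi_cache))
    return {name: feats[name] for name in FEATURE_NAMES}


def build_feature_table(
    pairs: Iterable[tuple[str, str]],
    profiles: Mapping[str, AnnotationProfile],
    hierarchy: MeddraHierarchy,
    targets: Mapping[str, TargetSet],
    hmap: Mapping[str, frozenset[str]],
    gmap: Mapping[tuple[str, str], float],
    scheme: ScoringScheme | None = None,
) -> pd.DataFrame:
    """Feature table indexed by canonical (drug_a, drug_b); NaN = unavailable.

    Sequence alignments and homology-mapped GI scores are cached per gene
    pair across drug pairs, so repeated targets cost one alignment.
    """
    scheme = scheme or ScoringScheme()
    sim_cache: dict = {}
    gi_cache: dict = {}
    rows = {}
    for a, b in pairs:
        key = canonical_pair(a, b)
        if key in rows:
            continue
        rows[key] = pair_features(
            *key,
            profiles,
            hierarchy,
            targets,
            hmap,
            gmap,
            scheme,
            similarity_cache=sim_cache,
            gi_cache=gi_cache,
        )
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))
    frame = frame.astype(float)
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["drug_a", "drug_b"])
    return frame.sort_index()
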