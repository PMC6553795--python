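"""Synthetic cohorts with planted interaction structure.

Real inputs to this pipeline come from licensed pharmacology and genetics
databases, so testing end to end requires a generator that emulates their
joint statistical structure: adversely interacting drug pairs have more
similar indications and side effects, more similar protein targets, and
more negative (synergistic) genetic-interaction scores between their
targets than non-interacting pairs.

The generator plants each of these contrasts explicitly:

* labels are drawn at a configurable prevalence over all drug pairs;
* each interacting pair receives a few shared indication and side-effect
  PT terms drawn from small "risk pools", boosting annotation overlap;
* each interacting pair (with probability ``target_boost_prob``) is given
  one target each from a paralog family — mutated copies of a common
  ancestral sequence — boosting target-sequence similarity;
* yeast GI scores for the homolog pairs of interacting drugs' targets are
  drawn from Normal(delta, sigma) with ``delta <= 0`` (synergistic shift),
  all other gene pairs from Normal(0, sigma).

Setting ``delta = 0`` and the boosts off yields a null cohort in which no
feature carries signal.  Every output parses through the package's own
readers, and generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align import ScoringScheme, TargetSet
from .gi import GiMeasurement, pair_key
from .meddra import AnnotationProfile, MeddraHierarchy
from .metrics import permutation_test_mean
from .pairs import canonical_pair

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions
    used throughout the test suite."""

    n_drugs: int = 150
    prevalence: float = 0.1
    # latent pharmacological classes: interaction propensity, annotation
    # pools and target families are all organized by cluster, so the
    # planted contrasts survive drug-based splitting
    n_clusters: int = 8
    within_cluster_odds: float = 12.0
    cluster_pool_size: int = 10
    cluster_target_prob: float = 0.8
    # MedDRA-like hierarchy shape
    n_soc: int = 10
    hlgt_per_soc: int = 3
    hlt_per_hlgt: int = 3
    pt_per_hlt: int = 4
    multi_parent_fraction: float = 0.1
    # targets and sequences
    n_base_genes: int = 60
    n_paralog_families: int = 8  # one per cluster by default
    variants_per_family: int = 4
    extra_targets_mean: float = 1.0
    max_targets: int = 4
    seq_len_range: tuple[int, int] = (80, 160)
    mutation_rate: float = 0.1
    # annotations
    annotation_size_range: tuple[int, int] = (4, 8)
    risk_pool_size: int = 15
    n_shared_terms: int = 3
    # planted effects
    target_boost_prob: float = 0.9
    gi_shift: float = -0.4  # delta; <= 0 (synergistic for interacting pairs)
    gi_sigma: float = 0.2
    gi_failing_fraction: float = 0.2
    gi_p_cutoff: float = 0.05
    max_alleles: int = 3
    # homology
    fraction_no_homolog: float = 0.02
    fraction_two_homologs: float = 0.05
    exclusion_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.gi_shift > 0:
            raise ValueError("gi_shift (delta) must be <= 0")
        for name in ("n_drugs", "n_soc", "hlgt_per_soc", "hlt_per_hlgt", "pt_per_hlt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_drugs < 2:
            raise ValueError("need at least 2 drugs to form pairs")
        if self.gi_sigma <= 0:
            raise ValueError("gi_sigma must be positive")
        n_pt = self.n_soc * self.hlgt_per_soc * self.hlt_per_hlgt * self.pt_per_hlt
        if self.annotation_size_range[1] + self.n_shared_terms > n_pt:
            raise ValueError("annotation sets larger than the PT term pool")
        if self.risk_pool_size > n_pt:
            raise ValueError("risk pool larger than the PT term pool")

    def null(self) -> "CohortConfig":
        """The matching no-signal cohort.

        Labels become independent of the latent clusters
        (``within_cluster_odds = 1``) and every planted effect is switched
        off, so no feature carries information about the labels.
        """
        return replace(
            self,
            gi_shift=0.0,
            n_shared_terms=0,
            target_boost_prob=0.0,
            within_cluster_odds=1.0,
        )


@dataclass
class SyntheticCohort:
    """All pipeline inputs for one synthetic study, plus the generator log."""

    config: CohortConfig | None
    drugs: list[str]
    hierarchy: MeddraHierarchy
    profiles: dict[str, AnnotationProfile]
    targets: dict[str, TargetSet]
    measurements: list[GiMeasurement]
    hmap: dict[str, frozenset[str]]
    positives: list[tuple[str, str]]
    exclusions: list[tuple[str, str]]
    truth: dict = field(default_factory=dict)

    def all_pairs(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for i, a in enumerate(self.drugs)
            for b in self.drugs[i + 1 :]
        ]

    def gene_sequences(self) -> dict[str, str]:
        seqs: dict[str, str] = {}
        for tset in self.targets.values():
            seqs.update(tset.sequences)
        return seqs

    def to_files(self, out_dir) -> dict[str, Path]:
        """Write the full input file set (TSV + FASTA) the pipeline consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        paths["meddra"] = out / "meddra.tsv"
        pd.DataFrame(
            self.hierarchy.paths, columns=["pt_id", "hlt_id", "hlgt_id", "soc_id"]
        ).to_csv(paths["meddra"], sep="\t", index=False)

        for name, attr in (("indications", "indication_terms"), ("side_effects", "side_effect_terms")):
            rows = [
                {"drug_id": d, "pt_id": t}
                for d in self.drugs
                for t in sorted(getattr(self.profiles[d], attr))
            ]
            paths[name] = out / f"{name}.tsv"
            pd.DataFrame(rows, columns=["drug_id", "pt_id"]).to_csv(
                paths[name], sep="\t", index=False
            )

        paths["drugs"] = out / "drugs.tsv"
        pd.DataFrame(
            [
                {"drug_id": d, "gene_id": g}
                for d in self.drugs
                for g in sorted(self.targets[d].sequences)
            ]
        ).to_csv(paths["drugs"], sep="\t", index=False)

        paths["fasta"] = out / "targets.fasta"
        with open(paths["fasta"], "w") as fh:
            for gene, seq in sorted(self.gene_sequences().items()):
                fh.write(f">{gene}\n{seq}\n")

        paths["gi"] = out / "gi.tsv"
        pd.DataFrame(
            [
                {
                    "gene_a": m.gene_a,
                    "gene_b": m.gene_b,
                    "allele_a": m.allele_a,
                    "allele_b": m.allele_b,
                    # repr round-trips doubles exactly through the TSV
                    "score": repr(m.score),
                    "p_value": repr(m.p_value),
                }
                for m in self.measurements
            ]
        ).to_csv(paths["gi"], sep="\t", index=False)

        paths["homologs"] = out / "homologs.tsv"
        pd.DataFrame(
            [
                {"human_gene": h, "model_gene": m}
                for h in sorted(self.hmap)
                for m in sorted(self.hmap[h])
            ],
            columns=["human_gene", "model_gene"],
        ).to_csv(paths["homologs"], sep="\t", index=False)

        paths["labels"] = out / "labels.tsv"
        rows = [{"drug_a": a, "drug_b": b, "label": 1} for a, b in self.positives]
        rows += [{"drug_a": a, "drug_b": b, "label": 0} for a, b in self.exclusions]
        pd.DataFrame(rows, columns=["drug_a", "drug_b", "label"]).to_csv(
            paths["labels"], sep="\t", index=False
        )
        return paths


def _make_hierarchy(cfg: CohortConfig, rng: np.random.Generator) -> MeddraHierarchy:
    paths = []
    pt_ids = []
    k = 0
    for s in range(cfg.n_soc):
        for g in range(cfg.hlgt_per_soc):
            for h in range(cfg.hlt_per_hlgt):
                for _ in range(cfg.pt_per_hlt):
                    pt = f"pt{k:04d}"
                    paths.append((pt, f"hlt_{s}_{g}_{h}", f"hlgt_{s}_{g}", f"soc_{s}"))
                    pt_ids.append(pt)
                    k += 1
    # multi-axial placements: a fraction of PTs gain a second path
    all_hlts = sorted({p[1] for p in paths})
    hlt_parent = {p[1]: (p[2], p[3]) for p in paths}
    n_multi = int(round(cfg.multi_parent_fraction * len(pt_ids)))
    for pt in rng.choice(pt_ids, size=n_multi, replace=False):
        hlt = str(rng.choice(all_hlts))
        hlgt, soc = hlt_parent[hlt]
        paths.append((str(pt), hlt, hlgt, soc))
    return MeddraHierarchy(tuple(sorted(set(paths))))


def _random_sequence(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_RESIDUES, size=n))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    arr[hits] = rng.choice(_RESIDUES, size=int(hits.sum()))
    return "".join(arr)


def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Generate a complete, internally consistent synthetic cohort."""
    rng = np.random.default_rng(cfg.seed)
    drugs = [f"D{i:03d}" for i in range(cfg.n_drugs)]
    hierarchy = _make_hierarchy(cfg, rng)
    pt_ids = sorted({p[0] for p in hierarchy.paths})

    # ancestral sequences and paralog families
    genes: dict[str, str] = {
        f"G{i:03d}": _random_sequence(rng, *cfg.seq_len_range)
        for i in range(cfg.n_base_genes)
    }
    families: list[list[str]] = []
    for f in range(cfg.n_paralog_families):
        ancestor = _random_sequence(rng, *cfg.seq_len_range)
        fam = []
        for v in range(cfg.variants_per_family):
            name = f"P{f:03d}v{v}"
            genes[name] = _mutate(ancestor, cfg.mutation_rate, rng)
            fam.append(name)
        families.append(fam)

    # latent pharmacological classes drive targets, annotations and labels
    cluster = {d: int(rng.integers(cfg.n_clusters)) for d in drugs}

    base_gene_ids = sorted(g for g in genes if g.startswith("G"))
    target_sets: dict[str, set[str]] = {}
    for d in drugs:
        n_t = 1 + min(int(rng.poisson(cfg.extra_targets_mean)), cfg.max_targets - 1)
        target_sets[d] = set(rng.choice(base_gene_ids, size=n_t, replace=False))
        if families and rng.random() < cfg.cluster_target_prob:
            fam = families[cluster[d] % len(families)]
            target_sets[d].add(str(rng.choice(fam)))

    # annotations: half of each drug's terms from its cluster pool
    ind_pool = [
        list(rng.choice(pt_ids, size=cfg.cluster_pool_size, replace=False))
        for _ in range(cfg.n_clusters)
    ]
    se_pool = [
        list(rng.choice(pt_ids, size=cfg.cluster_pool_size, replace=False))
        for _ in range(cfg.n_clusters)
    ]
    risk_ind = list(rng.choice(pt_ids, size=cfg.risk_pool_size, replace=False))
    risk_se = list(rng.choice(pt_ids, size=cfg.risk_pool_size, replace=False))
    ind_sets: dict[str, set[str]] = {}
    se_sets: dict[str, set[str]] = {}
    lo, hi = cfg.annotation_size_range
    for d in drugs:
        for store, pool in ((ind_sets, ind_pool), (se_sets, se_pool)):
            n = int(rng.integers(lo, hi + 1))
            n_cluster = min(n // 2, cfg.cluster_pool_size)
            terms = set(rng.choice(pool[cluster[d]], size=n_cluster, replace=False))
            terms |= set(rng.choice(pt_ids, size=n - n_cluster, replace=False))
            store[d] = terms

    # labels: interaction is within_cluster_odds times likelier inside a
    # cluster; the between-cluster rate is calibrated so the expected
    # overall prevalence matches the configured one
    all_pairs = [(a, b) for i, a in enumerate(drugs) for b in drugs[i + 1 :]]
    same = np.array([cluster[a] == cluster[b] for a, b in all_pairs])
    s = float(same.mean())
    p_out = cfg.prevalence / (s * cfg.within_cluster_odds + (1.0 - s))
    p_in = min(cfg.within_cluster_odds * p_out, 0.95)
    draw = rng.random(len(all_pairs))
    positives = [
        p
        for p, is_same, u in zip(all_pairs, same, draw)
        if u < (p_in if is_same else p_out)
    ]
    pos_set = set(positives)

    fam_members = {g for fam in families for g in fam}
    boosted_pairs = []
    for a, b in positives:
        if cfg.n_shared_terms > 0:
            shared_ind = rng.choice(risk_ind, size=cfg.n_shared_terms, replace=False)
            shared_se = rng.choice(risk_se, size=cfg.n_shared_terms, replace=False)
            ind_sets[a].update(shared_ind)
            ind_sets[b].update(shared_ind)
            se_sets[a].update(shared_se)
            se_sets[b].update(shared_se)
        if families and rng.random() < cfg.target_boost_prob:
            # give both drugs a (mutated-copy) member of one paralog family
            fam = families[cluster[a] % len(families)]
            for d in (a, b):
                if not target_sets[d] & fam_members:
                    target_sets[d].add(str(rng.choice(fam)))
            boosted_pairs.append((a, b))

    # homology: human gene -> 0, 1 or 2 yeast genes
    all_gene_ids = sorted(genes)
    hmap: dict[str, frozenset[str]] = {}
    yeast_of: dict[str, str] = {}
    u = rng.random(len(all_gene_ids))
    for g, p in zip(all_gene_ids, u):
        if p < cfg.fraction_no_homolog:
            hmap[g] = frozenset()
            continue
        primary = f"y_{g}"
        yeast_of[g] = primary
        if p < cfg.fraction_no_homolog + cfg.fraction_two_homologs:
            hmap[g] = frozenset((primary, f"y2_{g}"))
        else:
            hmap[g] = frozenset((primary,))

    # GI scores: the homolog pairs of same-family target genes — the gene
    # pairs characteristic of interacting drugs' targets — are drawn from
    # Normal(delta, sigma); every other yeast gene pair from Normal(0, sigma)
    shifted_yeast_pairs: set[tuple[str, str]] = set()
    if cfg.gi_shift < 0:
        for fam in families:
            for i, ga in enumerate(fam):
                for gb in fam[i + 1 :]:
                    for ya in hmap.get(ga, ()):
                        for yb in hmap.get(gb, ()):
                            if ya != yb:
                                shifted_yeast_pairs.add(pair_key(ya, yb))

    yeast_genes = sorted({y for hs in hmap.values() for y in hs})
    measurements: list[GiMeasurement] = []
    for i, ya in enumerate(yeast_genes):
        for yb in yeast_genes[i + 1 :]:
            mu = cfg.gi_shift if pair_key(ya, yb) in shifted_yeast_pairs else 0.0
            n_alleles = int(rng.integers(1, cfg.max_alleles + 1))
            for k in range(n_alleles):
                if rng.random() < cfg.gi_failing_fraction:
                    p = float(rng.uniform(cfg.gi_p_cutoff, 1.0))
                else:
                    p = float(rng.uniform(0.0, cfg.gi_p_cutoff))
                measurements.append(
                    GiMeasurement(
                        gene_a=ya,
                        gene_b=yb,
                        score=float(rng.normal(mu, cfg.gi_sigma)),
                        p_value=p,
                        allele_a=f"{ya}-a{k}",
                        allele_b=f"{yb}-a{k}",
                    )
                )

    negatives = [p for p in all_pairs if p not in pos_set]
    n_excl = int(round(cfg.exclusion_fraction * len(negatives)))
    excl_idx = rng.choice(len(negatives), size=n_excl, replace=False) if n_excl else []
    exclusions = [negatives[i] for i in sorted(excl_idx)]

    profiles = {
        d: AnnotationProfile(d, frozenset(ind_sets[d]), frozenset(se_sets[d]))
        for d in drugs
    }
    targets = {
        d: TargetSet(d, {g: genes[g] for g in sorted(target_sets[d])}) for d in drugs
    }
    return SyntheticCohort(
        config=cfg,
        drugs=drugs,
        hierarchy=hierarchy,
        profiles=profiles,
        targets=targets,
        measurements=measurements,
        hmap=hmap,
        positives=positives,
        exclusions=exclusions,
        truth={
            "boosted_target_pairs": boosted_pairs,
            "n_shifted_yeast_pairs": len(shifted_yeast_pairs),
        },
    )


def worked_fixture() -> SyntheticCohort:
    """A tiny frozen cohort whose per-pair features are hand-checkable.

    Six drugs, short explicit sequences, explicit term sets and GI scores.
    Drug ``D6`` has no yeast homologs for its only target, so all its pairs
    lack GI features and drop out of the complete-feature filter.  Intended
    for use with ``ScoringScheme(substitution=(1, -1), gap_open=1,
    gap_extend=1)`` so alignment scores are obvious by eye.
    """
    paths = (
        ("pt1", "h1", "g1", "s1"),
        ("pt1", "h2", "g1", "s1"),  # multi-parent PT
        ("pt2", "h1", "g1", "s1"),
        ("pt3", "h2", "g1", "s1"),
        ("pt4", "h3", "g2", "s1"),
        ("pt5", "h4", "g3", "s2"),
        ("pt6", "h4", "g3", "s2"),
    )
    hierarchy = MeddraHierarchy(paths)
    profiles = {
        "D1": AnnotationProfile("D1", frozenset({"pt1", "pt2"}), frozenset({"pt5"})),
        "D2": AnnotationProfile("D2", frozenset({"pt1", "pt2"}), frozenset({"pt6"})),
        "D3": AnnotationProfile("D3", frozenset({"pt3"}), frozenset({"pt5", "pt6"})),
        "D4": AnnotationProfile("D4", frozenset({"pt4"}), frozenset({"pt4"})),
        "D5": AnnotationProfile("D5", frozenset({"pt2", "pt3"}), frozenset({"pt5"})),
        "D6": AnnotationProfile("D6", frozenset({"pt1"}), frozenset({"pt6"})),
    }
    seqs = {
        "GA": "AAAA",
        "GB": "AACC",
        "GC": "CCCC",
        "GD": "AAAA",  # identical sequence to GA, different gene
        "GE": "ACAC",
    }
    targets = {
        "D1": TargetSet("D1", {"GA": seqs["GA"], "GB": seqs["GB"]}),
        "D2": TargetSet("D2", {"GC": seqs["GC"]}),
        "D3": TargetSet("D3", {"GA": seqs["GA"]}),
        "D4": TargetSet("D4", {"GD": seqs["GD"]}),
        "D5": TargetSet("D5", {"GB": seqs["GB"], "GC": seqs["GC"]}),
        "D6": TargetSet("D6", {"GE": seqs["GE"]}),
    }
    hmap = {
        "GA": frozenset({"yA"}),
        "GB": frozenset({"yB1", "yB2"}),
        "GC": frozenset({"yC"}),
        "GD": frozenset({"yD"}),
        "GE": frozenset(),  # D6's target has no homolog
    }
    measurements = [
        GiMeasurement("yA", "yC", score=-0.2, p_value=0.01),
        GiMeasurement("yA", "yC", score=-0.4, p_value=0.03),
        GiMeasurement("yA", "yC", score=0.5, p_value=0.2),  # fails the p-filter
        GiMeasurement("yB1", "yC", score=-0.1, p_value=0.02),
        GiMeasurement("yB2", "yC", score=-0.3, p_value=0.04),
        GiMeasurement("yA", "yB1", score=0.4, p_value=0.01),
        GiMeasurement("yA", "yD", score=-0.5, p_value=0.02),
        GiMeasurement("yB1", "yD", score=0.2, p_value=0.03),
        GiMeasurement("yC", "yD", score=0.1, p_value=0.01),
    ]
    positives = [("D1", "D2"), ("D3", "D4")]
    return SyntheticCohort(
        config=None,
        drugs=["D1", "D2", "D3", "D4", "D5", "D6"],
        hierarchy=hierarchy,
        profiles=profiles,
        targets=targets,
        measurements=measurements,
        hmap=hmap,
        positives=positives,
        exclusions=[("D1", "D5")],
    )


def contrast_report(
    features: pd.DataFrame,
    labels: Sequence[tuple[str, str, int]],
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature interacting-vs-non-interacting contrast with permutation p.

    Mirrors the feature-distribution comparison used to establish which
    similarity and GI features separate the two classes: for each feature,
    the mean in each class, their difference, and a two-sided permutation
    test on the sample mean over the pairs where the feature is available.
    """
    label_map = {canonical_pair(a, b): y for a, b, y in labels}
    rows = []
    for fi, feat in enumerate(features.columns):
        vals_pos, vals_neg = [], []
        for pair, v in features[feat].items():
            y = label_map.get(pair)
            if y is None or pd.isna(v):
                continue
            (vals_pos if y == 1 else vals_neg).append(float(v))
        if not vals_pos or not vals_neg:
            continue
        p = permutation_test_mean(vals_pos, vals_neg, n_perm=n_perm, seed=seed + fi)
        rows.append(
            {
                "feature": feat,
                "mean_interacting": np.mean(vals_pos),
                "mean_non_interacting": np.mean(vals_neg),
                "difference": np.mean(vals_pos) - np.mean(vals_neg),
                "p_value": p,
                "n_interacting": len(vals_pos),
                "n_non_interacting": len(vals_neg),
            }
        )
    return pd.DataFrame(rows)
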