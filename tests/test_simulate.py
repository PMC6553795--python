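import numpy as np
import pytest

from giddi import (
    CohortConfig,
    assemble_pairs,
    build_feature_table,
    collapse_allele_scores,
    contrast_report,
    filter_complete,
    generate_cohort,
)
from giddi.features import FEATURE_NAMES


class TestConfig:
    def test_defaults_validate(self):
        cfg = CohortConfig()
        assert cfg.n_drugs == 150
        assert cfg.prevalence == pytest.approx(0.1)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_drugs=1)
        with pytest.raises(ValueError):
            CohortConfig(prevalence=0.0)
        with pytest.raises(ValueError):
            CohortConfig(gi_sigma=-1.0)

    def test_null_variant_disables_every_planted_effect(self):
        null = CohortConfig().null()
        assert null.gi_shift == 0.0
        assert null.n_shared_terms == 0
        assert null.target_boost_prob == 0.0
        assert null.within_cluster_odds == 1.0
        # everything else is untouched
        assert null.n_drugs == CohortConfig().n_drugs
        assert null.seed == CohortConfig().seed


class TestGenerateCohort:
    def test_reproducible_from_seed(self):
        cfg = CohortConfig(n_drugs=20, seed=3)
        c1, c2 = generate_cohort(cfg), generate_cohort(cfg)
        assert c1.drugs == c2.drugs
        assert c1.positives == c2.positives
        assert {d: p.indication_terms for d, p in c1.profiles.items()} == {
            d: p.indication_terms for d, p in c2.profiles.items()
        }
        assert c1.measurements == c2.measurements

    def test_different_seeds_differ(self):
        c1 = generate_cohort(CohortConfig(n_drugs=20, seed=3))
        c2 = generate_cohort(CohortConfig(n_drugs=20, seed=4))
        assert c1.positives != c2.positives

    def test_prevalence_near_requested(self):
        cfg = CohortConfig(n_drugs=80, prevalence=0.1, seed=5)
        c = generate_cohort(cfg)
        n_all = len(c.all_pairs())
        assert 0.06 < len(c.positives) / n_all < 0.14

    def test_inputs_are_internally_consistent(self):
        c = generate_cohort(CohortConfig(n_drugs=25, seed=7))
        assert set(c.profiles) == set(c.drugs) == set(c.targets)
        known_pts = {p[0] for p in c.hierarchy.paths}
        for prof in c.profiles.values():
            assert prof.indication_terms <= known_pts
            assert prof.side_effect_terms <= known_pts
        yeast = {g for hs in c.hmap.values() for g in hs}
        for m in c.measurements:
            assert {m.gene_a, m.gene_b} <= yeast
            assert 0.0 <= m.p_value <= 1.0
        for a, b in c.positives + c.exclusions:
            assert a in c.drugs and b in c.drugs and a < b

    def test_feature_table_mostly_complete(self, small_planted):
        cohort, pair_set, features = small_planted
        assert list(features.columns) == list(FEATURE_NAMES)
        kept = filter_complete(pair_set, features)
        assert len(kept.pairs) / len(pair_set.pairs) > 0.8

    def test_round_trip_through_files(self, tmp_path):
        from giddi.io import (
            read_annotations,
            read_gi_table,
            read_hierarchy,
            read_homologs,
            read_label_pairs,
            read_targets,
        )

        c = generate_cohort(CohortConfig(n_drugs=12, seed=9))
        paths = c.to_files(tmp_path)
        hierarchy = read_hierarchy(paths["meddra"])
        assert set(hierarchy.paths) == set(c.hierarchy.paths)
        profiles = read_annotations(paths["indications"], paths["side_effects"])
        assert {d: p.indication_terms for d, p in profiles.items()} == {
            d: p.indication_terms for d, p in c.profiles.items()
        }
        targets = read_targets(paths["drugs"], paths["fasta"])
        assert {d: t.sequences for d, t in targets.items()} == {
            d: t.sequences for d, t in c.targets.items()
        }
        # genes with no homolog have no table row; absence and an empty
        # homolog set are equivalent downstream
        assert read_homologs(paths["homologs"]) == {
            g: s for g, s in c.hmap.items() if s
        }
        ms = read_gi_table(paths["gi"])
        assert collapse_allele_scores(ms, 0.05) == collapse_allele_scores(
            c.measurements, 0.05
        )
        positives, exclusions = read_label_pairs(paths["labels"])
        assert set(positives) == set(c.positives)
        assert set(exclusions) == set(c.exclusions)


class TestPlantedSignal:
    def test_planted_features_separate_classes(self, small_planted):
        cohort, pair_set, features = small_planted
        report = contrast_report(features, pair_set.pairs, n_perm=2000, seed=0)
        by_feat = report.set_index("feature")
        # the engineered contrasts: shared terms push similarity up for
        # interacting pairs, the GI shift pushes gi_min down
        assert by_feat.loc["ind_pt", "difference"] > 0
        assert by_feat.loc["se_pt", "difference"] > 0
        assert by_feat.loc["gi_min", "difference"] < 0
        assert by_feat.loc["ind_pt", "p_value"] < 0.01
        assert by_feat.loc["gi_min", "p_value"] < 0.01

    def test_null_cohort_shows_no_contrast(self, small_null):
        cohort, pair_set, features = small_null
        report = contrast_report(features, pair_set.pairs, n_perm=2000, seed=0)
        # no planted effect: at alpha = 0.01 at most a couple of the 16
        # features should reject by chance
        assert (report["p_value"] < 0.01).sum() <= 2


class TestWorkedFixture:
    def test_shape_and_labels(self, fixture_cohort):
        c = fixture_cohort
        assert c.drugs == ["D1", "D2", "D3", "D4", "D5", "D6"]
        assert set(c.positives) == {("D1", "D2"), ("D3", "D4")}
        assert c.exclusions == [("D1", "D5")]

    def test_hand_checked_feature_values(self, fixture_features):
        row = fixture_features.loc[("D1", "D2")]
        assert row["gi_min"] == pytest.approx(-0.3)
        assert row["gi_mean"] == pytest.approx(-0.25)
        # GB ("AACC") vs GC ("CCCC") under unit match scoring: raw 2, selves
        # 4 and 4 -> normalized 0.5
        assert row["ts_max"] == pytest.approx(0.5)

    def test_pair_set_after_completeness_filter(self, fixture_cohort, fixture_features):
        c = fixture_cohort
        ps = assemble_pairs(c.positives, c.drugs, c.exclusions)
        assert len(ps.pairs) == 14  # 15 pairs minus the exclusion
        kept = filter_complete(ps, fixture_features)
        assert len(kept.pairs) == 9
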