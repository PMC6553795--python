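import pytest

from giddi import (
    CohortConfig,
    ScoringScheme,
    assemble_pairs,
    build_feature_table,
    collapse_allele_scores,
    generate_cohort,
    worked_fixture,
)


@pytest.fixture(scope="session")
def simple_scheme():
    """Match/mismatch scoring that keeps fixture alignments hand-checkable."""
    return ScoringScheme(substitution=(1, -1), gap_open=1, gap_extend=1)


@pytest.fixture(scope="session")
def fixture_cohort():
    return worked_fixture()


@pytest.fixture(scope="session")
def fixture_gmap(fixture_cohort):
    return collapse_allele_scores(fixture_cohort.measurements, 0.05)


@pytest.fixture(scope="session")
def fixture_features(fixture_cohort, fixture_gmap, simple_scheme):
    c = fixture_cohort
    return build_feature_table(
        c.all_pairs(), c.profiles, c.hierarchy, c.targets, c.hmap, fixture_gmap, simple_scheme
    )


def _bundle(cfg):
    cohort = generate_cohort(cfg)
    gmap = collapse_allele_scores(cohort.measurements, cfg.gi_p_cutoff)
    pair_set = assemble_pairs(cohort.positives, cohort.drugs, cohort.exclusions)
    features = build_feature_table(
        [(a, b) for a, b, _ in pair_set.pairs],
        cohort.profiles,
        cohort.hierarchy,
        cohort.targets,
        cohort.hmap,
        gmap,
    )
    return cohort, pair_set, features


@pytest.fixture(scope="session")
def small_planted():
    """A 40-drug planted-signal cohort with its pair set and feature table."""
    return _bundle(CohortConfig(n_drugs=40, seed=11))


@pytest.fixture(scope="session")
def small_null():
    """The matching 40-drug no-signal cohort."""
    return _bundle(CohortConfig(n_drugs=40, seed=11).null())
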