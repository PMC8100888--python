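"""Shared fixtures: small synthetic worlds reused across test modules."""

import warnings

import pytest

import shadowharm as sh


@pytest.fixture(scope="session")
def vocab():
    return sh.generate_vocabulary(60, 3, seed=7)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete world: confounding, psychotherapy, under-coding."""
    gt = sh.default_ground_truth(seed=0)
    return sh.generate_population(gt, 400, 2555, seed=11, psychotherapy_fraction=0.3)


@pytest.fixture(scope="session")
def imputation_sim():
    """A world sized for the imputation stage: enough coded events to train
    on, with ordinary hospitalizations dominating uncoded events."""
    gt = sh.default_ground_truth(seed=0)
    return sh.generate_population(gt, 6000, 2920, seed=2, psychotherapy_fraction=0.3)


@pytest.fixture(scope="session")
def labeled_metavisits(imputation_sim):
    mv = sh.build_meta_visits(imputation_sim.visits)
    return sh.label_coded_selfharm(mv, imputation_sim.vocab)


@pytest.fixture(scope="session")
def scored_metavisits(imputation_sim, labeled_metavisits):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sh.crossfit_probabilities(
            labeled_metavisits, imputation_sim.patients, imputation_sim.vocab,
            k=5, seed=1,
        )
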