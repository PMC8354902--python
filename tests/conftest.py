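"""Shared fixtures: small task designs and scaled-down synthetic cohorts.

Cohort fixtures use reduced problem sizes (16 nodes, 2 runs, 120 volumes,
20 subjects per group) so the whole suite runs on one CPU; the full-size
study structure is exercised where it is cheap (task design, thresholding
counts, feature-model enumeration).
"""

import numpy as np
import pytest

import taskconn as tc

#: penalty grid used throughout the scaled-down tests
TEST_LAMBDA_GRID = np.logspace(-1.3, 0.0, 10)


def make_cohort_config(seed, *, planted=False, n_per_group=20,
                       n_timepoints=120, n_runs=2, tonic_multiplier=2.0):
    """16-node two-site cohort; optionally with a planted BPD tonic hub
    effect on the left amygdala."""
    tonic_effects = ()
    spec = tc.PrecisionSpec()
    if planted:
        tonic_effects = (tc.TonicEffect("BPD", ("amygdala_L",),
                                        tonic_multiplier),)
        spec = tc.PrecisionSpec(within_prob=0.4, min_degree=2, min_eig=0.5)
    return tc.CohortConfig(
        group_sizes={"BPD": n_per_group, "CLC": 0, "NPC": n_per_group},
        n_nodes=16,
        module_sizes={"emotion": 4, "motivation": 3, "cognitive_control": 4,
                      "default_mode": 3, "other": 2},
        sites={"siteA": tc.SiteConfig(n_timepoints, 0.0, 1.0),
               "siteB": tc.SiteConfig(n_timepoints, 0.2, 1.1)},
        n_runs=n_runs, trials_per_run=6,
        timing=tc.TimingConfig(run_duration=240.0),
        precision_spec=spec,
        tonic_effects=tonic_effects,
        seed=seed)


@pytest.fixture(scope="session")
def null_models():
    """Feature tables from a null cohort (no group effects) plus labels."""
    cohort = tc.simulate_cohort(make_cohort_config(99))
    models = tc.extract_features(cohort, 0.10, TEST_LAMBDA_GRID)
    sub, y = tc.select_groups(models, ("BPD", "NPC"))
    return sub, y, cohort


@pytest.fixture(scope="session")
def planted_models():
    """Feature tables from a cohort with an elevated BPD amygdala hub."""
    cohort = tc.simulate_cohort(make_cohort_config(0, planted=True))
    models = tc.extract_features(cohort, 0.10, TEST_LAMBDA_GRID)
    sub, y = tc.select_groups(models, ("BPD", "NPC"))
    return sub, y, cohort


@pytest.fixture()
def small_design():
    return tc.build_task_design(2, 6, tc.TimingConfig(run_duration=240.0),
                                seed=3)


@pytest.fixture()
def design_matrix(small_design):
    rng = np.random.default_rng(11)
    motion = np.cumsum(rng.normal(0, 0.02, size=(120, 6)), axis=0)
    return tc.build_design_matrix(small_design, 1, 120, 2.0, motion=motion)
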