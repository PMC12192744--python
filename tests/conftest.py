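"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

import pssmap as pm


@pytest.fixture(scope="session")
def small_grid():
    return pm.VoxelGrid.centered((20, 20, 20), 0.5)


@pytest.fixture(scope="session")
def tiny_sim_config():
    """A desk-scale protocol: 6 patients, short tracts, 32^3 grid."""
    return dict(
        n_patients=6,
        stims_per_patient_mean=8.0,
        stims_per_patient_sd=2.0,
        grid_shape=(32, 32, 32),
        tract_span_mm=8.0,
        depth_min_mm=-6.0,
        depth_max_mm=2.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_sim_config):
    cfg = pm.SimConfig(seed=101, **tiny_sim_config)
    cohort, gt_mask = pm.generate_cohort(cfg, pm.recovery_ground_truth())
    return cohort, gt_mask


@pytest.fixture(scope="session")
def tiny_stack(tiny_cohort):
    cohort, _ = tiny_cohort
    return pm.build_stack(cohort)


@pytest.fixture(scope="session")
def recovery_run():
    """Full-scale strong-signal cohort with its stack (seed 1)."""
    cohort, gt_mask = pm.generate_cohort(
        pm.strong_signal_config(seed=1), pm.recovery_ground_truth())
    return cohort, gt_mask, pm.build_stack(cohort)
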