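"""Shared fixtures.

The expensive artifacts (synthetic cohort, per-sample fits, and the
region-of-interest cross-validation run at the reduced training budget)
are session-scoped so the protocol-level tests share one computation.
"""

import logging

import numpy as np
import pytest

logging.getLogger("artmech.fitting").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 27-sample synthetic cohort (seed 1)."""
    from artmech.synthdata import CohortConfig, make_cohort

    config = CohortConfig(seed=1)
    samples, truths = make_cohort(config)
    return config, samples, truths


@pytest.fixture(scope="session")
def cohort_fits(default_cohort):
    """Per-sample least-squares fits of the default cohort."""
    from artmech.fitting import fit_material_params

    _, samples, _ = default_cohort
    return {s.sample_id: fit_material_params(s) for s in samples}


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-sample cohort for cheap pipeline tests."""
    from artmech.synthdata import CohortConfig, make_cohort

    config = CohortConfig(n_samples=6, seed=4)
    samples, truths = make_cohort(config)
    return config, samples, truths


@pytest.fixture(scope="session")
def roi_cv_run(default_cohort, cohort_fits):
    """Reduced-budget region-of-interest cross-validation of the hybrid
    model (200 epochs, 3 restarts, 8 augmentation copies, 6 most-central
    folds) plus the standard-fitting baseline on the same cohort."""
    from artmech.fitting import latent_point, loo_standard_prediction, roi_members
    from artmech.trainer import TrainConfig, loo_cv_roi

    _, samples, _ = default_cohort
    config = TrainConfig(epochs=200, restarts=3, aug_copies=8, master_seed=7)
    cv = loo_cv_roi(samples, config, fits=cohort_fits, max_folds=6)
    baseline = loo_standard_prediction(samples, fits=cohort_fits)
    points = {sid: latent_point(f.params) for sid, f in cohort_fits.items()}
    roi = roi_members(points)
    return {"cv": cv, "baseline": baseline, "roi": roi, "points": points,
            "train_config": config}
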