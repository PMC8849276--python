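"""Shared fixtures: small synthetic cohorts with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from csmomics.preprocess import transform_autoscale
from csmomics.simulate import GeneratorConfig, generate_cohort

from _util import make_pairs


@pytest.fixture(scope="session")
def small_cohort():
    """12-pair cohort with small panels; fast enough for unit tests."""
    cfg = GeneratorConfig(
        seed=101,
        n_pairs=12,
        n_metabolites=40,
        n_proteins=20,
        n_cytokines=8,
        n_differential={"metabolite": 4, "protein": 2, "cytokine": 1},
        n_corr_shift_pairs=2,
        frac_low_detection=0.05,
        frac_low_detection_cytokine=0.25,
        qc_cv_fail_frac=0.15,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """90 pairs, 5 strong true analytes among 100, no censoring/QC noise.

    The regime used for selection/power checks: clean columns so every
    analyte survives preprocessing.
    """
    cfg = GeneratorConfig(
        seed=11,
        n_pairs=90,
        n_metabolites=100,
        n_proteins=5,
        n_cytokines=5,
        n_differential={"metabolite": 5, "protein": 0, "cytokine": 0},
        delta_range=(1.5, 1.5),
        block_rho=0.2,
        frac_low_detection=0.0,
        frac_low_detection_cytokine=0.0,
        qc_cv_fail_frac=0.0,
        lod_quantile=0.0,
        severity_gradient=False,
        n_corr_shift_pairs=0,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_processed(planted_cohort):
    return transform_autoscale(planted_cohort.matrices["metabolite"].values)


@pytest.fixture()
def toy_pairs():
    return make_pairs(4)
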