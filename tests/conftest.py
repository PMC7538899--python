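"""Shared fixtures: small synthetic cohorts with known ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import octlayers as ol


@pytest.fixture(scope="session")
def onl_effects():
    """Single layer x subfield fixed effects at the reference cohort's
    ONL-center values (control 116.9 µm, difference -92.9 µm, STGD1
    thinning -2 µm/yr)."""
    return {("ONL", "center"): ol.LayerEffects(116.9, -92.9, 0.0, -2.0)}


@pytest.fixture(scope="session")
def small_cohort(onl_effects):
    """A 20-patient single-layer cohort with default variance components."""
    params = ol.CohortParams(
        n_patients_control=10, n_patients_stgd=10,
        fixed_effects=onl_effects, seed=101,
    )
    table, truth = ol.simulate_cohort(params)
    return params, table, truth


@pytest.fixture(scope="session")
def study_size_cohort(onl_effects):
    """A cohort at the study's size (40 control / 63 STGD1 patients),
    single layer x subfield for speed."""
    params = ol.CohortParams(fixed_effects=onl_effects, seed=202)
    table, truth = ol.simulate_cohort(params)
    return params, table, truth


@pytest.fixture(scope="session")
def full_profile_cohort():
    """A small cohort carrying the full 27-entry layer x subfield profile."""
    params = ol.CohortParams(n_patients_control=8, n_patients_stgd=8, seed=303)
    table, truth = ol.simulate_cohort(params)
    return params, table, truth


def brute_force_subfield_means(surfaces, spacing_b, spacing_a, fovea,
                               valid=None, radii=(0.5, 1.5, 3.0)):
    """Independent per-pixel enumeration of ETDRS subfield sublayer means.

    Deliberately written as plain Python loops with no masking shortcuts:
    this is the oracle the vectorized extractor is checked against.
    """
    n_surf, nb, na = surfaces.shape
    sums = {}
    counts = {}
    for b in range(nb):
        for a in range(na):
            if valid is not None and not valid[b][a]:
                continue
            db = (b - fovea[0]) * spacing_b
            da = (a - fovea[1]) * spacing_a
            r = (db * db + da * da) ** 0.5
            if r <= radii[0]:
                sf = "center"
            elif r <= radii[1]:
                sf = "inner_ring"
            elif r <= radii[2]:
                sf = "outer_ring"
            else:
                continue
            for k in range(n_surf - 1):
                t = surfaces[k + 1, b, a] - surfaces[k, b, a]
                sums[(k, sf)] = sums.get((k, sf), 0.0) + t
                counts[(k, sf)] = counts.get((k, sf), 0) + 1
    return {key: sums[key] / counts[key] for key in sums}, counts
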