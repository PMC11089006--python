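"""Shared fixtures: deterministic small spaces and a reusable tiny cohort."""

from __future__ import annotations

import numpy as np
import pytest

from precisionmap import CohortSpec, GrayordinateSpace, generate_cohort
from precisionmap import templates as templates_mod


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_space(rng) -> GrayordinateSpace:
    """120 grayordinates: 50 left cortex, 50 right cortex, 20 subcortex."""
    coords = np.vstack([
        rng.normal(loc=(-40, 0, 0), scale=15, size=(50, 3)),
        rng.normal(loc=(40, 0, 0), scale=15, size=(50, 3)),
        rng.normal(loc=(0, 0, 0), scale=8, size=(20, 3)),
    ])
    structure = np.array(["LEFT_CORTEX"] * 50 + ["RIGHT_CORTEX"] * 50
                         + ["SUBCORTEX"] * 20)
    return GrayordinateSpace(structure=structure, coords=coords)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, quiet cohort (6 participants, 600 grayordinates, SNR 8)."""
    spec = CohortSpec(n_participants=6, n_gray=600, n_networks=8,
                      jitter_sigma_mm=2.0, n_hubs=1, hub_radius_mm=12.0,
                      hub_n_networks=3, snr=8.0, n_frames=300, master_seed=3)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_templates(tiny_cohort):
    stack = np.stack([
        templates_mod.participant_seed_maps(p.timeseries,
                                            tiny_cohort.truth.group_labels)
        for p in tiny_cohort.participants])
    return templates_mod.build_templates(stack, tiny_cohort.spec.palette)
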