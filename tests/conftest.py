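from __future__ import annotations

import numpy as np
import pytest

from gidose.dose import DoseGrid
from gidose.grid import GridGeometry, StructureMask
from gidose.simulate import BaselineGap, CohortConfig, DoseModel, OrganSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(shape=(15, 15, 15), spacing=(1.0, 1.0, 1.0), origin=None) -> GridGeometry:
    if origin is None:
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return GridGeometry(origin=origin, spacing=spacing, shape=shape)


def mask_from_indices(grid: GridGeometry, indices, label="m") -> StructureMask:
    vox = np.zeros(grid.shape, dtype=bool)
    for idx in indices:
        vox[tuple(idx)] = True
    return StructureMask(label, grid, vox)


def random_mask(grid: GridGeometry, rng, p=0.2, label="m") -> StructureMask:
    return StructureMask(label, grid, rng.random(grid.shape) < p)


def ramp_dose(grid: GridGeometry, axis=0, scale=1.0) -> DoseGrid:
    """Dose increasing linearly along one axis (distinct value per slab)."""
    idx = np.indices(grid.shape)[axis].astype(float)
    return DoseGrid(grid, (idx + 1.0) * scale)


def small_cohort_config(n_patients=2, n_fractions=2, seed=11, **kw) -> CohortConfig:
    """Compact cohort (48^3 grid) for fast end-to-end tests; organs are
    placed closer so everything fits on the smaller grid."""
    organs = {
        "gastroduodenum": OrganSpec(
            radius_mm=10.0, length_mm=50.0, axis=2, direction=(1.0, 0.0, 0.0),
            gap=BaselineGap("atom_uniform", p_zero=0.5, hi=5.4),
            motion_mean_mm=0.5, motion_sd_mm=1.7,
        ),
        "small_intestine": OrganSpec(
            radius_mm=8.0, length_mm=50.0, axis=2, direction=(-1.0, 0.0, 0.0),
            gap=BaselineGap("normal", mean=12.0, sd=4.0, lo=3.0, hi=14.0),
            motion_mean_mm=0.0, motion_sd_mm=6.0,
        ),
        "large_intestine": OrganSpec(
            radius_mm=8.0, length_mm=50.0, axis=0, direction=(0.0, 1.0, 0.0),
            gap=BaselineGap("normal", mean=12.0, sd=4.0, lo=3.0, hi=14.0),
            motion_mean_mm=2.0, motion_sd_mm=5.0,
        ),
    }
    defaults = dict(
        n_patients=n_patients, n_fractions=n_fractions,
        shape=(48, 48, 48), spacing_mm=(2.0, 2.0, 2.0),
        gtv_volume_cc_median=5.0, gtv_volume_log_sd=0.3,
        organs=organs, seed=seed,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


def zero_motion_config(**kw) -> CohortConfig:
    """All motion and dose noise switched off; gastroduodenum kept at a
    strictly positive gap so every distance series has a nonzero mean."""
    organs = {
        name: OrganSpec(
            radius_mm=spec.radius_mm, length_mm=spec.length_mm, axis=spec.axis,
            direction=spec.direction,
            gap=BaselineGap("normal", mean=10.0, sd=2.0, lo=4.0, hi=14.0),
            motion_mean_mm=0.0, motion_sd_mm=0.0, motion_perp_sd_mm=0.0,
        )
        for name, spec in small_cohort_config().organs.items()
    }
    return small_cohort_config(
        organs=organs, dose=DoseModel(noise_sd=0.0), **kw
    )
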