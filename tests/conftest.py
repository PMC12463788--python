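"""Shared fixtures: small phantoms, toy systems, and the scaled study run.

Expensive fixtures are session-scoped so the noise-ordering study and the
high-resolution phantom are computed once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

import tcyspect as t
from tcyspect import phantom as ph
from tcyspect.pipeline import ExperimentConfig, run_experiment
from tcyspect.reconstruction import OsemConfig, osem


@pytest.fixture(scope="session")
def spectrum():
    return t.SpectrumModel.from_config()


@pytest.fixture(scope="session")
def collimators():
    return {name: t.CollimatorModel.from_config(name) for name in ("LEHR", "ME", "HE")}


@pytest.fixture(scope="session")
def test_spec():
    """Phantom spec on the coarse evaluation grid (64^3, 9.6 mm)."""
    return ph.PhantomSpec.from_config(grid_shape=64, voxel_mm=9.6)


@pytest.fixture(scope="session")
def test_phantom(test_spec):
    return ph.build_phantom(test_spec)


@pytest.fixture(scope="session")
def fine_phantom():
    """Phantom at the full 4.8 mm pitch, for voxelisation-accuracy checks."""
    spec = ph.PhantomSpec.from_config(grid_shape=128, voxel_mm=4.8)
    return ph.build_phantom(spec)


@pytest.fixture(scope="session")
def toy_recovery():
    """Noise-free two-sphere toy reconstructed with 50 MLEM iterations.

    A warm sphere (1.0) with an offset hot sphere (4.0, T/N = 4) in air,
    imaged with the LEHR collimator on a tight orbit so the geometric
    response is sharp relative to the spheres.
    """
    n = 32
    geom = t.SystemGeometry(n_angles=30, grid_shape=n, voxel_mm=4.8,
                            rotation_radius_mm=120.0)
    sm = t.SpectrumModel.from_config()
    lehr = t.CollimatorModel.from_config("LEHR")
    c = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    warm = (X ** 2 + Y ** 2 + Z ** 2) <= 13 ** 2
    hot = ((X - 5) ** 2 + Y ** 2 + Z ** 2) <= 5 ** 2
    x_true = np.where(warm, 1.0, 0.0)
    x_true[hot] = 4.0
    projector = t.Projector(np.zeros((n, n, n)), lehr, "Tc", "140", sm, geom,
                            include_diffuse=False)
    y = projector.forward(x_true) * 20.0
    recon = osem(y, projector, 20.0, None, OsemConfig(iterations=50, subsets=1))
    return {"x_true": x_true, "warm": warm, "hot": hot, "X": X, "Y": Y, "Z": Z,
            "projector": projector, "y": y, "recon": recon}


#: Conditions of the scaled-down noise-ordering study: coarse grid, 60
#: angles, 10 iterations of 4 subsets, 2 Poisson bases x 5 bootstrap
#: resamples = 10 realizations per cell, ME as the dual-isotope collimator
#: and Tc-only LEHR as the clinical reference.
STUDY_CONFIG = ExperimentConfig(
    grid_preset="test", collimators=["LEHR", "ME"], methods=["none", "mc"],
    ratios=["1:20", "1:60"], include_tc_only=True, dual_collimators=["ME"],
    tc_only_all_collimators=False, n_base=2, n_bootstrap=5, master_seed=2026)


@pytest.fixture(scope="session")
def study(test_phantom):
    """Scaled crosstalk study shared by the ordering and robustness checks."""
    return run_experiment(STUDY_CONFIG, phantom=test_phantom)


def mean_std_n(table, method, collimator, ratio, metric):
    sel = table[(table.method == method) & (table.collimator == collimator)
                & (table.ratio == ratio) & (table.metric == metric)]["value"]
    return float(sel.mean()), float(sel.std(ddof=1)), len(sel)
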