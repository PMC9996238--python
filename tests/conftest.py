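"""Shared fixtures: reduced spine phantoms, slab oracles, toy systems.

The "small" phantom is a compressed two-lead spine segment (4 contacts per
lead) sized so the whole basis-field stack runs in seconds with the direct
solver; steering tests derive floating / one-sided / shifted-target
variants from its cached basis fields.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cordsteer.config import (
    GeometrySection,
    LeadsSection,
    RunConfig,
    TargetSection,
)
from cordsteer.materials import MaterialTable
from cordsteer.phantom import ElectrodeSet, VoxelPhantom
from cordsteer.pipeline import run_pipeline
from cordsteer.solver import assemble_system, conductance_matrix, solve_basis_fields

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

SMALL_SHELLS = [
    ["grey_matter", 1.0],
    ["white_matter", 2.5],
    ["csf", 4.0],
    ["epidural_fat", 6.0],
    ["vertebral_bone", 8.0],
    ["muscle", 10.0],
    ["thorax", 11.5],
    ["fat", 12.5],
    ["skin", 13.5],
]

TINY_SHELLS = [
    ["grey_matter", 0.8],
    ["white_matter", 2.0],
    ["csf", 3.0],
    ["epidural_fat", 5.0],
    ["vertebral_bone", 6.5],
    ["skin", 7.5],
]


def make_small_config(**target_kwargs) -> RunConfig:
    target = dict(center=(0.0, 2.0, 0.0), diameter=1.2)
    target.update(target_kwargs)
    return RunConfig(
        geometry=GeometrySection(
            spacing=(0.5, 0.5, 1.0), shells=SMALL_SHELLS, z_length=24.0
        ),
        leads=LeadsSection(separation=3.0, depth_y=5.0, n_electrodes=4),
        target=TargetSection(**target),
    )


def make_tiny_config(**overrides) -> RunConfig:
    kwargs = dict(
        geometry=GeometrySection(
            spacing=(0.5, 0.5, 1.0), shells=TINY_SHELLS, z_length=16.0
        ),
        leads=LeadsSection(
            separation=2.5, depth_y=4.0, n_electrodes=2, lead_radius=0.5
        ),
        target=TargetSection(center=(0.0, 1.5, 0.0), diameter=1.0),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return make_small_config()


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_pipeline(small_config)


@pytest.fixture(scope="session")
def tiny_config() -> RunConfig:
    return make_tiny_config()


@pytest.fixture(scope="session")
def tiny_result(tiny_config):
    return run_pipeline(tiny_config)


# -- 1-D slab oracle -----------------------------------------------------
def build_slab(
    n_tissue: int,
    sigma1: float,
    sigma2: float,
    interface_frac: float,
    length: float = 1.0,
    ny: int = 3,
    nz: int = 3,
) -> tuple[VoxelPhantom, ElectrodeSet]:
    """Two-layer slab along x with full-face plate electrodes at both ends.

    Tissue spans x in [0, length]; voxels with center x < interface_frac *
    length carry sigma1 (S/m), the rest sigma2. Plate layers are
    near-perfectly conducting contact material.
    """
    hx = length / n_tissue
    nx = n_tissue + 2
    names = ["exterior", "contact", "t1", "t2"]
    mats = MaterialTable({"contact": 4e6, "t1": sigma1, "t2": sigma2})
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    xc = (np.arange(n_tissue) + 0.5) * hx
    labels[1:-1] = np.where(xc < interface_frac * length, 2, 3)[:, None, None]
    labels[0] = 1
    labels[-1] = 1
    ph = VoxelPhantom(
        labels=labels,
        label_names=names,
        spacing=(hx, 0.5, 0.5),
        origin=(-hx, 0.0, 0.0),
        materials=mats,
    )
    shape = ph.shape
    plates = {}
    for name, ix in (("P0", 0), ("P1", nx - 1)):
        ii, jj, kk = np.meshgrid(
            [ix], np.arange(ny), np.arange(nz), indexing="ij"
        )
        plates[name] = np.ravel_multi_index(
            (ii.ravel(), jj.ravel(), kk.ravel()), shape
        )
    electrodes = ElectrodeSet(
        ids=("P0", "P1"),
        voxels=plates,
        centroids={k: ph.voxel_centers(v).mean(axis=0) for k, v in plates.items()},
    )
    return ph, electrodes


def slab_divider_exact(
    sigma1: float, sigma2: float, interface_frac: float, length: float = 1.0
) -> float:
    """Continuum series-resistor interface potential for plates at 1 V / 0 V."""
    c = interface_frac * length
    r1 = c / sigma1
    r2 = (length - c) / sigma2
    return r2 / (r1 + r2)


def slab_series_current(
    sigma1_Sm: float,
    sigma2_Sm: float,
    interface_frac: float,
    length: float,
    area_mm2: float,
) -> float:
    """Series current (A) for a 1 V drive; conductivities in S/m, mm lengths."""
    c = interface_frac * length
    r1 = c / (sigma1_Sm * 1e-3 * area_mm2)
    r2 = (length - c) / (sigma2_Sm * 1e-3 * area_mm2)
    return 1.0 / (r1 + r2)


# -- heterogeneous 3-electrode toy ---------------------------------------
@pytest.fixture(scope="session")
def toy_three():
    """Random heterogeneous 6x5x5 phantom with three point electrodes,
    assembled operator, basis fields and conductance matrix."""
    rng = np.random.default_rng(7)
    names = ["exterior", "t1", "t2", "t3"]
    mats = MaterialTable({"t1": 100.0, "t2": 1000.0, "t3": 5000.0})
    labels = rng.integers(1, 4, size=(6, 5, 5)).astype(np.int16)
    ph = VoxelPhantom(
        labels=labels,
        label_names=names,
        spacing=(1.0, 1.0, 1.0),
        origin=(0.0, 0.0, 0.0),
        materials=mats,
    )
    spots = {"E1": (0, 2, 2), "E2": (5, 2, 2), "E3": (2, 0, 2)}
    voxels = {
        k: np.array([np.ravel_multi_index(v, ph.shape)]) for k, v in spots.items()
    }
    electrodes = ElectrodeSet(
        ids=("E1", "E2", "E3"),
        voxels=voxels,
        centroids={k: ph.voxel_centers(v)[0] for k, v in voxels.items()},
    )
    op = assemble_system(ph, electrodes)
    basis = solve_basis_fields(op)
    Y = conductance_matrix(op, basis)
    return ph, electrodes, op, basis, Y


def uniform_phantom(
    shape=(12, 12, 12), sigma_Sm: float = 1000.0, spacing=(1.0, 1.0, 1.0)
) -> VoxelPhantom:
    names = ["exterior", "tissue"]
    mats = MaterialTable({"tissue": sigma_Sm})
    labels = np.ones(shape, dtype=np.int16)
    return VoxelPhantom(
        labels=labels,
        label_names=names,
        spacing=spacing,
        origin=(0.0, 0.0, 0.0),
        materials=mats,
    )


def point_electrodes(ph: VoxelPhantom, spots: dict[str, tuple]) -> ElectrodeSet:
    voxels = {
        k: np.atleast_1d(np.ravel_multi_index(np.array(v).T, ph.shape)).ravel()
        for k, v in ((k, np.atleast_2d(v)) for k, v in spots.items())
    }
    return ElectrodeSet(
        ids=tuple(spots),
        voxels=voxels,
        centroids={k: ph.voxel_centers(v).mean(axis=0) for k, v in voxels.items()},
    )
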