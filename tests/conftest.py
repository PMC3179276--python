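"""Shared phantom fixtures.

All fixtures are session-scoped: phantom generation and segmentation are
deterministic, so every test sees identical data.
"""

import numpy as np
import pytest

from hrpqct import (
    PhantomSpec,
    PoreModel,
    TrabecularLattice,
    generate_phantom,
    segment_all,
)


@pytest.fixture(scope="session")
def lattice_spec():
    """Study-like distal-radius phantom: 0.9 mm cortex, enclosed pores,
    0.6 mm rod lattice, noiseless."""
    return PhantomSpec(
        n_slices=16,
        outer_radius_mm=4.0,
        cortical_thickness_mm=0.9,
        trabecular_lattice=TrabecularLattice(spacing_mm=0.6, rod_radius_mm=0.10),
        pore_model=PoreModel(n_pores=30, pore_radius_mm=0.12, axial_fraction=0.8),
        seed=3,
    )


@pytest.fixture(scope="session")
def lattice_phantom(lattice_spec):
    return generate_phantom(lattice_spec)


@pytest.fixture(scope="session")
def lattice_masks(lattice_phantom):
    vol, _ = lattice_phantom
    return segment_all(vol)


@pytest.fixture(scope="session")
def annulus_spec():
    """Pure cortical annulus (1 mm): no lattice, no pores, no taper."""
    return PhantomSpec(
        n_slices=12,
        outer_radius_mm=4.0,
        cortical_thickness_mm=1.0,
        taper_per_slice=0.0,
        trabecular_lattice=None,
        pore_model=None,
        seed=7,
    )


@pytest.fixture(scope="session")
def annulus_phantom(annulus_spec):
    return generate_phantom(annulus_spec)


@pytest.fixture(scope="session")
def annulus_masks(annulus_phantom):
    vol, _ = annulus_phantom
    return segment_all(vol)


@pytest.fixture(scope="session")
def pore_annulus_spec():
    """Annulus with 40 axial pores of radius 0.1 mm in a 1 mm cortex."""
    return PhantomSpec(
        n_slices=14,
        outer_radius_mm=4.0,
        cortical_thickness_mm=1.0,
        taper_per_slice=0.0,
        trabecular_lattice=None,
        pore_model=PoreModel(n_pores=40, pore_radius_mm=0.1, axial_fraction=1.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def pore_annulus_phantom(pore_annulus_spec):
    return generate_phantom(pore_annulus_spec)


@pytest.fixture(scope="session")
def fe_phantom():
    """Smaller lattice phantom sized for micro-FE tests."""
    spec = PhantomSpec(
        n_slices=10,
        outer_radius_mm=3.0,
        cortical_thickness_mm=0.8,
        trabecular_lattice=TrabecularLattice(spacing_mm=0.6, rod_radius_mm=0.10),
        pore_model=PoreModel(n_pores=20, pore_radius_mm=0.12, axial_fraction=0.8),
        seed=17,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def fe_masks(fe_phantom):
    vol, _ = fe_phantom
    return segment_all(vol)


@pytest.fixture(scope="session")
def fe_po_result(fe_phantom, fe_masks):
    """Pore-occlusion experiment on the FE phantom, shared across tests."""
    from hrpqct.microfe import pore_occlusion_experiment

    vol, _ = fe_phantom
    return pore_occlusion_experiment(fe_masks, vol.voxel_mm)


def solid_block_masks(n: int):
    """Fully mineralized n^3 block labeled cortical."""
    from hrpqct.segmentation import CompartmentMasks

    bone = np.ones((n, n, n), dtype=bool)
    zeros = np.zeros_like(bone)
    return CompartmentMasks(
        periosteal=bone,
        cortex_auto=bone,
        trabecular_region=zeros,
        trabecular_bone=zeros,
        pores=zeros,
    )


def ring_with_axial_pores(n_slices=20, size=40, r_out=18, r_in=12, n_pores=12,
                          seed=0):
    """Synthetic cortical ring with straight axial through-pores.

    Pores are 3x3 voxel square channels fully enclosed in the ring, so the
    parallel-springs closed form applies exactly.  Returns (masks,
    pore_area_fraction).
    """
    from hrpqct.segmentation import CompartmentMasks

    yy, xx = np.mgrid[:size, :size]
    c = (size - 1) / 2
    rho2 = (yy - c) ** 2 + (xx - c) ** 2
    ring = (rho2 <= r_out**2) & (rho2 >= r_in**2)
    rng = np.random.default_rng(seed)
    pores2d = np.zeros_like(ring)
    placed = 0
    while placed < n_pores:
        y, x = rng.integers(2, size - 2, 2)
        if (r_in + 1.5) ** 2 < (y - c) ** 2 + (x - c) ** 2 < (r_out - 1.5) ** 2:
            pores2d[y - 1 : y + 2, x - 1 : x + 2] = True
            placed += 1
    pores2d &= ring
    ring3 = np.broadcast_to(ring, (n_slices, size, size)).copy()
    pores3 = np.broadcast_to(pores2d, (n_slices, size, size)).copy()
    zeros = np.zeros_like(ring3)
    masks = CompartmentMasks(
        periosteal=ring3,
        cortex_auto=ring3 & ~pores3,
        trabecular_region=zeros,
        trabecular_bone=zeros,
        pores=pores3,
    )
    return masks, pores2d.sum() / ring.sum()
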