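"""Densitometric and direct-3D morphometry against closed forms and
voxel-counted phantom truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrpqct import CalibratedVolume, ChangeSpec, apply_change, compute_morphometry
from hrpqct.morphometry import (
    _intercept_gaps,
    areas,
    bvtv_from_density,
    ct_po,
    ct_th_areal,
    ct_th_direct,
    local_thickness,
    periosteal_perimeter,
    plate_model_derive,
    tb_n_direct,
    vbmd,
)
from hrpqct.phantom import CORTEX, MARROW, TRAB


class TestVbmd:
    def test_uniform_tissue(self):
        vol = CalibratedVolume(np.full((4, 6, 6), 1100.0), voxel_mm=0.082)
        assert vbmd(vol, np.ones((4, 6, 6), bool)) == pytest.approx(1100.0)

    def test_half_and_half(self):
        data = np.zeros((2, 4, 4))
        data[0] = 1100.0
        vol = CalibratedVolume(data, voxel_mm=0.082)
        assert vbmd(vol, np.ones((2, 4, 4), bool)) == pytest.approx(550.0)

    def test_empty_mask_errors(self):
        vol = CalibratedVolume(np.zeros((2, 4, 4)), voxel_mm=0.082)
        with pytest.raises(ValueError):
            vbmd(vol, np.zeros((2, 4, 4), bool))


class TestBvtv:
    @pytest.mark.parametrize("density,expected", [(1200.0, 1.0), (0.0, 0.0),
                                                  (300.0, 0.25)])
    def test_values(self, density, expected):
        assert bvtv_from_density(density) == pytest.approx(expected)

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            bvtv_from_density(-1.0)

    def test_supraphysiologic_clips_with_warning(self):
        with pytest.warns(UserWarning):
            assert bvtv_from_density(1300.0) == 1.0


class TestPlateModel:
    @pytest.mark.parametrize(
        "bvtv,tb_n,tb_th,tb_sp",
        [(0.5, 2.0, 0.25, 0.25), (0.0, 2.0, 0.0, 0.5), (1.0, 2.0, 0.5, 0.0)],
    )
    def test_examples(self, bvtv, tb_n, tb_th, tb_sp):
        th, sp = plate_model_derive(bvtv, tb_n)
        assert th == pytest.approx(tb_th)
        assert sp == pytest.approx(tb_sp)

    def test_zero_tb_n_errors(self):
        with pytest.raises(ValueError):
            plate_model_derive(0.5, 0.0)

    @given(bvtv=st.floats(0, 1), tb_n=st.floats(0.1, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_identities_exact(self, bvtv, tb_n):
        """Tb.Th*Tb.N = BV/TV and Tb.Sp*Tb.N = 1-BV/TV by construction."""
        th, sp = plate_model_derive(bvtv, tb_n)
        assert th * tb_n == pytest.approx(bvtv, abs=1e-12)
        assert sp * tb_n == pytest.approx(1 - bvtv, abs=1e-12)


class TestLocalThickness:
    def test_slab(self):
        m = np.zeros((20, 30, 20), bool)
        m[:, 10:20, :] = True
        lt = local_thickness(m)
        assert lt[m].mean() == pytest.approx(10.0, rel=0.02)

    def test_single_voxel_sheet(self):
        m = np.zeros((10, 10, 10), bool)
        m[:, 5, :] = True
        lt = local_thickness(m)
        assert lt[m].mean() <= 2.0  # a one-voxel sheet is ~1 voxel thick


class TestTbN:
    def test_ideal_plate_midplanes_recover_period(self):
        """Parallel mid-planes with period 10 voxels: the intercept spacing
        measure returns the period with near-zero heterogeneity."""
        n = 64
        skel = np.zeros((40, n, 40), bool)
        for y0 in range(5, n - 1, 10):
            skel[:, y0, :] = True
        region = np.ones_like(skel)
        gaps = _intercept_gaps(skel, region)
        assert gaps.mean() == pytest.approx(10.0, rel=0.05)
        assert gaps.std() < 0.5

    def test_rod_lattice_within_10pct(self, lattice_phantom, lattice_masks):
        vol, truth = lattice_phantom
        m = lattice_masks
        tn, sd = tb_n_direct(m.trabecular_bone, vol.voxel_mm, m.trabecular_region)
        assert abs(tn - truth.true_tb_n) / truth.true_tb_n < 0.10

    def test_regular_lattice_low_heterogeneity(self, lattice_phantom):
        """On the label-image skeleton of a perfectly regular lattice the
        spacing SD is a small fraction of the spacing itself."""
        vol, truth = lattice_phantom
        tb = truth.labels == TRAB
        region = np.isin(truth.labels, [TRAB, MARROW])
        tn, sd = tb_n_direct(tb, vol.voxel_mm, region)
        assert sd < 0.15 * (1.0 / truth.true_tb_n)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            tb_n_direct(np.zeros((4, 4, 4), bool), 0.082)


class TestCorticalThickness:
    def test_areal_closed_form(self):
        # annulus R=10, r=9: (pi(R^2-r^2)) / (2 pi R) = 0.95
        ct_ar = np.pi * (10.0**2 - 9.0**2)
        assert ct_th_areal(ct_ar, 2 * np.pi * 10.0) == pytest.approx(0.95)

    def test_thin_annulus_limit(self):
        R, t = 10.0, 0.05
        ct_ar = np.pi * (R**2 - (R - t) ** 2)
        assert ct_th_areal(ct_ar, 2 * np.pi * R) == pytest.approx(t, rel=0.01)

    def test_zero_perimeter_errors(self):
        with pytest.raises(ValueError):
            ct_th_areal(1.0, 0.0)

    def test_rasterized_annulus_within_5pct(self, annulus_phantom, annulus_masks):
        vol, truth = annulus_phantom
        m = annulus_masks
        ct_ar, _ = areas(m, vol.voxel_mm)
        perim = periosteal_perimeter(m.periosteal, vol.voxel_mm)
        R = truth.spec.outer_radius_mm
        r = R - truth.spec.cortical_thickness_mm
        closed = (R**2 - r**2) / (2 * R)
        assert ct_th_areal(ct_ar, perim) == pytest.approx(closed, rel=0.05)

    def test_direct_thickness_solid_annulus(self, annulus_phantom, annulus_masks):
        vol, truth = annulus_phantom
        m = annulus_masks
        est = ct_th_direct(m.cortex_auto, m.pores, vol.voxel_mm)
        assert abs(est - truth.true_ct_th) <= 2 * vol.voxel_mm

    def test_direct_thickness_ignores_enclosed_pores(
        self, pore_annulus_phantom
    ):
        """Filling the pores leaves Ct.Th* unchanged: the composite of
        cortex and pores is the same annulus."""
        from hrpqct import segment_all

        vol, truth = pore_annulus_phantom
        m = segment_all(vol)
        with_pores = ct_th_direct(m.cortex_auto, m.pores, vol.voxel_mm)
        # pore-free oracle: same phantom geometry without pores
        assert abs(with_pores - truth.true_ct_th) <= 2 * vol.voxel_mm

    def test_single_voxel_sheet(self):
        sheet = np.zeros((6, 8, 8), bool)
        sheet[:, 4, :] = True
        est = ct_th_direct(sheet, None, 1.0)
        assert est <= 2.0


class TestCtPo:
    @pytest.mark.parametrize("pov,bv,expected", [(0.0, 5.0, 0.0), (3.0, 3.0, 50.0)])
    def test_closed_form(self, pov, bv, expected):
        assert ct_po(pov, bv) == pytest.approx(expected)

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            ct_po(0.0, 0.0)

    def test_phantom_within_10pct_relative(self, pore_annulus_phantom):
        from hrpqct import segment_all

        vol, truth = pore_annulus_phantom
        m = segment_all(vol)
        pov = float(m.pores.sum()) * vol.voxel_mm**3
        bv = float(m.cortex_auto.sum()) * vol.voxel_mm**3
        est = ct_po(pov, bv)
        assert abs(est - truth.true_ct_po) / truth.true_ct_po < 0.10

    def test_monotone_under_pore_dilation(self, lattice_phantom):
        from hrpqct import segment_all

        vol, truth = lattice_phantom
        vol2, truth2 = apply_change(
            vol, truth, ChangeSpec(pore_dilation_voxels=1), seed=21
        )
        rec1 = compute_morphometry(vol, segment_all(vol))
        rec2 = compute_morphometry(vol2, segment_all(vol2))
        assert rec2.ct_po > rec1.ct_po


class TestAreas:
    def test_annulus_closed_forms(self, annulus_phantom, annulus_masks):
        vol, truth = annulus_phantom
        ct_ar, tb_ar = areas(annulus_masks, vol.voxel_mm)
        R = truth.spec.outer_radius_mm
        r = R - truth.spec.cortical_thickness_mm
        assert ct_ar == pytest.approx(np.pi * (R**2 - r**2), rel=0.10)
        assert tb_ar == pytest.approx(np.pi * r**2, rel=0.10)

    def test_partition_identity(self, lattice_masks):
        ct_ar, tb_ar = areas(lattice_masks, 0.082)
        peri = lattice_masks.periosteal.sum() * 0.082**2 / lattice_masks.periosteal.shape[0]
        assert ct_ar + tb_ar == pytest.approx(peri, rel=1e-9)


class TestGlobalRecord:
    def test_identities_hold_on_phantom_record(self, lattice_phantom, lattice_masks):
        vol, _ = lattice_phantom
        rec = compute_morphometry(vol, lattice_masks)
        assert rec.tb_th * rec.tb_n == pytest.approx(rec.bvtv, abs=1e-12)
        assert rec.tb_sp * rec.tb_n == pytest.approx(1 - rec.bvtv, abs=1e-12)
        assert rec.ct_po == pytest.approx(
            100 * rec.ct_pov / (rec.ct_pov + rec.ct_bv)
        )

    def test_densitometric_bvtv_below_voxel_counted(
        self, lattice_phantom, lattice_masks
    ):
        """Tissue density (1100) below the compact-bone constant (1200)
        biases densitometric BV/TV below the voxel-counted truth."""
        vol, truth = lattice_phantom
        rec = compute_morphometry(vol, lattice_masks)
        assert rec.bvtv < truth.true_bvtv

    def test_apposition_raises_thickness_and_shrinks_medulla(self, lattice_phantom):
        from hrpqct import segment_all

        vol, truth = lattice_phantom
        k = 2
        vol2, truth2 = apply_change(
            vol, truth, ChangeSpec(endocortical_apposition_voxels=k), seed=31
        )
        rec1 = compute_morphometry(vol, segment_all(vol))
        rec2 = compute_morphometry(vol2, segment_all(vol2))
        dth = rec2.ct_th_star - rec1.ct_th_star
        assert abs(dth - k * vol.voxel_mm) <= 1.5 * vol.voxel_mm
        assert rec2.tb_ar < rec1.tb_ar
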