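"""Domain rasterization and electrode placement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import endostim as es
from endostim import geometry as geo
from endostim import materials as mat

from conftest import COARSE


class TestBuildDomain:
    def test_wall_spans_six_rows_at_default_spacing(self):
        domain = es.build_domain()  # 0.25 mm across the wall
        i = domain.shape[1] // 2
        column = domain.material[:, i]
        upper_wall_rows = np.sum(
            (column == mat.WALL) & (domain.y.centers > 0))
        assert upper_wall_rows == 6

    def test_lumen_cross_section_height_is_12mm(self):
        domain = es.build_domain()
        i = domain.shape[1] // 2
        blood_rows = np.sum(domain.material[:, i] == mat.BLOOD)
        assert blood_rows * 0.25e-3 == pytest.approx(0.012)

    @pytest.mark.parametrize("spacing", [0.5e-3, 0.25e-3])
    def test_area_bookkeeping_matches_analytic_rectangles(self, spacing):
        domain = es.build_domain(spacing=spacing, axial_spacing=2 * spacing)
        p = domain.params
        lumen_area = p.vessel_length * p.lumen_diameter
        wall_area = 2 * p.vessel_length * p.wall_thickness
        total = p.muscle_width * p.muscle_height
        # interfaces are face-aligned, so blood/wall areas are exact; allow
        # one cell-row of the vessel-end interface as slack
        slack = 2 * spacing * p.vessel_length
        assert domain.label_area(mat.BLOOD) == pytest.approx(lumen_area,
                                                             abs=slack)
        assert domain.label_area(mat.WALL) == pytest.approx(wall_area,
                                                            abs=slack)
        assert (domain.label_area(mat.BLOOD) + domain.label_area(mat.WALL)
                + domain.label_area(mat.MUSCLE)) == pytest.approx(total,
                                                                  rel=1e-12)

    def test_every_cell_has_one_label(self):
        domain = es.build_domain(**COARSE)
        assert set(np.unique(domain.material)) <= {mat.BLOOD, mat.WALL,
                                                   mat.MUSCLE}

    def test_too_coarse_spacing_rejected(self):
        with pytest.raises(es.ResolutionError):
            es.build_domain(spacing=0.6e-3)

    def test_non_dividing_spacing_rejected(self):
        with pytest.raises(es.ResolutionError):
            es.build_domain(spacing=0.4e-3)

    def test_vessel_must_fit_in_muscle_box(self):
        params = es.GeometryParams(muscle_height=0.010)
        with pytest.raises(es.GeometryError):
            es.build_domain(params)


class TestElectrodePlacement:
    def test_four_electrode_group_spans_39mm_alternating(self):
        config = es.ElectrodeConfiguration(1, 4, 13e-3)
        electrodes = config.endovascular_electrodes()
        centers = [x for x, _ in electrodes]
        assert max(centers) - min(centers) == pytest.approx(0.039)
        assert [v for _, v in electrodes] == [40.0, 0.0, 40.0, 0.0]

    def test_three_electrodes_center_active(self):
        config = es.ElectrodeConfiguration(1, 3, 17e-3)
        assert [v for _, v in config.endovascular_electrodes()] == \
            [0.0, 40.0, 0.0]

    def test_zero_distance_is_overlap_error(self):
        with pytest.raises(es.ConfigurationError):
            es.ElectrodeConfiguration(1, 2, 0.0)

    def test_scheme3_remote_return_geometry(self):
        config = es.ElectrodeConfiguration(3, 1)
        domain = es.domain_for(config, **COARSE)
        pot = domain.electrode_potential
        grounded = np.isfinite(pot) & (pot == 0.0)
        ys = np.meshgrid(domain.x.centers, domain.y.centers)[1][grounded]
        # plate sits 40 cm above the outer wall
        assert ys.min() > 0.4
        actives = np.isfinite(pot) & (pot == 40.0)
        ya = np.meshgrid(domain.x.centers, domain.y.centers)[1][actives]
        assert np.all(np.abs(ya) < domain.params.lumen_radius)

    def test_scheme2_returns_flank_the_vessel(self):
        config = es.ElectrodeConfiguration(2, 2, 20e-3)
        domain = es.domain_for(config, **COARSE)
        pot = domain.electrode_potential
        yc = np.meshgrid(domain.x.centers, domain.y.centers)[1]
        grounded_y = yc[np.isfinite(pot) & (pot == 0.0)]
        outer = domain.params.outer_wall
        assert grounded_y.max() > outer and grounded_y.min() < -outer

    def test_band_pair_symmetric_about_centerline(self):
        config = es.ElectrodeConfiguration(1, 2, 19e-3)
        domain = es.domain_for(config, **COARSE)
        mask = domain.electrode_mask
        assert np.array_equal(mask, mask[::-1, :])

    def test_centerline_option_places_single_squares(self):
        config = es.ElectrodeConfiguration(1, 2, 19e-3, catheter_diameter=0.0)
        domain = es.domain_for(config, **COARSE)
        yc = np.meshgrid(domain.x.centers, domain.y.centers)[1]
        assert np.all(np.abs(yc[domain.electrode_mask]) < 0.6e-3)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(n=st.integers(2, 4), d_mm=st.integers(2, 20))
    def test_group_symmetric_about_axial_midpoint(self, n, d_mm):
        config = es.ElectrodeConfiguration(1, n, d_mm * 1e-3)
        base = es.build_domain(**COARSE)
        domain = es.place_electrodes(base, config)
        mask = domain.electrode_mask
        assert np.array_equal(mask, mask[:, ::-1])
        if n % 2 == 0:
            pot = domain.electrode_potential
            active = np.sum(np.isfinite(pot) & (pot > 0))
            ret = np.sum(np.isfinite(pot) & (pot == 0))
            assert active == ret

    def test_refinement_preserves_material_areas(self):
        # both resolutions stay within one boundary cell of the analytic
        # rectangle areas; the vessel ends fall in the graded far region,
        # so the slack is the widest axial cell there times the strip height
        p = es.GeometryParams()
        for spacing in (0.5e-3, 0.25e-3):
            domain = es.build_domain(spacing=spacing,
                                     axial_spacing=2 * spacing)
            slack_x = 2 * domain.x.widths.max()
            assert domain.label_area(mat.BLOOD) == pytest.approx(
                p.vessel_length * p.lumen_diameter,
                abs=slack_x * p.lumen_diameter)
            assert domain.label_area(mat.WALL) == pytest.approx(
                2 * p.vessel_length * p.wall_thickness,
                abs=slack_x * 2 * p.wall_thickness)


class TestCrop:
    def test_crop_preserves_material_and_faces(self):
        domain = es.build_domain(**COARSE)
        cropped, (rows, cols) = geo.crop_domain(domain, -0.02, 0.02,
                                                -0.01, 0.01)
        assert np.array_equal(cropped.material, domain.material[rows, cols])
        assert cropped.x.faces[0] <= -0.02 and cropped.x.faces[-1] >= 0.02

    def test_empty_crop_rejected(self):
        domain = es.build_domain(**COARSE)
        with pytest.raises(es.GeometryError):
            geo.crop_domain(domain, 5.0, 6.0, 5.0, 6.0)
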