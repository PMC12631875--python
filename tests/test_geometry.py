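"""Phantom discretization: labeled volumes, grading, refinement, symmetry."""

import math

import numpy as np
import pytest

from thermoseed.geometry import (
    GeometryError,
    PhantomSpec,
    REGION_AIR,
    REGION_SEED,
    REGION_TUMOR,
    SeedPlacement,
    build_liver_phantom,
    build_subcutaneous_phantom,
    graded_axis,
    refine_grid,
)


@pytest.fixture(scope="module")
def liver_spec(seed_spec):
    return PhantomSpec(kind="liver_sphere", seeds=(SeedPlacement(),),
                       seed_spec=seed_spec)


@pytest.fixture(scope="module")
def subq_spec(seed_spec):
    return PhantomSpec(
        kind="subcutaneous_ellipsoid",
        seeds=(SeedPlacement(center=(0, 0, 1.2e-3), axis=(1, 0, 0)),),
        seed_spec=seed_spec,
    )


class TestGradedAxis:
    def test_nodes_cover_domain_and_increase(self):
        ax = graded_axis(0.0, 25e-3, [(0.0, 1e-3)], 5e-5, 2e-3)
        assert ax[0] == 0.0 and ax[-1] == pytest.approx(25e-3)
        assert np.all(np.diff(ax) > 0)

    def test_fine_region_resolution(self):
        ax = graded_axis(-10e-3, 10e-3, [(-1e-3, 1e-3)], 1e-4, 2e-3)
        inside = np.diff(ax)[(ax[:-1] >= -1e-3) & (ax[1:] <= 1e-3)]
        assert inside.max() <= 1.05e-4

    def test_growth_ratio_bounded(self):
        ax = graded_axis(0.0, 25e-3, [(0.0, 1e-3)], 5e-5, 2e-3, ratio=1.3)
        h = np.diff(ax)
        ratios = h[1:] / h[:-1]
        assert ratios.max() <= 1.5  # rescaling can stretch slightly past 1.3


class TestLiverPhantom:
    def test_tumor_volume_close_to_analytic(self, liver_spec):
        grid = build_liver_phantom(liver_spec, target_resolution=1e-4,
                                   mode="axisymmetric", h_max=8e-4)
        analytic = 4.0 / 3.0 * math.pi * 15.0**3  # mm^3
        vol = grid.labeled_volume(REGION_TUMOR) * 1e9
        seed_vol = grid.labeled_volume(REGION_SEED) * 1e9
        assert (vol + seed_vol) == pytest.approx(analytic, rel=0.02)

    def test_seed_volume_close_to_analytic(self, liver_spec):
        grid = build_liver_phantom(liver_spec, target_resolution=5e-5,
                                   mode="axisymmetric")
        analytic = math.pi * 0.4**2 * 4.5  # mm^3
        assert grid.labeled_volume(REGION_SEED) * 1e9 == pytest.approx(
            analytic, rel=0.10
        )

    def test_zero_seed_grid_valid(self, seed_spec):
        spec = PhantomSpec(kind="liver_sphere", seeds=(), seed_spec=seed_spec)
        grid = build_liver_phantom(spec, target_resolution=2e-4, mode="full")
        assert not np.any(grid.cell_region == REGION_SEED)

    def test_overlapping_seeds_rejected(self, seed_spec):
        with pytest.raises(GeometryError):
            PhantomSpec(
                kind="liver_sphere",
                seeds=(SeedPlacement(center=(0, 0, 0)),
                       SeedPlacement(center=(0.5e-3, 0, 0))),
                seed_spec=seed_spec,
            )

    def test_seed_outside_tumor_rejected(self, seed_spec):
        with pytest.raises(GeometryError):
            PhantomSpec(
                kind="liver_sphere",
                seeds=(SeedPlacement(center=(14.9e-3, 0, 0)),),
                seed_spec=seed_spec,
            )

    def test_octant_volume_multiplicity(self, seed_spec):
        spec = PhantomSpec(
            kind="liver_sphere",
            seeds=(SeedPlacement(center=(1.5e-3, 0, 0)),
                   SeedPlacement(center=(-1.5e-3, 0, 0))),
            seed_spec=seed_spec,
        )
        grid = build_liver_phantom(spec, target_resolution=2e-4, mode="octant")
        analytic = 2 * math.pi * 0.4**2 * 4.5
        assert grid.symmetry_factor == 8.0
        assert grid.labeled_volume(REGION_SEED) * 1e9 == pytest.approx(
            analytic, rel=0.15
        )


class TestSubcutaneousPhantom:
    def test_tumor_volume_close_to_analytic(self, subq_spec):
        grid = build_subcutaneous_phantom(subq_spec, target_resolution=1e-4)
        analytic = 4.0 / 3.0 * math.pi * 5.0 * 3.5 * 2.0  # mm^3
        vol = (grid.labeled_volume(REGION_TUMOR)
               + grid.labeled_volume(REGION_SEED)) * 1e9
        assert vol == pytest.approx(analytic, rel=0.02)

    def test_embed_depth_one_fifth_minor_axis(self, subq_spec):
        grid = build_subcutaneous_phantom(subq_spec, target_resolution=2e-4)
        assert grid.meta["embed_depth_m"] == pytest.approx(0.8e-3)

    def test_air_above_surface(self, subq_spec):
        grid = build_subcutaneous_phantom(subq_spec, target_resolution=2e-4)
        zc = grid.centers()[2]
        air_share_top = (grid.cell_region[:, :, zc > 3.5e-3] == REGION_AIR).mean()
        assert air_share_top == 1.0

    def test_zero_embed_fraction_rejected(self, seed_spec):
        with pytest.raises(GeometryError):
            PhantomSpec(kind="subcutaneous_ellipsoid", embed_fraction=0.0,
                        seed_spec=seed_spec)


class TestRefinement:
    def test_cell_count_grows_by_factor_cubed(self, liver_spec):
        grid = build_liver_phantom(liver_spec, target_resolution=2e-4,
                                   mode="axisymmetric")
        fine = refine_grid(grid, 2)
        assert fine.n_cells == pytest.approx(4 * grid.n_cells, rel=0.05)

    def test_refined_volume_error_shrinks(self, liver_spec):
        """Labeled seed volume converges to the analytic cylinder volume;
        a single refinement step can wobble (staircase labeling), so the
        check compares a 4x refinement against the base grid."""
        grid = build_liver_phantom(liver_spec, target_resolution=2e-4,
                                   mode="axisymmetric")
        fine = refine_grid(grid, 4)
        analytic = math.pi * (0.4e-3) ** 2 * 4.5e-3
        err = abs(grid.labeled_volume(REGION_SEED) - analytic)
        err_fine = abs(fine.labeled_volume(REGION_SEED) - analytic)
        assert err_fine < err

    def test_labels_match_direct_build(self, liver_spec):
        grid = build_liver_phantom(liver_spec, target_resolution=2e-4,
                                   mode="axisymmetric")
        fine = refine_grid(grid, 2)
        rebuilt = fine.region_fn(
            *np.meshgrid(*fine.centers(), indexing="ij")
        )
        assert np.array_equal(fine.cell_region, rebuilt)

    def test_factor_one_rejected(self, liver_spec):
        grid = build_liver_phantom(liver_spec, target_resolution=2e-4,
                                   mode="axisymmetric")
        with pytest.raises(ValueError):
            refine_grid(grid, 1.0)


class TestSeedPlacement:
    def test_non_unit_axis_rejected(self):
        with pytest.raises(GeometryError):
            SeedPlacement(axis=(0.0, 0.0, 2.0))
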