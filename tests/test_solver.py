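"""Finite-volume Pennes solver: oracles, invariants, transient behavior."""

import math
from dataclasses import replace

import numpy as np
import pytest

from thermoseed.geometry import refine_grid
from thermoseed.materials import MaterialProps
from thermoseed.scenarios import (
    conduction_benchmark,
    conduction_benchmark_analytic,
    single_seed_liver,
    two_seed_liver,
)
from thermoseed.solver import (
    BioheatProblem,
    SolverError,
    energy_balance,
    solve_steady,
    solve_transient,
)


def _benchmark_error(problem, fld):
    rc, zc = problem.grid.centers()
    R, Z = np.meshgrid(rc, zc, indexing="ij")
    exact = conduction_benchmark_analytic(np.hypot(R, Z))
    interior = problem.grid.cell_region <= 2
    dT = exact.max() - 37.0
    return np.abs(fld.values - exact)[interior].max() / dT


class TestConductionOracle:
    def test_matches_closed_form_within_1pct(self, benchmark_problem,
                                             benchmark_field):
        """Heated sphere in a conducting medium vs the exact 1/r solution."""
        assert _benchmark_error(benchmark_problem, benchmark_field) < 0.01

    def test_richardson_convergence_order_about_two(self):
        """Peak-temperature self-convergence over three refinements."""
        base = conduction_benchmark(resolution=2e-4)
        grids = [base.grid]
        for _ in range(2):
            grids.append(refine_grid(grids[-1], 2))
        tmax = []
        for g in grids:
            fld = solve_steady(replace(base, grid=g))
            tmax.append(fld.values.max())
        exact = conduction_benchmark_analytic(0.0)
        errs = [abs(t - exact) for t in tmax]
        order = math.log2(errs[0] / errs[1]), math.log2(errs[1] / errs[2])
        assert min(order) > 1.2
        assert 1.5 < np.mean(order) < 3.0


class TestSteadyInvariants:
    def test_zero_sources_uniform_37(self, registry):
        """No seeds, no metabolism, no perfusion, boundary at 37 -> flat 37."""
        inert = MaterialProps(name="inert", density=1060, heat_capacity=3540,
                              conductivity=0.52)
        prob = single_seed_liver(resolution=2e-4)
        prob = replace(
            prob,
            region_materials={"seed": inert, "tumor": inert, "host": inert},
            slp=replace_slp_zero(),
        )
        fld = solve_steady(prob)
        assert np.allclose(fld.values, 37.0, atol=1e-9)

    def test_maximum_principle_without_sources(self, registry):
        inert = MaterialProps(name="inert", density=1000, heat_capacity=3600,
                              conductivity=0.52)
        prob = conduction_benchmark(resolution=1e-4)
        prob = replace(
            prob,
            region_materials={"seed": inert, "host": inert},
            slp=replace_slp_zero(),
        )
        fld = solve_steady(prob)
        assert fld.values.min() >= 37.0 - 1e-9
        assert fld.values.max() <= 37.0 + 1e-9

    def test_energy_balance_below_half_percent(self, single_seed_problem,
                                               single_seed_field):
        eb = energy_balance(single_seed_problem, single_seed_field)
        assert eb["relative_residual"] < 0.005
        assert eb["seed_power_W"] > 0
        assert eb["perfusion_W"] < 0  # net sink for heated tissue

    def test_unique_solution_from_different_starts(self, single_seed_problem):
        """Picard iteration on the self-regulating source is a contraction:
        cold and hot initial fields converge to the same steady state."""
        cold = solve_steady(single_seed_problem)
        hot = solve_steady(
            replace(single_seed_problem, initial_temperature=50.0)
        )
        assert np.max(np.abs(cold.values - hot.values)) < 1e-3

    def test_semi_implicit_source_agrees_with_picard(self, single_seed_problem,
                                                     single_seed_field):
        newton = solve_steady(single_seed_problem, semi_implicit_source=True)
        assert np.max(np.abs(newton.values - single_seed_field.values)) < 1e-3

    def test_missing_boundary_rejected(self, registry, seed_spec):
        grid = grideless_interior_grid(seed_spec)
        with pytest.raises(SolverError):
            BioheatProblem(
                grid=grid,
                region_materials={"tumor": registry["materials"]["tumor"],
                                  "host": registry["materials"]["liver"]},
            )


class TestTwoSeedSymmetry:
    def test_mirror_symmetry_of_full_domain_solution(self):
        """Two parallel seeds solved on the full domain: the field is
        mirror-symmetric about the mid-plane."""
        prob = two_seed_liver(3.0, resolution=3e-4, mode="full")
        fld = solve_steady(prob)
        flipped = fld.values[::-1, :, :]
        xc = prob.grid.centers()[0]
        sym = np.allclose(xc, -xc[::-1], atol=1e-12)
        assert sym
        assert np.max(np.abs(fld.values - flipped)) < 1e-3


class TestTransient:
    def test_initial_snapshot_uniform_37(self, single_seed_problem):
        res = solve_transient(single_seed_problem, t_end=10.0, dt=5.0,
                              output_times=[0.0, 10.0])
        assert np.allclose(res.fields[0].values, 37.0)

    def test_long_transient_approaches_steady(self, single_seed_problem,
                                              single_seed_field):
        res = solve_transient(single_seed_problem, t_end=1800.0, dt=5.0)
        diff = np.max(np.abs(res.final.values - single_seed_field.values))
        assert diff < 0.05

    def test_equilibration_time_five_to_fifteen_minutes(self, single_seed_problem,
                                                        single_seed_field):
        """The single-seed phantom reaches its steady field (within 0.1 degC)
        on the ~10 minute timescale."""
        res = solve_transient(single_seed_problem, t_end=1500.0, dt=5.0,
                              reference=single_seed_field, reference_tol=0.1)
        assert res.reference_convergence_time is not None
        assert 300.0 <= res.reference_convergence_time <= 900.0

    def test_invalid_dt_rejected(self, single_seed_problem):
        with pytest.raises(ValueError):
            solve_transient(single_seed_problem, t_end=1.0, dt=0.0)


# -- helpers ---------------------------------------------------------------

def replace_slp_zero():
    from thermoseed.slp import SLPGaussianParams

    return SLPGaussianParams(a=0.0, b=37.0, c=1.0, d=0.0)


def grideless_interior_grid(seed_spec):
    """A grid whose cells are all interior (no boundary): ill-posed."""
    import numpy as np

    from thermoseed.geometry import LabeledGrid, REGION_TUMOR

    ax = np.linspace(0.0, 1e-2, 6)
    shape = (5, 5, 5)
    return LabeledGrid(
        kind="cartesian",
        axes=(ax, ax, ax),
        cell_region=np.full(shape, REGION_TUMOR, dtype=np.int8),
    )
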