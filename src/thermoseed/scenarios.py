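"""Ready-made planning scenarios.

Each constructor assembles a :class:`~thermoseed.solver.BioheatProblem` from
the built-in material registry, the standard composite seed (0.8 mm diameter,
4.5 mm length, effective-medium properties) and the published self-regulating
SLP(T) constants:

* ``single_seed_liver`` — one seed centered in a 15 mm spherical tumor inside
  25 mm of liver, outer surface at 37 degC (axisymmetric fast path);
* ``two_seed_liver`` — two parallel seeds separated transversely by D;
* ``four_seed_liver`` — a 2x2 array of parallel seeds with spacing D along
  both transverse directions;
* ``subcutaneous_mouse`` — one seed in an ellipsoidal tumor partially embedded
  in muscle, the exposed surface cooled by natural air convection.

Multi-seed scenarios use mirror-symmetric octant domains.  Also provided is a
conduction-only benchmark with a closed-form solution, used for solver
verification.
"""

from __future__ import annotations

import numpy as np

from .geometry import (
    LabeledGrid,
    PhantomSpec,
    REGION_EXTERIOR,
    REGION_HOST,
    REGION_SEED,
    SeedPlacement,
    build_liver_phantom,
    build_subcutaneous_phantom,
)
from .materials import MaterialProps, default_registry, default_seed_spec
from .optimize import SpacingScenario
from .slp import DEFAULT_SLP_PARAMS, SLPGaussianParams
from .solver import BioheatProblem

__all__ = [
    "single_seed_liver",
    "two_seed_liver",
    "four_seed_liver",
    "subcutaneous_mouse",
    "two_seed_scenario",
    "four_seed_scenario",
    "conduction_benchmark",
    "conduction_benchmark_analytic",
    "SCENARIO_BUILDERS",
]


def _liver_problem(
    seeds: tuple[SeedPlacement, ...],
    resolution: float,
    mode: str,
    slp: SLPGaussianParams,
    registry: dict | None,
) -> BioheatProblem:
    reg = registry or default_registry()
    seed_spec = default_seed_spec(reg)
    spec = PhantomSpec(kind="liver_sphere", seeds=seeds, seed_spec=seed_spec)
    grid = build_liver_phantom(spec, target_resolution=resolution, mode=mode)
    return BioheatProblem(
        grid=grid,
        region_materials={
            "seed": seed_spec.effective,
            "tumor": reg["materials"]["tumor"],
            "host": reg["materials"]["liver"],
        },
        blood=reg["blood"],
        slp=slp,
    )


def single_seed_liver(
    resolution: float = 5e-5,
    mode: str = "axisymmetric",
    slp: SLPGaussianParams = DEFAULT_SLP_PARAMS,
    registry: dict | None = None,
) -> BioheatProblem:
    """One composite seed at the center of the deep-seated liver phantom."""
    return _liver_problem((SeedPlacement(),), resolution, mode, slp, registry)


def two_seed_liver(
    d_mm: float,
    resolution: float = 1.25e-4,
    mode: str = "octant",
    slp: SLPGaussianParams = DEFAULT_SLP_PARAMS,
    registry: dict | None = None,
) -> BioheatProblem:
    """Two parallel seeds at transverse distance ``d_mm`` (centers, mm)."""
    h = 0.5 * d_mm * 1e-3
    seeds = (
        SeedPlacement(center=(+h, 0.0, 0.0)),
        SeedPlacement(center=(-h, 0.0, 0.0)),
    )
    return _liver_problem(seeds, resolution, mode, slp, registry)


def four_seed_liver(
    d_mm: float,
    resolution: float = 1.25e-4,
    mode: str = "octant",
    arrangement: str = "cross",
    slp: SLPGaussianParams = DEFAULT_SLP_PARAMS,
    registry: dict | None = None,
) -> BioheatProblem:
    """Four parallel seeds with spacing ``d_mm``.

    ``arrangement="cross"`` (default) places one opposite pair in each of the
    two central planes containing the seed axis — seeds at (+-D/2, 0) and
    (0, +-D/2) — so D is the distance between the two seeds seen in each
    plane.  ``arrangement="square"`` places a 2x2 array at (+-D/2, +-D/2)
    with edge spacing D.
    """
    h = 0.5 * d_mm * 1e-3
    if arrangement == "cross":
        seeds = (
            SeedPlacement(center=(+h, 0.0, 0.0)),
            SeedPlacement(center=(-h, 0.0, 0.0)),
            SeedPlacement(center=(0.0, +h, 0.0)),
            SeedPlacement(center=(0.0, -h, 0.0)),
        )
    elif arrangement == "square":
        seeds = tuple(
            SeedPlacement(center=(sx * h, sy * h, 0.0))
            for sx in (+1, -1)
            for sy in (+1, -1)
        )
    else:
        raise ValueError("arrangement must be 'cross' or 'square'")
    return _liver_problem(seeds, resolution, mode, slp, registry)


def subcutaneous_mouse(
    resolution: float = 1.5e-4,
    convection_coefficient: float = 5.0,
    ambient_temperature: float = 25.0,
    slp: SLPGaussianParams = DEFAULT_SLP_PARAMS,
    registry: dict | None = None,
) -> BioheatProblem:
    """One seed in the ellipsoidal subcutaneous tumor, exposed to ambient air.

    The tumor (semi-axes 5 x 3.5 x 2 mm) is embedded 1/5 of its minor axis
    into muscle; the seed lies at the tumor center along the major (x) axis.
    The convection pair (h, T_ambient) defaults to free convection in still
    air; both are configurable.
    """
    reg = registry or default_registry()
    seed_spec = default_seed_spec(reg)
    spec = PhantomSpec(
        kind="subcutaneous_ellipsoid",
        seeds=(SeedPlacement(center=(0.0, 0.0, 1.2e-3), axis=(1.0, 0.0, 0.0)),),
        seed_spec=seed_spec,
        convection_coefficient=convection_coefficient,
        ambient_temperature=ambient_temperature,
    )
    grid = build_subcutaneous_phantom(spec, target_resolution=resolution)
    return BioheatProblem(
        grid=grid,
        region_materials={
            "seed": seed_spec.effective,
            "tumor": reg["materials"]["tumor"],
            "host": reg["materials"]["muscle"],
        },
        blood=reg["blood"],
        slp=slp,
        convection_coefficient=convection_coefficient,
        ambient_temperature=ambient_temperature,
    )


def two_seed_scenario(
    resolution: float = 1.25e-4, solver_kwargs: dict | None = None
) -> SpacingScenario:
    """Parametric two-seed scenario for sweeps/optimization."""
    return SpacingScenario(
        problem_factory=lambda d: two_seed_liver(d, resolution=resolution),
        name="two_seed_liver",
        solver_kwargs=solver_kwargs or {},
    )


def four_seed_scenario(
    resolution: float = 1.25e-4, solver_kwargs: dict | None = None
) -> SpacingScenario:
    """Parametric four-seed (cross) scenario for sweeps/optimization."""
    return SpacingScenario(
        problem_factory=lambda d: four_seed_liver(d, resolution=resolution),
        name="four_seed_liver",
        solver_kwargs=solver_kwargs or {},
    )


# ---------------------------------------------------------------------------
# conduction verification benchmark

def conduction_benchmark(
    resolution: float = 5e-5,
    source_radius: float = 1e-3,
    outer_radius: float = 25e-3,
    power_density: float = 1e7,
    conductivity: float = 0.52,
) -> BioheatProblem:
    """Uniformly heated sphere in a homogeneous conducting medium.

    Perfusion and metabolism are off, the source is temperature-independent
    (a flat SLP curve), and the outer spherical boundary is held at 37 degC —
    the configuration with the closed-form solution
    :func:`conduction_benchmark_analytic`.
    """
    from .geometry import graded_axis

    medium = MaterialProps(
        name="medium", density=1000.0, heat_capacity=3600.0,
        conductivity=conductivity,
    )
    source = MaterialProps(
        name="source", density=1000.0, heat_capacity=3600.0,
        conductivity=conductivity,
    )
    # P = SLP * rho(g/m^3): a flat curve with d = P0 / (rho * 1e3)
    slp = SLPGaussianParams(a=0.0, b=37.0, c=1.0, d=power_density / (1000.0 * 1e3))

    r_ax = graded_axis(0.0, outer_radius, [(0.0, source_radius + 3e-4)],
                       resolution, 2e-3)
    z_ax = graded_axis(0.0, outer_radius, [(0.0, source_radius + 3e-4)],
                       resolution, 2e-3)

    def fn(r, z):
        rad = np.sqrt(r * r + z * z)
        out = np.full(r.shape, REGION_HOST, dtype=np.int8)
        out[rad > outer_radius] = REGION_EXTERIOR
        out[rad <= source_radius] = REGION_SEED
        return out

    grid = LabeledGrid(
        kind="axisymmetric",
        axes=(r_ax, z_ax),
        cell_region=fn(*np.meshgrid(*[0.5 * (a[:-1] + a[1:]) for a in (r_ax, z_ax)],
                                    indexing="ij")).astype(np.int8),
        symmetry_factor=2.0,
        mirror_axes=(1,),
        region_fn=fn,
        meta={"phantom": "conduction_benchmark"},
    )
    grid.rebuild = lambda res: conduction_benchmark(
        res, source_radius, outer_radius, power_density, conductivity
    ).grid
    return BioheatProblem(
        grid=grid,
        region_materials={"seed": source, "host": medium},
        slp=slp,
    )


def conduction_benchmark_analytic(
    r,
    source_radius: float = 1e-3,
    outer_radius: float = 25e-3,
    power_density: float = 1e7,
    conductivity: float = 0.52,
    boundary_temperature: float = 37.0,
):
    """Closed-form steady temperature of the heated-sphere benchmark, degC.

    Outside the source sphere ``T = Tb + (P0 R0^3 / 3k)(1/r - 1/R_out)``;
    inside, the matching parabola
    ``T = T(R0) + (P0 / 6k)(R0^2 - r^2)``.
    """
    r = np.asarray(r, dtype=float)
    P0, R0, Rb, k = power_density, source_radius, outer_radius, conductivity
    outside = boundary_temperature + (P0 * R0**3 / (3.0 * k)) * (
        1.0 / np.maximum(r, R0) - 1.0 / Rb
    )
    t_surface = boundary_temperature + (P0 * R0**3 / (3.0 * k)) * (1.0 / R0 - 1.0 / Rb)
    inside = t_surface + (P0 / (6.0 * k)) * (R0**2 - np.minimum(r, R0) ** 2)
    return np.where(r <= R0, inside, outside)[()]


#: name -> builder, for the CLI and config files
SCENARIO_BUILDERS = {
    "single_seed_liver": single_seed_liver,
    "two_seed_liver": two_seed_liver,
    "four_seed_liver": four_seed_liver,
    "subcutaneous_mouse": subcutaneous_mouse,
}
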