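"""Inter-seed spacing sweeps and constrained spacing optimization.

For a parametric seed array (two parallel seeds, or a 2x2 array, spacing D in
mm) the planner maximizes the effective therapeutic volume Ve(D) subject to
zero overheating volume, Vo(D) = 0.  Physically: shrinking D merges the
heated zones and grows Ve until the inter-seed region exceeds 42 degC, so the
optimum sits at (or just above) the feasibility boundary.

The search is a coarse scan followed by bisection onto the Vo = 0 boundary
and, when the best feasible scan point is interior, golden-section refinement
of Ve among feasible spacings.  "Vo = 0" is enforced as Vo below half of one
near-seed cell volume, absorbing discretization noise in the cell-sum volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

from .geometry import REGION_SEED
from .metrics import TherapyMetrics, compute_metrics
from .solver import BioheatProblem, solve_steady

__all__ = [
    "SpacingScenario",
    "SpacingResult",
    "OptimizationResult",
    "InfeasibleError",
    "sweep_spacing",
    "optimize_spacing",
]


class InfeasibleError(RuntimeError):
    """No spacing in the search bounds satisfies the zero-overheating constraint."""


@dataclass
class SpacingScenario:
    """A parametric seed-array scenario: D (mm) -> bioheat problem."""

    problem_factory: Callable[[float], BioheatProblem]
    name: str = "spacing_scenario"
    solver_kwargs: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SpacingResult:
    """Steady-state metrics at one spacing."""

    d_mm: float
    metrics: TherapyMetrics
    feasible: bool
    vo_threshold_mm3: float


def _evaluate(scenario: SpacingScenario, d_mm: float) -> SpacingResult:
    problem = scenario.problem_factory(d_mm)
    fld = solve_steady(problem, **scenario.solver_kwargs)
    m = compute_metrics(fld, problem.grid)
    grid = problem.grid
    vols = grid.cell_volumes()
    near_seed = vols[grid.cell_region == REGION_SEED]
    cell_mm3 = float(near_seed.min() if near_seed.size else vols.min())
    threshold = 0.5 * cell_mm3 * 1e9 * grid.symmetry_factor
    return SpacingResult(
        d_mm=float(d_mm),
        metrics=m,
        feasible=m.vo_mm3 < threshold,
        vo_threshold_mm3=threshold,
    )


def sweep_spacing(
    scenario: SpacingScenario, d_values_mm: Sequence[float]
) -> list[SpacingResult]:
    """One steady solve + metrics per spacing; deterministic."""
    d_values_mm = list(d_values_mm)
    if any(d <= 0 for d in d_values_mm):
        raise ValueError("spacings must be positive")
    if sorted(d_values_mm) != d_values_mm:
        raise ValueError("spacings must be sorted ascending")
    return [_evaluate(scenario, d) for d in d_values_mm]


def results_table(results: Sequence[SpacingResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "D_mm": [r.d_mm for r in results],
            "Ve_mm3": [r.metrics.ve_mm3 for r in results],
            "Vo_mm3": [r.metrics.vo_mm3 for r in results],
            "Tmax_C": [r.metrics.tmax_seed for r in results],
            "feasible": [r.feasible for r in results],
        }
    )


@dataclass
class OptimizationResult:
    """Best feasible spacing and its metrics, plus every evaluation made."""

    d_star_mm: float
    ve_star_mm3: float
    metrics: TherapyMetrics
    evaluations: list[SpacingResult]
    verification: SpacingResult | None = None

    def __iter__(self):  # allow  d, ve = optimize_spacing(...)
        return iter((self.d_star_mm, self.ve_star_mm3))


_GOLD = (math.sqrt(5.0) - 1.0) / 2.0


def optimize_spacing(
    scenario: SpacingScenario,
    bounds: tuple[float, float],
    tolerance_mm: float = 0.01,
    coarse_step_mm: float = 0.5,
    verify_resolution: float | None = None,
) -> OptimizationResult:
    """Maximize Ve(D) subject to Vo(D) = 0 over D in ``bounds`` (mm).

    Coarse scan at ``coarse_step_mm``, then bisection of the feasibility
    boundary (the usual location of the optimum) and golden-section search
    when the scan maximum is interior to the feasible set; the returned
    D* is resolved to ``tolerance_mm``.  ``verify_resolution`` optionally
    re-solves the optimum on a finer grid and attaches the result.
    """
    d_lo, d_hi = bounds
    if not 0 < d_lo < d_hi:
        raise ValueError("bounds must satisfy 0 < D_lo < D_hi")
    if tolerance_mm < 0.01:
        raise ValueError("tolerance_mm must be >= 0.01")

    cache: dict[float, SpacingResult] = {}

    def ev(d: float) -> SpacingResult:
        key = round(d, 6)
        if key not in cache:
            cache[key] = _evaluate(scenario, key)
        return cache[key]

    n = max(2, int(math.ceil((d_hi - d_lo) / coarse_step_mm)))
    scan = [d_lo + (d_hi - d_lo) * i / n for i in range(n + 1)]
    results = [ev(d) for d in scan]
    feas = [r for r in results if r.feasible]
    if not feas:
        raise InfeasibleError(
            f"no feasible spacing in [{d_lo}, {d_hi}] mm "
            f"(min Vo {min(r.metrics.vo_mm3 for r in results):.3g} mm^3)"
        )

    best = max(feas, key=lambda r: r.metrics.ve_mm3)
    ds = [r.d_mm for r in results]
    i_best = ds.index(best.d_mm)

    # refine the infeasible/feasible boundary below the best feasible point
    if i_best > 0 and not results[i_best - 1].feasible:
        lo, hi = results[i_best - 1].d_mm, best.d_mm
        while hi - lo > tolerance_mm:
            mid = 0.5 * (lo + hi)
            r = ev(mid)
            if r.feasible:
                hi = mid
                if r.metrics.ve_mm3 >= best.metrics.ve_mm3:
                    best = r
            else:
                lo = mid
    elif 0 < i_best < len(results) - 1:
        # interior maximum: golden-section on the bracket around it
        a = results[i_best - 1].d_mm
        b = results[i_best + 1].d_mm
        x1 = b - _GOLD * (b - a)
        x2 = a + _GOLD * (b - a)
        while b - a > tolerance_mm:
            r1, r2 = ev(x1), ev(x2)
            v1 = r1.metrics.ve_mm3 if r1.feasible else -math.inf
            v2 = r2.metrics.ve_mm3 if r2.feasible else -math.inf
            if v1 >= v2:
                b, x2 = x2, x1
                x1 = b - _GOLD * (b - a)
            else:
                a, x1 = x1, x2
                x2 = a + _GOLD * (b - a)
        for r in (ev(x1), ev(x2)):
            if r.feasible and r.metrics.ve_mm3 > best.metrics.ve_mm3:
                best = r

    verification = None
    if verify_resolution is not None:
        prob = scenario.problem_factory(best.d_mm)
        if prob.grid.rebuild is not None:
            from dataclasses import replace as _replace

            g = prob.grid.rebuild(verify_resolution)
            fld = solve_steady(_replace(prob, grid=g), **scenario.solver_kwargs)
            m = compute_metrics(fld, g)
            vols = g.cell_volumes()
            near = vols[g.cell_region == REGION_SEED]
            thr = 0.5 * float(near.min()) * 1e9 * g.symmetry_factor
            verification = SpacingResult(
                d_mm=best.d_mm, metrics=m,
                feasible=m.vo_mm3 < thr, vo_threshold_mm3=thr,
            )

    evaluations = sorted(cache.values(), key=lambda r: r.d_mm)
    return OptimizationResult(
        d_star_mm=best.d_mm,
        ve_star_mm3=best.metrics.ve_mm3,
        metrics=best.metrics,
        evaluations=evaluations,
        verification=verification,
    )
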