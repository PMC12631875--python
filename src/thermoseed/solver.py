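"""Finite-volume solver for the coupled Pennes bioheat equations.

The model solved in each tissue/material region is

    rho c dT/dt = div(k grad T) + S(T),

with region-dependent sources:

* seed cells:    S = P(T) = SLP(T) * rho_seed  (self-regulating, nonlinear),
* tissue cells:  S = Q_m(T) + Q_b(T)
                   = Q_m0 (1 + 0.1 (T - 37)) + w_b rho_b c_b (T_a - T),

on the labeled tensor-product grids of :mod:`thermoseed.geometry`.  The
diffusion operator is the conservative finite-volume form with harmonic-mean
face conductivities across material interfaces (Cartesian 3-D or axisymmetric
r-z).  Boundary handling follows the cell labels: exterior cells impose a
fixed temperature, air cells impose a Robin (natural-convection) condition
-k dT/dn = h (T - T_ambient) on the exposed faces, and the computational-box
faces are zero-flux (symmetry) planes.

The tissue sources are affine in T and are folded into the linear system; only
the seed source is nonlinear.  Because SLP(T) decreases with temperature above
its peak, damped Picard iteration on the seed source is a contraction in all
planning scenarios, and the (factorized-once) linear operator is reused across
iterations.  A semi-implicit variant that also linearizes dP/dT into the
diagonal is available as a fallback for stiffer sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator, bicgstab, spilu, splu

from .geometry import (
    LabeledGrid,
    REGION_AIR,
    REGION_EXTERIOR,
    REGION_HOST,
    REGION_SEED,
    REGION_TUMOR,
)
from .materials import BloodProps, MaterialProps
from .slp import SLPGaussianParams, eval_slp

__all__ = [
    "BioheatProblem",
    "TemperatureField",
    "TransientResult",
    "SolverError",
    "ConvergenceError",
    "solve_steady",
    "solve_transient",
    "energy_balance",
]


#: direct sparse LU below this size; ILU-preconditioned BiCGStab above
_DIRECT_SOLVER_MAX_N = 25000


def _make_linear_solver(A):
    """Return ``solve(b, x0)`` for the (symmetric M-matrix) operator ``A``.

    Small systems use a cached direct LU factorization; large 3-D systems use
    an incomplete-LU-preconditioned BiCGStab with warm starts (the operator is
    reused across Picard iterations / time steps).  Falls back to the direct
    factorization if the iteration stalls.
    """
    A = A.tocsc()
    n = A.shape[0]
    if n <= _DIRECT_SOLVER_MAX_N:
        lu = splu(A)
        return lambda b, x0=None: lu.solve(b)
    ilu = spilu(A, drop_tol=1e-5, fill_factor=14)
    M = LinearOperator((n, n), ilu.solve)
    direct = []

    def solve(b, x0=None):
        x, info = bicgstab(A, b, x0=x0, rtol=1e-10, atol=0.0, M=M, maxiter=500)
        if info != 0:
            if not direct:
                direct.append(splu(A))
            x = direct[0].solve(b)
        return x

    return solve


class SolverError(RuntimeError):
    pass


class ConvergenceError(SolverError):
    """Nonlinear iteration failed; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass
class BioheatProblem:
    """A bioheat boundary-value problem on a labeled grid.

    ``region_materials`` maps the region names ``seed``/``tumor``/``host`` to
    their :class:`MaterialProps` (for the seed, the composite effective
    properties — its density also sets the SLP-to-power conversion).
    Boundary values: exterior cells are held at ``boundary_temperature``;
    faces exposed to air cells use the Robin pair
    (``convection_coefficient``, ``ambient_temperature``).
    """

    grid: LabeledGrid
    region_materials: dict[str, MaterialProps]
    blood: BloodProps = field(default_factory=BloodProps)
    slp: SLPGaussianParams | None = None
    boundary_temperature: float = 37.0
    convection_coefficient: float = 5.0
    ambient_temperature: float = 25.0
    initial_temperature: float = 37.0

    def __post_init__(self) -> None:
        present = set(np.unique(self.grid.cell_region))
        needed = {REGION_SEED: "seed", REGION_TUMOR: "tumor", REGION_HOST: "host"}
        for code, name in needed.items():
            if code in present and name not in self.region_materials:
                raise SolverError(f"no material given for region {name!r}")
        if REGION_SEED in present and self.slp is None:
            raise SolverError("seed cells present but no SLP(T) parameters given")
        if REGION_EXTERIOR not in present and REGION_AIR not in present:
            raise SolverError(
                "ill-posed problem: no fixed-temperature or convective boundary"
            )

    def seed_power_density(self, T):
        """Seed volumetric power P(T) = SLP(T) * rho_seed, W/m^3."""
        rho_g_per_m3 = self.region_materials["seed"].density * 1e3
        return eval_slp(self.slp, T) * rho_g_per_m3

    def seed_power_density_derivative(self, T):
        p = self.slp
        rho_g_per_m3 = self.region_materials["seed"].density * 1e3
        g = np.exp(-(((np.asarray(T, float) - p.b) / p.c) ** 2))
        return p.a * g * (-2.0 * (np.asarray(T, float) - p.b) / p.c**2) * rho_g_per_m3


@dataclass
class TemperatureField:
    """Per-cell temperatures (degC) on a grid, at a time point or steady state."""

    values: np.ndarray
    grid: LabeledGrid
    time: float | None = None
    steady: bool = False
    iterations: int = 0
    residual_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("temperature field contains non-finite values")


@dataclass
class TransientResult:
    """Transient solution snapshots plus optional approach-to-reference timing."""

    times: list[float]
    fields: list[TemperatureField]
    reference_convergence_time: float | None = None

    @property
    def final(self) -> TemperatureField:
        return self.fields[-1]


# ---------------------------------------------------------------------------
# discrete operator

class _Discretization:
    """Assembled linear operator and bookkeeping for one problem."""

    def __init__(self, problem: BioheatProblem):
        grid = problem.grid
        region = grid.cell_region
        shape = grid.shape
        n = region.size
        self.problem = problem
        self.grid = grid
        self.region = region

        mats = problem.region_materials
        k = np.empty(shape)
        k.fill(np.nan)
        host_k = mats.get("host", mats.get("tumor")).conductivity
        for code, name in ((REGION_SEED, "seed"), (REGION_TUMOR, "tumor"),
                           (REGION_HOST, "host")):
            if name in mats:
                k[region == code] = mats[name].conductivity
        k[region == REGION_EXTERIOR] = host_k  # half-cell path to the fixed boundary
        k[region == REGION_AIR] = 1.0          # unused (Robin faces)

        self.unknown = region <= REGION_HOST
        self.n_unknown = int(self.unknown.sum())
        idx = -np.ones(shape, dtype=np.int64)
        idx[self.unknown] = np.arange(self.n_unknown)
        self.index = idx
        self.volumes = grid.cell_volumes()

        # sub-cell seed volume fraction: anti-aliases the staircase source
        has_seed_cells = bool(np.any(region == REGION_SEED))
        if has_seed_cells:
            self.seed_frac = grid.region_fraction(REGION_SEED)
        else:
            self.seed_frac = np.zeros(shape)
        self.seed_frac[~self.unknown] = 0.0

        # affine tissue sources S = c0 + c1 T  (seed handled nonlinearly);
        # partially seed-covered cells carry the complementary tissue share
        blood = problem.blood
        c0 = np.zeros(shape)
        c1 = np.zeros(shape)
        for code, name in ((REGION_TUMOR, "tumor"), (REGION_HOST, "host")):
            if name not in mats:
                continue
            m = mats[name]
            wbc = m.perfusion_rate * blood.density * blood.heat_capacity
            sel = region == code
            tissue_share = 1.0 - self.seed_frac[sel]
            c0[sel] = (-2.7 * m.metabolic_q0
                       + wbc * blood.arterial_temperature) * tissue_share
            c1[sel] = (0.1 * m.metabolic_q0 - wbc) * tissue_share
        self.c0, self.c1 = c0, c1
        self.wb = np.zeros(shape)
        self.q0 = np.zeros(shape)
        for code, name in ((REGION_TUMOR, "tumor"), (REGION_HOST, "host")):
            if name in mats:
                self.wb[region == code] = mats[name].perfusion_rate
                self.q0[region == code] = mats[name].metabolic_q0

        rows, cols, vals = [], [], []
        diag = np.zeros(self.n_unknown)
        b0 = np.zeros(self.n_unknown)
        self._dirichlet_faces: list[tuple[np.ndarray, np.ndarray]] = []
        self._robin_faces: list[tuple[np.ndarray, np.ndarray]] = []

        ndim = len(shape)
        for axis in range(ndim):
            area, d_lo, d_hi = grid.face_geometry(axis)
            sl_lo = [slice(None)] * ndim
            sl_hi = [slice(None)] * ndim
            sl_lo[axis] = slice(None, -1)
            sl_hi[axis] = slice(1, None)
            sl_lo, sl_hi = tuple(sl_lo), tuple(sl_hi)

            kL, kR = k[sl_lo], k[sl_hi]
            trans = area / (d_lo / kL + d_hi / kR)
            regL, regR = region[sl_lo], region[sl_hi]
            iL, iR = idx[sl_lo], idx[sl_hi]
            unkL, unkR = regL <= REGION_HOST, regR <= REGION_HOST

            both = unkL & unkR
            tL, tR, tT = iL[both], iR[both], trans[both]
            rows += [tL, tR]
            cols += [tR, tL]
            vals += [-tT, -tT]
            np.add.at(diag, tL, tT)
            np.add.at(diag, tR, tT)

            for unk_sel, other_reg, unk_idx, k_unk, d_unk in (
                (unkL & ~unkR, regR, iL, kL, d_lo),
                (unkR & ~unkL, regL, iR, kR, d_hi),
            ):
                fixed = unk_sel & (other_reg == REGION_EXTERIOR)
                if np.any(fixed):
                    ti = unk_idx[fixed]
                    dist = self._surface_distance(
                        axis, fixed, toward_upper=(d_unk is d_lo),
                        d_total=(d_lo + d_hi)[fixed], d_face=d_unk[fixed],
                    )
                    dist = np.maximum(dist, 0.05 * d_unk[fixed])
                    tt = area[fixed] * k_unk[fixed] / dist
                    np.add.at(diag, ti, tt)
                    np.add.at(b0, ti, tt * problem.boundary_temperature)
                    self._dirichlet_faces.append((ti, tt))
                robin = unk_sel & (other_reg == REGION_AIR)
                if np.any(robin):
                    hA = problem.convection_coefficient * area[robin]
                    ti = unk_idx[robin]
                    np.add.at(diag, ti, hA)
                    np.add.at(b0, ti, hA * problem.ambient_temperature)
                    self._robin_faces.append((ti, hA))

        vol_u = self.volumes[self.unknown]
        diag -= self.c1[self.unknown] * vol_u
        b0 += self.c0[self.unknown] * vol_u

        rows.append(np.arange(self.n_unknown))
        cols.append(np.arange(self.n_unknown))
        vals.append(diag)
        self.matrix = sp.csr_matrix(
            (np.concatenate(vals),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_unknown, self.n_unknown),
        )
        self.b0 = b0
        self.vol_unknown = vol_u
        frac_u = self.seed_frac[self.unknown]
        self.seed_unknown = frac_u > 0.0
        self.seed_vol_eff = frac_u[self.seed_unknown] * vol_u[self.seed_unknown]
        self._lu = None

    def _surface_distance(self, axis, face_mask, toward_upper, d_total, d_face):
        """Distance from a boundary cell center to the analytic fixed surface.

        Bisects the grid's region function along the face normal so the fixed
        temperature acts at the true (sub-cell) surface position rather than
        at the staircase face.  Falls back to the face distance when the grid
        carries no analytic region function.
        """
        grid = self.grid
        if grid.region_fn is None:
            return d_face
        ndim = len(grid.shape)
        idx = np.argwhere(face_mask)
        cell_idx = idx.copy()
        if not toward_upper:
            cell_idx[:, axis] += 1
        centers = grid.centers()
        pts = np.stack([centers[d][cell_idx[:, d]] for d in range(ndim)], axis=1)
        sign = 1.0 if toward_upper else -1.0
        lo = np.zeros(len(idx))
        hi = np.asarray(d_total, dtype=float).copy()
        for _ in range(20):
            mid = 0.5 * (lo + hi)
            p = pts.copy()
            p[:, axis] += sign * mid
            ext = grid.region_fn(*[p[:, d] for d in range(ndim)]) == REGION_EXTERIOR
            hi = np.where(ext, mid, hi)
            lo = np.where(ext, lo, mid)
        return 0.5 * (lo + hi)

    def solver(self):
        if self._lu is None:
            self._lu = _make_linear_solver(self.matrix)
        return self._lu

    def rhs(self, T_flat: np.ndarray) -> np.ndarray:
        """b0 plus the lagged seed source evaluated at local temperatures."""
        b = self.b0.copy()
        if np.any(self.seed_unknown):
            Ts = T_flat[self.seed_unknown]
            b[self.seed_unknown] += (
                self.problem.seed_power_density(Ts) * self.seed_vol_eff
            )
        return b

    def full_field(self, T_flat: np.ndarray) -> np.ndarray:
        out = np.empty(self.grid.shape)
        out[self.region == REGION_EXTERIOR] = self.problem.boundary_temperature
        out[self.region == REGION_AIR] = self.problem.ambient_temperature
        out[self.unknown] = T_flat
        return out


def solve_steady(
    problem: BioheatProblem,
    tol: float = 1e-4,
    damping: float = 0.7,
    max_iterations: int = 80,
    initial_field: TemperatureField | None = None,
    semi_implicit_source: bool = False,
) -> TemperatureField:
    """Solve the steady (dT/dt = 0) coupled problem by damped Picard iteration.

    Converged when the maximum undamped temperature update falls below ``tol``
    (degC).  With ``semi_implicit_source`` the seed-source slope dP/dT is
    folded into the diagonal each iteration (refactoring the operator), which
    is unconditionally contractive for self-regulating sources.
    """
    disc = _Discretization(problem)
    T = (
        initial_field.values[disc.unknown].copy()
        if initial_field is not None
        else np.full(disc.n_unknown, problem.initial_temperature)
    )
    history: list[float] = []
    has_seed = bool(np.any(disc.seed_unknown))
    for it in range(1, max_iterations + 1):
        if semi_implicit_source and has_seed:
            dPV = np.zeros(disc.n_unknown)
            dPV[disc.seed_unknown] = (
                problem.seed_power_density_derivative(T[disc.seed_unknown])
                * disc.seed_vol_eff
            )
            A = disc.matrix - sp.diags(dPV)
            b = disc.rhs(T) - dPV * T
            T_new = _make_linear_solver(A)(b, x0=T)
        else:
            T_new = disc.solver()(disc.rhs(T), x0=T)
        resid = float(np.max(np.abs(T_new - T))) if disc.n_unknown else 0.0
        history.append(resid)
        if not has_seed or resid < tol:
            T = T_new
            break
        T = T + damping * (T_new - T)
    else:
        raise ConvergenceError(
            f"steady solve did not reach {tol} degC in {max_iterations} "
            f"iterations (last update {history[-1]:.3e})",
            history,
        )
    return TemperatureField(
        values=disc.full_field(T),
        grid=problem.grid,
        steady=True,
        iterations=len(history),
        residual_history=history,
    )


def solve_transient(
    problem: BioheatProblem,
    t_end: float,
    dt: float = 1.0,
    output_times: Sequence[float] | None = None,
    reference: TemperatureField | None = None,
    reference_tol: float = 0.1,
) -> TransientResult:
    """Implicit (backward-Euler) time integration from the uniform initial state.

    The seed source is lagged by one step (one Picard sweep per step).  Fields
    are returned at the requested ``output_times`` (snapped to time steps;
    default: final time only).  If a ``reference`` field is given, the first
    time at which max|T - T_ref| < ``reference_tol`` degC is recorded.
    """
    if dt <= 0 or t_end < dt:
        raise ValueError("need dt > 0 and t_end >= dt")
    disc = _Discretization(problem)
    grid = problem.grid
    mats = problem.region_materials
    rho_c = np.zeros(grid.shape)
    for code, name in ((REGION_SEED, "seed"), (REGION_TUMOR, "tumor"),
                       (REGION_HOST, "host")):
        if name in mats:
            m = mats[name]
            rho_c[grid.cell_region == code] = m.density * m.heat_capacity
    mass = rho_c[disc.unknown] * disc.vol_unknown / dt
    step_solver = _make_linear_solver(disc.matrix + sp.diags(mass))

    n_steps = int(round(t_end / dt))
    wanted = sorted(set(output_times)) if output_times is not None else [t_end]
    ref_vals = reference.values[disc.unknown] if reference is not None else None

    T = np.full(disc.n_unknown, problem.initial_temperature)
    times, fields = [], []
    ref_time = None

    def snapshot(t, vec):
        fields.append(
            TemperatureField(values=disc.full_field(vec), grid=grid, time=t)
        )
        times.append(t)

    if wanted and wanted[0] <= 0.0:
        snapshot(0.0, T)
        wanted = [w for w in wanted if w > 0.0]

    for step in range(1, n_steps + 1):
        t = step * dt
        T = step_solver(disc.rhs(T) + mass * T, x0=T)
        if ref_vals is not None and ref_time is None:
            if np.max(np.abs(T - ref_vals)) < reference_tol:
                ref_time = t
        while wanted and t >= wanted[0] - 0.5 * dt:
            snapshot(t, T)
            wanted.pop(0)
    if not fields:
        snapshot(n_steps * dt, T)
    return TransientResult(
        times=times, fields=fields, reference_convergence_time=ref_time
    )


def energy_balance(problem: BioheatProblem, fieldT: TemperatureField) -> dict:
    """Steady-state energy audit, W (computational-domain share).

    Returns the total seed power, net metabolic generation, net perfusion
    removal, boundary losses (fixed-temperature flux plus convection), and the
    relative residual |in - out| / seed power.
    """
    disc = _Discretization(problem)
    T = fieldT.values
    vol = disc.volumes
    T_u = T[disc.unknown]

    seed_W = float(
        np.sum(problem.seed_power_density(T_u[disc.seed_unknown])
               * disc.seed_vol_eff)
    ) if np.any(disc.seed_unknown) else 0.0

    # affine tissue source split into metabolic and perfusion shares
    from .materials import metabolic_heat, perfusion_heat

    tissue_share = 1.0 - disc.seed_frac
    met_W = float(
        np.sum(metabolic_heat(disc.q0, T) * tissue_share * vol)
    )
    perf_W = float(
        np.sum(perfusion_heat(disc.wb, problem.blood, T) * tissue_share * vol)
    )

    # boundary losses through fixed-temperature and convection faces
    bnd_W = 0.0
    for ti, tt in disc._dirichlet_faces:
        bnd_W += float(np.sum(tt * (T_u[ti] - problem.boundary_temperature)))
    for ti, hA in disc._robin_faces:
        bnd_W += float(np.sum(hA * (T_u[ti] - problem.ambient_temperature)))

    residual = seed_W + met_W + perf_W - bnd_W
    denom = seed_W if seed_W > 0 else max(abs(met_W) + abs(perf_W), 1e-30)
    return {
        "seed_power_W": seed_W,
        "metabolic_W": met_W,
        "perfusion_W": perf_W,
        "boundary_W": bnd_W,
        "residual_W": residual,
        "relative_residual": abs(residual) / denom,
    }
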