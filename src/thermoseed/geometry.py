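"""Labeled computational domains for seed-implant phantoms.

Two phantom families are supported:

* a deep-seated phantom — a spherical tumor (default radius 15 mm) embedded in
  a spherical shell of healthy liver (outer radius 25 mm, outer surface held
  at body temperature), with one or more cylindrical composite seeds at its
  center;
* a subcutaneous phantom — an ellipsoidal tumor partially embedded in a muscle
  half-space, its exposed surface cooled by natural air convection.

Domains are discretized on nonuniform tensor-product grids (Cartesian 3-D, or
axisymmetric r-z for a single centered seed), graded from sub-millimeter cells
across the seeds to coarse cells at the far boundary.  Cells are labeled by
cell-center membership in the analytic geometry; labels are re-derived (never
interpolated) on refinement, so labeled volumes converge to the analytic
volumes as the mesh is refined.

Symmetry (mirror planes through the seed array) is exploited by building only
an octant/quadrant of the domain; the grid carries the corresponding volume
multiplicity, which therapy metrics apply when summing volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .materials import CompositeSeedSpec

__all__ = [
    "REGION_SEED",
    "REGION_TUMOR",
    "REGION_HOST",
    "REGION_EXTERIOR",
    "REGION_AIR",
    "REGION_NAMES",
    "GeometryError",
    "SeedPlacement",
    "PhantomSpec",
    "LabeledGrid",
    "graded_axis",
    "build_liver_phantom",
    "build_subcutaneous_phantom",
    "refine_grid",
]

# integer region codes stored per cell
REGION_SEED = 0
REGION_TUMOR = 1
REGION_HOST = 2
REGION_EXTERIOR = 3  # outside the phantom, held at the fixed boundary temperature
REGION_AIR = 4       # ambient air above the subcutaneous surface (convection)

REGION_NAMES = {
    REGION_SEED: "seed",
    REGION_TUMOR: "tumor",
    REGION_HOST: "host",
    REGION_EXTERIOR: "exterior",
    REGION_AIR: "air",
}


class GeometryError(ValueError):
    """Invalid phantom geometry (overlapping seeds, seed outside tumor, ...)."""


@dataclass(frozen=True)
class SeedPlacement:
    """Position and orientation of one cylindrical seed (SI meters)."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
            raise GeometryError(f"seed axis {self.axis} is not a unit vector")


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic description of a phantom scenario.

    ``kind`` selects the family; liver-sphere fields are tumor/liver radii,
    subcutaneous fields are the ellipsoid semi-axes, the embedded fraction of
    the (full) minor axis, and the convection parameters of the exposed
    surface.
    """

    kind: str = "liver_sphere"
    tumor_radius: float = 15e-3
    liver_radius: float = 25e-3
    ellipsoid_semiaxes: tuple[float, float, float] = (5e-3, 3.5e-3, 2e-3)
    embed_fraction: float = 0.2
    body_temperature: float = 37.0
    convection_coefficient: float = 5.0
    ambient_temperature: float = 25.0
    seeds: tuple[SeedPlacement, ...] = (SeedPlacement(),)
    seed_spec: CompositeSeedSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("liver_sphere", "subcutaneous_ellipsoid"):
            raise GeometryError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "liver_sphere":
            if not 0 < self.tumor_radius < self.liver_radius:
                raise GeometryError("need 0 < tumor_radius < liver_radius")
        else:
            if not 0.0 < self.embed_fraction < 1.0:
                raise GeometryError(
                    "embed_fraction must lie strictly in (0, 1): a zero fraction "
                    "detaches the tumor from the muscle"
                )
        if self.seed_spec is not None:
            self._validate_seeds()

    # -- seed geometry checks ------------------------------------------------
    def _validate_seeds(self) -> None:
        spec = self.seed_spec
        r, hl = spec.radius, 0.5 * spec.length
        for s in self.seeds:
            c = np.asarray(s.center)
            a = np.asarray(s.axis)
            # farthest point of the cylinder from the tumor center
            ends = [c + hl * a, c - hl * a]
            reach = max(np.linalg.norm(e) + r for e in ends)
            if self.kind == "liver_sphere":
                if reach > self.tumor_radius:
                    raise GeometryError("seed extends outside the tumor")
            else:
                ax_, ay, az = self.ellipsoid_semiaxes
                zc = az - self.embed_fraction * 2.0 * az
                for e in ends:
                    p = e - np.array([0.0, 0.0, zc])
                    # conservative: inflate the point by the seed radius
                    q = (np.abs(p) + r) / np.array([ax_, ay, az])
                    if np.sum(q**2) > 1.0:
                        raise GeometryError("seed extends outside the tumor")
        # pairwise overlap for parallel seeds
        for i in range(len(self.seeds)):
            for j in range(i + 1, len(self.seeds)):
                si, sj = self.seeds[i], self.seeds[j]
                if abs(np.dot(si.axis, sj.axis)) > 1 - 1e-9:
                    d_axis = np.asarray(sj.center) - np.asarray(si.center)
                    perp = d_axis - np.dot(d_axis, si.axis) * np.asarray(si.axis)
                    axial = abs(np.dot(d_axis, si.axis))
                    if np.linalg.norm(perp) < 2 * r and axial < spec.length:
                        raise GeometryError(
                            f"seeds {i} and {j} overlap "
                            f"(transverse gap {np.linalg.norm(perp) - 2 * r:.2e} m)"
                        )


def _cylinder_mask(x, y, z, placement: SeedPlacement, radius: float, half_len: float):
    """Vectorized membership test for a finite cylinder."""
    cx, cy, cz = placement.center
    ax, ay, az = placement.axis
    dx, dy, dz = x - cx, y - cy, z - cz
    s = dx * ax + dy * ay + dz * az            # axial coordinate
    p2 = dx * dx + dy * dy + dz * dz - s * s   # squared perpendicular distance
    return (np.abs(s) <= half_len) & (p2 <= radius * radius)


# ---------------------------------------------------------------------------
# graded axes

def _geometric_fill(length, h_left, h_right, ratio, h_max):
    """Spacings covering ``length``, growing geometrically from both ends.

    ``h_left``/``h_right`` may be None for a free (domain-boundary) end.
    Spacings are rescaled uniformly so they sum to ``length`` exactly.
    """
    if length <= 0:
        return []

    def ramp(h0):
        out, h = [], h0
        while h < h_max:
            h = min(h * ratio, h_max)
            out.append(h)
        return out

    left = ramp(h_left) if h_left else []
    right = ramp(h_right) if h_right else []
    if h_left is None and h_right is None:
        n = max(1, round(length / h_max))
        return [length / n] * n
    spac = left + right[::-1]
    total = sum(spac)
    if total < length:
        n_mid = max(1, round((length - total) / h_max))
        spac = left + [(length - total) / n_mid] * n_mid + right[::-1]
    else:
        # ramps overlap: drop the coarsest spacings until they fit
        order = sorted(range(len(spac)), key=lambda i: spac[i])
        keep, acc = [], 0.0
        for i in order:
            if acc + spac[i] > length and keep:
                break
            keep.append(i)
            acc += spac[i]
        spac = [spac[i] for i in sorted(keep)] or [length]
    scale = length / sum(spac)
    return [h * scale for h in spac]


def graded_axis(
    lo: float,
    hi: float,
    fine_intervals: Sequence[tuple[float, float]],
    h_fine: float,
    h_max: float,
    ratio: float = 1.3,
) -> np.ndarray:
    """Node coordinates on [lo, hi], fine inside given intervals, graded outside.

    Intervals are clipped to the domain and merged when overlapping; spacing is
    ~``h_fine`` (uniform) inside them and grows geometrically by ``ratio`` up
    to ``h_max`` in the gaps.
    """
    if hi <= lo:
        raise ValueError("need hi > lo")
    ivs = []
    for a, b in sorted((max(lo, a), min(hi, b)) for a, b in fine_intervals):
        if b <= a:
            continue
        if ivs and a <= ivs[-1][1] + 0.5 * h_fine:
            ivs[-1] = (ivs[-1][0], max(ivs[-1][1], b))
        else:
            ivs.append((a, b))

    nodes = [lo]
    cursor = lo
    for k, (a, b) in enumerate(ivs):
        gap = a - cursor
        if gap > 1e-12:
            left_h = h_fine if k > 0 else None
            spac = _geometric_fill(gap, left_h, h_fine, ratio, h_max)
            for h in spac:
                cursor += h
                nodes.append(cursor)
        n_fine = max(1, round((b - a) / h_fine))
        for i in range(n_fine):
            nodes.append(a + (b - a) * (i + 1) / n_fine)
        cursor = b
    if hi - cursor > 1e-12:
        left_h = h_fine if ivs else None
        spac = _geometric_fill(hi - cursor, left_h, None, ratio, h_max)
        for h in spac:
            cursor += h
            nodes.append(cursor)
    nodes[-1] = hi
    arr = np.array(nodes)
    if np.any(np.diff(arr) <= 0):
        arr = np.unique(arr)
    return arr


# ---------------------------------------------------------------------------
# labeled grid

@dataclass
class LabeledGrid:
    """Nonuniform tensor-product grid with per-cell region labels.

    ``kind`` is ``"cartesian"`` (axes x, y, z) or ``"axisymmetric"`` (axes
    r, z).  ``axes`` hold node coordinates (cells are the half-open intervals
    between consecutive nodes); ``cell_region`` holds integer region codes at
    cell centers.  ``symmetry_factor`` is the number of symmetric copies of the
    computational domain making up the full phantom; ``mirror_axes`` lists the
    axes mirrored at coordinate 0.
    """

    kind: str
    axes: tuple[np.ndarray, ...]
    cell_region: np.ndarray
    symmetry_factor: float = 1.0
    mirror_axes: tuple[int, ...] = ()
    region_fn: Callable | None = None
    rebuild: Callable | None = None
    meta: dict = field(default_factory=dict)

    # -- basic geometry ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(ax) - 1 for ax in self.axes)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (ax[:-1] + ax[1:]) for ax in self.axes)

    def spacings(self) -> tuple[np.ndarray, ...]:
        return tuple(np.diff(ax) for ax in self.axes)

    def cell_volumes(self) -> np.ndarray:
        """Geometric cell volumes of the computational domain, m^3."""
        if self.kind == "cartesian":
            dx, dy, dz = self.spacings()
            return dx[:, None, None] * dy[None, :, None] * dz[None, None, :]
        r = self.axes[0]
        dz = np.diff(self.axes[1])
        ring = math.pi * (r[1:] ** 2 - r[:-1] ** 2)
        return ring[:, None] * dz[None, :]

    def labeled_volume(self, region: int) -> float:
        """Full-phantom volume of one region (symmetry applied), m^3."""
        vols = self.cell_volumes()
        return float(self.symmetry_factor * vols[self.cell_region == region].sum())

    # -- face geometry for the finite-volume solver ---------------------------
    def face_geometry(self, axis: int):
        """Areas and center-to-face distances for internal faces along ``axis``.

        Returns ``(area, d_lo, d_hi)``: arrays shaped like the cell array with
        one fewer entry along ``axis``.  ``d_lo``/``d_hi`` are the distances
        from the lower/upper cell center to the shared face.
        """
        spac = self.spacings()
        ndim = len(self.axes)

        def along(vec, ax):
            shape = [1] * ndim
            shape[ax] = len(vec)
            return np.asarray(vec).reshape(shape)

        d_lo = along(0.5 * spac[axis][:-1], axis)
        d_hi = along(0.5 * spac[axis][1:], axis)

        if self.kind == "cartesian":
            area = 1.0
            for a in range(ndim):
                if a == axis:
                    continue
                area = area * along(spac[a], a)
            area = np.broadcast_to(
                area, tuple(s - 1 if a == axis else s for a, s in enumerate(self.shape))
            )
        else:  # axisymmetric (r, z)
            r = self.axes[0]
            dz = np.diff(self.axes[1])
            if axis == 0:  # radial faces: cylinders of radius r_face
                r_face = r[1:-1]
                area = 2.0 * math.pi * r_face[:, None] * dz[None, :]
            else:  # axial faces: annuli
                ring = math.pi * (r[1:] ** 2 - r[:-1] ** 2)
                area = np.broadcast_to(
                    ring[:, None], (self.shape[0], self.shape[1] - 1)
                )
        d_lo = np.broadcast_to(d_lo, area.shape)
        d_hi = np.broadcast_to(d_hi, area.shape)
        return area, d_lo, d_hi

    def region_fraction(self, region: int, subdiv: int = 3) -> np.ndarray:
        """Per-cell volume fraction occupied by ``region``.

        Estimated by subsampling the analytic region function on a
        ``subdiv``-per-axis sub-grid of each cell (falls back to 0/1
        cell-center membership when no region function is attached).  Used to
        anti-alias the seed source term; region *labels* remain cell-center
        membership.
        """
        if self.region_fn is None:
            return (self.cell_region == region).astype(float)
        sub_centers = []
        for ax in self.axes:
            a, b = ax[:-1], ax[1:]
            offs = (np.arange(subdiv) + 0.5) / subdiv
            sub_centers.append((a[:, None] + (b - a)[:, None] * offs[None, :]).ravel())
        mesh = np.meshgrid(*sub_centers, indexing="ij")
        lab = (self.region_fn(*mesh) == region).astype(float)
        ndim = len(self.axes)
        shape = []
        for s in self.shape:
            shape += [s, subdiv]
        lab = lab.reshape(shape)
        if self.kind == "axisymmetric":
            # ring volume grows with r: weight radial subcells by their radius
            w = sub_centers[0].reshape(self.shape[0], subdiv)
            num = (lab * w[:, :, None, None]).sum(axis=(1, 3))
            return num / (w.sum(axis=1)[:, None] * subdiv)
        return lab.mean(axis=tuple(range(1, 2 * ndim, 2)))

    def to_symmetric_coords(self, points: np.ndarray) -> np.ndarray:
        """Map physical (x, y, z) points into the computational domain.

        Applies the mirror symmetries (absolute value on mirrored axes) and,
        for axisymmetric grids, the (r, z) reduction.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "axisymmetric":
            r = np.hypot(pts[:, 0], pts[:, 1])
            z = np.abs(pts[:, 2]) if 1 in self.mirror_axes else pts[:, 2]
            return np.column_stack([r, z])
        out = pts.copy()
        for ax in self.mirror_axes:
            out[:, ax] = np.abs(out[:, ax])
        return out


def _label(grid_axes, kind, region_fn) -> np.ndarray:
    centers = [0.5 * (ax[:-1] + ax[1:]) for ax in grid_axes]
    mesh = np.meshgrid(*centers, indexing="ij")
    return region_fn(*mesh).astype(np.int8)


def _check_seed_cells(grid: LabeledGrid, n_seeds: int) -> None:
    n = int(np.sum(grid.cell_region == REGION_SEED))
    if n * grid.symmetry_factor < 8 * n_seeds:
        raise GeometryError(
            f"seed(s) resolved by only {n} cells; refine target_resolution"
        )


def _phantom_meta(phantom, mode, spec, resolution):
    seed = spec.seed_spec
    return {
        "phantom": phantom,
        "mode": mode,
        "target_resolution_m": resolution,
        "seed_surfaces": tuple(
            {
                "center": tuple(p.center),
                "axis": tuple(p.axis),
                "radius": seed.radius,
                "half_length": 0.5 * seed.length,
            }
            for p in spec.seeds
        ),
    }


# ---------------------------------------------------------------------------
# phantom builders

def _liver_region_fn(spec: PhantomSpec):
    seed = spec.seed_spec
    r_s, hl = seed.radius, 0.5 * seed.length

    def fn(x, y, z):
        rad = np.sqrt(x * x + y * y + z * z)
        out = np.full(x.shape, REGION_HOST, dtype=np.int8)
        out[rad > spec.liver_radius] = REGION_EXTERIOR
        out[rad <= spec.tumor_radius] = REGION_TUMOR
        for p in spec.seeds:
            out[_cylinder_mask(x, y, z, p, r_s, hl)] = REGION_SEED
        return out

    return fn


def build_liver_phantom(
    spec: PhantomSpec,
    target_resolution: float = 1e-4,
    mode: str = "auto",
    h_max: float = 2.5e-3,
    ratio: float = 1.3,
    fine_margin: float = 5e-4,
) -> LabeledGrid:
    """Discretize the deep-seated (sphere-in-sphere) phantom.

    ``mode``: ``"axisymmetric"`` (single centered z-axis seed only),
    ``"octant"`` (mirror symmetry about all three coordinate planes, volumes
    carried with multiplicity 8), ``"full"``, or ``"auto"`` (axisymmetric when
    possible, else octant).  ``target_resolution`` is the cell size across the
    seeds.
    """
    if spec.kind != "liver_sphere":
        raise GeometryError("spec.kind must be 'liver_sphere'")
    if spec.seed_spec is None:
        raise GeometryError("spec.seed_spec is required")
    seed = spec.seed_spec
    R = spec.liver_radius

    single_centered = (
        len(spec.seeds) == 1
        and np.allclose(spec.seeds[0].center, 0.0)
        and np.allclose(spec.seeds[0].axis, (0, 0, 1))
    )
    if mode == "auto":
        mode = "axisymmetric" if single_centered else "octant"
    if mode == "axisymmetric" and not single_centered:
        raise GeometryError("axisymmetric mode needs one centered z-axis seed")

    if mode == "axisymmetric":
        r_ax = graded_axis(
            0.0, R, [(0.0, seed.radius + fine_margin)],
            target_resolution, h_max, ratio,
        )
        z_ax = graded_axis(
            0.0, R, [(0.0, 0.5 * seed.length + fine_margin)],
            target_resolution, h_max, ratio,
        )

        def fn(r, z):
            rad = np.sqrt(r * r + z * z)
            out = np.full(r.shape, REGION_HOST, dtype=np.int8)
            out[rad > spec.liver_radius] = REGION_EXTERIOR
            out[rad <= spec.tumor_radius] = REGION_TUMOR
            out[(r <= seed.radius) & (np.abs(z) <= 0.5 * seed.length)] = REGION_SEED
            return out

        grid = LabeledGrid(
            kind="axisymmetric",
            axes=(r_ax, z_ax),
            cell_region=_label((r_ax, z_ax), "axisymmetric", fn),
            symmetry_factor=2.0,
            mirror_axes=(1,),
            region_fn=fn,
            meta=_phantom_meta("liver_sphere", "axisymmetric", spec, target_resolution),
        )
    else:
        if mode == "octant":
            for p in spec.seeds:
                mirrored = {
                    tuple(np.round([sx * p.center[0], sy * p.center[1],
                                    sz * p.center[2]], 12))
                    for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)
                }
                existing = {tuple(np.round(q.center, 12)) for q in spec.seeds}
                if not mirrored <= existing:
                    raise GeometryError(
                        "octant mode requires a seed array symmetric about all "
                        "three coordinate planes"
                    )
            lo, factor, mirror = 0.0, 8.0, (0, 1, 2)
        else:
            lo, factor, mirror = -R, 1.0, ()

        fine: list[list[tuple[float, float]]] = [[], [], []]
        r_s, hl = seed.radius, 0.5 * seed.length
        for p in spec.seeds:
            ax = np.asarray(p.axis)
            half = np.abs(ax) * hl + np.sqrt(np.clip(1 - ax**2, 0, 1)) * r_s
            for d in range(3):
                fine[d].append(
                    (p.center[d] - half[d] - fine_margin,
                     p.center[d] + half[d] + fine_margin)
                )
        axes = tuple(
            graded_axis(lo, R, fine[d], target_resolution, h_max, ratio)
            for d in range(3)
        )
        fn = _liver_region_fn(spec)
        grid = LabeledGrid(
            kind="cartesian",
            axes=axes,
            cell_region=_label(axes, "cartesian", fn),
            symmetry_factor=factor,
            mirror_axes=mirror,
            region_fn=fn,
            meta=_phantom_meta("liver_sphere", mode, spec, target_resolution),
        )

    grid.rebuild = lambda res: build_liver_phantom(
        spec, res, mode=mode, h_max=h_max, ratio=ratio, fine_margin=fine_margin
    )
    _check_seed_cells(grid, len(spec.seeds))
    return grid


def build_subcutaneous_phantom(
    spec: PhantomSpec,
    target_resolution: float = 2e-4,
    mode: str = "quadrant",
    lateral_extent: float = 15e-3,
    depth: float = 25e-3,
    h_max: float = 2.5e-3,
    ratio: float = 1.3,
    fine_margin: float = 5e-4,
) -> LabeledGrid:
    """Discretize the subcutaneous (ellipsoid-on-muscle) phantom.

    The tumor ellipsoid (semi-axes a >= b >= c, minor axis vertical) sits on a
    muscle half-space z < 0, embedded to a depth of ``embed_fraction`` times
    the full minor axis; the exposed tumor and muscle surfaces see ambient
    air (convection).  The far muscle boundary (lateral and at depth) is held
    at body temperature.  ``mode`` is ``"quadrant"`` (x/y mirror planes) or
    ``"full"``.
    """
    if spec.kind != "subcutaneous_ellipsoid":
        raise GeometryError("spec.kind must be 'subcutaneous_ellipsoid'")
    if spec.seed_spec is None:
        raise GeometryError("spec.seed_spec is required")
    seed = spec.seed_spec
    sa, sb, sc = spec.ellipsoid_semiaxes
    embed_depth = spec.embed_fraction * 2.0 * sc
    zc = sc - embed_depth  # tumor center height above the muscle surface

    r_s, hl = seed.radius, 0.5 * seed.length
    z_top = zc + sc + 1.5e-3

    def fn(x, y, z):
        out = np.full(x.shape, REGION_HOST, dtype=np.int8)
        out[z >= 0.0] = REGION_AIR
        ell = (x / sa) ** 2 + (y / sb) ** 2 + ((z - zc) / sc) ** 2
        out[ell <= 1.0] = REGION_TUMOR
        far = (
            (np.abs(x) > lateral_extent - 1e-9)
            | (np.abs(y) > lateral_extent - 1e-9)
            | (z < -depth + 1e-9)
        )
        out[far & (out == REGION_HOST)] = REGION_EXTERIOR
        for p in spec.seeds:
            out[_cylinder_mask(x, y, z, p, r_s, hl)] = REGION_SEED
        return out

    if mode == "quadrant":
        lo_x = lo_y = 0.0
        factor, mirror = 4.0, (0, 1)
    else:
        lo_x = lo_y = -lateral_extent - h_max
        factor, mirror = 1.0, ()
    hi_xy = lateral_extent + h_max

    fine_x: list[tuple[float, float]] = [(-sa - fine_margin, sa + fine_margin)]
    fine_y: list[tuple[float, float]] = [(-sb - fine_margin, sb + fine_margin)]
    fine_z: list[tuple[float, float]] = [
        (zc - sc - fine_margin, zc + sc + fine_margin)
    ]
    for p in spec.seeds:
        ax = np.asarray(p.axis)
        half = np.abs(ax) * hl + np.sqrt(np.clip(1 - ax**2, 0, 1)) * r_s
        for d, fl in enumerate((fine_x, fine_y, fine_z)):
            fl.append(
                (p.center[d] - half[d] - fine_margin,
                 p.center[d] + half[d] + fine_margin)
            )

    x_ax = graded_axis(lo_x, hi_xy, fine_x, target_resolution, h_max, ratio)
    y_ax = graded_axis(lo_y, hi_xy, fine_y, target_resolution, h_max, ratio)
    z_ax = graded_axis(-depth - h_max, z_top, fine_z, target_resolution, h_max, ratio)
    axes = (x_ax, y_ax, z_ax)
    grid = LabeledGrid(
        kind="cartesian",
        axes=axes,
        cell_region=_label(axes, "cartesian", fn),
        symmetry_factor=factor,
        mirror_axes=mirror,
        region_fn=fn,
        meta={
            **_phantom_meta("subcutaneous_ellipsoid", mode, spec, target_resolution),
            "embed_depth_m": embed_depth,
        },
    )
    grid.rebuild = lambda res: build_subcutaneous_phantom(
        spec, res, mode=mode, lateral_extent=lateral_extent, depth=depth,
        h_max=h_max, ratio=ratio, fine_margin=fine_margin,
    )
    _check_seed_cells(grid, len(spec.seeds))
    return grid


def refine_grid(grid: LabeledGrid, factor: float) -> LabeledGrid:
    """Refine every axis so cell counts grow by ~``factor``; relabel analytically.

    Each cell interval is subdivided into an integer number of equal pieces,
    with the subdivision counts chosen by cumulative rounding so the total
    count per axis is within one cell of ``factor`` times the original.
    Labels are re-derived from the grid's analytic region function.
    """
    if factor <= 1:
        raise ValueError("refinement factor must be > 1")
    if grid.region_fn is None:
        raise ValueError("grid has no analytic region function to relabel from")

    new_axes = []
    for ax in grid.axes:
        nodes = [ax[0]]
        acc = 0.0
        for a, b in zip(ax[:-1], ax[1:]):
            acc += factor
            n_sub = max(1, int(round(acc)))
            acc -= n_sub
            for i in range(1, n_sub + 1):
                nodes.append(a + (b - a) * i / n_sub)
        new_axes.append(np.array(nodes))
    new_axes = tuple(new_axes)
    return LabeledGrid(
        kind=grid.kind,
        axes=new_axes,
        cell_region=_label(new_axes, grid.kind, grid.region_fn),
        symmetry_factor=grid.symmetry_factor,
        mirror_axes=grid.mirror_axes,
        region_fn=grid.region_fn,
        rebuild=grid.rebuild,
        meta=dict(grid.meta),
    )
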