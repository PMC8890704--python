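"""Conversion of cone geometry into a relative-permittivity lattice.

Meshes are voxelized by a slab-decomposed point-in-polygon test performed at
double the simulation resolution (matching the Yee half-step field offsets);
each 2x2x2 block of fine points yields one simulation voxel with a volumetric
fill fraction.  Voxels straddling a membrane surface become *interface
records* carrying the surface normal and fill fraction, from which an
anisotropic effective-permittivity tensor is built: the component along the
normal is the fill-weighted harmonic mean of the permittivities on either
side, the tangential components the fill-weighted arithmetic mean.  The 10-nm
membranes (plasma and mitochondrial), far thinner than a voxel, enter purely
through a membrane volume fraction in these records.

Relative permittivity is eps_r = n^2 exactly; bulk voxels only ever take
values from the material table.  Absorption and dispersion are not modeled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
from numba import njit
from scipy import ndimage

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_geometry import ConeModel

__all__ = [
    "MaterialTable",
    "CristaeSpec",
    "DielectricGrid",
    "voxelize_mesh",
    "assign_materials",
    "evaluate_cristae",
    "subpixel_tensor",
    "ablate",
    "extend_base",
    "uniform_grid",
    "save_grid",
    "load_grid",
]

# material label codes
EXTRACELLULAR, CYTOPLASM, MITOCHONDRION, MATRIX, INTRAMEMBRANE, INTERNAL_MEMBRANE = range(6)

ABLATION_MODES = ("intact", "no_mitochondria", "mitochondria_only")


@dataclass(frozen=True)
class MaterialTable:
    """Refractive indices of the cone's optical compartments (dimensionless)."""

    n_extracellular: float = 1.34
    n_cytoplasm: float = 1.36
    n_mitochondrion: float = 1.40
    n_membrane: float = 1.46
    n_matrix: float = 1.41          # cristae mode: inner matrix
    n_intramembrane: float = 1.37   # cristae mode: intramembrane space
    membrane_thickness_um: float = 0.010

    def __post_init__(self) -> None:
        for name in ("n_extracellular", "n_cytoplasm", "n_mitochondrion",
                     "n_membrane", "n_matrix", "n_intramembrane"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if self.membrane_thickness_um <= 0:
            raise ValueError("membrane_thickness_um must be positive")

    def eps_by_label(self) -> np.ndarray:
        """eps_r = n^2 for label codes 0..5."""
        n = np.array([self.n_extracellular, self.n_cytoplasm, self.n_mitochondrion,
                      self.n_matrix, self.n_intramembrane, self.n_membrane])
        return n ** 2

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, s: str) -> "MaterialTable":
        return cls(**json.loads(s))


@dataclass
class CristaeSpec:
    """Random cosine-sum field partitioning a mitochondrion's interior.

    f(p) = sum_i A_i cos(2 pi k_i . p + phi_i); matrix where f > 0,
    intramembrane space where f < 0, internal membrane where
    |f| / ||grad f|| < membrane_halfwidth (5 nm by default).
    """

    frequencies: np.ndarray       # (T, 3) um^-1
    phases: np.ndarray            # (T,) rad
    amplitudes: np.ndarray        # (T,)
    membrane_halfwidth_um: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.atleast_2d(np.asarray(self.frequencies, float))
        self.phases = np.atleast_1d(np.asarray(self.phases, float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, float))
        if len(self.frequencies) < 1:
            raise ValueError("need at least one cosine term")

    def evaluate(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (f, ||grad f||) at the given (N, 3) points."""
        p = np.atleast_2d(np.asarray(points, float))
        arg = 2 * np.pi * (p @ self.frequencies.T) + self.phases  # (N, T)
        f = np.cos(arg) @ self.amplitudes
        # grad f = sum_i -2 pi A_i k_i sin(arg_i)
        s = np.sin(arg) * self.amplitudes                          # (N, T)
        grad = -2 * np.pi * (s @ self.frequencies)                 # (N, 3)
        return f, np.linalg.norm(grad, axis=1)


def evaluate_cristae(spec: CristaeSpec, points: np.ndarray) -> np.ndarray:
    """Compartment labels at points inside a mitochondrion.

    Returns MATRIX / INTRAMEMBRANE / INTERNAL_MEMBRANE codes.  Degenerate
    points where the gradient vanishes inside the membrane band are assigned
    by the sign of f alone (a measure-zero set).
    """
    f, gnorm = spec.evaluate(points)
    labels = np.where(f > 0, MATRIX, INTRAMEMBRANE).astype(np.uint8)
    ok = gnorm > 1e-12
    band = ok & (np.abs(f) / np.where(ok, gnorm, 1.0) < spec.membrane_halfwidth_um)
    labels[band] = INTERNAL_MEMBRANE
    return labels


# ---------------------------------------------------------------------------
# voxelization


@njit(cache=True)
def _crossing_counts(tri, x0, y0, z0, h, nx, ny, nz):
    """Count, per fine lattice point column, upward ray crossings below each z.

    Fine points sit at (x0 + (i+.5) h, y0 + (j+.5) h, z0 + (k+.5) h).  For each
    triangle, every column whose (x, y) projects strictly inside it adds one
    crossing at the triangle plane height; crossings accumulate at the first
    fine index above that height.  Parity of the z-cumulative sum gives
    inside/outside.
    """
    cnt = np.zeros((nx, ny, nz + 1), dtype=np.int16)
    for t in range(tri.shape[0]):
        ax, ay, az = tri[t, 0, 0], tri[t, 0, 1], tri[t, 0, 2]
        bx, by, bz = tri[t, 1, 0], tri[t, 1, 1], tri[t, 1, 2]
        cx, cy, cz = tri[t, 2, 0], tri[t, 2, 1], tri[t, 2, 2]
        # projected signed area; skip triangles vertical in z
        area2 = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        if abs(area2) < 1e-14:
            continue
        xmin = min(ax, min(bx, cx))
        xmax = max(ax, max(bx, cx))
        ymin = min(ay, min(by, cy))
        ymax = max(ay, max(by, cy))
        i0 = max(0, int(np.ceil((xmin - x0) / h - 0.5)))
        i1 = min(nx - 1, int(np.floor((xmax - x0) / h - 0.5)))
        j0 = max(0, int(np.ceil((ymin - y0) / h - 0.5)))
        j1 = min(ny - 1, int(np.floor((ymax - y0) / h - 0.5)))
        inv = 1.0 / area2
        for i in range(i0, i1 + 1):
            px = x0 + (i + 0.5) * h
            for j in range(j0, j1 + 1):
                py = y0 + (j + 0.5) * h
                # barycentric coordinates in the xy projection
                w0 = ((bx - px) * (cy - py) - (by - py) * (cx - px)) * inv
                w1 = ((cx - px) * (ay - py) - (cy - py) * (ax - px)) * inv
                w2 = 1.0 - w0 - w1
                if w0 < 0.0 or w1 < 0.0 or w2 < 0.0:
                    continue
                zc = w0 * az + w1 * bz + w2 * cz
                k = int(np.ceil((zc - z0) / h - 0.5))
                if k < 0:
                    k = 0
                if k <= nz:
                    cnt[i, j, k] += 1
    return cnt


@dataclass
class Voxelization:
    """Occupancy of one mesh on the simulation lattice."""

    fill: np.ndarray           # (nx, ny, nz) float32 volumetric fill fraction
    resolution: float          # simulation voxels per um
    origin: np.ndarray         # um, corner of voxel (0,0,0)

    @property
    def occupied_volume_um3(self) -> float:
        return float(self.fill.sum()) / self.resolution ** 3


def voxelize_mesh(mesh, resolution: float, bounds: np.ndarray,
                  jitter: float = 1e-6, clip: bool = False) -> Voxelization:
    """Voxelize a watertight mesh at double resolution onto the lattice defined
    by ``bounds`` (2x3 array, um) and ``resolution`` (voxels per um).

    Each simulation voxel's fill fraction is the mean of its 2x2x2 fine-point
    occupancies.  A tiny lattice jitter avoids rays hitting edges exactly.
    With ``clip=True`` the mesh may extend outside the bounds and only the
    in-bounds occupancy is returned (used for thin-slab 2D conversions);
    otherwise an out-of-bounds mesh is an error.
    """
    if not mesh.is_watertight:
        raise ValueError("refusing to voxelize a non-watertight mesh")
    bounds = np.asarray(bounds, float)
    out = (np.any(mesh.bounds[0] < bounds[0] - 1e-9)
           or np.any(mesh.bounds[1] > bounds[1] + 1e-9))
    if out and not clip:
        raise ValueError("mesh extends outside the requested bounds")
    dx = 1.0 / resolution
    h = dx / 2.0
    shape = np.maximum(np.round((bounds[1] - bounds[0]) / dx), 1).astype(int)
    origin = bounds[0]
    tri = mesh.triangles.astype(np.float64)
    off = origin + jitter * dx * np.array([1.0, np.sqrt(2.0), np.sqrt(3.0)])
    cnt = _crossing_counts(tri, off[0], off[1], off[2], h,
                           2 * shape[0], 2 * shape[1], 2 * shape[2])
    occ = (np.cumsum(cnt[:, :, :-1], axis=2) % 2).astype(np.float32)
    fill = occ.reshape(shape[0], 2, shape[1], 2, shape[2], 2).mean(axis=(1, 3, 5))
    return Voxelization(fill=fill.astype(np.float32), resolution=float(resolution),
                        origin=origin.copy())


def _voxelize_into(mesh, resolution: float, bounds: np.ndarray,
                   target: np.ndarray, accumulate: str = "max") -> None:
    """Voxelize ``mesh`` over its own (lattice-snapped) sub-box of ``bounds``
    and paste the fill into ``target``; keeps fine-grid memory local."""
    dx = 1.0 / resolution
    lo = np.floor((np.maximum(mesh.bounds[0] - 2 * dx, bounds[0]) - bounds[0]) / dx)
    hi = np.ceil((np.minimum(mesh.bounds[1] + 2 * dx, bounds[1]) - bounds[0]) / dx)
    lo = lo.astype(int)
    hi = np.minimum(hi.astype(int), target.shape)
    if np.any(hi <= lo):
        return
    sub_bounds = np.array([bounds[0] + lo * dx, bounds[0] + hi * dx])
    vox = voxelize_mesh(mesh, resolution, sub_bounds, clip=True)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    if accumulate == "max":
        np.maximum(target[sl], vox.fill, out=target[sl])
    else:
        target[sl] += vox.fill


def _interface_normals(fill: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Outward unit normals at interface voxels from the smoothed fill gradient.

    The fill gradient points from outside (fill 0) toward inside (fill 1); the
    outward surface normal is its negation.  Exact for axis-aligned faces,
    accurate to a few degrees on smooth curved surfaces.
    """
    sm = ndimage.gaussian_filter(fill, sigma=1.0, mode="nearest")
    grads = np.gradient(sm)
    g = np.stack([gr[idx[:, 0], idx[:, 1], idx[:, 2]] for gr in grads], axis=1)
    norm = np.linalg.norm(g, axis=1)
    norm[norm == 0] = 1.0
    n = -g / norm[:, None]
    return n.astype(np.float32)


# ---------------------------------------------------------------------------
# the grid


@dataclass
class DielectricGrid:
    """Voxel lattice of relative permittivity with interface records.

    ``eps`` holds bulk values (exactly n^2 of a table entry per voxel);
    sub-voxel structure lives in the interface record arrays.  The per-mesh
    fill fractions are retained so ablation variants re-skin material indices
    without re-voxelizing.
    """

    resolution: float
    origin: np.ndarray
    labels: np.ndarray                    # (nx, ny, nz) uint8 material codes
    eps: np.ndarray                       # (nx, ny, nz) float32 bulk eps_r
    table: MaterialTable
    fill_envelope: np.ndarray | None = None
    fill_mito: np.ndarray | None = None
    # interface record arrays (N records)
    if_index: np.ndarray = field(default_factory=lambda: np.empty((0, 3), np.int32))
    if_normal: np.ndarray = field(default_factory=lambda: np.empty((0, 3), np.float32))
    if_fill: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    if_eps_in: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    if_eps_out: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    if_mem_fraction: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    if_eps_mem: np.ndarray = field(default_factory=lambda: np.empty(0, np.float32))
    mode: str = "intact"
    cristae: CristaeSpec | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple:
        return self.eps.shape

    @property
    def dx(self) -> float:
        return 1.0 / self.resolution

    def extent_um(self) -> np.ndarray:
        return np.asarray(self.shape) * self.dx

    def voxel_centers_z(self) -> np.ndarray:
        return self.origin[2] + (np.arange(self.shape[2]) + 0.5) * self.dx

    def yee_eps_3d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Diagonal effective permittivity per voxel for the Yee update.

        Interface voxels get the diagonal projection of their subpixel tensor:
        eps_aa = eps_perp n_a^2 + eps_par (1 - n_a^2).
        """
        base = self.eps.astype(np.float32)
        epsx, epsy, epsz = base.copy(), base.copy(), base.copy()
        if len(self.if_index):
            perp, par = _mixing_eps(self.if_fill, self.if_eps_in, self.if_eps_out,
                                    self.if_mem_fraction, self.if_eps_mem)
            n2 = self.if_normal.astype(np.float64) ** 2
            i, j, k = self.if_index.T
            for axis, arr in enumerate((epsx, epsy, epsz)):
                arr[i, j, k] = (perp * n2[:, axis] + par * (1.0 - n2[:, axis])
                                ).astype(np.float32)
        return epsx, epsy, epsz

    def yee_eps_2d(self) -> np.ndarray:
        """Out-of-plane (Ey) permittivity on the central XZ slice.

        The out-of-plane direction is tangential to every interface, so the
        subpixel value is the fill-weighted arithmetic mean.
        """
        jmid = self.shape[1] // 2
        eps = self.eps[:, jmid, :].astype(np.float32).copy()
        if len(self.if_index):
            sel = self.if_index[:, 1] == jmid
            if sel.any():
                _, par = _mixing_eps(self.if_fill[sel], self.if_eps_in[sel],
                                     self.if_eps_out[sel], self.if_mem_fraction[sel],
                                     self.if_eps_mem[sel])
                i, _, k = self.if_index[sel].T
                eps[i, k] = par.astype(np.float32)
        return eps


def _mixing_eps(fill, eps_in, eps_out, mem_fraction, eps_mem):
    """Three-phase fill-weighted harmonic (perp) and arithmetic (par) means."""
    fill = np.asarray(fill, np.float64)
    f_mem = np.clip(np.asarray(mem_fraction, np.float64), 0.0, 1.0)
    f_in = np.clip(fill - f_mem / 2.0, 0.0, None)
    f_out = np.clip(1.0 - fill - f_mem / 2.0, 0.0, None)
    tot = f_in + f_out + f_mem
    f_in, f_out, f_mem = f_in / tot, f_out / tot, f_mem / tot
    e_in = np.asarray(eps_in, np.float64)
    e_out = np.asarray(eps_out, np.float64)
    e_mem = np.where(f_mem > 0, np.asarray(eps_mem, np.float64), 1.0)
    perp = 1.0 / (f_in / e_in + f_out / e_out + f_mem / e_mem)
    par = f_in * e_in + f_out * e_out + f_mem * e_mem
    return perp, par


def subpixel_tensor(record: dict) -> np.ndarray:
    """3x3 effective permittivity tensor of one interface record.

    ``record`` needs ``normal``, ``fill_fraction``, ``eps_in``, ``eps_out``;
    optional ``mem_fraction`` and ``eps_mem`` add the 10-nm membrane phase.
    The normal component is the (fill-weighted) harmonic mean, the tangential
    components the arithmetic mean; the tensor is symmetric positive-definite
    with eigenvalues between the extreme phase permittivities.
    """
    n = np.asarray(record["normal"], float)
    n = n / np.linalg.norm(n)
    perp, par = _mixing_eps(
        np.atleast_1d(record["fill_fraction"]),
        np.atleast_1d(record["eps_in"]), np.atleast_1d(record["eps_out"]),
        np.atleast_1d(record.get("mem_fraction", 0.0)),
        np.atleast_1d(record.get("eps_mem", 1.0)))
    perp, par = float(perp[0]), float(par[0])
    P = np.outer(n, n)
    return perp * P + par * (np.eye(3) - P)


# ---------------------------------------------------------------------------
# material assignment


def assign_materials(model: "ConeModel", table: MaterialTable, resolution: float,
                     cristae: CristaeSpec | None = None,
                     bounds: np.ndarray | None = None,
                     mode: str = "intact") -> DielectricGrid:
    """Voxelize a ConeModel and assign permittivities.

    Material priority per voxel: mitochondrial membrane (interface record) >
    mitochondrial interior (uniform or cristae compartments) > envelope
    membrane (interface record) > cytoplasm > extracellular.
    """
    meshes = model.all_meshes() if model.envelope is not None else model.mitochondria
    if bounds is None:
        if not meshes:
            raise ValueError("empty model needs explicit bounds")
        mb = np.array([m.bounds for m in meshes])
        bounds = np.array([mb[:, 0].min(axis=0) - 0.25, mb[:, 1].max(axis=0) + 0.25])
    bounds = np.asarray(bounds, float)

    shape = tuple(np.maximum(np.round((bounds[1] - bounds[0]) * resolution), 1).astype(int))
    fill_env = np.zeros(shape, np.float32)
    if model.envelope is not None:
        _voxelize_into(model.envelope, resolution, bounds, fill_env, accumulate="max")
    fill_mito = np.zeros(shape, np.float32)
    if model.mitochondria:
        interior_count = np.zeros(shape, np.int8)
        for m in model.mitochondria:
            v = np.zeros(shape, np.float32)
            _voxelize_into(m, resolution, bounds, v, accumulate="max")
            np.maximum(fill_mito, v, out=fill_mito)
            interior_count += (v >= 0.5)
        if interior_count.max() > 1:
            warnings.warn("overlapping mitochondrion meshes; priority by list order")
    grid = _skin(fill_env, fill_mito, table, resolution, bounds[0], cristae, mode)
    grid.provenance = {"tilt_deg": getattr(model, "tilt_deg", 0.0),
                       "distal_tip": list(np.asarray(getattr(model, "distal_tip",
                                                             (0, 0, 0)), float))}
    return grid


def _skin(fill_env, fill_mito, table, resolution, origin, cristae, mode):
    """Assign labels, bulk eps, and interface records from stored fills."""
    if mode not in ABLATION_MODES:
        raise ValueError(f"unknown ablation mode {mode!r}")
    if mode == "no_mitochondria":
        fill_mito = np.zeros_like(fill_mito)
    if mode == "mitochondria_only":
        fill_env = np.zeros_like(fill_env)

    eps_of = table.eps_by_label()
    dx = 1.0 / resolution
    labels = np.zeros(fill_env.shape, np.uint8)
    env_in = fill_env >= 0.5
    mito_in = fill_mito >= 0.5
    labels[env_in] = CYTOPLASM
    if cristae is None:
        labels[mito_in] = MITOCHONDRION
    else:
        idx = np.argwhere(mito_in)
        pts = origin + (idx + 0.5) * dx
        labels[mito_in] = evaluate_cristae(cristae, pts)
    eps = eps_of[labels].astype(np.float32)

    mem_frac = np.float32(min(table.membrane_thickness_um / dx, 1.0))
    eps_mem = np.float32(table.n_membrane ** 2)

    recs = []
    mito_if = (fill_mito > 0.0) & (fill_mito < 1.0)
    if mito_if.any():
        idx = np.argwhere(mito_if).astype(np.int32)
        normals = _interface_normals(fill_mito, idx)
        f = fill_mito[mito_if].astype(np.float32)
        if cristae is None:
            e_in = np.full(len(idx), eps_of[MITOCHONDRION], np.float32)
        else:
            pts = origin + (idx + 0.5) * dx
            e_in = eps_of[evaluate_cristae(cristae, pts)].astype(np.float32)
        e_out = np.where(env_in[tuple(idx.T)], eps_of[CYTOPLASM],
                         eps_of[EXTRACELLULAR]).astype(np.float32)
        recs.append((idx, normals, f, e_in, e_out,
                     np.full(len(idx), mem_frac, np.float32),
                     np.full(len(idx), eps_mem, np.float32)))
    env_if = (fill_env > 0.0) & (fill_env < 1.0) & ~mito_in & ~mito_if
    if env_if.any():
        idx = np.argwhere(env_if).astype(np.int32)
        normals = _interface_normals(fill_env, idx)
        f = fill_env[env_if].astype(np.float32)
        recs.append((idx, normals, f,
                     np.full(len(idx), eps_of[CYTOPLASM], np.float32),
                     np.full(len(idx), eps_of[EXTRACELLULAR], np.float32),
                     np.full(len(idx), mem_frac, np.float32),
                     np.full(len(idx), eps_mem, np.float32)))
    if recs:
        cat = [np.concatenate(a) for a in zip(*recs)]
    else:
        cat = [np.empty((0, 3), np.int32), np.empty((0, 3), np.float32)] + \
              [np.empty(0, np.float32)] * 5
    return DielectricGrid(
        resolution=float(resolution), origin=np.asarray(origin, float),
        labels=labels, eps=eps, table=table,
        fill_envelope=fill_env.astype(np.float32),
        fill_mito=fill_mito.astype(np.float32),
        if_index=cat[0], if_normal=cat[1], if_fill=cat[2], if_eps_in=cat[3],
        if_eps_out=cat[4], if_mem_fraction=cat[5], if_eps_mem=cat[6],
        mode=mode, cristae=cristae)


def ablate(grid: DielectricGrid, mode: str) -> DielectricGrid:
    """Re-skin a grid under an ablation mode without re-voxelizing.

    ``no_mitochondria`` reassigns mitochondrial voxels (and their membranes) to
    cytoplasm; ``mitochondria_only`` strips the envelope, leaving mitochondria
    and their membranes in extracellular medium.
    """
    if mode not in ABLATION_MODES:
        raise ValueError(f"unknown ablation mode {mode!r}")
    if mode == "intact" and grid.mode == "intact":
        return grid
    if grid.fill_envelope is None or grid.fill_mito is None:
        raise ValueError("grid carries no stored fills; cannot re-skin")
    out = _skin(grid.fill_envelope, grid.fill_mito, grid.table, grid.resolution,
                grid.origin, grid.cristae, mode)
    out.provenance = dict(grid.provenance)
    return out


def extend_base(grid: DielectricGrid, pad_above_um: float = 0.0) -> DielectricGrid:
    """Tile the proximal-most occupied layer down to z = 0.

    Mirrors the continuous homogeneous base below the model; optionally pads
    extra extracellular space above.  No-op (with a warning) when the model
    already reaches the bottom of the lattice.
    """
    if grid.fill_envelope is None:
        raise ValueError("grid carries no stored fills")
    occ = np.maximum(grid.fill_envelope, grid.fill_mito)
    occupied_z = np.argwhere(occ.any(axis=(0, 1))).ravel()
    fe, fm = grid.fill_envelope.copy(), grid.fill_mito.copy()
    if len(occupied_z) == 0 or occupied_z[0] == 0:
        if len(occupied_z) and occupied_z[0] == 0:
            warnings.warn("model already reaches the lattice base; extend_base is a no-op")
    else:
        k0 = occupied_z[0]
        fe[:, :, :k0] = fe[:, :, k0:k0 + 1]
        fm[:, :, :k0] = fm[:, :, k0:k0 + 1]
    if pad_above_um > 0:
        pad = int(round(pad_above_um * grid.resolution))
        zpad = ((0, 0), (0, 0), (0, pad))
        fe = np.pad(fe, zpad)
        fm = np.pad(fm, zpad)
    out = _skin(fe, fm, grid.table, grid.resolution, grid.origin,
                grid.cristae, grid.mode)
    out.provenance = dict(grid.provenance)
    return out


def uniform_grid(shape, resolution: float, n: float = 1.34,
                 origin=(0.0, 0.0, 0.0)) -> DielectricGrid:
    """Homogeneous lattice at refractive index ``n`` (the 'empty' background)."""
    table = MaterialTable(n_extracellular=n)
    labels = np.zeros(tuple(shape), np.uint8)
    eps = np.full(tuple(shape), n ** 2, np.float32)
    return DielectricGrid(resolution=float(resolution),
                          origin=np.asarray(origin, float),
                          labels=labels, eps=eps, table=table,
                          fill_envelope=np.zeros(tuple(shape), np.float32),
                          fill_mito=np.zeros(tuple(shape), np.float32))


# ---------------------------------------------------------------------------
# persistence (chunked HDF5 container; fills retained for re-skinning)


def save_grid(grid: DielectricGrid, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["resolution"] = grid.resolution
        f.attrs["origin"] = grid.origin
        f.attrs["mode"] = grid.mode
        f.attrs["table"] = grid.table.to_json()
        f.create_dataset("labels", data=grid.labels, compression="gzip")
        f.create_dataset("eps", data=grid.eps, compression="gzip")
        for name in ("fill_envelope", "fill_mito"):
            arr = getattr(grid, name)
            if arr is not None:
                f.create_dataset(name, data=arr, compression="gzip")
        g = f.create_group("interfaces")
        for name in ("if_index", "if_normal", "if_fill", "if_eps_in",
                     "if_eps_out", "if_mem_fraction", "if_eps_mem"):
            g.create_dataset(name, data=getattr(grid, name))
        if grid.cristae is not None:
            c = f.create_group("cristae")
            c.create_dataset("frequencies", data=grid.cristae.frequencies)
            c.create_dataset("phases", data=grid.cristae.phases)
            c.create_dataset("amplitudes", data=grid.cristae.amplitudes)
            c.attrs["membrane_halfwidth_um"] = grid.cristae.membrane_halfwidth_um


def load_grid(path) -> DielectricGrid:
    import h5py

    with h5py.File(path, "r") as f:
        cristae = None
        if "cristae" in f:
            c = f["cristae"]
            cristae = CristaeSpec(
                frequencies=c["frequencies"][()], phases=c["phases"][()],
                amplitudes=c["amplitudes"][()],
                membrane_halfwidth_um=float(c.attrs["membrane_halfwidth_um"]))
        kw = {}
        for name in ("fill_envelope", "fill_mito"):
            kw[name] = f[name][()] if name in f else None
        g = f["interfaces"]
        return DielectricGrid(
            resolution=float(f.attrs["resolution"]),
            origin=np.asarray(f.attrs["origin"], float),
            labels=f["labels"][()], eps=f["eps"][()],
            table=MaterialTable.from_json(f.attrs["table"]),
            mode=str(f.attrs["mode"]), cristae=cristae,
            if_index=g["if_index"][()], if_normal=g["if_normal"][()],
            if_fill=g["if_fill"][()], if_eps_in=g["if_eps_in"][()],
            if_eps_out=g["if_eps_out"][()],
            if_mem_fraction=g["if_mem_fraction"][()],
            if_eps_mem=g["if_eps_mem"][()], **kw)
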