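"""Finite-difference time-domain propagation of a CW plane wave.

Maxwell's curl equations are leapfrogged on a Yee lattice in natural units
(length unit = 1 um, time unit = 1 um / c0, eps0 = mu0 = 1), so a source
wavelength of 450 nm is 0.45 length units and one optical period 0.45 time
units.  Light is launched as a soft additive current source on a full-width
plane (Ex-polarized in 3D; out-of-plane E in the 2D XZ mode, whose focusing is
cylindrical-lens-like and is used for fast oracles).  All outer boundaries
carry a polynomial-graded convolutional PML; the 2D mode can instead be
periodic in x, which reduces exactly to 1D plane-wave propagation for
laterally uniform media.

Interface voxels use the diagonal projection of their subpixel-averaged
permittivity tensors (``DielectricGrid.yee_eps_*``).  The exported energy
density u = (eps |E|^2 + |H|^2) / 2 is averaged over the final full optical
cycle of the fixed-duration run; output is deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dielectric_grid import DielectricGrid, uniform_grid

__all__ = [
    "SourceSpec",
    "RunSpec",
    "EnergyDensityVolume",
    "FS_PER_TIME_UNIT",
    "time_units_to_fs",
    "grid_spacing_nm",
    "run_fdtd",
    "run_background",
]

C0_M_PER_S = 299792458.0
FS_PER_TIME_UNIT = 1e-6 / C0_M_PER_S * 1e15  # 3.33564... fs per (1 um)/c0


def time_units_to_fs(duration: float, length_unit_um: float = 1.0) -> float:
    """Physical time of a simulation duration (time unit = length unit / c0)."""
    return duration * length_unit_um * FS_PER_TIME_UNIT


def grid_spacing_nm(resolution: float, length_unit_um: float = 1.0) -> float:
    """Grid spacing in nm for ``resolution`` steps per length unit."""
    return 1000.0 * length_unit_um / resolution


class StabilityError(ValueError):
    pass


class NumericalError(RuntimeError):
    pass


@dataclass
class SourceSpec:
    """Continuous-wave, linearly polarized plane current source."""

    wavelength_nm: float = 450.0
    polarization: str = "Ex"
    source_plane_z: float = 9.0    # um; 9 = "close source", 5 = "far source"
    amplitude: float = 1.0
    ramp_cycles: float = 3.0       # smooth turn-on to suppress transients
    pulse_cycles: float | None = None  # finite wave train (None = CW)

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.polarization != "Ex":
            raise ValueError("only Ex polarization is supported")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm / 1000.0

    @property
    def frequency(self) -> float:  # per time unit (c0 = 1)
        return 1.0 / self.wavelength_um


@dataclass
class RunSpec:
    """Run control: fixed duration, Courant factor, PML, dimensionality."""

    duration: float = 50.0         # time units; 50 units = 166.78 fs
    courant: float = 0.5
    pml_um: float = 1.0
    dimensionality: int = 3
    x_boundary: str = "pml"        # 2D only: "pml" | "periodic"
    average_cycles: float = 1.0    # energy-density averaging window

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        limit = 1.0 / np.sqrt(self.dimensionality)
        if not 0 < self.courant <= limit + 1e-12:
            raise StabilityError(
                f"courant {self.courant} violates the {self.dimensionality}D "
                f"stability bound {limit:.4f}")


@dataclass
class EnergyDensityVolume:
    """Cycle-averaged EM energy density paired with its eps_r volume."""

    values: np.ndarray             # (nx, ny, nz) or (nx, nz), >= 0
    eps: np.ndarray                # same shape: cell-centered bulk eps_r
    resolution: float
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def dx(self) -> float:
        return 1.0 / self.resolution


# ---------------------------------------------------------------------------
# CPML coefficients

_PML_M = 3.0
_PML_ALPHA = 0.05
_PML_SIGMA_FACTOR = 0.8  # sigma_max = factor * (m + 1) / dx


def _pml_profiles(n: int, npml: int, dx: float, dt: float):
    """(b, c) arrays at integer (E) and half-integer (H) positions along an axis."""
    sigma_max = _PML_SIGMA_FACTOR * (_PML_M + 1.0) / dx

    def bc(pos):
        depth = np.maximum.reduce([
            npml - pos, pos - (n - 1 - npml), np.zeros_like(pos)]) / max(npml, 1)
        sigma = sigma_max * depth ** _PML_M
        b = np.exp(-(sigma + _PML_ALPHA) * dt)
        c = np.where(sigma > 0, sigma * (b - 1.0) / (sigma + _PML_ALPHA), 0.0)
        b = np.where(sigma > 0, b, 1.0)
        return b.astype(np.float32), c.astype(np.float32)

    idx = np.arange(n, dtype=np.float64)
    be, ce = bc(idx)
    bh, ch = bc(idx + 0.5)
    if npml == 0:
        be = bh = np.ones(n, np.float32)
        ce = ch = np.zeros(n, np.float32)
    return be, ce, bh, ch


# ---------------------------------------------------------------------------
# 2D kernels (XZ plane, out-of-plane E)


@njit(cache=True)
def _step_h_2d(Ey, Hx, Hz, dt, inv, periodic_x,
               bhx, chx, bhz, chz, psi_hx, psi_hz):
    nx, nz = Ey.shape
    for i in range(nx):
        for k in range(nz - 1):
            d = (Ey[i, k + 1] - Ey[i, k]) * inv
            if chz[k] != 0.0:
                psi_hx[i, k] = bhz[k] * psi_hx[i, k] + chz[k] * d
                d += psi_hx[i, k]
            Hx[i, k] += dt * d
    ilim = nx if periodic_x else nx - 1
    for i in range(ilim):
        i2 = (i + 1) % nx
        ci = chx[i]
        bi = bhx[i]
        for k in range(nz):
            d = (Ey[i2, k] - Ey[i, k]) * inv
            if ci != 0.0:
                psi_hz[i, k] = bi * psi_hz[i, k] + ci * d
                d += psi_hz[i, k]
            Hz[i, k] -= dt * d


@njit(cache=True)
def _step_e_2d(Ey, Hx, Hz, eps, dt, inv, periodic_x,
               bex, cex, bez, cez, psi_ez, psi_ex):
    nx, nz = Ey.shape
    i0, i1 = (0, nx) if periodic_x else (1, nx - 1)
    for i in range(i0, i1):
        im = (i - 1) % nx
        ci = cex[i]
        bi = bex[i]
        for k in range(1, nz - 1):
            dz = (Hx[i, k] - Hx[i, k - 1]) * inv
            if cez[k] != 0.0:
                psi_ez[i, k] = bez[k] * psi_ez[i, k] + cez[k] * dz
                dz += psi_ez[i, k]
            dxh = (Hz[i, k] - Hz[im, k]) * inv
            if ci != 0.0:
                psi_ex[i, k] = bi * psi_ex[i, k] + ci * dxh
                dxh += psi_ex[i, k]
            Ey[i, k] += dt * (dz - dxh) / eps[i, k]


@njit(cache=True)
def _accum_u_2d(Ey, Hx, Hz, eps, usum):
    nx, nz = Ey.shape
    for i in range(nx):
        for k in range(nz):
            usum[i, k] += 0.5 * (eps[i, k] * Ey[i, k] * Ey[i, k]
                                 + Hx[i, k] * Hx[i, k] + Hz[i, k] * Hz[i, k])


# ---------------------------------------------------------------------------
# 3D kernels (Ex polarization)


@njit(cache=True)
def _step_h_3d(Ex, Ey, Ez, Hx, Hy, Hz, dt, inv,
               bhx, chx, bhy, chy, bhz, chz,
               p_hx_y, p_hx_z, p_hy_z, p_hy_x, p_hz_x, p_hz_y):
    nx, ny, nz = Ex.shape
    for i in range(nx):
        cix = chx[i]
        bix = bhx[i]
        for j in range(ny):
            cjy = chy[j]
            bjy = bhy[j]
            for k in range(nz):
                ckz = chz[k]
                bkz = bhz[k]
                # Hx needs dEz/dy, dEy/dz
                if j < ny - 1 and k < nz - 1:
                    dzy = (Ez[i, j + 1, k] - Ez[i, j, k]) * inv
                    dyz = (Ey[i, j, k + 1] - Ey[i, j, k]) * inv
                    if cjy != 0.0:
                        p_hx_y[i, j, k] = bjy * p_hx_y[i, j, k] + cjy * dzy
                        dzy += p_hx_y[i, j, k]
                    if ckz != 0.0:
                        p_hx_z[i, j, k] = bkz * p_hx_z[i, j, k] + ckz * dyz
                        dyz += p_hx_z[i, j, k]
                    Hx[i, j, k] -= dt * (dzy - dyz)
                # Hy needs dEx/dz, dEz/dx
                if i < nx - 1 and k < nz - 1:
                    dxz = (Ex[i, j, k + 1] - Ex[i, j, k]) * inv
                    dzx = (Ez[i + 1, j, k] - Ez[i, j, k]) * inv
                    if ckz != 0.0:
                        p_hy_z[i, j, k] = bkz * p_hy_z[i, j, k] + ckz * dxz
                        dxz += p_hy_z[i, j, k]
                    if cix != 0.0:
                        p_hy_x[i, j, k] = bix * p_hy_x[i, j, k] + cix * dzx
                        dzx += p_hy_x[i, j, k]
                    Hy[i, j, k] -= dt * (dxz - dzx)
                # Hz needs dEy/dx, dEx/dy
                if i < nx - 1 and j < ny - 1:
                    dyx = (Ey[i + 1, j, k] - Ey[i, j, k]) * inv
                    dxy = (Ex[i, j + 1, k] - Ex[i, j, k]) * inv
                    if cix != 0.0:
                        p_hz_x[i, j, k] = bix * p_hz_x[i, j, k] + cix * dyx
                        dyx += p_hz_x[i, j, k]
                    if cjy != 0.0:
                        p_hz_y[i, j, k] = bjy * p_hz_y[i, j, k] + cjy * dxy
                        dxy += p_hz_y[i, j, k]
                    Hz[i, j, k] -= dt * (dyx - dxy)


@njit(cache=True)
def _step_e_3d(Ex, Ey, Ez, Hx, Hy, Hz, epsx, epsy, epsz, dt, inv,
               bex, cex, bey, cey, bez, cez,
               p_ex_y, p_ex_z, p_ey_z, p_ey_x, p_ez_x, p_ez_y):
    nx, ny, nz = Ex.shape
    for i in range(nx):
        cix = cex[i]
        bix = bex[i]
        for j in range(ny):
            cjy = cey[j]
            bjy = bey[j]
            for k in range(nz):
                ckz = cez[k]
                bkz = bez[k]
                # Ex needs dHz/dy, dHy/dz (PEC on the outer walls)
                if 0 < j < ny - 1 and 0 < k < nz - 1:
                    dzy = (Hz[i, j, k] - Hz[i, j - 1, k]) * inv
                    dyz = (Hy[i, j, k] - Hy[i, j, k - 1]) * inv
                    if cjy != 0.0:
                        p_ex_y[i, j, k] = bjy * p_ex_y[i, j, k] + cjy * dzy
                        dzy += p_ex_y[i, j, k]
                    if ckz != 0.0:
                        p_ex_z[i, j, k] = bkz * p_ex_z[i, j, k] + ckz * dyz
                        dyz += p_ex_z[i, j, k]
                    Ex[i, j, k] += dt * (dzy - dyz) / epsx[i, j, k]
                # Ey needs dHx/dz, dHz/dx
                if 0 < i < nx - 1 and 0 < k < nz - 1:
                    dxz = (Hx[i, j, k] - Hx[i, j, k - 1]) * inv
                    dzx = (Hz[i, j, k] - Hz[i - 1, j, k]) * inv
                    if ckz != 0.0:
                        p_ey_z[i, j, k] = bkz * p_ey_z[i, j, k] + ckz * dxz
                        dxz += p_ey_z[i, j, k]
                    if cix != 0.0:
                        p_ey_x[i, j, k] = bix * p_ey_x[i, j, k] + cix * dzx
                        dzx += p_ey_x[i, j, k]
                    Ey[i, j, k] += dt * (dxz - dzx) / epsy[i, j, k]
                # Ez needs dHy/dx, dHx/dy
                if 0 < i < nx - 1 and 0 < j < ny - 1:
                    dyx = (Hy[i, j, k] - Hy[i - 1, j, k]) * inv
                    dxy = (Hx[i, j, k] - Hx[i, j - 1, k]) * inv
                    if cix != 0.0:
                        p_ez_x[i, j, k] = bix * p_ez_x[i, j, k] + cix * dyx
                        dyx += p_ez_x[i, j, k]
                    if cjy != 0.0:
                        p_ez_y[i, j, k] = bjy * p_ez_y[i, j, k] + cjy * dxy
                        dxy += p_ez_y[i, j, k]
                    Ez[i, j, k] += dt * (dyx - dxy) / epsz[i, j, k]


@njit(cache=True)
def _accum_u_3d(Ex, Ey, Ez, Hx, Hy, Hz, epsx, epsy, epsz, usum):
    nx, ny, nz = Ex.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                usum[i, j, k] += 0.5 * (
                    epsx[i, j, k] * Ex[i, j, k] * Ex[i, j, k]
                    + epsy[i, j, k] * Ey[i, j, k] * Ey[i, j, k]
                    + epsz[i, j, k] * Ez[i, j, k] * Ez[i, j, k]
                    + Hx[i, j, k] * Hx[i, j, k]
                    + Hy[i, j, k] * Hy[i, j, k]
                    + Hz[i, j, k] * Hz[i, j, k])


def _averaging_steps(cycles: float, period: float, dt: float, nsteps: int) -> int:
    """Averaging window: at least ``cycles`` optical periods, extended to the
    multiple of the period (up to 4x) that best aligns with whole steps.

    A window misaligned by a fractional step leaves a residual standing
    ripple in the cycle-averaged energy density.
    """
    best, best_err = None, None
    k0 = max(1, int(np.ceil(cycles)))
    for k in range(k0, k0 + 4):
        steps = k * period / dt
        err = abs(steps - round(steps)) / steps
        if best is None or err < best_err - 1e-12:
            best, best_err = int(round(steps)), err
        if err < 1e-9:
            break
    return max(1, min(best, nsteps))


# ---------------------------------------------------------------------------
# drivers


def _source_index(source: SourceSpec, nz: int, dx: float, npml: int) -> int:
    ksrc = int(round(source.source_plane_z / dx - 0.5))
    if not npml < ksrc < nz - npml:
        raise ValueError(
            f"source plane z={source.source_plane_z} um lies outside the "
            "lattice interior (PML excluded)")
    return ksrc


def _source_waveform(source: SourceSpec, t: np.ndarray) -> np.ndarray:
    """Smoothly ramped CW (or finite wave-train) drive at E-update times."""
    omega = 2 * np.pi * source.frequency
    t_ramp = source.ramp_cycles * source.wavelength_um
    ramp = np.clip(t / max(t_ramp, 1e-12), 0.0, 1.0)
    env = np.sin(0.5 * np.pi * ramp) ** 2
    if source.pulse_cycles is not None:
        t_end = source.pulse_cycles * source.wavelength_um
        down = np.clip((t_end - t) / max(t_ramp, 1e-12), 0.0, 1.0)
        env = env * np.sin(0.5 * np.pi * down) ** 2
    return (source.amplitude * env * np.sin(omega * t)).astype(np.float32)


def run_fdtd(grid: DielectricGrid, source: SourceSpec, run: RunSpec,
             probes: np.ndarray | None = None) -> EnergyDensityVolume:
    """Propagate the CW source through the grid; export cycle-averaged energy
    density over the whole volume.

    ``probes`` is an optional (P, dim) integer index array; the E-field time
    series at those voxels is returned in ``meta['probe_series']``.
    """
    if run.dimensionality == 2:
        return _run_2d(grid, source, run, probes)
    return _run_3d(grid, source, run, probes)


def run_background(grid: DielectricGrid, source: SourceSpec, run: RunSpec,
                   n: float | None = None) -> EnergyDensityVolume:
    """Empty simulation paired with ``grid``: same lattice and source geometry,
    constant index (extracellular by default)."""
    n = grid.table.n_extracellular if n is None else n
    bg = uniform_grid(grid.shape, grid.resolution, n=n, origin=grid.origin)
    return run_fdtd(bg, source, run)


def _prep(run: RunSpec, resolution: float):
    dx = 1.0 / resolution
    dt = run.courant * dx
    nsteps = int(np.ceil(run.duration / dt))
    npml = int(round(run.pml_um * resolution))
    return dx, dt, nsteps, npml


def _run_2d(grid, source, run, probes):
    eps = grid.yee_eps_2d()
    nx, nz = eps.shape
    dx, dt, nsteps, npml = _prep(run, grid.resolution)
    periodic = run.x_boundary == "periodic"
    npml_x = 0 if periodic else npml
    ksrc = _source_index(source, nz, dx, npml)

    Ey = np.zeros((nx, nz), np.float32)
    Hx = np.zeros((nx, nz), np.float32)
    Hz = np.zeros((nx, nz), np.float32)
    psi_hx = np.zeros((nx, nz), np.float32)
    psi_hz = np.zeros((nx, nz), np.float32)
    psi_ez = np.zeros((nx, nz), np.float32)
    psi_ex = np.zeros((nx, nz), np.float32)
    bex, cex, bhx, chx = _pml_profiles(nx, npml_x, dx, dt)
    bez, cez, bhz, chz = _pml_profiles(nz, npml, dx, dt)

    usum = np.zeros((nx, nz), np.float64)
    n_avg = _averaging_steps(run.average_cycles, source.wavelength_um, dt, nsteps)
    t_e = (np.arange(nsteps) + 1) * dt
    wave = _source_waveform(source, t_e)
    series = (np.zeros((nsteps, len(probes)), np.float32)
              if probes is not None else None)

    inv = np.float32(1.0 / dx)
    dtf = np.float32(dt)
    for s in range(nsteps):
        _step_h_2d(Ey, Hx, Hz, dtf, inv, periodic, bhx, chx, bhz, chz,
                   psi_hx, psi_hz)
        _step_e_2d(Ey, Hx, Hz, eps, dtf, inv, periodic, bex, cex, bez, cez,
                   psi_ez, psi_ex)
        Ey[:, ksrc] += dtf * wave[s]
        if s >= nsteps - n_avg:
            _accum_u_2d(Ey, Hx, Hz, eps, usum)
        if series is not None:
            for p, (ip, kp) in enumerate(probes):
                series[s, p] = Ey[ip, kp]
    if not np.isfinite(Ey).all():
        raise NumericalError(f"field diverged (NaN/inf) within {nsteps} steps")
    values = (usum / n_avg).astype(np.float32)
    return EnergyDensityVolume(
        values=values, eps=eps, resolution=grid.resolution,
        origin=np.asarray(getattr(grid, "origin", np.zeros(3)), float),
        meta=_meta(source, run, dt, nsteps, npml, series))


def _run_3d(grid, source, run, probes):
    epsx, epsy, epsz = grid.yee_eps_3d()
    nx, ny, nz = epsx.shape
    dx, dt, nsteps, npml = _prep(run, grid.resolution)
    ksrc = _source_index(source, nz, dx, npml)

    F = [np.zeros((nx, ny, nz), np.float32) for _ in range(6)]
    Ex, Ey, Ez, Hx, Hy, Hz = F
    psis_h = [np.zeros((nx, ny, nz), np.float32) for _ in range(6)]
    psis_e = [np.zeros((nx, ny, nz), np.float32) for _ in range(6)]
    bex, cex, bhx, chx = _pml_profiles(nx, npml, dx, dt)
    bey, cey, bhy, chy = _pml_profiles(ny, npml, dx, dt)
    bez, cez, bhz, chz = _pml_profiles(nz, npml, dx, dt)

    usum = np.zeros((nx, ny, nz), np.float64)
    n_avg = _averaging_steps(run.average_cycles, source.wavelength_um, dt, nsteps)
    wave = _source_waveform(source, (np.arange(nsteps) + 1) * dt)
    series = (np.zeros((nsteps, len(probes)), np.float32)
              if probes is not None else None)

    inv = np.float32(1.0 / dx)
    dtf = np.float32(dt)
    for s in range(nsteps):
        _step_h_3d(Ex, Ey, Ez, Hx, Hy, Hz, dtf, inv,
                   bhx, chx, bhy, chy, bhz, chz, *psis_h)
        _step_e_3d(Ex, Ey, Ez, Hx, Hy, Hz, epsx, epsy, epsz, dtf, inv,
                   bex, cex, bey, cey, bez, cez, *psis_e)
        Ex[:, :, ksrc] += dtf * wave[s]
        if s >= nsteps - n_avg:
            _accum_u_3d(Ex, Ey, Ez, Hx, Hy, Hz, epsx, epsy, epsz, usum)
        if series is not None:
            for p, (ip, jp, kp) in enumerate(probes):
                series[s, p] = Ex[ip, jp, kp]
    if not np.isfinite(Ex).all():
        raise NumericalError(f"field diverged (NaN/inf) within {nsteps} steps")
    values = (usum / n_avg).astype(np.float32)
    return EnergyDensityVolume(
        values=values, eps=grid.eps.astype(np.float32), resolution=grid.resolution,
        origin=np.asarray(grid.origin, float),
        meta=_meta(source, run, dt, nsteps, npml, series))


def _meta(source, run, dt, nsteps, npml, series):
    meta = {
        "wavelength_nm": source.wavelength_nm,
        "source_plane_z": source.source_plane_z,
        "amplitude": source.amplitude,
        "duration": run.duration,
        "dt": dt,
        "n_steps": nsteps,
        "n_pml": npml,
        "elapsed_fs": time_units_to_fs(run.duration),
        "dimensionality": run.dimensionality,
    }
    if series is not None:
        meta["probe_series"] = series
        meta["probe_dt"] = dt
    return meta
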