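"""Yee-grid FDTD solver for steady-state RF fields in lossy dielectrics.

A standard uniform-grid finite-difference time-domain scheme: E components
live on cell edges, H components on cell faces, leapfrogged in time under
the CFL limit.  Impressed electric currents (the birdcage rungs) drive the
grid; perfect-conductor regions are realized by zeroed update coefficients;
the open ends of the domain carry an 8-cell graded, impedance-matched lossy
absorber inside the outer PEC box.

The solver runs to sinusoidal steady state, monitored by phase-locked field
energy once per drive period, then extracts complex phasors at the drive
frequency with a single-period discrete Fourier projection (convention
``f(t) = Re(F e^{+i w t})``, so ``|F|`` is the peak amplitude).

Time-critical loops are numba-compiled; everything is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

C0 = 299792458.0
EPS0 = 8.8541878128e-12
MU0 = 4e-7 * np.pi

__all__ = ["FdtdResult", "run_birdcage_fdtd", "solve_plane_wave_1d",
           "C0", "EPS0", "MU0"]


# --------------------------------------------------------------------------- kernels

@njit(cache=True)
def _step_h(Ex, Ey, Ez, Hx, Hy, Hz, daHx, dbHx, daHy, dbHy, daHz, dbHz,
            nx, ny, nz):
    for i in range(nx + 1):
        for j in range(ny):
            for k in range(nz):
                Hx[i, j, k] = daHx[i, j, k] * Hx[i, j, k] - dbHx[i, j, k] * (
                    (Ez[i, j + 1, k] - Ez[i, j, k]) - (Ey[i, j, k + 1] - Ey[i, j, k]))
    for i in range(nx):
        for j in range(ny + 1):
            for k in range(nz):
                Hy[i, j, k] = daHy[i, j, k] * Hy[i, j, k] - dbHy[i, j, k] * (
                    (Ex[i, j, k + 1] - Ex[i, j, k]) - (Ez[i + 1, j, k] - Ez[i, j, k]))
    for i in range(nx):
        for j in range(ny):
            for k in range(nz + 1):
                Hz[i, j, k] = daHz[i, j, k] * Hz[i, j, k] - dbHz[i, j, k] * (
                    (Ey[i + 1, j, k] - Ey[i, j, k]) - (Ex[i, j + 1, k] - Ex[i, j, k]))


@njit(cache=True)
def _step_e(Ex, Ey, Ez, Hx, Hy, Hz, caEx, cbEx, caEy, cbEy, caEz, cbEz,
            nx, ny, nz):
    for i in range(nx):
        for j in range(1, ny):
            for k in range(1, nz):
                Ex[i, j, k] = caEx[i, j, k] * Ex[i, j, k] + cbEx[i, j, k] * (
                    (Hz[i, j, k] - Hz[i, j - 1, k]) - (Hy[i, j, k] - Hy[i, j, k - 1]))
    for i in range(1, nx):
        for j in range(ny):
            for k in range(1, nz):
                Ey[i, j, k] = caEy[i, j, k] * Ey[i, j, k] + cbEy[i, j, k] * (
                    (Hx[i, j, k] - Hx[i, j, k - 1]) - (Hz[i, j, k] - Hz[i - 1, j, k]))
    for i in range(1, nx):
        for j in range(1, ny):
            for k in range(nz):
                Ez[i, j, k] = caEz[i, j, k] * Ez[i, j, k] + cbEz[i, j, k] * (
                    (Hy[i, j, k] - Hy[i - 1, j, k]) - (Hx[i, j, k] - Hx[i, j - 1, k]))


@njit(cache=True)
def _add_rung_currents(Ez, cbEz, src_i, src_j, src_w, src_phase,
                       k0, k1, amp, omega, t, d):
    # impressed Jz over the rung span; Ez -= cb * I * w / d  (J = I w / d^2)
    for s in range(src_i.size):
        cur = amp * np.cos(omega * t + src_phase[s]) * src_w[s] / d
        i, j = src_i[s], src_j[s]
        for k in range(k0, k1):
            Ez[i, j, k] -= cbEz[i, j, k] * cur


@njit(cache=True)
def _run_periods(Ex, Ey, Ez, Hx, Hy, Hz,
                 caEx, cbEx, caEy, cbEy, caEz, cbEz,
                 daHx, dbHx, daHy, dbHy, daHz, dbHz,
                 src_i, src_j, src_w, src_phase, k0, k1,
                 nx, ny, nz, dt, omega, d, t0, nsteps, t_ramp):
    t = t0
    for _ in range(nsteps):
        _step_h(Ex, Ey, Ez, Hx, Hy, Hz, daHx, dbHx, daHy, dbHy, daHz, dbHz,
                nx, ny, nz)
        _step_e(Ex, Ey, Ez, Hx, Hy, Hz, caEx, cbEx, caEy, cbEy, caEz, cbEz,
                nx, ny, nz)
        t += dt
        if t_ramp > 0 and t < t_ramp:
            amp = 0.5 * (1.0 - np.cos(np.pi * t / t_ramp))
        else:
            amp = 1.0
        _add_rung_currents(Ez, cbEz, src_i, src_j, src_w, src_phase,
                           k0, k1, amp, omega, t, d)
    return t


@njit(cache=True)
def _accumulate3(a1, a2, a3, f1, f2, f3, ph):
    n0, n1, n2 = a1.shape
    for i in range(n0):
        for j in range(n1):
            for k in range(n2):
                a1[i, j, k] += f1[i, j, k] * ph
                a2[i, j, k] += f2[i, j, k] * ph
                a3[i, j, k] += f3[i, j, k] * ph


@njit(cache=True)
def _run_period_dft(Ex, Ey, Ez, Hx, Hy, Hz,
                    caEx, cbEx, caEy, cbEy, caEz, cbEz,
                    daHx, dbHx, daHy, dbHy, daHz, dbHz,
                    src_i, src_j, src_w, src_phase, k0, k1,
                    nx, ny, nz, dt, omega, d, t0, nsteps,
                    accEx, accEy, accEz, accHx, accHy, accHz):
    t = t0
    for _ in range(nsteps):
        _step_h(Ex, Ey, Ez, Hx, Hy, Hz, daHx, dbHx, daHy, dbHy, daHz, dbHz,
                nx, ny, nz)
        th = t + 0.5 * dt
        ph_h = complex(np.cos(omega * th), -np.sin(omega * th))
        _accumulate3(accHx, accHy, accHz, Hx, Hy, Hz, ph_h)
        _step_e(Ex, Ey, Ez, Hx, Hy, Hz, caEx, cbEx, caEy, cbEy, caEz, cbEz,
                nx, ny, nz)
        t += dt
        _add_rung_currents(Ez, cbEz, src_i, src_j, src_w, src_phase,
                           k0, k1, 1.0, omega, t, d)
        ph_e = complex(np.cos(omega * t), -np.sin(omega * t))
        _accumulate3(accEx, accEy, accEz, Ex, Ey, Ez, ph_e)
    return t


# --------------------------------------------------------------------------- assembly

def _avg4(pad: np.ndarray, axis: int) -> np.ndarray:
    """Average the 4 cells sharing an edge along `axis`.

    `pad` is a cell array padded by one on every side; the result has the
    E-component staggered shape (nx+1, ny+1, nz+1) trimmed appropriately.
    """
    sl = [slice(1, -1)] * 3
    out = None
    for da in (0, 1):
        for db in (0, 1):
            s = list(sl)
            axes = [a for a in range(3) if a != axis]
            s[axes[0]] = slice(da, pad.shape[axes[0]] - 1 + da)
            s[axes[1]] = slice(db, pad.shape[axes[1]] - 1 + db)
            v = pad[tuple(s)]
            out = v if out is None else out + v
    return out / 4.0


def _avg2(pad: np.ndarray, axis: int) -> np.ndarray:
    """Average the 2 cells sharing a face normal to `axis` (H components)."""
    s0 = [slice(1, -1)] * 3
    s1 = list(s0)
    s0[axis] = slice(0, pad.shape[axis] - 1)
    s1[axis] = slice(1, pad.shape[axis])
    return 0.5 * (pad[tuple(s0)] + pad[tuple(s1)])


def _pad_cells(arr: np.ndarray, value: float) -> np.ndarray:
    return np.pad(arr, 1, mode="constant", constant_values=value)


@dataclass
class FdtdResult:
    """Complex field phasors at cell centers plus convergence diagnostics."""

    E: np.ndarray          # (nx, ny, nz, 3) complex, V/m
    H: np.ndarray          # (nx, ny, nz, 3) complex, A/m
    periods_run: int
    energy_history: list = field(default_factory=list)
    converged: bool = True

    @property
    def B(self) -> np.ndarray:
        return MU0 * self.H


def run_birdcage_fdtd(
    eps_r: np.ndarray,
    sigma: np.ndarray,
    pec_cells: np.ndarray,
    d_m: float,
    frequency_hz: float,
    src_i: np.ndarray,
    src_j: np.ndarray,
    src_w: np.ndarray,
    src_phase: np.ndarray,
    src_k0: int,
    src_k1: int,
    absorber_cells: int = 8,
    min_periods: int = 20,
    max_periods: int = 80,
    energy_tol: float = 0.01,
    ramp_periods: float = 3.0,
    courant: float = 0.99,
    on_nonconvergence: str = "raise",
) -> FdtdResult:
    """Time-step the grid to steady state and return drive-frequency phasors.

    ``eps_r``/``sigma``/``pec_cells`` are cell-centered material arrays of
    shape (nx, ny, nz); the impressed z-directed rung currents are given as
    flattened (i, j) edge columns with bilinear weights and per-rung phases
    over the axial span [src_k0, src_k1).
    """
    nx, ny, nz = eps_r.shape
    if courant <= 0 or courant >= 1:
        raise ValueError("Courant factor must lie in (0, 1)")
    dt_cfl = d_m / (C0 * np.sqrt(3.0))
    period = 1.0 / frequency_hz
    steps_per_period = int(np.ceil(period / (courant * dt_cfl)))
    dt = period / steps_per_period
    if dt > dt_cfl:
        raise ValueError("time step violates the CFL stability bound")
    omega = 2 * np.pi * frequency_hz

    # graded matched absorber at both z ends (inside the PEC box)
    sig_abs = np.zeros((nx, ny, nz))
    if absorber_cells > 0:
        # polynomial grading, matched sigma_m/mu0 = sigma/eps0
        smax = -(3 + 1) * np.log(1e-4) * EPS0 * C0 / (2.0 * absorber_cells * d_m)
        prof = smax * ((np.arange(absorber_cells, 0, -1) - 0.5) / absorber_cells) ** 3
        sig_abs[:, :, :absorber_cells] = np.maximum(
            sig_abs[:, :, :absorber_cells], prof[::-1][None, None, :])
        sig_abs[:, :, nz - absorber_cells:] = np.maximum(
            sig_abs[:, :, nz - absorber_cells:], prof[None, None, :])
    sigma_eff = sigma + sig_abs
    sigma_m = sig_abs * MU0 / EPS0  # matched magnetic loss

    eps = _pad_cells(eps_r, 1.0) * EPS0
    sig = _pad_cells(sigma_eff, 0.0)
    sgm = _pad_cells(sigma_m, 0.0)
    pec = _pad_cells(pec_cells.astype(float), 0.0)

    shape_e = (nx + 1, ny + 1, nz + 1)

    def e_coeffs(axis):
        epsa = _avg4(eps, axis)
        siga = _avg4(sig, axis)
        peca = _avg4(pec, axis)
        loss = siga * dt / (2.0 * epsa)
        ca = (1.0 - loss) / (1.0 + loss)
        cb = dt / epsa / (1.0 + loss) / d_m
        dead = peca > 0
        ca[dead] = 0.0
        cb[dead] = 0.0
        # embed into full staggered shape
        CA = np.zeros(shape_e); CB = np.zeros(shape_e)
        sl = [slice(None)] * 3
        sl[axis] = slice(0, shape_e[axis] - 1)
        CA[tuple(sl)] = ca
        CB[tuple(sl)] = cb
        return CA, CB

    caEx, cbEx = e_coeffs(0)
    caEy, cbEy = e_coeffs(1)
    caEz, cbEz = e_coeffs(2)

    def h_coeffs(axis):
        sgma = _avg2(sgm, axis)
        loss = sgma * dt / (2.0 * MU0)
        da = (1.0 - loss) / (1.0 + loss)
        db = dt / MU0 / (1.0 + loss) / d_m
        DA = np.zeros(shape_e); DB = np.zeros(shape_e)
        sl = [slice(None)] * 3
        for a in range(3):
            if a != axis:
                sl[a] = slice(0, shape_e[a] - 1)
        sl[axis] = slice(0, shape_e[axis])
        DA[tuple(sl)] = sgma * 0 + da
        DB[tuple(sl)] = db
        return DA, DB

    daHx, dbHx = h_coeffs(0)
    daHy, dbHy = h_coeffs(1)
    daHz, dbHz = h_coeffs(2)

    F = [np.zeros(shape_e) for _ in range(6)]
    Ex, Ey, Ez, Hx, Hy, Hz = F

    args_core = (caEx, cbEx, caEy, cbEy, caEz, cbEz,
                 daHx, dbHx, daHy, dbHy, daHz, dbHz,
                 np.ascontiguousarray(src_i.astype(np.int64)),
                 np.ascontiguousarray(src_j.astype(np.int64)),
                 np.ascontiguousarray(src_w.astype(np.float64)),
                 np.ascontiguousarray(src_phase.astype(np.float64)),
                 int(src_k0), int(src_k1), nx, ny, nz, dt, omega, d_m)

    t = 0.0
    t_ramp = ramp_periods * period
    energy_hist: list[float] = []
    converged = False
    periods = 0
    u_prev = None
    while periods < max_periods:
        t = _run_periods(Ex, Ey, Ez, Hx, Hy, Hz, *args_core, t,
                         steps_per_period, t_ramp)
        periods += 1
        u = float(np.sum(Ex * Ex) + np.sum(Ey * Ey) + np.sum(Ez * Ez))
        energy_hist.append(u)
        if u_prev is not None:
            denom = max(u, u_prev, 1e-300)
            if abs(u - u_prev) / denom < energy_tol and periods >= min_periods:
                converged = True
                u_prev = u
                break
        u_prev = u
    if not converged:
        msg = (f"FDTD did not reach steady state within {max_periods} periods "
               f"(last relative energy change "
               f"{abs(energy_hist[-1] - energy_hist[-2]) / max(energy_hist[-1], 1e-300):.3g})")
        if on_nonconvergence == "raise":
            raise RuntimeError(msg)
        import logging
        logging.getLogger(__name__).warning(msg)

    acc = [np.zeros(shape_e, dtype=np.complex128) for _ in range(6)]
    t = _run_period_dft(Ex, Ey, Ez, Hx, Hy, Hz, *args_core, t,
                        steps_per_period, *acc)
    scale = 2.0 / steps_per_period
    phasors = [a * scale for a in acc]

    # stagger -> cell centers
    pEx, pEy, pEz, pHx, pHy, pHz = phasors
    E = np.empty((nx, ny, nz, 3), dtype=np.complex128)
    H = np.empty((nx, ny, nz, 3), dtype=np.complex128)
    E[..., 0] = 0.25 * (pEx[:nx, :ny, :nz] + pEx[:nx, 1:, :nz]
                        + pEx[:nx, :ny, 1:] + pEx[:nx, 1:, 1:])
    E[..., 1] = 0.25 * (pEy[:nx, :ny, :nz] + pEy[1:, :ny, :nz]
                        + pEy[:nx, :ny, 1:] + pEy[1:, :ny, 1:])
    E[..., 2] = 0.25 * (pEz[:nx, :ny, :nz] + pEz[1:, :ny, :nz]
                        + pEz[:nx, 1:, :nz] + pEz[1:, 1:, :nz])
    H[..., 0] = 0.5 * (pHx[:nx, :ny, :nz] + pHx[1:, :ny, :nz])
    H[..., 1] = 0.5 * (pHy[:nx, :ny, :nz] + pHy[:nx, 1:, :nz])
    H[..., 2] = 0.5 * (pHz[:nx, :ny, :nz] + pHz[:nx, :ny, 1:])
    return FdtdResult(E=E, H=H, periods_run=periods + 1,
                      energy_history=energy_hist, converged=converged)


# --------------------------------------------------------------------------- 1-D oracle

def solve_plane_wave_1d(
    eps_r: np.ndarray,
    sigma: np.ndarray,
    dz_m: float,
    frequency_hz: float,
    src_cell: int,
    n_periods: int = 40,
    courant: float = 0.99,
) -> np.ndarray:
    """1-D normal-incidence plane wave; returns the complex Ex(z) phasor.

    A soft sinusoidal current source at ``src_cell`` launches waves in both
    directions; the left boundary carries a first-order Mur absorber (vacuum
    assumed there), the right end is PEC and should sit behind enough loss
    that no reflection returns.  Used as a closed-form-checkable oracle for
    skin-depth attenuation.
    """
    n = eps_r.size
    dt = courant * dz_m / C0
    period = 1.0 / frequency_hz
    steps_per_period = int(np.ceil(period / dt))
    dt = period / steps_per_period
    omega = 2 * np.pi * frequency_hz

    eps = eps_r * EPS0
    loss = sigma * dt / (2 * eps)
    ca = (1 - loss) / (1 + loss)
    cb = dt / eps / (1 + loss) / dz_m
    dbh = dt / MU0 / dz_m

    Ex = np.zeros(n)
    Hy = np.zeros(n - 1)
    mur = (C0 * dt - dz_m) / (C0 * dt + dz_m)
    t = 0.0
    nsteps = n_periods * steps_per_period
    t_ramp = 3 * period
    acc = np.zeros(n, dtype=np.complex128)
    for step in range(nsteps):
        Hy += dbh * (Ex[1:] - Ex[:-1])
        e0_old, e1_old = Ex[0], Ex[1]
        Ex[1:-1] = ca[1:-1] * Ex[1:-1] + cb[1:-1] * (Hy[1:] - Hy[:-1])
        t += dt
        amp = 0.5 * (1 - np.cos(np.pi * t / t_ramp)) if t < t_ramp else 1.0
        Ex[src_cell] += amp * np.sin(omega * t)
        Ex[0] = e1_old + mur * (Ex[1] - e0_old)  # Mur-1, vacuum
        if step >= nsteps - steps_per_period:
            acc += Ex * (np.cos(omega * t) - 1j * np.sin(omega * t))
    return acc * (2.0 / steps_per_period)
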