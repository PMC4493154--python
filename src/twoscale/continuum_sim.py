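"""Deterministic integration of the nonlocal mean-field density equation.

In the mean-field (fluctuation-free) limit the particle model becomes a
nonlinear, nonlocal diffusion equation for the population density:

    d rho / dt = D0 * Laplacian[ g(a - b*rho_s + c*rho_l) * rho ]

where the smoothed densities ``rho_s`` and ``rho_l`` are circular
convolutions of ``rho`` with normalized top-hat kernels of radius ``R_s``
and ``R_l``.  The equation is in divergence form, so total mass is
conserved; the uniform state is always stationary.

The integrator is an explicit (forward) Euler scheme on a periodic grid,
with convolutions done spectrally and the Laplacian as a second-order
centered stencil.  Both 1D and 2D domains are supported; in 1D the
kernel is the normalized interval indicator 1/(2R).

Kernel transforms: by default the top-hat is rasterized onto the grid
(with sub-cell supersampling of the boundary cells) and transformed with
the FFT, which keeps the discrete convolution exactly mass-preserving and
self-consistent with the grid.  Sampling the analytic transform
(2*J1(kR)/(kR) in 2D, sinc in 1D) on the reciprocal lattice is available
via ``kernel_method="analytic"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sfft

from .model_core import ModelParams, kernel_ft, kernel_ft_1d

__all__ = [
    "DensityField",
    "DiffusivityField",
    "nonlocal_density",
    "rhs",
    "integrate",
    "diffusivity_field",
    "laplacian",
    "stable_dt",
]


@dataclass
class DensityField:
    """Population density sampled on a uniform periodic grid.

    Attributes
    ----------
    values : ndarray
        Density samples, shape (n,) in 1D or (n, n) in 2D; units
        1/length^dim.  Non-negative.
    L : float
        Domain side (the domain is [0, L)^dim, periodic).
    t : float
        Simulation time of the snapshot.
    """

    values: np.ndarray
    L: float
    t: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (1, 2):
            raise ValueError("DensityField must be 1D or 2D")
        if self.values.ndim == 2 and self.values.shape[0] != self.values.shape[1]:
            raise ValueError("2D DensityField must be square")
        if self.L <= 0:
            raise ValueError("L must be positive")

    @property
    def dim(self) -> int:
        return self.values.ndim

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dx(self) -> float:
        return self.L / self.n

    @property
    def mass(self) -> float:
        """Total population integral(rho) = sum * dx^dim."""
        return float(self.values.sum() * self.dx**self.dim)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def copy(self) -> "DensityField":
        return DensityField(self.values.copy(), self.L, self.t)


@dataclass
class DiffusivityField:
    """Pointwise diffusivity factor g in [0, 1] on the same grid as rho."""

    values: np.ndarray
    L: float
    t: float = 0.0


# cache of kernel transforms keyed by grid geometry and radius
_KERNEL_CACHE: dict = {}


def _kernel_hat(n: int, L: float, radius: float, dim: int, method: str, supersample: int = 4):
    """rFFT of the normalized top-hat on an n^dim periodic grid.

    Multiplying the rFFT of rho by this array and inverting yields the
    periodic convolution integral(G(r - r') rho(r') dr').
    """
    key = (n, round(L, 12), round(radius, 12), dim, method, supersample)
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    dx = L / n
    if method == "raster":
        # indicator of |r| <= R sampled on a supersampled grid, then
        # block-averaged down: boundary cells get fractional coverage
        m = n * supersample
        x = np.arange(m) * (L / m)
        xm = np.minimum(x, L - x)  # min-image distance from origin
        if dim == 1:
            w = (xm <= radius).astype(float)
            w = w.reshape(n, supersample).mean(axis=1)
        else:
            r2 = xm[:, None] ** 2 + xm[None, :] ** 2
            w = (r2 <= radius**2).astype(float)
            w = w.reshape(n, supersample, n, supersample).mean(axis=(1, 3))
        w /= w.sum() * dx**dim  # discrete normalization: exact mass 1
        hat = sfft.rfftn(w) * dx**dim
    elif method == "analytic":
        k1 = 2.0 * np.pi * sfft.fftfreq(n, d=dx)
        if dim == 1:
            kmag = np.abs(k1[: n // 2 + 1])
            hat = kernel_ft_1d(kmag, radius).astype(complex)
        else:
            kr = k1[: n // 2 + 1]
            kmag = np.sqrt(k1[:, None] ** 2 + kr[None, :] ** 2)
            hat = kernel_ft(kmag, radius).astype(complex)
    else:
        raise ValueError(f"unknown kernel method {method!r}")
    _KERNEL_CACHE[key] = hat
    return hat


def nonlocal_density(field: DensityField, radius: float, kernel_method: str = "raster"):
    """Density smoothed over a disk (2D) or interval (1D) of given radius.

    Periodic circular convolution of ``field.values`` with the normalized
    top-hat, computed spectrally.  A constant field is returned unchanged;
    a point mass spreads into ``1/(pi R^2)`` (or ``1/(2R)``) inside the
    radius.

    Parameters
    ----------
    field : DensityField
    radius : float
        Kernel radius; must be < L/2 so the periodic images do not overlap.
    kernel_method : {"raster", "analytic"}

    Returns
    -------
    ndarray
        Smoothed density, same shape as ``field.values``.
    """
    if not (0 < radius < field.L / 2):
        raise ValueError(f"kernel radius must lie in (0, L/2), got {radius}")
    hat = _kernel_hat(field.n, field.L, radius, field.dim, kernel_method)
    return sfft.irfftn(sfft.rfftn(field.values) * hat, s=field.values.shape)


def laplacian(arr: np.ndarray, dx: float) -> np.ndarray:
    """Second-order centered Laplacian with periodic wrap."""
    out = -2.0 * arr.ndim * arr
    for ax in range(arr.ndim):
        out += np.roll(arr, 1, axis=ax) + np.roll(arr, -1, axis=ax)
    return out / dx**2


def _g_field(field: DensityField, params: ModelParams, kernel_method: str) -> np.ndarray:
    rho_s = nonlocal_density(field, params.R_s, kernel_method)
    rho_l = nonlocal_density(field, params.R_l, kernel_method)
    return params.g(params.diffusivity_arg(rho_s, rho_l))


def rhs(field: DensityField, params: ModelParams, kernel_method: str = "raster") -> np.ndarray:
    """Time derivative D0 * Laplacian[g * rho] of the density field.

    Being a pure Laplacian of a flux potential, it sums to zero over the
    periodic domain (mass conservation) and vanishes identically on a
    uniform field.
    """
    g = _g_field(field, params, kernel_method)
    return params.D0 * laplacian(g * field.values, field.dx)


def diffusivity_field(
    field: DensityField, params: ModelParams, kernel_method: str = "raster"
) -> DiffusivityField:
    """Pointwise diffusivity factor g(a - b*rho_s + c*rho_l) of a snapshot.

    In saturated patterns g is orders of magnitude below 1 inside the
    clusters but never exactly zero, which is what makes hollow (ring)
    structures long-lived transients rather than true steady states.
    """
    return DiffusivityField(_g_field(field, params, kernel_method), field.L, field.t)


def stable_dt(field: DensityField, params: ModelParams) -> float:
    """Explicit-Euler stability bound dx^2 / (2 * dim * D0).

    The effective diffusivity D0*g never exceeds D0, so this bound is
    conservative for the full nonlinear flux.
    """
    return field.dx**2 / (2.0 * field.dim * params.D0)


def integrate(
    initial: DensityField,
    params: ModelParams,
    t_end: float,
    dt: float | None = None,
    snapshot_every: float | None = None,
    kernel_method: str = "raster",
    neg_tol: float = 1e-12,
    progress: bool = False,
) -> list[DensityField]:
    """Forward-Euler trajectory of the nonlocal diffusion equation.

    Parameters
    ----------
    initial : DensityField
        Starting density; not modified.
    params : ModelParams
    t_end : float
        Final time.  ``t_end = 0`` returns just (a copy of) the initial
        field.
    dt : float, optional
        Time step; defaults to half the explicit stability bound
        ``dx^2 / (2 dim D0)`` and may not exceed that bound.
    snapshot_every : float, optional
        Interval between stored snapshots (in time units).  The initial
        and final fields are always included.  ``None`` stores only those
        two.
    kernel_method : {"raster", "analytic"}
        How the convolution kernels are represented spectrally.
    neg_tol : float
        Negative values smaller in magnitude than ``neg_tol * mean(rho)``
        (discretization undershoot) are clipped to zero and the mass
        renormalized; anything more negative aborts the run.

    Returns
    -------
    list of DensityField
        Snapshots in time order.

    Raises
    ------
    ValueError
        If ``dt`` violates the stability bound.
    RuntimeError
        If the solution blows up (|rho| > 1e6 * mean or NaN) or goes
        genuinely negative.
    """
    bound = stable_dt(initial, params)
    if dt is None:
        dt = 0.5 * bound
    if dt <= 0 or dt > bound:
        raise ValueError(
            f"dt={dt} violates the explicit Euler stability bound {bound:.3e} "
            f"(dx^2 / (2*dim*D0))"
        )

    shape = initial.values.shape
    hat_s = _kernel_hat(initial.n, initial.L, params.R_s, initial.dim, kernel_method)
    hat_l = _kernel_hat(initial.n, initial.L, params.R_l, initial.dim, kernel_method)

    rho = initial.values.copy()
    rho0 = rho.mean()
    mass0 = rho.sum()
    t = initial.t
    n_steps = int(np.ceil(t_end / dt - 1e-12)) if t_end > 0 else 0
    snap_stride = (
        max(1, int(round(snapshot_every / dt))) if snapshot_every is not None else n_steps + 1
    )

    snaps = [DensityField(rho.copy(), initial.L, t)]
    for step in range(1, n_steps + 1):
        h = min(dt, t_end + initial.t - t)  # last step lands exactly on t_end
        f = sfft.rfftn(rho)
        rho_s = sfft.irfftn(f * hat_s, s=shape)
        rho_l = sfft.irfftn(f * hat_l, s=shape)
        g = params.g(params.a - params.b * rho_s + params.c * rho_l)
        rho += h * params.D0 * laplacian(g * rho, initial.dx)
        t += h

        mn = rho.min()
        if mn < 0.0:
            if mn < -neg_tol * rho0:
                raise RuntimeError(
                    f"density went negative (min {mn:.3e}) at t={t:.4g}; "
                    "reduce dt or refine the grid"
                )
            np.clip(rho, 0.0, None, out=rho)
            rho *= mass0 / rho.sum()
        if not np.isfinite(rho).all() or np.abs(rho).max() > 1e6 * rho0:
            raise RuntimeError(f"integration diverged at t={t:.4g} (dt={dt:.3e})")

        if step % snap_stride == 0 and step != n_steps:
            snaps.append(DensityField(rho.copy(), initial.L, t))
        if progress and step % max(1, n_steps // 20) == 0:
            print(f"  t = {t:.4g} / {t_end + initial.t:.4g}", flush=True)

    if n_steps > 0:
        snaps.append(DensityField(rho.copy(), initial.L, t))
    return snaps


def perturbed_uniform(
    n: int, L: float, rho0: float, eps: float = 1e-2, seed: int | None = None, dim: int = 2
) -> DensityField:
    """Uniform density rho0 with i.i.d. relative perturbation eps*U(-1, 1).

    The standard initial condition for pattern runs; the perturbation
    seeds every wavenumber so the linearly fastest-growing band can
    emerge.  Mass is corrected to exactly rho0 * L^dim.
    """
    rng = np.random.default_rng(seed)
    shape = (n,) * dim
    vals = rho0 * (1.0 + eps * rng.uniform(-1.0, 1.0, size=shape))
    vals *= rho0 / vals.mean()
    return DensityField(vals, L, 0.0)
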