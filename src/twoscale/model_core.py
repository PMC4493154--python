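"""Model parameters, the diffusivity response, and top-hat interaction kernels.

The model describes a population of organisms that move as Brownian
particles whose diffusivity depends on how crowded their surroundings are
at two spatial scales.  The local diffusion coefficient is

    D = D0 * g(a - b*rho_s + c*rho_l)

where ``rho_s`` and ``rho_l`` are the mean population densities inside
concentric disks of radius ``R_s`` (short range) and ``R_l`` (long range,
``R_s < R_l``), and ``g`` is a sigmoid mapping to [0, 1].  Crowding at
short range suppresses movement (aggregation is favourable, e.g. mussels
clumping against predation and wave stress) while crowding at long range
promotes it (competition for resources drives dispersal).  ``a`` sets the
baseline mobility, ``b`` and ``c`` weight the two density scales and carry
units of area per individual so that the argument of ``g`` is
dimensionless.

Everything downstream — the particle simulator, the continuum integrator
and the linear stability analysis — consumes the types and functions
defined here.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import j1, jn_zeros

__all__ = [
    "ModelParams",
    "Kernel",
    "diffusivity_factor",
    "tophat_kernel",
    "kernel_ft",
    "kernel_ft_1d",
    "J1_FIRST_ZERO",
]

#: First positive zero of the Bessel function J1; the 2D top-hat transform
#: vanishes at k*R equal to this value.
J1_FIRST_ZERO: float = float(jn_zeros(1, 1)[0])


def diffusivity_factor(x):
    """Sigmoid response g(x) = (1 + tanh(2x - 1)) / 2.

    Maps the weighted two-scale density combination
    ``x = a - b*rho_s + c*rho_l`` to a fraction of the maximal diffusion
    coefficient.  Strictly increasing, with g -> 0 for strongly negative
    arguments (short-range crowding dominates: the particle stalls) and
    g -> 1 for strongly positive ones (long-range pressure dominates: free
    diffusion at D0).  At x = 1 with no neighbours, g = (1 + tanh 1)/2.

    Parameters
    ----------
    x : float or array_like
        Dimensionless argument; must be finite.

    Returns
    -------
    float or ndarray
        Value(s) in the open interval (0, 1).
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("diffusivity_factor: argument must be finite")
    out = 0.5 * (1.0 + np.tanh(2.0 * arr - 1.0))
    return out if isinstance(x, np.ndarray) else float(out) if arr.ndim == 0 else out


def tophat_kernel(r, radius: float, dim: int = 2):
    """Normalized top-hat (uniform disk) kernel evaluated at distance r.

    Returns ``1/(pi*R^2)`` for ``|r| <= R`` in 2D and ``1/(2R)`` in 1D,
    zero outside, so the kernel integrates to one in either dimension.

    Parameters
    ----------
    r : float or array_like
        Distance(s) from the kernel center (length units).
    radius : float
        Support radius R > 0.
    dim : {1, 2}
        Spatial dimension; sets the normalization.
    """
    if radius <= 0:
        raise ValueError(f"tophat_kernel: radius must be positive, got {radius}")
    if dim not in (1, 2):
        raise ValueError(f"tophat_kernel: dim must be 1 or 2, got {dim}")
    norm = 1.0 / (math.pi * radius**2) if dim == 2 else 1.0 / (2.0 * radius)
    arr = np.abs(np.asarray(r, dtype=float))
    out = np.where(arr <= radius, norm, 0.0)
    return float(out) if out.ndim == 0 else out


def kernel_ft(k, radius: float):
    """2D Fourier transform of the normalized top-hat: 2*J1(kR)/(kR).

    Radially symmetric, equals 1 at k = 0 (the kernel is normalized; the
    0/0 at the origin is a removable singularity set to its analytic
    limit), oscillates with decaying amplitude, and first vanishes at
    ``k*R = J1_FIRST_ZERO`` (~3.8317).

    Parameters
    ----------
    k : float or array_like
        Wavenumber magnitude(s), >= 0.
    radius : float
        Kernel radius R > 0.
    """
    if radius <= 0:
        raise ValueError(f"kernel_ft: radius must be positive, got {radius}")
    arr = np.asarray(k, dtype=float)
    kr = arr * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(kr == 0.0, 1.0, 2.0 * j1(kr) / np.where(kr == 0.0, 1.0, kr))
    return float(out) if out.ndim == 0 else out


def kernel_ft_1d(k, radius: float):
    """1D Fourier transform of the normalized top-hat: sin(kR)/(kR)."""
    if radius <= 0:
        raise ValueError(f"kernel_ft_1d: radius must be positive, got {radius}")
    arr = np.asarray(k, dtype=float)
    kr = arr * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(kr == 0.0, 1.0, np.sin(kr) / np.where(kr == 0.0, 1.0, kr))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Kernel:
    """A normalized top-hat interaction kernel of a given radius.

    Attributes
    ----------
    radius : float
        Support radius (length units).
    dim : {1, 2}
        Spatial dimension, which fixes the normalization constant.
    """

    radius: float
    dim: int = 2

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("Kernel radius must be positive")
        if self.dim not in (1, 2):
            raise ValueError("Kernel dim must be 1 or 2")

    @property
    def norm(self) -> float:
        """Kernel height: 1/(pi R^2) in 2D, 1/(2R) in 1D."""
        if self.dim == 2:
            return 1.0 / (math.pi * self.radius**2)
        return 1.0 / (2.0 * self.radius)

    def __call__(self, r):
        return tophat_kernel(r, self.radius, self.dim)

    def ft(self, k):
        """Analytic Fourier transform at wavenumber magnitude k."""
        if self.dim == 2:
            return kernel_ft(k, self.radius)
        return kernel_ft_1d(k, self.radius)


@dataclass(frozen=True)
class ModelParams:
    """All parameters of the two-scale movement model, validated.

    Parameters
    ----------
    D0 : float
        Maximal diffusivity (length^2 / time); the diffusion coefficient
        of an isolated individual under strong long-range pressure.
    a : float
        Dimensionless mobility offset: the argument of ``g`` when the two
        weighted densities cancel.
    b : float
        Weight of the short-range density (area per individual in 2D).
        Larger ``b`` means stronger movement suppression by close
        neighbours.
    c : float
        Weight of the long-range density (same units as ``b``).  Larger
        ``c`` means stronger dispersal under regional crowding.
    R_s, R_l : float
        Short and long interaction radii, ``0 < R_s < R_l < L/2``.
    L : float
        Side of the periodic domain.
    N : int, optional
        Number of individuals (constant: the model has no demography).
    rho0 : float, optional
        Global mean density N / L^dim.  Derived from ``N`` when omitted;
        when both are given they must agree.
    dim : {1, 2}
        Spatial dimension (default 2).
    g : callable
        Monotone map from the weighted density combination to [0, 1].
        Defaults to :func:`diffusivity_factor`; any user-supplied
        increasing function with that range is accepted, as the
        qualitative behaviour of the model does not hinge on the tanh
        form.
    """

    D0: float
    a: float
    b: float
    c: float
    R_s: float
    R_l: float
    L: float = 1.0
    N: int | None = None
    rho0: float | None = None
    dim: int = 2
    g: Callable = field(default=diffusivity_factor, repr=False, compare=False)

    def __post_init__(self):
        if self.D0 <= 0:
            raise ValueError("D0 must be positive")
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("a, b, c must be non-negative")
        if not (0 < self.R_s < self.R_l):
            raise ValueError("radii must satisfy 0 < R_s < R_l")
        if not (self.R_l < self.L / 2):
            raise ValueError("R_l must be smaller than L/2 on a periodic domain")
        if self.dim not in (1, 2):
            raise ValueError("dim must be 1 or 2")
        if self.N is not None and self.N < 1:
            raise ValueError("N must be a positive integer")
        if self.N is not None:
            derived = self.N / self.L**self.dim
            if self.rho0 is None:
                object.__setattr__(self, "rho0", derived)
            elif not math.isclose(self.rho0, derived, rel_tol=1e-9):
                raise ValueError(
                    f"inconsistent density: rho0={self.rho0} but N/L^{self.dim}={derived}"
                )

    def diffusivity_arg(self, rho_s, rho_l):
        """Weighted density combination a - b*rho_s + c*rho_l."""
        return self.a - self.b * np.asarray(rho_s) + self.c * np.asarray(rho_l)

    def diffusivity(self, rho_s, rho_l):
        """Local diffusion coefficient D0 * g(a - b*rho_s + c*rho_l)."""
        return self.D0 * self.g(self.diffusivity_arg(rho_s, rho_l))

    def kernel(self, scale: str) -> Kernel:
        """Interaction kernel for ``scale`` in {'s', 'l'} (short/long)."""
        if scale == "s":
            return Kernel(self.R_s, self.dim)
        if scale == "l":
            return Kernel(self.R_l, self.dim)
        raise ValueError("scale must be 's' or 'l'")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        if ("N" in changes or "L" in changes or "dim" in changes) and "rho0" not in changes:
            changes.setdefault("rho0", None)
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        """Plain-scalar view for serialization (custom ``g`` is not stored)."""
        d = {k: getattr(self, k) for k in ("D0", "a", "b", "c", "R_s", "R_l", "L", "dim")}
        if self.N is not None:
            d["N"] = self.N
        if self.rho0 is not None:
            d["rho0"] = self.rho0
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        keys = {"D0", "a", "b", "c", "R_s", "R_l", "L", "N", "rho0", "dim"}
        kwargs = {k: d[k] for k in keys if k in d}
        if "N" in kwargs and kwargs["N"] is not None:
            kwargs["N"] = int(round(kwargs["N"]))
        return cls(**kwargs)
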