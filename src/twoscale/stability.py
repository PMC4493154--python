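"""Linear stability of the homogeneous state of the nonlocal diffusion model.

The uniform density ``rho0 = N / L^2`` is always a stationary solution of
the continuum equation.  Perturbing it with a plane wave
``rho = rho0 + eps * exp(i k.r + lambda t)`` and linearizing gives the
dispersion relation

    lambda(k) = -(D0/2) * [ 1 + tanh(gamma)
                            + 2*rho0*(c*Gl(k) - b*Gs(k)) / cosh(gamma)^2 ] * k^2

with ``gamma = 2*(a - b*rho0 + c*rho0) - 1`` and ``Gs``, ``Gl`` the 2D
Fourier transforms of the short- and long-range top-hat kernels.  Patterns
emerge when the most unstable mode has a positive growth rate.

Two instability classes occur.  Type A leaves low wavenumbers stable and
destabilizes a finite-k band, selecting a well-defined wavelength
(hexagonal spot arrangements).  Type B destabilizes a band starting at
k = 0, which permits coarsening and produces labyrinths.  The boundary
between them is where the curvature of lambda(k) at k = 0 changes sign,
i.e. where

    F0 = 1 + tanh(gamma) + 2*rho0*(c - b) / cosh(gamma)^2

crosses zero.  Note that ``F0`` carries the same ``rho0`` factor as the
k-dependent bracket: the k -> 0 limit of the dispersion relation requires
it, and with densities of order 1e4 and weights of order 1e-4 the
boundary is only meaningful with the density included.  A literal variant
without the density factor is available behind ``include_density=False``
for comparison.

A practical caveat: because the top-hat transform oscillates, the global
argmax of lambda(k) for type-B parameter sets can sit in a secondary
high-k window rather than at the first local maximum.  The first local
maximum is what the saturated pattern's structure function reflects, so
:class:`DispersionCurve` records both.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import argrelmax

from .model_core import J1_FIRST_ZERO, ModelParams, kernel_ft

__all__ = [
    "InstabilityType",
    "DispersionCurve",
    "PhaseDiagram",
    "gamma",
    "growth_rate",
    "most_unstable_mode",
    "curvature_at_zero",
    "instability_type",
    "phase_diagram",
]


class InstabilityType(str, enum.Enum):
    """Classification of the homogeneous state's linear stability."""

    HOMOGENEOUS = "homogeneous"  # lambda(k) <= 0 for all k: no pattern
    A = "A"  # finite-k band unstable, k=0 stable: periodic spots
    B = "B"  # unstable band starting at k=0: labyrinths, coarsening


def _require_rho0(params: ModelParams) -> float:
    if params.rho0 is None:
        raise ValueError("stability analysis requires rho0 (or N) to be set")
    return params.rho0


def gamma(params: ModelParams) -> float:
    """Homogeneous-state argument of tanh: 2*(a - (b - c)*rho0) - 1."""
    rho0 = _require_rho0(params)
    return 2.0 * (params.a - (params.b - params.c) * rho0) - 1.0


def growth_rate(k, params: ModelParams):
    """Perturbation growth rate lambda(k) about the homogeneous state.

    Uses the analytic 2D kernel transforms.  Vanishes exactly at k = 0
    (mass conservation: the uniform mode cannot grow), and behaves as
    ``-(D0/2)*(1 + tanh(gamma))*k^2`` for large k where the kernel
    transforms have decayed.

    Parameters
    ----------
    k : float or array_like
        Wavenumber magnitude(s), >= 0 (1/length).
    params : ModelParams
        Must have ``rho0`` set.

    Returns
    -------
    float or ndarray
        Growth rate(s), units 1/time.
    """
    rho0 = _require_rho0(params)
    g = gamma(params)
    karr = np.asarray(k, dtype=float)
    bracket = (
        1.0
        + np.tanh(g)
        + 2.0
        * rho0
        * (params.c * kernel_ft(karr, params.R_l) - params.b * kernel_ft(karr, params.R_s))
        / np.cosh(g) ** 2
    )
    out = -(params.D0 / 2.0) * bracket * karr**2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DispersionCurve:
    """Sampled dispersion relation with its maxima and classification.

    Attributes
    ----------
    k : ndarray
        Scanned wavenumbers (1/length), starting at 0.
    lam : ndarray
        Growth rates lambda(k) (1/time).
    gamma : float
        Homogeneous tanh argument.
    k_c : float
        Wavenumber of the global maximum of lambda (refined beyond the
        scan grid); 0 when the state is stable.
    lam_max : float
        lambda(k_c).
    k_first_peak : float
        First local maximum of lambda with positive growth; equals k_c
        for type-A sets but can be smaller for type-B sets whose global
        argmax falls in a secondary kernel-oscillation window.  NaN when
        no unstable local maximum exists.
    kind : InstabilityType
        HOMOGENEOUS, A or B.
    """

    k: np.ndarray
    lam: np.ndarray
    gamma: float
    k_c: float
    lam_max: float
    k_first_peak: float
    kind: InstabilityType


def _refine_max(params: ModelParams, k_lo: float, k_hi: float) -> float:
    res = minimize_scalar(
        lambda kk: -growth_rate(kk, params),
        bounds=(k_lo, k_hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def default_k_max(params: ModelParams) -> float:
    """Default scan limit: past the first few kernel-transform lobes."""
    return 4.0 * J1_FIRST_ZERO / params.R_s


def most_unstable_mode(
    params: ModelParams, k_max: float | None = None, n_scan: int = 2000
) -> DispersionCurve:
    """Scan lambda(k) on [0, k_max] and locate its maxima.

    A dense coarse scan is followed by bounded parabolic refinement of
    the argmax, so ``k_c`` is resolved far below the scan spacing.  Ties
    on the coarse grid break toward smaller k.

    Parameters
    ----------
    params : ModelParams
        Must have ``rho0`` set.
    k_max : float, optional
        Upper end of the scan; defaults to ``4 * 3.8317 / R_s``, beyond
        the first oscillations of both kernel transforms.
    n_scan : int
        Number of coarse scan points.
    """
    _require_rho0(params)
    if k_max is None:
        k_max = default_k_max(params)
    ks = np.linspace(0.0, k_max, n_scan)
    lam = growth_rate(ks, params)

    i = int(np.argmax(lam))  # first index on ties -> smaller k
    if 0 < i < n_scan - 1:
        k_c = _refine_max(params, ks[i - 1], ks[i + 1])
    else:
        k_c = float(ks[i])
    lam_max = float(growth_rate(k_c, params))
    if lam_max <= 0.0:
        k_c, lam_max = 0.0, 0.0

    # first local maximum with positive growth (pattern-scale candidate)
    k_first = float("nan")
    peaks = argrelmax(lam)[0]
    for j in peaks:
        if lam[j] > 0.0:
            k_first = _refine_max(params, ks[max(j - 1, 0)], ks[min(j + 1, n_scan - 1)])
            break

    kind = _classify(params, lam_max, ks, lam)
    return DispersionCurve(
        k=ks,
        lam=lam,
        gamma=gamma(params),
        k_c=k_c,
        lam_max=lam_max,
        k_first_peak=k_first,
        kind=kind,
    )


def curvature_at_zero(params: ModelParams, include_density: bool = True) -> float:
    """Second derivative of lambda at k = 0: -D0 * F0.

    ``F0 = 1 + tanh(gamma) + 2*rho0*(c - b)/cosh(gamma)^2`` is the k -> 0
    limit of the dispersion bracket.  ``include_density=False`` drops the
    ``rho0`` factor from the (c - b) term, reproducing the dimensionally
    inconsistent literal form for comparison; it is not used anywhere in
    the package.
    """
    rho0 = _require_rho0(params)
    g = gamma(params)
    factor = rho0 if include_density else 1.0
    f0 = 1.0 + np.tanh(g) + 2.0 * factor * (params.c - params.b) / np.cosh(g) ** 2
    return -params.D0 * f0


def _classify(params, lam_max, ks, lam) -> InstabilityType:
    if lam_max <= 0.0:
        return InstabilityType.HOMOGENEOUS
    f0 = -curvature_at_zero(params) / params.D0
    if f0 > 0.0:
        return InstabilityType.A
    if f0 < 0.0:
        return InstabilityType.B
    # exactly on the boundary: decide by the sign of lambda at the
    # smallest scanned nonzero wavenumber
    return InstabilityType.B if lam[1] > 0.0 else InstabilityType.A


def instability_type(params: ModelParams, k_max: float | None = None) -> InstabilityType:
    """Classify the homogeneous state: HOMOGENEOUS, A (spots) or B (labyrinths)."""
    return most_unstable_mode(params, k_max=k_max).kind


@dataclass(frozen=True)
class PhaseDiagram:
    """Instability classification over a (b, c) parameter grid.

    Attributes
    ----------
    b_values, c_values : ndarray
        Grid axes (area per individual).
    kinds : ndarray of object, shape (len(b_values), len(c_values))
        InstabilityType at each cell.
    boundary : list of ndarray
        Polylines (columns b, c) of the F0 = 0 contour separating type-A
        from type-B behaviour.
    """

    b_values: np.ndarray
    c_values: np.ndarray
    kinds: np.ndarray
    boundary: list

    def kind_at(self, b: float, c: float) -> InstabilityType:
        i = int(np.argmin(np.abs(self.b_values - b)))
        j = int(np.argmin(np.abs(self.c_values - c)))
        return self.kinds[i, j]


def phase_diagram(
    params: ModelParams,
    b_values,
    c_values,
    k_max: float | None = None,
) -> PhaseDiagram:
    """Classify every (b, c) cell of a grid, holding other parameters fixed.

    Within the scanned window patterns require b > c (short-range
    suppression strong enough relative to long-range dispersal), and the
    b = 0 column is homogeneous for every c.

    Parameters
    ----------
    params : ModelParams
        Template; its ``b`` and ``c`` are overridden cell by cell.
    b_values, c_values : array_like
        Grid axes to scan.
    """
    b_values = np.asarray(b_values, dtype=float)
    c_values = np.asarray(c_values, dtype=float)
    kinds = np.empty((b_values.size, c_values.size), dtype=object)
    f0 = np.empty_like(kinds, dtype=float)
    for i, b in enumerate(b_values):
        for j, c in enumerate(c_values):
            p = params.replace(b=float(b), c=float(c))
            kinds[i, j] = instability_type(p, k_max=k_max)
            f0[i, j] = -curvature_at_zero(p) / p.D0

    boundary = []
    if f0.min() < 0.0 < f0.max() and min(f0.shape) >= 2:
        from skimage import measure

        for contour in measure.find_contours(f0, 0.0):
            bb = np.interp(contour[:, 0], np.arange(b_values.size), b_values)
            cc = np.interp(contour[:, 1], np.arange(c_values.size), c_values)
            boundary.append(np.column_stack([bb, cc]))
    return PhaseDiagram(b_values=b_values, c_values=c_values, kinds=kinds, boundary=boundary)
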