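"""Spectral and morphological diagnostics of simulated patterns.

The central quantity is the structure function: for a set of particle
positions it is

    S(k) = < | (1/N) * sum_j exp(i k . r_j) |^2 >

evaluated on the reciprocal lattice of the periodic box (k a multiple of
2*pi/L componentwise), averaged over annuli of |k| and over late-time
snapshots; for a density field it is the annulus- and time-averaged
modulus of the spatial Fourier transform (the squared version is also
available — the peak location is the same).  The first/highest peak k_c
gives the typical spacing between clusters d = 2*pi/k_c.

Ring-like (hollow) clusters are quantified by radial density profiles
around detected cluster centers, summarized by a hollowness index: the
ratio of the density in the innermost radial bin to the density in the
peak bin.  Values near 1 mean filled clusters, values near 0 mean the
population sits on the perimeter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .continuum_sim import DensityField, nonlocal_density
from .particle_sim import ParticleState

__all__ = [
    "Spectrum",
    "RadialProfile",
    "structure_function_particles",
    "structure_function_field",
    "typical_distance",
    "bin_particles",
    "find_cluster_centers",
    "radial_cluster_profile",
]


@dataclass(frozen=True)
class Spectrum:
    """Annulus-averaged spectral profile S(|k|) with its peak.

    Attributes
    ----------
    k : ndarray
        Bin centers (1/length), multiples of the bin width; the k = 0
        mode is excluded.
    S : ndarray
        Averaged spectral values (dimensionless), >= 0.
    counts : ndarray
        Number of reciprocal-lattice modes per bin.
    bin_width : float
        Annulus width, 2*pi/L by default (one lattice shell per bin).
    n_snapshots : int
        Snapshots averaged over.
    k_c : float
        Location of the highest peak (ties break toward smaller k).
    """

    k: np.ndarray
    S: np.ndarray
    counts: np.ndarray
    bin_width: float
    n_snapshots: int
    k_c: float

    @property
    def spectral_mass(self) -> float:
        """Sum over bins of count * S — equals the sum over lattice modes."""
        return float((self.counts * self.S).sum())


def _bin_spectrum(kmag, power, bin_width, n_snapshots):
    """Annulus-average spectral values by |k|; exclude the k=0 mode."""
    kmag = np.asarray(kmag).ravel()
    power = np.asarray(power).ravel()
    keep = kmag > 0.5 * bin_width  # drops only the zero mode
    kmag, power = kmag[keep], power[keep]
    idx = np.rint(kmag / bin_width).astype(int)
    nb = idx.max() + 1
    counts = np.bincount(idx, minlength=nb)
    sums = np.bincount(idx, weights=power, minlength=nb)
    occupied = counts > 0
    k = np.arange(nb)[occupied] * bin_width
    S = sums[occupied] / counts[occupied]
    k_c = float(k[np.argmax(S)])
    return Spectrum(
        k=k,
        S=S,
        counts=counts[occupied],
        bin_width=bin_width,
        n_snapshots=n_snapshots,
        k_c=k_c,
    )


def structure_function_particles(
    snapshots, bin_width: float | None = None, k_max: float | None = None
) -> Spectrum:
    """Discrete structure function of one or more particle snapshots.

    ``S(k) = <|sum_j exp(i k.r_j)|^2> / N^2`` on the reciprocal lattice
    of the box, annulus-averaged over |k| and averaged over snapshots.
    For a coherent configuration (all particles at one point) S = 1 at
    every k; for an ideal uniform-random configuration S ~ 1/N.

    Parameters
    ----------
    snapshots : ParticleState or sequence of ParticleState
        At least one snapshot with N >= 2 particles.
    bin_width : float, optional
        Annulus width, default 2*pi/L.
    k_max : float, optional
        Largest |k| evaluated; default 32 lattice shells.
    """
    if isinstance(snapshots, ParticleState):
        snapshots = [snapshots]
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("structure_function_particles: need at least one snapshot")
    L = snapshots[0].L
    if snapshots[0].N < 2:
        raise ValueError("structure_function_particles: need N >= 2")
    dk = 2.0 * math.pi / L
    if bin_width is None:
        bin_width = dk
    if k_max is None:
        k_max = 32 * dk
    M = int(math.ceil(k_max / dk))
    m = np.arange(-M, M + 1)
    kx, ky = np.meshgrid(m * dk, m * dk, indexing="ij")
    kmag = np.hypot(kx, ky)
    sel = kmag <= k_max + 0.5 * dk

    acc = np.zeros(kmag.shape)
    for s in snapshots:
        if s.L != L:
            raise ValueError("snapshots must share the same box size")
        ex = np.exp(1j * dk * np.outer(s.positions[:, 0], m))  # (N, 2M+1)
        ey = np.exp(1j * dk * np.outer(s.positions[:, 1], m))
        F = ex.T @ ey  # F[mx, my] = sum_j exp(i k.r_j)
        acc += np.abs(F) ** 2 / s.N**2
    acc /= len(snapshots)
    return _bin_spectrum(kmag[sel], acc[sel], bin_width, len(snapshots))


def structure_function_field(
    snapshots, bin_width: float | None = None, squared: bool = False
) -> Spectrum:
    """Structure function of one or more density fields.

    The modulus (default) or modulus squared of the discrete Fourier
    transform of rho, normalized by the number of grid points so the
    k = 0 amplitude would equal the mean density, annulus-averaged over
    |k| and averaged over snapshots; the k = 0 mode is excluded.  The
    peak location is unaffected by the modulus/modulus-squared choice.
    """
    if isinstance(snapshots, DensityField):
        snapshots = [snapshots]
    snapshots = list(snapshots)
    if not snapshots:
        raise ValueError("structure_function_field: need at least one field")
    f0 = snapshots[0]
    if f0.dim != 2:
        raise ValueError("structure_function_field expects 2D fields")
    n, L = f0.n, f0.L
    if bin_width is None:
        bin_width = 2.0 * math.pi / L
    k1 = 2.0 * math.pi * sfft.fftfreq(n, d=f0.dx)
    kmag = np.hypot(k1[:, None], k1[None, :])

    acc = np.zeros((n, n))
    for s in snapshots:
        if s.n != n or s.L != L:
            raise ValueError("fields must share grid and box size")
        amp = np.abs(sfft.fftn(s.values)) / n**2
        acc += amp**2 if squared else amp
    acc /= len(snapshots)
    return _bin_spectrum(kmag, acc, bin_width, len(snapshots))


def typical_distance(spectrum: Spectrum, noise_floor: float = 0.0) -> float:
    """Typical inter-cluster spacing d = 2*pi/k_c from a spectrum's peak.

    If the peak does not rise above ``noise_floor`` (e.g. 1/N for an
    uncorrelated particle configuration) the spacing is undefined and NaN
    is returned with a warning.
    """
    if spectrum.S.max() <= noise_floor or spectrum.k_c <= 0:
        warnings.warn("typical_distance: no spectral peak above the noise floor")
        return float("nan")
    return 2.0 * math.pi / spectrum.k_c


# ---------------------------------------------------------------- clusters


@dataclass(frozen=True)
class RadialProfile:
    """Annulus-averaged density around one cluster center.

    Attributes
    ----------
    center : ndarray, shape (2,)
        Cluster center.
    r : ndarray
        Radial bin centers (length units).
    density : ndarray
        Mean density per annulus (1/area).
    hollowness : float
        Density in the innermost bin divided by the peak-bin density;
        ~1 for a filled (flat) cluster, ~0 for a ring.
    """

    center: np.ndarray
    r: np.ndarray
    density: np.ndarray
    hollowness: float


def bin_particles(state: ParticleState, n: int) -> DensityField:
    """Histogram particle positions onto an n x n density grid."""
    H, _, _ = np.histogram2d(
        state.positions[:, 0],
        state.positions[:, 1],
        bins=n,
        range=[[0, state.L], [0, state.L]],
    )
    dx = state.L / n
    return DensityField(H / dx**2, state.L, state.t)


def find_cluster_centers(field: DensityField, smooth_radius: float) -> np.ndarray:
    """Detect cluster centers in a density field.

    The field is smoothed with a top-hat of ``smooth_radius``, thresholded
    at the Otsu bimodal split, and connected components are labelled;
    centers are the density-weighted component centroids.  Components are
    merged across the periodic seam by rolling the labels.

    Returns an array of shape (n_clusters, 2).
    """
    from skimage.filters import threshold_otsu

    smoothed = nonlocal_density(field, smooth_radius)
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    labels, nlab = ndimage.label(mask)
    if nlab == 0:
        return np.empty((0, 2))
    # merge components that touch across the periodic boundary
    for ax in range(2):
        lo = labels.take(0, axis=ax)
        hi = labels.take(-1, axis=ax)
        for p, q in zip(lo, hi):
            if p > 0 and q > 0 and p != q:
                labels[labels == q] = p
    ids = [i for i in np.unique(labels) if i > 0]
    dx = field.dx
    centers = []
    for i in ids:
        ix, iy = np.nonzero(labels == i)
        w = smoothed[ix, iy]
        # periodic centroid via circular mean of each coordinate
        n = field.n
        cs = []
        for idx in (ix, iy):
            ang = 2.0 * math.pi * idx / n
            mean_ang = math.atan2((w * np.sin(ang)).sum(), (w * np.cos(ang)).sum())
            cs.append((mean_ang % (2.0 * math.pi)) / (2.0 * math.pi) * field.L)
        centers.append([cs[0] + dx / 2, cs[1] + dx / 2])
    return np.asarray(centers) % field.L


def radial_cluster_profile(
    data,
    smooth_radius: float,
    centers: np.ndarray | None = None,
    r_max: float | None = None,
    bin_width: float | None = None,
    grid_n: int = 256,
) -> list[RadialProfile]:
    """Radial density profile (and hollowness) of each detected cluster.

    Parameters
    ----------
    data : ParticleState or DensityField
        Pattern to analyze; particles are binned onto ``grid_n``^2 cells
        for center detection but profiled from their exact positions.
    smooth_radius : float
        Smoothing radius for cluster detection (typically R_s).
    centers : ndarray, optional
        Cluster centers; auto-detected when omitted.
    r_max : float, optional
        Profile extent; default 2 * smooth_radius.  If it exceeds half
        the nearest inter-center distance it is truncated (with a
        warning) so neighbouring clusters do not contaminate the profile.
    bin_width : float, optional
        Radial bin width; default r_max / 12.
    """
    is_particles = isinstance(data, ParticleState)
    field = bin_particles(data, grid_n) if is_particles else data
    if centers is None:
        centers = find_cluster_centers(field, smooth_radius)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        return []
    if r_max is None:
        r_max = 2.0 * smooth_radius
    L = field.L
    if len(centers) > 1:
        d = centers[:, None, :] - centers[None, :, :]
        d -= L * np.round(d / L)
        dist = np.sqrt((d**2).sum(axis=2))
        np.fill_diagonal(dist, np.inf)
        half_nn = dist.min() / 2.0
        if r_max > half_nn:
            warnings.warn(
                f"radial_cluster_profile: r_max={r_max:.3g} truncated to half the "
                f"nearest inter-cluster distance {half_nn:.3g}"
            )
            r_max = half_nn
    if bin_width is None:
        bin_width = r_max / 12.0
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    areas = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    mids = 0.5 * (edges[1:] + edges[:-1])

    if not is_particles:
        n = field.n
        x = (np.arange(n) + 0.5) * field.dx
        profiles = []
        for cen in centers:
            dxs = x[:, None] - cen[0]
            dys = x[None, :] - cen[1]
            dxs -= L * np.round(dxs / L)
            dys -= L * np.round(dys / L)
            rr = np.sqrt(dxs**2 + dys**2).ravel()
            vv = field.values.ravel()
            sums, _ = np.histogram(rr, bins=edges, weights=vv)
            cnts, _ = np.histogram(rr, bins=edges)
            with np.errstate(invalid="ignore"):
                dens = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
            profiles.append(_make_profile(cen, mids, dens))
        return profiles

    profiles = []
    for cen in centers:
        d = data.positions - cen
        d -= L * np.round(d / L)
        rr = np.sqrt((d**2).sum(axis=1))
        cnt, _ = np.histogram(rr, bins=edges)
        profiles.append(_make_profile(cen, mids, cnt / areas))
    return profiles


def _make_profile(center, r, density) -> RadialProfile:
    dens = np.asarray(density, dtype=float)
    finite = np.isfinite(dens)
    peak = dens[finite].max() if finite.any() else float("nan")
    inner = dens[finite][0] if finite.any() else float("nan")
    hollow = float(inner / peak) if peak and peak > 0 else float("nan")
    return RadialProfile(
        center=np.asarray(center, dtype=float), r=r, density=dens, hollowness=hollow
    )
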