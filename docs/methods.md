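# Methods

## Model

`twoscale` simulates a population of N identical organisms whose movement
responds to crowding at two spatial scales.  Each individual performs
Brownian motion on a periodic square of side L with a position-dependent
diffusion coefficient

    D_i = D0 * g( a − b·ρ̃_s(r_i) + c·ρ̃_l(r_i) ),

where ρ̃_s and ρ̃_l are the mean population densities inside concentric
disks of radius R_s and R_l (R_s < R_l) around the individual.  Crowding
at short range *suppresses* movement (aggregation is advantageous —
mussels clumping against predation and wave stress are the motivating
example) while crowding at long range *promotes* it (competition for
resources drives dispersal).  The response g maps the weighted density
combination to [0, 1]; the default is the sigmoid

    g(x) = (1 + tanh(2x − 1)) / 2,

but any monotone map to [0, 1] can be supplied (`ModelParams.g`): the
qualitative phenomenology does not depend on the tanh form, only on
monotonicity and saturation.  There is no birth, death or reproduction:
N (equivalently the global density ρ0 = N/L²) is strictly conserved.

In the mean-field limit the density ρ(r, t) obeys the nonlocal nonlinear
diffusion equation

    ∂ρ/∂t = D0 ∇²[ g(a − b·ρ̃_s + c·ρ̃_l) ρ ],     ρ̃_μ = G_μ ∗ ρ,

with G_μ the normalized top-hat (uniform disk) kernel of radius R_μ.
The equation is in divergence form, so mass is conserved; the uniform
state ρ = ρ0 is always stationary.

The stochastic dynamics is interpreted in the Itô sense: the
stop-or-move decision is taken at the *start* of each step, so the
Euler–Maruyama update evaluates all densities at the pre-step
configuration and displaces every particle synchronously by
√(2 D_i dt)·ξ with ξ a standard Gaussian pair.

### Neighbourhood counts

The per-particle densities are ρ̃_μ = N_μ / (π R_μ²), where N_μ counts
neighbours within R_μ *including the focal particle itself*, and the
long-range neighbourhood is the full disk (concentric with the short
one), not an annulus.  Self-inclusion keeps the discrete densities
consistent with the continuum convolution, which integrates the full
density — including the focal neighbourhood's own mass — under the
kernel.  Distances use the minimum-image convention.  Counting uses
uniform cell lists (cell size ≥ R_l, numba-compiled, O(N) per step)
whenever the box holds at least 3×3 cells; an O(N²) all-pairs loop is
the fallback and a vectorized all-pairs oracle backs both in the tests.

## Linear stability

Perturbing ρ0 with a plane wave gives the growth rate

    λ(k) = −(D0/2) [ 1 + tanh γ + 2ρ0 (c·Ĝ_l(k) − b·Ĝ_s(k)) / cosh²γ ] k²,
    γ = 2(a − bρ0 + cρ0) − 1,  Ĝ_μ(k) = 2 J1(k R_μ) / (k R_μ).

Patterns form when max_k λ(k) > 0.  The curvature of λ at k = 0 is
−D0·F0 with F0 = 1 + tanh γ + 2ρ0(c − b)/cosh²γ; F0 > 0 (k = 0 stable,
finite-k band unstable) is instability type A, which selects a fixed
wavelength and yields hexagonal spot arrangements; F0 < 0 (unstable band
from k = 0) is type B, which permits coarsening and yields labyrinths.
Note the ρ0 factor in F0: it is required by the k → 0 limit of λ(k), and
with densities of order 10⁴ against weights of order 10⁻⁴ the A/B
boundary is only meaningful with it.  A literal variant without the
factor exists behind `curvature_at_zero(..., include_density=False)` for
comparison only.

Because the top-hat transform oscillates, the *global* argmax of λ(k)
for type-B parameter sets can fall in a secondary high-k lobe (k ≈ 176
for the labyrinth reference set) rather than at the first local maximum
(k ≈ 51.3).  The saturated pattern's structure function reflects the
first local maximum; `DispersionCurve` therefore reports both `k_c`
(global argmax, scanned on 2000 points then refined by bounded parabolic
minimization, ties toward smaller k) and `k_first_peak`.  In the
continuum simulations the fast-growing high-k lobe is visible as an
early transient that the nonlinear dynamics replaces with the
first-peak scale within t ≈ 120.

## Numerics

**Continuum.**  Forward Euler on a periodic grid (default 256² for
L = 1, i.e. dx ≈ R_s/13; 600 points at dx = 0.01 for the 1D runs) with
the time step capped at the explicit stability bound dx²/(2·dim·D0) —
conservative, since the effective diffusivity D0·g never exceeds D0 —
and defaulting to half of it.  The Laplacian is the second-order centered
stencil with periodic wrap.  Convolutions are spectral: the kernel is
rasterized onto the grid with 4× sub-cell supersampling of the boundary
cells and normalized so a constant field is an exact fixed point
(discrete mass 1); sampling the analytic transform on the reciprocal
lattice is available via `kernel_method="analytic"`.  Negative
undershoot smaller than 10⁻¹²·mean(ρ) is clipped and the mass
renormalized; anything larger, or |ρ| exceeding 10⁶·mean(ρ), aborts with
a diagnostic.  Measured modal growth rates match the dispersion relation
within ~3% across stable and unstable wavenumbers at the default
operators, the strongest cross-module consistency check in the suite.

**Particles.**  Default dt sets the rms free displacement √(2 D0 dt) to
R_s/4 (dt = 0.78 for the 2D reference sets); a hard guard rejects steps
beyond R_s/2, which would hop over the neighbourhood structure.  The
pattern wavenumbers are insensitive to dt from 1.56 down to 0.05.

**Structure functions.**  For particles, S(k) = ⟨|Σ_j e^{i k·r_j}/N|²⟩
on the reciprocal lattice of the box (k a componentwise multiple of
2π/L), averaged over annuli of width 2π/L (one lattice shell per bin)
and over snapshots; the k = 0 mode is excluded and ties at the peak
break toward smaller k.  A coherent configuration gives S ≡ 1, an ideal
gas S ≈ 1/N.  For fields, the annulus- and time-averaged modulus of the
DFT (the squared variant is available; the peak location is identical).
Snapshots from the second half of a run enter the time average.

**Cluster morphology.**  Cluster centers are detected by smoothing the
density with a top-hat of radius R_s, thresholding at the Otsu bimodal
split, labelling connected components (merged across the periodic seam)
and taking density-weighted circular-mean centroids.  Radial profiles
are annulus averages around each center, truncated at half the nearest
inter-center distance; the hollowness index is the innermost-bin density
over the peak-bin density (≈1 for filled clusters, ≈0 for rings).

## Canonical experiments and their run lengths

The shipped configs fix the reference conditions: D0 = 10⁻⁴, a = 1,
R_s = 0.05, R_l = 0.1, L = 1, N = 10⁴ (ρ0 = 10⁴), with (b, c) =
(3.5, 7.0)×10⁻⁴ homogeneous, (8.5, 7.0)×10⁻⁴ labyrinth and
(4.3, 3.9)×10⁻⁴ spots; 2D continuum runs start from ρ0 with a seeded
1% i.i.d. uniform perturbation, particle runs from uniform-random
positions.  Run lengths are set by the linear instability timescale
(λ_max ≈ 0.38 for spots, ≈ 0.07 at the labyrinth first peak):
continuum spots integrate to t = 80 (the spectral peak is stationary
from t ≈ 16) and the labyrinth to t = 400 (stationary from t ≈ 120,
after the early high-k transient); particle runs integrate to t = 400
with snapshots every 10.  The 1D ring experiment uses a = 1, b = 3.33,
c = 2.67, R_s = 0.4, R_l = 0.75 on L = 6 (dx = 0.01, chosen so the
pulse sits ≥ 3 R_l from the boundary; the domain length is a free
choice of this package) with an initial rectangular pulse of height 1
and support 2 R_l (mass 1.5), integrated to t = 6×10⁵.

## What the experiments show — and their limits

The continuum spot and labyrinth runs place the structure-function peak
in the k = 50.27 spectral bin (bin width 2π), one bin around the
linear-theory values 49.5 and 51.3, robustly across seeds.  The
particle runs produce the same patterns but their discrete structure
functions have a *broad* plateau spanning roughly shells 6–9 (k ≈ 38–57)
whose single-bin argmax is fragile: at the canonical protocol it falls
on shell 8 (50.27) or shell 7 (43.98) depending on the seed, and at
much longer times (t ≳ 1000) slow noise-induced cluster merging drifts
it one shell lower.  A one-shell (±2π) uncertainty should therefore be
attached to any single-run discrete k_c.  The 1D ring run develops the
double-peak profile (separation 0.37 ≈ R_s) with a central diffusivity
plateau g ≈ 5×10⁻⁶, the mechanism that makes rings very-long-lived
transients rather than steady states: over times of order R_s²/(g D0)
the interior fills in.

The synthetic initial conditions are idealized: uniform-random particle
placement and i.i.d. density perturbations contain no spatial
correlations, boundaries are periodic, and the population is closed (no
demography, no environmental heterogeneity, no advection).  Passing
tests therefore validate the model's self-consistency and its published
phenomenology, not the fidelity of any particular field system; applying
the model to data would require calibrating a, b, c, R_s, R_l against
observed movement statistics.

## Known limitations

- The continuum integrator is explicit Euler only; stiff parameter sets
  (large D0 or fine grids) pay the full dx² step-size penalty.
- Fluctuations are absent from the continuum equation by construction
  (mean-field); the particle model is the reference where they matter,
  e.g. for the slow ripening of the discrete patterns noted above.
- Cluster detection assumes a bimodal density histogram; it
  under-segments labyrinths (which have no isolated clusters) and merges
  spot clusters connected by faint bridges.
- The 2D dispersion relation is implemented for the 2D kernel transform;
  1D runs are integrated numerically without a matching 1D linear
  analysis (none is needed for the shipped experiments).
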