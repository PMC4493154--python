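"""Experiment configuration, fixtures, text I/O and the experiment runner.

Experiments are described by flat key-value config files (one experiment
per file, ``#`` comments, optional ``include = other.cfg``).  A set of
canonical configs ships with the package — the three particle regimes
(homogeneous, labyrinth, spots), the two continuum pattern runs, the
dispersion-curve and phase-diagram scans, the 1D ring experiment and the
2D diffusivity map — so each headline result is reproducible with one
command.  All randomness is seeded and every output header records the
seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np

from . import continuum_sim, particle_sim, pattern_metrics, stability
from .continuum_sim import DensityField
from .model_core import ModelParams
from .particle_sim import ParticleState

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "load_config",
    "save_config",
    "canonical_config",
    "list_experiments",
    "make_fixture",
    "run_experiment",
    "late_snapshots",
    "write_particles",
    "write_field",
    "write_spectrum",
]

log = logging.getLogger(__name__)

_FIXTURES = ("pulse1d", "perturbed_homogeneous", "uniform_particles", "annulus", "lattice")


@dataclass
class ExperimentConfig:
    """Validated description of one simulation + analysis experiment.

    Attributes
    ----------
    name : str
        Experiment identifier (used for output file names).
    simulator : {"particle", "continuum", "stability"}
    params : ModelParams
        Physical parameters (dimension included).
    grid : int
        Grid points per side (continuum runs).
    dt : float or None
        Time step; simulator default when None.
    t_end : float
        Total integrated time.
    seed : int
        Seed for every random element of the experiment.
    snapshot_every : float or None
        Snapshot interval.
    perturbation : float
        Relative amplitude of the initial density perturbation
        (continuum 2D runs).
    initial : {"uniform", "perturbed_homogeneous", "pulse1d"}
    pulse_height : float
        Height of the 1D initial pulse.
    analyses : tuple of str
        Any of "structure_function", "profile", "diffusivity",
        "dispersion", "phase_diagram", "ring1d".
    b_range, c_range : tuple (min, max, n) or None
        Scan axes for phase-diagram experiments.
    """

    name: str = "experiment"
    simulator: str = "particle"
    params: ModelParams = None
    grid: int = 256
    dt: float | None = None
    t_end: float = 0.0
    seed: int = 0
    snapshot_every: float | None = None
    perturbation: float = 1e-2
    initial: str = "uniform"
    pulse_height: float = 1.0
    analyses: tuple = ("structure_function",)
    b_range: tuple | None = None
    c_range: tuple | None = None

    def __post_init__(self):
        if self.simulator not in ("particle", "continuum", "stability"):
            raise ValueError(f"unknown simulator {self.simulator!r}")
        if self.params is None:
            raise ValueError("ExperimentConfig requires model params")
        if self.t_end < 0:
            raise ValueError("t_end must be >= 0")
        if self.simulator == "particle":
            if self.params.N is None:
                raise ValueError("particle experiments require N")
            dt = self.dt if self.dt is not None else particle_sim.default_dt(self.params)
            if math.sqrt(2 * self.params.D0 * dt) > self.params.R_s / 2 * (1 + 1e-12):
                raise ValueError("dt violates the particle displacement guard (R_s/2)")
        if self.simulator == "continuum":
            if self.grid < 4:
                raise ValueError("continuum grid too small")
            dx = self.params.L / self.grid
            bound = dx**2 / (2 * self.params.dim * self.params.D0)
            if self.dt is not None and self.dt > bound:
                raise ValueError(f"dt={self.dt} exceeds the Euler stability bound {bound:.3e}")

    def replace(self, **changes) -> "ExperimentConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "simulator": self.simulator,
            "grid": self.grid,
            "t_end": self.t_end,
            "seed": self.seed,
            "perturbation": self.perturbation,
            "initial": self.initial,
            "pulse_height": self.pulse_height,
            "analyses": ",".join(self.analyses),
        }
        if self.dt is not None:
            d["dt"] = self.dt
        if self.snapshot_every is not None:
            d["snapshot_every"] = self.snapshot_every
        if self.b_range is not None:
            d["b_range"] = "{}:{}:{}".format(*self.b_range)
        if self.c_range is not None:
            d["c_range"] = "{}:{}:{}".format(*self.c_range)
        d.update(self.params.to_dict())
        return d


def _parse_value(s: str):
    s = s.strip()
    if s == "None":
        return None
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def _config_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    params = ModelParams.from_dict(d)
    kwargs = {"params": params}
    for key in (
        "name",
        "simulator",
        "grid",
        "dt",
        "t_end",
        "seed",
        "snapshot_every",
        "perturbation",
        "initial",
        "pulse_height",
    ):
        if key in d:
            kwargs[key] = d[key]
    if "analyses" in d:
        kwargs["analyses"] = tuple(a.strip() for a in str(d["analyses"]).split(",") if a.strip())
    for key in ("b_range", "c_range"):
        if key in d:
            lo, hi, n = str(d[key]).split(":")
            kwargs[key] = (float(lo), float(hi), int(n))
    if "grid" in kwargs:
        kwargs["grid"] = int(kwargs["grid"])
    if "seed" in kwargs:
        kwargs["seed"] = int(kwargs["seed"])
    return ExperimentConfig(**kwargs)


def _load_dict(path: Path) -> dict:
    d: dict = {}
    for raw in path.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed line {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key == "include":
            base = _load_dict(path.parent / val)
            base.update(d)
            d = base
        else:
            d[key] = _parse_value(val)
    return d


def load_config(path) -> ExperimentConfig:
    """Read a flat key-value config file (``include = file`` merges, local
    keys override included ones)."""
    path = Path(path)
    d = _load_dict(path)
    d.setdefault("name", path.stem)
    return _config_from_dict(d)


def save_config(config: ExperimentConfig, path) -> None:
    """Write a config as flat key-value text (lossless round trip)."""
    lines = [f"{k} = {v}" for k, v in config.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def list_experiments() -> list[str]:
    """Names of the canonical experiments shipped with the package."""
    pkg = resources.files("twoscale") / "configs"
    return sorted(
        p.name[: -len(".cfg")]
        for p in pkg.iterdir()
        if p.name.endswith(".cfg") and not p.name.startswith("base")
    )


def canonical_config(name: str) -> ExperimentConfig:
    """Load a shipped experiment config by name (see :func:`list_experiments`)."""
    pkg = resources.files("twoscale") / "configs" / f"{name}.cfg"
    if not pkg.is_file():
        raise KeyError(f"unknown experiment {name!r}; available: {list_experiments()}")
    with resources.as_file(pkg) as p:
        return load_config(p)


# ---------------------------------------------------------------- fixtures


def make_fixture(name: str, **kw):
    """Construct a named initial condition.

    Available fixtures
    ------------------
    pulse1d(R_l, L=6, dx=0.01, height=1)
        1D density: a centered rectangular pulse of the given height and
        support 2*R_l, i.e. total mass height * 2 * R_l.
    perturbed_homogeneous(n, L, rho0, eps=1e-2, seed=None, dim=2)
        Uniform density with an i.i.d. relative perturbation.
    uniform_particles(N, L, seed=None)
        Uniform-random particle positions.
    annulus(n, r0, L, center=None, jitter=0.0, seed=None)
        Particles on a ring of radius r0 (a synthetic hollow cluster).
    lattice(n_side, L)
        Particles on a square lattice.
    """
    if name == "pulse1d":
        return _pulse1d(**kw)
    if name == "perturbed_homogeneous":
        return continuum_sim.perturbed_uniform(**kw)
    if name == "uniform_particles":
        return particle_sim.uniform_particles(**kw)
    if name == "annulus":
        return _annulus(**kw)
    if name == "lattice":
        return _lattice(**kw)
    raise ValueError(f"unknown fixture {name!r}; valid names: {_FIXTURES}")


def _pulse1d(R_l: float, L: float = 6.0, dx: float = 0.01, height: float = 1.0) -> DensityField:
    n = int(round(L / dx))
    x = (np.arange(n) + 0.5) * (L / n)
    vals = np.where(np.abs(x - L / 2) <= R_l, height, 0.0)
    return DensityField(vals, L, 0.0)


def _annulus(
    n: int, r0: float, L: float, center=None, jitter: float = 0.0, seed=None
) -> ParticleState:
    rng = np.random.default_rng(seed)
    if center is None:
        center = (L / 2, L / 2)
    theta = rng.uniform(0, 2 * math.pi, n)
    r = r0 + jitter * rng.standard_normal(n)
    pos = np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]) % L
    return ParticleState(pos, L, seed=seed, rng=rng)


def _lattice(n_side: int, L: float) -> ParticleState:
    x = (np.arange(n_side) + 0.5) * (L / n_side)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    return ParticleState(np.column_stack([xx.ravel(), yy.ravel()]), L)


def late_snapshots(snaps: list) -> list:
    """Snapshots from the second half of a run (the post-transient window)."""
    t0, t1 = snaps[0].t, snaps[-1].t
    cut = t0 + 0.5 * (t1 - t0)
    late = [s for s in snaps if s.t >= cut]
    return late if late else [snaps[-1]]


# ------------------------------------------------------------------ runner


@dataclass
class ExperimentResult:
    """Bundle returned by :func:`run_experiment`."""

    config: ExperimentConfig
    snapshots: list = dc_field(default_factory=list)
    metrics: dict = dc_field(default_factory=dict)
    extras: dict = dc_field(default_factory=dict)
    log: list = dc_field(default_factory=list)

    def _log(self, msg: str):
        self.log.append(msg)
        log.info("%s: %s", self.config.name, msg)


def run_experiment(
    config: ExperimentConfig, out_dir=None, dry_run: bool = False
) -> ExperimentResult:
    """Execute one experiment end to end: simulate, analyze, optionally write.

    Guard violations (time-step bounds, radii) surface at config
    construction, before any compute.  With ``dry_run=True`` the validated
    config is echoed back without computing anything.
    """
    result = ExperimentResult(config=config)
    if dry_run:
        result._log(f"dry run; validated config: {config.to_dict()}")
        return result

    t0 = time.perf_counter()
    result._log(f"seed={config.seed} simulator={config.simulator} t_end={config.t_end}")
    if config.simulator == "particle":
        _run_particle(config, result)
    elif config.simulator == "continuum":
        if config.params.dim == 1:
            _run_continuum_1d(config, result)
        else:
            _run_continuum_2d(config, result)
    else:
        _run_stability(config, result)
    result.metrics["runtime_s"] = round(time.perf_counter() - t0, 3)
    result._log(f"done in {result.metrics['runtime_s']} s; metrics: {result.metrics}")

    if out_dir is not None:
        _write_results(result, Path(out_dir))
    return result


def _run_particle(config: ExperimentConfig, result: ExperimentResult):
    p = config.params
    initial = particle_sim.uniform_particles(p.N, p.L, seed=config.seed)
    snaps = particle_sim.run(
        initial, p, t_end=config.t_end, dt=config.dt, snapshot_every=config.snapshot_every
    )
    result.snapshots = snaps
    late = late_snapshots(snaps)
    if "structure_function" in config.analyses:
        spec = pattern_metrics.structure_function_particles(late)
        result.extras["spectrum"] = spec
        result.metrics["k_c"] = spec.k_c
        result.metrics["d"] = pattern_metrics.typical_distance(spec, noise_floor=2.0 / p.N)
    if "profile" in config.analyses:
        profiles = pattern_metrics.radial_cluster_profile(snaps[-1], smooth_radius=p.R_s)
        result.extras["profiles"] = profiles
        if profiles:
            result.metrics["hollowness"] = float(
                np.nanmedian([pr.hollowness for pr in profiles])
            )
            result.metrics["n_clusters"] = len(profiles)


def _run_continuum_2d(config: ExperimentConfig, result: ExperimentResult):
    p = config.params
    initial = continuum_sim.perturbed_uniform(
        config.grid, p.L, p.rho0, eps=config.perturbation, seed=config.seed
    )
    snaps = continuum_sim.integrate(
        initial, p, t_end=config.t_end, dt=config.dt, snapshot_every=config.snapshot_every
    )
    result.snapshots = snaps
    result.metrics["mass_drift"] = abs(snaps[-1].mass / snaps[0].mass - 1.0)
    late = late_snapshots(snaps)
    if "structure_function" in config.analyses:
        spec = pattern_metrics.structure_function_field(late)
        result.extras["spectrum"] = spec
        result.metrics["k_c"] = spec.k_c
        result.metrics["d"] = pattern_metrics.typical_distance(spec)
    if "diffusivity" in config.analyses:
        gfield = continuum_sim.diffusivity_field(snaps[-1], p)
        result.extras["diffusivity"] = gfield
        result.metrics["g_min"] = float(gfield.values.min())
    if "profile" in config.analyses:
        profiles = pattern_metrics.radial_cluster_profile(snaps[-1], smooth_radius=p.R_s)
        result.extras["profiles"] = profiles
        if profiles:
            result.metrics["hollowness"] = float(
                np.nanmedian([pr.hollowness for pr in profiles])
            )
            result.metrics["n_clusters"] = len(profiles)


def _run_continuum_1d(config: ExperimentConfig, result: ExperimentResult):
    p = config.params
    initial = _pulse1d(p.R_l, L=p.L, dx=p.L / config.grid, height=config.pulse_height)
    result.metrics["initial_mass"] = initial.mass
    snaps = continuum_sim.integrate(
        initial, p, t_end=config.t_end, dt=config.dt, snapshot_every=config.snapshot_every
    )
    result.snapshots = snaps
    result.metrics["mass_drift"] = abs(snaps[-1].mass / snaps[0].mass - 1.0)
    if "ring1d" in config.analyses:
        result.metrics.update(ring_profile_metrics(snaps[-1], p))
        result.extras["diffusivity"] = continuum_sim.diffusivity_field(snaps[-1], p)


def ring_profile_metrics(field: DensityField, params: ModelParams) -> dict:
    """Peak structure and central diffusivity plateau of a 1D profile.

    Identifies the two dominant density peaks, their separation, and the
    diffusivity factor g evaluated at the midpoint between them — the
    "plateau" that controls how long the double-peak (ring) structure
    survives before diffusing into a filled cluster.
    """
    from scipy.signal import find_peaks

    vals = field.values
    idx, props = find_peaks(vals, height=0.05 * vals.max())
    out: dict = {"n_peaks": int(len(idx))}
    if len(idx) < 2:
        return out
    # two highest peaks
    top2 = idx[np.argsort(props["peak_heights"])[-2:]]
    i1, i2 = sorted(int(i) for i in top2)
    x = (np.arange(field.n) + 0.5) * field.dx
    out["peak_positions"] = (float(x[i1]), float(x[i2]))
    out["peak_separation"] = float(x[i2] - x[i1])
    mid = (i1 + i2) // 2
    gfield = continuum_sim.diffusivity_field(field, params)
    out["g_mid"] = float(gfield.values[mid])
    return out


def _run_stability(config: ExperimentConfig, result: ExperimentResult):
    p = config.params
    if "phase_diagram" in config.analyses:
        if config.b_range is None or config.c_range is None:
            raise ValueError("phase-diagram experiments need b_range and c_range")
        bs = np.linspace(*config.b_range[:2], config.b_range[2])
        cs = np.linspace(*config.c_range[:2], config.c_range[2])
        pd = stability.phase_diagram(p, bs, cs)
        result.extras["phase_diagram"] = pd
        counts = {
            k.value: sum(cell is k for cell in pd.kinds.ravel())
            for k in stability.InstabilityType
        }
        result.metrics.update({f"n_{k}": v for k, v in counts.items()})
    else:
        curve = stability.most_unstable_mode(p)
        result.extras["dispersion"] = curve
        result.metrics["k_c"] = curve.k_c
        result.metrics["lambda_max"] = curve.lam_max
        result.metrics["type"] = curve.kind.value


# --------------------------------------------------------------------- I/O


def _header(meta: dict) -> str:
    return "\n".join(f"# {k} = {v}" for k, v in meta.items())


def write_particles(path, state: ParticleState, params: ModelParams | None = None) -> None:
    """Write one particle snapshot as delimited text (x y per row)."""
    meta = {"t": state.t, "N": state.N, "L": state.L, "seed": state.seed}
    if params is not None:
        meta.update(params.to_dict())
    np.savetxt(path, state.positions, header=_header(meta), comments="")


def read_particles(path) -> ParticleState:
    meta = _read_header(path)
    pos = np.loadtxt(path, comments="#")
    seed = meta.get("seed")
    return ParticleState(
        pos, float(meta["L"]), float(meta.get("t", 0.0)), seed=None if seed is None else int(seed)
    )


def write_field(path, field: DensityField, params: ModelParams | None = None) -> None:
    """Write a density field as a plain-text matrix with a metadata header."""
    meta = {"t": field.t, "L": field.L, "n": field.n, "dim": field.dim}
    if params is not None:
        meta.update(params.to_dict())
    np.savetxt(path, np.atleast_2d(field.values), header=_header(meta), comments="")


def read_field(path) -> DensityField:
    meta = _read_header(path)
    vals = np.loadtxt(path, comments="#")
    if int(meta.get("dim", vals.ndim)) == 1:
        vals = vals.ravel()
    return DensityField(vals, float(meta["L"]), float(meta.get("t", 0.0)))


def write_spectrum(path, spectrum) -> None:
    """Two-column (k, S) delimited text with header metadata."""
    meta = {
        "k_c": spectrum.k_c,
        "bin_width": spectrum.bin_width,
        "n_snapshots": spectrum.n_snapshots,
    }
    np.savetxt(path, np.column_stack([spectrum.k, spectrum.S]), header=_header(meta), comments="")


def _read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = (s.strip() for s in body.split("=", 1))
                meta[k] = _parse_value(v)
    return meta


def _write_results(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    name = result.config.name
    cfg = result.config
    save_config(cfg, out_dir / f"{name}.cfg")
    if result.snapshots:
        last = result.snapshots[-1]
        if isinstance(last, ParticleState):
            write_particles(out_dir / f"{name}_final.txt", last, cfg.params)
        else:
            write_field(out_dir / f"{name}_final.txt", last, cfg.params)
    if "spectrum" in result.extras:
        write_spectrum(out_dir / f"{name}_spectrum.txt", result.extras["spectrum"])
    if "dispersion" in result.extras:
        curve = result.extras["dispersion"]
        np.savetxt(
            out_dir / f"{name}_dispersion.txt",
            np.column_stack([curve.k, curve.lam]),
            header=_header({"k_c": curve.k_c, "lambda_max": curve.lam_max, "type": curve.kind.value}),
            comments="",
        )
    if "phase_diagram" in result.extras:
        pd = result.extras["phase_diagram"]
        codes = np.vectorize(lambda k: {"homogeneous": 0, "A": 1, "B": 2}[k.value])(pd.kinds)
        np.savetxt(
            out_dir / f"{name}_phase.txt",
            codes,
            fmt="%d",
            header=_header(
                {
                    "rows_b": " ".join(f"{b:g}" for b in pd.b_values),
                    "cols_c": " ".join(f"{c:g}" for c in pd.c_values),
                    "codes": "0=homogeneous 1=A 2=B",
                }
            ),
            comments="",
        )
    lines = [f"# metrics for {name} (seed={cfg.seed})"]
    lines += [f"{k} = {v}" for k, v in result.metrics.items()]
    lines += [f"# {msg}" for msg in result.log]
    (out_dir / f"{name}_metrics.txt").write_text("\n".join(lines) + "\n")
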