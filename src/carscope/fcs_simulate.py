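"""Brownian-dynamics simulation of photon-count traces for FCS.

Generates synthetic fluorescence fluctuation records from a mixture of
freely diffusing 3D species (e.g. a dye or a labeled ligand in solution)
and 2D membrane-confined species (e.g. receptors in the plasma membrane),
observed through a 3D Gaussian detection volume with triplet (dark-state)
blinking.  The simulator is the ground-truth oracle for the correlation
and model-fitting stages: every input parameter (diffusion coefficient,
occupancy, focus geometry, triplet kinetics) is known exactly, so
parameter recovery can be tested end to end.

Model
-----
Each particle performs an independent Brownian walk with Gaussian
increments of variance ``2 D dt`` per axis (2D species are confined to the
z = 0 membrane plane) inside a periodic box.  Each particle carries a
two-state bright/dark telegraph process with stationary dark fraction
``T_t`` and relaxation time ``tau_t``.  The expected count in a time bin is

    sum over bright particles of
        brightness
        * mean over position samples of exp(-2(x^2+y^2)/w_r^2 - 2 z^2/(S w_r)^2)
        * bin_width

where the bright/dark state is sampled at the bin centre (bins are
required to resolve the triplet time, so this is statistically exact at
all fitted lags).

and the realized count is Poisson-distributed around that expectation.

Units: lengths in micrometres, times in seconds, brightness in counts per
second at the beam centre.
"""

from __future__ import annotations

import hashlib
import io
import math
from dataclasses import dataclass, field, replace

import numba
import numpy as np

__all__ = [
    "SpeciesConfig",
    "SimulationConfig",
    "PhotonTrace",
    "simulate_trace",
    "simulate_runs",
    "effective_volume",
    "effective_area",
    "n_effective",
    "trace_to_csv",
    "trace_from_csv",
]

@dataclass(frozen=True)
class SpeciesConfig:
    """One diffusing species.

    Parameters
    ----------
    name : str
        Label carried through to metadata.
    dimensionality : int
        3 for free solution diffusion, 2 for membrane-confined diffusion
        in the z = 0 plane.
    diffusion_coefficient : float
        D in um^2/s.
    mean_count : float
        Mean number of particles in the simulation box (realized counts
        are Poisson-distributed per run).
    brightness : float
        Molecular brightness at the beam centre, counts/s.
    """

    name: str
    dimensionality: int
    diffusion_coefficient: float
    mean_count: float
    brightness: float

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if not np.isfinite(self.diffusion_coefficient) or self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be positive and finite")
        if not np.isfinite(self.mean_count) or self.mean_count < 0:
            raise ValueError("mean_count must be non-negative and finite")
        if not np.isfinite(self.brightness) or self.brightness < 0:
            raise ValueError("brightness must be non-negative and finite")


@dataclass(frozen=True)
class SimulationConfig:
    """Full study condition for one simulated FCS run.

    The detection volume is a 3D Gaussian with lateral 1/e^2 radius
    ``omega_r`` and axial radius ``S * omega_r``.  The box defaults to
    10 * omega_r laterally and 10 * S * omega_r axially (periodic
    boundaries), large enough that the detection profile is negligible at
    the boundary.
    """

    species: tuple[SpeciesConfig, ...]
    omega_r: float = 0.2
    structural_parameter: float = 4.0
    triplet_fraction: float = 0.15
    triplet_tau: float = 5e-6
    duration: float = 2.0
    bin_width: float = 2e-6
    position_resolution: float = 20.0
    box_xy: float | None = None
    box_z: float | None = None
    poisson_count: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species is required")
        if not np.isfinite(self.omega_r) or self.omega_r <= 0:
            raise ValueError("omega_r must be positive")
        if not np.isfinite(self.structural_parameter) or self.structural_parameter < 1:
            raise ValueError("structural parameter S must be >= 1")
        if not (0 <= self.triplet_fraction < 1):
            raise ValueError("triplet fraction must be in [0, 1)")
        if not np.isfinite(self.triplet_tau) or self.triplet_tau <= 0:
            raise ValueError("triplet tau must be positive")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError("duration must be positive")
        if not np.isfinite(self.bin_width) or self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.triplet_fraction > 0 and self.bin_width >= self.triplet_tau:
            raise ValueError(
                "bin width must be smaller than the triplet tau so the dark-state "
                "dynamics is resolved"
            )
        if self.position_resolution < 2:
            raise ValueError("position_resolution must be >= 2 steps per transit")
        if self.lateral_extent < 10 * self.omega_r - 1e-12:
            raise ValueError("lateral box extent must be >= 10 * omega_r")
        if self.axial_extent < 10 * self.omega_r - 1e-12:
            raise ValueError("axial box extent must be >= 10 * omega_r")

    @property
    def lateral_extent(self) -> float:
        return self.box_xy if self.box_xy is not None else 10.0 * self.omega_r

    @property
    def axial_extent(self) -> float:
        if self.box_z is not None:
            return self.box_z
        return 10.0 * self.structural_parameter * self.omega_r

    @property
    def omega_z(self) -> float:
        return self.structural_parameter * self.omega_r

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in trace metadata."""
        raw = repr(self).encode()
        return hashlib.sha1(raw).hexdigest()[:12]


@dataclass
class PhotonTrace:
    """Binned photon counts over time.

    ``counts`` are non-negative integers; ``duration`` equals
    ``n_bins * bin_width`` by construction.
    """

    counts: np.ndarray
    bin_width: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    @property
    def mean_rate(self) -> float:
        """Mean count rate in counts/s."""
        return float(self.counts.mean()) / self.bin_width

    def times(self) -> np.ndarray:
        """Bin start times in seconds."""
        return np.arange(self.n_bins) * self.bin_width


def effective_volume(config: SimulationConfig) -> float:
    """Effective detection volume pi^1.5 * omega_r^2 * omega_z in um^3."""
    return math.pi ** 1.5 * config.omega_r**2 * config.omega_z


def effective_area(config: SimulationConfig) -> float:
    """Effective detection area pi * omega_r^2 for membrane species, um^2."""
    return math.pi * config.omega_r**2


def n_effective(config: SimulationConfig, species: SpeciesConfig) -> float:
    """Mean number of particles of ``species`` in the effective volume/area."""
    if species.dimensionality == 3:
        box = config.lateral_extent**2 * config.axial_extent
        return species.mean_count * effective_volume(config) / box
    box = config.lateral_extent**2
    return species.mean_count * effective_area(config) / box


def _telegraph_events(
    rng: np.random.Generator,
    n_particles: int,
    duration: float,
    t_frac: float,
    tau_t: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bright/dark switching events for all particles of one species.

    Returns (times, cum_bright, bright) where ``times[i, p]`` is the end of
    dwell i for particle p, ``cum_bright`` the cumulative bright time up to
    that event, and ``bright[i, p]`` whether dwell i was bright.  The chain
    has stationary dark fraction ``t_frac`` and relaxation time ``tau_t``
    (rates: bright->dark t_frac/tau_t, dark->bright (1-t_frac)/tau_t).
    """
    mean_bright = tau_t / t_frac  # mean bright dwell = 1/k(bright->dark)
    mean_dark = tau_t / (1.0 - t_frac)
    mean_cycle = mean_bright + mean_dark
    n_cycles = duration / mean_cycle
    n_events = int(2 * (n_cycles + 8.0 * math.sqrt(n_cycles + 1.0) + 10.0))
    start_bright = rng.random(n_particles) < (1.0 - t_frac)
    while True:
        idx = np.arange(n_events)[:, None]
        bright = (idx % 2 == 0) == start_bright[None, :]
        means = np.where(bright, mean_bright, mean_dark)
        dwells = rng.exponential(1.0, size=(n_events, n_particles)) * means
        times = np.cumsum(dwells, axis=0)
        if times[-1].min() > duration:
            break
        n_events *= 2  # pragma: no cover - overshoot margin almost always enough
    cum_bright = np.cumsum(np.where(bright, dwells, 0.0), axis=0)
    # row-contiguous per particle for fast per-particle searchsorted
    return (
        np.ascontiguousarray(times.T),
        np.ascontiguousarray(cum_bright.T),
        np.ascontiguousarray(bright.T),
    )


_EMPTY_F8 = np.empty(0, dtype=np.float64)
_EMPTY_B = np.empty(0, dtype=np.bool_)


@numba.njit(cache=True, fastmath=True, nogil=True)
def _accumulate_particle_sparse(
    delta, disp, x, y, z, dims, upd,
    lx, lz, inv_wr2, inv_wz2,
    ev_times, ev_bright, use_triplet, bin_width, amp, n_bins,
):  # pragma: no cover - exercised through simulate_trace
    """Segment-based accumulation for species updated every ``upd`` bins.

    The detection weight is constant within an update block and the bright
    state is constant between switching events, so each particle's
    contribution is piecewise constant over bin segments.  Segment starts
    and ends are written into ``delta`` (length n_bins + 1); the caller
    recovers the per-bin rate with a cumulative sum.  This replaces
    per-bin work with ~(n_events + n_updates) operations per particle.
    """
    half_lx = 0.5 * lx
    half_lz = 0.5 * lz
    n_events = ev_times.shape[0]
    k = 0
    si = 0
    j = 0  # block index
    while j * upd < n_bins:
        b0 = j * upd
        b1 = min(b0 + upd, n_bins)
        x += disp[si, 0]
        if x > half_lx:
            x -= lx
        elif x < -half_lx:
            x += lx
        y += disp[si, 1]
        if y > half_lx:
            y -= lx
        elif y < -half_lx:
            y += lx
        arg = (x * x + y * y) * inv_wr2
        if dims == 3:
            z += disp[si, 2]
            if z > half_lz:
                z -= lz
            elif z < -half_lz:
                z += lz
            arg += z * z * inv_wz2
        si += 1
        c = amp * math.exp(-arg)
        if not use_triplet:
            delta[b0] += c
            delta[b1] -= c
        else:
            b = b0
            while b < b1:
                t_center = (b + 0.5) * bin_width
                while k < n_events and ev_times[k] <= t_center:
                    k += 1
                if k < n_events:
                    # bins with center < ev_times[k] share this state
                    b_end = int(math.ceil(ev_times[k] / bin_width - 0.5))
                    if b_end > b1:
                        b_end = b1
                    elif b_end <= b:
                        b_end = b + 1
                else:
                    b_end = b1
                if ev_bright[k]:
                    delta[b] += c
                    delta[b_end] -= c
                b = b_end
        j += 1


@numba.njit(cache=True, fastmath=True, nogil=True)
def _accumulate_particle(
    lam, disp, x, y, z, dims, n_sub, upd,
    lx, lz, inv_wr2, inv_wz2,
    ev_times, ev_bright, use_triplet, bin_width, amp,
):  # pragma: no cover - exercised through simulate_trace
    """Add one particle's expected counts to ``lam`` (fused inner loop).

    ``disp`` holds the particle's pre-scaled Gaussian steps; the walk is
    advanced per substep (fast species, detection weight averaged within
    the bin) or per ``upd``-bin block (slow species, weight held constant).
    The bright/dark state is read by walking the particle's switching-event
    times once.  Dark bins contribute nothing.
    """
    n_bins = lam.shape[0]
    half_lx = 0.5 * lx
    half_lz = 0.5 * lz
    k = 0
    si = 0
    w = 0.0
    for b in range(n_bins):
        if n_sub == 1:
            if b % upd == 0:
                x += disp[si, 0]
                if x > half_lx:
                    x -= lx
                elif x < -half_lx:
                    x += lx
                y += disp[si, 1]
                if y > half_lx:
                    y -= lx
                elif y < -half_lx:
                    y += lx
                arg = (x * x + y * y) * inv_wr2
                if dims == 3:
                    z += disp[si, 2]
                    if z > half_lz:
                        z -= lz
                    elif z < -half_lz:
                        z += lz
                    arg += z * z * inv_wz2
                w = math.exp(-arg)
                si += 1
        else:
            acc = 0.0
            for _ in range(n_sub):
                x += disp[si, 0]
                if x > half_lx:
                    x -= lx
                elif x < -half_lx:
                    x += lx
                y += disp[si, 1]
                if y > half_lx:
                    y -= lx
                elif y < -half_lx:
                    y += lx
                arg = (x * x + y * y) * inv_wr2
                if dims == 3:
                    z += disp[si, 2]
                    if z > half_lz:
                        z -= lz
                    elif z < -half_lz:
                        z += lz
                    arg += z * z * inv_wz2
                acc += math.exp(-arg)
                si += 1
            w = acc / n_sub
        if use_triplet:
            t = (b + 0.5) * bin_width
            while k < ev_times.shape[0] and ev_times[k] <= t:
                k += 1
            if not ev_bright[k]:
                continue
        lam[b] += amp * w


def _species_stepping(config: SimulationConfig, sp: SpeciesConfig) -> tuple[int, int]:
    """(n_sub, update_every) for one species.

    The position sampling interval targets ``tau_d / position_resolution``
    where tau_d = omega_r^2 / (4 D) is the species' focus transit time:
    fast species get sub-bin substeps (detection weight averaged within the
    bin), slow species are updated every ``update_every`` bins (weight held
    constant in between, a << tau_d plateau).  Exactly one of the two
    factors exceeds 1.
    """
    tau_d = config.omega_r**2 / (4.0 * sp.diffusion_coefficient)
    dt_target = tau_d / config.position_resolution
    if dt_target < config.bin_width:
        n_sub = min(math.ceil(config.bin_width / dt_target), 64)
        return n_sub, 1
    update_every = min(int(dt_target / config.bin_width), 1024)
    return 1, max(1, update_every)


def simulate_trace(config: SimulationConfig) -> PhotonTrace:
    """Simulate one photon-count trace. Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_bins = int(round(config.duration / config.bin_width))
    lam = np.zeros(n_bins, dtype=np.float64)

    lx = config.lateral_extent
    lz = config.axial_extent
    inv_wr2 = 2.0 / config.omega_r**2
    inv_wz2 = 2.0 / config.omega_z**2
    use_triplet = config.triplet_fraction > 0

    for sp in config.species:
        # grand-canonical occupancy by default: the observation region
        # exchanges particles with a vast reservoir (bulk solution,
        # surrounding membrane), which is the ensemble the standard FCS
        # model describes -- a fixed (canonical) particle number shifts
        # G(tau) down by ~ sum_i (R_i^2/N_i) at all finite lags relative
        # to that model.  poisson_count=False gives the canonical variant.
        if config.poisson_count:
            n_part = int(rng.poisson(sp.mean_count))
        else:
            n_part = int(round(sp.mean_count))
        if n_part == 0 or sp.brightness == 0:
            continue
        dims = sp.dimensionality
        n_sub, upd = _species_stepping(config, sp)
        dt = config.bin_width / n_sub if n_sub > 1 else config.bin_width * upd
        step_sigma = math.sqrt(2.0 * sp.diffusion_coefficient * dt)
        pos = np.zeros((n_part, 3), dtype=np.float64)
        pos[:, :2] = rng.uniform(-lx / 2, lx / 2, size=(n_part, 2))
        if dims == 3:
            pos[:, 2] = rng.uniform(-lz / 2, lz / 2, size=n_part)

        if use_triplet:
            ev_times, _, ev_bright = _telegraph_events(
                rng, n_part, config.duration * (1 + 1e-9) + config.bin_width,
                config.triplet_fraction, config.triplet_tau,
            )

        n_steps = (-(-n_bins // upd)) * n_sub  # position samples per particle
        sparse = n_sub == 1 and upd > 1
        delta = np.zeros(n_bins + 1, dtype=np.float64) if sparse else None
        for p in range(n_part):
            disp = rng.standard_normal((n_steps, dims), dtype=np.float32)
            disp *= np.float32(step_sigma)
            tv = ev_times[p] if use_triplet else _EMPTY_F8
            bv = ev_bright[p] if use_triplet else _EMPTY_B
            if sparse:
                _accumulate_particle_sparse(
                    delta, disp, pos[p, 0], pos[p, 1], pos[p, 2], dims, upd,
                    lx, lz, inv_wr2, inv_wz2, tv, bv, use_triplet,
                    config.bin_width, sp.brightness * config.bin_width, n_bins,
                )
            else:
                _accumulate_particle(
                    lam, disp, pos[p, 0], pos[p, 1], pos[p, 2], dims, n_sub, upd,
                    lx, lz, inv_wr2, inv_wz2, tv, bv, use_triplet,
                    config.bin_width, sp.brightness * config.bin_width,
                )
        if sparse:
            lam += np.cumsum(delta[:n_bins])

    # cancellation in the segment sums can leave -1e-18-scale residues
    np.clip(lam, 0.0, None, out=lam)
    counts = rng.poisson(lam)
    meta = {"seed": config.seed, "config_digest": config.digest(),
            "species": tuple(sp.name for sp in config.species)}
    return PhotonTrace(counts=counts, bin_width=config.bin_width, metadata=meta)


def simulate_runs(config: SimulationConfig, n_runs: int, seed: int | None = None) -> list[PhotonTrace]:
    """Simulate ``n_runs`` independent traces.

    Run seeds are derived from ``seed`` (default: ``config.seed``) so that
    the whole set is reproducible from a single integer.
    """
    base = config.seed if seed is None else seed
    run_seeds = np.random.default_rng(base).integers(2**31 - 1, size=n_runs)
    return [simulate_trace(replace(config, seed=int(s))) for s in run_seeds]


def trace_to_csv(trace: PhotonTrace, path_or_buf) -> None:
    """Write a trace as two-column CSV (time_s, counts)."""
    arr = np.column_stack([trace.times(), trace.counts])
    header = f"time_s,counts  # bin_width={trace.bin_width!r}"
    np.savetxt(path_or_buf, arr, delimiter=",", header=header, comments="# ")


def trace_from_csv(path_or_buf) -> PhotonTrace:
    """Read a trace written by :func:`trace_to_csv`."""
    if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "read"):
        arr = np.loadtxt(path_or_buf, delimiter=",", comments="#")
    else:  # pragma: no cover
        arr = np.loadtxt(io.StringIO(str(path_or_buf)), delimiter=",", comments="#")
    times, counts = arr[:, 0], arr[:, 1]
    if times.size < 2:
        raise ValueError("trace must contain at least two bins")
    bin_width = float(np.median(np.diff(times)))
    return PhotonTrace(counts=counts.astype(np.int64), bin_width=bin_width)
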