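"""Synthetic Brownian-dynamics engine for umbrella-sampling analyses.

This module generates the raw material the rest of the package consumes: a
tagged ion (or blocker) diffusing along a pore axis ``z`` over a configurable
free-energy landscape with a single Gaussian barrier at a constriction (the
"collar"), a continuous hydration-coordination coordinate ``n`` harmonically
coupled to a z-dependent mean, an optional uniform axial electric field, a
harmonic umbrella bias (fixed or steered), and a flat-bottomed lateral
restraint.  It also fabricates solvation snapshots (labelled oxygen clouds
around the ion) and exponentially decaying fluorescence traces for the
flux-assay analytics.

Dynamics are overdamped Langevin (Euler-Maruyama):

    z <- z - (D_z / k_B T) * dU/dz * dt + sqrt(2 D_z dt) * xi

with an analogous update for ``n`` and free lateral diffusion confined by a
one-sided harmonic wall beyond the flat-bottom radius.  All randomness is
driven by explicit integer seeds; identical seeds give bitwise-identical
trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .constants import FIELD_SLOPE_KJ_PER_MOL_A, kbt


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeSpec:
    """Ground-truth free-energy surface U(z, n) and dynamics parameters.

    U(z, n) = cavity_plateau
              + barrier_height * exp(-(z - barrier_center_z)^2 / (2 w^2))
              + 1/2 * coupling_kappa * (n - nbar(z))^2
              - ion_charge * field_strength * u_conv * z

    with nbar(z) = n_bulk - (n_bulk - n_collar) *
                   exp(-(z - barrier_center_z)^2 / (2 n_dip_width^2)).

    Units: lengths A, energies kJ/mol, time ps, field V/nm, charge e.
    """

    barrier_height: float = 6.0
    barrier_center_z: float = 22.0
    barrier_width: float = 1.5
    cavity_plateau: float = 0.0
    n_bulk: float = 6.5
    n_collar: float = 3.0
    n_dip_width: float = 1.5
    coupling_kappa: float = 5.0
    temperature: float = 303.15
    diffusion_z: float = 0.2
    diffusion_n: float = 0.5
    diffusion_xy: float = 0.2
    field_strength: float = 0.0
    ion_charge: float = 1.0
    box_length_z: float = 88.0

    def __post_init__(self) -> None:
        for name in ("barrier_width", "temperature"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("diffusion_z", "diffusion_n", "diffusion_xy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("barrier_height", "cavity_plateau", "n_bulk", "n_collar",
                     "n_dip_width", "coupling_kappa", "diffusion_n",
                     "field_strength", "ion_charge", "box_length_z"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def kbt(self) -> float:
        return kbt(self.temperature)

    @property
    def field_slope(self) -> float:
        """dU_field/dz = -field_slope, in kJ/mol/A."""
        return self.ion_charge * self.field_strength * FIELD_SLOPE_KJ_PER_MOL_A


@dataclass(frozen=True)
class UmbrellaWindowSpec:
    """One biased sampling window.

    ``force_constant`` is in the package's canonical kJ/mol/A^2 (the field's
    customary 3000 kJ/mol/nm^2 is 30 kJ/mol/A^2; convert at the I/O boundary).
    ``pulling_rate`` is in A/ns; 0 means a fixed-center window.
    """

    center_xi: float
    force_constant: float = 30.0
    duration: float = 2000.0
    sample_interval: float = 1.0
    seed: int = 0
    flat_bottom_radius: float = 2.0
    pulling_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        n = self.duration / self.sample_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sample_interval must divide duration evenly")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration / self.sample_interval))


@dataclass
class BrownianTrajectory:
    """Recorded samples of one Brownian run."""

    times: np.ndarray          # ps
    z: np.ndarray              # A
    n: np.ndarray | None = None
    xy: np.ndarray | None = None   # (N, 2), A
    window_id: int | str | None = None
    seed_used: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.times) != len(self.z):
            raise ValueError("times and z must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for arr in (self.n, self.xy):
            if arr is not None and len(arr) != len(self.times):
                raise ValueError("auxiliary arrays must match times length")


@dataclass
class SolvationSnapshot:
    """Ion position plus labelled oxygen coordinates for one frame."""

    ion_xyz: np.ndarray
    oxygens: list  # list of (xyz ndarray, label in {"water", "hydroxyl"})
    frame_time: float = 0.0
    frame_z: float = 0.0

    def __post_init__(self) -> None:
        self.ion_xyz = np.asarray(self.ion_xyz, dtype=float)
        if not np.all(np.isfinite(self.ion_xyz)):
            raise ValueError("ion coordinates must be finite")
        for xyz, label in self.oxygens:
            if label not in ("water", "hydroxyl"):
                raise ValueError(f"unknown oxygen label {label!r}")
            if not np.all(np.isfinite(np.asarray(xyz, dtype=float))):
                raise ValueError("oxygen coordinates must be finite")


class StabilityError(RuntimeError):
    """Raised when an integration step diverges; use a smaller dt."""


# --------------------------------------------------------------------------
# potential
# --------------------------------------------------------------------------

class GaussianChannelPotential:
    """Analytic U(z, n) evaluator with exact partial derivatives."""

    def __init__(self, spec: LandscapeSpec):
        self.spec = spec

    def n_mean(self, z):
        s = self.spec
        g = np.exp(-((np.asarray(z) - s.barrier_center_z) ** 2)
                   / (2.0 * s.n_dip_width ** 2))
        return s.n_bulk - (s.n_bulk - s.n_collar) * g

    def u(self, z, n=None):
        s = self.spec
        z = np.asarray(z, dtype=float)
        gb = np.exp(-((z - s.barrier_center_z) ** 2) / (2.0 * s.barrier_width ** 2))
        u = s.cavity_plateau + s.barrier_height * gb - s.field_slope * z
        if n is not None:
            u = u + 0.5 * s.coupling_kappa * (np.asarray(n) - self.n_mean(z)) ** 2
        return u

    def du_dz(self, z, n=None):
        s = self.spec
        z = np.asarray(z, dtype=float)
        dz = z - s.barrier_center_z
        gb = np.exp(-(dz ** 2) / (2.0 * s.barrier_width ** 2))
        grad = -s.barrier_height * dz / s.barrier_width ** 2 * gb - s.field_slope
        if n is not None and s.coupling_kappa != 0.0:
            gw = np.exp(-(dz ** 2) / (2.0 * s.n_dip_width ** 2))
            dnbar = (s.n_bulk - s.n_collar) * dz / s.n_dip_width ** 2 * gw
            grad = grad - s.coupling_kappa * (np.asarray(n) - self.n_mean(z)) * dnbar
        return grad

    def du_dn(self, z, n):
        s = self.spec
        return s.coupling_kappa * (np.asarray(n) - self.n_mean(z))


def build_potential(spec: LandscapeSpec) -> GaussianChannelPotential:
    """Build the analytic potential evaluator for a landscape spec."""
    return GaussianChannelPotential(spec)


# --------------------------------------------------------------------------
# Euler-Maruyama kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _em_kernel(z0, n0, nsteps, dt, record_every,
               barrier, zc, sigma, kappa, n_bulk, n_collar, n_dip_w,
               field_slope, dz_diff, dn_diff, dxy_diff, kt,
               bias_k, bias_c0, pull_rate_ps, wall_k, wall_r,
               noise_z, noise_n, noise_x, noise_y,
               out_z, out_n, out_x, out_y, out_t):  # pragma: no cover - jit
    z = z0
    n = n0
    x = 0.0
    y = 0.0
    dn_amp = n_bulk - n_collar
    sq_z = math.sqrt(2.0 * dz_diff * dt)
    sq_n = math.sqrt(2.0 * dn_diff * dt)
    sq_xy = math.sqrt(2.0 * dxy_diff * dt)
    mob_z = dz_diff / kt * dt
    mob_n = dn_diff / kt * dt
    mob_xy = dxy_diff / kt * dt
    irec = 0
    for step in range(nsteps):
        dzz = z - zc
        gb = math.exp(-(dzz * dzz) / (2.0 * sigma * sigma))
        gw = math.exp(-(dzz * dzz) / (2.0 * n_dip_w * n_dip_w))
        nbar = n_bulk - dn_amp * gw
        dnbar_dz = dn_amp * dzz / (n_dip_w * n_dip_w) * gw
        grad_z = (-barrier * dzz / (sigma * sigma) * gb
                  - field_slope
                  - kappa * (n - nbar) * dnbar_dz)
        cen = bias_c0 + pull_rate_ps * (step * dt)
        grad_z += bias_k * (z - cen)
        grad_n = kappa * (n - nbar)
        dzstep = -mob_z * grad_z + sq_z * noise_z[step]
        if abs(dzstep) > 5.0 * sigma:
            return step + 1
        z += dzstep
        n += -mob_n * grad_n + sq_n * noise_n[step]
        # lateral: free diffusion with one-sided harmonic wall at wall_r
        r = math.sqrt(x * x + y * y)
        fx = 0.0
        fy = 0.0
        if r > wall_r and r > 0.0:
            f = wall_k * (r - wall_r) / r
            fx = f * x
            fy = f * y
        x += -mob_xy * fx + sq_xy * noise_x[step]
        y += -mob_xy * fy + sq_xy * noise_y[step]
        if (step + 1) % record_every == 0:
            out_z[irec] = z
            out_n[irec] = n
            out_x[irec] = x
            out_y[irec] = y
            out_t[irec] = (step + 1) * dt
            irec += 1
    return 0


def _run_em(spec: LandscapeSpec, window: UmbrellaWindowSpec, dt: float,
            z0: float | None, rng: np.random.Generator,
            pull_rate_A_per_ns: float) -> BrownianTrajectory:
    ratio = window.sample_interval / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("dt must divide sample_interval evenly")
    record_every = int(round(ratio))
    nsteps = window.n_samples * record_every
    pot = GaussianChannelPotential(spec)
    start = window.center_xi if z0 is None else z0
    n_start = float(pot.n_mean(start))

    noise_z = rng.standard_normal(nsteps)
    noise_n = rng.standard_normal(nsteps)
    noise_x = rng.standard_normal(nsteps)
    noise_y = rng.standard_normal(nsteps)
    m = window.n_samples
    out_z = np.empty(m)
    out_n = np.empty(m)
    out_x = np.empty(m)
    out_y = np.empty(m)
    out_t = np.empty(m)

    status = _em_kernel(
        start, n_start, nsteps, dt, record_every,
        spec.barrier_height, spec.barrier_center_z, spec.barrier_width,
        spec.coupling_kappa, spec.n_bulk, spec.n_collar, spec.n_dip_width,
        spec.field_slope, spec.diffusion_z, spec.diffusion_n, spec.diffusion_xy,
        spec.kbt, window.force_constant, window.center_xi,
        pull_rate_A_per_ns * 1e-3, 100.0, window.flat_bottom_radius,
        noise_z, noise_n, noise_x, noise_y,
        out_z, out_n, out_x, out_y, out_t)
    if status != 0:
        raise StabilityError(
            f"divergent step at integration step {status}; use a smaller dt")
    xy = np.column_stack([out_x, out_y])
    return BrownianTrajectory(times=out_t, z=out_z, n=out_n, xy=xy,
                              seed_used=window.seed)


def simulate_window(potential: GaussianChannelPotential,
                    window: UmbrellaWindowSpec,
                    spec: LandscapeSpec | None = None,
                    dt: float = 0.01) -> BrownianTrajectory:
    """Sample one umbrella window by overdamped Euler-Maruyama dynamics.

    The ion starts at the bias center; the biased relaxation time
    k_B T / (k D_z) is orders of magnitude shorter than the default window
    duration, so no burn-in is discarded.
    """
    spec = spec if spec is not None else potential.spec
    rng = np.random.default_rng(window.seed)
    traj = _run_em(spec, window, dt, None, rng, window.pulling_rate)
    traj.window_id = window.center_xi
    return traj


def simulate_pull(potential: GaussianChannelPotential, start: float, end: float,
                  rate: float, k: float, spec: LandscapeSpec | None = None,
                  window_centers: Sequence[float] | None = None,
                  seed: int = 0, dt: float = 0.01,
                  sample_interval: float = 1.0):
    """Steered run with a harmonic restraint moving from start to end.

    ``rate`` is in A/ns.  Returns ``(trajectory, snapshots)`` where
    ``snapshots`` maps each requested window center to the recorded frame
    whose scheduled restraint position is nearest that center, for use as a
    window initialisation structure.
    """
    if not start < end:
        raise ValueError("start must be < end")
    if not rate > 0:
        raise ValueError("rate must be positive")
    spec = spec if spec is not None else potential.spec
    duration_ps = (end - start) / (rate * 1e-3)
    # round duration up to a whole number of sample intervals
    n_samp = int(math.ceil(duration_ps / sample_interval - 1e-9))
    window = UmbrellaWindowSpec(center_xi=start, force_constant=k,
                                duration=n_samp * sample_interval,
                                sample_interval=sample_interval, seed=seed,
                                pulling_rate=rate)
    rng = np.random.default_rng(seed)
    traj = _run_em(spec, window, dt, None, rng, rate)
    traj.window_id = "pull"
    snapshots = {}
    if window_centers is not None:
        sched = start + rate * 1e-3 * traj.times  # restraint position per frame
        for c in window_centers:
            if c < start - 1e-9 or c > end + 1e-9:
                raise ValueError(f"requested center {c} outside [{start}, {end}]")
            i = int(np.argmin(np.abs(sched - c)))
            snapshots[float(c)] = {"frame_index": i, "time": float(traj.times[i]),
                                   "z": float(traj.z[i]), "n": float(traj.n[i])}
    return traj, snapshots


def pull_schedule_duration(start: float, end: float, rate: float) -> float:
    """Scheduled steered-run duration in ns for a pull at ``rate`` A/ns."""
    if not start < end:
        raise ValueError("start must be < end")
    return (end - start) / rate


# --------------------------------------------------------------------------
# solvation snapshots
# --------------------------------------------------------------------------

def _random_shell_points(rng, count, r_lo, r_hi, center):
    """Points with uniform direction and radius uniform in [r_lo, r_hi]."""
    if count == 0:
        return np.empty((0, 3))
    v = rng.standard_normal((count, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(r_lo, r_hi, size=count)
    return center + v * r[:, None]


def generate_solvation_snapshots(traj: BrownianTrajectory,
                                 spec: LandscapeSpec,
                                 n_hydroxyl_near_collar: int = 1,
                                 seed: int = 0,
                                 cutoff: float = 3.0,
                                 decoy_rate: float = 12.0) -> list[SolvationSnapshot]:
    """Fabricate labelled oxygen clouds around the ion for each frame.

    Water oxygens within the first shell are drawn Poisson with mean equal to
    the frame's coordination value ``n`` and placed at r in [2.6, cutoff];
    decoy water oxygens (outside the cutoff, r in (cutoff, 6.0]) are Poisson
    with mean ``decoy_rate``.  Hydroxyl-labelled oxygens are placed inside the
    cutoff only for frames within ``n_dip_width`` of the collar, emulating
    transient tyrosine-OH coordination at the constriction.
    """
    if traj.n is None:
        raise ValueError("trajectory has no coordination series n")
    rng = np.random.default_rng(seed)
    snaps = []
    for i in range(len(traj.times)):
        z = float(traj.z[i])
        if traj.xy is not None:
            ion = np.array([traj.xy[i, 0], traj.xy[i, 1], z])
        else:
            ion = np.array([0.0, 0.0, z])
        lam = max(float(traj.n[i]), 0.0)
        n_in = rng.poisson(lam)
        n_out = rng.poisson(decoy_rate)
        oxygens = []
        for p in _random_shell_points(rng, n_in, 2.6, cutoff, ion):
            oxygens.append((p, "water"))
        for p in _random_shell_points(rng, n_out, cutoff + 1e-6, 6.0, ion):
            oxygens.append((p, "water"))
        if abs(z - spec.barrier_center_z) < spec.n_dip_width:
            for p in _random_shell_points(rng, n_hydroxyl_near_collar,
                                          2.6, cutoff, ion):
                oxygens.append((p, "hydroxyl"))
        snaps.append(SolvationSnapshot(ion_xyz=ion, oxygens=oxygens,
                                       frame_time=float(traj.times[i]),
                                       frame_z=z))
    return snaps


# --------------------------------------------------------------------------
# fluorescence traces
# --------------------------------------------------------------------------

def generate_flux_trace(rate: float, amplitude: float = 100.0,
                        offset: float = 0.0, noise_sd: float = 0.0,
                        t_cccp: float = 0.0, t_val: float = 35.0,
                        seed: int = 0, dt_min: float = 1.0,
                        t_start: float = -3.0, t_end: float = 55.0):
    """Synthetic normalized ACMA fluorescence trace (percent scale).

    F(t) = offset + amplitude * exp(-rate * (t - t_cccp)) + N(0, noise_sd^2)
    for t >= t_cccp, flat at amplitude + offset before the protonophore
    addition at ``t_cccp``.  ``rate`` is in 1/min on a uniform grid of
    ``dt_min``-minute spacing spanning [t_start, t_end].
    """
    from .flux import FluxTrace  # local import to avoid a cycle

    if rate < 0:
        raise ValueError("rate must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    times = np.arange(t_start, t_end + 0.5 * dt_min, dt_min)
    f = np.where(times < t_cccp, amplitude + offset,
                 offset + amplitude * np.exp(-rate * (times - t_cccp)))
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=times.shape)
    return FluxTrace(times=times, fluorescence=f, t_cccp=t_cccp, t_val=t_val,
                     normalized=True, condition="synthetic", replicate=seed)


# --------------------------------------------------------------------------
# window schedules
# --------------------------------------------------------------------------

def default_window_centers(lo: float = 16.5, hi: float = 36.5,
                           spacing: float = 0.2) -> np.ndarray:
    """Uniform window centers spanning [lo, hi] at ``spacing`` A."""
    n = int(math.floor((hi - lo) / spacing + 1e-9)) + 1
    return lo + spacing * np.arange(n)


def make_window_specs(centers: Sequence[float], force_constant: float = 30.0,
                      duration: float = 2000.0, sample_interval: float = 1.0,
                      base_seed: int = 0) -> list[UmbrellaWindowSpec]:
    """One fixed-center window spec per center, with distinct derived seeds."""
    return [UmbrellaWindowSpec(center_xi=float(c), force_constant=force_constant,
                               duration=duration, sample_interval=sample_interval,
                               seed=int(base_seed + 1000 + i))
            for i, c in enumerate(centers)]
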