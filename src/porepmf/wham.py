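"""Weighted histogram analysis method (WHAM) with Bayesian-bootstrap errors.

Combines harmonically biased umbrella-window histograms along a scalar
reaction coordinate z into one unbiased density rho(z) by self-consistent
iteration of

    rho(z_b) = sum_i h_ib / sum_i N_i exp((f_i - w_i(z_b)) / k_B T)
    f_i      = -k_B T ln sum_b rho(z_b) exp(-w_i(z_b) / k_B T)

with w_i(z) = 1/2 k_i (z - c_i)^2, iterated until max_i |delta f_i| falls
below a tolerance.  The free-energy profile is F(z) = -k_B T ln rho(z),
shifted per a reference policy.  Uncertainties come from a Bayesian
bootstrap: complete windows are reweighted by Dirichlet(1, ..., 1) draws and
the per-bin standard deviation across re-referenced replicate profiles is
reported as the SEM.  A 2D extension reweights per-sample (z, n) pairs with
the converged window free energies to produce an unbiased PMF over position
and coordination number.

Iteration runs in log space (logsumexp) so that steep biases far from a
window center cannot overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .constants import kbt


class DisconnectedSupportError(RuntimeError):
    """Window histograms leave a gap in the sampled range."""


class ConvergenceError(RuntimeError):
    """WHAM iteration failed to reach tolerance within max_iter."""

    def __init__(self, msg: str, residual: float):
        super().__init__(msg)
        self.residual = residual


@dataclass
class UmbrellaWindow:
    """Samples from one harmonically biased window."""

    center: float                       # A
    force_constant: float               # kJ/mol/A^2
    samples_z: np.ndarray               # A
    samples_aux: np.ndarray | None = None   # per-sample coordination
    temperature: float = 303.15

    def __post_init__(self) -> None:
        self.samples_z = np.asarray(self.samples_z, dtype=float)
        if self.samples_z.size < 1:
            raise ValueError("window must contain at least one sample")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.samples_aux is not None:
            self.samples_aux = np.asarray(self.samples_aux, dtype=float)
            if self.samples_aux.shape != self.samples_z.shape:
                raise ValueError("aux array must match samples_z length")

    @property
    def n_samples(self) -> int:
        return self.samples_z.size

    def bias(self, z):
        return 0.5 * self.force_constant * (np.asarray(z) - self.center) ** 2


@dataclass
class PMFProfile:
    """Free-energy profile on a grid, with bootstrap SEM."""

    bin_centers: np.ndarray
    free_energy: np.ndarray             # kJ/mol
    sem: np.ndarray | None = None
    window_free_energies: np.ndarray | None = None
    reference_policy: str = "min_zero"
    converged: bool = True
    iterations: int = 0
    log_density: np.ndarray | None = field(default=None, repr=False)
    temperature: float = 303.15

    def interp(self, z):
        """Free energy at arbitrary positions by linear interpolation."""
        z = np.asarray(z, dtype=float)
        lo, hi = self.bin_centers[0], self.bin_centers[-1]
        if np.any(z < lo) or np.any(z > hi):
            raise ValueError(f"position outside profile support [{lo}, {hi}]")
        return np.interp(z, self.bin_centers, self.free_energy)


@dataclass
class PMF2D:
    """Unbiased free energy over (z, coordination)."""

    z_centers: np.ndarray
    n_centers: np.ndarray
    free_energy: np.ndarray      # shape (nz, nn); +inf on unvisited cells
    visited: np.ndarray          # bool mask
    temperature: float = 303.15


# --------------------------------------------------------------------------
# core solver
# --------------------------------------------------------------------------

def _reference(f: np.ndarray, policy, bin_centers) -> np.ndarray:
    if policy == "min_zero":
        return f - np.nanmin(f)
    if isinstance(policy, tuple) and policy[0] == "plateau_zero":
        lo, hi = policy[1]
        sel = (bin_centers >= lo) & (bin_centers <= hi)
        if not np.any(sel):
            raise ValueError("plateau reference range contains no bins")
        return f - np.nanmean(f[sel])
    raise ValueError(f"unknown reference policy {policy!r}")


def _check_support(windows, edges, counts):
    total = counts.sum(axis=0)
    if not np.any(total > 0):
        raise DisconnectedSupportError("no samples fall inside the grid")
    # warn when adjacent windows (by center) share no occupied bin
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            warnings.warn(
                f"adjacent windows at {windows[a].center} and {windows[b].center} A "
                "share no occupied bin; PMF may be poorly determined",
                stacklevel=3)
    # windows must form one connected component under shared-occupied-bin
    # overlap; isolated empty interior bins are tolerable (they come out as
    # +inf free energy), a split support is not
    occ = counts > 0
    nwin = len(windows)
    adj = (occ.astype(int) @ occ.astype(int).T) > 0
    component = np.full(nwin, -1)
    label = 0
    for start in range(nwin):
        if component[start] >= 0:
            continue
        stack = [start]
        component[start] = label
        while stack:
            i = stack.pop()
            for j in np.flatnonzero(adj[i]):
                if component[j] < 0:
                    component[j] = label
                    stack.append(j)
        label += 1
    if label > 1:
        spans = []
        for c in range(label):
            bins = np.flatnonzero(occ[component == c].any(axis=0))
            spans.append((bins.min(), bins.max()))
        spans.sort()
        lo_bin = spans[0][1]
        hi_bin = spans[1][0]
        raise DisconnectedSupportError(
            "window histograms do not overlap across the gap "
            f"[{edges[lo_bin + 1]:.3f}, {edges[hi_bin]:.3f}] A")


def _logsumexp_ax(a, axis):
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out


def _wham_iterate(counts, n_eff, log_bias_bt, tolerance, max_iter,
                  f_init=None, accelerate=True):
    """Solve the WHAM self-consistency equations (all energies in kBT units).

    counts: (nwin, nbins) effective histogram counts (may be non-integer),
    n_eff: (nwin,) effective samples per window,
    log_bias_bt: (nwin, nbins) of -w_i(z_b)/kBT.

    The fixed point is the stationary point of the convex objective
    Phi(f) = sum_b H_b ln sum_i N_i exp(f_i - w_ib) - sum_i N_i f_i, so when
    ``accelerate`` is set an L-BFGS minimisation of Phi supplies a warm
    start; convergence is then certified by direct self-consistent iteration
    until max_i |delta f_i| < tolerance, the reported metric.
    Returns (log_rho, f, iterations, residual).
    """
    from scipy.optimize import minimize

    nwin = counts.shape[0]
    f = np.zeros(nwin) if f_init is None else np.array(f_init, dtype=float)
    total = counts.sum(axis=0)
    occupied = total > 0
    log_total = np.full(total.shape, -np.inf)
    log_total[occupied] = np.log(total[occupied])
    with np.errstate(divide="ignore"):
        log_n = np.where(n_eff > 0, np.log(np.maximum(n_eff, 1e-300)), -np.inf)

    if accelerate and nwin > 1:
        h_occ = total[occupied]
        lb_occ = log_bias_bt[:, occupied]

        def objective(g):
            a = log_n[:, None] + g[:, None] + lb_occ
            log_denom = _logsumexp_ax(a, axis=0)
            phi = float(np.sum(h_occ * log_denom) - np.dot(n_eff, g))
            # gradient: N_i * sum_b H_b softmax_i(a_ib) - N_i
            p = np.exp(a - log_denom[None, :])
            grad = p @ h_occ - n_eff
            return phi, grad

        res = minimize(objective, f, jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10})
        f = res.x - res.x[0]

    residual = np.inf
    for it in range(1, max_iter + 1):
        # log denom_b = logsumexp_i [ log N_i + (f_i - w_ib)/kBT ]
        log_denom = _logsumexp_ax(log_n[:, None] + f[:, None] + log_bias_bt,
                                  axis=0)
        log_rho = log_total - log_denom
        # f_i = -ln sum_b rho_b exp(-w_ib/kBT)   (in kBT units here)
        f_new = -_logsumexp_ax(log_rho[None, :] + log_bias_bt, axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tolerance:
            return log_rho, f, it, residual
    raise ConvergenceError(
        f"WHAM did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})", residual)


def _prepare(windows, grid):
    edges = np.asarray(grid, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("grid must be a 1D array of at least two bin edges")
    centers = 0.5 * (edges[:-1] + edges[1:])
    temps = {w.temperature for w in windows}
    if len(temps) != 1:
        raise ValueError("all windows must share one temperature")
    temperature = temps.pop()
    kt = kbt(temperature)
    counts = np.stack([np.histogram(w.samples_z, bins=edges)[0].astype(float)
                       for w in windows])
    bias = np.stack([w.bias(centers) for w in windows])
    return edges, centers, temperature, kt, counts, -bias / kt


def solve_wham(windows, grid, tolerance: float = 1e-6, max_iter: int = 100_000,
               reference_policy="min_zero", f_init=None) -> PMFProfile:
    """Solve the WHAM equations on a 1D grid of bin edges.

    ``tolerance`` is on max_i |delta f_i| in kJ/mol per iteration.  The first
    window's free energy is pinned to zero.  Raises
    :class:`DisconnectedSupportError` if the pooled histogram has an interior
    gap and :class:`ConvergenceError` past ``max_iter``.
    """
    if len(windows) < 1:
        raise ValueError("need at least one window")
    edges, centers, temperature, kt, counts, log_bias_bt = _prepare(windows, grid)
    _check_support(windows, edges, counts)
    n_eff = counts.sum(axis=1)  # samples inside the grid
    log_rho, f_bt, iters, _ = _wham_iterate(
        counts, n_eff, log_bias_bt, tolerance / kt, max_iter,
        None if f_init is None else np.asarray(f_init) / kt)
    free = np.where(np.isfinite(log_rho), -kt * log_rho, np.inf)
    free = _reference(np.where(np.isfinite(free), free, np.nan),
                      reference_policy, centers)
    free = np.where(np.isnan(free), np.inf, free)
    return PMFProfile(bin_centers=centers, free_energy=free,
                      window_free_energies=f_bt * kt,
                      reference_policy="min_zero" if reference_policy == "min_zero"
                      else "plateau_zero", converged=True, iterations=iters,
                      log_density=log_rho, temperature=temperature)


def bootstrap_pmf(windows, grid, B: int = 200, seed: int = 0,
                  tolerance: float = 1e-6, max_iter: int = 100_000,
                  reference_policy="min_zero",
                  resample: str = "windows") -> np.ndarray:
    """Bayesian-bootstrap per-bin SEM of the WHAM profile.

    Each of the ``B`` replicates reweights complete window histograms by
    Dirichlet(1, ..., 1) weights over windows (``resample="windows"``, the
    default, respecting within-window autocorrelation) or reweights samples
    within each window (``resample="samples"``).  Replicates are re-referenced
    before the standard deviation across them is taken, so the arbitrary
    additive constant does not inflate the SEM.  Deterministic under ``seed``.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if resample not in ("windows", "samples"):
        raise ValueError("resample must be 'windows' or 'samples'")
    edges, centers, temperature, kt, counts, log_bias_bt = _prepare(windows, grid)
    _check_support(windows, edges, counts)
    nwin = len(windows)
    n_eff = counts.sum(axis=1)
    # warm start from the full-data solution
    _, f_full, _, _ = _wham_iterate(counts, n_eff, log_bias_bt,
                                    tolerance / kt, max_iter)
    rng = np.random.default_rng(seed)
    profiles = np.empty((B, centers.size))
    for b in range(B):
        if resample == "windows":
            lam = rng.dirichlet(np.ones(nwin)) * nwin
            c = counts * lam[:, None]
        else:
            c = np.empty_like(counts)
            for i, w in enumerate(windows):
                wts = rng.dirichlet(np.ones(w.n_samples)) * w.n_samples
                c[i] = np.histogram(w.samples_z, bins=edges, weights=wts)[0]
        ne = c.sum(axis=1)
        log_rho, _, _, _ = _wham_iterate(c, ne, log_bias_bt, tolerance / kt,
                                         max_iter, f_init=f_full)
        free = np.where(np.isfinite(log_rho), -kt * log_rho, np.nan)
        profiles[b] = _reference(free, reference_policy, centers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        sem = np.nanstd(profiles, axis=0, ddof=1)
    return np.where(np.isnan(sem), np.inf, sem)


def solve_wham_with_sem(windows, grid, tolerance: float = 1e-6,
                        B: int = 200, seed: int = 0,
                        reference_policy="min_zero") -> PMFProfile:
    """Convenience wrapper: full WHAM solve plus Bayesian-bootstrap SEM."""
    profile = solve_wham(windows, grid, tolerance=tolerance,
                         reference_policy=reference_policy)
    profile.sem = bootstrap_pmf(windows, grid, B=B, seed=seed,
                                tolerance=tolerance,
                                reference_policy=reference_policy)
    return profile


# --------------------------------------------------------------------------
# 2D reweighting
# --------------------------------------------------------------------------

def reweight_2d(windows, f_i, z_grid, n_grid,
                temperature: float | None = None) -> PMF2D:
    """Unbiased 2D PMF over (z, n) from per-sample reweighting.

    Each sample (z, n) from window i carries weight
    1 / sum_j N_j exp((f_j - w_j(z_b)) / k_B T), where z_b is the center of
    the z bin holding the sample — the same discretisation the 1D WHAM solve
    uses, so the n-marginal of the 2D histogram is consistent with the 1D
    unbiased density.  The weighted histogram is Boltzmann-inverted and
    min-zeroed.  ``f_i`` are the converged window free energies from
    :func:`solve_wham` (kJ/mol); samples outside the z grid are dropped.
    """
    for w in windows:
        if w.samples_aux is None:
            raise ValueError(
                f"window at {w.center} A has no auxiliary coordination samples")
    if temperature is None:
        temperature = windows[0].temperature
    kt = kbt(temperature)
    f_i = np.asarray(f_i, dtype=float)
    z_edges = np.asarray(z_grid, dtype=float)
    n_edges = np.asarray(n_grid, dtype=float)
    log_n = np.log(np.array([w.n_samples for w in windows], dtype=float))

    # log denom_b = logsumexp_j [ ln N_j + (f_j - w_j(z_b))/kBT ], shared
    # across windows, evaluated at bin centers like the 1D solve
    z_centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    bias_bt = np.stack([w.bias(z_centers) for w in windows]) / kt
    log_denom = logsumexp(log_n[:, None] + f_i[:, None] / kt - bias_bt, axis=0)
    log_w_bin = -(log_denom - log_denom.min())  # common scale drops out
    hist = np.zeros((z_edges.size - 1, n_edges.size - 1))
    nz = z_edges.size - 1
    for w in windows:
        ib = np.digitize(w.samples_z, z_edges) - 1
        inside = (ib >= 0) & (ib < nz)
        h, _, _ = np.histogram2d(w.samples_z[inside],
                                 w.samples_aux[inside],
                                 bins=(z_edges, n_edges),
                                 weights=np.exp(log_w_bin[ib[inside]]))
        hist += h
    visited = hist > 0
    free = np.full(hist.shape, np.inf)
    free[visited] = -kt * np.log(hist[visited])
    free[visited] -= free[visited].min()
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    nc = 0.5 * (n_edges[:-1] + n_edges[1:])
    return PMF2D(z_centers=zc, n_centers=nc, free_energy=free,
                 visited=visited, temperature=temperature)


def marginalize_z(pmf2d: PMF2D) -> np.ndarray:
    """Collapse a 2D PMF over n back to a 1D profile, min-zeroed."""
    kt = kbt(pmf2d.temperature)
    with np.errstate(over="ignore"):
        p = np.where(pmf2d.visited, np.exp(-pmf2d.free_energy / kt), 0.0)
    pz = p.sum(axis=1)
    out = np.full(pz.shape, np.inf)
    m = pz > 0
    out[m] = -kt * np.log(pz[m])
    out[m] -= out[m].min()
    return out


# --------------------------------------------------------------------------
# profile utilities
# --------------------------------------------------------------------------

def barrier_height(profile: PMFProfile, barrier_range, reference_range):
    """Barrier height: max F over barrier_range minus mean F over
    reference_range, with SEM propagated in quadrature (treating bins as
    independent, which overstates the reference-mean SEM slightly).

    Returns ``(height, sem)``; ``sem`` is None when the profile carries none.
    """
    z = profile.bin_centers
    bsel = (z >= barrier_range[0]) & (z <= barrier_range[1])
    rsel = (z >= reference_range[0]) & (z <= reference_range[1])
    bsel &= np.isfinite(profile.free_energy)
    rsel &= np.isfinite(profile.free_energy)
    if not np.any(bsel) or not np.any(rsel):
        raise ValueError("barrier or reference range contains no occupied bins")
    i_max = np.flatnonzero(bsel)[np.argmax(profile.free_energy[bsel])]
    height = float(profile.free_energy[i_max]
                   - profile.free_energy[rsel].mean())
    if profile.sem is None:
        return height, None
    sem_ref = float(np.sqrt(np.sum(profile.sem[rsel] ** 2)) / rsel.sum())
    sem = float(np.hypot(profile.sem[i_max], sem_ref))
    return height, sem


def windows_from_trajectories(specs, trajectories, temperature: float):
    """Package simulated trajectories as WHAM input windows."""
    out = []
    for spec, traj in zip(specs, trajectories):
        out.append(UmbrellaWindow(center=spec.center_xi,
                                  force_constant=spec.force_constant,
                                  samples_z=traj.z,
                                  samples_aux=traj.n,
                                  temperature=temperature))
    return out


def default_grid(windows, n_bins: int = 100) -> np.ndarray:
    """Uniform bin edges spanning the union of window sample supports."""
    lo = min(w.samples_z.min() for w in windows)
    hi = max(w.samples_z.max() for w in windows)
    pad = 1e-9 * max(1.0, abs(hi - lo))
    return np.linspace(lo - pad, hi + pad, n_bins + 1)
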