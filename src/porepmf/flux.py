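"""Liposome flux-assay analytics.

In the ACMA assay, proton influx through a protonophore (CCCP, added at
t = 0) quenches a pH-sensitive dye only when counter-ion K+ flux through the
reconstituted channel permits it; the K+ ionophore valinomycin (added at
t = 35 min) defines the fluorescence floor.  Traces are normalized between
the value at CCCP addition (100%) and the post-valinomycin floor (0%), and a
first-order exponential decay fitted over the CCCP-to-valinomycin window
gives a rate constant per condition.  Conditions are compared to a control
with a two-sided Dunnett many-to-one test at family-wise alpha = 0.05, with
adjusted p-values from a Monte Carlo estimate of the joint null of the
maximum |t|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class FluxTrace:
    """One fluorescence time series (raw units or percent)."""

    times: np.ndarray          # min
    fluorescence: np.ndarray
    t_cccp: float = 0.0
    t_val: float = 35.0
    normalized: bool = False
    condition: str = ""
    replicate: int | str = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.times) != len(self.fluorescence):
            raise ValueError("times and fluorescence must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class DecayFit:
    """First-order decay F(t) = A exp(-k t) + C fitted over a window."""

    amplitude: float           # A, percent
    rate_per_min: float        # k
    offset: float              # C
    rss: float
    fit_window: tuple = (0.0, 35.0)
    converged: bool = True
    no_flux: bool = False

    @property
    def rate_per_s(self) -> float:
        return self.rate_per_min / 60.0

    @property
    def tau_min(self) -> float:
        return 1.0 / self.rate_per_min if self.rate_per_min > 0 else np.inf


@dataclass
class DunnettResult:
    """Many-to-one comparisons of condition means against a control."""

    control: str
    labels: list
    mean_differences: np.ndarray
    t_statistics: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    n_per_group: dict
    alpha: float = 0.05
    dof: int = 0


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def normalize_trace(raw: FluxTrace, f_t0: float, f_val: float) -> FluxTrace:
    """Two-point normalization: f_t0 maps to 100%, f_val to 0%."""
    if f_t0 == f_val:
        raise ValueError("degenerate normalization: f_t0 equals f_val")
    scaled = 100.0 * (raw.fluorescence - f_val) / (f_t0 - f_val)
    return FluxTrace(times=raw.times.copy(), fluorescence=scaled,
                     t_cccp=raw.t_cccp, t_val=raw.t_val, normalized=True,
                     condition=raw.condition, replicate=raw.replicate)


def denormalize_trace(trace: FluxTrace, f_t0: float, f_val: float) -> FluxTrace:
    """Algebraic inverse of :func:`normalize_trace`."""
    raw = trace.fluorescence / 100.0 * (f_t0 - f_val) + f_val
    return FluxTrace(times=trace.times.copy(), fluorescence=raw,
                     t_cccp=trace.t_cccp, t_val=trace.t_val, normalized=False,
                     condition=trace.condition, replicate=trace.replicate)


# --------------------------------------------------------------------------
# decay fitting
# --------------------------------------------------------------------------

def _model(t, a, k, c):
    return a * np.exp(-k * t) + c


def fit_decay(trace: FluxTrace, window: tuple | None = None) -> DecayFit:
    """Least-squares first-order decay fit over [t_cccp, t_val].

    Multistart over a grid of initial rates; the best residual sum of
    squares wins.  Non-convergence is flagged on the result rather than
    raised; a non-positive fitted rate or vanishing amplitude is flagged
    ``no_flux``.
    """
    if not trace.normalized:
        raise ValueError("fit_decay expects a normalized trace")
    lo, hi = window if window is not None else (trace.t_cccp, trace.t_val)
    sel = (trace.times >= lo) & (trace.times <= hi)
    if sel.sum() < 5:
        raise ValueError("need at least 5 samples inside the fit window")
    t = trace.times[sel] - lo
    f = trace.fluorescence[sel]
    scale = max(np.abs(f).max(), 1e-12)
    a0 = f[0] - f[-1]
    c0 = f[-1]
    import warnings as _warnings
    from scipy.optimize import OptimizeWarning

    best = None
    for k0 in (1e-3, 0.01, 0.05, 0.1, 0.3, 1.0):
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(_model, t, f, p0=[a0, k0, c0],
                                    maxfev=20000)
        except RuntimeError:
            continue
        rss = float(np.sum((_model(t, *popt) - f) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return DecayFit(amplitude=np.nan, rate_per_min=np.nan, offset=np.nan,
                        rss=np.nan, fit_window=(lo, hi), converged=False,
                        no_flux=True)
    (a, k, c), rss = best
    no_flux = (k <= 0) or (abs(a) <= 1e-7 * scale)
    return DecayFit(amplitude=float(a), rate_per_min=float(k), offset=float(c),
                    rss=rss, fit_window=(lo, hi), converged=True,
                    no_flux=bool(no_flux))


# --------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# --------------------------------------------------------------------------

def _max_abs_t_null(n_control: int, n_groups, dof: int, n_mc: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo draws of max_j |T_j| under the joint Dunnett null."""
    k = len(n_groups)
    z0 = rng.standard_normal(n_mc) / np.sqrt(n_control)
    zj = rng.standard_normal((n_mc, k)) / np.sqrt(np.asarray(n_groups))
    s = np.sqrt(rng.chisquare(dof, size=n_mc) / dof)
    se = np.sqrt(1.0 / np.asarray(n_groups) + 1.0 / n_control)
    t = (zj - z0[:, None]) / (s[:, None] * se)
    return np.abs(t).max(axis=1)


def dunnett_critical_value(n_control: int, n_groups, dof: int,
                           alpha: float = 0.05, n_mc: int = 200_000,
                           seed: int = 0) -> float:
    """Two-sided Dunnett critical value by Monte Carlo."""
    rng = np.random.default_rng(seed)
    draws = _max_abs_t_null(n_control, n_groups, dof, n_mc, rng)
    return float(np.quantile(draws, 1.0 - alpha))


def dunnett_test(groups: dict, control: str, alpha: float = 0.05,
                 seed: int = 0, n_mc: int = 200_000) -> DunnettResult:
    """Two-sided Dunnett many-to-one comparisons against ``control``.

    ``groups`` maps condition label to an array of per-replicate values.
    Pooled-variance t statistics; the adjusted p-value of comparison i is
    the Monte Carlo probability that max_j |T_j| exceeds |t_i| under the
    joint null implied by the group sizes (>= 2e5 draws, fixed seed).
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not found")
    if len(groups) < 2:
        raise ValueError("need the control plus at least one comparison group")
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    labels = [k for k in data if k != control]
    y0 = data[control]
    n0 = y0.size
    nj = np.array([data[k].size for k in labels])
    dof = int(sum(v.size for v in data.values()) - len(data))
    ss = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    s2 = ss / dof
    diffs = np.array([data[k].mean() - y0.mean() for k in labels])
    se = np.sqrt(s2 * (1.0 / nj + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(diffs == 0, 0.0, diffs / se)
        t = np.where(np.isnan(t), 0.0, t)  # 0/0: no difference, no evidence
    rng = np.random.default_rng(seed)
    null_max = _max_abs_t_null(n0, nj, dof, n_mc, rng)
    p_adj = np.array([np.mean(null_max >= abs(ti)) if np.isfinite(ti) else 0.0
                      for ti in t])
    return DunnettResult(control=control, labels=labels,
                         mean_differences=diffs, t_statistics=t,
                         p_adjusted=p_adj, significant=p_adj < alpha,
                         n_per_group={k: int(v.size) for k, v in data.items()},
                         alpha=alpha, dof=dof)
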