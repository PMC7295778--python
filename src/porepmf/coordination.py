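"""Coordination-shell counting and normalized per-position histograms.

The coordination number of a permeating K+ ion is the count of oxygen atoms
(water or tyrosine hydroxyl) within a cutoff distance — 3.0 A by default,
boundary inclusive — of the ion.  Binned along the axial coordinate z, the
distribution of counts reveals where the hydration shell is depleted: a
modal count near six in the cavity dropping to three or four at the
constriction signals partial dehydration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import SolvationSnapshot

DEFAULT_CUTOFF = 3.0
MAX_CATEGORY = 10  # counts above this land in a single overflow category


@dataclass
class CoordinationSeries:
    """Per-frame coordination counts split by ligand type."""

    frame_times: np.ndarray
    frame_z: np.ndarray
    count_water: np.ndarray
    count_hydroxyl: np.ndarray
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.frame_z = np.asarray(self.frame_z, dtype=float)
        self.count_water = np.asarray(self.count_water, dtype=int)
        self.count_hydroxyl = np.asarray(self.count_hydroxyl, dtype=int)
        n = len(self.frame_times)
        for arr in (self.frame_z, self.count_water, self.count_hydroxyl):
            if len(arr) != n:
                raise ValueError("all series must have equal length")
        if np.any(self.count_water < 0) or np.any(self.count_hydroxyl < 0):
            raise ValueError("counts must be non-negative")
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")

    @property
    def count_total(self) -> np.ndarray:
        return self.count_water + self.count_hydroxyl

    def __len__(self) -> int:
        return len(self.frame_times)


@dataclass
class CoordinationHistogram:
    """Percentage of frames in each count category, per z bin."""

    z_bin_edges: np.ndarray
    count_categories: np.ndarray          # 0..MAX_CATEGORY, last = overflow
    percentage: np.ndarray                # (n_zbins, n_categories)
    occupied: np.ndarray                  # bool per z bin
    frames_per_bin: np.ndarray

    def modal_count(self, z_lo: float, z_hi: float) -> int:
        """Most frequent count category across occupied bins in [z_lo, z_hi]."""
        zc = 0.5 * (self.z_bin_edges[:-1] + self.z_bin_edges[1:])
        sel = (zc >= z_lo) & (zc <= z_hi) & self.occupied
        if not np.any(sel):
            raise ValueError("no occupied bins in requested range")
        pooled = (self.percentage[sel] * self.frames_per_bin[sel, None]).sum(axis=0)
        return int(self.count_categories[np.argmax(pooled)])


def count_coordinating_oxygens(snapshot: SolvationSnapshot,
                               cutoff: float = DEFAULT_CUTOFF):
    """Count oxygens within ``cutoff`` of the ion (inclusive boundary).

    Returns ``(water_count, hydroxyl_count)``.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if not snapshot.oxygens:
        return 0, 0
    coords = np.array([np.asarray(xyz, dtype=float)
                       for xyz, _ in snapshot.oxygens])
    labels = np.array([label for _, label in snapshot.oxygens])
    within = np.linalg.norm(coords - snapshot.ion_xyz, axis=1) <= cutoff
    water = int(np.count_nonzero(within & (labels == "water")))
    hydroxyl = int(np.count_nonzero(within & (labels == "hydroxyl")))
    return water, hydroxyl


def series_from_snapshots(snapshots, cutoff: float = DEFAULT_CUTOFF) -> CoordinationSeries:
    """Apply the cutoff count to every snapshot of a trajectory."""
    times = np.array([s.frame_time for s in snapshots])
    z = np.array([s.frame_z for s in snapshots])
    counts = np.array([count_coordinating_oxygens(s, cutoff) for s in snapshots])
    return CoordinationSeries(frame_times=times, frame_z=z,
                              count_water=counts[:, 0],
                              count_hydroxyl=counts[:, 1], cutoff=cutoff)


def coordination_histogram(series: CoordinationSeries,
                           z_edges) -> CoordinationHistogram:
    """Per-z-bin distribution of total counts, normalized to 100 percent.

    Counts above :data:`MAX_CATEGORY` are pooled in an overflow category.
    Unoccupied z bins are flagged via ``occupied`` rather than zero-filled
    silently.
    """
    if len(series) == 0:
        raise ValueError("empty coordination series")
    z_edges = np.asarray(z_edges, dtype=float)
    nz = z_edges.size - 1
    categories = np.arange(MAX_CATEGORY + 2)  # 0..10 plus overflow slot
    totals = np.minimum(series.count_total, MAX_CATEGORY + 1)
    iz = np.digitize(series.frame_z, z_edges) - 1
    inside = (iz >= 0) & (iz < nz)
    if not np.any(inside):
        raise ValueError("all frames fall outside the z range")
    pct = np.zeros((nz, categories.size))
    frames = np.zeros(nz, dtype=int)
    for b in range(nz):
        sel = inside & (iz == b)
        frames[b] = sel.sum()
        if frames[b]:
            counts = np.bincount(totals[sel], minlength=categories.size)
            pct[b] = 100.0 * counts / frames[b]
    return CoordinationHistogram(z_bin_edges=z_edges, count_categories=categories,
                                 percentage=pct, occupied=frames > 0,
                                 frames_per_bin=frames)


def mean_coordination_profile(series: CoordinationSeries, z_edges,
                              min_frames: int = 10):
    """Binned mean and SD of total counts, with water/hydroxyl components.

    Returns a dict of arrays keyed ``z_centers``, ``mean_total``, ``sd_total``,
    ``mean_water``, ``mean_hydroxyl``, ``frames``, ``low_occupancy`` (bins with
    fewer than ``min_frames`` frames are flagged, not dropped).
    """
    if len(series) == 0:
        raise ValueError("empty coordination series")
    z_edges = np.asarray(z_edges, dtype=float)
    nz = z_edges.size - 1
    iz = np.digitize(series.frame_z, z_edges) - 1
    inside = (iz >= 0) & (iz < nz)
    if not np.any(inside):
        raise ValueError("all frames fall outside the z range")
    out = {"z_centers": 0.5 * (z_edges[:-1] + z_edges[1:]),
           "mean_total": np.full(nz, np.nan), "sd_total": np.full(nz, np.nan),
           "mean_water": np.full(nz, np.nan),
           "mean_hydroxyl": np.full(nz, np.nan),
           "frames": np.zeros(nz, dtype=int)}
    tot = series.count_total
    for b in range(nz):
        sel = inside & (iz == b)
        m = sel.sum()
        out["frames"][b] = m
        if m:
            out["mean_total"][b] = tot[sel].mean()
            out["sd_total"][b] = tot[sel].std(ddof=0)
            out["mean_water"][b] = series.count_water[sel].mean()
            out["mean_hydroxyl"][b] = series.count_hydroxyl[sel].mean()
    out["low_occupancy"] = out["frames"] < min_frames
    return out
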