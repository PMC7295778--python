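"""Collar-aperture geometry and Calpha structure superposition.

Covers the aperture statistics at the tyrosine collar of a Kir pore — the
two diagonal O...O distances between diagonally opposed hydroxyl oxygens
("couplets"), their exchange symmetrization, van der Waals spacings, and the
extraction of barrier-crossing events from a trajectory — plus rigid-body
Kabsch superposition and RMSD of Calpha traces read from PDB files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import R_VDW_OXYGEN
from .landscape import BrownianTrajectory


# --------------------------------------------------------------------------
# diagonal couplets
# --------------------------------------------------------------------------

@dataclass
class DiagonalCoupletSeries:
    """Per-frame diagonal distances D1 = |A-C|, D2 = |B-D| at the collar."""

    frame_times: np.ndarray
    d1: np.ndarray
    d2: np.ndarray

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.d1 = np.asarray(self.d1, dtype=float)
        self.d2 = np.asarray(self.d2, dtype=float)
        if not (len(self.frame_times) == len(self.d1) == len(self.d2)):
            raise ValueError("couplet arrays must have equal length")
        if np.any(self.d1 <= 0) or np.any(self.d2 <= 0):
            raise ValueError("diagonal distances must be positive")

    def __len__(self) -> int:
        return len(self.frame_times)


def diagonal_couplets(frame_times, positions) -> DiagonalCoupletSeries:
    """Diagonal distances from per-frame collar-oxygen positions.

    ``positions`` has shape (n_frames, 4, 3) with the four oxygens in fixed
    subunit order A, B, C, D; the diagonals are (A, C) and (B, D).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[1:] != (4, 3):
        raise ValueError(
            f"expected positions of shape (n, 4, 3), got {pos.shape}")
    d1 = np.linalg.norm(pos[:, 0] - pos[:, 2], axis=1)
    d2 = np.linalg.norm(pos[:, 1] - pos[:, 3], axis=1)
    return DiagonalCoupletSeries(frame_times=frame_times, d1=d1, d2=d2)


def symmetrize_couplets(series: DiagonalCoupletSeries) -> DiagonalCoupletSeries:
    """Duplicate every couplet (D1, D2) as (D2, D1).

    The two diagonals are physically interchangeable; after symmetrization
    the marginal distributions of D1 and D2 are identical multisets.  Output
    length is exactly twice the input length.
    """
    return DiagonalCoupletSeries(
        frame_times=np.concatenate([series.frame_times, series.frame_times]),
        d1=np.concatenate([series.d1, series.d2]),
        d2=np.concatenate([series.d2, series.d1]))


# --------------------------------------------------------------------------
# crossing events
# --------------------------------------------------------------------------

@dataclass
class CrossingEvent:
    """One passage of the tagged ion through the collar plane."""

    frame_index: int            # first frame past the plane
    crossing_time: float        # ps, linearly interpolated
    z_before: float
    z_after: float
    couplet: tuple | None       # (D1, D2) at the reported frame
    direction: str              # "outward" (increasing z) or "inward"


def extract_crossing_events(traj: BrownianTrajectory,
                            couplets: DiagonalCoupletSeries | None,
                            z_collar: float) -> list[CrossingEvent]:
    """Find every sign change of (z - z_collar) between consecutive frames.

    The reported frame is the first frame past the plane; the crossing time
    is linearly interpolated between the two straddling frames.  Frames
    landing exactly on the plane are treated as already past it.
    """
    if couplets is not None and len(couplets) != len(traj.times):
        raise ValueError("couplet series must align with trajectory frames")
    s = np.sign(traj.z - z_collar)
    events: list[CrossingEvent] = []
    for i in range(1, len(s)):
        if s[i - 1] == 0 or s[i] == s[i - 1] or s[i] == 0 and s[i - 1] == 0:
            continue
        if s[i] == 0:
            frac = 1.0
        else:
            frac = (z_collar - traj.z[i - 1]) / (traj.z[i] - traj.z[i - 1])
        t = traj.times[i - 1] + frac * (traj.times[i] - traj.times[i - 1])
        events.append(CrossingEvent(
            frame_index=i, crossing_time=float(t),
            z_before=float(traj.z[i - 1]), z_after=float(traj.z[i]),
            couplet=None if couplets is None else (float(couplets.d1[i]),
                                                   float(couplets.d2[i])),
            direction="outward" if traj.z[i] > traj.z[i - 1] else "inward"))
    return events


# --------------------------------------------------------------------------
# vdW spacing
# --------------------------------------------------------------------------

def vdw_spacing(internuclear_distance, r_vdw: float = R_VDW_OXYGEN):
    """Free aperture between two atoms: d - 2 r_vdw, floored at zero.

    The paper-style "vdW spacing" subtracts one van der Waals radius per
    atom from the internuclear distance; the radius (oxygen, Bondi 1.52 A by
    default) is a parameter.
    """
    d = np.asarray(internuclear_distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("internuclear distance must be non-negative")
    spacing = d - 2.0 * r_vdw
    if np.any(spacing < 0):
        warnings.warn("distance below atomic contact; spacing floored at 0",
                      stacklevel=2)
        spacing = np.maximum(spacing, 0.0)
    return spacing if spacing.ndim else float(spacing)


# --------------------------------------------------------------------------
# Calpha structures and superposition
# --------------------------------------------------------------------------

@dataclass
class StructureCA:
    """Calpha trace: chain id -> {residue number -> xyz}."""

    chains: dict                 # {chain: {resnum: np.ndarray(3)}}
    label: str = ""
    source: str = ""

    def select(self, residue_range=None, chain_ids=None):
        """Flattened (chain, resnum) -> coordinate mapping after filtering."""
        out = {}
        for ch, residues in self.chains.items():
            if chain_ids is not None and ch not in chain_ids:
                continue
            for rn, xyz in residues.items():
                if residue_range is not None and not (
                        residue_range[0] <= rn <= residue_range[1]):
                    continue
                out[(ch, rn)] = xyz
        return out


def read_structure_ca(path, label: str = "") -> StructureCA:
    """Read the Calpha trace of a PDB file (via gemmi).

    Keeps the highest-occupancy altloc per residue; rejects insertion codes
    (the KirBac entries use plain author numbering).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chains: dict = {}
    model = st[0]
    for chain in model:
        per_res: dict = {}
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise ValueError(
                    f"insertion code {res.seqid.icode!r} at {chain.name} "
                    f"{res.seqid.num} is not supported")
            best = None
            for atom in res:
                if atom.name != "CA":
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is not None:
                per_res[res.seqid.num] = np.array(
                    [best.pos.x, best.pos.y, best.pos.z])
        if per_res:
            chains[chain.name] = per_res
    return StructureCA(chains=chains, label=label or str(path),
                       source=str(path))


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation matrix aligning centred ``mobile`` onto ``reference``.

    Standard Kabsch: SVD of the covariance, with the determinant-sign
    correction that excludes reflections.
    """
    h = mobile.T @ reference
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    if s[1] < 1e-10 * max(s[0], 1.0):
        warnings.warn("selection is (near-)collinear; rotation is degenerate",
                      stacklevel=2)
    return vt.T @ corr @ u.T


def superpose_rmsd(mobile: StructureCA, reference: StructureCA,
                   residue_range=None, chains=None) -> float:
    """RMSD after optimal rigid superposition of paired Calpha atoms.

    Residues are paired by (chain id, author residue number); only residues
    present in both structures within the selection are used.
    """
    sel_m = mobile.select(residue_range, chains)
    sel_r = reference.select(residue_range, chains)
    keys = sorted(set(sel_m) & set(sel_r))
    if len(keys) < 3:
        raise ValueError(
            f"only {len(keys)} paired Calpha atoms in selection; need >= 3")
    xm = np.array([sel_m[k] for k in keys])
    xr = np.array([sel_r[k] for k in keys])
    xm_c = xm - xm.mean(axis=0)
    xr_c = xr - xr.mean(axis=0)
    rot = kabsch_rotation(xm_c, xr_c)
    diff = xm_c @ rot.T - xr_c
    return float(np.sqrt((diff ** 2).sum() / len(keys)))
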