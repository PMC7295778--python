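"""Plain-text I/O: window TSVs with a JSON manifest, XVG pull files, PMF
tables and flux-trace CSVs.

All lengths on disk are A and times ps unless a format's own header says
otherwise (GROMACS-style XVG files carry positions in nm, converted to A on
read).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .wham import PMFProfile, UmbrellaWindow


# --------------------------------------------------------------------------
# umbrella windows
# --------------------------------------------------------------------------

def write_windows(outdir, windows, trajectories, temperature: float,
                  field_strength: float = 0.0, seeds=None) -> Path:
    """Write one TSV per window (time_ps, z_A, n) plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (w, traj) in enumerate(zip(windows, trajectories)):
        name = f"window_{i:04d}.tsv"
        cols = [traj.times, traj.z]
        header = "time_ps\tz_A"
        if traj.n is not None:
            cols.append(traj.n)
            header += "\tn"
        np.savetxt(outdir / name, np.column_stack(cols), delimiter="\t",
                   header=header, comments="", fmt="%.17g")
        entries.append({
            "file": name,
            "center_A": w.center_xi,
            "force_constant_kJ_per_mol_A2": w.force_constant,
            "force_constant_kJ_per_mol_nm2": w.force_constant * 100.0,
            "seed": w.seed,
        })
    manifest = {"temperature_K": temperature,
                "field_strength_V_per_nm": field_strength,
                "windows": entries}
    if seeds is not None:
        manifest["base_seed"] = seeds
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_windows(rundir) -> tuple[list[UmbrellaWindow], dict]:
    """Read windows written by :func:`write_windows`."""
    rundir = Path(rundir)
    manifest = json.loads((rundir / "manifest.json").read_text())
    temperature = manifest["temperature_K"]
    windows = []
    for entry in manifest["windows"]:
        data = np.loadtxt(rundir / entry["file"], delimiter="\t", skiprows=1,
                          ndmin=2)
        aux = data[:, 2] if data.shape[1] > 2 else None
        windows.append(UmbrellaWindow(
            center=entry["center_A"],
            force_constant=entry["force_constant_kJ_per_mol_A2"],
            samples_z=data[:, 1], samples_aux=aux, temperature=temperature))
    return windows, manifest


# --------------------------------------------------------------------------
# XVG pull files
# --------------------------------------------------------------------------

def read_xvg(path):
    """Read a GROMACS-style two-column XVG series as (time_ps, position_A).

    Lines starting with ``#`` or ``@`` are comments/metadata; positions are
    converted nm -> A when an axis label mentions nm (the GROMACS default),
    and taken as A when a label says so explicitly.
    """
    path = Path(path)
    times, pos = [], []
    unit_scale = 10.0  # GROMACS writes nm unless the header says otherwise
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(("#", "@")):
                low = s.lower()
                if s.startswith("@") and "axis" in low and "label" in low:
                    if "(nm)" in low:
                        unit_scale = 10.0
                    elif any(u in low for u in ("(a)", "(å)", "(angstrom)")):
                        unit_scale = 1.0
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                t, x = float(parts[0]), float(parts[1])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed line {s!r}") from err
            times.append(t)
            pos.append(x)
    if not times:
        raise ValueError(f"{path}: no numeric rows")
    return np.asarray(times), np.asarray(pos) * unit_scale


# --------------------------------------------------------------------------
# PMF tables
# --------------------------------------------------------------------------

def write_pmf_tsv(path, profile: PMFProfile) -> None:
    sem = profile.sem if profile.sem is not None else np.full(
        profile.bin_centers.shape, np.nan)
    np.savetxt(path, np.column_stack([profile.bin_centers,
                                      profile.free_energy, sem]),
               delimiter="\t", header="z_A\tF_kJmol\tsem_kJmol", comments="",
               fmt="%.10g")


def read_pmf_tsv(path, temperature: float = 303.15) -> PMFProfile:
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    sem = data[:, 2] if data.shape[1] > 2 and not np.all(np.isnan(data[:, 2])) \
        else None
    return PMFProfile(bin_centers=data[:, 0], free_energy=data[:, 1], sem=sem,
                      temperature=temperature)


# --------------------------------------------------------------------------
# flux traces
# --------------------------------------------------------------------------

def read_flux_csv(path):
    """Read traces from CSV with columns time_min, fluor, condition, replicate.

    Returns a list of :class:`~porepmf.flux.FluxTrace` (raw scale).
    """
    from .flux import FluxTrace

    df = pd.read_csv(path)
    required = {"time_min", "fluor", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        traces.append(FluxTrace(times=grp["time_min"].to_numpy(),
                                fluorescence=grp["fluor"].to_numpy(),
                                condition=str(cond), replicate=rep))
    return traces


def write_snapshots_tsv(path, snapshots) -> None:
    """Write solvation snapshots as a flat TSV: frame, time_ps, label, x, y, z.

    One ``ion`` row per frame followed by its labelled oxygens.
    """
    with open(path, "w") as fh:
        fh.write("frame\ttime_ps\tlabel\tx\ty\tz\n")
        for i, s in enumerate(snapshots):
            fh.write(f"{i}\t{s.frame_time:.6g}\tion\t"
                     f"{s.ion_xyz[0]:.6f}\t{s.ion_xyz[1]:.6f}\t{s.ion_xyz[2]:.6f}\n")
            for xyz, label in s.oxygens:
                fh.write(f"{i}\t{s.frame_time:.6g}\t{label}\t"
                         f"{xyz[0]:.6f}\t{xyz[1]:.6f}\t{xyz[2]:.6f}\n")


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
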