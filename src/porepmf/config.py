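"""Run configuration: YAML with unit-suffixed keys, strict about unknowns.

Physical quantities carry explicit unit suffixes in the file (e.g.
``force_constant_kJ_per_mol_nm2``); conversion to the package's internal
units (A, kJ/mol, ps) happens once, at parse time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import force_constant_nm2_to_A2
from .landscape import LandscapeSpec, default_window_centers, make_window_specs

_LANDSCAPE_KEYS = {
    "barrier_height_kJ_per_mol": "barrier_height",
    "barrier_center_z_A": "barrier_center_z",
    "barrier_width_A": "barrier_width",
    "cavity_plateau_kJ_per_mol": "cavity_plateau",
    "n_bulk": "n_bulk",
    "n_collar": "n_collar",
    "n_dip_width_A": "n_dip_width",
    "coupling_kappa_kJ_per_mol": "coupling_kappa",
    "temperature_K": "temperature",
    "diffusion_z_A2_per_ps": "diffusion_z",
    "diffusion_n_per_ps": "diffusion_n",
    "diffusion_xy_A2_per_ps": "diffusion_xy",
    "field_strength_V_per_nm": "field_strength",
    "ion_charge_e": "ion_charge",
    "box_length_z_A": "box_length_z",
}

_WINDOW_KEYS = {"center_min_A", "center_max_A", "spacing_A", "centers_A",
                "force_constant_kJ_per_mol_nm2", "duration_ps",
                "sample_interval_ps"}
_WHAM_KEYS = {"n_bins", "tolerance", "bootstraps"}
_COORD_KEYS = {"cutoff_A", "snapshot_stride", "n_hydroxyl_near_collar"}
_BARRIER_KEYS = {"barrier_range_A", "reference_range_A"}
_FLUX_KEYS = {"rate_per_min", "amplitude_pct", "noise_sd_pct", "n_replicates"}
_TOP_KEYS = {"landscape", "windows", "wham", "coordination", "barrier",
             "flux", "seed"}


def _reject_unknown(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    landscape: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    wham: dict = field(default_factory=lambda: {"n_bins": 100,
                                                "tolerance": 1e-6,
                                                "bootstraps": 200})
    coordination: dict = field(default_factory=lambda: {
        "cutoff_A": 3.0, "snapshot_stride": 10, "n_hydroxyl_near_collar": 1})
    barrier: dict = field(default_factory=lambda: {
        "barrier_range_A": [19.0, 25.0], "reference_range_A": [16.5, 18.5]})
    flux: dict = field(default_factory=lambda: {
        "rate_per_min": 0.12, "amplitude_pct": 100.0, "noise_sd_pct": 2.0,
        "n_replicates": 3})
    seed: int = 1

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _reject_unknown(raw, _TOP_KEYS, "config")
        cfg = cls()
        _reject_unknown(raw.get("landscape", {}), _LANDSCAPE_KEYS, "landscape")
        _reject_unknown(raw.get("windows", {}), _WINDOW_KEYS, "windows")
        _reject_unknown(raw.get("wham", {}), _WHAM_KEYS, "wham")
        _reject_unknown(raw.get("coordination", {}), _COORD_KEYS, "coordination")
        _reject_unknown(raw.get("barrier", {}), _BARRIER_KEYS, "barrier")
        _reject_unknown(raw.get("flux", {}), _FLUX_KEYS, "flux")
        cfg.landscape.update(raw.get("landscape", {}))
        cfg.windows.update(raw.get("windows", {}))
        cfg.wham.update(raw.get("wham", {}))
        cfg.coordination.update(raw.get("coordination", {}))
        cfg.barrier.update(raw.get("barrier", {}))
        cfg.flux.update(raw.get("flux", {}))
        cfg.seed = int(raw.get("seed", 1))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def landscape_spec(self) -> LandscapeSpec:
        kwargs = {_LANDSCAPE_KEYS[k]: v for k, v in self.landscape.items()}
        return LandscapeSpec(**kwargs)

    def window_specs(self):
        w = self.windows
        if "centers_A" in w:
            centers = list(w["centers_A"])
        else:
            centers = default_window_centers(w.get("center_min_A", 16.5),
                                             w.get("center_max_A", 36.5),
                                             w.get("spacing_A", 0.2))
        k = force_constant_nm2_to_A2(w.get("force_constant_kJ_per_mol_nm2",
                                           3000.0))
        return make_window_specs(centers, force_constant=k,
                                 duration=w.get("duration_ps", 2000.0),
                                 sample_interval=w.get("sample_interval_ps", 1.0),
                                 base_seed=self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()
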