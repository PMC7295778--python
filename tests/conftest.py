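"""Shared fixtures: full-scale synthetic umbrella runs, reused across tests.

The "default run" reproduces the package's reference protocol: 101 windows
at 0.2 A spacing over 16.5-36.5 A, bias constant 30 kJ/mol/A^2, 2000
decorrelated samples per window, over a 6 kJ/mol Gaussian collar barrier
(and a 1 kJ/mol variant).  Session scope keeps the suite inside a desk-scale
time budget.
"""

from __future__ import annotations

import numpy as np
import pytest

import porepmf as pp


from porepmf import protocols


@pytest.fixture(scope="session")
def default_run():
    """Reference umbrella run over the 6 kJ/mol collar barrier."""
    return protocols.umbrella_run(6.0, seed=1)


@pytest.fixture(scope="session")
def low_barrier_run():
    """Same protocol over the 1 kJ/mol (crosslinked-mutant-like) barrier."""
    return protocols.umbrella_run(1.0, seed=11)


def make_tetramer_ca(seed: int = 0, n_res: int = 284, first_res: int = 12):
    """Synthetic four-chain Calpha stand-in for a tetrameric channel.

    Each chain is a coarse helical trace; chains are related by a 4-fold
    axis.  Purely synthetic geometry for exercising superposition — not a
    deposited structure.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_res)
    backbone = np.column_stack([
        8.0 + 2.0 * np.cos(t / 3.6 * 2 * np.pi),
        2.0 * np.sin(t / 3.6 * 2 * np.pi) + rng.normal(0, 0.3, n_res),
        1.5 * t / n_res * 60.0,
    ])
    chains = {}
    for k, ch in enumerate("ABCD"):
        ang = k * np.pi / 2
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        coords = backbone @ rot.T
        chains[ch] = {first_res + i: coords[i] for i in range(n_res)}
    return pp.StructureCA(chains=chains, label=f"synthetic-tetramer-{seed}")


def rigid_transform(structure, angle_deg: float, translation):
    """Apply one rigid rotation (about z) plus translation to all chains."""
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a), 0],
                    [np.sin(a), np.cos(a), 0], [0, 0, 1]])
    t = np.asarray(translation, dtype=float)
    chains = {ch: {rn: rot @ xyz + t for rn, xyz in res.items()}
              for ch, res in structure.chains.items()}
    return pp.StructureCA(chains=chains, label=structure.label + "-moved")
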