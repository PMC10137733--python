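"""Deterministic synthetic fixtures used by tests and the CLI.

These generate the study conditions in memory: discrete joint tables with
hand-computable mutual information, Gaussian grid densities, the canonical
linear-sensing scenario (b = 2, Xbar = 2, beta' = 0, g in {0, 1}) and an
Ornstein-Uhlenbeck SDE specification.  Everything is reproducible from a
single seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .config import default_fig2_config
from .distributions import Grid1D, GridDensity1D, JointTable, normalize

__all__ = [
    "canonical_joint_2x2",
    "random_joint",
    "gaussian_density",
    "quartic_density",
    "ou_sde_block",
    "generate_fixtures",
]

#: the canonical 2x2 joint with hand-computable mutual information
CANONICAL_2X2 = [[0.4, 0.1], [0.1, 0.4]]


def canonical_joint_2x2() -> JointTable:
    return JointTable(probs=np.array(CANONICAL_2X2))


def random_joint(nx: int, ny: int, seed: int) -> JointTable:
    """A strictly positive random joint table (Dirichlet-like)."""
    rng = np.random.default_rng(seed)
    probs = rng.gamma(2.0, size=(nx, ny)) + 0.05
    return JointTable(probs=probs / probs.sum())


def gaussian_density(
    mu: float = 0.0,
    sigma: float = 1.0,
    lower: float = -8.0,
    upper: float = 8.0,
    n_points: int = 2001,
) -> GridDensity1D:
    grid = Grid1D(lower, upper, n_points)
    vals = np.exp(-0.5 * ((grid.x - mu) / sigma) ** 2)
    return normalize(GridDensity1D(grid, vals))


def quartic_density(
    lower: float = -6.0, upper: float = 6.0, n_points: int = 2401
) -> GridDensity1D:
    """The non-Gaussian fixture p propto exp(-x^4 / 4)."""
    grid = Grid1D(lower, upper, n_points)
    vals = np.exp(-0.25 * grid.x**4)
    return normalize(GridDensity1D(grid, vals))


def ou_sde_block(k: float = 1.0, sigma22: float = 0.5, seed: int = 0) -> dict:
    """Config block for an Ornstein-Uhlenbeck slow variable."""
    return {
        "sigma11": 0.5,
        "sigma12": 0.0,
        "sigma22": sigma22,
        "epsilon": 1.0,
        "dt": 0.01,
        "n_steps": 8000,
        "n_paths": 400,
        "seed": seed,
    }


def generate_fixtures(seed: int, outdir) -> dict:
    """Write the deterministic fixture bundle; returns its manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "files": []}

    def _write(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        manifest["files"].append(name)

    j22 = canonical_joint_2x2()
    _write("joint_2x2.json", json.dumps({"probs": j22.probs.tolist()}, indent=2) + "\n")
    j55 = random_joint(5, 5, seed)
    _write("joint_5x5.json", json.dumps({"probs": j55.probs.tolist(), "seed": seed}, indent=2) + "\n")

    gauss = gaussian_density()
    rows = ["x,density"] + [f"{repr(float(x))},{repr(float(v))}" for x, v in zip(gauss.x, gauss.values)]
    _write("gaussian_density.csv", "\n".join(rows) + "\n")

    for g in (0.0, 1.0):
        cfg = default_fig2_config(g)
        _write(f"scenario_fig2_g{int(g)}.yaml", yaml.safe_dump(cfg.to_dict(), sort_keys=True))

    _write("ou_sde.yaml", yaml.safe_dump(ou_sde_block(seed=seed), sort_keys=True))
    _write("manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
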