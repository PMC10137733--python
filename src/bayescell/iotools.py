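"""Structured output: density/trajectory CSVs and JSON run records."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .distributions import GridDensity1D

__all__ = ["write_density_csv", "write_trajectory_csv", "write_run_record"]

_TRAJECTORY_COLUMNS = ["step", "y_obs", "kl", "mi", "sigma_x2", "cond_entropy", "cov_xy"]


def _fmt(v) -> str:
    return repr(float(v))


def write_density_csv(
    density: GridDensity1D, path, potential: Optional[np.ndarray] = None
) -> Path:
    """Write a density as `x,density[,potential]` with a header row."""
    p = Path(path)
    header = "x,density" + (",potential" if potential is not None else "")
    lines = [header]
    for i, (x, d) in enumerate(zip(density.x, density.values)):
        row = f"{_fmt(x)},{_fmt(d)}"
        if potential is not None:
            row += f",{_fmt(potential[i])}"
        lines.append(row)
    p.write_text("\n".join(lines) + "\n")
    return p


def write_trajectory_csv(rows: Iterable[dict], path) -> Path:
    """Write learning-trajectory rows (header-only file for empty runs)."""
    p = Path(path)
    lines = [",".join(_TRAJECTORY_COLUMNS)]
    for row in rows:
        lines.append(
            ",".join(
                str(row[c]) if c == "step" else _fmt(row[c])
                for c in _TRAJECTORY_COLUMNS
            )
        )
    p.write_text("\n".join(lines) + "\n")
    return p


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_run_record(config_echo: dict, seed, outputs: Iterable, path) -> Path:
    """Write the once-per-run JSON record with an output manifest and hashes."""
    from . import __version__

    p = Path(path)
    manifest = [
        {"path": str(Path(o)), "sha256": _sha256(Path(o))} for o in outputs
    ]
    record = {
        "config": config_echo,
        "seed": seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "outputs": manifest,
    }
    p.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return p
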