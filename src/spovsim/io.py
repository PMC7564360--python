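"""Deterministic on-disk formats: trajectory CSV, run manifest JSON."""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import Trajectory

__all__ = ["TRAJECTORY_COLUMNS", "write_trajectory", "read_trajectory", "RunManifest"]

TRAJECTORY_COLUMNS = [
    "generation", "p", "n_es_females", "n_mfcl_females",
    "survivors_es", "survivors_mfcl", "matings_es", "matings_mfcl",
    "males_cannibalized", "mfcl_mating_pct", "rel_fitness_es",
]


def write_trajectory(trajectory: Trajectory | pd.DataFrame, path: str | Path) -> Path:
    """Write a trajectory as CSV, floats at 6 significant digits.

    An empty trajectory produces a header-only file; a round-trip read
    reproduces values to the printed precision.
    """
    path = Path(path)
    frame = trajectory.to_frame() if isinstance(trajectory, Trajectory) else trajectory
    frame.to_csv(path, index=False, float_format="%.6g")
    return path


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunManifest:
    """Everything needed to re-run an experiment bit-identically."""

    config: dict
    seed: int | None
    stream_ids: list[str] = field(default_factory=list)
    rng_family: str = "numpy.random.Generator(PCG64)"
    code_version: str = ""
    numpy_version: str = np.__version__
    python_version: str = platform.python_version()
    timestamp: str = ""
    outputs: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.code_version:
            from . import __version__

            self.code_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path
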