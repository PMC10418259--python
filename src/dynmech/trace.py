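"""Bead position/force time series from an optical trap.

A :class:`ForceTrace` is a uniformly sampled record of the bead position
relative to the trap center (nm) and the restoring force the trap exerts
(pN).  For a calibrated trap the two are proportional through the trap
stiffness, ``force = stiffness * position``, and the container enforces
that relation when both series are present.

On disk a trace is a plain TSV (columns ``time_s``, ``position_nm``,
``force_pN``) with a JSON sidecar carrying the sampling rate, trap
stiffness, seed and any simulation parameters.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["ForceTrace"]

_GRID_JITTER_S = 1e-9
_FORCE_RTOL = 1e-6


@dataclass
class ForceTrace:
    """Uniformly sampled bead position/force series with trap metadata."""

    time: np.ndarray
    position: np.ndarray
    force: np.ndarray
    sampling_rate: float
    trap_stiffness: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if self.position.size != n or self.force.size != n:
            raise ValueError("time, position and force must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if n > 1:
            dt = np.diff(self.time)
            if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > _GRID_JITTER_S:
                raise ValueError("time grid is not uniform at the stated sampling rate")
        if self.trap_stiffness is not None and n > 0:
            expected = self.trap_stiffness * self.position
            scale = max(np.max(np.abs(expected)), 1.0)
            if np.max(np.abs(self.force - expected)) > _FORCE_RTOL * scale:
                raise ValueError("force does not equal stiffness * position")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Time span between the first and last sample, s."""
        if self.n_samples < 2:
            return 0.0
        return float(self.time[-1] - self.time[0])

    @classmethod
    def from_position(
        cls,
        position: np.ndarray,
        sampling_rate: float,
        trap_stiffness: float,
        metadata: dict[str, Any] | None = None,
    ) -> "ForceTrace":
        """Build a trace from a position series, deriving force from stiffness."""
        position = np.asarray(position, dtype=float)
        time = np.arange(position.size) / sampling_rate
        return cls(
            time=time,
            position=position,
            force=trap_stiffness * position,
            sampling_rate=sampling_rate,
            trap_stiffness=trap_stiffness,
            metadata=dict(metadata or {}),
        )

    # ------------------------------------------------------------------ I/O

    def write_tsv(self, path: str | Path) -> None:
        """Write the trace as TSV plus a ``<stem>.json`` metadata sidecar."""
        path = Path(path)
        frame = pd.DataFrame(
            {"time_s": self.time, "position_nm": self.position, "force_pN": self.force}
        )
        frame.to_csv(path, sep="\t", index=False, float_format="%.9g")
        sidecar = {
            "sampling_rate_hz": self.sampling_rate,
            "trap_stiffness_pn_per_nm": self.trap_stiffness,
            "seed": self.metadata.get("seed"),
            "params": {
                k: v for k, v in self.metadata.items() if k != "seed"
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ForceTrace":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t")
        sidecar_path = path.with_suffix(".json")
        stiffness = None
        rate = None
        metadata: dict[str, Any] = {}
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            stiffness = sidecar.get("trap_stiffness_pn_per_nm")
            rate = sidecar.get("sampling_rate_hz")
            metadata = dict(sidecar.get("params") or {})
            if sidecar.get("seed") is not None:
                metadata["seed"] = sidecar["seed"]
        time = frame["time_s"].to_numpy()
        if rate is None:
            if time.size < 2:
                raise ValueError("cannot infer sampling rate from fewer than 2 samples")
            rate = 1.0 / float(np.median(np.diff(time)))
        return cls(
            time=time,
            position=frame["position_nm"].to_numpy(),
            force=frame["force_pN"].to_numpy(),
            sampling_rate=float(rate),
            trap_stiffness=stiffness,
            metadata=metadata,
        )
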