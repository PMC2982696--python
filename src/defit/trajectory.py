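"""Time-course containers, CSV round-tripping, and the noise generator.

A :class:`Trajectory` holds time-aligned values of one or more model
variables with a role tag: ``"calculated"`` for simulated curves
(x^c in the objective) or ``"measured"`` for reference/observed data
(x^m).  Noise is added with the Box-Muller transform from a seeded
uniform stream, mimicking noisy measurements of a reference curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "NoiseSpec", "box_muller", "add_noise"]


@dataclass
class Trajectory:
    """Time-indexed values of model variables.

    ``times`` must be strictly increasing; every value vector must match
    its length.  ``provenance`` records how the data were produced
    (model name, parameter vector, seed) and is empty for external data.
    """

    times: np.ndarray
    values: dict[str, np.ndarray]
    role: str = "calculated"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D vector")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.role not in ("calculated", "measured"):
            raise ValueError(f"unknown role {self.role!r}")
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for k, v in self.values.items():
            if v.shape != self.times.shape:
                raise ValueError(f"values for {k!r} do not align with times")

    def __len__(self) -> int:
        return self.times.size

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.values)

    def __getitem__(self, var: str) -> np.ndarray:
        return self.values[var]

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times})
        for k, v in self.values.items():
            df[k] = v
        return df

    def subset(self, variables) -> "Trajectory":
        """Restrict to the given variables (e.g. the observed set)."""
        return replace(self, values={v: self.values[v] for v in variables})

    def with_role(self, role: str) -> "Trajectory":
        return replace(self, role=role)

    # -- I/O -------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write as delimited text, lossless at 17 significant digits."""
        self.frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, role: str = "measured") -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        if "time" not in df.columns:
            raise ValueError(f"{path}: first column must be 'time'")
        values = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "time"}
        return cls(times=df["time"].to_numpy(dtype=float), values=values, role=role)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement-noise settings.

    ``c`` is the noise scale (c = 0.666 in the benchmark protocol),
    ``seed`` makes the draw reproducible, and ``mode`` selects the
    combining rule: additive ``X + c*Rn`` (default) or multiplicative
    ``X * (1 + c*Rn)``.
    """

    c: float = 0.666
    seed: int = 0
    mode: str = "additive"

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("noise scale c must be non-negative")
        if self.mode not in ("additive", "multiplicative"):
            raise ValueError(f"unknown noise mode {self.mode!r}")


def box_muller(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` standard-normal variates via the Box-Muller transform.

    Draws pairs of uniforms u1, u2 on (0, 1] and maps them to
    z0 = sqrt(-2 ln u1) cos(2 pi u2), z1 = sqrt(-2 ln u1) sin(2 pi u2).
    """
    m = (n + 1) // 2
    u1 = 1.0 - rng.random(m)  # (0, 1]: keeps log finite
    u2 = rng.random(m)
    r = np.sqrt(-2.0 * np.log(u1))
    z = np.empty(2 * m)
    z[0::2] = r * np.cos(2.0 * np.pi * u2)
    z[1::2] = r * np.sin(2.0 * np.pi * u2)
    return z[:n]


def add_noise(traj: Trajectory, spec: NoiseSpec) -> Trajectory:
    """Corrupt every value column with seeded Box-Muller Gaussian noise.

    Deterministic given ``spec.seed``; with ``c = 0`` the output equals
    the input exactly.
    """
    rng = np.random.default_rng(spec.seed)
    values = {}
    for k, v in traj.values.items():
        rn = box_muller(v.size, rng)
        if spec.mode == "additive":
            values[k] = v + spec.c * rn
        else:
            values[k] = v * (1.0 + spec.c * rn)
    prov = dict(traj.provenance)
    prov.update(noise_c=spec.c, noise_seed=spec.seed, noise_mode=spec.mode)
    return Trajectory(times=traj.times.copy(), values=values, role="measured", provenance=prov)
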