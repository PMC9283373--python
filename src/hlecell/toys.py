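"""Low-dimensional toy energies with closed-form reference quantities.

Validation fixtures for the sampling and integration machinery: each system
exposes the energy, its gradient and the closed forms (stationary variance,
mean energy above the minimum, Boltzmann occupancy ratios) that the
Metropolis and Langevin engines must reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ParameterError

__all__ = ["ToyEnergySpec", "ToySystem", "make_toy_system"]


@dataclass(frozen=True)
class ToyEnergySpec:
    kind: str                   # "quadratic" | "double_well" | "two_state"
    d: int = 1
    stiffness: float | tuple = 1.0   # quadratic: k (scalar or per-dof)
    barrier: float = 1.0        # double_well: height of the central barrier
    spacing: float = 1.0        # double_well: half-distance between wells
    delta_G: float = 1.0        # two_state: energy gap


@dataclass
class ToySystem:
    spec: ToyEnergySpec
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    reference: dict = field(default_factory=dict)

    def stationary_variance(self, zeta: float) -> np.ndarray:
        """Per-coordinate Boltzmann variance (quadratic systems only)."""
        k = self.reference.get("stiffness")
        if k is None:
            raise ParameterError("closed-form variance only for quadratic toys")
        return 1.0 / (zeta * np.asarray(k, float))

    def mean_energy(self, zeta: float) -> float:
        """Equipartition: <G> - G_min = d / (2 zeta) for quadratic toys."""
        if self.spec.kind == "quadratic":
            return self.spec.d / (2.0 * zeta)
        if self.spec.kind == "two_state":
            dG = self.spec.delta_G
            w = math.exp(-zeta * dG)
            return dG * w / (1.0 + w)
        raise ParameterError(f"no closed-form mean energy for {self.spec.kind}")


def make_toy_system(spec: ToyEnergySpec) -> ToySystem:
    """Build a toy energy with its gradient and closed-form references."""
    if spec.kind == "quadratic":
        k = np.broadcast_to(np.asarray(spec.stiffness, float), (spec.d,)).copy()
        if np.any(k <= 0):
            raise ParameterError("quadratic stiffness must be positive")

        def energy(x):
            x = np.asarray(x, float)
            return 0.5 * float(k @ (x * x))

        def gradient(x):
            return k * np.asarray(x, float)

        return ToySystem(spec, energy, gradient, {"stiffness": k, "G_min": 0.0})

    if spec.kind == "double_well":
        a, b = spec.barrier, spec.spacing
        if spec.d != 1:
            raise ParameterError("double_well toy is one-dimensional")

        # G = a * ((x/b)^2 - 1)^2: minima at +-b, barrier a at x = 0
        def energy(x):
            u = float(np.asarray(x, float).reshape(()))
            return a * ((u / b) ** 2 - 1.0) ** 2

        def gradient(x):
            u = float(np.asarray(x, float).reshape(()))
            return np.array([4.0 * a * u / b**2 * ((u / b) ** 2 - 1.0)])

        return ToySystem(spec, energy, gradient,
                         {"minima": (-b, b), "G_min": 0.0, "barrier": a})

    if spec.kind == "two_state":
        # two levels {0, delta_G} indexed by sign(x), each with an identical
        # confining well at +-1 so the chain cannot wander off; symmetric
        # wells leave the occupancy ratio exactly exp(-zeta * delta_G)
        dG = spec.delta_G
        kw = 5.0

        def energy(x):
            u = float(np.asarray(x, float).reshape(()))
            level = dG if u > 0 else 0.0
            return level + kw * (abs(u) - 1.0) ** 2

        def gradient(x):
            u = float(np.asarray(x, float).reshape(()))
            return np.array([2.0 * kw * (abs(u) - 1.0) * math.copysign(1.0, u)])

        return ToySystem(spec, energy, gradient,
                         {"levels": (0.0, dG), "G_min": 0.0})

    raise ParameterError(f"unknown toy energy kind {spec.kind!r}")
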