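"""Service-time and dwell-time distributions for the ED simulator.

Durations are specified in either minutes or hours and always sampled in
minutes.  The triangular parameterisation follows the (min, max, mode)
convention used by healthcare simulation packages, so a triple like
``Triangular(3, 15, 5)`` means minimum 3, maximum 15, mode 5 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DistributionSpec", "sample_duration"]

_KINDS = ("uniform", "triangular", "exponential", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """A duration distribution.

    Parameters
    ----------
    kind : {"uniform", "triangular", "exponential", "fixed"}
    a : float
        Lower bound (uniform/triangular), value (fixed), or mean (exponential).
    b : float, optional
        Upper bound (uniform/triangular).
    c : float, optional
        Mode (triangular only).
    unit : {"minutes", "hours"}
        Unit of the parameters; samples are converted to minutes.
    """

    kind: str
    a: float
    b: float | None = None
    c: float | None = None
    unit: str = "minutes"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, stage: str | None = None) -> None:
        where = f" in stage '{stage}'" if stage else ""
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}{where}")
        if self.unit not in ("minutes", "hours"):
            raise ValueError(f"unknown unit {self.unit!r}{where}")
        if self.kind in ("uniform", "triangular"):
            if self.b is None:
                raise ValueError(f"{self.kind} needs an upper bound b{where}")
            if self.a > self.b:
                raise ValueError(
                    f"{self.kind} bounds out of order (a={self.a} > b={self.b}){where}"
                )
        if self.kind == "triangular":
            if self.c is None:
                raise ValueError(f"triangular needs a mode c{where}")
            if not (self.a <= self.c <= self.b):
                raise ValueError(
                    f"triangular mode {self.c} outside [{self.a}, {self.b}]{where}"
                )
        if self.kind == "exponential" and self.a <= 0:
            raise ValueError(f"exponential mean must be positive{where}")
        if self.a < 0:
            raise ValueError(f"negative duration parameter a={self.a}{where}")

    @property
    def mean(self) -> float:
        """Analytic mean, in the spec's own unit."""
        if self.kind == "fixed":
            return self.a
        if self.kind == "uniform":
            return (self.a + self.b) / 2.0
        if self.kind == "triangular":
            return (self.a + self.b + self.c) / 3.0
        return self.a  # exponential

    def _scale(self) -> float:
        return 60.0 if self.unit == "hours" else 1.0

    def sample(self, rng: np.random.Generator) -> float:
        """Draw one duration in minutes."""
        s = self._scale()
        if self.kind == "fixed":
            return self.a * s
        if self.kind == "uniform":
            if self.a == self.b:
                return self.a * s
            return rng.uniform(self.a, self.b) * s
        if self.kind == "triangular":
            if self.a == self.b:
                return self.a * s
            return rng.triangular(self.a, self.c, self.b) * s
        return rng.exponential(self.a) * s


def sample_duration(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one duration (minutes) from ``spec`` using ``rng``."""
    return spec.sample(rng)
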