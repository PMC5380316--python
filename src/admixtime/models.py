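"""Admixture-history parameter bundles."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PulseModel:
    """A single ("pulse") admixture event.

    ``proportions`` maps source labels to the fraction of ancestry each
    contributed; ``t`` is the admixture time in generations before present.
    For the two-source EU/ME case the first label plays the role of source A
    (fraction q) and the second of source B.
    """

    proportions: dict[str, float]
    t: float

    def __post_init__(self) -> None:
        if not self.proportions:
            raise ValueError("empty source proportions")
        vals = list(self.proportions.values())
        if any(p < 0 or p > 1 for p in vals):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {sum(vals)}, expected 1")
        if self.t <= 0:
            raise ValueError(f"admixture time must be positive, got {self.t}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.proportions)

    @property
    def q(self) -> float:
        """Fraction contributed by the first source (source A)."""
        return next(iter(self.proportions.values()))


@dataclass
class TwoWaveModel:
    """Two admixture events: a founding A/B merge followed by A replacement.

    Populations A and B merged ``t1`` generations ago with A contributing a
    fraction ``q``.  Then, ``t2`` (< t1) generations ago, migrants from A
    replaced a fraction ``mu`` of the admixed gene pool.
    """

    q: float
    t1: float
    mu: float
    t2: float
    labels: tuple[str, str] = field(default=("A", "B"))

    def __post_init__(self) -> None:
        if not (0 <= self.q <= 1 and 0 <= self.mu <= 1):
            raise ValueError("q and mu must lie in [0, 1]")
        if not (0 < self.t2 < self.t1):
            raise ValueError(
                f"require 0 < t2 < t1, got t1={self.t1}, t2={self.t2}"
            )
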