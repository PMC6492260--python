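"""Discretized arterial-transit-time priors for prior-averaged design.

The design criterion is averaged over a discretized prior on ATT.  The
default prior is uniform over the range expected in grey matter of healthy
adults (0.5-1.8 s), extended on either side by a linear taper (0.3 s) so
the design does not over-commit to hard range edges.

Per-slice truncation removes ATT samples that a slice cannot inform: if
every effective PLD of a slice is at or above the ATT, all of its samples
fall on the post-bolus decay where the CBF and ATT sensitivities are
collinear, and the Fisher matrix for that slice is singular.  Truncated
weights are deliberately *not* renormalized so that masses remain
comparable across slices when the per-slice sums are combined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["ATTPrior", "make_att_prior", "truncate_below", "point_prior"]


@dataclass(frozen=True)
class ATTPrior:
    """Equally spaced ATT samples with probability masses.

    ``weights`` sum to 1 for a freshly constructed prior; a truncated prior
    retains the original masses of the surviving samples.
    """

    att_values: np.ndarray
    weights: np.ndarray
    core_range: tuple[float, float]
    taper: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "att_values", np.asarray(self.att_values, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.att_values.shape != self.weights.shape:
            raise InvalidParameterError("att_values and weights must have equal length")
        if np.any(self.weights < 0):
            raise InvalidParameterError("weights must be non-negative")
        if self.att_values.size > 1 and np.any(np.diff(self.att_values) <= 0):
            raise InvalidParameterError("att_values must be strictly increasing")

    @property
    def support(self) -> tuple[float, float]:
        if self.is_empty:
            return (np.nan, np.nan)
        return float(self.att_values[0]), float(self.att_values[-1])

    @property
    def is_empty(self) -> bool:
        return self.att_values.size == 0

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())

    def __len__(self) -> int:
        return self.att_values.size


def make_att_prior(
    core_min: float = 0.5,
    core_max: float = 1.8,
    taper: float = 0.3,
    step: float = 0.001,
) -> ATTPrior:
    """Build the tapered-uniform ATT prior on an equally spaced grid.

    The prior is constant on ``[core_min, core_max]`` and falls linearly to
    exactly zero at ``core_min - taper`` and ``core_max + taper``.  The
    default 1 ms step makes prior-averaged criteria stable well below 0.1%
    relative to finer discretizations.
    """
    if not core_min < core_max:
        raise InvalidParameterError("core_min must be < core_max")
    if taper < 0 or step <= 0:
        raise InvalidParameterError("taper must be >= 0 and step > 0")
    lo, hi = core_min - taper, core_max + taper
    if lo < 0:
        raise InvalidParameterError("prior support extends below zero ATT")
    n = int(round((hi - lo) / step))
    if n < 1:
        raise InvalidParameterError("step larger than the prior support")
    values = lo + step * np.arange(n + 1)
    weights = np.ones_like(values)
    if taper > 0:
        weights = np.where(values < core_min, (values - lo) / taper, weights)
        weights = np.where(values > core_max, (hi - values) / taper, weights)
        weights = np.clip(weights, 0.0, None)
    weights = weights / weights.sum()
    return ATTPrior(values, weights, core_range=(core_min, core_max), taper=taper)


def point_prior(att: float) -> ATTPrior:
    """A degenerate prior with all mass at a single ATT value."""
    return ATTPrior(np.array([att]), np.array([1.0]), core_range=(att, att), taper=0.0)


def truncate_below(prior: ATTPrior, min_att: float) -> ATTPrior:
    """Restrict ``prior`` to samples with ``att >= min_att``.

    Masses are retained, not renormalized.  An empty result is valid and
    signals that the slice contributes no information at any ATT.
    """
    if not np.isfinite(min_att):
        raise InvalidParameterError("min_att must be finite")
    keep = prior.att_values >= min_att
    return ATTPrior(
        prior.att_values[keep],
        prior.weights[keep],
        core_range=prior.core_range,
        taper=prior.taper,
    )
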