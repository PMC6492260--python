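"""Protocols: PLD schedules plus readout timing, averages, and file I/O.

A protocol is the design variable of this package: an ordered list of
post-labeling delays together with the readout geometry (2D multi-slice EPI
with a fixed per-slice acquisition duration) and the number of averages the
scan-time budget allows.

Timing model (variable TR): one label-control *pair* at PLD ``p`` costs
``2 * (tau + p + readout_duration)`` seconds, so the number of averages
within a budget is

    A = floor( budget / (2 * sum_i (tau + p_i + readout)) ).

Slice ``k`` of a 2D readout is acquired ``k * slice_duration`` later than
slice 0, giving it an effective PLD of ``p + k * slice_duration`` and a
sample time (from the start of labeling) of ``tau + p + k * slice_duration``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "Protocol",
    "compute_averages",
    "effective_plds",
    "load_protocol",
    "save_protocol",
    "read_plds_csv",
    "builtin_protocol",
    "BUILTIN_PROTOCOLS",
]

#: names of the protocol fixtures shipped with the package
BUILTIN_PROTOCOLS = (
    "single_pld",
    "reference_multi_pld",
    "cbf_att_optimized",
    "cbf_optimized",
)


def compute_averages(
    plds,
    label_duration: float,
    readout_duration: float,
    scan_time_budget: float,
) -> int:
    """Integer number of label-control pair averages fitting the budget.

    May legitimately return 0, signaling an infeasible design.
    """
    plds = np.asarray(plds, dtype=float)
    if plds.size == 0:
        raise InvalidParameterError("plds must be nonempty")
    if not scan_time_budget > 0:
        raise InvalidParameterError("scan_time_budget must be > 0")
    pair_time = 2.0 * float(np.sum(label_duration + plds + readout_duration))
    return int(scan_time_budget // pair_time)


def effective_plds(pld: float, slice_duration: float, n_slices: int) -> np.ndarray:
    """Per-slice effective PLDs ``pld + k * slice_duration``, k = 0..n-1."""
    if n_slices < 1:
        raise InvalidParameterError("n_slices must be >= 1")
    return pld + slice_duration * np.arange(n_slices)


@dataclass(frozen=True)
class Protocol:
    """A multi-PLD PCASL acquisition schedule."""

    plds: np.ndarray
    label_duration: float = 1.4
    readout_duration: float = 1.275
    slice_duration: float = 0.053125
    n_slices: int = 5
    n_averages: int = 1
    scan_time_budget: float = 300.0
    name: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.plds, dtype=float)
        if p.size == 0:
            raise InvalidParameterError("protocol needs at least one PLD")
        if np.any(np.diff(p) < 0):
            raise InvalidParameterError("plds must be non-decreasing")
        if self.n_slices < 1 or self.n_averages < 0:
            raise InvalidParameterError("n_slices >= 1 and n_averages >= 0 required")
        object.__setattr__(self, "plds", p)

    @property
    def n_plds(self) -> int:
        return self.plds.size

    @property
    def pair_time(self) -> float:
        """Scan time of one average (one label-control pair per PLD)."""
        return 2.0 * float(
            np.sum(self.label_duration + self.plds + self.readout_duration)
        )

    @property
    def total_scan_time(self) -> float:
        return self.n_averages * self.pair_time

    def with_averages_from_budget(self) -> "Protocol":
        """Recompute ``n_averages`` from the scan-time budget."""
        a = compute_averages(
            self.plds, self.label_duration, self.readout_duration, self.scan_time_budget
        )
        return replace(self, n_averages=a)

    def slice_sample_times(self, slice_index: int) -> np.ndarray:
        """Sample times of one slice, seconds from the start of labeling."""
        if not 0 <= slice_index < self.n_slices:
            raise InvalidParameterError("slice_index out of range")
        return self.label_duration + self.plds + slice_index * self.slice_duration

    def sample_times(self) -> np.ndarray:
        """(n_plds, n_slices) array of sample times."""
        return (
            self.label_duration
            + self.plds[:, None]
            + self.slice_duration * np.arange(self.n_slices)[None, :]
        )

    def min_effective_pld(self, slice_index: int) -> float:
        return float(self.plds.min()) + slice_index * self.slice_duration


def _to_dict(protocol: Protocol) -> dict:
    return {
        "name": protocol.name,
        "plds_s": [float(p) for p in protocol.plds],
        "label_duration_s": protocol.label_duration,
        "readout_duration_s": protocol.readout_duration,
        "slice_duration_s": protocol.slice_duration,
        "n_slices": protocol.n_slices,
        "n_averages": protocol.n_averages,
        "scan_time_budget_s": protocol.scan_time_budget,
    }


def _from_dict(d: dict) -> Protocol:
    return Protocol(
        plds=np.asarray(d["plds_s"], dtype=float),
        label_duration=float(d["label_duration_s"]),
        readout_duration=float(d["readout_duration_s"]),
        slice_duration=float(d["slice_duration_s"]),
        n_slices=int(d["n_slices"]),
        n_averages=int(d["n_averages"]),
        scan_time_budget=float(d["scan_time_budget_s"]),
        name=str(d.get("name", "")),
    )


def save_protocol(protocol: Protocol, path) -> None:
    Path(path).write_text(json.dumps(_to_dict(protocol), indent=2) + "\n")


def load_protocol(path) -> Protocol:
    return _from_dict(json.loads(Path(path).read_text()))


def read_plds_csv(path) -> np.ndarray:
    """Read a one-PLD-per-row CSV (plain values, optional 'pld_s' header)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and not lines[0].replace(".", "", 1).replace("-", "", 1).isdigit():
        lines = lines[1:]
    return np.asarray([float(x) for x in lines])


def builtin_protocol(name: str) -> Protocol:
    """Load one of the shipped protocol fixtures by name."""
    if name not in BUILTIN_PROTOCOLS:
        raise InvalidParameterError(
            f"unknown protocol {name!r}; choose from {BUILTIN_PROTOCOLS}"
        )
    ref = resources.files("asldesign").joinpath(f"data/{name}.json")
    return _from_dict(json.loads(ref.read_text()))
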