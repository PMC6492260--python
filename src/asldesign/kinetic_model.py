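"""PCASL general kinetic model and its analytic sensitivity functions.

The label-control difference signal of a (pseudo-)continuous ASL experiment
is modelled with the single-compartment general kinetic model: labeled blood
arrives at the tissue after the arterial transit time ``att`` (s), inflows
for the labeling duration ``tau``, and then decays with the apparent tissue
relaxation time T1' which accounts for venous outflow of label,

    1/T1' = 1/T1t + f/lambda,

with ``f`` the perfusion rate in s^-1. User-facing CBF is expressed in
mL/100g/min and converted internally via ``f = cbf / 6000``.

All times are measured from the start of labeling, so a post-labeling delay
``pld`` samples the curve at ``t = tau + pld``.

Two evaluation modes are provided for T1':

``self``
    T1' uses the CBF value being evaluated.  This is the exact model, used
    in simulation and model fitting.
``fixed``
    T1' is frozen at a nominal outflow CBF (default 50 mL/100g/min).  Under
    this approximation the signal is exactly linear in CBF, which makes the
    CBF sensitivity independent of CBF and lets optimal designs be computed
    without a CBF prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "CBF_TO_RATE",
    "AcquisitionConstants",
    "PhysioParams",
    "apparent_t1",
    "gkm_signal",
    "cbf_sensitivity_simplified",
    "cbf_sensitivity_complete",
    "att_sensitivity",
    "fixed_outflow_max_relative_error",
]

#: conversion from mL/100g/min to s^-1 (100 g of tissue, 60 s per minute)
CBF_TO_RATE = 1.0 / 6000.0


@dataclass(frozen=True)
class AcquisitionConstants:
    """Fixed acquisition and physiological constants of the signal model.

    Parameters
    ----------
    label_duration
        PCASL labeling duration tau (s).
    labeling_efficiency
        Labeling efficiency alpha, in (0, 1].
    partition_coeff
        Brain-blood water partition coefficient lambda (mL/g).
    t1_blood
        Longitudinal relaxation time of arterial blood T1b (s).
    t1_tissue
        Longitudinal relaxation time of tissue T1t (s).
    m0_blood
        Equilibrium magnetization of arterial blood (signal units).
    fixed_outflow_cbf
        CBF (mL/100g/min) at which T1' is frozen in ``fixed`` mode.
    """

    label_duration: float = 1.4
    labeling_efficiency: float = 0.85
    partition_coeff: float = 0.9
    t1_blood: float = 1.65
    t1_tissue: float = 1.445
    m0_blood: float = 1.0
    fixed_outflow_cbf: float = 50.0

    def __post_init__(self) -> None:
        if not (
            self.label_duration > 0
            and self.t1_blood > 0
            and self.t1_tissue > 0
            and self.partition_coeff > 0
        ):
            raise InvalidParameterError("time constants and lambda must be positive")
        if not 0 < self.labeling_efficiency <= 1:
            raise InvalidParameterError("labeling efficiency must be in (0, 1]")
        if self.fixed_outflow_cbf < 0:
            raise InvalidParameterError("fixed_outflow_cbf must be non-negative")


@dataclass(frozen=True)
class PhysioParams:
    """The two parameters being estimated: CBF (mL/100g/min) and ATT (s)."""

    cbf: float
    att: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cbf) and self.cbf >= 0):
            raise InvalidParameterError(f"cbf must be finite and >= 0, got {self.cbf}")
        if not (np.isfinite(self.att) and self.att >= 0):
            raise InvalidParameterError(f"att must be finite and >= 0, got {self.att}")

    @property
    def f(self) -> float:
        """Perfusion rate in s^-1."""
        return self.cbf * CBF_TO_RATE


def apparent_t1(f: float, acq: AcquisitionConstants) -> float:
    """Apparent tissue relaxation time T1' (s) at perfusion rate ``f`` (s^-1).

    1/T1' = 1/T1t + f/lambda.  Monotonically decreasing in f and equal to
    T1t at zero flow.
    """
    f = np.asarray(f, dtype=float)
    if np.any(~np.isfinite(f)) or np.any(f < 0):
        raise InvalidParameterError("perfusion rate must be finite and >= 0")
    out = 1.0 / (1.0 / acq.t1_tissue + f / acq.partition_coeff)
    return float(out) if out.ndim == 0 else out


def _t1prime(phys: PhysioParams, acq: AcquisitionConstants, mode: str) -> float:
    if mode == "self":
        return apparent_t1(phys.f, acq)
    if mode == "fixed":
        return apparent_t1(acq.fixed_outflow_cbf * CBF_TO_RATE, acq)
    raise InvalidParameterError(f"t1prime_mode must be 'self' or 'fixed', got {mode!r}")


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise InvalidParameterError("sample times must be finite and >= 0")
    return t


def _piecewise(t: np.ndarray, att: float, tau: float, inflow, decay):
    """Assemble the three-phase curve.  The inflow branch owns t = att and
    the decay branch owns t = tau + att (both are continuity points of the
    signal, so ownership only matters for the ATT sensitivity, which jumps
    at the end of inflow)."""
    return np.where(t < att, 0.0, np.where(t < tau + att, inflow, decay))


def gkm_signal(t, phys: PhysioParams, acq: AcquisitionConstants, t1prime_mode: str = "self"):
    """Difference signal dM(t) of the general kinetic model.

    Zero before arrival, rising during bolus inflow, and relaxing after the
    trailing edge of the bolus passes at ``t = tau + att``, where the signal
    peaks.

    Parameters
    ----------
    t
        Time(s) from the start of labeling (s); scalar or array.
    t1prime_mode
        ``"self"`` (exact) or ``"fixed"`` (T1' frozen; signal linear in CBF).
    """
    t = _check_times(t)
    tau = acq.label_duration
    tp = _t1prime(phys, acq, t1prime_mode)
    pre = 2.0 * acq.m0_blood * phys.f * tp * acq.labeling_efficiency * np.exp(
        -phys.att / acq.t1_blood
    )
    inflow = pre * (1.0 - np.exp(-(t - phys.att) / tp))
    decay = pre * np.exp(-(t - tau - phys.att) / tp) * (1.0 - np.exp(-tau / tp))
    out = _piecewise(t, phys.att, tau, inflow, decay)
    return float(out) if out.ndim == 0 else out


def cbf_sensitivity_simplified(t, phys: PhysioParams, acq: AcquisitionConstants):
    """d(dM)/df with T1' frozen at the nominal outflow CBF (signal per s^-1).

    Because the frozen-T1' signal is exactly linear in f, this is simply the
    fixed-mode signal evaluated at unit perfusion rate; it does not depend
    on ``phys.cbf``.  Freezing the outflow introduces a small model error
    (at most a couple of percent over physiological CBF; see
    :func:`fixed_outflow_max_relative_error`).
    """
    t = _check_times(t)
    tau = acq.label_duration
    tp = _t1prime(phys, acq, "fixed")
    pre = 2.0 * acq.m0_blood * tp * acq.labeling_efficiency * np.exp(
        -phys.att / acq.t1_blood
    )
    inflow = pre * (1.0 - np.exp(-(t - phys.att) / tp))
    decay = pre * np.exp(-(t - tau - phys.att) / tp) * (1.0 - np.exp(-tau / tp))
    out = _piecewise(t, phys.att, tau, inflow, decay)
    return float(out) if out.ndim == 0 else out


def cbf_sensitivity_complete(t, phys: PhysioParams, acq: AcquisitionConstants):
    """Exact d(dM)/df including the dependence of T1' on f (signal per s^-1).

    Obtained by the chain rule with dT1'/df = -T1'^2 / lambda applied to
    every appearance of T1' in the model.
    """
    t = _check_times(t)
    tau = acq.label_duration
    f = phys.f
    tp = apparent_t1(f, acq)
    dtp = -(tp**2) / acq.partition_coeff
    base = 2.0 * acq.m0_blood * acq.labeling_efficiency * np.exp(-phys.att / acq.t1_blood)
    x = t - phys.att
    y = t - tau - phys.att
    E = np.exp(-x / tp)
    Q = np.exp(-tau / tp)
    D = np.exp(-y / tp)
    # d/df of exp(-z/T1') is exp(-z/T1') * (z/T1'^2) * dT1'/df
    dE = E * (x / tp**2) * dtp
    dQ = Q * (tau / tp**2) * dtp
    dD = D * (y / tp**2) * dtp
    inflow = base * (tp * (1.0 - E) + f * dtp * (1.0 - E) - f * tp * dE)
    decay = base * (
        tp * D * (1.0 - Q)
        + f * dtp * D * (1.0 - Q)
        + f * tp * dD * (1.0 - Q)
        - f * tp * D * dQ
    )
    out = _piecewise(t, phys.att, tau, inflow, decay)
    return float(out) if out.ndim == 0 else out


def att_sensitivity(t, phys: PhysioParams, acq: AcquisitionConstants, t1prime_mode: str = "fixed"):
    """d(dM)/d(att) of the kinetic model (signal per second).

    Proportional to CBF.  During inflow the derivative combines blood T1
    decay of the arriving label with the shifted arrival edge; after the
    bolus it is the signal scaled by (1/T1' - 1/T1b).  The derivative is
    discontinuous at ``t = tau + att`` (the signal has a kink there as a
    function of ATT); the decay branch owns the breakpoint.

    ``t1prime_mode`` defaults to ``"fixed"``, the convention used inside the
    design optimizer; ``"self"`` gives the exact-model derivative used for
    fitting Jacobians.
    """
    t = _check_times(t)
    tau = acq.label_duration
    tp = _t1prime(phys, acq, t1prime_mode)
    t1b = acq.t1_blood
    pre = 2.0 * acq.m0_blood * phys.f * tp * acq.labeling_efficiency * np.exp(
        -phys.att / t1b
    )
    x = t - phys.att
    y = t - tau - phys.att
    Q = np.exp(-tau / tp)
    inflow = pre * (-1.0 / t1b - np.exp(-x / tp) * (1.0 / tp - 1.0 / t1b))
    decay = pre * np.exp(-y / tp) * (1.0 - Q) * (1.0 / tp - 1.0 / t1b)
    out = _piecewise(t, phys.att, tau, inflow, decay)
    return float(out) if out.ndim == 0 else out


def fixed_outflow_max_relative_error(
    acq: AcquisitionConstants | None = None,
    cbf_max: float = 100.0,
    att: float = 0.5,
    n_cbf: int = 401,
    n_t: int = 2001,
) -> float:
    """Maximum relative error of the frozen-T1' CBF sensitivity.

    Scans true CBF over [0, ``cbf_max``] mL/100g/min and time over the rising
    part of the curve (arrival through the signal peak at ``tau + att``,
    where CBF information is concentrated), comparing the simplified
    sensitivity against the exact derivative pointwise.  Returns the largest
    relative deviation (fraction, not percent).

    The comparison window stops at the peak because past it the two
    expressions decay at different exponential rates, so their pointwise
    ratio diverges as the signal itself vanishes.
    """
    if acq is None:
        acq = AcquisitionConstants()
    tau = acq.label_duration
    ts = np.linspace(att + 1e-9, tau + att, n_t)
    worst = 0.0
    for cbf in np.linspace(0.0, cbf_max, n_cbf):
        phys = PhysioParams(cbf=cbf, att=att)
        exact = cbf_sensitivity_complete(ts, phys, acq)
        approx = cbf_sensitivity_simplified(ts, phys, acq)
        worst = max(worst, float(np.max(np.abs((approx - exact) / exact))))
    return worst
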