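"""Maximum-likelihood (least-squares) recovery of CBF and ATT.

With Gaussian noise of equal variance at every sample, maximizing the
likelihood is minimizing the residual sum of squares of the exact kinetic
model.  Fits are initialized by a coarse exhaustive grid search and refined
with bounded trust-region least squares using analytic Jacobians; bounds
are 0 <= CBF <= 200 mL/100g/min and 0 <= ATT <= 2.5 s.

Single-PLD data cannot identify both parameters, so the standard procedure
fixes ATT at an assumed value and fits CBF alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidParameterError
from .kinetic_model import (
    CBF_TO_RATE,
    AcquisitionConstants,
    PhysioParams,
    att_sensitivity,
    cbf_sensitivity_complete,
    gkm_signal,
)

__all__ = [
    "CBF_BOUNDS",
    "ATT_BOUNDS",
    "FitResult",
    "grid_init",
    "fit_nlls",
    "fit_single_pld",
    "error_metrics",
]

CBF_BOUNDS = (0.0, 200.0)
ATT_BOUNDS = (0.0, 2.5)

#: coarse initialization lattice (CBF step 10 mL/100g/min, ATT step 0.1 s)
_GRID_CBF = np.arange(0.0, 200.0 + 1e-9, 10.0)
_GRID_ATT = np.arange(0.0, 2.5 + 1e-9, 0.1)


@dataclass(frozen=True)
class FitResult:
    """Point estimates and fit diagnostics for one dataset."""

    cbf_hat: float
    att_hat: float
    residual_ss: float
    noise_hat: float  # residual variance, normalized by degrees of freedom
    converged: bool


def _model(times: np.ndarray, cbf: float, att: float, acq: AcquisitionConstants) -> np.ndarray:
    return np.atleast_1d(gkm_signal(times, PhysioParams(cbf=cbf, att=att), acq, "self"))


def _model_lattice(times: np.ndarray, acq: AcquisitionConstants) -> np.ndarray:
    """(n_cbf, n_att, n_times) model values on the init lattice (cached)."""
    key = (times.tobytes(), id(acq))
    cached = _lattice_cache.get(key)
    if cached is not None:
        return cached
    out = np.empty((_GRID_CBF.size, _GRID_ATT.size, times.size))
    for i, cbf in enumerate(_GRID_CBF):
        for j, att in enumerate(_GRID_ATT):
            out[i, j] = _model(times, cbf, att, acq)
    if len(_lattice_cache) > 8:
        _lattice_cache.clear()
    _lattice_cache[key] = out
    return out


_lattice_cache: dict = {}


def grid_init(times, values, acq: AcquisitionConstants | None = None) -> tuple[float, float]:
    """Exhaustive coarse-lattice search for a least-squares starting point."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        raise InvalidParameterError("empty dataset")
    if acq is None:
        acq = AcquisitionConstants()
    lattice = _model_lattice(times, acq)
    sse = ((lattice - values[None, None, :]) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return float(_GRID_CBF[i]), float(_GRID_ATT[j])


def _fit_one(times, values, acq, x0) -> tuple[float, float, float, bool]:
    def residual(x):
        return _model(times, x[0], x[1], acq) - values

    def jac(x):
        phys = PhysioParams(cbf=x[0], att=x[1])
        d_cbf = np.atleast_1d(cbf_sensitivity_complete(times, phys, acq)) * CBF_TO_RATE
        d_att = np.atleast_1d(att_sensitivity(times, phys, acq, t1prime_mode="self"))
        return np.stack([d_cbf, d_att], axis=1)

    res = least_squares(
        residual,
        x0=np.asarray(x0, dtype=float),
        jac=jac,
        bounds=([CBF_BOUNDS[0], ATT_BOUNDS[0]], [CBF_BOUNDS[1], ATT_BOUNDS[1]]),
        method="trf",
        ftol=1e-10,
        xtol=1e-10,
        max_nfev=200,
    )
    return float(res.x[0]), float(res.x[1]), float(2.0 * res.cost), bool(res.success)


def fit_nlls(series, acq: AcquisitionConstants | None = None, repeat: int = 0) -> FitResult:
    """Bounded two-parameter least-squares fit of one simulated dataset.

    ``series`` is a :class:`~asldesign.simulator.SimulatedSeries` (one
    repeat is selected) or a ``(times, values)`` pair of flat arrays.
    """
    if acq is None:
        acq = AcquisitionConstants()
    times, values = _extract(series, repeat)
    if np.unique(times).size < 2:
        raise InvalidParameterError("need >= 2 distinct sample times to fit 2 parameters")
    x0 = grid_init(times, values, acq)
    cbf, att, rss, ok = _fit_one(times, values, acq, x0)
    dof = max(times.size - 2, 1)
    return FitResult(cbf, att, rss, rss / dof, ok)


def fit_single_pld(
    series,
    assumed_att: float,
    acq: AcquisitionConstants | None = None,
    repeat: int = 0,
) -> FitResult:
    """One-parameter CBF fit with ATT fixed at ``assumed_att``."""
    if acq is None:
        acq = AcquisitionConstants()
    times, values = _extract(series, repeat)
    cbf, rss, ok = _fit_single(times, values, assumed_att, acq)
    dof = max(times.size - 1, 1)
    return FitResult(cbf, float(assumed_att), rss, rss / dof, ok)


def _fit_single(times, values, assumed_att, acq) -> tuple[float, float, bool]:
    def residual(x):
        return _model(times, x[0], assumed_att, acq) - values

    def jac(x):
        phys = PhysioParams(cbf=x[0], att=assumed_att)
        d = np.atleast_1d(cbf_sensitivity_complete(times, phys, acq)) * CBF_TO_RATE
        return d[:, None]

    lattice = _model_lattice(times, acq)
    j0 = int(np.argmin(np.abs(_GRID_ATT - assumed_att)))
    sse = ((lattice[:, j0, :] - values[None, :]) ** 2).sum(axis=-1)
    x0 = [float(_GRID_CBF[int(np.argmin(sse))])]
    res = least_squares(
        residual,
        x0=x0,
        jac=jac,
        bounds=([CBF_BOUNDS[0]], [CBF_BOUNDS[1]]),
        method="trf",
        ftol=1e-10,
        xtol=1e-10,
        max_nfev=200,
    )
    return float(res.x[0]), float(2.0 * res.cost), bool(res.success)


def _extract(series, repeat: int):
    if isinstance(series, tuple):
        times, values = series
        return np.asarray(times, float).ravel(), np.asarray(values, float).ravel()
    return series.dataset(repeat)


def fit_nlls_arrays(times, values_2d, acq) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit many repeats (rows of ``values_2d``); returns (cbf, att, converged)."""
    times = np.asarray(times, dtype=float)
    values_2d = np.atleast_2d(values_2d)
    n = values_2d.shape[0]
    cbf = np.empty(n)
    att = np.empty(n)
    ok = np.empty(n, dtype=bool)
    lattice = _model_lattice(times, acq)
    flat = lattice.reshape(-1, times.size)
    for r in range(n):
        sse = ((flat - values_2d[r][None, :]) ** 2).sum(axis=-1)
        i, j = np.unravel_index(np.argmin(sse), (lattice.shape[0], lattice.shape[1]))
        x0 = (float(_GRID_CBF[i]), float(_GRID_ATT[j]))
        cbf[r], att[r], _, ok[r] = _fit_one(times, values_2d[r], acq, x0)
    return cbf, att, ok


def fit_single_pld_arrays(times, values_2d, assumed_att, acq) -> tuple[np.ndarray, np.ndarray]:
    """Single-PLD CBF fits for many repeats; returns (cbf, converged)."""
    times = np.asarray(times, dtype=float)
    values_2d = np.atleast_2d(values_2d)
    n = values_2d.shape[0]
    cbf = np.empty(n)
    ok = np.empty(n, dtype=bool)
    for r in range(n):
        cbf[r], _, ok[r] = _fit_single(times, values_2d[r], assumed_att, acq)
    return cbf, ok


def error_metrics(estimates, truths) -> tuple[float, float, float]:
    """(RMSE, bias, SD) of estimates against truth.

    bias = mean(est - truth); SD is the sample standard deviation (ddof=1)
    of the estimates; RMSE = sqrt(mean((est - truth)^2)), so
    RMSE^2 = bias^2 + SD^2 * (n-1)/n for constant truth.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise InvalidParameterError("need at least two estimates")
    err = est - np.asarray(truths, dtype=float)
    rmse = float(np.sqrt(np.mean(err**2)))
    bias = float(np.mean(err))
    sd = float(np.std(est, ddof=1))
    return rmse, bias, sd
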