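"""Fisher information, Cramér-Rao bounds, and optimality criteria.

The two estimated parameters are ordered ``[CBF, ATT]`` with CBF in
mL/100g/min and ATT in seconds, so the diagonal of the CRLB matrix reads
directly as variances in those user units.

For ``A`` averaged label-control pairs, each difference measurement having
noise variance ``sigma^2``, the information from sample times ``t_i`` is

    F_jk = (A / sigma^2) * sum_i s_j(t_i) s_k(t_i),

where ``s = [d(dM)/dCBF, d(dM)/dATT]`` are the sensitivity functions.  The
design convention uses the frozen-T1' (simplified) CBF sensitivity, which
makes F independent of the CBF point value up to an overall scaling of the
ATT column (ATT sensitivity is proportional to CBF) - hence optimal designs
do not require a CBF prior.

``sigma^2`` here is the variance of a single label-control *difference*
image; the noise of one acquired image is smaller by a factor sqrt(2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import (
    InvalidParameterError,
    SingularInformationError,
    UndefinedBiasError,
)
from .kinetic_model import (
    CBF_TO_RATE,
    AcquisitionConstants,
    PhysioParams,
    att_sensitivity,
    cbf_sensitivity_simplified,
    gkm_signal,
)

__all__ = [
    "CONDITION_LIMIT",
    "FisherInfo",
    "CriterionSpec",
    "build_fim",
    "crlb",
    "criterion_value",
    "cbf_information",
    "single_pld_bias",
    "single_pld_rmse",
    "optimal_assumed_att",
]

#: condition-number threshold above which a 2x2 FIM is treated as singular
CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class FisherInfo:
    """A 2x2 Fisher information matrix with its scaling metadata."""

    matrix: np.ndarray
    n_averages: int = 1
    noise_variance: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 2):
            raise InvalidParameterError("FisherInfo.matrix must be 2x2")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class CriterionSpec:
    """Which scalar functional of the CRLB matrix to minimize.

    ``d_optimal`` minimizes det(F^-1) (volume of the confidence ellipsoid,
    i.e. joint CBF-ATT precision); ``l_optimal`` minimizes the CBF variance
    [F^-1]_00 alone; ``weighted_trace`` minimizes trace(W F^-1) for an
    arbitrary positive semi-definite weight matrix W.
    """

    kind: str = "d_optimal"
    weight_matrix: np.ndarray | None = None

    _KINDS = ("d_optimal", "l_optimal", "weighted_trace")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InvalidParameterError(f"criterion kind must be one of {self._KINDS}")
        if self.kind == "weighted_trace":
            w = np.asarray(self.weight_matrix, dtype=float)
            if w.shape != (2, 2) or not np.allclose(w, w.T):
                raise InvalidParameterError("weight_matrix must be symmetric 2x2")
            if np.any(np.linalg.eigvalsh(w) < -1e-12):
                raise InvalidParameterError("weight_matrix must be PSD")
            object.__setattr__(self, "weight_matrix", w)

    @classmethod
    def d_optimal(cls) -> "CriterionSpec":
        return cls(kind="d_optimal")

    @classmethod
    def l_optimal(cls) -> "CriterionSpec":
        # W = diag(1, 0): only the CBF variance counts
        return cls(kind="l_optimal")


def _sensitivities(
    sample_times, phys: PhysioParams, acq: AcquisitionConstants
) -> np.ndarray:
    """(n, 2) design-convention sensitivity matrix in user units."""
    t = np.asarray(sample_times, dtype=float)
    s_cbf = cbf_sensitivity_simplified(t, phys, acq) * CBF_TO_RATE
    s_att = att_sensitivity(t, phys, acq, t1prime_mode="fixed")
    return np.stack([np.atleast_1d(s_cbf), np.atleast_1d(s_att)], axis=1)


def build_fim(
    sample_times,
    phys: PhysioParams,
    acq: AcquisitionConstants,
    n_averages: int = 1,
    noise_variance: float = 1.0,
) -> FisherInfo:
    """Fisher information of ``sample_times`` (seconds from labeling start).

    Uses the optimizer convention: simplified CBF sensitivity and the
    frozen-T1' ATT sensitivity.  Scales linearly with ``n_averages`` and
    with ``1 / noise_variance``.
    """
    t = np.asarray(sample_times, dtype=float)
    if t.size == 0:
        raise InvalidParameterError("sample_times must be nonempty")
    if n_averages < 1:
        raise InvalidParameterError("n_averages must be >= 1")
    if not noise_variance > 0:
        raise InvalidParameterError("noise_variance must be > 0")
    s = _sensitivities(t, phys, acq)
    f = (n_averages / noise_variance) * (s.T @ s)
    return FisherInfo(matrix=f, n_averages=int(n_averages), noise_variance=float(noise_variance))


def _condition_2x2(m: np.ndarray) -> float:
    ev = np.linalg.eigvalsh(m)
    lo, hi = float(ev[0]), float(ev[-1])
    if lo <= 0:
        return np.inf
    return hi / lo


def crlb(fim: FisherInfo) -> np.ndarray:
    """Closed-form inverse of a 2x2 FIM: the parameter covariance bound.

    Raises :class:`SingularInformationError` when the matrix is singular or
    has condition number above :data:`CONDITION_LIMIT` - for ASL designs
    this signals a lack of ATT information (all samples post-bolus).
    """
    m = fim.matrix
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if not np.isfinite(det) or det <= 0 or _condition_2x2(m) > CONDITION_LIMIT:
        raise SingularInformationError(
            "Fisher information matrix is singular or ill-conditioned "
            "(likely no sample precedes bolus arrival)"
        )
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def criterion_value(fim: FisherInfo, spec: CriterionSpec) -> float:
    """Evaluate the design criterion on one information matrix."""
    cov = crlb(fim)
    if spec.kind == "d_optimal":
        return float(cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0])
    if spec.kind == "l_optimal":
        return float(cov[0, 0])
    return float(np.trace(spec.weight_matrix @ cov))


def cbf_information(
    sample_times,
    att: float,
    acq: AcquisitionConstants,
    n_averages: int = 1,
    noise_variance: float = 1.0,
) -> float:
    """Scalar CBF-only information (ATT assumed known), user units^-2."""
    if n_averages < 1 or not noise_variance > 0:
        raise InvalidParameterError("need n_averages >= 1 and noise_variance > 0")
    phys = PhysioParams(cbf=acq.fixed_outflow_cbf, att=att)
    t = np.asarray(sample_times, dtype=float)
    s = np.atleast_1d(cbf_sensitivity_simplified(t, phys, acq)) * CBF_TO_RATE
    return float(n_averages / noise_variance * np.sum(s * s))


def _single_pld_times(
    pld: float, acq: AcquisitionConstants, slice_duration: float, n_slices: int
) -> np.ndarray:
    return acq.label_duration + pld + slice_duration * np.arange(n_slices)


def single_pld_bias(
    pld: float,
    assumed_att: float,
    true_phys: PhysioParams,
    acq: AcquisitionConstants,
    slice_duration: float = 0.0,
    n_slices: int = 1,
) -> float:
    """Systematic CBF error (mL/100g/min) of a fixed-ATT single-PLD fit.

    Each slice is an independent voxel population sampled at its own
    effective delay, so the mismatch problem is solved per slice (the CBF
    whose model value at ``assumed_att`` reproduces the true noiseless
    signal) and the per-slice biases are averaged.  Zero when the assumed
    ATT equals the truth.
    """
    ts = _single_pld_times(pld, acq, slice_duration, n_slices)
    probe = np.atleast_1d(
        gkm_signal(ts, PhysioParams(cbf=acq.fixed_outflow_cbf, att=assumed_att), acq)
    )
    if np.all(probe == 0.0):
        raise UndefinedBiasError(
            "model signal is identically zero at the sample times; "
            "CBF is unidentifiable"
        )
    biases = []
    for t in np.atleast_1d(ts):
        target = gkm_signal(float(t), true_phys, acq, t1prime_mode="self")

        def sse(cbf: float) -> float:
            m = gkm_signal(float(t), PhysioParams(cbf=cbf, att=assumed_att), acq, "self")
            return (m - target) ** 2

        res = minimize_scalar(
            sse, bounds=(0.0, 200.0), method="bounded", options={"xatol": 1e-10}
        )
        biases.append(float(res.x) - true_phys.cbf)
    return float(np.mean(biases))


def single_pld_rmse(
    pld: float,
    assumed_att: float,
    true_phys: PhysioParams,
    acq: AcquisitionConstants,
    n_averages: int = 1,
    noise_variance: float = 1.0,
    slice_duration: float = 0.0,
    n_slices: int = 1,
) -> float:
    """Theoretical RMSE of single-PLD CBF estimation (mL/100g/min).

    Per slice: sqrt(CRLB variance + bias^2), where the variance is the
    scalar CBF-only bound of that slice's single sample at the *assumed*
    ATT (the model actually fitted) and the bias is its noiseless mismatch
    error against the true ATT.  Returns the mean over slices.
    """
    ts = np.atleast_1d(_single_pld_times(pld, acq, slice_duration, n_slices))
    rmses = []
    for t in ts:
        info = cbf_information([float(t)], assumed_att, acq, n_averages, noise_variance)
        if info <= 0:
            raise SingularInformationError("no CBF information at this sample time")
        b = single_pld_bias(
            pld + (t - ts[0]), assumed_att, true_phys, acq, slice_duration=0.0, n_slices=1
        )
        rmses.append(np.sqrt(1.0 / info + b * b))
    return float(np.mean(rmses))


def optimal_assumed_att(
    pld: float,
    acq: AcquisitionConstants,
    n_averages: int,
    noise_variance: float,
    cbf: float = 50.0,
    candidate_atts=None,
    true_atts=None,
    slice_duration: float = 0.0,
    n_slices: int = 1,
) -> tuple[float, np.ndarray]:
    """Assumed ATT minimizing mean theoretical single-PLD RMSE.

    Sweeps candidate assumed-ATT values (default 0.5-1.8 s in 0.05 s steps),
    averaging the RMSE uniformly over the true-ATT range (default 0.5-1.8 s
    in 0.01 s steps).  Returns the minimizer and the mean-RMSE curve.
    """
    if candidate_atts is None:
        candidate_atts = np.round(np.arange(0.5, 1.8 + 1e-9, 0.05), 6)
    if true_atts is None:
        true_atts = np.round(np.arange(0.5, 1.8 + 1e-9, 0.01), 6)
    candidate_atts = np.asarray(candidate_atts, dtype=float)
    mean_rmse = np.empty(candidate_atts.size)
    for i, assumed in enumerate(candidate_atts):
        vals = [
            single_pld_rmse(
                pld,
                assumed,
                PhysioParams(cbf=cbf, att=float(ta)),
                acq,
                n_averages,
                noise_variance,
                slice_duration,
                n_slices,
            )
            for ta in true_atts
        ]
        mean_rmse[i] = float(np.mean(vals))
    best = int(np.argmin(mean_rmse))
    return float(candidate_atts[best]), mean_rmse
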