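"""Prior-averaged optimal PLD selection by coordinate exchange.

The design cost of a protocol is the optimality criterion (D- or
L-optimality of the 2x2 CBF/ATT Fisher matrix) averaged over a discretized
ATT prior and over slices.  For each slice the prior is truncated below the
slice's shortest effective PLD: ATT values that no sample of the slice
precedes leave every measurement on the post-bolus decay, where the two
sensitivities are collinear and the information matrix is singular.  The
surviving (slice, ATT) terms are combined as

    cost = sum_{l,k in contrib} phi(slice k; att_l) p_l  /  sum_{l,k in contrib} p_l,

i.e. a mass-weighted mean in which an ATT sample counts once per slice that
can inform it.

The search itself is an iterative exchange: cycle through the PLDs in
ascending index order and replace each one with the best value on a 25 ms
grid between its neighbors (monotonicity is enforced by the candidate
interval itself), recomputing the scan-time-limited number of averages for
every candidate.  Passes repeat until a full pass changes nothing.  The
noise variance is a pure scale factor of every criterion and is fixed at 1
inside the optimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .att_prior import ATTPrior
from .errors import (
    InfeasibleDesignError,
    InvalidParameterError,
    OptimizationFailedError,
)
from .information import CONDITION_LIMIT, CriterionSpec
from .kinetic_model import CBF_TO_RATE, AcquisitionConstants, apparent_t1
from .protocol import Protocol, compute_averages, effective_plds  # noqa: F401  (re-export)

__all__ = [
    "OptimizerConfig",
    "OptimizeResult",
    "expected_cost",
    "optimize_plds",
    "sweep_num_plds",
    "compute_averages",
    "effective_plds",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizerConfig:
    """Search-space and convergence settings for the exchange algorithm."""

    n_plds: int
    pld_min: float = 0.2
    pld_max: float = 3.0
    pld_step: float = 0.025
    init_range: tuple[float, float] = (0.25, 1.5)
    max_passes: int = 50
    criterion: CriterionSpec = field(default_factory=CriterionSpec.d_optimal)

    def __post_init__(self) -> None:
        if self.n_plds < 2:
            raise InvalidParameterError("n_plds must be >= 2 (two parameters)")
        if not (self.pld_min < self.pld_max and self.pld_step > 0):
            raise InvalidParameterError("need pld_min < pld_max and pld_step > 0")


@dataclass(frozen=True)
class OptimizeResult:
    """Optimized protocol plus convergence diagnostics."""

    protocol: Protocol
    cost: float
    cost_history: list[float]
    n_passes: int


class _CostEngine:
    """Vectorized evaluation of the prior-averaged criterion.

    Precomputes, per (slice, ATT sample), the sensitivity ingredients so
    that exchanging one PLD only requires adding a rank-one update to the
    cached Gram-matrix entries of the remaining PLDs.
    """

    def __init__(
        self,
        prior: ATTPrior,
        acq: AcquisitionConstants,
        criterion: CriterionSpec,
        n_slices: int,
        slice_duration: float,
        readout_duration: float,
        scan_time_budget: float,
        noise_variance: float = 1.0,
        slice_weighting: str = "mass",
        cbf_point: float = 50.0,
    ) -> None:
        if prior.is_empty:
            raise InvalidParameterError("prior is empty")
        if slice_weighting not in ("mass", "mean_over_slices"):
            raise InvalidParameterError("slice_weighting must be 'mass' or 'mean_over_slices'")
        self.prior = prior
        self.acq = acq
        self.criterion = criterion
        self.n_slices = n_slices
        self.slice_duration = slice_duration
        self.readout = readout_duration
        self.budget = scan_time_budget
        self.sigma2 = noise_variance
        self.slice_weighting = slice_weighting
        self.cbf_point = cbf_point  # CBF point prior; designs are invariant to it
        self.slice_offsets = slice_duration * np.arange(n_slices)
        self.tp = apparent_t1(acq.fixed_outflow_cbf * CBF_TO_RATE, acq)

    # -- sensitivity ingredients ------------------------------------------

    def _uv(self, plds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Design-convention sensitivities, shape (n_slices, n_att, n_pld).

        u = d(dM)/dCBF in user units (frozen T1'), v = d(dM)/dATT at the
        CBF point prior.
        """
        acq, tp = self.acq, self.tp
        tau = acq.label_duration
        t = tau + plds[None, None, :] + self.slice_offsets[:, None, None]
        att = self.prior.att_values[None, :, None]
        f0 = self.cbf_point * CBF_TO_RATE
        pre = 2.0 * acq.m0_blood * tp * acq.labeling_efficiency * np.exp(-att / acq.t1_blood)
        x = t - att
        y = t - tau - att
        q = np.exp(-tau / tp)
        ex = np.exp(-np.maximum(x, 0.0) / tp)
        dy = np.exp(-np.maximum(y, 0.0) / tp)
        u_in = pre * (1.0 - ex)
        u_de = pre * dy * (1.0 - q)
        v_in = pre * f0 * (-1.0 / acq.t1_blood - ex * (1.0 / tp - 1.0 / acq.t1_blood))
        v_de = pre * f0 * dy * (1.0 - q) * (1.0 / tp - 1.0 / acq.t1_blood)
        before = t < att
        inflow = t < tau + att
        u = np.where(before, 0.0, np.where(inflow, u_in, u_de)) * CBF_TO_RATE
        v = np.where(before, 0.0, np.where(inflow, v_in, v_de))
        # identifiability indicators (1 ns guard bands keep them consistent
        # with the floating-point branch assignment above)
        nonzero = t > att + 1e-9
        strict_inflow = nonzero & (t < tau + att - 1e-9)
        return u, v, nonzero, strict_inflow

    def gram(self, plds: np.ndarray):
        """Per-(slice, ATT) Gram entries and identifiability counts.

        Returns (sum u^2, sum uv, sum v^2, n_nonzero, n_inflow) over the
        PLD axis, each of shape (n_slices, n_att).
        """
        u, v, nz, si = self._uv(plds)
        return (
            (u * u).sum(-1),
            (u * v).sum(-1),
            (v * v).sum(-1),
            nz.sum(-1),
            si.sum(-1),
        )

    def n_averages(self, plds: np.ndarray) -> int:
        return compute_averages(plds, self.acq.label_duration, self.readout, self.budget)

    # -- criterion ---------------------------------------------------------

    def _phi(self, a, b, c, n_avg):
        """Criterion value per (slice, ATT) from unit-noise Gram entries."""
        det = a * c - b * b
        scale = self.sigma2 / n_avg
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.criterion.kind == "d_optimal":
                phi = scale * scale / det
            elif self.criterion.kind == "l_optimal":
                phi = scale * c / det
            else:
                w = self.criterion.weight_matrix
                phi = scale * (w[0, 0] * c - 2.0 * w[0, 1] * b + w[1, 1] * a) / det
        return det, phi

    @staticmethod
    def contrib_mask(n_nonzero: np.ndarray, n_inflow: np.ndarray) -> np.ndarray:
        """(n_slices, n_att) mask of prior samples each slice can inform.

        Generalized truncation: a slice identifies both parameters at an
        ATT only if at least one of its samples falls strictly inside the
        inflow phase (arrival information) and at least two fall after
        arrival (two independent directions).  When the ATT is at or below
        the slice's shortest effective PLD every sample is post-bolus and
        the mask is False - the classic per-slice prior truncation.
        """
        return (n_inflow >= 1) & (n_nonzero >= 2)

    def cost_of_gram(self, a, b, c, n_nonzero, n_inflow, n_avg: int, *, strict: bool = False):
        """Combine per-(slice, ATT) criteria into the scalar design cost.

        Returns inf for infeasible combinations; with ``strict`` raises the
        diagnostic errors instead (used by :func:`expected_cost`).
        """
        if n_avg < 1:
            if strict:
                raise InfeasibleDesignError("scan-time budget admits zero averages")
            return np.inf
        mask = self.contrib_mask(n_nonzero, n_inflow)
        det, phi = self._phi(a, b, c, n_avg)
        tr = a + c
        disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
        lam_min = 0.5 * (tr - disc)
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = np.where(lam_min > 0, 0.5 * (tr + disc) / np.where(lam_min > 0, lam_min, 1.0), np.inf)
        bad = mask & ((det <= 0) | (cond > CONDITION_LIMIT))
        if bad.any():
            if strict:
                n_bad = int(bad.sum())
                raise InfeasibleDesignError(
                    f"{n_bad} contributing (slice, ATT) pairs have singular "
                    "information after truncation"
                )
            return np.inf
        weights = np.broadcast_to(self.prior.weights[None, :], mask.shape)
        phi = np.where(mask, phi, 0.0)  # non-contributing entries may be inf/nan
        if self.slice_weighting == "mass":
            num = (phi * weights).sum()
            den = np.where(mask, weights, 0.0).sum()
        else:  # mean over contributing slices, then mass-weighted over ATT
            n_contrib = mask.sum(axis=0)
            ok = n_contrib > 0
            per_att = phi.sum(axis=0)[ok] / n_contrib[ok]
            num = (per_att * self.prior.weights[ok]).sum()
            den = self.prior.weights[ok].sum()
        if den == 0:
            if strict:
                raise InfeasibleDesignError("no (slice, ATT) pair survives truncation")
            return np.inf
        return float(num / den)

    def cost(self, plds: np.ndarray, *, strict: bool = False) -> float:
        a, b, c, nz, si = self.gram(plds)
        return self.cost_of_gram(a, b, c, nz, si, self.n_averages(plds), strict=strict)


def expected_cost(
    protocol: Protocol,
    prior: ATTPrior,
    spec: CriterionSpec,
    acq: AcquisitionConstants,
    noise_variance: float = 1.0,
    slice_weighting: str = "mass",
    cbf_point: float = 50.0,
) -> float:
    """Prior-averaged criterion of a fixed protocol.

    Uses the protocol's stored ``n_averages``.  Raises
    :class:`InfeasibleDesignError` if the protocol admits no averages or a
    contributing (slice, ATT) pair has singular information.
    """
    engine = _CostEngine(
        prior,
        acq,
        spec,
        protocol.n_slices,
        protocol.slice_duration,
        protocol.readout_duration,
        protocol.scan_time_budget,
        noise_variance,
        slice_weighting,
        cbf_point,
    )
    a, b, c, nz, si = engine.gram(protocol.plds)
    return engine.cost_of_gram(a, b, c, nz, si, protocol.n_averages, strict=True)


def _snap_to_grid(values: np.ndarray, config: OptimizerConfig) -> np.ndarray:
    k = np.round((values - config.pld_min) / config.pld_step)
    snapped = config.pld_min + k * config.pld_step
    return np.clip(snapped, config.pld_min, config.pld_max)


def optimize_plds(
    config: OptimizerConfig,
    prior: ATTPrior,
    acq: AcquisitionConstants,
    scan_time_budget: float = 300.0,
    readout_duration: float = 1.275,
    slice_duration: float = 0.053125,
    n_slices: int = 5,
    init_plds=None,
    noise_variance: float = 1.0,
    slice_weighting: str = "mass",
    cbf_point: float = 50.0,
    name: str = "optimized",
) -> OptimizeResult:
    """Run the coordinate-exchange search for an optimal PLD schedule.

    Starts from PLDs equally spaced over ``config.init_range`` (or an
    explicit ``init_plds``), snapped to the PLD grid.  Each accepted
    exchange strictly lowers the cost, so the per-update cost history is
    non-increasing; convergence is a full pass with no change.
    """
    engine = _CostEngine(
        prior,
        acq,
        config.criterion,
        n_slices,
        slice_duration,
        readout_duration,
        scan_time_budget,
        noise_variance,
        slice_weighting,
        cbf_point,
    )
    if init_plds is None:
        init_plds = np.linspace(config.init_range[0], config.init_range[1], config.n_plds)
    plds = np.sort(_snap_to_grid(np.asarray(init_plds, dtype=float), config))
    if plds.size != config.n_plds:
        raise InvalidParameterError("init_plds length must equal config.n_plds")

    current = engine.cost(plds)
    # an infinite initial cost is recoverable: the first exchange pass may
    # move a PLD into a feasible position
    history = [current]
    tau, ro = acq.label_duration, readout_duration
    n_passes = 0
    for n_passes in range(1, config.max_passes + 1):
        changed = False
        for i in range(config.n_plds):
            lo = plds[i - 1] if i > 0 else config.pld_min
            hi = plds[i + 1] if i < config.n_plds - 1 else config.pld_max
            k0 = int(np.ceil(round((lo - config.pld_min) / config.pld_step, 9)))
            k1 = int(np.floor(round((hi - config.pld_min) / config.pld_step, 9)))
            candidates = config.pld_min + config.pld_step * np.arange(k0, k1 + 1)
            rest = np.delete(plds, i)
            a_r, b_r, c_r, nz_r, si_r = engine.gram(rest)
            u, v, nz_c, si_c = engine._uv(candidates)
            pair_rest = 2.0 * float(np.sum(tau + rest + ro))
            costs = np.empty(candidates.size)
            for j, cand in enumerate(candidates):
                n_avg = int(scan_time_budget // (pair_rest + 2.0 * (tau + cand + ro)))
                costs[j] = engine.cost_of_gram(
                    a_r + u[:, :, j] ** 2,
                    b_r + u[:, :, j] * v[:, :, j],
                    c_r + v[:, :, j] ** 2,
                    nz_r + nz_c[:, :, j],
                    si_r + si_c[:, :, j],
                    n_avg,
                )
            if not np.any(np.isfinite(costs)):
                raise OptimizationFailedError(
                    f"no feasible candidate for PLD index {i}; contributing "
                    f"(slice, ATT) pairs with the remaining PLDs: "
                    f"{int(engine.contrib_mask(nz_r, si_r).sum())}"
                )
            j_best = int(np.argmin(costs))
            if costs[j_best] < current and not np.isclose(candidates[j_best], plds[i]):
                plds[i] = candidates[j_best]
                current = float(costs[j_best])
                history.append(current)
                changed = True
        logger.info("pass %d: cost %.6e", n_passes, current)
        if not np.isfinite(current):
            raise OptimizationFailedError(
                "no feasible design found in a full exchange pass (zero "
                "averages or singular information for every contributing "
                "prior sample)"
            )
        if not changed:
            break
    plds = np.sort(plds)
    n_avg = engine.n_averages(plds)
    protocol = Protocol(
        plds=plds,
        label_duration=acq.label_duration,
        readout_duration=readout_duration,
        slice_duration=slice_duration,
        n_slices=n_slices,
        n_averages=n_avg,
        scan_time_budget=scan_time_budget,
        name=name,
    )
    return OptimizeResult(protocol=protocol, cost=current, cost_history=history, n_passes=n_passes)


def sweep_num_plds(
    n_values,
    prior: ATTPrior,
    acq: AcquisitionConstants,
    criterion: CriterionSpec | None = None,
    scan_time_budget: float = 300.0,
    readout_duration: float = 1.275,
    slice_duration: float = 0.053125,
    n_slices: int = 5,
    **config_kwargs,
) -> tuple[dict[int, OptimizeResult], OptimizeResult]:
    """Optimize for each requested number of PLDs; also return the best.

    Returns ``(per_n, best)`` where ``per_n`` maps each n to its
    :class:`OptimizeResult` and ``best`` minimizes the expected cost.
    """
    if criterion is None:
        criterion = CriterionSpec.d_optimal()
    results: dict[int, OptimizeResult] = {}
    for n in n_values:
        config = OptimizerConfig(n_plds=int(n), criterion=criterion, **config_kwargs)
        results[int(n)] = optimize_plds(
            config,
            prior,
            acq,
            scan_time_budget,
            readout_duration,
            slice_duration,
            n_slices,
            name=f"optimized_n{int(n)}",
        )
    best = min(results.values(), key=lambda r: r.cost)
    return results, best
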