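# asldesign

Optimal experimental design for multi-delay pseudo-continuous arterial spin
labeling (PCASL) perfusion MRI.

ASL measures cerebral blood flow (CBF) with magnetically labeled blood as an
endogenous tracer.  In a multi-delay experiment the free design choice is
the set of post-labeling delays (PLDs) at which the label-control
difference signal is sampled.  Poorly placed delays waste scan time:
samples before the bolus arrives carry no signal, samples long after it
carry little information about the arterial transit time (ATT).  This
package chooses the PLDs that minimize the predicted estimation error of
CBF (and optionally ATT) within a fixed scan-time budget, and validates
designs by Monte Carlo simulation with maximum-likelihood fitting.  It is
aimed at ASL sequence developers and perfusion researchers planning
multi-PLD protocols.

## Method

The difference signal follows the general kinetic model: for time *t* from
the start of a labeling block of duration τ,

    ΔM(t) = 0                                                        t < Δt
          = 2 M0B f T1′ α e^(−Δt/T1b) (1 − e^(−(t−Δt)/T1′))          Δt ≤ t < τ+Δt
          = 2 M0B f T1′ α e^(−Δt/T1b) e^(−(t−τ−Δt)/T1′) (1 − e^(−τ/T1′))   t ≥ τ+Δt

with perfusion rate *f* (user-facing CBF in mL/100g/min, f = CBF/6000 s⁻¹),
transit time Δt, and apparent relaxation 1/T1′ = 1/T1t + f/λ.  For θ =
[CBF, ATT], A averages, and difference-image noise variance σ², the Fisher
information of sample times t_i is

    F_jk = (A/σ²) Σ_i (∂ΔM(t_i)/∂θ_j)(∂ΔM(t_i)/∂θ_k),

and F⁻¹ lower-bounds the estimator covariance (Cramér-Rao).  Designs
minimize either det F⁻¹ (D-optimality: joint CBF-ATT precision) or
[F⁻¹]₁₁ (L-optimality: CBF variance alone), averaged over a discretized
ATT prior - by default uniform on 0.5-1.8 s with 0.3 s linear tapers.
Freezing T1′ at a nominal outflow makes the criteria independent of the
CBF value, so no CBF prior is needed.  A 2D multi-slice readout shifts each
slice's effective PLD; ATT values that a slice cannot inform (every sample
post-bolus) are excluded per slice.  The search is a coordinate exchange on
a 25 ms PLD grid under the scan-time constraint
A = floor(budget / (2 Σ_i (τ + PLD_i + readout))).

## Worked example

Design a six-delay protocol for a 5-minute scan and compare its predicted
errors against the conventional evenly spaced protocol:

```python
import numpy as np
from asldesign import (AcquisitionConstants, CriterionSpec, OptimizerConfig,
                       builtin_protocol, calibrated_noise, make_att_prior,
                       optimize_plds)
from asldesign.reporting import mean_predicted_errors

acq = AcquisitionConstants()                      # tau=1.4 s, T1b=1.65 s, ...
prior = make_att_prior(0.5, 1.8, taper=0.3, step=0.001)
result = optimize_plds(OptimizerConfig(n_plds=6, criterion=CriterionSpec.d_optimal()),
                       prior, acq)
prot = result.protocol
print("optimal PLDs (s):", np.round(prot.plds, 3))
print("averages:", prot.n_averages, "| scan time: %.1f s" % prot.total_scan_time)

noise = calibrated_noise(acq)
cbf_sd, att_sd = mean_predicted_errors(prot, acq, noise.diff_variance)
ref_cbf, ref_att = mean_predicted_errors(builtin_protocol("reference_multi_pld"),
                                         acq, noise.diff_variance)
print("mean predicted CBF error: %.2f mL/100g/min (reference protocol: %.2f)"
      % (cbf_sd, ref_cbf))
```

Output:

```
optimal PLDs (s): [0.375 0.5   0.625 0.7   1.5   1.675]
averages: 7 | scan time: 299.9 s
mean predicted CBF error: 6.21 mL/100g/min (reference protocol: 6.29)
```

The optimizer concentrates delays where the signal is most informative:
short PLDs sampling bolus arrival (ATT information) and long PLDs near the
signal peak (CBF information).  The predicted errors are mean CRLB standard
deviations over the 0.5-1.8 s ATT range at a noise level calibrated so the
reference protocol's CBF error is 10% of a typical grey-matter CBF.
Allowing more delays improves this further - the shipped 40-delay
D-optimal protocol (`builtin_protocol("cbf_att_optimized")`) reaches
5.59 mL/100g/min in the same scan time.

The same workflow is available from the shell:

```
asldesign optimize --criterion cbf-att --n-plds 6 --out protocol.json
asldesign crlb --protocol protocol.json --out errors.csv
asldesign simulate --protocol protocol.json --reps 500 --seed 1 --out mc.csv
asldesign compare ref.json opt.json --seed 1 --out-dir report/
```

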