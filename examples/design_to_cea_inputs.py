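"""From a survival-efficacy design to cost-effectiveness power inputs.

A trial planned around exponential survival — control-arm survival 36.8% at
one year, target hazard ratio 0.5, 500 patients analysed at 400 events —
implies the incremental effectiveness, a pooled effectiveness SD, and the
event ratio pi that the sample-size formula needs.
"""

import math

import inbpower as ip

design = ip.TrialDesign(
    control_survival=math.exp(-1),  # 36.8% at the landmark
    landmark_time=1.0,
    hazard_ratio=0.5,
    n_expected=500,
    d_expected=400,
)
inputs = ip.effectiveness_inputs_from_design(design)
print(f"delta_E   = {inputs.delta_e:.3f} life-years (mean survival 2.0 vs 1.0)")
print(f"sigma_E   = {inputs.sd_effect:.4f} life-years (rms of the arm SDs 1 and 2)")
print(f"pi        = {inputs.pi:.2f} (= 500/400)")

params = ip.SimplifiedCEAParams(
    n_total=500,
    sd_effect=inputs.sd_effect,
    sd_cost=16_130.0,
    rho=0.3,
    delta_e=inputs.delta_e,
    delta_c=60_000.0,
    pi=inputs.pi,
)
res = ip.sample_size(params, ip.TestSpec(wtp=100_000.0))
print(
    f"\nWith sd_C = $16,130, rho = 0.3, delta_C = $60,000 at WTP $100,000:"
    f" required n = {res.n_total} (exact {res.n_exact:.1f})"
)
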