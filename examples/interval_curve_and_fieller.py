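"""INB confidence band across willingness-to-pay, and the Fieller limits.

The INB estimate b(lambda) = lambda*delta_E - delta_C is a straight line in
the willingness-to-pay lambda; it crosses zero at the ICER, and the 95%
confidence bounds cross zero at the Fieller limits of the ICER.
"""

import numpy as np

import inbpower as ip

params = ip.load_cctg_fixtures()["CO.17 (all patients)"].to_params(
    delta_e=0.1, delta_c=3_000.0  # illustrative increments: 0.1 life-years, $3,000
)

curve = ip.inb_interval_curve(params, wtp_grid=np.arange(0.0, 250_001.0, 1_000.0))
print("ICER:", f"${ip.icer(params.delta_e, params.delta_c):,.0f} per life-year")
lo, hi = curve.fieller
print(f"Fieller 95% limits: ${lo:,.0f} to ${hi:,.0f} per life-year")

for lam in (50_000.0, 100_000.0, 200_000.0):
    i = int(np.searchsorted(curve.wtp_grid, lam))
    print(
        f"  wtp ${lam:9,.0f}: b = {curve.estimate[i]:9,.0f} "
        f"[{curve.lower[i]:10,.0f}, {curve.upper[i]:10,.0f}]"
    )

print(
    "\nThe band widens as the willingness-to-pay grows (the effectiveness"
    " variance term scales with lambda^2); between the Fieller limits the"
    " treatment's cost-effectiveness is not distinguishable from the"
    " threshold."
)
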