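"""Monte-Carlo validation of the analytic power formula.

Simulates correlated patient-level (effectiveness, cost) data from a
Gaussian copula, runs the INB z-test on every replicate, and compares the
rejection fraction with the closed-form normal-approximation power.
"""

import inbpower as ip

rho, wtp = 0.44, 100_000.0
arm0 = ip.ArmStats(n=250, mean_effect=1.0, sd_effect=0.309,
                   mean_cost=20_000.0, sd_cost=16_130.0, rho=rho)
arm1 = ip.ArmStats(n=250, mean_effect=1.1, sd_effect=0.309,
                   mean_cost=23_000.0, sd_cost=16_130.0, rho=rho)
spec = ip.SimSpec(arm0=arm0, arm1=arm1, seed=20_230_803)
test = ip.TestSpec(wtp=wtp)

params = ip.SimplifiedCEAParams(
    n_total=500, sd_effect=0.309, sd_cost=16_130.0, rho=rho,
    delta_e=0.1, delta_c=3_000.0,
)
analytic = ip.analytic_power(params, test).power
emp = ip.empirical_power(spec, test, replicates=2_000)

print(f"analytic power : {analytic:.3f}")
print(f"empirical power: {emp.power:.3f} +/- {emp.se:.3f} ({emp.replicates} replicates)")
print(
    "\nAgreement within a few binomial standard errors confirms the normal"
    " approximation behind the power and sample-size formulas at this"
    " sample size."
)
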