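"""Mismatch-distribution fit and expansion dating for one population.

Fits the sudden-expansion model to the pooled mismatch distribution of a
simulated expanding population, bootstraps the goodness of fit, and dates
the expansion with the control-region mutation rate.
"""

import numpy as np

from hv2pop import (
    DEFAULT_MU_SITE_PER_YEAR,
    expansion_time,
    fit_population,
    simulate_sample,
    SimulationConfig,
    SuddenExpansion,
)

sim = simulate_sample(
    SimulationConfig(
        n_pops=1, samples_per_pop=60,
        demography=SuddenExpansion(theta0=0.5, theta1=50.0, tau=5.0),
        seed=8,
    )
)
fit, obs = fit_population(sim.alignment, n_boot=300, seed=8)

print(f"observed mismatch frequencies: {np.round(obs.frequencies, 3)}")
print(f"fitted tau={fit.tau:.2f}  theta0={fit.theta0:.2f}  theta1={fit.theta1:.1f}")
print(f"SSD={fit.ssd:.4f} (p={fit.p_ssd:.2f})  rg={fit.rg:.4f} (p={fit.p_rg:.2f})")
print(f"tau 95% CI: {fit.tau_ci[0]:.2f}-{fit.tau_ci[1]:.2f}")
t = fit.time_years(DEFAULT_MU_SITE_PER_YEAR, sim.alignment.length)
print(f"expansion time: {t:.0f} years before present")
print(
    "\ntau is the mismatch peak in mutational units; a non-significant "
    "p_SSD means the sudden-expansion model cannot be rejected.  The "
    "dating uses t = tau / (2 mu L)."
)
print(
    f"(worked check: tau=5.66 at mu=0.32e-6, L=294 gives "
    f"{expansion_time(5.66, 0.32e-6, 294):.0f} years)"
)
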