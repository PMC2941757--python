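"""Recover hazard coefficients by calibrating the simulator to targets.

Targets are self-generated here (simulated at the published recovery
equation), so the true coefficients are known and the search - a
bounded Nelder-Mead over (alpha, log-time) with common random numbers -
should land on them with a near-zero objective.
"""

import time

from mdesim import (
    SimulationConfig,
    calibrate,
    published_recovery,
    published_recurrence,
    targets_from_simulation,
)

recovery = published_recovery()
recurrence = published_recurrence()
config = SimulationConfig(
    recovery=recovery, recurrence=recurrence, n_entities_per_profile=100, seed=11
)

targets = targets_from_simulation(recovery, recurrence, config)
print("Targets generated from the published equations (truth known).")

t0 = time.time()
result = calibrate(
    targets,
    config,
    search_spec={"recovery.alpha": (-2.3, -0.3), "recovery.log_time": (-1.2, 0.0)},
    budget=150,
    restarts=2,
    seed=7,
)
print(f"Search finished in {time.time() - t0:.0f} s, {result.n_evaluations} evaluations.")
print(f"  recovered alpha    = {result.recovery.alpha:+.3f}   (truth {recovery.alpha:+.3f})")
print(f"  recovered log_time = {result.recovery.log_time:+.3f}   (truth {recovery.log_time:+.3f})")
print(f"  objective at optimum = {result.objective:.2e}")
print(
    "\nCommon random numbers make the objective deterministic given the"
    "\nseed, so the self-generated targets are exactly attainable and the"
    "\nobjective can reach (numerically) zero at the generating values."
)
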