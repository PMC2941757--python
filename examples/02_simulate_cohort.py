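"""Simulate a cohort of entities and summarise their episode histories.

Each of the 40 attribute profiles gets the same number of entities; a
single new episode onset falls uniformly in the two-year run-in, then
weekly recovery/recurrence draws run to the 208-week horizon.
"""

import numpy as np

from mdesim import SimulationConfig, published_recovery, published_recurrence, simulate_cohort

config = SimulationConfig(
    recovery=published_recovery(),
    recurrence=published_recurrence(),
    n_entities_per_profile=200,
    seed=1,
)
cohort = simulate_cohort(config)
print(f"Simulated {len(cohort)} entities ({config.n_entities_per_profile} per profile).")

by_age: dict[str, list] = {}
for record in cohort:
    by_age.setdefault(record.profile.age_group, []).append(record)

print("\nFirst-episode duration and episode count by age group:")
for age, records in by_age.items():
    first = [r.episodes[0] for r in records]
    done = [e.end_week - e.start_week + 1 for e in first if not e.censored]
    n_rec = np.mean([len(r.episodes) > 1 for r in records])
    print(
        f"  age {age:>5}: mean completed first-episode duration "
        f"{np.mean(done):5.1f} weeks, recurrence by horizon in {100*n_rec:4.1f}% of entities"
    )

print(
    "\nDurations broadly lengthen with age (increasingly negative age"
    "\ncoefficients in the recovery equation; adjacent groups differ"
    "\nlittle and can swap under sampling noise, and censoring at the"
    "\nhorizon trims the longest episodes).  Recurrence shares reflect"
    "\neach profile's constant weekly recurrence odds."
)
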