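"""Variability between subjects and between nucleation spots.

Draws a small seeded population: each subject gets a bubble-production
sensitivity from the fitted subject-variability curve and per-vessel
counts of active hydrophobic spots (AHS) from the density distribution;
each spot gets a productivity from the fitted spot curve.  Also prints
the activation schedule — the fitted interval between successive
detachments, which shortens toward 1.657 min as a spot activates.
"""

import numpy as np

from decobubble import activation_interval, build_sites, make_fixture_population

subjects = make_fixture_population(n_subjects=4, seed=11, age_years=40.0)
print("subject  sensitivity_b(bubbles/h)  total AHS  age factor")
for i, s in enumerate(subjects):
    sites = build_sites(s, index=i)
    print(f"  {i}        {s.sensitivity_b:7.1f}              "
          f"{len(sites):4d}      {s.age_factor:.2f}")

print("\nactivation: interval before detachment number s (minutes)")
for s in (1, 2, 5, 10, 20, 50):
    print(f"  s={s:3d}  {float(activation_interval(s)):6.2f}")

print("\nLow-sensitivity subjects (small b) dominate the population, as in"
      "\nthe fitted frequency curve; the activation interval decays from"
      "\n~15 min toward its 1.657 min floor, which is why a second exposure"
      "\non the same day produces bubbles sooner.")
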