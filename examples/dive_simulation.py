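"""A full seeded run: exposure -> gas kinetics -> bubbles -> loads.

Uses the reference saturation exposure (1000 kPa held for 20 h, then
decompression to the surface — a saline-bath chamber, so no alveolar
water-vapor step): the eight tissue compartments saturate, and after
decompression every nucleation spot of a two-subject population can
initiate, grow and shed bubbles.  Detachments are aggregated into
venous and arterial bubble loads with a 10% PFO shunt.

For contrast, the same pipeline on a moderate 500 kPa / 2 h dive is run
last: the ~30 kPa residual supersaturation makes diameter growth ~30x
slower than at the reference exposure, so few or no bubbles detach
within the observation window.
"""

import numpy as np

from decobubble import (
    arterialize,
    build_sites,
    make_fixture_population,
    make_fixture_profile,
    risk_tier,
    run_profile,
    simulate_sites,
    summarize_loads,
)


def run(profile, water_vapor_kpa, label, seed=5):
    venous = run_profile(profile, water_vapor_kpa=water_vapor_kpa)
    duration_min = profile.duration_s / 60.0
    print(label)
    for i, subject in enumerate(make_fixture_population(n_subjects=2, seed=seed)):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, 2)))
        sites = build_sites(subject, index=i)
        records = simulate_sites(sites, venous, profile, duration_min, rng)
        summary = arterialize(summarize_loads(records, duration_min),
                              pfo_fraction=0.10)
        tier = risk_tier(summary, subject.sensitivity_b)
        print(f"  subject {i}: {len(sites)} AHS, {len(records)} detachments, "
              f"venous {summary.venous_count_per_h:.1f}/h "
              f"({summary.venous_volume_mm3_per_h:.2f} mm^3/h), "
              f"PFO arterial {summary.arterial_per_h['PFO']:.2f}/h, tier {tier}")


run(make_fixture_profile("methods_exposure", tail_min=240.0), 0.0,
    "saturation exposure, 1000 kPa / 20 h:")
run(make_fixture_profile("square", plateau_kpa=500.0, bottom_min=120.0,
                         tail_min=120.0), 6.3,
    "\nmoderate dive, 500 kPa / 2 h:")

print("\nCounts are bubbles per hour over the whole window; the PFO pathway"
      "\nshunts 10% of the venous count to the arterial side. Tiers are the"
      "\nordinal summary (low/moderate/high) of combined load + sensitivity.")
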