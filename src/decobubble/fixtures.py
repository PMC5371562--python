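"""Synthetic dive profiles and subject populations.

These generators define the study conditions every other module is
exercised under: a square chamber exposure (saturation at 1000 kPa for
~20 h, then decompression to the surface), "yo-yo" profiles with
repeated ascents and descents, and seeded subject populations drawn
from the fitted variability curves.  Subject random streams are
spawned independently from the root seed, so adding or removing one
subject never perturbs the draws of another.
"""

from __future__ import annotations

import numpy as np

from .ahs_population import (
    Subject,
    VesselPatch,
    age_modifier,
    sample_ahs_count,
    sample_productivity,
    sample_sensitivity,
)
from .bubble_dynamics import AHSite
from .gas_kinetics import SURFACE_PRESSURE_KPA, DiveProfile

#: Chamber pressure and duration of the reference saturation exposure.
METHODS_PRESSURE_KPA = 1000.0
METHODS_DURATION_MIN = 20.0 * 60.0

#: Vessel patches sampled per subject (name, area cm^2): the vessels in
#: which nucleation spots were surveyed.
DEFAULT_VESSELS: tuple[tuple[str, float], ...] = (
    ("aorta", 4.0),
    ("vena_cava", 4.0),
    ("pulmonary_artery", 3.0),
    ("pulmonary_vein", 3.0),
)


def make_fixture_profile(kind: str, rng: np.random.Generator | None = None, **params):
    """Build a named synthetic dive profile.

    Kinds
    -----
    ``square``
        Surface -> plateau -> surface.  Params: ``plateau_kpa``,
        ``bottom_min``, ``ramp_min`` (default 5), ``tail_min`` (default 60),
        ``inert_fraction`` (default 0.79), ``surface_kpa``.
    ``methods_exposure``
        The reference saturation exposure: 1000 kPa held for 20 h, then
        decompression to the surface, dissolved-gas fraction 1.0 (the whole
        chamber gas equilibrates with the liquid).  Params: ``tail_min``.
    ``yoyo``
        ``n_cycles`` (default 3) repeated excursions to ``plateau_kpa``
        with ``bottom_min`` at pressure and ``surface_min`` between.
    """
    surface = params.pop("surface_kpa", SURFACE_PRESSURE_KPA)
    if kind == "square":
        plateau = params.pop("plateau_kpa", 400.0)
        bottom = params.pop("bottom_min", 60.0)
        ramp = params.pop("ramp_min", 5.0)
        tail = params.pop("tail_min", 60.0)
        fr = params.pop("inert_fraction", 0.79)
        _reject_unknown(kind, params)
        t = np.array([0.0, ramp, ramp + bottom, 2 * ramp + bottom,
                      2 * ramp + bottom + tail]) * 60.0
        p = np.array([surface, plateau, plateau, surface, surface])
        return DiveProfile(t, p, np.full_like(p, fr))
    if kind == "methods_exposure":
        tail = params.pop("tail_min", 120.0)
        _reject_unknown(kind, params)
        ramp = 5.0
        t = np.array(
            [0.0, ramp, ramp + METHODS_DURATION_MIN,
             2 * ramp + METHODS_DURATION_MIN,
             2 * ramp + METHODS_DURATION_MIN + tail]
        ) * 60.0
        p = np.array(
            [surface, METHODS_PRESSURE_KPA, METHODS_PRESSURE_KPA, surface, surface]
        )
        return DiveProfile(t, p, np.ones_like(p))
    if kind == "yoyo":
        n_cycles = int(params.pop("n_cycles", 3))
        plateau = params.pop("plateau_kpa", 400.0)
        bottom = params.pop("bottom_min", 10.0)
        surface_min = params.pop("surface_min", 5.0)
        ramp = params.pop("ramp_min", 2.0)
        fr = params.pop("inert_fraction", 0.79)
        _reject_unknown(kind, params)
        times = [0.0]
        pressures = [surface]
        for _ in range(n_cycles):
            t0 = times[-1]
            times += [t0 + ramp, t0 + ramp + bottom, t0 + 2 * ramp + bottom,
                      t0 + 2 * ramp + bottom + surface_min]
            pressures += [plateau, plateau, surface, surface]
        t = np.asarray(times) * 60.0
        p = np.asarray(pressures, dtype=float)
        return DiveProfile(t, p, np.full_like(p, fr))
    raise ValueError(f"unknown profile kind {kind!r}")


def _reject_unknown(kind: str, params: dict) -> None:
    if params:
        raise ValueError(f"unknown parameter(s) for {kind!r}: {sorted(params)}")


def subject_rng(seed: int, index: int) -> np.random.Generator:
    """Independent random stream for subject ``index`` under root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def make_fixture_population(
    n_subjects: int,
    seed: int,
    age_years: float = 30.0,
    vessels: tuple[tuple[str, float], ...] = DEFAULT_VESSELS,
    b_max: float = 250.0,
) -> list[Subject]:
    """Draw a reproducible subject population.

    Each subject gets an independent substream keyed by (seed, index):
    a sensitivity draw from the subject-variability curve and, per
    vessel patch, an AHS count from the density distribution with the
    patch area scaled by the age modifier.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    factor = age_modifier(age_years)
    subjects = []
    for k in range(n_subjects):
        rng = subject_rng(seed, k)
        b = sample_sensitivity(rng, b_max=b_max)
        patches = [
            VesselPatch(name, area * factor, sample_ahs_count(rng, area * factor))
            for name, area in vessels
        ]
        subjects.append(
            Subject(
                seed=seed,
                sensitivity_b=b,
                age_years=age_years,
                age_factor=factor,
                vessels=patches,
            )
        )
    return subjects


def build_sites(subject: Subject, index: int = 0) -> list[AHSite]:
    """Materialise a subject's AHS as simulation sites.

    Productivities are drawn from the spot-productivity curve using a
    dedicated substream (seed, index, 1), so site construction never
    consumes draws from the population stream.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(subject.seed, spawn_key=(index, 1))
    )
    sites = []
    for patch in subject.vessels:
        for j in range(patch.ahs_count):
            sites.append(
                AHSite(
                    id=f"s{index}_{patch.name}_{j}",
                    vessel=patch.name,
                    productivity_per_h=sample_productivity(rng),
                    dppc_pool=subject.dppc_pool,
                )
            )
    return sites
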