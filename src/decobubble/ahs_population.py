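"""Population variability of active hydrophobic spots (AHS).

Bubble production after decompression varies strongly between subjects
("bubblers" vs "non-bubblers") and between the individual nucleation
spots on the vessel wall.  Three fitted frequency curves quantify this:

* subject sensitivity — frequency of subjects producing ``b`` bubbles/h:
  ``0.0582 + 0.7419 * exp(-0.0278 * b)``
* AHS productivity — frequency of spots detaching ``n`` bubbles in 1 h:
  ``1.256 * exp(-1.139 * n) + 0.078 * exp(-0.1632 * n)``
* AHS density on the vessel wall — a six-bin empirical distribution.

The curves are frequency fits, not normalized densities (the
productivity curve exceeds 1 at n=0), so the samplers treat them as
unnormalized weights on a truncated support.  Age raises the number and
area of spots (surfactant deposits accumulate through life); each
detached bubble strips part of the spot's DPPC surfactant pool, which is
how acclimation to frequent diving lowers bubble production.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SensitivityCurve:
    """Fitted frequency of subjects vs bubble production rate (bubbles/h)."""

    floor: float = 0.0582
    amplitude: float = 0.7419
    rate_per_bubbles_h: float = 0.0278

    def __call__(self, b: float | np.ndarray) -> float | np.ndarray:
        b = np.asarray(b, dtype=float)
        if np.any(b < 0):
            raise ValueError("bubble rate b must be non-negative")
        out = self.floor + self.amplitude * np.exp(-self.rate_per_bubbles_h * b)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ProductivityCurve:
    """Fitted frequency of AHS vs bubbles produced within one hour."""

    c1: float = 1.256
    r1: float = 1.139
    c2: float = 0.078
    r2: float = 0.1632

    def __call__(self, n: float | np.ndarray) -> float | np.ndarray:
        n = np.asarray(n, dtype=float)
        if np.any(n < 0):
            raise ValueError("bubble count n must be non-negative")
        out = self.c1 * np.exp(-self.r1 * n) + self.c2 * np.exp(-self.r2 * n)
        return float(out) if out.ndim == 0 else out


DEFAULT_SENSITIVITY = SensitivityCurve()
DEFAULT_PRODUCTIVITY = ProductivityCurve()


def sensitivity_frequency(
    b: float | np.ndarray, curve: SensitivityCurve = DEFAULT_SENSITIVITY
) -> float | np.ndarray:
    """Frequency weight of a subject producing ``b`` bubbles/h."""
    return curve(b)


def productivity_frequency(
    n: float | np.ndarray, curve: ProductivityCurve = DEFAULT_PRODUCTIVITY
) -> float | np.ndarray:
    """Frequency weight of an AHS producing ``n`` bubbles in one hour."""
    return curve(n)


def sample_sensitivity(
    rng: np.random.Generator,
    b_max: float = 250.0,
    curve: SensitivityCurve = DEFAULT_SENSITIVITY,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw subject bubble rates from the sensitivity curve on [0, b_max].

    Exact inverse-CDF sampling of the density proportional to
    ``floor + amplitude * exp(-k b)`` truncated to [0, b_max]: the
    constant term is a uniform component, the exponential term a
    truncated exponential component, mixed by their integrated masses.
    """
    if b_max <= 0:
        raise ValueError("b_max must be positive")
    k = curve.rate_per_bubbles_h
    mass_uniform = curve.floor * b_max
    tail = 1.0 - np.exp(-k * b_max)
    mass_exp = curve.amplitude / k * tail
    p_uniform = mass_uniform / (mass_uniform + mass_exp)

    n = 1 if size is None else size
    pick_uniform = rng.random(n) < p_uniform
    u = rng.random(n)
    draws = np.where(
        pick_uniform,
        u * b_max,
        -np.log1p(-u * tail) / k,
    )
    return float(draws[0]) if size is None else draws


def sample_productivity(
    rng: np.random.Generator,
    n_max: int = 50,
    curve: ProductivityCurve = DEFAULT_PRODUCTIVITY,
    size: int | None = None,
) -> int | np.ndarray:
    """Draw AHS productivities (bubbles in 1 h) over the integers 1..n_max."""
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    support = np.arange(1, n_max + 1)
    w = np.asarray(curve(support), dtype=float)
    p = w / w.sum()
    draws = rng.choice(support, p=p, size=1 if size is None else size)
    return int(draws[0]) if size is None else draws


@dataclass(frozen=True)
class DensityBins:
    """Six-bin distribution of AHS density (spots per cm^2) on a vessel.

    The default weights are a synthetic geometric-decay stand-in for the
    measured six-bin histogram (low densities most common); override with
    measured weights where available.
    """

    centers_per_cm2: tuple[float, ...] = (0.5, 1.5, 2.5, 3.5, 4.5, 5.5)
    weights: tuple[float, ...] = (32.0, 16.0, 8.0, 4.0, 2.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.centers_per_cm2) != len(self.weights):
            raise ValueError("centers and weights must have equal length")
        if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
            raise ValueError("weights must be non-negative with positive sum")

    @property
    def probabilities(self) -> np.ndarray:
        w = np.asarray(self.weights, dtype=float)
        return w / w.sum()

    @property
    def mean_density(self) -> float:
        return float(np.dot(self.probabilities, self.centers_per_cm2))


DEFAULT_DENSITY_BINS = DensityBins()


def sample_ahs_count(
    rng: np.random.Generator,
    area_cm2: float,
    bins: DensityBins = DEFAULT_DENSITY_BINS,
    size: int | None = None,
) -> int | np.ndarray:
    """Draw an AHS count for a vessel patch: density draw times area, rounded."""
    if area_cm2 <= 0:
        raise ValueError("area_cm2 must be positive")
    density = rng.choice(
        bins.centers_per_cm2, p=bins.probabilities, size=1 if size is None else size
    )
    counts = np.rint(np.asarray(density) * area_cm2).astype(int)
    return int(counts[0]) if size is None else counts


def age_modifier(
    age_years: float,
    reference_age_years: float = 20.0,
    slope_per_year: float = 0.02,
    floor: float = 0.2,
) -> float:
    """Multiplier on AHS count and area: 1 + slope * (age - reference).

    Linear in age (surfactant deposits accumulate through life), floored
    at a small positive value so young ages never zero out the population.
    """
    if age_years <= 0:
        raise ValueError("age_years must be positive")
    if floor <= 0:
        raise ValueError("floor must be positive")
    return max(floor, 1.0 + slope_per_year * (age_years - reference_age_years))


def acclimation_update(
    dppc_pool: float, detachments: int, stripping_fraction: float
) -> tuple[float, float]:
    """Strip surfactant from a spot after ``detachments`` bubble departures.

    Each detaching bubble carries away a fixed fraction of the spot's
    remaining DPPC pool, so the pool decays geometrically; the spot's
    productivity multiplier equals the remaining pool.

    Returns ``(updated_pool, productivity_multiplier)``.
    """
    if not 0 <= stripping_fraction < 1:
        raise ValueError("stripping_fraction must lie in [0, 1)")
    if detachments < 0:
        raise ValueError("detachments must be non-negative")
    pool = dppc_pool * (1.0 - stripping_fraction) ** detachments
    return pool, pool


@dataclass
class VesselPatch:
    """A sampled vessel-wall patch carrying AHS."""

    name: str
    area_cm2: float
    ahs_count: int


@dataclass
class Subject:
    """One simulated subject: sensitivity, vessel patches, modifiers."""

    seed: int
    sensitivity_b: float
    age_years: float
    age_factor: float
    vessels: list[VesselPatch] = field(default_factory=list)
    dppc_pool: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.dppc_pool <= 1:
            raise ValueError("dppc_pool must lie in [0, 1]")
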