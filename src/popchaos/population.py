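"""Individual-based, age-structured daphnid population simulator.

The model tracks every individual's age, body length, fixed maximum
lifetime and brood timer. A shared food pool couples individuals through
competition: daily ingestion scales with body length squared and saturates
in food density, and realized ration drives growth, brood size and
starvation. A constant toxicant concentration acts as a press disturbance
whose sub-lethal effect is log-logistic inhibition of reproduction.

Randomness enters exactly once: the maximum lifetime assigned to each
individual at birth. Everything else is deterministic given the state, so
two runs with the same seed are bit-identical and runs at different
concentrations sharing a seed share their lifetime draws (a paired design).

The three age classes are defined by body length: neonates < 1.4 mm,
juveniles in [1.4, 2.6) mm, adults >= 2.6 mm.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .config import DoseResponse, TreatmentConfig

#: Age-class length boundaries (mm): neonate < NEONATE_MAX, adult >= ADULT_MIN.
NEONATE_MAX = 1.4
ADULT_MIN = 2.6

AGE_CLASSES = ("neonates", "juveniles", "adults")


def reproduction_inhibition(concentration: float, dr: DoseResponse) -> float:
    """Fractional brood-size inhibition at a given concentration (µg/l).

    Log-logistic: ``c**h / (c**h + EC50**h)``; zero at zero dose, one half
    at the EC50, strictly increasing and < 1 for any finite concentration.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        return 0.0
    ch = concentration ** dr.hill_slope
    return ch / (ch + dr.ec50_repro ** dr.hill_slope)


def classify_by_length(lengths: Sequence[float]) -> tuple[int, int, int]:
    """Counts of (neonates, juveniles, adults) for body lengths in mm."""
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        return (0, 0, 0)
    if np.any(arr <= 0):
        raise ValueError("body lengths must be > 0")
    neo = int(np.sum(arr < NEONATE_MAX))
    adu = int(np.sum(arr >= ADULT_MIN))
    return (neo, arr.size - neo - adu, adu)


@dataclass(frozen=True)
class Individual:
    """A single daphnid record (view onto the vectorised state)."""

    age: int
    body_length: float
    max_lifetime: int
    days_since_brood: int
    days_starved: int = 0


@dataclass
class PopulationState:
    """Vectorised population state on one simulation day.

    Parallel arrays, one entry per live individual. ``days_since_brood`` is
    meaningful for adults only (reset when an individual matures).
    """

    day: int
    age: np.ndarray
    length: np.ndarray
    max_lifetime: np.ndarray
    days_since_brood: np.ndarray
    days_starved: np.ndarray
    food: float

    @classmethod
    def empty(cls, day: int = 0, food: float = 0.0) -> "PopulationState":
        z = np.zeros(0, dtype=int)
        return cls(day, z.copy(), np.zeros(0), z.copy(), z.copy(), z.copy(), food)

    @property
    def size(self) -> int:
        return int(self.age.size)

    @property
    def individuals(self) -> list[Individual]:
        return [
            Individual(int(a), float(l), int(m), int(b), int(s))
            for a, l, m, b, s in zip(
                self.age, self.length, self.max_lifetime,
                self.days_since_brood, self.days_starved,
            )
        ]

    def census(self) -> tuple[int, int, int]:
        return classify_by_length(self.length)


@dataclass
class AbundanceSeries:
    """Daily class-resolved abundance of one simulation run.

    Arrays of length ``n_days + 1`` (day 0 is the pre-update census).
    """

    day: np.ndarray
    neonates: np.ndarray
    juveniles: np.ndarray
    adults: np.ndarray
    concentration: float = 0.0
    run: int = 0
    seed: int = 0

    @property
    def total(self) -> np.ndarray:
        return self.neonates + self.juveniles + self.adults

    def series(self, age_class: str) -> np.ndarray:
        """The scalar series for one of neonates/juveniles/adults/total."""
        if age_class == "total":
            return self.total
        if age_class not in AGE_CLASSES:
            raise KeyError(f"unknown age class {age_class!r}")
        return getattr(self, age_class)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "neonates": self.neonates,
                "juveniles": self.juveniles,
                "adults": self.adults,
                "total": self.total,
            }
        )

    def __len__(self) -> int:
        return int(self.day.size)


def initial_state(cfg: TreatmentConfig, rng: np.random.Generator) -> PopulationState:
    """Founding population: 5 neonates and 3 adults with random fixed lifetimes."""
    lh = cfg.life_history
    lo, hi = lh.lifetime_range
    lifetimes = rng.integers(lo, hi + 1, size=8)
    length = np.concatenate(
        [np.full(5, lh.length_at_birth), np.full(3, lh.adult_initial_length)]
    )
    return PopulationState(
        day=0,
        age=np.zeros(8, dtype=int),
        length=length,
        max_lifetime=np.asarray(lifetimes, dtype=int),
        days_since_brood=np.zeros(8, dtype=int),
        days_starved=np.zeros(8, dtype=int),
        food=lh.initial_food,
    )


def step_day(
    state: PopulationState, cfg: TreatmentConfig, rng: np.random.Generator
) -> PopulationState:
    """Advance the population one day.

    Fixed stage order: food replenishment → ingestion → growth →
    reproduction → survival → ageing. The generator is consulted only for
    the lifetime draws of this day's newborns, in array order, so the update
    is deterministic given the state and the seed. An empty population is
    absorbing (only the food pool changes).
    """
    lh = cfg.life_history
    food = state.food + lh.food_input
    if lh.food_cap is not None:
        food = min(food, lh.food_cap)  # algal standing stock saturates

    if state.size == 0:
        return replace(state, day=state.day + 1, food=food)

    # (2) ingestion from the shared pool: demand ∝ length², saturating in
    # food density; if total demand exceeds the pool everyone is scaled down.
    max_ration = lh.ingestion_coeff * state.length**2
    sat = food / (food + lh.half_saturation) if food > 0 else 0.0
    demand = max_ration * sat
    total_demand = float(demand.sum())
    scale = 1.0 if total_demand <= food else food / total_demand
    consumed = demand * scale
    food = max(food - float(consumed.sum()), 0.0)
    ration = np.divide(consumed, max_ration, out=np.zeros_like(consumed),
                       where=max_ration > 0)

    # (3) growth: von Bertalanffy increment scaled by realized ration.
    was_adult = state.length >= ADULT_MIN
    length = state.length + lh.growth_rate * (lh.asymptotic_length - state.length) * ration
    is_adult = length >= ADULT_MIN
    days_since_brood = state.days_since_brood.copy()
    days_since_brood[is_adult & ~was_adult] = 0  # brood timer starts at maturity

    # (4) reproduction: adults past the brood interval release a brood whose
    # size scales with the mother's ration and the toxicant inhibition.
    inhibition = reproduction_inhibition(cfg.concentration, cfg.dose_response)
    brooding = is_adult & (days_since_brood >= lh.brood_interval)
    crowding = 1.0
    if lh.crowding_scale is not None:
        crowding = float(np.exp(-state.size / lh.crowding_scale))
    brood = np.rint(lh.max_brood_size * ration[brooding] * crowding
                    * (1.0 - inhibition)).astype(int)
    brood = np.maximum(brood, 0)
    n_born = int(brood.sum())
    days_since_brood[brooding] = 0  # the molt cycle restarts even for empty broods

    # (5) survival: fixed lifetime exceeded, or too many starvation days.
    starved_today = ration < lh.starvation_ration
    days_starved = np.where(
        starved_today, state.days_starved + 1, np.maximum(state.days_starved - 1, 0)
    )
    tolerance = lh.starvation_days + np.rint(
        lh.starvation_length_scale * length
    ).astype(int)
    if lh.starvation_jitter > 0:
        # per-individual condition offset derived from the fixed lifetime
        # trait: desynchronises famine mortality without extra randomness
        tolerance = tolerance + state.max_lifetime % (lh.starvation_jitter + 1)
    dead = (state.age >= state.max_lifetime) | (days_starved >= tolerance)
    if cfg.dose_response.acute_mortality and cfg.concentration > 0:
        # linear-in-log daily hazard anchored at the acute LC50 (µg/l scale)
        lc50_ug = cfg.dose_response.lc50_acute * 1000.0
        hazard = max(0.0, 0.5 * np.log10(cfg.concentration / lc50_ug) + 0.5)
        if hazard > 0:
            # deterministic thinning is impossible without extra randomness;
            # acute mortality therefore consumes rng draws when enabled.
            dead |= rng.random(state.size) < hazard
    keep = ~dead

    # (6) ageing and assembly; newborns appended with age 0 and fresh
    # lifetime draws (the only stochastic element of the update).
    new_lifetimes = rng.integers(*_lifetime_bounds(lh), size=n_born)
    return PopulationState(
        day=state.day + 1,
        age=np.concatenate([state.age[keep] + 1, np.zeros(n_born, dtype=int)]),
        length=np.concatenate([length[keep], np.full(n_born, lh.length_at_birth)]),
        max_lifetime=np.concatenate(
            [state.max_lifetime[keep], np.asarray(new_lifetimes, dtype=int)]
        ),
        days_since_brood=np.concatenate(
            [days_since_brood[keep] + 1, np.zeros(n_born, dtype=int)]
        ),
        days_starved=np.concatenate([days_starved[keep], np.zeros(n_born, dtype=int)]),
        food=food,
    )


def _lifetime_bounds(lh) -> tuple[int, int]:
    lo, hi = lh.lifetime_range
    return lo, hi + 1


def run_simulation(cfg: TreatmentConfig, seed: int | None = None) -> AbundanceSeries:
    """One simulation run: census at day 0, then ``n_days`` daily updates."""
    if seed is None:
        seed = cfg.base_seed
    rng = np.random.default_rng(seed)
    state = initial_state(cfg, rng)
    neo = np.empty(cfg.n_days + 1, dtype=int)
    juv = np.empty(cfg.n_days + 1, dtype=int)
    adu = np.empty(cfg.n_days + 1, dtype=int)
    neo[0], juv[0], adu[0] = state.census()
    for t in range(1, cfg.n_days + 1):
        state = step_day(state, cfg, rng)
        neo[t], juv[t], adu[t] = state.census()
    return AbundanceSeries(
        day=np.arange(cfg.n_days + 1),
        neonates=neo,
        juveniles=juv,
        adults=adu,
        concentration=cfg.concentration,
        run=0,
        seed=int(seed),
    )


def run_ensemble(cfg: TreatmentConfig) -> list[AbundanceSeries]:
    """Monte-Carlo ensemble: run ``i`` uses seed ``base_seed + i``.

    Concentration never enters the seed, so run ``i`` shares its lifetime
    draws across treatments — the pairing the signed-rank test relies on.
    """
    if cfg.n_runs < 2:
        raise ValueError("n_runs must be >= 2 (ensemble statistics undefined)")
    out = []
    for i in range(cfg.n_runs):
        s = run_simulation(cfg, seed=cfg.base_seed + i)
        s.run = i
        out.append(s)
    return out
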