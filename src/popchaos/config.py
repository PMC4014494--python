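"""Configuration objects for simulation and analysis.

All parameters carry explicit units in their docstrings; configs round-trip
losslessly through YAML so a whole experiment is reproducible from one file
plus a seed.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

#: Default constant-exposure concentration panel (µg/l).
DEFAULT_PANEL: tuple[float, ...] = (0.0, 2.5, 5.0, 10.0, 20.0, 40.0)


@dataclass(frozen=True)
class DoseResponse:
    """Log-logistic concentration–response for sub-lethal reproduction effects.

    Parameters
    ----------
    ec50_repro : float
        Concentration (µg/l) halving the brood size.
    hill_slope : float
        Dimensionless steepness of the log-logistic curve.
    lc50_acute : float
        48-h acute LC50 (mg/l). Only consulted when ``acute_mortality`` is on;
        the default panel stays far below acute lethality.
    acute_mortality : bool
        Enable a linear-in-log(concentration) daily mortality term anchored
        at ``lc50_acute``. Off by default.
    """

    ec50_repro: float = 21.5
    hill_slope: float = 0.82
    lc50_acute: float = 0.23
    acute_mortality: bool = False

    def __post_init__(self) -> None:
        if self.ec50_repro <= 0:
            raise ValueError("ec50_repro must be > 0")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be > 0")


@dataclass(frozen=True)
class LifeHistoryParams:
    """Life-history and resource parameters of the daphnid-like simulator.

    Units: lengths in mm, food in mg C per litre, times in days.
    ``ingestion_coeff`` scales the length²-proportional maximum daily ration;
    ``half_saturation`` is the food density at half-maximal ingestion.
    ``starvation_ration`` is the realized-ration fraction below which a day
    counts toward starvation; an individual dies after
    ``starvation_days + round(starvation_length_scale * body_length)``
    accumulated starvation days, so larger animals (more reserves) survive
    famines longer and stage-graded mortality desynchronises crashes. ``lifetime_range`` is the inclusive integer
    range from which each individual's fixed maximum lifetime is drawn — the
    single source of randomness in a run.
    """

    length_at_birth: float = 0.8
    asymptotic_length: float = 4.0
    growth_rate: float = 0.10
    brood_interval: int = 3
    max_brood_size: int = 12
    lifetime_range: tuple[int, int] = (30, 60)
    food_input: float = 20.0
    food_cap: float | None = 40.0
    ingestion_coeff: float = 0.05
    half_saturation: float = 3.0
    starvation_ration: float = 0.1
    starvation_days: int = 6
    starvation_length_scale: float = 0.0
    starvation_jitter: int = 0
    crowding_scale: float | None = None
    initial_food: float = 20.0
    adult_initial_length: float = 3.0
    carrying_ceiling: int = 5000

    def __post_init__(self) -> None:
        lo, hi = self.lifetime_range
        if not (0 < lo <= hi):
            raise ValueError("lifetime_range must satisfy 0 < lo <= hi")
        if self.length_at_birth <= 0 or self.asymptotic_length <= self.length_at_birth:
            raise ValueError("need 0 < length_at_birth < asymptotic_length")


@dataclass(frozen=True)
class TreatmentConfig:
    """One treatment level: constant (press) exposure at ``concentration`` µg/l."""

    concentration: float = 0.0
    n_days: int = 365
    n_runs: int = 100
    base_seed: int = 0
    dose_response: DoseResponse = field(default_factory=DoseResponse)
    life_history: LifeHistoryParams = field(default_factory=LifeHistoryParams)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")


@dataclass(frozen=True)
class AnalysisParams:
    """Defaults of the nonlinear-analysis layer.

    ``n_cut`` initial days discarded as transient; scalar analyses use
    embedding dimension ``m`` with delay ``d``; the Poincaré section uses
    ``m_poincare``. ``eps_recurrence`` is the recurrence neighbourhood in
    absolute abundance units. ``nf_min`` is the minimum neighbourhood size
    for a Lyapunov reference point; ``alpha`` the test level.
    """

    n_cut: int = 50
    m: int = 2
    d: int = 1
    m_poincare: int = 3
    eps_recurrence: float = 1.0
    nf_min: int = 10
    t_max: int = 12
    alpha: float = 0.05


@dataclass(frozen=True)
class ExperimentConfig:
    """Full experiment: a concentration panel crossed with a Monte-Carlo ensemble."""

    concentrations: tuple[float, ...] = DEFAULT_PANEL
    n_days: int = 365
    n_runs: int = 100
    base_seed: int = 0
    dose_response: DoseResponse = field(default_factory=DoseResponse)
    life_history: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        if len(self.concentrations) < 2:
            raise ValueError("need at least two concentrations (control + one)")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be >= 0")
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2 (ensemble statistics undefined)")

    def treatment(self, concentration: float) -> TreatmentConfig:
        """The per-treatment config for one panel member (shared base seed)."""
        return TreatmentConfig(
            concentration=concentration,
            n_days=self.n_days,
            n_runs=self.n_runs,
            base_seed=self.base_seed,
            dose_response=self.dose_response,
            life_history=self.life_history,
        )

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["concentrations"] = list(self.concentrations)
        d["life_history"]["lifetime_range"] = list(self.life_history.lifetime_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        lh = dict(d.pop("life_history", {}))
        if "lifetime_range" in lh:
            lh["lifetime_range"] = tuple(lh["lifetime_range"])
        dr = dict(d.pop("dose_response", {}))
        an = dict(d.pop("analysis", {}))
        d["concentrations"] = tuple(d.get("concentrations", DEFAULT_PANEL))
        return cls(
            life_history=LifeHistoryParams(**lh),
            dose_response=DoseResponse(**dr),
            analysis=AnalysisParams(**an),
            **d,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
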