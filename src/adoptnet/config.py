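"""Configuration objects for the synthetic cohort generator and pipeline runs.

The synthetic generator emulates a state-wide prescriber cohort: physicians
with demographic / training / practice covariates, a weighted patient-sharing
graph built from a bipartite patient->physician assignment, medical-group and
hospital co-affiliation graphs, a training (school / residency) graph, and a
binary adoption outcome produced by a linear-in-means structural equation with
known peer-effect coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

NETWORK_KINDS = ("P", "G", "H", "T")

#: structural coefficients on physician covariates (columns of the roster).
#: Chosen so that covariates contribute meaningful variation to the adoption
#: propensity -- this is what makes peer-mean characteristics informative
#: instruments for peer adoption rates downstream.
DEFAULT_TRUE_BETA: dict[str, float] = {
    "female": -0.05,
    "years_since_grad_std": -0.04,
    "us_school": 0.04,
    "rural": -0.04,
    "medicare_share": 0.45,
    "specialist": 0.05,
    "log_volume_std": 0.03,
}

#: canonical strength of the community-level shared shock when peer-correlated
#: confounding is switched on in validation experiments.
DEFAULT_CONFOUNDER_SD = 0.03

#: peer-effect coefficients per network kind; patient-sharing strongest, as in
#: observed prescribing cohorts.
DEFAULT_TRUE_GAMMA: dict[str, float] = {"P": 0.6, "G": 0.0, "H": 0.3, "T": 0.0}


class ConfigurationError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study cohort.

    The defaults describe a mid-sized prescriber cohort (2,000 physicians)
    with an adoption rate of 25% -- the regime of a first-in-class oral
    anticoagulant in its first 15 months on the market.
    """

    n_physicians: int = 2000
    n_patients: int | None = None  # default: 4 * n_physicians
    n_groups: int | None = None  # default: n_physicians // 13 (small groups)
    n_hospitals: int | None = None  # default: 8 per location (large orgs)
    n_schools: int = 40
    n_residencies: int = 60
    n_locations: int | None = None  # default: max(4, n_physicians // 125)
    communities_per_location: int = 4
    grad_year_range: tuple[int, int] = (1970, 2005)
    patients_per_physician_mean: float = 4.0
    sharing_concentration: float = 1.7
    same_community_prob: float = 0.5
    same_location_prob: float = 0.3
    group_coverage: float = 0.72
    hospital_coverage: float = 0.90
    second_hospital_prob: float = 0.10
    specialty_shares: tuple[float, float, float] = (0.65, 0.08, 0.27)
    payer_community_sd: float = 0.28  # community-level spread of the Medicare weight
    true_gamma: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_GAMMA)
    )
    true_beta: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETA)
    )
    clip_bounds: tuple[float, float] = (0.01, 0.99)
    confounder_sd: float = 0.0
    confounder_unit: str = "group"  # sharing unit of the confounder shock
    idiosyncratic_sd: float = 0.02
    bernoulli_noise: bool = True
    target_adoption_rate: float = 0.25
    target_median: int = 7  # intended new-drug prescription median
    nonadopter_rx_prob: float | None = None  # default: min(0.3, r/(2(1-r)))
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    # derived defaults -------------------------------------------------
    @property
    def resolved_n_patients(self) -> int:
        if self.n_patients is not None:
            return self.n_patients
        return int(round(self.patients_per_physician_mean * self.n_physicians))

    @property
    def resolved_n_locations(self) -> int:
        if self.n_locations is not None:
            return self.n_locations
        return max(4, self.n_physicians // 125)

    @property
    def resolved_n_groups(self) -> int:
        if self.n_groups is not None:
            return self.n_groups
        return max(2, self.n_physicians // 13)

    @property
    def resolved_n_hospitals(self) -> int:
        if self.n_hospitals is not None:
            return self.n_hospitals
        return max(2, 8 * self.resolved_n_locations)

    @property
    def resolved_nonadopter_rx_prob(self) -> float:
        """Probability a non-adopter prescribes the new drug at all.

        Kept below r / (2 (1 - r)) so that adopters form a strict majority of
        physicians who prescribe at least once, which pins the cohort median
        at the intended threshold and lets the median rule recover truth.
        """
        if self.nonadopter_rx_prob is not None:
            return self.nonadopter_rx_prob
        r = self.target_adoption_rate
        return min(0.3, 0.5 * r / (1.0 - r))

    # ------------------------------------------------------------------
    def validate(self) -> None:
        counts = {
            "n_physicians": self.n_physicians,
            "n_schools": self.n_schools,
            "n_residencies": self.n_residencies,
            "communities_per_location": self.communities_per_location,
        }
        for name, value in counts.items():
            if not isinstance(value, (int,)) or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        for name in ("n_patients", "n_groups", "n_hospitals", "n_locations"):
            value = getattr(self, name)
            if value is not None and (not isinstance(value, int) or value < 1):
                raise ConfigurationError(f"{name} must be a positive integer or None, got {value!r}")
        lo, hi = self.grad_year_range
        if lo > hi:
            raise ConfigurationError(f"grad_year_range must be an inclusive interval, got {self.grad_year_range!r}")
        if self.patients_per_physician_mean <= 0:
            raise ConfigurationError("patients_per_physician_mean must be positive")
        if self.sharing_concentration < 1:
            raise ConfigurationError("sharing_concentration must be >= 1 (physicians per patient)")
        if not 0 < self.target_adoption_rate < 1:
            raise ConfigurationError(f"target_adoption_rate must lie in (0, 1), got {self.target_adoption_rate}")
        if self.confounder_sd < 0:
            raise ConfigurationError("confounder_sd must be nonnegative")
        if self.idiosyncratic_sd < 0:
            raise ConfigurationError("idiosyncratic_sd must be nonnegative")
        if self.target_median < 1:
            raise ConfigurationError("target_median must be >= 1")
        for kind, value in self.true_gamma.items():
            if kind not in NETWORK_KINDS:
                raise ConfigurationError(f"true_gamma has unknown network kind {kind!r}")
            if abs(value) >= 1:
                raise ConfigurationError(
                    f"true_gamma[{kind!r}] must have absolute value < 1 "
                    f"(contraction of the structural map), got {value}"
                )
        total = sum(abs(v) for v in self.true_gamma.values())
        if total >= 1:
            raise ConfigurationError(
                f"sum of |true_gamma| must be < 1 for a contraction, got {total}"
            )
        shares = self.specialty_shares
        if len(shares) != 3 or abs(sum(shares) - 1.0) > 1e-9 or min(shares) < 0:
            raise ConfigurationError("specialty_shares must be three nonnegative values summing to 1")
        for name in ("same_community_prob", "same_location_prob", "group_coverage",
                     "hospital_coverage", "second_hospital_prob"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.same_community_prob + self.same_location_prob > 1:
            raise ConfigurationError("same_community_prob + same_location_prob must be <= 1")
        if self.nonadopter_rx_prob is not None and not 0 <= self.nonadopter_rx_prob < 1:
            raise ConfigurationError("nonadopter_rx_prob must lie in [0, 1)")
        lo_c, hi_c = self.clip_bounds
        if not 0 < lo_c < hi_c < 1:
            raise ConfigurationError("clip_bounds must satisfy 0 < low < high < 1")
        if self.confounder_unit not in {"group", "community"}:
            raise ConfigurationError(
                f"confounder_unit must be 'group' or 'community', got {self.confounder_unit!r}"
            )

    # serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "grad_year_range" in data:
            data["grad_year_range"] = tuple(data["grad_year_range"])
        if "specialty_shares" in data:
            data["specialty_shares"] = tuple(data["specialty_shares"])
        if "clip_bounds" in data:
            data["clip_bounds"] = tuple(data["clip_bounds"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(load_config_file(path))


def load_config_file(path: str | Path) -> dict:
    """Load a flat YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration file {path} must contain a mapping")
    return data
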