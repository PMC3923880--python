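"""Study configuration: every fixed constant of the assessment in one place.

Defaults encode the assessment's standard conditions: kernel inflections of
300 km now, 630 km by 2055 and 1080 km by 2085 (an expansion allowance of
15 km per year between horizons), open-water crossing cost 2 (100 under the
barrier scenario), exposure cuts of 2 SD (single factor) and 1 SD (two or
more factors), the 10%-within-1-m sea-level rule, a sensitivity cut of 1,
a 30-level threshold sweep with slope cut -1, dispersal-pressure flag at 3
of 5 points, and roster cuts of 30 (modelled) / 15 (uncommon) subcatchments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


@dataclass
class ScenarioSpec:
    name: str
    horizon: int
    kernel_threshold: float  # km


def _default_scenarios():
    return [
        ScenarioSpec("RCP8.5-2055", 2055, 630.0),
        ScenarioSpec("RCP8.5-2085", 2085, 1080.0),
    ]


@dataclass
class AssessmentConfig:
    # reproducibility
    seed: int = 1

    # synthetic landscape (the demo study system)
    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 40.0  # km; 50x50 cells span a 2000 km continent
    n_subcatchments: int = 400
    sea_fraction: float = 0.15
    max_elev: float = 1200.0
    n_bias_centers: int = 3

    # synthetic species and sampling
    n_species: int = 30
    n_records_per_species: int = 150
    bias_strength: float = 2.0
    year_window: tuple = (1990, 2013)

    # scenarios and dispersal kernel
    scenarios: list = field(default_factory=_default_scenarios)
    current_threshold: float = 300.0  # km
    kernel_b: float = 4.0
    dispersal_rate_km_per_yr: float = 15.0  # documentation: encoded by thresholds

    # movement costs
    water_multiplier: float = 2.0
    barrier_multiplier: float = 100.0

    # exposure rules
    exposure_single_cut: float = 2.0  # SD
    exposure_multi_cut: float = 1.0  # SD
    exposure_multi_n: int = 2
    sea_cut: float = 0.10
    sea_level_rise: float = 1.0  # m

    # sensitivity
    sensitivity_cut: float = 1.0

    # threshold sweep
    sweep_levels: int = 30
    slope_cut: float = -1.0

    # dispersal pressure
    pressure_cut: int = 3

    # roster filters
    min_model_subcatchments: int = 30
    min_uncommon_subcatchments: int = 15
    removals: list = field(default_factory=list)

    # pseudo-absences (paper-scale default 10,000; scaled for synthetic runs)
    pa_radius_km: float = 300.0
    pa_n_total: int = 300

    # ensemble fitting
    ensemble_replicates: int = 5
    train_fraction: float = 0.7
    model_kind: str = "gaussian"

    # clamping
    clamp_max_exceed: int = 1
    clamp_penalty: float = 0.0

    # priority maps
    priority_categories: tuple = (1, 2)

    def __post_init__(self):
        self.scenarios = [
            s if isinstance(s, ScenarioSpec) else ScenarioSpec(**s)
            for s in self.scenarios
        ]
        thresholds = [self.current_threshold] + [
            s.kernel_threshold for s in sorted(self.scenarios, key=lambda s: s.horizon)
        ]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            raise ValueError("kernel thresholds must increase strictly across horizons")
        if self.min_uncommon_subcatchments >= self.min_model_subcatchments:
            raise ValueError("uncommon cutoff must be below the modelling cutoff")

    def implied_expansion_rate(self) -> float:
        """km/yr implied by the future kernel thresholds, e.g.
        (1080 - 630) / (2085 - 2055) = 15."""
        sc = sorted(self.scenarios, key=lambda s: s.horizon)
        if len(sc) < 2:
            first = sc[0]
            return (first.kernel_threshold - self.current_threshold) / max(
                first.horizon - 2025, 1
            )
        (a, b) = sc[0], sc[-1]
        return (b.kernel_threshold - a.kernel_threshold) / (b.horizon - a.horizon)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = [dataclasses.asdict(s) for s in self.scenarios]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "AssessmentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "year_window" in raw:
            raw["year_window"] = tuple(raw["year_window"])
        if "priority_categories" in raw:
            raw["priority_categories"] = tuple(raw["priority_categories"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
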