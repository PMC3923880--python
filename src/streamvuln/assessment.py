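"""Combining exposure, sensitivity and dispersal into vulnerability
categories, roster filtering, barrier comparisons and priority maps.

Category scheme (exposed, sensitive, pressured):
    (T, T, T) -> 1  highly vulnerable: at risk across all components
    (T, T, F) -> 2  vulnerable: exposed and sensitive, no long-distance shift
    (T, F, T) -> 3  potential to persist: habitat exists but needs dispersal
    (F, T, T) -> 4  declining and shifting before becoming exposed
    others    -> LC (not at risk under this scheme; flags kept for re-binning)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AssessmentConfig
from .dispersal import (
    DispersalResult,
    DistanceField,
    dispersal_pressure,
    habitat_shift_score,
    threshold_sweep,
)
from .exposure import ExposureResult, assess_exposure
from .landscape import OccurrenceSet, ScenarioStack
from .sensitivity import SensitivityResult, priority_weight, sensitivity_weight
from .suitability import SuitabilitySurface, binarize


@dataclass
class VulnerabilityRecord:
    species: str
    scenario: str
    exposure: ExposureResult
    sensitivity: SensitivityResult
    dispersal: DispersalResult
    category: str  # "1".."4" or "LC"
    region_limited: bool = False  # future habitat confined to current region(s)

    @property
    def exposed(self) -> bool:
        return self.exposure.exposed

    @property
    def sensitive(self) -> bool:
        return self.sensitivity.sensitive

    @property
    def pressured(self) -> bool:
        return self.dispersal.pressured


@dataclass
class PriorityMap:
    scenario: str
    category_group: str
    scores: pd.Series  # per-subcatchment, >= 0


@dataclass
class RosterFilter:
    min_model_subcatchments: int = 30
    min_uncommon_subcatchments: int = 15
    removals: list = field(default_factory=list)

    def __post_init__(self):
        if self.min_uncommon_subcatchments >= self.min_model_subcatchments:
            raise ValueError("uncommon cutoff must be below modelling cutoff")


def assign_category(exposed: bool, sensitive: bool, pressured: bool) -> str:
    """Map the three component flags to a vulnerability category."""
    key = (bool(exposed), bool(sensitive), bool(pressured))
    table = {
        (True, True, True): "1",
        (True, True, False): "2",
        (True, False, True): "3",
        (False, True, True): "4",
    }
    return table.get(key, "LC")


def assess_species(
    species: str,
    scenario: str,
    current_surface: SuitabilitySurface,
    future_surface: SuitabilitySurface,
    future_surface_unkerneled: SuitabilitySurface,
    current_stack: ScenarioStack,
    future_stack: ScenarioStack,
    elevation: pd.Series,
    distances: DistanceField,
    occurrences: OccurrenceSet,
    config: AssessmentConfig | None = None,
    future_threshold: float | None = None,
    region_of_sub: pd.Series | None = None,
) -> VulnerabilityRecord:
    """Run all three components for one species under one future scenario.

    ``current_surface`` and ``future_surface`` are the dispersal-weighted,
    clamped surfaces; ``future_surface_unkerneled`` is the clamped surface
    before kernel weighting, needed by the threshold sweep.
    """
    cfg = config or AssessmentConfig()
    stage_inputs = {
        "exposure": (current_stack, future_stack, elevation),
        "sensitivity": (current_surface, future_surface),
        "dispersal": (distances, occurrences, future_surface_unkerneled),
    }
    for stage, items in stage_inputs.items():
        if any(x is None for x in items):
            raise ValueError(f"missing input for stage {stage!r} "
                             f"(species {species}, scenario {scenario})")

    habitat_mask = binarize(current_surface)
    if not habitat_mask.any():
        raise ValueError(
            f"stage exposure: species {species} has no current suitable habitat"
        )
    exp = assess_exposure(
        current_stack.factors,
        future_stack.factors,
        habitat_mask,
        elevation,
        rise=cfg.sea_level_rise,
        single_cut=cfg.exposure_single_cut,
        multi_cut=cfg.exposure_multi_cut,
        multi_n=cfg.exposure_multi_n,
        sea_cut=cfg.sea_cut,
    )

    sens = sensitivity_weight(current_surface, future_surface)

    current_set = set(habitat_mask.index[habitat_mask])
    future_mask = binarize(future_surface)
    future_set = set(future_mask.index[future_mask])
    shift = habitat_shift_score(occurrences, current_set, future_set, distances)
    fut_thr = future_threshold
    if fut_thr is None:
        matches = [s.kernel_threshold for s in cfg.scenarios if s.name == scenario]
        fut_thr = matches[0] if matches else max(
            s.kernel_threshold for s in cfg.scenarios
        )
    sweep = threshold_sweep(
        future_surface_unkerneled,
        current_surface,
        distances,
        base_threshold=cfg.current_threshold,
        future_threshold=fut_thr,
        n_levels=cfg.sweep_levels,
        slope_cut=cfg.slope_cut,
        kernel_b=cfg.kernel_b,
    )
    disp = dispersal_pressure(
        shift.score, sweep.score, pressure_cut=cfg.pressure_cut,
        z=shift.z, slopes=sweep.slopes,
    )

    region_limited = False
    if region_of_sub is not None and future_set:
        current_regions = set(region_of_sub.loc[sorted(current_set)])
        future_regions = set(region_of_sub.loc[sorted(future_set)])
        region_limited = future_regions <= current_regions

    category = assign_category(exp.exposed, sens.sensitive, disp.pressured)
    return VulnerabilityRecord(
        species=species,
        scenario=scenario,
        exposure=exp,
        sensitivity=sens,
        dispersal=disp,
        category=category,
        region_limited=region_limited,
    )


def barrier_impact(records_base: list, records_barrier: list) -> pd.DataFrame:
    """Species whose sensitive flag or category changed under the barrier.

    Compares two record lists from the same species set and scenario (base
    movement costs vs sea crossing at barrier cost) and tabulates per-species
    deltas.  Only changed species are returned.
    """
    base = {r.species: r for r in records_base}
    barr = {r.species: r for r in records_barrier}
    if set(base) != set(barr):
        raise ValueError("barrier comparison requires identical species rosters")
    scenarios = {r.scenario for r in records_base} | {r.scenario for r in records_barrier}
    if len(scenarios) > 1:
        raise ValueError("barrier comparison requires a single shared scenario")
    rows = []
    for sp in sorted(base):
        b, a = base[sp], barr[sp]
        changed = (b.sensitive != a.sensitive) or (b.category != a.category)
        if not changed:
            continue
        dS = (
            float("nan")
            if (b.sensitivity.degenerate or a.sensitivity.degenerate)
            else a.sensitivity.S - b.sensitivity.S
        )
        rows.append(
            {
                "species": sp,
                "scenario": b.scenario,
                "S_base": b.sensitivity.S,
                "S_barrier": a.sensitivity.S,
                "delta_S": dS,
                "sensitive_base": b.sensitive,
                "sensitive_barrier": a.sensitive,
                "category_base": b.category,
                "category_barrier": a.category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "scenario", "S_base", "S_barrier", "delta_S",
            "sensitive_base", "sensitive_barrier",
            "category_base", "category_barrier",
        ],
    )


def filter_roster(record_counts: dict, roster: RosterFilter) -> pd.DataFrame:
    """Classify species by occupied-subcatchment count.

    count >= 30 -> modelled; 15 <= count < 30 -> uncommon; below -> excluded.
    The removal list is applied last and marks species excluded regardless of
    count (with removed=True).  Returns a DataFrame (species, count, status,
    removed) sorted by species id.
    """
    rows = []
    for sp in sorted(record_counts):
        n = record_counts[sp]
        if n < 0:
            raise ValueError(f"negative subcatchment count for {sp}")
        if n >= roster.min_model_subcatchments:
            status = "modelled"
        elif n >= roster.min_uncommon_subcatchments:
            status = "uncommon"
        else:
            status = "excluded"
        rows.append({"species": sp, "count": n, "status": status, "removed": False})
    df = pd.DataFrame(rows, columns=["species", "count", "status", "removed"])
    for sp in roster.removals:
        if sp not in record_counts:
            warnings.warn(f"removal id {sp!r} not in roster; ignored", stacklevel=2)
            continue
        df.loc[df["species"] == sp, ["status", "removed"]] = ["excluded", True]
    return df


def assessed_species(roster_df: pd.DataFrame) -> list:
    """Species entering the assessment: modelled + uncommon, removals out."""
    keep = roster_df["status"].isin(["modelled", "uncommon"]) & ~roster_df["removed"]
    return list(roster_df.loc[keep, "species"])


def conservation_priority(
    surfaces: dict,
    records: list,
    categories: tuple = (1, 2),
    scenario: str | None = None,
) -> PriorityMap:
    """Sensitivity-weighted priority score per subcatchment.

    score_j = sum over species in the chosen categories of
    max(S, 0) * suitability_j, with suitability below the species' TSS
    threshold zeroed (consistent with the sensitivity stage).  Species that
    lose all future habitat contribute nothing (their thresholded future
    suitability is zero everywhere).
    """
    cat_labels = {str(c) for c in categories}
    included = [r for r in records if r.category in cat_labels]
    scen = scenario
    if scen is None and records:
        scen = records[0].scenario
    base_index = None
    for surf in surfaces.values():
        base_index = surf.values.index
        break
    if base_index is None:
        raise ValueError("no surfaces supplied")
    scores = pd.Series(0.0, index=base_index)
    for rec in included:
        if rec.species not in surfaces:
            raise ValueError(f"species {rec.species} has a record but no surface")
        surf = surfaces[rec.species]
        w = priority_weight(rec.sensitivity)
        v = surf.values.copy()
        v[v < surf.tss_threshold] = 0.0
        scores = scores + w * v
    group = "+".join(sorted(cat_labels))
    return PriorityMap(scenario=scen or "", category_group=group, scores=scores)
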