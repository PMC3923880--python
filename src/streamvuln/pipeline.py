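"""End-to-end assessment pipeline.

generate -> fit -> project (all scenarios) -> clamp -> dispersal-weight ->
assess (exposure, sensitivity, dispersal pressure) -> categorise -> barrier
compare -> prioritise; each stage logs input/output counts so the roster
bookkeeping stays auditable, and every report file carries the config hash
and master seed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as svio
from .assessment import (
    PriorityMap,
    RosterFilter,
    assess_species,
    assessed_species,
    barrier_impact,
    conservation_priority,
    filter_roster,
)
from .config import AssessmentConfig
from .dispersal import (
    KernelParams,
    apply_kernel,
    build_cost_surface,
    cost_distance,
    occurrence_source_cells,
)
from .suitability import (
    clamp,
    ensemble_project,
    ensemble_training_limits,
    fit_species_ensemble,
    select_pseudo_absences,
)
from .synthetic import (
    default_anomalies,
    default_baseline,
    generate_landscape,
    generate_scenarios,
    generate_species_truth,
    sample_occurrences,
)

log = logging.getLogger("streamvuln")

REPORT_FILES = (
    "evaluation.csv",
    "exposure.csv",
    "sensitivity.csv",
    "dispersal.csv",
    "vulnerability.csv",
    "priority.csv",
)


@dataclass
class PipelineResult:
    landscape: object
    stacks: dict
    niches: list
    occurrences: dict
    ensembles: dict
    surfaces: dict  # (species, scenario) -> unkerneled clamped surface
    kerneled: dict  # (species, scenario) -> dispersal-weighted surface
    distances: dict  # species -> DistanceField (base costs)
    records: dict  # scenario -> list of VulnerabilityRecord
    barrier_records: dict
    barrier_deltas: pd.DataFrame
    priorities: list
    roster: pd.DataFrame
    skipped: list = field(default_factory=list)


def _spawn_seeds(master: int, n: int) -> list:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def _future_anomalies(config: AssessmentConfig) -> dict:
    """Anomaly tables keyed by the configured scenario names; the 2055-style
    table is used for the earliest horizon and scaled with horizon distance."""
    base = default_anomalies()
    names = sorted(base)
    out = {}
    horizons = sorted(s.horizon for s in config.scenarios)
    for spec in config.scenarios:
        if spec.name in base:
            out[spec.name] = base[spec.name]
        else:
            # map by horizon rank onto the default tables
            rank = horizons.index(spec.horizon)
            out[spec.name] = base[names[min(rank, len(names) - 1)]]
    return out


def run_pipeline(config: AssessmentConfig, outdir: str) -> PipelineResult:
    os.makedirs(outdir, exist_ok=True)
    meta = {"config": config.config_hash(), "seed": config.seed}
    seeds = _spawn_seeds(config.seed, 6)
    log.info(
        "kernel thresholds imply an expansion rate of %.3g km/yr",
        config.implied_expansion_rate(),
    )

    # ---- generate ----------------------------------------------------
    landscape = generate_landscape(
        config.n_rows,
        config.n_cols,
        config.cell_size,
        config.n_subcatchments,
        config.sea_fraction,
        seed=seeds[0],
        max_elev=config.max_elev,
        n_bias_centers=config.n_bias_centers,
    )
    stacks_list = generate_scenarios(
        landscape, default_baseline(), _future_anomalies(config), seed=seeds[1]
    )
    stacks = {s.scenario: s for s in stacks_list}
    current = stacks["current"]
    niches = generate_species_truth(
        config.n_species, current, seed=seeds[2], landscape=landscape
    )
    occ_seeds = _spawn_seeds(seeds[3], len(niches))
    occurrences = {}
    for niche, s in zip(niches, occ_seeds):
        occurrences[niche.species] = sample_occurrences(
            niche,
            landscape,
            current,
            config.n_records_per_species,
            config.bias_strength,
            seed=s,
            year_window=config.year_window,
        )
    log.info(
        "generate: %d subcatchments, %d scenarios, %d species, %d records",
        landscape.n_subcatchments,
        len(stacks),
        len(niches),
        sum(len(o) for o in occurrences.values()),
    )

    # ---- roster ------------------------------------------------------
    counts = {sp: len(set(o.records["subcatchment"])) for sp, o in occurrences.items()}
    roster = filter_roster(
        counts,
        RosterFilter(
            config.min_model_subcatchments,
            config.min_uncommon_subcatchments,
            list(config.removals),
        ),
    )
    kept = assessed_species(roster)
    log.info(
        "roster: %d modelled + %d uncommon - %d removed = %d assessed",
        (roster["status"] == "modelled").sum(),
        (roster["status"] == "uncommon").sum(),
        roster["removed"].sum(),
        len(kept),
    )

    # ---- fit + project ----------------------------------------------
    background = pd.concat(
        [o.records[["subcatchment", "x", "y"]] for o in occurrences.values()],
        ignore_index=True,
    ).drop_duplicates(subset=["x", "y"])
    fit_seeds = dict(zip(sorted(kept), _spawn_seeds(seeds[4], len(kept))))
    ensembles, surfaces, eval_rows, skipped = {}, {}, [], []
    for sp in sorted(kept):
        occ = occurrences[sp]
        try:
            absences = select_pseudo_absences(
                occ,
                background,
                landscape,
                radius_km=config.pa_radius_km,
                n_total=config.pa_n_total,
                seed=fit_seeds[sp],
            )
            ensemble, tau, reports = fit_species_ensemble(
                occ,
                absences,
                current,
                n_replicates=config.ensemble_replicates,
                train_fraction=config.train_fraction,
                model_kind=config.model_kind,
                seed=fit_seeds[sp],
            )
        except ValueError as err:
            log.warning("fit: species %s skipped (%s)", sp, err)
            skipped.append((sp, "fit", str(err)))
            continue
        ensembles[sp] = ensemble
        limits = ensemble_training_limits(ensemble)
        for rep in reports:
            eval_rows.append(
                {
                    "species": sp,
                    "replicate": rep.replicate,
                    "auc": rep.auc,
                    "tss": rep.tss,
                    "threshold": rep.tss_threshold,
                }
            )
        for scen, stack in stacks.items():
            surf = ensemble_project(ensemble, stack, species=sp, tss_threshold=tau)
            surfaces[(sp, scen)] = clamp(
                surf,
                stack,
                limits,
                max_exceed=config.clamp_max_exceed,
                penalty=config.clamp_penalty,
            )
    log.info("fit+project: %d species fitted, %d surfaces", len(ensembles), len(surfaces))

    # ---- distances and kernel weighting ------------------------------
    def _distance_fields(multiplier):
        costs = build_cost_surface(landscape, multiplier)
        return {
            sp: cost_distance(
                costs, occurrence_source_cells(occurrences[sp], landscape),
                landscape, species=sp,
            )
            for sp in sorted(ensembles)
        }

    distances = _distance_fields(config.water_multiplier)
    distances_barrier = _distance_fields(config.barrier_multiplier)
    log.info("distances: %d species x 2 cost scenarios", len(distances))

    def _kerneled(dist_fields):
        out = {}
        for (sp, scen), surf in surfaces.items():
            if scen == "current":
                d0 = config.current_threshold
            else:
                d0 = next(s.kernel_threshold for s in config.scenarios if s.name == scen)
            out[(sp, scen)] = apply_kernel(
                surf, dist_fields[sp], KernelParams(d0=d0, b=config.kernel_b)
            )
        return out

    kerneled = _kerneled(distances)
    kerneled_barrier = _kerneled(distances_barrier)

    # ---- assess -------------------------------------------------------
    elevation = landscape.subcatchments.set_index("id")["mean_elev"]
    region = landscape.subcatchments.set_index("id")["region"]

    def _assess(kern, dist_fields):
        recs = {spec.name: [] for spec in config.scenarios}
        for spec in config.scenarios:
            for sp in sorted(ensembles):
                try:
                    rec = assess_species(
                        sp,
                        spec.name,
                        kern[(sp, "current")],
                        kern[(sp, spec.name)],
                        surfaces[(sp, spec.name)],
                        current,
                        stacks[spec.name],
                        elevation,
                        dist_fields[sp],
                        occurrences[sp],
                        config=config,
                        future_threshold=spec.kernel_threshold,
                        region_of_sub=region,
                    )
                except ValueError as err:
                    log.warning(
                        "assess: species %s (%s) skipped (%s)", sp, spec.name, err
                    )
                    skipped.append((sp, f"assess:{spec.name}", str(err)))
                    continue
                recs[spec.name].append(rec)
        return recs

    records = _assess(kerneled, distances)
    barrier_records = _assess(kerneled_barrier, distances_barrier)
    for scen, recs in records.items():
        log.info("assess %s: %d species categorised", scen, len(recs))

    # ---- barrier comparison ------------------------------------------
    delta_frames = []
    for spec in config.scenarios:
        base_sp = {r.species for r in records[spec.name]}
        barr_sp = {r.species for r in barrier_records[spec.name]}
        shared = base_sp & barr_sp
        delta_frames.append(
            barrier_impact(
                [r for r in records[spec.name] if r.species in shared],
                [r for r in barrier_records[spec.name] if r.species in shared],
            )
        )
    barrier_deltas = pd.concat(delta_frames, ignore_index=True)
    log.info("barrier: %d species changed flag or category", len(barrier_deltas))

    # ---- priorities ---------------------------------------------------
    priorities = []
    for spec in config.scenarios:
        surfs = {
            sp: kerneled[(sp, spec.name)]
            for sp in sorted(ensembles)
            if (sp, spec.name) in kerneled
        }
        if surfs:
            pm = conservation_priority(
                surfs,
                records[spec.name],
                categories=config.priority_categories,
                scenario=spec.name,
            )
        else:  # nothing assessed under this scenario: all-zero map
            pm = PriorityMap(
                scenario=spec.name,
                category_group="+".join(str(c) for c in config.priority_categories),
                scores=pd.Series(
                    0.0, index=pd.Index(landscape.subcatchments["id"],
                                        name="subcatchment"),
                ),
            )
        priorities.append(pm)
    log.info("priorities: %d maps", len(priorities))

    # ---- write --------------------------------------------------------
    svio.write_landscape(landscape, os.path.join(outdir, "landscape"), meta)
    svio.write_scenarios(stacks_list, os.path.join(outdir, "scenarios.csv"), meta)
    svio.write_occurrences(
        [occurrences[sp] for sp in sorted(occurrences)],
        os.path.join(outdir, "occurrences.csv"),
        meta,
    )
    svio.write_surfaces(
        [kerneled[k] for k in sorted(kerneled)],
        os.path.join(outdir, "surfaces.csv"),
        meta,
    )
    svio.write_csv(roster, os.path.join(outdir, "roster.csv"), meta)
    svio.write_csv(
        pd.DataFrame(eval_rows), os.path.join(outdir, "evaluation.csv"), meta
    )

    exp_rows, sens_rows, disp_rows, vuln_rows = [], [], [], []
    for scen, recs in records.items():
        for r in recs:
            for fac, val in r.exposure.factor_exposures.items():
                exp_rows.append(
                    {
                        "species": r.species,
                        "scenario": scen,
                        "factor": fac,
                        "exposure_sd": val,
                        "sea_fraction": r.exposure.sea_fraction,
                        "exposed": r.exposure.exposed,
                        "reasons": ";".join(r.exposure.reasons),
                    }
                )
            sens_rows.append(
                {
                    "species": r.species,
                    "scenario": scen,
                    "sum_current": r.sensitivity.sum_current,
                    "sum_future": r.sensitivity.sum_future,
                    "S": r.sensitivity.S,
                    "degenerate": r.sensitivity.degenerate,
                    "sensitive": r.sensitivity.sensitive,
                }
            )
            disp_rows.append(
                {
                    "species": r.species,
                    "scenario": scen,
                    "shift_score": r.dispersal.shift_score,
                    "z": r.dispersal.z,
                    "slope_low": r.dispersal.slopes.get("low"),
                    "slope_medium": r.dispersal.slopes.get("medium"),
                    "slope_high": r.dispersal.slopes.get("high"),
                    "sweep_score": r.dispersal.sweep_score,
                    "total": r.dispersal.total,
                    "pressured": r.dispersal.pressured,
                }
            )
            vuln_rows.append(
                {
                    "species": r.species,
                    "scenario": scen,
                    "exposed": r.exposed,
                    "sensitive": r.sensitive,
                    "pressured": r.pressured,
                    "S": r.sensitivity.S,
                    "dispersal_total": r.dispersal.total,
                    "category": r.category,
                    "region_limited": r.region_limited,
                }
            )
    svio.write_csv(pd.DataFrame(exp_rows), os.path.join(outdir, "exposure.csv"), meta)
    svio.write_csv(
        pd.DataFrame(sens_rows), os.path.join(outdir, "sensitivity.csv"), meta
    )
    svio.write_csv(pd.DataFrame(disp_rows), os.path.join(outdir, "dispersal.csv"), meta)
    svio.write_csv(
        pd.DataFrame(vuln_rows), os.path.join(outdir, "vulnerability.csv"), meta
    )

    prio_frames = []
    for pm in priorities:
        df = pm.scores.rename("score").reset_index()
        df.insert(0, "category_group", pm.category_group)
        df.insert(0, "scenario", pm.scenario)
        prio_frames.append(df)
    svio.write_csv(
        pd.concat(prio_frames, ignore_index=True),
        os.path.join(outdir, "priority.csv"),
        meta,
    )
    svio.write_csv(barrier_deltas, os.path.join(outdir, "barrier_deltas.csv"), meta)
    log.info("reports written to %s", outdir)

    return PipelineResult(
        landscape=landscape,
        stacks=stacks,
        niches=niches,
        occurrences=occurrences,
        ensembles=ensembles,
        surfaces=surfaces,
        kerneled=kerneled,
        distances=distances,
        records=records,
        barrier_records=barrier_records,
        barrier_deltas=barrier_deltas,
        priorities=priorities,
        roster=roster,
        skipped=skipped,
    )
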