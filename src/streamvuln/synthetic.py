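"""Synthetic landscapes, climate scenarios, species niches and occurrence samples.

Everything downstream of this module is pure post-processing, so a landscape
with the right *statistical* structure — land/sea grid, contiguous
subcatchments, seven spatially structured environmental factors, additive
scenario anomalies, Gaussian-niche species and spatially biased sampling —
makes the whole assessment testable without any external data, and supplies
ground truth for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape import FACTORS, Landscape, OccurrenceSet, ScenarioStack, SpeciesNiche

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass
class FactorParams:
    """Baseline spatial model for one environmental factor.

    value = mean + gradient_x * (x/W - 1/2) + gradient_y * (y/H - 1/2)
            + elev_coef * (elevation_km) + Normal(0, noise_sd)

    so ``gradient_*`` is the total swing across the grid in factor units and
    ``elev_coef`` is a per-km-elevation lapse term.
    """

    mean: float
    gradient_x: float = 0.0
    gradient_y: float = 0.0
    noise_sd: float = 0.0
    elev_coef: float = 0.0
    nonnegative: bool = False


def default_baseline() -> dict:
    """Continental-flavour defaults: temperature falls poleward and with
    elevation, rainfall and flow swing coast-to-interior, each factor keeps
    independent local noise so factors are not collinear across space."""
    return {
        "tmean": FactorParams(22.0, 0.0, -8.0, 0.8, -6.5),
        "tseasonality": FactorParams(1.3, 0.3, 0.5, 0.15),
        "tmin_coldest": FactorParams(8.0, 0.0, -6.0, 1.0, -6.5),
        "p_wet": FactorParams(420.0, 250.0, -60.0, 60.0, 40.0, nonnegative=True),
        "p_dry": FactorParams(90.0, 40.0, -15.0, 18.0, nonnegative=True),
        "p_seasonality": FactorParams(0.85, -0.3, 0.1, 0.1),
        "flow": FactorParams(160.0, 90.0, 30.0, 45.0, 20.0, nonnegative=True),
    }


def default_anomalies() -> dict:
    """High-emissions-flavour anomalies (mean shift, spatial SD) per factor.

    The 2085 horizon roughly doubles the 2055 warming/drying, mirroring a
    non-mitigation trajectory; SDs give the anomaly fields spatial texture.
    """
    a2055 = {
        "tmean": (1.8, 0.3),
        "tseasonality": (0.08, 0.03),
        "tmin_coldest": (1.6, 0.35),
        "p_wet": (-45.0, 18.0),
        "p_dry": (-12.0, 6.0),
        "p_seasonality": (0.05, 0.02),
        "flow": (-25.0, 10.0),
    }
    a2085 = {k: (2.1 * m, 1.6 * s) for k, (m, s) in a2055.items()}
    return {"RCP8.5-2055": a2055, "RCP8.5-2085": a2085}


@dataclass
class NicheSpread:
    """Hyperparameters for drawing species niches.

    Tolerances are drawn uniformly from ``tolerance_range`` times the spatial
    SD of each factor; peaks uniformly from ``peak_range``; optima are
    anchored at the realized factor vector of a random subcatchment with a
    jitter of ``optimum_jitter`` tolerances, which guarantees every species
    has near-peak habitat somewhere on the landscape.
    """

    tolerance_range: tuple = (0.5, 1.5)
    peak_range: tuple = (0.6, 0.95)
    optimum_jitter: float = 0.25


def generate_landscape(
    n_rows: int,
    n_cols: int,
    cell_size: float,
    n_subcatchments: int,
    sea_fraction: float,
    seed: int,
    max_elev: float = 1200.0,
    n_bias_centers: int = 3,
    strait_position: float = 0.12,
    strait_width: float = 0.08,
) -> Landscape:
    """Generate a land/sea grid partitioned into contiguous subcatchments.

    Elevation is a smoothed random field rescaled to [0, max_elev]; the
    lowest ``sea_fraction`` of cells become open water, and land cells
    touching water are forced below 1 m so the sea-level exposure rule has
    something to bite on.  Whenever there is any sea, a full-width sea
    strait is carved ``strait_position`` of the way up from the southern
    edge, ``strait_width`` of the grid tall, separating a southern island
    from the mainland — the geography the dispersal-barrier scenario turns
    on.  Subcatchments grow region-by-region from random land seeds, giving
    irregular contiguous units; rare land pockets cut off from every seed by
    water are attached to the nearest seed.
    """
    if not 0 <= sea_fraction < 1:
        raise ValueError("sea_fraction must be in [0, 1)")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    rng = np.random.default_rng(seed)

    rough = rng.normal(size=(n_rows, n_cols))
    smooth = ndimage.gaussian_filter(rough, sigma=max(min(n_rows, n_cols) / 8.0, 1.5))
    if sea_fraction > 0:
        cut = np.quantile(smooth, sea_fraction)
        is_water = smooth < cut
        if not is_water.any():  # quantile ties can leave no cell below the cut
            is_water.flat[np.argmin(smooth)] = True
        r0 = int(round(strait_position * n_rows))
        r1 = min(r0 + max(int(round(strait_width * n_rows)), 1), n_rows)
        if r0 > 0:  # leave at least one southern row for the island
            is_water[r0:r1, :] = True
    else:
        is_water = np.zeros((n_rows, n_cols), dtype=bool)
    land = ~is_water
    n_land = int(land.sum())
    if n_subcatchments > n_land:
        raise ValueError(
            f"cannot partition {n_land} land cells into {n_subcatchments} subcatchments"
        )
    if n_subcatchments < 1:
        raise ValueError("need at least one subcatchment")

    lo, hi = smooth[land].min(), smooth[land].max()
    elevation = np.zeros((n_rows, n_cols))
    if hi > lo:
        elevation[land] = (smooth[land] - lo) / (hi - lo) * max_elev
    coastal = land & (ndimage.binary_dilation(is_water, structure=_EIGHT))
    elevation[coastal] = rng.uniform(0.0, 0.9, size=int(coastal.sum()))
    elevation[is_water] = 0.0

    sub_index = _grow_subcatchments(land, n_subcatchments, rng)

    regions = _label_regions(land)
    xx, yy = _cell_centers(n_rows, n_cols, cell_size)
    rows_tab = []
    for k in range(n_subcatchments):
        members = sub_index == k
        reg = regions[members]
        reg_label = pd.Series(reg).mode().iloc[0]
        rows_tab.append(
            {
                "id": f"sc{k:04d}",
                "centroid_x": float(xx[members].mean()),
                "centroid_y": float(yy[members].mean()),
                "mean_elev": float(elevation[members].mean()),
                "region": reg_label,
                "code": f"{reg_label}-{k:04d}",
            }
        )
    subcatchments = pd.DataFrame(rows_tab)

    if n_bias_centers > 0 and n_land > 0:
        flat = np.flatnonzero(land.ravel())
        picks = rng.choice(flat, size=min(n_bias_centers, n_land), replace=False)
        bias_centers = [
            (float(xx.ravel()[p]), float(yy.ravel()[p])) for p in sorted(picks)
        ]
    else:
        bias_centers = []

    ls = Landscape(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell_size,
        elevation=elevation,
        is_water=is_water,
        sub_index=sub_index,
        subcatchments=subcatchments,
        bias_centers=bias_centers,
    )
    ls.validate()
    return ls


def _cell_centers(n_rows, n_cols, cell_size):
    y = (np.arange(n_rows) + 0.5) * cell_size
    x = (np.arange(n_cols) + 0.5) * cell_size
    return np.meshgrid(x, y)


def _label_regions(land: np.ndarray) -> np.ndarray:
    """Label connected landmasses: largest is 'mainland', rest 'island<i>'
    in decreasing size order.  Water cells get ''."""
    lab, n = ndimage.label(land, structure=_EIGHT)
    out = np.full(land.shape, "", dtype=object)
    if n == 0:
        return out
    sizes = ndimage.sum_labels(land, lab, index=np.arange(1, n + 1))
    order = np.argsort(-sizes, kind="stable")
    names = {}
    for rank, comp in enumerate(order):
        names[comp + 1] = "mainland" if rank == 0 else f"island{rank}"
    for comp, name in names.items():
        out[lab == comp] = name
    return out


def _grow_subcatchments(land: np.ndarray, n_sub: int, rng) -> np.ndarray:
    """Seeded region growing: each unassigned land cell adjacent to an
    assigned one adopts the label of a randomly chosen assigned neighbour,
    iterated to fixpoint; stranded pockets attach to the nearest seed."""
    n_rows, n_cols = land.shape
    sub = np.full((n_rows, n_cols), -1, dtype=int)
    flat_land = np.flatnonzero(land.ravel())
    seeds = rng.choice(flat_land, size=n_sub, replace=False)
    seed_rc = np.column_stack(np.unravel_index(seeds, land.shape))
    for k, (r, c) in enumerate(seed_rc):
        sub[r, c] = k

    while True:
        assigned = sub >= 0
        frontier = land & ~assigned & ndimage.binary_dilation(assigned, _EIGHT)
        rr, cc = np.nonzero(frontier)
        if len(rr) == 0:
            break
        order = rng.permutation(len(rr))
        for i in order:
            r, c = rr[i], cc[i]
            r0, r1 = max(r - 1, 0), min(r + 2, n_rows)
            c0, c1 = max(c - 1, 0), min(c + 2, n_cols)
            neigh = sub[r0:r1, c0:c1]
            labels = neigh[neigh >= 0]
            sub[r, c] = labels[rng.integers(len(labels))]

    stranded = land & (sub < 0)
    if stranded.any():
        rr, cc = np.nonzero(stranded)
        for r, c in zip(rr, cc):
            d2 = (seed_rc[:, 0] - r) ** 2 + (seed_rc[:, 1] - c) ** 2
            sub[r, c] = int(np.argmin(d2))
    return sub


def generate_scenarios(
    landscape: Landscape,
    baseline_params: dict,
    anomalies: dict,
    seed: int,
) -> list:
    """One 'current' stack plus one stack per named future scenario.

    Future value = current value + Normal(shift, shift_sd) per subcatchment;
    a factor absent from a scenario's anomaly table gets no shift.  Null
    anomalies (shift 0, SD 0) reproduce the current stack exactly.
    """
    missing = set(FACTORS) - set(baseline_params)
    if missing:
        raise ValueError(f"baseline_params missing factors: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    sc = landscape.subcatchments
    w = landscape.n_cols * landscape.cell_size
    h = landscape.n_rows * landscape.cell_size
    n = len(sc)

    current = pd.DataFrame(index=pd.Index(sc["id"], name="subcatchment"))
    for f in FACTORS:
        p = baseline_params[f]
        vals = (
            p.mean
            + p.gradient_x * (sc["centroid_x"].to_numpy() / w - 0.5)
            + p.gradient_y * (sc["centroid_y"].to_numpy() / h - 0.5)
            + p.elev_coef * (sc["mean_elev"].to_numpy() / 1000.0)
            + rng.normal(0.0, p.noise_sd, size=n)
        )
        if p.nonnegative:
            vals = np.maximum(vals, 0.0)
        current[f] = vals

    stacks = [ScenarioStack("current", current)]
    for name in anomalies:
        fut = current.copy()
        for f in FACTORS:
            shift, sd = anomalies[name].get(f, (0.0, 0.0))
            fut[f] = fut[f] + rng.normal(shift, sd, size=n)
            if baseline_params[f].nonnegative:
                fut[f] = np.maximum(fut[f], 0.0)
        stacks.append(ScenarioStack(name, fut))
    for s in stacks:
        s.validate()
    return stacks


def generate_species_truth(
    n_species: int,
    current_stack: ScenarioStack,
    niche_spread: NicheSpread = None,
    seed: int = 0,
    landscape: Landscape = None,
) -> list:
    """Draw ground-truth Gaussian niches anchored on realized environments.

    With a landscape supplied, each species' home region is the landmass of
    its anchor subcatchment: its records will be confined there (ranges are
    dispersal-limited), though other landmasses may still be climatically
    suitable — the situation the dispersal-barrier scenario probes.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    spread = niche_spread or NicheSpread()
    rng = np.random.default_rng(seed)
    env = current_stack.factors
    sd = env.std(ddof=0).replace(0.0, 1.0)
    lo, hi = env.min(), env.max()
    regions = None
    if landscape is not None:
        regions = landscape.subcatchments.set_index("id")["region"]

    niches = []
    for i in range(n_species):
        k = rng.integers(len(env))
        anchor = env.iloc[k]
        tol = sd * rng.uniform(*spread.tolerance_range, size=len(env.columns))
        opt = anchor + rng.normal(0.0, spread.optimum_jitter, len(tol)) * tol
        opt = opt.clip(lo, hi)
        peak = rng.uniform(*spread.peak_range)
        home = None
        if regions is not None:
            home = str(regions.get(env.index[k], None))
        niches.append(
            SpeciesNiche(
                species=f"sp{i:04d}",
                optima=opt.astype(float),
                tolerances=tol.astype(float),
                peak=float(peak),
                home_region=home,
            )
        )
    return niches


def sample_occurrences(
    niche: SpeciesNiche,
    landscape: Landscape,
    current_stack: ScenarioStack,
    n_records: int,
    bias_strength: float,
    seed: int,
    year_window: tuple = (1990, 2013),
) -> OccurrenceSet:
    """Draw occurrence records with probability ∝ occupancy × sampling bias.

    Bias emulates collection effort concentrated near settlements: weight
    exp(-bias_strength * d / L) where d is the distance to the nearest bias
    centre and L the landscape diagonal, so bias_strength 0 means unbiased
    occupancy-proportional sampling and larger values concentrate records.
    """
    if n_records < 0:
        raise ValueError("n_records must be >= 0")
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    rng = np.random.default_rng(seed)
    cols = ["subcatchment", "x", "y", "year", "stage", "sex"]
    if n_records == 0:
        return OccurrenceSet(niche.species, pd.DataFrame(columns=cols))

    occ = niche.occupancy(current_stack)
    land = ~landscape.is_water
    rr, cc = np.nonzero(land)
    sub_codes = landscape.sub_index[rr, cc]
    cell_occ = occ.to_numpy()[sub_codes]
    if niche.home_region is not None:
        reg = landscape.subcatchments["region"].to_numpy()[sub_codes]
        cell_occ = np.where(reg == niche.home_region, cell_occ, 0.0)

    xx, yy = landscape.cell_centers()
    cx, cy = xx[rr, cc], yy[rr, cc]
    if bias_strength > 0 and landscape.bias_centers:
        diag = float(
            np.hypot(
                landscape.n_cols * landscape.cell_size,
                landscape.n_rows * landscape.cell_size,
            )
        )
        d = np.min(
            [np.hypot(cx - bx, cy - by) for bx, by in landscape.bias_centers],
            axis=0,
        )
        bias = np.exp(-bias_strength * d / diag)
    else:
        bias = np.ones_like(cell_occ)

    w = cell_occ * bias
    total = w.sum()
    if total <= 0:
        raise ValueError(
            f"species {niche.species}: zero occupancy everywhere, cannot sample"
        )
    picks = rng.choice(len(w), size=n_records, p=w / total)
    ids = landscape.subcatchments["id"].to_numpy()
    records = pd.DataFrame(
        {
            "subcatchment": ids[sub_codes[picks]],
            "x": cx[picks],
            "y": cy[picks],
            "year": rng.integers(year_window[0], year_window[1] + 1, n_records),
            "stage": rng.choice(["adult", "larva"], n_records),
            "sex": rng.choice(["F", "M"], n_records),
        }
    )
    return OccurrenceSet(niche.species, records)
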