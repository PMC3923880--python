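"""Dispersal constraints and dispersal-pressure scoring.

Suitable habitat only counts if a species can plausibly reach it.  Reach is
modelled with least-cost distances over the grid (open water costs more to
cross than land) passed through a four-parameter logistic kernel that maps
distance to a dispersal probability in [0, 1].  Kernel inflection distances
of 300 km (current), 630 km (2055) and 1080 km (2085) encode an upper-bound
range expansion of 15 km per year.

Dispersal *pressure* is scored out of 5: up to 2 points from how much
farther future suitable habitat lies from the species' records (one-sided
rank-sum test), plus up to 3 points from how fast the sensitivity weight
deteriorates as the dispersal threshold is swept back down towards the
current limit.  Species scoring 3 or more are considered to face
significant dispersal pressure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import dijkstra

from .landscape import Landscape, OccurrenceSet
from .sensitivity import sensitivity_weight
from .suitability import SuitabilitySurface


@dataclass
class CostSurface:
    costs: np.ndarray  # per-cell traversal cost, >= 1
    cell_size: float

    def __post_init__(self):
        if np.any(self.costs < 1) or not np.all(np.isfinite(self.costs)):
            raise ValueError("traversal costs must be finite and >= 1")


@dataclass
class DistanceField:
    species: str
    per_sub: pd.Series  # km, +inf where unreachable
    cell_distances: np.ndarray | None = None


@dataclass
class KernelParams:
    """Four-parameter logistic dispersal kernel.

    k(d) = c + (a - c) / (1 + (d / d0)**b)

    a: upper asymptote (probability at distance 0), c: lower asymptote,
    d0: inflection distance in km (k(d0) = (a + c) / 2), b: steepness.
    """

    d0: float
    b: float = 4.0
    a: float = 1.0
    c: float = 0.0

    def __post_init__(self):
        if self.d0 <= 0:
            raise ValueError("inflection distance d0 must be positive")
        if self.b <= 0:
            raise ValueError("steepness b must be positive")
        if self.a <= self.c:
            raise ValueError("upper asymptote must exceed lower asymptote")


def build_cost_surface(landscape: Landscape, water_multiplier: float = 2.0) -> CostSurface:
    """Land cells cost 1; open-water cells cost ``water_multiplier``
    (2 by default; 100 under the barrier scenario)."""
    if water_multiplier < 1:
        raise ValueError("water_multiplier must be >= 1")
    costs = np.ones((landscape.n_rows, landscape.n_cols))
    costs[landscape.is_water] = water_multiplier
    return CostSurface(costs=costs, cell_size=landscape.cell_size)


def _grid_graph(costs: np.ndarray, cell_size: float) -> sparse.csr_matrix:
    """Sparse 8-connected grid graph; a step costs cell_size times the mean
    of the two endpoint cell costs, times sqrt(2) for diagonal steps."""
    n_rows, n_cols = costs.shape
    n = n_rows * n_cols
    idx = np.arange(n).reshape(n_rows, n_cols)
    rows, cols, data = [], [], []
    shifts = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))]
    for dr, dc, mult in shifts:
        r0 = slice(0, n_rows - dr)
        r1 = slice(dr, n_rows)
        if dc >= 0:
            c0, c1 = slice(0, n_cols - dc), slice(dc, n_cols)
        else:
            c0, c1 = slice(-dc, n_cols), slice(0, n_cols + dc)
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        w = cell_size * mult * 0.5 * (costs[r0, c0].ravel() + costs[r1, c1].ravel())
        rows.append(a)
        cols.append(b)
        data.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    g = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
    return (g + g.T).tocsr()


def cost_distance(
    costs: CostSurface,
    sources: list,
    landscape: Landscape,
    species: str = "",
) -> DistanceField:
    """Least-cost-path distance (km) from a set of source cells.

    ``sources`` is a list of (row, col) cells.  Per-subcatchment distance is
    read at the member cell nearest the subcatchment centroid; an
    unreachable subcatchment keeps distance +inf.
    """
    if not sources:
        raise ValueError("source cell set is empty")
    n_rows, n_cols = costs.costs.shape
    g = _grid_graph(costs.costs, costs.cell_size)
    src_idx = sorted({r * n_cols + c for r, c in sources})
    d = dijkstra(g, directed=False, indices=src_idx, min_only=True)
    cells = d.reshape(n_rows, n_cols)
    cen = landscape.centroid_cells()
    per_sub = pd.Series(
        cells[cen[:, 0], cen[:, 1]],
        index=pd.Index(landscape.subcatchments["id"], name="subcatchment"),
    )
    return DistanceField(species=species, per_sub=per_sub, cell_distances=cells)


def occurrence_source_cells(occ: OccurrenceSet, landscape: Landscape) -> list:
    """Grid cells occupied by a species' records (distance-field sources)."""
    cs = landscape.cell_size
    cells = {
        (int(y / cs), int(x / cs))
        for x, y in zip(occ.records["x"], occ.records["y"])
    }
    return sorted(cells)


def kernel_value(d, params: KernelParams):
    """Dispersal probability at cost distance d (km); scalar or array."""
    d = np.asarray(d, dtype=float)
    out = np.full(d.shape, params.c, dtype=float)
    finite = np.isfinite(d)
    with np.errstate(over="ignore"):
        ratio = (d[finite] / params.d0) ** params.b
    out[finite] = params.c + (params.a - params.c) / (1.0 + ratio)
    if out.ndim == 0:
        return float(out)
    return out


def apply_kernel(
    surface: SuitabilitySurface,
    distances: DistanceField,
    params: KernelParams,
) -> SuitabilitySurface:
    """Weight suitability by dispersal probability; unreachable subcatchments
    (infinite distance) drop to zero.  The TSS threshold is unchanged."""
    d = distances.per_sub.reindex(surface.values.index)
    if d.isna().any():
        raise ValueError("distance field does not cover the surface's subcatchments")
    k = kernel_value(d.to_numpy(), params)
    k[~np.isfinite(d.to_numpy())] = 0.0
    return surface.copy_with(values=surface.values * k)


@dataclass
class RankSumResult:
    z: float
    p_one_sided: float
    W: float  # rank sum of sample b


def rank_sum_z(sample_a, sample_b, exact: bool = False) -> RankSumResult:
    """Wilcoxon rank-sum test that sample_b is stochastically larger.

    Midranks for ties; z is the plain standardized rank sum with
    tie-corrected variance (the scoring thresholds are expressed on this
    scale); the one-sided p applies the usual 0.5 continuity correction.
    With ``exact=True`` the p is instead computed by enumerating all
    labelings of the combined sample (small n only).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    na, nb = len(a), len(b)
    n = na + nb
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    W = float(ranks[na:].sum())
    E = nb * (n + 1) / 2.0
    _, t = np.unique(combined, return_counts=True)
    tie_term = float(((t**3 - t).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankSumResult(z=0.0, p_one_sided=0.5, W=W)
    z = (W - E) / math.sqrt(var)
    if exact:
        count = 0
        total = 0
        for pick in itertools.combinations(range(n), nb):
            total += 1
            if ranks[list(pick)].sum() >= W - 1e-9:
                count += 1
        p = count / total
    else:
        p = float(stats.norm.sf((W - E - 0.5) / math.sqrt(var)))
    return RankSumResult(z=float(z), p_one_sided=p, W=W)


@dataclass
class ShiftResult:
    score: int  # 0, 1 or 2
    z: float
    p_one_sided: float
    degenerate: bool = False


def habitat_shift_score(
    occurrences: OccurrenceSet,
    current_suitable: set,
    future_suitable: set,
    distances: DistanceField,
    z_significant: float = 1.96,
    z_strong: float = 3.0,
) -> ShiftResult:
    """Score how much farther future suitable habitat lies from the records.

    Distance samples are the least-cost distances from the species' records
    to every currently suitable vs every future-suitable subcatchment.  The
    one-sided rank-sum z (future farther) scores 0 below ~2 SDs, 1 between
    2 and 3 SDs and 2 beyond 3 SDs.  A species with no future habitat at
    all scores 2 with a sentinel infinite z and a degenerate flag.
    """
    if not current_suitable:
        raise ValueError("current suitable set is empty")
    if not future_suitable:
        return ShiftResult(score=2, z=float("inf"), p_one_sided=0.0, degenerate=True)
    d = distances.per_sub
    a = d.loc[sorted(current_suitable)].to_numpy()
    b = d.loc[sorted(future_suitable)].to_numpy()
    if len(a) < 2 or len(b) < 2 or (np.ptp(np.concatenate([a, b])) == 0):
        return ShiftResult(score=0, z=0.0, p_one_sided=0.5)
    rs = rank_sum_z(a, b)
    if rs.z >= z_strong:
        score = 2
    elif rs.z >= z_significant:
        score = 1
    else:
        score = 0
    return ShiftResult(score=score, z=rs.z, p_one_sided=rs.p_one_sided)


@dataclass
class SweepResult:
    score: int  # 0..3
    slopes: dict  # tercile -> OLS slope of S on ln(d0)
    degenerate: bool = False
    levels: np.ndarray | None = None
    S_values: np.ndarray | None = None


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return float("-inf")  # habitat vanished: maximal dependence
    x, y = x[ok], y[ok]
    xc = x - x.mean()
    denom = (xc**2).sum()
    if denom == 0:
        return 0.0
    return float((xc * (y - y.mean())).sum() / denom)


def threshold_sweep(
    surface_future_unkerneled: SuitabilitySurface,
    surface_current: SuitabilitySurface,
    distances: DistanceField,
    base_threshold: float = 300.0,
    future_threshold: float = 630.0,
    n_levels: int = 30,
    slope_cut: float = -1.0,
    kernel_b: float = 4.0,
    spacing: str = "linear",
) -> SweepResult:
    """Score dependence of the sensitivity weight on the dispersal threshold.

    The kernel inflection d0 is swept over ``n_levels`` values between the
    current habitat limit and the future threshold (10 low, 10 medium and
    10 high levels by default), the future surface re-weighted and S
    recomputed at each level, and S regressed on ln(d0) within each tercile.
    A slope at or below ``slope_cut`` (default -1: S rises by more than one
    per log-distance as the threshold falls) scores 3 in the high tercile,
    else 2 in the medium, else 1 in the low tercile, else 0.
    """
    if base_threshold >= future_threshold:
        raise ValueError("base_threshold must be below future_threshold")
    if n_levels % 3 != 0:
        raise ValueError("n_levels must be divisible by 3")
    if spacing == "linear":
        levels = np.linspace(base_threshold, future_threshold, n_levels)
    elif spacing == "log":
        levels = np.geomspace(base_threshold, future_threshold, n_levels)
    else:
        raise ValueError(f"unknown spacing {spacing!r}")

    S_vals = np.empty(n_levels)
    for i, d0 in enumerate(levels):
        kerneled = apply_kernel(
            surface_future_unkerneled, distances, KernelParams(d0=d0, b=kernel_b)
        )
        try:
            res = sensitivity_weight(surface_current, kerneled)
            S_vals[i] = np.nan if res.degenerate else res.S
        except ValueError:
            S_vals[i] = np.nan

    if np.all(~np.isfinite(S_vals)):
        return SweepResult(
            score=3,
            slopes={"low": float("-inf"), "medium": float("-inf"), "high": float("-inf")},
            degenerate=True, levels=levels, S_values=S_vals,
        )
    score, slopes = sweep_score_from_series(levels, S_vals, slope_cut)
    return SweepResult(score=score, slopes=slopes, levels=levels, S_values=S_vals)


def sweep_score_from_series(levels, S_vals, slope_cut: float = -1.0):
    """Tercile OLS slopes of S on ln(d0) and the resulting sweep score.

    The level range splits into low/medium/high terciles; the first tercile
    (scanning high, then medium, then low) whose slope is at or below
    ``slope_cut`` sets the score (3/2/1), else 0.
    """
    levels = np.asarray(levels, dtype=float)
    S_vals = np.asarray(S_vals, dtype=float)
    if len(levels) % 3 != 0:
        raise ValueError("series length must be divisible by 3")
    third = len(levels) // 3
    lnx = np.log(levels)
    slopes = {
        "low": _ols_slope(lnx[:third], S_vals[:third]),
        "medium": _ols_slope(lnx[third : 2 * third], S_vals[third : 2 * third]),
        "high": _ols_slope(lnx[2 * third :], S_vals[2 * third :]),
    }
    if slopes["high"] <= slope_cut:
        score = 3
    elif slopes["medium"] <= slope_cut:
        score = 2
    elif slopes["low"] <= slope_cut:
        score = 1
    else:
        score = 0
    return score, slopes


@dataclass
class DispersalResult:
    shift_score: int
    sweep_score: int
    total: int
    pressured: bool
    z: float = float("nan")
    slopes: dict = field(default_factory=dict)


def dispersal_pressure(
    shift_score: int,
    sweep_score: int,
    pressure_cut: int = 3,
    z: float = float("nan"),
    slopes: dict | None = None,
) -> DispersalResult:
    """Combine the habitat-shift score (0-2) and sweep score (0-3): a
    maximum of 5 points, with dispersal pressure flagged at 3 or more."""
    if shift_score not in (0, 1, 2):
        raise ValueError("shift_score must be in {0, 1, 2}")
    if sweep_score not in (0, 1, 2, 3):
        raise ValueError("sweep_score must be in {0, 1, 2, 3}")
    total = shift_score + sweep_score
    return DispersalResult(
        shift_score=shift_score,
        sweep_score=sweep_score,
        total=total,
        pressured=total >= pressure_cut,
        z=z,
        slopes=slopes or {},
    )
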