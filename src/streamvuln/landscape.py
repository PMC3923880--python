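"""Core spatial containers: gridded landscapes, scenario stacks, niches, occurrences.

The analysis grain is the *subcatchment*: an irregular, contiguous group of
grid cells standing in for the smallest unit of a stream network.  Climate
and hydrology factors live on subcatchments; movement costs live on cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven environmental factors used for habitat modelling: three
#: temperature (annual mean degC, seasonality, minimum of the coldest month
#: degC), three precipitation (wettest-quarter mm, driest-quarter mm,
#: seasonality) and one hydrological (mean annual flow).
FACTORS = (
    "tmean",
    "tseasonality",
    "tmin_coldest",
    "p_wet",
    "p_dry",
    "p_seasonality",
    "flow",
)


@dataclass
class Landscape:
    """A gridded land/sea landscape partitioned into subcatchments.

    Attributes
    ----------
    n_rows, n_cols : int
        Grid shape; row 0 is the southern edge (y increases with row index).
    cell_size : float
        Cell edge length in km.
    elevation : ndarray of shape (n_rows, n_cols)
        Cell elevation in metres (water cells hold 0).
    is_water : ndarray of bool
        Open-water mask.
    sub_index : ndarray of int
        Positional subcatchment code per cell; -1 for water cells.
    subcatchments : DataFrame
        One row per subcatchment, positionally aligned with ``sub_index``
        codes; columns ``id`` (opaque string), ``centroid_x``/``centroid_y``
        (km), ``mean_elev`` (m), ``region`` (connected-landmass label) and
        ``code`` (hierarchical text code).
    bias_centers : list of (x, y)
        Designated sampling-bias centres (stand-ins for towns/roads) used by
        the occurrence sampler.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    elevation: np.ndarray
    is_water: np.ndarray
    sub_index: np.ndarray
    subcatchments: pd.DataFrame
    bias_centers: list = field(default_factory=list)

    @property
    def n_subcatchments(self) -> int:
        return len(self.subcatchments)

    @property
    def sub_ids(self) -> list:
        return list(self.subcatchments["id"])

    def cell_centers(self):
        """(x, y) km coordinates of every cell centre, shape (n_rows, n_cols)."""
        y = (np.arange(self.n_rows) + 0.5) * self.cell_size
        x = (np.arange(self.n_cols) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(x, y)
        return xx, yy

    def subcatchment_of_cell(self, row: int, col: int):
        """Subcatchment id string at a cell, or None for water."""
        code = int(self.sub_index[row, col])
        if code < 0:
            return None
        return self.subcatchments["id"].iloc[code]

    def centroid_cells(self) -> np.ndarray:
        """Per-subcatchment (row, col) of the member cell nearest the centroid.

        Centroids of irregular units can fall outside the unit itself, so the
        representative cell is the member cell closest to the centroid.
        """
        xx, yy = self.cell_centers()
        out = np.empty((self.n_subcatchments, 2), dtype=int)
        for k in range(self.n_subcatchments):
            rows, cols = np.nonzero(self.sub_index == k)
            cx = self.subcatchments["centroid_x"].iloc[k]
            cy = self.subcatchments["centroid_y"].iloc[k]
            d2 = (xx[rows, cols] - cx) ** 2 + (yy[rows, cols] - cy) ** 2
            j = int(np.argmin(d2))
            out[k] = rows[j], cols[j]
        return out

    def validate(self) -> None:
        """Raise ValueError on any violated structural invariant."""
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        land = ~self.is_water
        if np.any(self.sub_index[land] < 0):
            raise ValueError("every land cell must belong to a subcatchment")
        if np.any(self.sub_index[self.is_water] >= 0):
            raise ValueError("water cells must not belong to a subcatchment")
        counts = np.bincount(
            self.sub_index[land].ravel(), minlength=self.n_subcatchments
        )
        if np.any(counts == 0):
            raise ValueError("every subcatchment must contain at least one cell")
        w = self.n_cols * self.cell_size
        h = self.n_rows * self.cell_size
        sc = self.subcatchments
        if ((sc["centroid_x"] < 0) | (sc["centroid_x"] > w)).any() or (
            (sc["centroid_y"] < 0) | (sc["centroid_y"] > h)
        ).any():
            raise ValueError("subcatchment centroids must lie inside the grid")


@dataclass
class ScenarioStack:
    """Per-subcatchment values of every environmental factor for one scenario.

    ``factors`` is a DataFrame indexed by subcatchment id with one column per
    factor name; the factor set must be identical across the scenarios of one
    study.
    """

    scenario: str
    factors: pd.DataFrame

    def factor(self, name: str) -> pd.Series:
        return self.factors[name]

    @property
    def sub_ids(self) -> list:
        return list(self.factors.index)

    def validate(self, expected_factors=FACTORS) -> None:
        missing = set(expected_factors) - set(self.factors.columns)
        if missing:
            raise ValueError(
                f"scenario {self.scenario!r} missing factors: {sorted(missing)}"
            )
        if self.factors.isna().any().any():
            raise ValueError(f"scenario {self.scenario!r} contains NaN values")


@dataclass
class SpeciesNiche:
    """Synthetic ground-truth niche: independent Gaussian response per factor.

    Occupancy probability at a subcatchment with factor vector v is

        peak * prod_f exp(-0.5 * ((v_f - optimum_f) / tolerance_f)**2)

    i.e. each factor's Gaussian response is normalised to 1 at its optimum so
    occupancy equals ``peak`` exactly at the optimum vector.
    """

    species: str
    optima: pd.Series
    tolerances: pd.Series
    peak: float
    #: landmass the species is established on (None = unrestricted); real
    #: ranges are dispersal-limited, so records only fall on the home
    #: landmass even where other landmasses are climatically suitable
    home_region: str | None = None

    def __post_init__(self):
        if (self.tolerances <= 0).any():
            raise ValueError("tolerances must be positive")
        if not 0 < self.peak <= 1:
            raise ValueError("peak occupancy must be in (0, 1]")

    def occupancy(self, stack: ScenarioStack) -> pd.Series:
        """True occupancy probability for every subcatchment in the stack."""
        z = (stack.factors[self.optima.index] - self.optima) / self.tolerances
        return self.peak * np.exp(-0.5 * (z**2).sum(axis=1))


@dataclass
class OccurrenceSet:
    """Occurrence records for one species.

    ``records`` columns: subcatchment (id string), x, y (km), year, stage,
    sex.  All records must fall on land cells.
    """

    species: str
    records: pd.DataFrame

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subcatchments(self) -> list:
        """Distinct occupied subcatchment ids, in first-seen order."""
        return list(dict.fromkeys(self.records["subcatchment"]))

    def validate(self, landscape: Landscape) -> None:
        for i, rec in self.records.iterrows():
            col = int(rec["x"] / landscape.cell_size)
            row = int(rec["y"] / landscape.cell_size)
            if not (0 <= row < landscape.n_rows and 0 <= col < landscape.n_cols):
                raise ValueError(f"record {i}: coordinates outside the grid")
            if landscape.is_water[row, col]:
                raise ValueError(f"record {i}: falls on a water cell")
            sub = landscape.subcatchment_of_cell(row, col)
            if sub != rec["subcatchment"]:
                raise ValueError(
                    f"record {i}: subcatchment {rec['subcatchment']!r} "
                    f"inconsistent with coordinates (cell belongs to {sub!r})"
                )
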