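"""Exposure: how far a species' current habitat departs from current
conditions under a future scenario, in standard-deviation units, plus the
sea-level-rise rule.

A species is taken to have evolved to cope with the variation inside its
current environment, so departures are scaled by the SD of current
conditions across its own suitable habitat (by default; externally supplied
per-factor SDs, e.g. inter-annual SDs, can be passed instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default mapping from the seven modelling factors to the five exposure
#: factors: mean and seasonality of temperature and precipitation, plus
#: mean annual flow.  A composite exposure factor is the row-mean of its
#: source columns.
DEFAULT_EXPOSURE_FACTORS = {
    "tmean": ["tmean"],
    "tseasonality": ["tseasonality"],
    "p_mean": ["p_wet", "p_dry"],
    "p_seasonality": ["p_seasonality"],
    "flow": ["flow"],
}


@dataclass
class ExposureResult:
    factor_exposures: dict
    sea_fraction: float
    exposed: bool
    reasons: list = field(default_factory=list)


def _composite(factors: pd.DataFrame, sources: list) -> pd.Series:
    return factors[sources].mean(axis=1)


def factor_exposure(
    current: pd.Series,
    future: pd.Series,
    habitat_mask: pd.Series,
    sd_mode: str = "habitat",
    external_sd: float | None = None,
    factor_name: str = "",
) -> float:
    """Mean |future - current| / SD over the species' suitable subcatchments.

    sd_mode "habitat" (default) uses the spatial SD of current values across
    the suitable subcatchments; sd_mode "external" divides by
    ``external_sd`` (e.g. an inter-annual SD supplied by the user).
    """
    mask = habitat_mask.astype(bool)
    if not mask.any():
        raise ValueError("habitat mask is empty")
    cur = current[mask.index][mask]
    fut = future[mask.index][mask]
    if sd_mode == "habitat":
        sd = float(cur.std(ddof=0))
    elif sd_mode == "external":
        sd = float(external_sd) if external_sd is not None else 0.0
    else:
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError(
            f"zero or non-finite SD for factor {factor_name or '<unnamed>'}; "
            "exposure is undefined"
        )
    return float((fut - cur).abs().mean() / sd)


def sea_level_fraction(
    habitat_mask: pd.Series, elevation: pd.Series, rise: float = 1.0
) -> float:
    """Fraction of currently suitable subcatchments with mean elevation at or
    below the sea-level rise (default 1 m)."""
    mask = habitat_mask.astype(bool)
    if not mask.any():
        raise ValueError("habitat mask is empty")
    elev = elevation[mask.index][mask]
    return float((elev <= rise).mean())


def exposure_flag(
    factor_exposures: dict,
    sea_fraction: float,
    single_cut: float = 2.0,
    multi_cut: float = 1.0,
    multi_n: int = 2,
    sea_cut: float = 0.10,
) -> ExposureResult:
    """Apply the exposure rules.

    Exposed if any factor shifts more than ``single_cut`` SDs, or at least
    ``multi_n`` factors shift more than ``multi_cut`` SDs, or at least
    ``sea_cut`` of the habitat lies within the sea-level rise.
    """
    if not factor_exposures:
        raise ValueError("need at least one factor exposure")
    reasons = []
    vals = np.array(list(factor_exposures.values()), dtype=float)
    if np.any(vals > single_cut):
        reasons.append("single-factor>2SD")
    if int((vals > multi_cut).sum()) >= multi_n:
        reasons.append("multi-factor>1SD")
    if sea_fraction >= sea_cut:
        reasons.append("sea-level")
    return ExposureResult(
        factor_exposures=dict(factor_exposures),
        sea_fraction=float(sea_fraction),
        exposed=bool(reasons),
        reasons=reasons,
    )


def assess_exposure(
    current_factors: pd.DataFrame,
    future_factors: pd.DataFrame,
    habitat_mask: pd.Series,
    elevation: pd.Series,
    exposure_factors: dict | None = None,
    sd_mode: str = "habitat",
    external_sds: dict | None = None,
    rise: float = 1.0,
    single_cut: float = 2.0,
    multi_cut: float = 1.0,
    multi_n: int = 2,
    sea_cut: float = 0.10,
) -> ExposureResult:
    """Full exposure assessment of one species under one future scenario."""
    mapping = exposure_factors or DEFAULT_EXPOSURE_FACTORS
    exps = {}
    for name, sources in mapping.items():
        exps[name] = factor_exposure(
            _composite(current_factors, sources),
            _composite(future_factors, sources),
            habitat_mask,
            sd_mode=sd_mode,
            external_sd=(external_sds or {}).get(name),
            factor_name=name,
        )
    sea = sea_level_fraction(habitat_mask, elevation, rise=rise)
    return exposure_flag(
        exps, sea, single_cut=single_cut, multi_cut=multi_cut,
        multi_n=multi_n, sea_cut=sea_cut,
    )
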