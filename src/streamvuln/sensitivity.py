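"""Sensitivity weight S: loss of thresholded habitat suitability, scaled by
what remains.

S = (sum_current - sum_future) / sum_future, with suitability below the
species' TSS threshold zeroed before summing.  S > 1 flags high
vulnerability (more habitat value lost than remains); negative S means the
species is projected to expand.  A species whose future total is zero is
reported as *degenerate* (S undefined but maximally sensitive) rather than
as an infinity, which keeps reports finite and sortable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .suitability import SuitabilitySurface


@dataclass
class SensitivityResult:
    S: float  # NaN when degenerate
    sum_current: float
    sum_future: float
    sensitive: bool
    degenerate: bool

    @property
    def percent_change(self) -> float:
        """Percent change of total thresholded suitability, future vs current.

        Equals -100 * S / (S + 1); e.g. S = 30.5 is a -97% collapse.
        """
        if self.sum_current == 0:
            return float("nan")
        return 100.0 * (self.sum_future - self.sum_current) / self.sum_current


def thresholded_sum(surface: SuitabilitySurface) -> float:
    """Total suitability with sub-threshold scores zeroed."""
    v = surface.values.to_numpy(dtype=float)
    return float(v[v >= surface.tss_threshold].sum())


def sensitivity_weight(
    current: SuitabilitySurface, future: SuitabilitySurface
) -> SensitivityResult:
    """Compute S from a species' current and future surfaces (shared tau)."""
    if set(current.values.index) != set(future.values.index):
        raise ValueError("surfaces must share the same subcatchment set")
    if current.tss_threshold != future.tss_threshold:
        raise ValueError("surfaces must share the same TSS threshold")
    sum_c = thresholded_sum(current)
    sum_f = thresholded_sum(future)
    if sum_c == 0 and sum_f == 0:
        raise ValueError(
            f"species {current.species!r}: no suitable habitat in either "
            "scenario; species was never modelled as present"
        )
    if sum_f == 0:
        return SensitivityResult(
            S=float("nan"), sum_current=sum_c, sum_future=0.0,
            sensitive=True, degenerate=True,
        )
    S = (sum_c - sum_f) / sum_f
    return SensitivityResult(
        S=float(S), sum_current=sum_c, sum_future=sum_f,
        sensitive=bool(S > 1.0), degenerate=False,
    )


def classify_sensitivity(result: SensitivityResult) -> bool:
    """Highly vulnerable iff S strictly exceeds 1, or the species loses all
    future habitat while having some now."""
    if result.degenerate:
        return result.sum_current > 0
    return bool(result.S > 1.0)


def priority_weight(result: SensitivityResult) -> float:
    """Sensitivity weight used in priority maps: max(S, 0); degenerate
    species contribute 0 (their future suitability is zero everywhere)."""
    if result.degenerate or not np.isfinite(result.S):
        return 0.0
    return max(float(result.S), 0.0)
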