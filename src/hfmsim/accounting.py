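"""Harvest Fraction of Management (HFM) accounting.

The HFM proxy for "continuation of forest management" relates total
harvested volume (H) to the total growing stock available (TBA) over the
Reference Period (RP): HFM_RP = H_RP / TBA_RP.  The allowable harvest of a
later Compliance Period (CP) is then HFM_RP × TBA_CP.  A run whose realized
CP harvest exceeds the projection books a computational carbon source; one
at or below it books a sink — without any change in management, purely from
the age-class dynamics.  Biomass expansion factors are omitted, so
"biomass" is growing-stock volume throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import Trajectory

SOURCE = "source"
SINK = "sink"

#: relative tolerance below which realized and projected CP totals count as
#: a tie (classified sink).  Reconstructing the harvest as (H/TBA)·stock
#: incurs last-bit rounding, so an exactly stationary forest would otherwise
#: be classified by floating-point noise.
TIE_RTOL = 1e-9


@dataclass(frozen=True)
class PeriodLayout:
    """Which simulation periods (1-based) form the RP and the CP.

    Defaults are RP = periods 1–2 (years 2000–2009) and CP = periods 5–6
    (2021–2030 in calendar terms, periods starting 2020 and 2025 here).
    """

    rp_periods: tuple[int, ...] = (1, 2)
    cp_periods: tuple[int, ...] = (5, 6)

    def __post_init__(self) -> None:
        rp, cp = set(self.rp_periods), set(self.cp_periods)
        if not rp or not cp:
            raise ValueError("RP and CP must be non-empty")
        if rp & cp:
            raise ValueError("RP and CP must be disjoint")
        if min(rp | cp) < 1:
            raise ValueError("period indices are 1-based")
        if max(rp) >= min(cp):
            raise ValueError("the RP must end before the CP starts")

    @property
    def max_period(self) -> int:
        return max(self.cp_periods)


@dataclass
class HFMAssessment:
    label: str
    mode: str
    hfm_rp: float
    realized_harvest_by_period: np.ndarray
    projected_harvest_by_period: np.ndarray
    realized_cp_total: float
    projected_cp_total: float
    classification: str

    def to_row(self) -> dict:
        return {
            "label": self.label,
            "mode": self.mode,
            "hfm_rp": self.hfm_rp,
            "realized_cp_total": self.realized_cp_total,
            "projected_cp_total": self.projected_cp_total,
            "classification": self.classification,
        }

    def comparison_frame(self) -> pd.DataFrame:
        n = len(self.realized_harvest_by_period)
        return pd.DataFrame(
            {
                "label": self.label,
                "mode": self.mode,
                "period_index": np.arange(1, n + 1),
                "realized": self.realized_harvest_by_period,
                "projected": self.projected_harvest_by_period,
            }
        )


def _idx(periods) -> np.ndarray:
    return np.asarray(periods, dtype=int) - 1


def compute_hfm(traj: Trajectory, layout: PeriodLayout = PeriodLayout()) -> float:
    """HFM_RP = Σ_RP harvested volume / Σ_RP period-start stock.

    Lies in [0, 1] because each period's harvest is part of that period's
    pre-harvest stock.
    """
    if traj.n_periods < layout.max_period:
        raise ValueError(
            f"trajectory has {traj.n_periods} periods but the layout needs {layout.max_period}"
        )
    h_rp = float(traj.harvested_volume[_idx(layout.rp_periods)].sum())
    tba_rp = float(traj.stock_pre_harvest[_idx(layout.rp_periods)].sum())
    if tba_rp == 0:
        raise ValueError("total biomass available over the RP is zero")
    return h_rp / tba_rp


def assess(traj: Trajectory, layout: PeriodLayout = PeriodLayout()) -> HFMAssessment:
    """Classify a run as computational source or sink.

    The projected (allowable) harvest of period p is HFM_RP times that
    period's pre-harvest stock; CP totals are compared by strict
    inequality, so a tie (up to relative rounding noise, ``TIE_RTOL``)
    counts as a sink.
    """
    hfm = compute_hfm(traj, layout)
    projected = hfm * traj.stock_pre_harvest
    cp = _idx(layout.cp_periods)
    realized_cp = float(traj.harvested_volume[cp].sum())
    projected_cp = float(projected[cp].sum())
    is_source = realized_cp - projected_cp > TIE_RTOL * max(abs(realized_cp), abs(projected_cp))
    return HFMAssessment(
        label=traj.label,
        mode=traj.mode,
        hfm_rp=hfm,
        realized_harvest_by_period=traj.harvested_volume.copy(),
        projected_harvest_by_period=projected,
        realized_cp_total=realized_cp,
        projected_cp_total=projected_cp,
        classification=SOURCE if is_source else SINK,
    )


def aggregate(assessments: list[HFMAssessment], trajs: list[Trajectory]) -> pd.DataFrame:
    """Per-period totals over all runs, plus the source/sink counts.

    Columns: period_index, year_start, total_area_km2, total_harvested_volume,
    total_growing_stock, n_sources, n_sinks (counts repeated on every row).
    """
    if not assessments or not trajs:
        raise ValueError("nothing to aggregate")
    n_periods = {t.n_periods for t in trajs}
    if len(n_periods) != 1:
        raise ValueError("all trajectories must have the same number of periods")
    harvested = np.sum([t.harvested_volume for t in trajs], axis=0)
    stock = np.sum([t.stock_pre_harvest for t in trajs], axis=0)
    area = np.sum([[s.total_area for s in t.states[:-1]] for t in trajs], axis=0)
    n_sources = sum(a.classification == SOURCE for a in assessments)
    return pd.DataFrame(
        {
            "period_index": np.arange(1, n_periods.pop() + 1),
            "year_start": trajs[0].period_years,
            "total_area_km2": area,
            "total_harvested_volume": harvested,
            "total_growing_stock": stock,
            "n_sources": n_sources,
            "n_sinks": len(assessments) - n_sources,
        }
    )
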