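"""Age-class transition dynamics under harvest-oldest-class management.

Each five-year step applies the textbook recipe: (1) harvest the whole
oldest age class, (2) move the harvested area into the youngest class,
(3) move every uncut class up by one.  On the area vector this is a pure
cyclic permutation, so total area is conserved exactly, 24 steps make one
full 120-year rotation back to the initial state, and the inverse
(backcasting) is the opposite rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import AgeClassDistribution, N_CLASSES
from .growth import GrowthParams, class_volumes

BASE_YEAR = 2000
PERIOD_YEARS = 5

FORECAST = "forecast"
BACKCAST = "backcast"


@dataclass(frozen=True)
class StepResult:
    """Outcome of one five-year step from a given period-start state."""

    next_state: AgeClassDistribution
    harvested_area: float
    harvested_volume: float
    stock_pre_harvest: float


@dataclass
class Trajectory:
    """One simulation run: period-start states plus per-period harvest records.

    ``states`` has one more entry than the per-period arrays (initial state
    plus the state after each step).  ``stock_pre_harvest`` is the
    period-start growing stock, including the class about to be cut.
    """

    label: str
    mode: str
    states: list[AgeClassDistribution]
    harvested_area: np.ndarray
    harvested_volume: np.ndarray
    stock_pre_harvest: np.ndarray
    period_years: np.ndarray

    @property
    def n_periods(self) -> int:
        return len(self.period_years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.label,
                "mode": self.mode,
                "period_index": np.arange(1, self.n_periods + 1),
                "year_start": self.period_years,
                "harvested_area_km2": self.harvested_area,
                "harvested_volume": self.harvested_volume,
                "stock_pre_harvest": self.stock_pre_harvest,
            }
        )

    def states_frame(self) -> pd.DataFrame:
        """Wide per-period state snapshots: one row per state, one column per class."""
        rows = {}
        for k, st in enumerate(self.states):
            rows[BASE_YEAR + PERIOD_YEARS * k] = st.areas
        frame = pd.DataFrame(rows).T
        frame.columns = [f"class_{i}" for i in range(1, N_CLASSES + 1)]
        frame.index.name = "year_start"
        return frame.reset_index()


def forward_transition_matrix() -> np.ndarray:
    """The 24×24 permutation matrix P with next_areas = P @ areas."""
    mat = np.zeros((N_CLASSES, N_CLASSES))
    mat[0, N_CLASSES - 1] = 1.0  # harvested oldest class regenerates as youngest
    for i in range(N_CLASSES - 1):
        mat[i + 1, i] = 1.0  # uncut classes age by one class
    return mat


def step_forward(state: AgeClassDistribution, params: GrowthParams = GrowthParams()) -> StepResult:
    """One harvest-and-age step; harvest is evaluated on the period-start state."""
    vol = class_volumes(params)
    harvested_area = float(state.areas[-1])
    next_areas = np.roll(state.areas, 1)
    next_state = state.replace(areas=next_areas, nominal_year=state.nominal_year + PERIOD_YEARS)
    return StepResult(
        next_state=next_state,
        harvested_area=harvested_area,
        harvested_volume=harvested_area * float(vol[-1]),
        stock_pre_harvest=float(state.areas @ vol),
    )


def step_backward(state: AgeClassDistribution) -> AgeClassDistribution:
    """Exact inverse of the forward permutation (backcasting one period)."""
    return state.replace(
        areas=np.roll(state.areas, -1), nominal_year=state.nominal_year - PERIOD_YEARS
    )


def initialize_state(
    dist: AgeClassDistribution, mode: str, backcast_steps: int = 4
) -> AgeClassDistribution:
    """Produce the year-2000 starting state.

    ``forecast``: the generated distribution is the year-2000 state.
    ``backcast``: the generated distribution represents year 2020 and is
    backcast ``backcast_steps`` periods so the projection starts in 2000.
    """
    if mode == FORECAST:
        return dist.replace(nominal_year=BASE_YEAR)
    if mode == BACKCAST:
        state = dist
        for _ in range(backcast_steps):
            state = step_backward(state)
        return state.replace(nominal_year=BASE_YEAR)
    raise ValueError(f"mode must be '{FORECAST}' or '{BACKCAST}', got {mode!r}")


def run_trajectory(
    initial: AgeClassDistribution,
    n_periods: int = 13,
    params: GrowthParams = GrowthParams(),
    label: str | None = None,
    mode: str = FORECAST,
) -> Trajectory:
    """Iterate ``step_forward`` for ``n_periods`` five-year periods from 2000."""
    if n_periods < 1:
        raise ValueError("n_periods must be at least 1")
    states = [initial.replace(nominal_year=BASE_YEAR)]
    harvested_area = np.empty(n_periods)
    harvested_volume = np.empty(n_periods)
    stock = np.empty(n_periods)
    for p in range(n_periods):
        res = step_forward(states[-1], params)
        harvested_area[p] = res.harvested_area
        harvested_volume[p] = res.harvested_volume
        stock[p] = res.stock_pre_harvest
        states.append(res.next_state)
    return Trajectory(
        label=initial.label if label is None else label,
        mode=mode,
        states=states,
        harvested_area=harvested_area,
        harvested_volume=harvested_volume,
        stock_pre_harvest=stock,
        period_years=BASE_YEAR + PERIOD_YEARS * np.arange(n_periods),
    )
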