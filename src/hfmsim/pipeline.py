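"""Orchestration of the full experiment.

Six descriptive age-class shapes are each sampled once; the sampled
distribution is treated as the state of the forest in both 2000 (forecast
variant) and 2020 (backcast variant, shifted back four periods), giving
12 simulation runs of 13 five-year periods (2000–2065).  Each run is
projected, assessed against its HFM_RP, and the per-period totals are
aggregated over all 120,000 km².
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .accounting import HFMAssessment, aggregate, assess
from .config import ScenarioConfig
from .distributions import AgeClassDistribution, sample_age_distribution
from .dynamics import BACKCAST, FORECAST, Trajectory, initialize_state, run_trajectory
from .growth import volume_table

log = logging.getLogger(__name__)


@dataclass
class ExperimentBundle:
    """All artifacts of one full experiment."""

    config: ScenarioConfig
    distributions: dict[str, AgeClassDistribution]
    trajectories: list[Trajectory]
    assessments: list[HFMAssessment]
    aggregate_frame: pd.DataFrame


def run_experiment(config: ScenarioConfig) -> ExperimentBundle:
    """Run the 6-shape × {forecast, backcast} experiment defined by ``config``."""
    distributions: dict[str, AgeClassDistribution] = {}
    trajectories: list[Trajectory] = []
    assessments: list[HFMAssessment] = []
    for spec in config.effective_catalog():
        # one sample per shape, reused as both the 2000 and the 2020 state
        dist = sample_age_distribution(spec, config.total_area_km2)
        distributions[spec.name] = dist
        for mode in (FORECAST, BACKCAST):
            initial = initialize_state(dist, mode, config.backcast_steps)
            traj = run_trajectory(
                initial, config.n_periods, config.growth, label=spec.name, mode=mode
            )
            result = assess(traj, config.layout)
            log.info(
                "%s/%s: hfm_rp=%.4f realized_cp=%.1f projected_cp=%.1f -> %s",
                spec.name, mode, result.hfm_rp,
                result.realized_cp_total, result.projected_cp_total,
                result.classification,
            )
            log.debug("%s/%s initial areas: %s", spec.name, mode, initial.areas)
            trajectories.append(traj)
            assessments.append(result)
    agg = aggregate(assessments, trajectories)
    return ExperimentBundle(config, distributions, trajectories, assessments, agg)


def write_outputs(bundle: ExperimentBundle, output_dir=None) -> Path:
    """Write all experiment CSVs; returns the output directory."""
    out = Path(output_dir if output_dir is not None else bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    for name, dist in bundle.distributions.items():
        dist.write_csv(out / f"distribution_{name}.csv")
    volume_table(bundle.config.growth).to_csv(out / "volume_table.csv", index=False)
    pd.concat([t.to_frame() for t in bundle.trajectories]).to_csv(
        out / "trajectories.csv", index=False
    )
    pd.DataFrame([a.to_row() for a in bundle.assessments]).to_csv(
        out / "assessments.csv", index=False
    )
    pd.concat([a.comparison_frame() for a in bundle.assessments]).to_csv(
        out / "harvest_comparison.csv", index=False
    )
    bundle.aggregate_frame.to_csv(out / "aggregate.csv", index=False)
    bundle.config.save(out / "config.yaml")
    return out


def sensitivity_suite(
    config: ScenarioConfig, shape_exponents=(1.0, 10.0)
) -> dict[float, ExperimentBundle]:
    """Re-run the experiment with alternative Chapman-Richards shape exponents.

    The structural invariants (area conservation, harvest/stock bounds,
    HFM in [0, 1]) hold for any positive exponent; sink/source signs may
    move, which is exactly the point of the sensitivity check.
    """
    bundles: dict[float, ExperimentBundle] = {}
    for exponent in shape_exponents:
        if not exponent > 0:
            raise ValueError(f"shape exponent must be positive, got {exponent}")
        growth = dataclasses.replace(config.growth, shape=float(exponent))
        cfg = dataclasses.replace(config, growth=growth)
        bundles[float(exponent)] = run_experiment(cfg)
    return bundles


def make_plots(bundle: ExperimentBundle, output_dir=None) -> Path:
    """Optional per-run harvest-comparison lines and aggregate bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(output_dir if output_dir is not None else bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    shapes = list(bundle.distributions)
    fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharex=True)
    for ax, name in zip(axes.ravel(), shapes):
        for a in bundle.assessments:
            if a.label != name:
                continue
            style = "-" if a.mode == FORECAST else "--"
            periods = range(1, len(a.realized_harvest_by_period) + 1)
            ax.plot(periods, a.realized_harvest_by_period, "k" + style, label=f"realized ({a.mode})")
            ax.plot(periods, a.projected_harvest_by_period, "r" + style, label=f"HFM projection ({a.mode})")
        ax.set_title(name)
        ax.set_xlabel("period")
    axes[0, 0].set_ylabel("harvested volume")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "harvest_comparison.png", dpi=150)
    plt.close(fig)

    agg = bundle.aggregate_frame
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.bar(agg["period_index"], agg["total_harvested_volume"], color="0.4")
    ax1.set_title("total harvested volume")
    ax2.bar(agg["period_index"], agg["total_growing_stock"], color="0.4")
    ax2.set_title("total growing stock")
    for ax in (ax1, ax2):
        ax.set_xlabel("period")
    fig.tight_layout()
    fig.savefig(out / "aggregate.png", dpi=150)
    plt.close(fig)
    return out
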