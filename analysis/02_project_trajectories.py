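#!/usr/bin/env python
"""Project all 12 simulations forward for 13 five-year periods (2000-2065).

Runs the harvest-oldest-class dynamics for each shape in both the forecast
and backcast initialization and writes the per-period harvests and stocks
to results/trajectories.csv.
"""

from pathlib import Path

import pandas as pd

from hfmsim import ScenarioConfig, run_experiment

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    bundle = run_experiment(ScenarioConfig())
    out = ROOT / "results"
    out.mkdir(parents=True, exist_ok=True)
    frame = pd.concat([t.to_frame() for t in bundle.trajectories])
    frame.to_csv(out / "trajectories.csv", index=False)

    print(f"{len(bundle.trajectories)} trajectories × "
          f"{bundle.trajectories[0].n_periods} periods -> {out / 'trajectories.csv'}")
    summary = (
        frame.groupby(["label", "mode"])
        .agg(total_harvest=("harvested_volume", "sum"),
             mean_stock=("stock_pre_harvest", "mean"))
        .round(1)
    )
    print("\nTotal harvested volume (2000-2065) and mean period-start stock:")
    print(summary.to_string())
    print("\nHarvest timing varies strongly with the initial age structure; "
          "total area stays at 10,000 km² in every period of every run.")


if __name__ == "__main__":
    main()
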