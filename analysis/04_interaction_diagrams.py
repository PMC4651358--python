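"""Attraction/repulsion interaction diagrams from the fitted models.

For each focal species and species pair, compute the median predicted
change in separation versus current separation (negative = attraction,
positive = repulsion) for the nearest neighbour, write tidy CSV curves,
and plot the four-panel figure.
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import swarmstate as ss
from swarmstate.diagrams import curve_to_frame
from swarmstate.rbf import RBFModel
from swarmstate.tracks_io import Species

OUT = Path(__file__).resolve().parent.parent / "results"
GRID = np.arange(0.0, 301.0, 5.0)


def main() -> None:
    tracks = ss.read_tracks(OUT / "tracks_observed.csv")
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    frames = []
    for row_i, species in enumerate((Species.SHEEP, Species.DEER)):
        ds = ss.assemble_dataset(tracks, species, m=1, n=1)
        model = RBFModel.load(OUT / f"model_{species.value}.json")
        for col_i, block in enumerate(("conspecific", "heterospecific")):
            pairs = ss.separation_pairs(model, ds, 1, block,
                                        labels={"focal": species.value})
            cur = ss.interaction_curve(pairs, GRID, 10.0, min_count=30)
            frames.append(curve_to_frame(cur))
            ax = axes[row_i, col_i]
            ax.axhline(0, color="grey", lw=0.6)
            ax.plot(cur.grid_m[cur.defined], cur.median[cur.defined],
                    color="red", label="nearest neighbour")
            ax.set_title(f"{species.value} vs {block}")
            crossings = [f"{c:.0f}" for c in
                         _crossings(cur.grid_m, cur.median)]
            print(f"{species.value}/{block}: zero crossing(s) at "
                  f"{', '.join(crossings) or 'none'} m")
    for ax in axes[-1]:
        ax.set_xlabel("separation distance (m)")
    for ax in axes[:, 0]:
        ax.set_ylabel("predicted change in\nseparation (m)")
    fig.tight_layout()
    fig.savefig(OUT / "interaction_diagrams.png", dpi=150)
    import pandas as pd
    pd.concat(frames, ignore_index=True).to_csv(OUT / "interaction_curves.csv",
                                                index=False)
    print(f"curves and figure written to {OUT}")


def _crossings(grid, median):
    from swarmstate.diagrams import _zero_crossings
    return _zero_crossings(grid, median)


if __name__ == "__main__":
    main()
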