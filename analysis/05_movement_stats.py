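"""Descriptive movement statistics.

Daily distance travelled with the species x season mixed model (generated
at the study's effect magnitudes so both seasons are represented), the
least-squares means and Bonferroni pairwise comparisons, monthly RMS
predictability of the fitted one-step models, and the neighbour-density
function D(k).
"""

from pathlib import Path

import numpy as np

import swarmstate as ss
from swarmstate.rbf import RBFModel
from swarmstate.tracks_io import Species

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 9


def main() -> None:
    # daily-distance mixed model on a full year of animal-days
    df = ss.simulate_daily_distances(seed=SEED, days_per_season=120)
    fit = ss.fit_distance_lmm(df)
    fit.fixed_effects.to_csv(OUT / "lmm_fixed_effects.csv")
    fit.ls_means.to_csv(OUT / "lmm_ls_means.csv", index=False)
    fit.pairwise.to_csv(OUT / "lmm_pairwise.csv", index=False)
    print("fixed effects (m/day):")
    print(fit.fixed_effects.round(2).to_string())
    print(f"animal variance {fit.var_animal:.0f}, residual {fit.var_residual:.0f}, "
          f"random-effect chi2(1) = {fit.lr_chi2:.1f}")

    # monthly RMS of the fitted one-step models on the simulated tracks
    tracks = ss.read_tracks(OUT / "tracks_observed.csv")
    entries = []
    for species in (Species.SHEEP, Species.DEER):
        model = RBFModel.load(OUT / f"model_{species.value}.json")
        months = sorted({t.month for tr in tracks for t in tr.times})
        for month in months:
            try:
                ds = ss.assemble_dataset(tracks, species, m=1, n=1,
                                         months=[month])
            except ValueError:
                ds = None
            entries.append((month, species, model, ds))
    rms = ss.monthly_rms(entries)
    rms.to_csv(OUT / "monthly_rms.csv", index=False)
    print(rms.round(2).to_string(index=False))

    # neighbour-density function on the final snapshot
    snap = ss.snapshots_from_tracks(tracks)[-1]
    dk = {k: ss.density_function(snap, k) for k in range(1, 7)}
    print("D(k), m:", {k: round(v, 1) for k, v in dk.items()})
    import pandas as pd
    pd.Series(dk, name="D_k_m").rename_axis("k").to_csv(OUT / "density_function.csv")


if __name__ == "__main__":
    main()
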