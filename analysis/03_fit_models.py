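"""Fit the rotation-equivariant one-step predictors F (sheep) and G (deer).

For each focal species: draw a candidate basis dictionary, run greedy
description-length selection, report model size / DL / one-step RMS, and
serialise the fitted models as JSON.
"""

from pathlib import Path

import swarmstate as ss
from swarmstate.tracks_io import Species

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 5


def main() -> None:
    tracks = ss.read_tracks(OUT / "tracks_observed.csv")
    for species in (Species.SHEEP, Species.DEER):
        ds = ss.assemble_dataset(tracks, species, m=1, n=1)
        dic = ss.candidate_dictionary(ds, 60, seed=SEED)
        model = ss.select_model(ds, dic, max_size=20)
        model.save(OUT / f"model_{species.value}.json")
        print(f"{species.value}: {len(model.bases)} bases "
              f"(+{model.dim_v} linear), DL={model.mdl_bits:.1f} nats, "
              f"one-step RMS={model.rms_m:.2f} m, n={model.training_n}")


if __name__ == "__main__":
    main()
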