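"""Build the supervised one-step datasets from the observed tracks.

Reads the collared-animal tracks written by 01_simulate.py, assembles the
interaction-vector datasets for each focal species (m = 1 conspecific,
n = 1 heterospecific neighbour) and reports the skip histogram — how many
(animal, hour) candidates were lost to missing fixes or missing
neighbours.
"""

from pathlib import Path

import swarmstate as ss
from swarmstate.tracks_io import Species

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    tracks = ss.read_tracks(OUT / "tracks_observed.csv")
    for species in (Species.SHEEP, Species.DEER):
        ds = ss.assemble_dataset(tracks, species, m=1, n=1)
        df = ds.to_frame()
        df.to_csv(OUT / f"dataset_{species.value}.csv", index=False)
        print(f"{species.value}: {len(ds)} rows "
              f"(skips: { {k: v for k, v in ds.skip_counts.items() if v} })")


if __name__ == "__main__":
    main()
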