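"""Simulate the study system: environment, two-species swarm, GPS collars.

Generates the default study conditions (60 sheep + 20 red deer on a
~1 km² plot, hourly fixes over 240 h), writes the vegetation raster, the
true tracks and the GPS-noised observations of the collared subset
(23 ewes + 17 hinds) under ``results/``.
"""

from pathlib import Path

import swarmstate as ss

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
HOURS = 240


def main() -> None:
    OUT.mkdir(exist_ok=True)
    env = ss.simulate_environment((1000.0, 1040.0), 20.0, 6, seed=SEED,
                                  hours=HOURS)
    ss.write_raster_ascii(env, OUT / "vegetation.asc")

    params = ss.SwarmParams()
    tracks = ss.simulate_swarm(params, env, hours=HOURS, seed=SEED + 1)
    ss.write_tracks(tracks, OUT / "tracks_true.csv")

    collared = [t for t in tracks if t.species.value == "sheep"][:23] + \
               [t for t in tracks if t.species.value == "deer"][:17]
    obs = ss.observe(collared, ss.ObservationParams(), seed=SEED + 2)
    ss.write_tracks(obs, OUT / "tracks_observed.csv")

    print(f"simulated {len(tracks)} animals for {HOURS} h; "
          f"{len(obs)} collared tracks written to {OUT}")


if __name__ == "__main__":
    main()
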