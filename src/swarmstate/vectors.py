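"""Interaction vectors and the supervised one-step dataset.

For a focal animal i at time t the interaction vector stacks the relative
offsets (focal minus neighbour) to its m nearest conspecifics and n nearest
heterospecifics, ordered by increasing distance within each species block::

    v(s_i(t)) = (s_i - s_k(1), ..., s_i - s_k(m); s_i - d_h(1), ..., s_i - d_h(n))

Location covariates w (one-hot vegetation, standardised thermal stress,
season indicator — as configured) describe where the focal animal stands.
The supervised target is the next-hour position; rows lacking a full
neighbour set or a t+1 fix are skipped, never padded, and every skip is
counted by reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from swarmstate.tracks_io import (
    EnvironmentRaster,
    RasterLookupError,
    Species,
    Track,
    point_lookup,
    season_of_month,
    SEASON_RULE_DEFAULT,
)

__all__ = [
    "Snapshot", "InteractionRow", "InteractionDataset",
    "nearest_neighbours", "build_row", "rotate_row", "assemble_dataset",
    "snapshots_from_tracks", "InsufficientNeighboursError",
]

#: Anticlockwise 90-degree rotation.
ROT90 = np.array([[0.0, -1.0], [1.0, 0.0]])


class InsufficientNeighboursError(ValueError):
    """Fewer than k candidates of the requested species in the snapshot."""


@dataclass
class Snapshot:
    """All synchronous positions at one time."""

    time: pd.Timestamp
    positions: Mapping[str, np.ndarray]   # animal_id -> (2,) easting/northing
    species: Mapping[str, Species]

    def __post_init__(self) -> None:
        if set(self.positions) != set(self.species):
            raise ValueError("positions and species keys differ")
        for aid, p in self.positions.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (2,) or not np.all(np.isfinite(p)):
                raise ValueError(f"{aid}: bad position {p}")


@dataclass
class InteractionRow:
    """One supervised training row.

    ``v`` has length 2(m+n): m conspecific then n heterospecific offset
    pairs, each (focal - neighbour), distance-ordered within block.
    ``position`` is the focal animal's current position s_i(t) and ``y`` its
    position at t+1; the regression target is the displacement y - position.
    """

    target_id: str
    time: pd.Timestamp
    v: np.ndarray
    w: np.ndarray
    y: np.ndarray
    position: np.ndarray
    m: int
    n: int
    neighbour_ids: tuple[str, ...] = ()
    habitat: str | None = None

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.v.shape != (2 * (self.m + self.n),):
            raise ValueError(f"v must have length 2(m+n)={2 * (self.m + self.n)}")

    @property
    def displacement(self) -> np.ndarray:
        return self.y - self.position

    def offsets(self, block: str = "conspecific") -> np.ndarray:
        """(k, 2) offsets of one species block, distance-ordered."""
        pairs = self.v.reshape(-1, 2)
        if block == "conspecific":
            return pairs[: self.m]
        if block == "heterospecific":
            return pairs[self.m:]
        raise ValueError(f"unknown block {block!r}")


@dataclass
class InteractionDataset:
    """Stacked rows sharing (focal species, m, n, covariate spec)."""

    rows: list[InteractionRow]
    focal_species: Species
    m: int
    n: int
    covariate_spec: tuple[str, ...] = ()
    skip_counts: Mapping[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def inputs(self) -> np.ndarray:
        """(N, 2(m+n)+|w|) design inputs: interaction vector then covariates."""
        return np.array([np.concatenate([r.v, r.w]) for r in self.rows])

    def displacements(self) -> np.ndarray:
        return np.array([r.displacement for r in self.rows])

    def to_frame(self) -> pd.DataFrame:
        """Flat table serialisation (schema metadata in ``attrs``)."""
        cols = {}
        d = 2 * (self.m + self.n)
        V = np.array([r.v for r in self.rows])
        for j in range(d):
            cols[f"v{j}"] = V[:, j]
        if self.rows and self.rows[0].w.size:
            W = np.array([r.w for r in self.rows])
            for j in range(W.shape[1]):
                cols[f"w{j}"] = W[:, j]
        df = pd.DataFrame({
            "target_id": [r.target_id for r in self.rows],
            "time": [r.time for r in self.rows],
            **cols,
            "x": [r.position[0] for r in self.rows],
            "y_pos": [r.position[1] for r in self.rows],
            "next_x": [r.y[0] for r in self.rows],
            "next_y": [r.y[1] for r in self.rows],
        })
        df.attrs.update(m=self.m, n=self.n, focal_species=self.focal_species.value,
                        covariate_spec=self.covariate_spec)
        return df


def nearest_neighbours(
    snapshot: Snapshot,
    target_id: str,
    species_filter: Species,
    k: int,
) -> list[tuple[str, float]]:
    """k nearest animals of one species, ascending distance.

    The focal animal is never a candidate. Exact distance ties break by
    animal_id lexicographic order so results are deterministic.
    """
    if target_id not in snapshot.positions:
        raise KeyError(f"{target_id} not in snapshot")
    p0 = np.asarray(snapshot.positions[target_id], dtype=float)
    cand = sorted(
        (float(np.linalg.norm(np.asarray(snapshot.positions[a], dtype=float) - p0)), a)
        for a, sp in snapshot.species.items()
        if a != target_id and sp == species_filter
    )
    if len(cand) < k:
        raise InsufficientNeighboursError(
            f"{target_id}: {len(cand)} candidates of {species_filter.value}, need {k}"
        )
    return [(a, d) for d, a in cand[:k]]


def _covariates(
    point: np.ndarray,
    time: pd.Timestamp,
    env: EnvironmentRaster | None,
    covariate_spec: Sequence[str],
    season_rule: Mapping[int, str],
    thermal_stats: tuple[float, float] | None,
) -> np.ndarray:
    parts: list[float] = []
    veg = thermal = None
    if ("vegetation" in covariate_spec) or ("thermal_stress" in covariate_spec):
        if env is None:
            raise ValueError("covariate_spec needs an environment raster")
        veg, thermal = point_lookup(
            env, (float(point[0]), float(point[1])),
            time if "thermal_stress" in covariate_spec else None,
        )
    if "vegetation" in covariate_spec:
        onehot = [1.0 if c == veg else 0.0 for c in env.vegetation_classes]
        parts.extend(onehot)
    if "thermal_stress" in covariate_spec:
        if thermal is None:
            raise RasterLookupError("no thermal value at this time")
        if thermal_stats is not None:
            mu, sd = thermal_stats
            thermal = (thermal - mu) / (sd if sd > 0 else 1.0)
        parts.append(float(thermal))
    if "season" in covariate_spec:
        parts.append(1.0 if season_of_month(time.month, season_rule) == "winter" else 0.0)
    return np.asarray(parts, dtype=float)


def build_row(
    snapshot_t: Snapshot,
    snapshot_t1: Snapshot,
    target_id: str,
    m: int,
    n: int,
    env: EnvironmentRaster | None = None,
    covariate_spec: Sequence[str] = (),
    season_rule: Mapping[int, str] | None = None,
    thermal_stats: tuple[float, float] | None = None,
) -> InteractionRow:
    """Build one supervised row for ``target_id`` at snapshot_t's time."""
    season_rule = SEASON_RULE_DEFAULT if season_rule is None else season_rule
    if target_id not in snapshot_t1.positions:
        raise KeyError(f"{target_id} missing at t+1")
    focal_sp = snapshot_t.species[target_id]
    other_sp = Species.DEER if focal_sp == Species.SHEEP else Species.SHEEP
    p0 = np.asarray(snapshot_t.positions[target_id], dtype=float)

    con = nearest_neighbours(snapshot_t, target_id, focal_sp, m)
    het = nearest_neighbours(snapshot_t, target_id, other_sp, n)
    offsets = [p0 - np.asarray(snapshot_t.positions[a], dtype=float) for a, _ in con + het]
    v = np.concatenate(offsets)
    w = _covariates(p0, snapshot_t.time, env, covariate_spec, season_rule, thermal_stats)
    return InteractionRow(
        target_id=target_id, time=snapshot_t.time, v=v, w=w,
        y=np.asarray(snapshot_t1.positions[target_id], dtype=float),
        position=p0, m=m, n=n,
        neighbour_ids=tuple(a for a, _ in con + het),
    )


def rotate_row(row: InteractionRow, direction: str = "+90") -> InteractionRow:
    """Rotate every 2-D offset and the displacement; scalars unchanged.

    ``direction`` is "+90" (anticlockwise) or "-90". The next position is
    rotated about the focal animal's current position, so the displacement
    rotates while the current position stays put. rotate(+90) then
    rotate(-90) is the exact identity.
    """
    if direction == "+90":
        R = ROT90
    elif direction == "-90":
        R = ROT90.T
    else:
        raise ValueError(f"direction must be '+90' or '-90', got {direction!r}")
    pairs = row.v.reshape(-1, 2) @ R.T
    disp = R @ (row.y - row.position)
    return InteractionRow(
        target_id=row.target_id, time=row.time,
        v=pairs.ravel(), w=row.w.copy(),
        y=row.position + disp, position=row.position.copy(),
        m=row.m, n=row.n, neighbour_ids=row.neighbour_ids, habitat=row.habitat,
    )


def snapshots_from_tracks(tracks: Sequence[Track]) -> list[Snapshot]:
    """Synchronous snapshots at every hour where >= 2 animals have fixes."""
    by_time: dict[pd.Timestamp, tuple[dict, dict]] = {}
    for tr in tracks:
        obs = tr.observed
        for t, p in zip(tr.times[obs], tr.positions[obs]):
            pos, sp = by_time.setdefault(t, ({}, {}))
            pos[tr.animal_id] = p
            sp[tr.animal_id] = tr.species
    out = []
    for t in sorted(by_time):
        pos, sp = by_time[t]
        if len(pos) >= 2:
            out.append(Snapshot(time=t, positions=pos, species=sp))
    return out


def assemble_dataset(
    tracks: Sequence[Track],
    focal_species: Species,
    m: int,
    n: int,
    env: EnvironmentRaster | None = None,
    covariate_spec: Sequence[str] = (),
    months: Iterable[int] | None = None,
    season_rule: Mapping[int, str] | None = None,
) -> InteractionDataset:
    """One row per (focal animal, hour) with full neighbour sets and a t+1 fix.

    Rows failing any availability requirement are skipped and counted by
    reason (``insufficient_neighbours``, ``missing_next_fix``,
    ``out_of_extent``, ``month_filtered``); row count plus skip counts equals
    the number of candidate (animal, hour) pairs. Thermal stress, when
    requested, is standardised to zero mean / unit variance over the
    assembled training window.
    """
    covariate_spec = tuple(covariate_spec)
    snaps = snapshots_from_tracks(tracks)
    index = {s.time: s for s in snaps}
    skip = {"insufficient_neighbours": 0, "missing_next_fix": 0,
            "out_of_extent": 0, "month_filtered": 0}

    thermal_stats = None
    if "thermal_stress" in covariate_spec:
        if env is None or env.thermal_stress is None:
            raise ValueError("thermal_stress covariate needs a raster with a thermal stack")
        thermal_stats = (float(env.thermal_stress.mean()), float(env.thermal_stress.std()))

    rows: list[InteractionRow] = []
    for s in snaps:
        t1 = index.get(s.time + pd.Timedelta(hours=1))
        focal_ids = [a for a, sp in s.species.items() if sp == focal_species]
        for aid in sorted(focal_ids):
            if months is not None and s.time.month not in set(months):
                skip["month_filtered"] += 1
                continue
            if t1 is None or aid not in t1.positions:
                skip["missing_next_fix"] += 1
                continue
            try:
                rows.append(build_row(s, t1, aid, m, n, env, covariate_spec,
                                      season_rule, thermal_stats))
            except InsufficientNeighboursError:
                skip["insufficient_neighbours"] += 1
            except RasterLookupError:
                skip["out_of_extent"] += 1

    if not rows:
        raise ValueError(f"empty dataset; skip histogram: {skip}")
    return InteractionDataset(rows=rows, focal_species=focal_species, m=m, n=n,
                              covariate_spec=covariate_spec, skip_counts=skip)
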