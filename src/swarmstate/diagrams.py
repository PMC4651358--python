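"""Attraction/repulsion interaction diagrams.

For each training row we compute the mean separation Δ between the focal
animal and its n' nearest neighbours of one species block, and the
predicted separation p between the model's one-step prediction and those
same neighbours (held at their current positions). The scatter of Δ against
p − Δ measures the predicted change in separation as a function of current
separation: negative values are attraction, positive repulsion.

The curve summarises that scatter: at each grid distance, rows are weighted
by a Gaussian kernel in Δ, a Gaussian kernel density is formed over the
predicted changes, and its median is reported. Points supported by fewer
than ``min_count`` rows inside one bandwidth are left undefined. The sums
in the separation definitions are divided by n' (the quantity is described
as a mean separation) so curves for different n' share a distance scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from swarmstate.rbf import RBFModel, predict_displacements
from swarmstate.vectors import InteractionDataset, InteractionRow

__all__ = [
    "SeparationPair", "InteractionCurve", "mean_separation",
    "predicted_separation", "separation_pairs", "interaction_curve",
    "compare_curves", "curve_to_frame",
]


@dataclass(frozen=True)
class SeparationPair:
    """One (current separation, predicted change in separation) point."""

    delta_m: float
    pred_change_m: float
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.delta_m <= 0:
            raise ValueError("delta_m must be positive")
        if not np.isfinite(self.pred_change_m):
            raise ValueError("pred_change_m must be finite")


@dataclass
class InteractionCurve:
    """Median predicted change in separation on a distance grid.

    ``median`` is NaN where fewer than ``min_count`` pairs fall within one
    bandwidth of the grid point. Negative medians mean attraction, positive
    repulsion.
    """

    grid_m: np.ndarray
    median: np.ndarray
    count: np.ndarray
    bandwidth_m: float
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_m = np.asarray(self.grid_m, dtype=float)
        if np.any(np.diff(self.grid_m) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.median)


def mean_separation(row: InteractionRow, n_prime: int,
                    block: str = "conspecific") -> float:
    """Mean distance to the n' nearest neighbours of one species block."""
    offs = row.offsets(block)
    if not (1 <= n_prime <= len(offs)):
        raise ValueError(f"n_prime must be in 1..{len(offs)}")
    return float(np.linalg.norm(offs[:n_prime], axis=1).mean())


def predicted_separation(model: RBFModel, row: InteractionRow, n_prime: int,
                         block: str = "conspecific") -> float:
    """Mean distance from the predicted next position to the n' neighbours.

    Neighbours are held at their time-t positions, so a zero-displacement
    prediction gives exactly the current mean separation.
    """
    from swarmstate.rbf import predict
    offs = row.offsets(block)
    if not (1 <= n_prime <= len(offs)):
        raise ValueError(f"n_prime must be in 1..{len(offs)}")
    pred = predict(model, row)
    neigh = row.position[None, :] - offs[:n_prime]     # offset = focal - neighbour
    return float(np.linalg.norm(pred[None, :] - neigh, axis=1).mean())


def separation_pairs(
    model: RBFModel,
    dataset: InteractionDataset,
    n_prime: int,
    block: str = "conspecific",
    labels: Mapping[str, str] | None = None,
) -> list[SeparationPair]:
    """All (Δ, p − Δ) pairs for a dataset under a fitted model (vectorised)."""
    disp = predict_displacements(model, dataset)
    labels = dict(labels or {})
    labels.setdefault("block", block)
    labels.setdefault("n_prime", str(n_prime))
    out = []
    for row, d in zip(dataset.rows, disp):
        offs = row.offsets(block)[:n_prime]
        if len(offs) < n_prime:
            continue
        delta = float(np.linalg.norm(offs, axis=1).mean())
        neigh = row.position[None, :] - offs
        pred = row.position + d
        p = float(np.linalg.norm(pred[None, :] - neigh, axis=1).mean())
        out.append(SeparationPair(delta_m=delta, pred_change_m=p - delta, labels=labels))
    return out


def _kde_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Median of the weighted Gaussian kernel density over ``values``."""
    w = weights / weights.sum()
    mu = float(np.sum(w * values))
    sd = float(np.sqrt(max(np.sum(w * (values - mu) ** 2), 0.0)))
    q75, q25 = np.quantile(values, [0.75, 0.25])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        return mu                      # degenerate: all mass at one value
    n_eff = float(w.sum() ** 2 / np.sum(w**2))
    h = 0.9 * spread * n_eff ** (-0.2)   # Silverman's rule

    def cdf_minus_half(t: float) -> float:
        return float(np.sum(w * norm.cdf((t - values) / h))) - 0.5

    lo = float(values.min() - 10 * h)
    hi = float(values.max() + 10 * h)
    return float(brentq(cdf_minus_half, lo, hi, xtol=1e-9))


def interaction_curve(
    pairs: Sequence[SeparationPair],
    grid_m: np.ndarray | None = None,
    bandwidth_m: float = 10.0,
    min_count: int = 30,
    labels: Mapping[str, str] | None = None,
) -> InteractionCurve:
    """Median predicted change in separation versus separation distance."""
    if not pairs:
        raise ValueError("no pairs")
    if bandwidth_m <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_m is None:
        grid_m = np.arange(0.0, 300.0 + 1e-9, 5.0)
    grid_m = np.asarray(grid_m, dtype=float)

    delta = np.array([p.delta_m for p in pairs])
    change = np.array([p.pred_change_m for p in pairs])
    median = np.full(len(grid_m), np.nan)
    count = np.zeros(len(grid_m), dtype=int)

    for i, d0 in enumerate(grid_m):
        z = (delta - d0) / bandwidth_m
        inside = np.abs(z) <= 1.0
        count[i] = int(inside.sum())
        if count[i] < min_count:
            continue
        window = np.abs(z) <= 4.0
        wts = np.exp(-0.5 * z[window] ** 2)
        median[i] = _kde_median(change[window], wts)

    if not np.any(~np.isnan(median)):
        import warnings
        warnings.warn("interaction curve undefined everywhere (too few pairs)",
                      stacklevel=2)
    lab = dict(labels or (pairs[0].labels if pairs else {}))
    return InteractionCurve(grid_m=grid_m, median=median, count=count,
                            bandwidth_m=bandwidth_m, labels=lab)


def _zero_crossings(grid: np.ndarray, y: np.ndarray) -> list[float]:
    """Sign-change distances of a (possibly partially undefined) curve."""
    ok = ~np.isnan(y)
    g, v = grid[ok], y[ok]
    out = []
    for i in range(len(v) - 1):
        if v[i] == 0.0:
            out.append(float(g[i]))
        elif v[i] * v[i + 1] < 0:
            t = v[i] / (v[i] - v[i + 1])
            out.append(float(g[i] + t * (g[i + 1] - g[i])))
    if len(v) and v[-1] == 0.0:
        out.append(float(g[-1]))
    return out


def compare_curves(
    curves: Sequence[InteractionCurve],
    pairs_per_curve: Sequence[Sequence[SeparationPair]] | None = None,
    n_boot: int = 200,
    seed: int = 0,
    band: float = 0.95,
) -> dict:
    """Per-distance differences, zero crossings and optional bootstrap bands.

    Differences are relative to the first curve. When the raw pairs are
    supplied, pairs are resampled with replacement ``n_boot`` times per
    curve and percentile bands of the curve returned.
    """
    grids = [c.grid_m for c in curves]
    for g in grids[1:]:
        if len(g) != len(grids[0]) or not np.allclose(g, grids[0]):
            raise ValueError("curves must share a common grid")
    base = curves[0]
    result: dict = {
        "grid_m": base.grid_m,
        "differences": [c.median - base.median for c in curves],
        "zero_crossings": [_zero_crossings(c.grid_m, c.median) for c in curves],
    }
    if pairs_per_curve is not None:
        rng = np.random.default_rng(seed)
        alpha = (1.0 - band) / 2.0
        bands = []
        for c, pairs in zip(curves, pairs_per_curve):
            pairs = list(pairs)
            boot = np.full((n_boot, len(c.grid_m)), np.nan)
            for b in range(n_boot):
                idx = rng.integers(0, len(pairs), size=len(pairs))
                resampled = [pairs[i] for i in idx]
                bc = interaction_curve(resampled, grid_m=c.grid_m,
                                       bandwidth_m=c.bandwidth_m,
                                       min_count=1, labels=c.labels)
                boot[b] = bc.median
            with np.errstate(all="ignore"):
                lo = np.nanquantile(boot, alpha, axis=0)
                hi = np.nanquantile(boot, 1 - alpha, axis=0)
            bands.append((lo, hi))
        result["bands"] = bands
    return result


def curve_to_frame(curve: InteractionCurve) -> pd.DataFrame:
    """Tidy-table serialisation of a curve."""
    df = pd.DataFrame({
        "distance_m": curve.grid_m,
        "median_change_m": curve.median,
        "count": curve.count,
    })
    for k, v in curve.labels.items():
        df[k] = v
    return df
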