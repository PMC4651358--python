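"""Descriptive movement statistics.

* Daily distance travelled per animal-day (sum of consecutive-fix
  step lengths within a calendar day), analysed with a linear mixed model:
  species, season and their interaction as fixed effects, animal identity
  as a random intercept, REML estimation, Satterthwaite degrees of freedom
  for the fixed-effect t-tests, a likelihood-ratio chi-square for the random
  intercept, least-squares means per species x season cell and
  Bonferroni-corrected pairwise comparisons.
* The neighbour-density function D(k): population-average distance to the
  k-th nearest neighbour in a synchronous snapshot — a circle of diameter
  below D(k) centred on an animal is expected to hold only k-1 others.
* Monthly RMS predictability of the one-step model per (month, species)
  stratum.

The mixed model is estimated by statsmodels MixedLM; the Satterthwaite
approximation, the REML likelihood-ratio test and the LS-mean tables are
computed here from the closed-form REML quantities of the random-intercept
model (variance V_g = sigma_e^2 I + sigma_a^2 J per animal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from swarmstate.rbf import RBFModel, rms_error
from swarmstate.tracks_io import SEASON_RULE_DEFAULT, Species, Track, season_of_month
from swarmstate.vectors import InteractionDataset, Snapshot

__all__ = [
    "DailyDistanceRecord", "LMMFit", "daily_distance", "daily_distance_table",
    "fit_distance_lmm", "density_function", "monthly_rms",
]


@dataclass(frozen=True)
class DailyDistanceRecord:
    animal_id: str
    species: Species
    date: pd.Timestamp
    season: str
    distance_m: float

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ValueError("distance must be >= 0")


@dataclass
class LMMFit:
    """Mixed-model summary for daily distance travelled."""

    fixed_effects: pd.DataFrame      # estimate, se, t, df, p per term
    var_animal: float
    var_residual: float
    lr_chi2: float                   # random intercept vs none, REML LRT
    lr_p: float
    ls_means: pd.DataFrame           # species, season, mean, se, df, ci_lo, ci_hi
    pairwise: pd.DataFrame           # 6 cell contrasts, Bonferroni p
    n_obs: int
    n_animals: int
    converged: bool = True
    singular: bool = False


# ---------------------------------------------------------------------------
# Daily distances


def daily_distance(track: Track) -> list[DailyDistanceRecord]:
    """Distance travelled per calendar day for one animal.

    Sums Euclidean distances between consecutive observed fixes whose both
    endpoints fall on the same day (days break at midnight; a step spanning
    midnight contributes to neither day). Days with fewer than two fixes
    are skipped.
    """
    obs = track.observed
    times = track.times[obs]
    pos = track.positions[obs]
    out = []
    if len(times) < 2:
        return out
    dates = times.normalize()
    for day in dates.unique():
        sel = dates == day
        if sel.sum() < 2:
            continue
        p = pos[sel]
        dist = float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
        out.append(DailyDistanceRecord(
            animal_id=track.animal_id, species=track.species,
            date=pd.Timestamp(day),
            season=season_of_month(pd.Timestamp(day).month),
            distance_m=dist,
        ))
    return out


def daily_distance_table(
    tracks: Sequence[Track],
    season_rule: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Stacked animal-day records as a tidy table."""
    rule = SEASON_RULE_DEFAULT if season_rule is None else season_rule
    recs = []
    for tr in tracks:
        for r in daily_distance(tr):
            recs.append({
                "animal_id": r.animal_id, "species": r.species.value,
                "date": r.date, "season": season_of_month(r.date.month, rule),
                "distance_m": r.distance_m,
            })
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Mixed model with Satterthwaite df

_CELLS = [("sheep", "summer"), ("deer", "summer"), ("sheep", "winter"), ("deer", "winter")]


def _cell_vector(species: str, season: str) -> np.ndarray:
    d = 1.0 if species == "deer" else 0.0
    w = 1.0 if season == "winter" else 0.0
    return np.array([1.0, d, w, d * w])


def _group_blocks(df: pd.DataFrame) -> tuple[list[np.ndarray], list[np.ndarray]]:
    Xs, ys = [], []
    deer = (df["species"] == "deer").astype(float).to_numpy()
    wint = (df["season"] == "winter").astype(float).to_numpy()
    X = np.column_stack([np.ones(len(df)), deer, wint, deer * wint])
    y = df["distance_m"].to_numpy(dtype=float)
    for _, idx in df.groupby("animal_id").indices.items():
        Xs.append(X[idx])
        ys.append(y[idx])
    return Xs, ys


def _reml_quantities(Xs, ys, va: float, ve: float):
    """Closed-form REML pieces at variance components (va, ve).

    Returns (loglike, beta_hat, C) with C = Cov(beta_hat) = (sum X'V^-1X)^-1.
    """
    p = Xs[0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdetV = 0.0
    for Xg, yg in zip(Xs, ys):
        ng = len(yg)
        a = va / (ve + ng * va)
        # V^-1 x = (x - a * J x) / ve
        Xv = (Xg - a * Xg.sum(axis=0)) / ve
        yv = (yg - a * yg.sum()) / ve
        XtVX += Xg.T @ Xv
        XtVy += Xg.T @ yv
        logdetV += (ng - 1) * np.log(ve) + np.log(ve + ng * va)
    C = np.linalg.inv(XtVX)
    beta = C @ XtVy
    quad = 0.0
    for Xg, yg in zip(Xs, ys):
        ng = len(yg)
        a = va / (ve + ng * va)
        r = yg - Xg @ beta
        quad += (r @ r - a * r.sum() ** 2) / ve
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    N = sum(len(y) for y in ys)
    ll = -0.5 * (logdetV + logdetXtVX + quad + (N - p) * np.log(2 * np.pi))
    return ll, beta, C


def _satterthwaite_df(Xs, ys, va: float, ve: float, c: np.ndarray) -> float:
    """Approximate df of the t-statistic for contrast c'beta."""

    def vfun(theta):
        _, _, C = _reml_quantities(Xs, ys, max(theta[0], 0.0), max(theta[1], 1e-12))
        return float(c @ C @ c)

    def llfun(theta):
        ll, _, _ = _reml_quantities(Xs, ys, max(theta[0], 0.0), max(theta[1], 1e-12))
        return ll

    theta = np.array([va, ve])
    h = np.maximum(1e-5 * np.abs(theta), 1e-10)

    grad = np.zeros(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        grad[i] = (vfun(theta + e) - vfun(theta - e)) / (2 * h[i])

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2); ei[i] = h[i]
            ej = np.zeros(2); ej[j] = h[j]
            H[i, j] = (llfun(theta + ei + ej) - llfun(theta + ei - ej)
                       - llfun(theta - ei + ej) + llfun(theta - ei - ej)) / (4 * h[i] * h[j])
    try:
        A = np.linalg.inv(-H)   # asymptotic Var of variance-component estimates
    except np.linalg.LinAlgError:
        return float(sum(len(y) for y in ys) - 4)
    denom = float(grad @ A @ grad)
    v = vfun(theta)
    if denom <= 0:
        return float(sum(len(y) for y in ys) - 4)
    return float(2.0 * v**2 / denom)


def fit_distance_lmm(records: pd.DataFrame | Sequence[DailyDistanceRecord]) -> LMMFit:
    """REML mixed model of daily distance on species x season.

    Accepts the tidy table from :func:`daily_distance_table` (columns
    animal_id, species, season, distance_m) or a sequence of records.
    Raises if a species x season cell is empty; a zero animal variance
    (singular fit) only warns.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([{
            "animal_id": r.animal_id, "species": r.species.value,
            "season": r.season, "distance_m": r.distance_m} for r in records])
    df = records
    for sp, se in _CELLS:
        if not ((df["species"] == sp) & (df["season"] == se)).any():
            raise ValueError(f"empty cell: species={sp}, season={se}")
    for sp in ("sheep", "deer"):
        if df.loc[df["species"] == sp, "animal_id"].nunique() < 2:
            raise ValueError(f"need >= 2 animals of species {sp}")

    import statsmodels.api as sm

    deer = (df["species"] == "deer").astype(float)
    wint = (df["season"] == "winter").astype(float)
    X = np.column_stack([np.ones(len(df)), deer, wint, deer * wint])
    y = df["distance_m"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(y, X, groups=df["animal_id"].to_numpy()).fit(reml=True)
    va = float(np.asarray(res.cov_re)[0, 0])
    ve = float(res.scale)
    singular = va <= 1e-8 * max(va + ve, 1e-12)
    if singular:
        warnings.warn("singular fit: animal variance estimated at zero", stacklevel=2)

    Xs, ys = _group_blocks(df)
    ll_full, beta, C = _reml_quantities(Xs, ys, va, ve)

    # REML LRT against the no-random-intercept model (sigma_a^2 = 0 profile)
    p = X.shape[1]
    bh, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ bh) ** 2))
    ve0 = rss / (len(y) - p)
    ll_null, _, _ = _reml_quantities(Xs, ys, 0.0, ve0)
    lr = max(0.0, 2.0 * (ll_full - ll_null))
    lr_p = float(sps.chi2.sf(lr, df=1))

    terms = ["Intercept", "species (deer)", "season (winter)", "species x season"]
    rows = []
    for i, name in enumerate(terms):
        c = np.zeros(p)
        c[i] = 1.0
        se = float(np.sqrt(C[i, i]))
        dof = _satterthwaite_df(Xs, ys, va, ve, c)
        t = beta[i] / se
        rows.append({"term": name, "estimate": float(beta[i]), "se": se,
                     "t": float(t), "df": dof,
                     "p": float(2 * sps.t.sf(abs(t), dof))})
    fixed = pd.DataFrame(rows).set_index("term")

    ls_rows = []
    for sp, se_ in _CELLS:
        c = _cell_vector(sp, se_)
        mu = float(c @ beta)
        sem = float(np.sqrt(c @ C @ c))
        dof = _satterthwaite_df(Xs, ys, va, ve, c)
        tcrit = sps.t.ppf(0.975, dof)
        ls_rows.append({"species": sp, "season": se_, "mean": mu, "se": sem,
                        "df": dof, "ci_lo": mu - tcrit * sem, "ci_hi": mu + tcrit * sem})
    ls_means = pd.DataFrame(ls_rows)

    pw_rows = []
    n_comp = 6
    for i in range(4):
        for j in range(i + 1, 4):
            ci = _cell_vector(*_CELLS[i]) - _cell_vector(*_CELLS[j])
            est = float(ci @ beta)
            sem = float(np.sqrt(ci @ C @ ci))
            dof = _satterthwaite_df(Xs, ys, va, ve, ci)
            t = est / sem
            praw = 2 * sps.t.sf(abs(t), dof)
            pw_rows.append({
                "pair": f"{_CELLS[i][0]}-{_CELLS[i][1]} vs {_CELLS[j][0]}-{_CELLS[j][1]}",
                "estimate": est, "se": sem, "t": float(t), "df": dof,
                "p_bonferroni": float(min(1.0, praw * n_comp)),
            })
    pairwise = pd.DataFrame(pw_rows)

    return LMMFit(
        fixed_effects=fixed, var_animal=va, var_residual=ve,
        lr_chi2=float(lr), lr_p=lr_p, ls_means=ls_means, pairwise=pairwise,
        n_obs=len(df), n_animals=df["animal_id"].nunique(),
        converged=bool(res.converged), singular=singular,
    )


# ---------------------------------------------------------------------------
# Density function and monthly RMS


def density_function(snapshot: Snapshot, k: int) -> float:
    """Mean distance to the k-th nearest neighbour across all animals."""
    ids = sorted(snapshot.positions)
    if k < 1 or k > len(ids) - 1:
        raise ValueError(f"k must be in 1..{len(ids) - 1}")
    P = np.array([snapshot.positions[a] for a in ids], dtype=float)
    d = np.linalg.norm(P[:, None, :] - P[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    kth = np.sort(d, axis=1)[:, k - 1]
    return float(kth.mean())


def monthly_rms(
    entries: Sequence[tuple[int, Species, RBFModel, InteractionDataset | None]],
) -> pd.DataFrame:
    """RMS one-step error per (month, species) stratum.

    Each entry is (month, species, fitted model, stratum dataset); an empty
    or missing stratum is flagged (NaN rms, n = 0) rather than dropped.
    """
    rows = []
    for month, species, model, ds in entries:
        if ds is None or len(ds) == 0:
            rows.append({"month": month, "species": species.value,
                         "rms_m": np.nan, "n": 0, "flag": "empty"})
        else:
            rows.append({"month": month, "species": species.value,
                         "rms_m": rms_error(model, ds), "n": len(ds), "flag": ""})
    return pd.DataFrame(rows)
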