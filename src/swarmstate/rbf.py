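"""Rotation-equivariant RBF one-step predictor with MDL model selection.

The one-step map F predicts the focal animal's next position from its
interaction vector v and location covariates w. A single scalar surface f
(linear part plus a selected set of radial basis functions) supplies both
displacement components through the rotation composition

    F(v; w) = [f(v; w), 0] + R [f(R^-1 v; w), 0],

where R rotates every 2-D offset anticlockwise through 90 degrees. The
surface is fitted on the union of the original rows (target: the
x-displacement) and the -90°-rotated rows (target: the y-displacement),
and is odd under 180-degree rotation of the vector inputs by construction:
its columns are the linear terms in v together with antisymmetrised basis
evaluations phi(x) = (b(x) - b(R² x)) / 2 (constant and covariate-only
terms are even and therefore vanish — a configuration with no directional
information predicts no displacement; covariates act through basis
functions that mix v and w). Oddness makes the equivariance identity
F(Rv) = R F(v) hold to machine precision for any basis choice, while
covariates (non-directional scalars) pass through unrotated.

Model complexity is controlled by a two-part description length

    DL = (N/2) ln(RSS/N) + lambda (k/2) ln N    [nats]

(an SIC-style approximation to Judd-Mees description-length coding; the
penalty multiplier lambda defaults to 1). Basis functions are selected
greedily: forward passes add the candidate with the greatest residual
reduction via incremental orthogonalisation, backward passes prune, and
selection stops when no single move lowers the description length; the
lowest visited DL wins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from swarmstate.tracks_io import Species
from swarmstate.vectors import InteractionDataset, InteractionRow

__all__ = [
    "BasisFunction", "RBFModel", "evaluate_basis", "candidate_dictionary",
    "fit_weights", "description_length", "select_model", "predict",
    "predict_displacements", "rms_error", "augmented_problem",
]

_KINDS = ("gaussian", "wavelet", "tophat")
_RANK_TOL = 1e-10


@dataclass(frozen=True)
class BasisFunction:
    """One radially symmetric bump in the model's input space.

    gaussian: exp(-r²/(2 scale²)); tophat: exp(-(r/scale)^(2 q)), a
    sharpened (q>1) or flattened (q<1) Gaussian; wavelet: the Ricker
    (Mexican-hat) profile (1 - r²/scale²) exp(-r²/(2 scale²)).
    """

    kind: str
    centre: tuple[float, ...]
    scale: float
    shape_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.shape_exponent <= 0:
            raise ValueError("shape_exponent must be positive")


def evaluate_basis(b: BasisFunction, x: np.ndarray) -> np.ndarray:
    """Evaluate a basis function at one point (1-D x) or many (2-D x)."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(b.centre, dtype=float)
    if x.shape[-1] != c.shape[0]:
        raise ValueError(f"dimension mismatch: x has {x.shape[-1]}, centre {c.shape[0]}")
    r2 = np.sum((x - c) ** 2, axis=-1) / b.scale**2
    if b.kind == "gaussian":
        return np.exp(-0.5 * r2)
    if b.kind == "tophat":
        return np.exp(-(r2 ** b.shape_exponent))
    return (1.0 - r2) * np.exp(-0.5 * r2)   # Ricker wavelet


@dataclass
class RBFModel:
    """Fitted one-step predictor: affine part + weighted basis functions."""

    focal_species: Species
    m: int
    n: int
    covariate_spec: tuple[str, ...]
    dim_v: int                                   # 2(m+n): rotating input dims
    affine_weights: np.ndarray                   # (1 + dim,) constant then linear
    bases: list[BasisFunction]
    basis_weights: np.ndarray
    training_n: int
    rss: float = np.nan                          # over both coordinates, m²
    rms_m: float = np.nan                        # sqrt(RSS / (2N)), metres
    mdl_bits: float = np.nan
    trace: list[dict] = field(default_factory=list)

    @property
    def k_params(self) -> int:
        """Free parameters: v-linear weights plus one weight per basis.

        (Constant and covariate-linear slots of ``affine_weights`` are
        structurally zero — even terms vanish from the odd surface.)
        """
        return self.dim_v + len(self.bases)

    def _g(self, X: np.ndarray) -> np.ndarray:
        """Raw scalar surface on (N, dim) inputs."""
        X = np.atleast_2d(X)
        out = self.affine_weights[0] + X @ self.affine_weights[1:]
        for b, wb in zip(self.bases, self.basis_weights):
            out = out + wb * evaluate_basis(b, X)
        return out

    def scalar(self, X: np.ndarray) -> np.ndarray:
        """Antisymmetrised scalar surface f~ (odd under 180° rotation of v)."""
        X = np.atleast_2d(X)
        Xneg = X.copy()
        Xneg[:, : self.dim_v] *= -1.0
        return 0.5 * (self._g(X) - self._g(Xneg))

    # -- serialisation ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": "swarmstate-rbf-model", "version": 1,
            "focal_species": self.focal_species.value,
            "m": self.m, "n": self.n, "covariate_spec": list(self.covariate_spec),
            "dim_v": self.dim_v,
            "affine_weights": self.affine_weights.tolist(),
            "bases": [
                {"kind": b.kind, "centre": list(b.centre), "scale": b.scale,
                 "shape_exponent": b.shape_exponent} for b in self.bases
            ],
            "basis_weights": self.basis_weights.tolist(),
            "training_n": self.training_n, "rss": self.rss,
            "rms_m": self.rms_m, "mdl_bits": self.mdl_bits,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RBFModel":
        doc = json.loads(text)
        if doc.get("format") != "swarmstate-rbf-model":
            raise ValueError("not a swarmstate RBF model document")
        return cls(
            focal_species=Species(doc["focal_species"]),
            m=doc["m"], n=doc["n"], covariate_spec=tuple(doc["covariate_spec"]),
            dim_v=doc["dim_v"],
            affine_weights=np.asarray(doc["affine_weights"], dtype=float),
            bases=[BasisFunction(b["kind"], tuple(b["centre"]), b["scale"],
                                 b["shape_exponent"]) for b in doc["bases"]],
            basis_weights=np.asarray(doc["basis_weights"], dtype=float),
            training_n=doc["training_n"], rss=doc["rss"],
            rms_m=doc["rms_m"], mdl_bits=doc["mdl_bits"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "RBFModel":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Training problem


def _rotate_inputs(X: np.ndarray, dim_v: int, k: int) -> np.ndarray:
    """Rotate each 2-vector of the v-block by R^k (k quarter-turns CCW)."""
    k = k % 4
    out = X.copy()
    V = out[:, :dim_v].reshape(len(X), -1, 2)
    if k == 1:
        V = np.stack([-V[..., 1], V[..., 0]], axis=-1)
    elif k == 2:
        V = -V
    elif k == 3:
        V = np.stack([V[..., 1], -V[..., 0]], axis=-1)
    out[:, :dim_v] = V.reshape(len(X), -1)
    return out


def augmented_problem(dataset: InteractionDataset) -> tuple[np.ndarray, np.ndarray, int]:
    """Rotation-augmented scalar regression problem.

    The union of the original rows (target: x-displacement) and the
    -90°-rotated rows (target: y-displacement), so a single scalar surface
    supplies both components. Returns (X, y, dim_v).
    """
    X = dataset.inputs()
    D = dataset.displacements()
    dim_v = 2 * (dataset.m + dataset.n)
    return (np.vstack([X, _rotate_inputs(X, dim_v, -1)]),
            np.concatenate([D[:, 0], D[:, 1]]), dim_v)


def _odd_columns(bases: Sequence[BasisFunction], X: np.ndarray,
                 dim_v: int) -> np.ndarray:
    """Design of the odd scalar surface: v-linear terms + antisymmetrised bases."""
    Xneg = X.copy()
    Xneg[:, :dim_v] *= -1.0
    cols = [X[:, j] for j in range(dim_v)]
    for b in bases:
        cols.append(0.5 * (evaluate_basis(b, X) - evaluate_basis(b, Xneg)))
    return np.column_stack(cols)


def _design(bases: Sequence[BasisFunction], X: np.ndarray) -> np.ndarray:
    cols = [np.ones(len(X)), *X.T]
    for b in bases:
        cols.append(evaluate_basis(b, X))
    return np.column_stack(cols)


def fit_weights(
    bases: Sequence[BasisFunction],
    X: np.ndarray,
    y: np.ndarray,
    dim_v: int | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares weights of the scalar surface.

    With ``dim_v=None`` the design is the generic affine-plus-bases model
    (weights: constant, linear terms, one per basis). With ``dim_v`` given,
    the odd equivariant design is used instead: linear terms on the first
    ``dim_v`` inputs plus antisymmetrised basis columns (weights: dim_v
    linear, one per basis). Returns (weights, RSS). Rank-deficient designs
    are solved minimum-norm with a warning (dependent directions get no
    weight; the fit never fails silently).
    """
    X = np.atleast_2d(X)
    A = _design(bases, X) if dim_v is None else _odd_columns(bases, X, dim_v)
    y = np.asarray(y, dtype=float)
    w, _, rank, sv = np.linalg.lstsq(A, y, rcond=_RANK_TOL)
    if rank < A.shape[1]:
        warnings.warn(
            f"rank-deficient design ({rank}/{A.shape[1]} independent columns); "
            "minimum-norm solution used", stacklevel=2)
    rss = float(np.sum((y - A @ w) ** 2))
    return w, rss


def description_length(N: int, RSS: float, k_params: int,
                       penalty_multiplier: float = 1.0) -> float:
    """Two-part description length (nats): fit cost plus parameter cost.

    DL = (N/2) ln(max(RSS, eps)/N) + lambda (k/2) ln N. Monotone increasing
    in k at fixed RSS. Requires N > k (identifiability).
    """
    if k_params < 0 or RSS < 0:
        raise ValueError("k_params and RSS must be non-negative")
    if N <= k_params:
        raise ValueError(f"model not identifiable: N={N} <= k_params={k_params}")
    eps = 1e-12
    return float(0.5 * N * np.log(max(RSS, eps) / N)
                 + penalty_multiplier * 0.5 * k_params * np.log(N))


def candidate_dictionary(
    dataset: InteractionDataset,
    size: int,
    seed: int,
    max_size: int = 2000,
) -> list[BasisFunction]:
    """Seeded candidate basis pool.

    Centres are sampled from the (rotation-augmented) training inputs,
    scales from the {10, 25, 50, 75}% quantiles of pairwise input distances
    on a subsample, kinds cycled over the three families.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if size < 1 or size > max_size:
        raise ValueError(f"size must be in 1..{max_size}")
    rng = np.random.default_rng(seed)
    X, _, _ = augmented_problem(dataset)
    sub = X[rng.choice(len(X), size=min(200, len(X)), replace=False)]
    d = np.sqrt(((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1))
    d = d[np.triu_indices(len(sub), k=1)]
    d = d[d > 0]
    scales = np.quantile(d, [0.10, 0.25, 0.50, 0.75]) if d.size else np.array([1.0])
    scales = scales[scales > 0]
    if scales.size == 0:
        scales = np.array([1.0])
    centres = X[rng.integers(0, len(X), size=size)]
    out = []
    for i in range(size):
        out.append(BasisFunction(
            kind=_KINDS[i % 3],
            centre=tuple(float(v) for v in centres[i]),
            scale=float(scales[i % len(scales)]),
            shape_exponent=2.0,
        ))
    return out


def _greedy_select(
    A_affine: np.ndarray,
    Phi: np.ndarray,
    y: np.ndarray,
    max_size: int,
    penalty_multiplier: float,
) -> tuple[list[int], float, list[dict]]:
    """Forward-backward greedy DL minimisation over candidate columns.

    Forward adds by greatest RSS reduction (exact, via orthogonalised
    candidate columns); backward pruning refits without each active basis.
    Returns (active indices, best DL, trace).
    """
    N, n_aff = A_affine.shape
    n_cand = Phi.shape[1]

    def dl(rss: float, k: int) -> float:
        return description_length(N, rss, k, penalty_multiplier)

    def refit(idx: list[int]) -> float:
        A = np.column_stack([A_affine, Phi[:, idx]]) if idx else A_affine
        w, *_ = np.linalg.lstsq(A, y, rcond=_RANK_TOL)
        return float(np.sum((y - A @ w) ** 2))

    active: list[int] = []
    rss = refit(active)
    cur_dl = dl(rss, n_aff)
    trace = [{"op": "affine", "k": n_aff, "rss": rss, "dl": cur_dl}]
    best = (cur_dl, list(active))

    def forward() -> bool:
        """Add by greatest RSS reduction while DL drops; True if anything added."""
        nonlocal active, rss, cur_dl, best
        # orthonormalise the current active design; candidates ⟂ its span
        A = np.column_stack([A_affine, Phi[:, active]]) if active else A_affine
        Q, _ = np.linalg.qr(A)
        r = y - Q @ (Q.T @ y)
        C = Phi - Q @ (Q.T @ Phi)
        added = False
        while len(active) < max_size:
            norms2 = np.einsum("ij,ij->j", C, C)
            usable = norms2 > _RANK_TOL * max(1.0, norms2.max(initial=0.0))
            usable[active] = False
            if not usable.any():
                break
            scores = np.zeros(n_cand)
            proj = C.T @ r
            scores[usable] = proj[usable] ** 2 / norms2[usable]
            j = int(np.argmax(scores))
            if scores[j] <= 0:
                break
            new_rss = max(rss - float(scores[j]), 0.0)
            new_dl = dl(new_rss, n_aff + len(active) + 1)
            if new_dl >= cur_dl:
                break
            q = C[:, j] / np.sqrt(norms2[j])
            C = C - np.outer(q, q @ C)
            r = r - q * (q @ r)
            rss, cur_dl = new_rss, new_dl
            active.append(j)
            added = True
            trace.append({"op": "add", "basis": j, "rss": rss, "dl": cur_dl})
            if cur_dl < best[0]:
                best = (cur_dl, list(active))
        return added

    def backward() -> bool:
        """Prune while any single removal lowers DL; True if anything pruned."""
        nonlocal active, rss, cur_dl, best
        pruned = False
        improved = True
        while improved and active:
            improved = False
            options = []
            for j in active:
                rest = [i for i in active if i != j]
                rss_j = refit(rest)
                options.append((dl(rss_j, n_aff + len(rest)), rss_j, j, rest))
            dl_j, rss_j, j, rest = min(options)
            if dl_j < cur_dl - 1e-12:
                active, rss, cur_dl = rest, rss_j, dl_j
                trace.append({"op": "prune", "basis": j, "rss": rss, "dl": cur_dl})
                if cur_dl < best[0]:
                    best = (cur_dl, list(active))
                improved = pruned = True
        return pruned

    # alternate phases until neither a single add nor a single prune lowers DL
    moved = True
    while moved:
        moved = forward()
        moved = backward() or moved

    return best[1], best[0], trace


def select_model(
    dataset: InteractionDataset,
    dictionary: Sequence[BasisFunction],
    max_size: int = 25,
    penalty_multiplier: float = 1.0,
) -> RBFModel:
    """Fit the one-step predictor by greedy DL-minimising basis selection."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    if not dictionary:
        raise ValueError("dictionary is empty")
    X, y, dim_v = augmented_problem(dataset)
    A_lin = _odd_columns([], X, dim_v)
    Phi = _odd_columns(list(dictionary), X, dim_v)[:, dim_v:]

    active, best_dl, trace = _greedy_select(A_lin, Phi, y, max_size,
                                            penalty_multiplier)
    chosen = [dictionary[j] for j in active]
    w, _ = fit_weights(chosen, X, y, dim_v=dim_v)

    dim = X.shape[1]
    affine = np.zeros(1 + dim)
    affine[1:1 + dim_v] = w[:dim_v]
    model = RBFModel(
        focal_species=dataset.focal_species, m=dataset.m, n=dataset.n,
        covariate_spec=dataset.covariate_spec, dim_v=dim_v,
        affine_weights=affine, bases=chosen, basis_weights=w[dim_v:],
        training_n=len(dataset), mdl_bits=best_dl,
        trace=[{"candidates": len(dictionary)}, *trace],
    )
    pred = predict_displacements(model, dataset)
    model.rss = float(np.sum((dataset.displacements() - pred) ** 2))
    model.rms_m = float(np.sqrt(model.rss / (2 * len(dataset))))
    return model


# ---------------------------------------------------------------------------
# Prediction


def predict_displacements(model: RBFModel, dataset: InteractionDataset) -> np.ndarray:
    """(N, 2) predicted displacements for every row (vectorised)."""
    X = dataset.inputs()
    dx = model.scalar(X)
    dy = model.scalar(_rotate_inputs(X, model.dim_v, -1))
    return np.column_stack([dx, dy])


def predict(model: RBFModel, row: InteractionRow) -> np.ndarray:
    """Predicted next position for one row.

    The scalar surface applied to the row gives the x-displacement; applied
    to the -90°-rotated row it gives the y-displacement. The construction is
    exactly rotation-equivariant: predicting on a +90°-rotated row returns
    the +90°-rotation of the unrotated prediction.
    """
    if (row.m, row.n) != (model.m, model.n):
        raise ValueError(f"row (m,n)=({row.m},{row.n}) != model ({model.m},{model.n})")
    x = np.concatenate([row.v, row.w])
    if x.size != len(model.affine_weights) - 1:
        raise ValueError(
            f"row input dim {x.size} != model dim {len(model.affine_weights) - 1}")
    dx = float(model.scalar(x[None, :])[0])
    dy = float(model.scalar(_rotate_inputs(x[None, :], model.dim_v, -1))[0])
    return row.position + np.array([dx, dy])


def rms_error(model: RBFModel, dataset: InteractionDataset) -> float:
    """One-step RMS prediction error over rows and both coordinates (m)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    err = dataset.displacements() - predict_displacements(model, dataset)
    return float(np.sqrt(np.mean(err**2)))
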