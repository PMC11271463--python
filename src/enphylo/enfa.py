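"""Ecological-Niche Factor Analysis and Mahalanobis habitat suitability.

ENFA contrasts the environment a species uses (presence cells) against the
available environment (background cells), both expressed in background
z-score units:

* the **marginality** vector ``m`` is the presence mean — how far, in
  background standard deviations, the species' mean habitat sits from the
  background mean.  The scalar marginality ``M = ||m|| / 1.96`` follows the
  ENFA literature so that M ≈ 1 means a 1-sd displacement at the 95%
  envelope.
* **specialization** axes are directions, orthogonal to the marginality
  direction, maximizing the background-to-presence variance ratio
  (eigenvalue λ ≫ 1 ⇒ the species tolerates a much narrower slice of that
  axis than is available).

Suitability is obtained by projecting cells onto the retained factor axes
(marginality axis first) and mapping the Mahalanobis distance D² to the
presence cloud's centroid through the chi-square survival function with
df = number of retained factors, giving a calibrated [0, 1] scale.

Population (1/n) variance estimators are used throughout so 5-point and
500-point fits share conventions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .errors import InputError
from .geodata import BackgroundSample, Cell, EnvStack


@dataclass
class Standardization:
    """Per-layer background mean/sd; reused verbatim on future stacks."""

    layer_names: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def apply(self, stack: EnvStack) -> EnvStack:
        """Standardize a stack's layers with THESE parameters."""
        idx = [stack.layer_names.index(n) for n in self.layer_names]
        vals = (stack.values[idx] - self.mean[:, None, None]) / self.sd[:, None, None]
        return EnvStack(list(self.layer_names), vals, stack.cell_size,
                        tuple(stack.origin), stack.nodata_mask.copy())


def standardize(
    stack: EnvStack, background: BackgroundSample | Sequence[Cell]
) -> tuple[Standardization, EnvStack]:
    """Center/scale each layer to mean 0, sd 1 over background cells."""
    cells = background.cell_ids if isinstance(background, BackgroundSample) else list(background)
    X = stack.values_at(cells)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    for name, s in zip(stack.layer_names, sd):
        if s <= 0:
            raise InputError(f"layer {name!r} has zero variance over the background")
    std = Standardization(list(stack.layer_names), mean, sd)
    return std, std.apply(stack)


def _sign_fix(u: np.ndarray) -> np.ndarray:
    """Scale an axis so its largest-|loading| entry is positive."""
    i = int(np.argmax(np.abs(u)))
    return u if u[i] >= 0 else -u


@dataclass
class EnfaModel:
    """Fitted ENFA niche: marginality, specialization, factor-space cloud."""

    layer_names: list[str]
    m: np.ndarray                 # marginality vector, standardized units
    U: np.ndarray                 # retained factor axes as columns (V x k)
    lam: np.ndarray               # specialization eigenvalues (k-1 of them)
    mu_F: np.ndarray              # presence centroid in factor space (k,)
    S_F: np.ndarray               # presence covariance in factor space (k x k)
    standardization: Standardization | None = None

    @property
    def M(self) -> float:
        """Overall marginality, ||m|| / 1.96."""
        return float(np.linalg.norm(self.m) / 1.96)

    @property
    def k(self) -> int:
        return self.U.shape[1]

    @property
    def df(self) -> int:
        return self.k

    def project(self, X: np.ndarray) -> np.ndarray:
        """Project standardized environment rows onto the factor axes."""
        return X @ self.U

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "layer_names": self.layer_names,
            "m": self.m.tolist(),
            "U": self.U.tolist(),
            "lambda": self.lam.tolist(),
            "mu_F": self.mu_F.tolist(),
            "S_F": self.S_F.tolist(),
        }
        if self.standardization is not None:
            d["standardization"] = {
                "layer_names": self.standardization.layer_names,
                "mean": self.standardization.mean.tolist(),
                "sd": self.standardization.sd.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnfaModel":
        std = None
        if "standardization" in d:
            s = d["standardization"]
            std = Standardization(list(s["layer_names"]), np.array(s["mean"]),
                                  np.array(s["sd"]))
        return cls(
            list(d["layer_names"]), np.array(d["m"]), np.array(d["U"]),
            np.array(d["lambda"]), np.array(d["mu_F"]), np.array(d["S_F"]),
            std,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "EnfaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _pop_cov(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / X.shape[0]


def _ridge(S: np.ndarray) -> np.ndarray:
    k = S.shape[0]
    tr = float(np.trace(S))
    eps = 1e-6 * (tr / k if tr > 0 else 1.0)
    return S + eps * np.eye(k)


def presence_cloud(U: np.ndarray, Z_p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and (ridged) covariance of presences in factor space."""
    F = Z_p @ U
    return F.mean(axis=0), _ridge(_pop_cov(F))


def fit_enfa(
    std_stack: EnvStack,
    presence_cells: Sequence[Cell],
    background_cells: Sequence[Cell],
    k_spec: int = 2,
) -> EnfaModel:
    """Fit ENFA on a well-sampled species.

    Requires at least 5 presence cells; rarer species go through the
    phylogenetic imputation route (see :mod:`enphylo.phylo_niche`).
    Retains ``min(k_spec + 1, n_layers, n_presences - 2)`` factors, the
    marginality axis first, then specialization axes sorted by descending
    eigenvalue and sign-fixed for cross-species comparability.
    """
    presence_cells = list(presence_cells)
    if len(presence_cells) < 5:
        raise InputError(
            "fewer than 5 presence cells: use the rare-species extension "
            "(enphylo.phylo_niche.fit_enphylo)"
        )
    Z_p = std_stack.values_at(presence_cells)
    Z_g = std_stack.values_at(list(background_cells))
    V = Z_p.shape[1]
    m = Z_p.mean(axis=0)

    S_p = _pop_cov(Z_p)
    S_g = _pop_cov(Z_g)
    if np.linalg.matrix_rank(S_p) < V:
        warnings.warn("singular presence covariance; ridge applied")
    S_p = _ridge(S_p)

    # orthonormal basis of the complement of the marginality direction
    norm_m = np.linalg.norm(m)
    m_hat = m / norm_m if norm_m > 1e-10 else np.eye(V)[:, 0]
    Q, _ = np.linalg.qr(np.column_stack([m_hat, np.eye(V)]))
    B = Q[:, 1:V]  # V x (V-1)
    A_p = B.T @ S_p @ B
    A_g = B.T @ S_g @ B
    lam, W = linalg.eigh(A_g, _ridge(A_p))  # A_g w = lam A_p w
    order = np.argsort(lam)[::-1]
    lam = np.maximum(lam[order], 0.0)
    axes = B @ W[:, order]
    axes /= np.linalg.norm(axes, axis=0, keepdims=True)
    axes = np.column_stack([_sign_fix(axes[:, j]) for j in range(axes.shape[1])])

    k = min(k_spec + 1, V, len(presence_cells) - 2)
    k = max(k, 1)
    U = np.column_stack([_sign_fix(m_hat)] + [axes[:, j] for j in range(k - 1)])
    mu_F, S_F = presence_cloud(U, Z_p)
    return EnfaModel(list(std_stack.layer_names), m, U, lam[: max(k - 1, 0)],
                     mu_F, S_F)


def mahalanobis_suitability(model: EnfaModel, std_stack: EnvStack) -> np.ndarray:
    """Habitat suitability grid in [0, 1] from factor-space Mahalanobis D².

    The stack must be standardized with the model's own Standardization;
    layers are matched by name, so layer order is irrelevant.  Suitability
    is ``P(chi2_df >= D²)``; nodata cells are NaN.
    """
    idx = [std_stack.layer_names.index(n) for n in model.layer_names]
    vals = std_stack.values[idx]
    nrows, ncols = std_stack.shape
    X = vals.reshape(len(idx), -1).T  # cells x V
    F = model.project(X) - model.mu_F
    try:
        L = np.linalg.cholesky(model.S_F)
    except np.linalg.LinAlgError as exc:
        raise InputError("factor covariance is not positive definite") from exc
    sol = np.linalg.solve(L, F.T)
    d2 = np.sum(sol**2, axis=0)
    suit = stats.chi2.sf(d2, df=model.df).reshape(nrows, ncols)
    suit[std_stack.nodata_mask] = np.nan
    return suit


def score_cells(model: EnfaModel, std_stack: EnvStack,
                cells: Sequence[Cell]) -> np.ndarray:
    """Suitability at specific cells (same mapping as the full grid)."""
    X = std_stack.values_at(list(cells), layers=model.layer_names)
    F = model.project(X) - model.mu_F
    L = np.linalg.cholesky(model.S_F)
    sol = np.linalg.solve(L, F.T)
    d2 = np.sum(sol**2, axis=0)
    return stats.chi2.sf(d2, df=model.df)
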