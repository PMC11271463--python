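"""Phylogenetic niche imputation and the rare-species (ENphylo) fit.

Niche axes fitted by ENFA on well-sampled species carry phylogenetic
signal, so a data-poor relative's marginality and specialization can be
imputed as the Brownian-motion conditional expectation given the observed
tips.  The imputed niche is converted into habitat suitability using the
species' few real occurrence cells — topped up, when fewer than five exist,
with pseudo-presences chosen among knight-move neighbours of the reference
cells by environmental similarity.  Phylogenetic uncertainty is handled by
repeating the fit over randomly perturbed trees and keeping the best-AUC
replicate; fits below AUC 0.7 are rejected.

The encoding imputed per species is ``[m; sqrt(λ₁)·U₁; …; sqrt(λ_s)·U_s]``
— the marginality vector followed by the first ``s`` sign-fixed
specialization axes scaled by the square root of their eigenvalues, so
specialization magnitude survives averaging across the tree.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy import linalg

from .enfa import EnfaModel, _sign_fix, presence_cloud, score_cells
from .ensemble import EvalRecord, bootstrap_evaluate
from .errors import InputError, ModelRejectedError
from .geodata import Cell, EnvStack

KNIGHT_MOVES = (
    (-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1),
)


# ---------------------------------------------------------------------------
# Niche-trait encoding
# ---------------------------------------------------------------------------

@dataclass
class NicheTraitTable:
    """Per-species niche trait vectors (observed or imputed)."""

    traits: dict[str, np.ndarray] = field(default_factory=dict)
    observed: dict[str, bool] = field(default_factory=dict)
    n_layers: int = 0
    s_axes: int = 0
    donor_marg_var: list[float] = field(default_factory=list)

    @property
    def median_marg_var(self) -> float:
        """Median presence variance along the marginality axis across
        donor species — the clade-level prior for the axis whose width the
        trait encoding does not carry."""
        return float(np.median(self.donor_marg_var)) if self.donor_marg_var else 0.5

    def add(self, species: str, vector: np.ndarray, observed: bool = True) -> None:
        vector = np.asarray(vector, dtype=float)
        if self.traits and vector.shape != next(iter(self.traits.values())).shape:
            raise InputError("trait vectors must share length")
        self.traits[species] = vector
        self.observed[species] = observed

    @property
    def observed_species(self) -> list[str]:
        return [s for s, f in self.observed.items() if f]


def encode_niche(model: EnfaModel, s_axes: int = 2) -> np.ndarray:
    """Flatten an ENFA fit into the imputable trait vector."""
    V = len(model.m)
    parts = [model.m]
    spec_axes = model.U[:, 1:]
    for j in range(s_axes):
        if j < spec_axes.shape[1] and j < model.lam.size:
            parts.append(np.sqrt(max(model.lam[j], 0.0)) * spec_axes[:, j])
        else:
            parts.append(np.zeros(V))
    return np.concatenate(parts)


def decode_niche(
    vector: np.ndarray,
    layer_names: Sequence[str],
    presence_Z: np.ndarray,
    s_axes: int = 2,
    marg_var_floor: float | None = None,
) -> EnfaModel:
    """Rebuild an ENFA model from an (imputed) trait vector.

    The marginality vector and specialization axes come from the vector;
    the factor-space centroid and covariance are re-estimated from the
    standardized environments of the presence cells supplied (ridged).
    The retained factor count is capped at ``n_presences - 2``.

    When ``marg_var_floor`` is given (the rare-species route), the
    factor covariance diagonal is floored by the niche widths the imputed
    vector itself implies — ``min(1/λ_j, 1)`` along specialization axis j
    (λ is the background-to-species variance ratio, so 1/λ is the species
    variance in standardized units) and ``marg_var_floor`` along the
    marginality axis.  A handful of presence cells chosen for mutual
    environmental similarity has near-zero empirical spread; the presences
    locate the niche centroid while the imputed niche supplies the metric.
    """
    V = len(layer_names)
    if vector.size != V * (1 + s_axes):
        raise InputError("trait vector length does not match layer count")
    m = vector[:V]
    axes, lams = [], []
    for j in range(s_axes):
        block = vector[V * (j + 1): V * (j + 2)]
        norm = np.linalg.norm(block)
        if norm > 1e-10:
            axes.append(_sign_fix(block / norm))
            lams.append(norm**2)
    norm_m = np.linalg.norm(m)
    m_hat = m / norm_m if norm_m > 1e-10 else np.eye(V)[:, 0]
    k = min(1 + len(axes), V, max(presence_Z.shape[0] - 2, 1))
    U = np.column_stack([_sign_fix(m_hat)] + axes[: k - 1])
    mu_F, S_F = presence_cloud(U, presence_Z)
    if marg_var_floor is not None:
        floor = np.r_[marg_var_floor,
                      [min(1.0 / max(l, 1e-6), 1.0) for l in lams[: k - 1]]]
        for j in range(k):
            S_F[j, j] = max(S_F[j, j], floor[j])
    return EnfaModel(list(layer_names), m, U, np.array(lams[: k - 1]), mu_F, S_F)


def build_trait_table(
    models: dict[str, EnfaModel], s_axes: int = 2
) -> NicheTraitTable:
    """Encode fitted ENFA models of well-sampled species into a table."""
    table = NicheTraitTable(s_axes=s_axes)
    for sp, model in models.items():
        table.n_layers = len(model.m)
        table.add(sp, encode_niche(model, s_axes), observed=True)
        table.donor_marg_var.append(float(model.S_F[0, 0]))
    return table


# ---------------------------------------------------------------------------
# Brownian-motion imputation
# ---------------------------------------------------------------------------

def _phylo_vcv(tree: dendropy.Tree, labels: Sequence[str]) -> np.ndarray:
    """Phylogenetic variance–covariance: shared root-to-MRCA path lengths."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [l for l in labels if l not in taxa]
    if missing:
        raise InputError(f"species not in tree: {missing}")
    depth = {}
    for leaf in tree.leaf_node_iter():
        depth[leaf.taxon.label] = leaf.distance_from_root()
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i > j:
                continue
            if a == b:
                C[i, j] = depth[a]
            else:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                C[i, j] = C[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return C


def impute_tip_traits(
    tree: dendropy.Tree,
    traits: NicheTraitTable,
    target_species: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Brownian-motion conditional expectation of a tip's trait vector.

    The root state is the GLS estimate over observed tips under the
    phylogenetic covariance C; the imputed vector is
    ``μ̂ + C_to C_oo⁻¹ (x_obs − μ̂)`` per trait dimension.  Returns the
    imputed vector and a per-dimension conditional variance (the BM rate
    per dimension estimated by GLS, times the schur complement).
    """
    observed = [s for s in traits.observed_species if s != target_species]
    if len(observed) < 3:
        raise InputError("need at least 3 observed tips for imputation")
    labels = observed + [target_species]
    C = _phylo_vcv(tree, labels)
    if np.any(np.diag(C) <= 0):
        raise InputError("tree has tips at zero depth; cannot impute")
    n_obs = len(observed)
    C_oo = C[:n_obs, :n_obs]
    C_to = C[n_obs, :n_obs]
    C_tt = C[n_obs, n_obs]
    Ci = linalg.pinvh(C_oo)
    ones = np.ones(n_obs)
    X = np.stack([traits.traits[s] for s in observed])  # n_obs x p
    denom = ones @ Ci @ ones
    mu = (ones @ Ci @ X) / denom                         # root state per dim
    resid = X - mu
    w = C_to @ Ci                                        # 1 x n_obs
    imputed = mu + w @ resid
    # per-dimension BM rate by GLS, scaled by the conditional variance
    sig2 = np.einsum("ip,ij,jp->p", resid, Ci, resid) / n_obs
    cond = max(C_tt - w @ C_to, 0.0)
    return imputed, sig2 * cond


def perturb_tree(tree: dendropy.Tree, seed: int = 0,
                 branch_jitter_sd: float = 0.1) -> dendropy.Tree:
    """Random tree perturbation for phylogenetic-uncertainty replicates.

    One nearest-neighbour tip swap (a random tip's label exchanged with a
    tip from its aunt clade) plus multiplicative log-normal jitter on all
    branch lengths.  Ultrametricity is not enforced.  Trees with fewer
    than 4 tips are returned unchanged with a warning.  Deterministic
    under ``seed``.
    """
    out = tree.clone(depth=1)
    leaves = list(out.leaf_node_iter())
    if len(leaves) < 4:
        warnings.warn("tree has fewer than 4 tips; returned unchanged")
        return out
    rng = random.Random(int(seed))
    # pick a tip whose parent has a grandparent, swap with a tip from a
    # sibling subtree of the parent
    order = list(range(len(leaves)))
    rng.shuffle(order)
    for i in order:
        tip = leaves[i]
        parent = tip.parent_node
        if parent is None or parent.parent_node is None:
            continue
        grand = parent.parent_node
        aunts = [ch for ch in grand.child_nodes() if ch is not parent]
        aunt_tips = [lf for a in aunts for lf in a.leaf_iter()]
        if not aunt_tips:
            continue
        other = rng.choice(aunt_tips)
        tip.taxon, other.taxon = other.taxon, tip.taxon
        break
    nprng = np.random.default_rng(seed)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length * nprng.lognormal(0.0, branch_jitter_sd))
    return out


# ---------------------------------------------------------------------------
# Pseudo-presence selection (the <5-occurrence extension)
# ---------------------------------------------------------------------------

def knight_candidates(
    reference_cells: Sequence[Cell], stack: EnvStack
) -> list[Cell]:
    """Union of the 8 chess-knight neighbours of every reference cell.

    Off-grid, nodata and reference cells are excluded; result is
    de-duplicated and in stable row-major order.
    """
    refs = set(reference_cells)
    out: set[Cell] = set()
    for r, c in reference_cells:
        for dr, dc in KNIGHT_MOVES:
            cell = (r + dr, c + dc)
            if cell in refs or not stack.in_bounds(cell):
                continue
            if stack.nodata_mask[cell]:
                continue
            out.add(cell)
    if not out:
        raise InputError("no valid pseudo-presence candidates")
    return sorted(out)


def angle_similarity(
    candidate_cell: Cell,
    reference_cells: Sequence[Cell],
    std_stack: EnvStack,
) -> float:
    """Mean Pearson correlation between a candidate's standardized
    environmental vector and each reference's vector (the 'angle').

    A constant vector (zero variance across layers) yields ``-inf`` with a
    warning so it always ranks last.
    """
    cand = std_stack.values_at([candidate_cell])[0]
    if np.std(cand) == 0:
        warnings.warn("constant environmental vector at candidate cell")
        return float("-inf")
    rs = []
    for ref in reference_cells:
        vec = std_stack.values_at([ref])[0]
        if np.std(vec) == 0:
            warnings.warn("constant environmental vector at reference cell")
            return float("-inf")
        rs.append(np.corrcoef(cand, vec)[0, 1])
    return float(np.mean(rs))


def _nearest_ref_distance(cell: Cell, refs: Sequence[Cell]) -> float:
    return min(
        float(np.hypot(cell[0] - r, cell[1] - c)) for r, c in refs
    )


def select_pseudo_presences(
    reference_cells: Sequence[Cell],
    std_stack: EnvStack,
) -> list[Cell]:
    """Top up 2–4 reference cells to 5 presences with knight-move cells.

    Selects the ``n = 5 − n_references`` candidates most environmentally
    similar to the references; ties are broken by smaller Euclidean cell
    distance to the nearest reference, then by row-major index.  Species
    with ≥ 5 references need no extension (empty list); a single reference
    is an error (such species are excluded upstream).
    """
    refs = list(reference_cells)
    if len(refs) < 2:
        raise InputError("species occupying a single cell are excluded")
    if len(refs) >= 5:
        return []
    n = 5 - len(refs)
    candidates = knight_candidates(refs, std_stack)
    ranked = sorted(
        candidates,
        key=lambda cell: (
            -angle_similarity(cell, refs, std_stack),
            _nearest_ref_distance(cell, refs),
            cell,
        ),
    )
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} pseudo-presence candidates for {n} slots"
        )
    return ranked[:n]


# ---------------------------------------------------------------------------
# The full rare-species fit
# ---------------------------------------------------------------------------

@dataclass
class RareFit:
    """Result of the rare-species (imputed-niche) fit."""

    species_id: str
    reference_cells: list[Cell]
    pseudo_cells: list[Cell]
    model: EnfaModel
    suitability: np.ndarray
    eval_record: EvalRecord
    chosen_tree_index: int

    @property
    def presence_cells(self) -> list[Cell]:
        return self.reference_cells + self.pseudo_cells


def fit_enphylo(
    species_id: str,
    reference_cells: Sequence[Cell],
    tree: dendropy.Tree,
    trait_table: NicheTraitTable,
    std_stack: EnvStack,
    background_cells: Sequence[Cell],
    n_tree_reps: int = 50,
    seed: int = 0,
    cv_reps: int = 10,
    auc_min: float = 0.7,
) -> RareFit:
    """Fit a rare species (< 15 occurrence cells) by phylogenetic imputation.

    The presence set is the reference cells plus, below 5 references,
    knight-move pseudo-presences.  The niche trait vector is imputed under
    Brownian motion on the input tree and ``n_tree_reps − 1`` random
    perturbations of it; each candidate is scored by bootstrap
    cross-validated AUC (the factor-space cloud refitted on each training
    draw), candidates below ``auc_min`` are rejected, and the best-AUC
    survivor is refitted on all presences and projected.  Deterministic
    under ``seed``.
    """
    refs = list(reference_cells)
    if len(refs) >= 15:
        raise InputError("species has >= 15 cells; use the ESM/SDM tiers")
    pseudo = select_pseudo_presences(refs, std_stack) if len(refs) < 5 else []
    presences = refs + pseudo
    bg = list(background_cells)
    rng = np.random.default_rng(seed)
    trees = [tree] + [
        perturb_tree(tree, seed=int(rng.integers(2**31)))
        for _ in range(max(n_tree_reps - 1, 0))
    ]
    s_axes = trait_table.s_axes
    layers = list(std_stack.layer_names)

    best: tuple[float, int, np.ndarray, EvalRecord] | None = None
    for t_idx, t in enumerate(trees):
        try:
            vector, _ = impute_tip_traits(t, trait_table, species_id)
        except InputError:
            raise
        def fitter(train_pres, train_bg, rep_seed, _vec=vector):
            Z = std_stack.values_at(list(train_pres))
            model = decode_niche(_vec, layers, Z, s_axes,
                                 marg_var_floor=trait_table.median_marg_var)
            return _EnfaScorer(model)
        rec = bootstrap_evaluate(
            fitter, presences, bg, std_stack, n_reps=cv_reps,
            seed=int(rng.integers(2**31)), min_test_presences=1,
        )
        if rec.auc_mean < auc_min:
            continue
        if best is None or rec.auc_mean > best[0]:
            best = (rec.auc_mean, t_idx, vector, rec)
    if best is None:
        raise ModelRejectedError(
            f"{species_id}: every tree replicate fell below AUC {auc_min}"
        )
    _, t_idx, vector, rec = best
    Z = std_stack.values_at(presences)
    model = decode_niche(vector, layers, Z, s_axes,
                         marg_var_floor=trait_table.median_marg_var)
    from .enfa import mahalanobis_suitability

    suit = mahalanobis_suitability(model, std_stack)
    return RareFit(species_id, refs, pseudo, model, suit, rec, t_idx)


class _EnfaScorer:
    """Adapter exposing an ENFA model through the scorer protocol."""

    def __init__(self, model: EnfaModel):
        self.model = model

    def score_cells(self, std_stack: EnvStack, cells: Sequence[Cell]) -> np.ndarray:
        return score_cells(self.model, std_stack, cells)

    def score_grid(self, std_stack: EnvStack) -> np.ndarray:
        from .enfa import mahalanobis_suitability

        return mahalanobis_suitability(self.model, std_stack)


def enfa_scorer(model: EnfaModel) -> _EnfaScorer:
    """Wrap an ENFA model as a scorer usable by evaluation/projection."""
    return _EnfaScorer(model)
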