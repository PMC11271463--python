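"""Tier routing, base learners, small-model ensembles and evaluation.

Species are routed by occurrence-cell count: fewer than 15 cells go to the
phylogenetic-imputation route, 15–30 to ensembles of small (bivariate)
models, more than 30 to a conventional multi-predictor ensemble.  Three
presence–background learners are provided: a quadratic logistic GLM, a
random forest, and a MaxEnt-style L1-penalized logistic model on expanded
features.  Skill is measured by bootstrap cross-validation (with-replacement
draw of an 80% training portion, clean 20% holdout, 10 repeats) with AUC,
TSS and the continuous Boyce index; models below mean AUC 0.7 are discarded
and survivors are averaged with AUC weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .errors import ExcludedSpeciesError, InputError, ModelRejectedError
from .geodata import Cell, EnvStack

AUC_MIN = 0.7

TIER_ENPHYLO = "ENPHYLO"
TIER_ESM = "ESM"
TIER_SDM = "SDM"

LearnerKind = Literal["GLM_QUAD", "RF", "MAXENT_LIKE"]
LEARNER_KINDS: tuple[str, ...] = ("GLM_QUAD", "RF", "MAXENT_LIKE")


@dataclass
class TierAssignment:
    species_id: str
    n_cells: int
    tier: str


def assign_tier(species_id: str, n_cells: int) -> TierAssignment:
    """Route a species to ENPHYLO (<15), ESM (15–30) or SDM (>30 cells)."""
    if n_cells < 2:
        raise ExcludedSpeciesError(
            f"{species_id}: occupies a single geographic cell; excluded"
        )
    if n_cells < 15:
        tier = TIER_ENPHYLO
    elif n_cells <= 30:
        tier = TIER_ESM
    else:
        tier = TIER_SDM
    return TierAssignment(species_id, n_cells, tier)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Mann–Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InputError("both score sets must be non-empty")
    allv = np.concatenate([pos, neg])
    ranks = stats.rankdata(allv)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def tss(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """True Skill Statistic: max over observed-score thresholds of
    sensitivity + specificity − 1 (prediction rule: score >= threshold)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InputError("both score sets must be non-empty")
    cand = np.unique(np.concatenate([pos, neg]))
    best = -1.0
    for t in cand:
        sens = np.mean(pos >= t)
        spec = np.mean(neg < t)
        best = max(best, float(sens + spec - 1.0))
    return best


def boyce(scores_pos: Sequence[float], scores_background: Sequence[float],
          n_windows: int = 101) -> float:
    """Continuous Boyce index.

    Overlapping windows of width (max−min)/10 span the background score
    range; per window, P/E = (presence fraction) / (background fraction);
    the index is the Spearman correlation of P/E against window midpoints.
    Windows with zero background fraction are dropped; returns NaN (with a
    warning) when fewer than 3 usable windows remain or P/E is constant.
    """
    pos = np.asarray(scores_pos, dtype=float)
    bg = np.asarray(scores_background, dtype=float)
    if pos.size == 0 or bg.size == 0:
        raise InputError("both score sets must be non-empty")
    lo, hi = bg.min(), bg.max()
    if hi <= lo:
        warnings.warn("degenerate background score range; Boyce undefined")
        return float("nan")
    width = (hi - lo) / 10.0
    starts = np.linspace(lo, hi - width, n_windows)
    mids, ratios = [], []
    for s in starts:
        e = s + width
        p_frac = np.mean((pos >= s) & (pos <= e))
        e_frac = np.mean((bg >= s) & (bg <= e))
        if e_frac == 0:
            continue
        mids.append(s + width / 2)
        ratios.append(p_frac / e_frac)
    if len(mids) < 3:
        warnings.warn("fewer than 3 usable windows; Boyce undefined")
        return float("nan")
    if np.ptp(ratios) == 0:
        warnings.warn("constant P/E ratio; Boyce undefined")
        return float("nan")
    rho, _ = stats.spearmanr(ratios, mids)
    return float(rho)


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------

def _expand_features(X: np.ndarray, quadratic: bool = True,
                     products: bool = True) -> np.ndarray:
    cols = [X]
    if quadratic:
        cols.append(X**2)
    if products and X.shape[1] > 1:
        cols.append(np.column_stack(
            [X[:, i] * X[:, j] for i, j in combinations(range(X.shape[1]), 2)]
        ))
    return np.hstack(cols)


@dataclass
class LearnerScorer:
    """A fitted presence–background learner usable on any matching stack."""

    kind: str
    layer_names: list[str]
    model: object
    quadratic: bool = True
    products: bool = True

    def _features(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "RF":
            return X
        return _expand_features(X, self.quadratic, self.products)

    def score_cells(self, std_stack: EnvStack, cells: Sequence[Cell]) -> np.ndarray:
        X = std_stack.values_at(list(cells), layers=self.layer_names)
        return self.model.predict_proba(self._features(X))[:, 1]

    def score_grid(self, std_stack: EnvStack) -> np.ndarray:
        cells = std_stack.valid_cells()
        out = np.full(std_stack.shape, np.nan)
        vals = self.score_cells(std_stack, cells)
        for (r, c), v in zip(cells, vals):
            out[r, c] = v
        return out

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "layer_names": self.layer_names,
             "quadratic": self.quadratic, "products": self.products}
        if hasattr(self.model, "coef_"):
            d["coef"] = np.asarray(self.model.coef_).ravel().tolist()
            d["intercept"] = float(np.asarray(self.model.intercept_).ravel()[0])
        return d


def fit_learner(
    kind: str,
    presence_cells: Sequence[Cell],
    background_cells: Sequence[Cell],
    std_stack: EnvStack,
    layer_subset: Sequence[str] | None = None,
    seed: int = 0,
    n_trees: int = 500,
    include_products: bool = True,
) -> LearnerScorer:
    """Fit one base learner on standardized environment values.

    GLM_QUAD: unpenalized logistic regression on linear + quadratic terms
    (plus pairwise products of the linear terms when ``include_products``),
    falling back to a ridge (L2) fit with a warning on perfect separation.
    RF: 500-tree random forest; probability = out-of-bag-free vote fraction.
    MAXENT_LIKE: L1-penalized presence–background logistic model on the
    expanded features with balanced class weighting (penalty strength by
    5-fold cross-validation) — a penalized logistic stand-in with the same
    use profile as maximum-entropy SDMs.
    """
    if kind not in LEARNER_KINDS:
        raise InputError(f"unknown learner kind {kind!r}")
    presence_cells = list(presence_cells)
    background_cells = list(background_cells)
    if len(presence_cells) < 5:
        raise InputError("need at least 5 presence cells")
    if not background_cells:
        raise InputError("empty background")
    layers = list(layer_subset) if layer_subset is not None else list(std_stack.layer_names)
    if len(layers) < 2 and kind != "RF":
        raise InputError("need at least 2 layers (1 allowed for RF)")
    Xp = std_stack.values_at(presence_cells, layers=layers)
    Xb = std_stack.values_at(background_cells, layers=layers)
    X = np.vstack([Xp, Xb])
    y = np.r_[np.ones(len(Xp)), np.zeros(len(Xb))]

    if kind == "RF":
        model = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        ).fit(X, y)
        return LearnerScorer(kind, layers, model)

    F = _expand_features(X, True, include_products)
    if kind == "GLM_QUAD":
        model = LogisticRegression(penalty=None, max_iter=2000).fit(F, y)
        if np.max(np.abs(model.coef_)) > 1e4:
            warnings.warn("perfect separation in GLM; ridge fallback")
            model = LogisticRegression(penalty="l2", C=1.0, max_iter=2000).fit(F, y)
    else:  # MAXENT_LIKE
        model = LogisticRegressionCV(
            Cs=[0.01, 0.1, 1.0], penalty="l1", solver="liblinear",
            cv=5, class_weight="balanced", random_state=seed, max_iter=2000,
        ).fit(F, y)
    return LearnerScorer(kind, layers, model, products=include_products)


@dataclass
class WeightedScorer:
    """AUC-weighted average of component scorers."""

    members: list[object]
    weights: list[float]

    def score_cells(self, std_stack: EnvStack, cells: Sequence[Cell]) -> np.ndarray:
        w = np.asarray(self.weights)
        scores = np.stack([m.score_cells(std_stack, cells) for m in self.members])
        return (w[:, None] * scores).sum(axis=0) / w.sum()

    def score_grid(self, std_stack: EnvStack) -> np.ndarray:
        cells = std_stack.valid_cells()
        out = np.full(std_stack.shape, np.nan)
        vals = self.score_cells(std_stack, cells)
        for (r, c), v in zip(cells, vals):
            out[r, c] = v
        return out


def ensemble_average(scored: Sequence[tuple[object, "EvalRecord"]]) -> WeightedScorer:
    """Combine passing scorers, weighting each by its mean AUC."""
    passing = [(s, e) for s, e in scored if e.pass_flag]
    if not passing:
        raise ModelRejectedError("no scorer passed the AUC threshold")
    return WeightedScorer([s for s, _ in passing],
                          [e.auc_mean for _, e in passing])


# ---------------------------------------------------------------------------
# Bootstrap evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalRecord:
    """Per-replicate AUC/TSS/Boyce with aggregates and the pass flag."""

    auc_values: list[float] = field(default_factory=list)
    tss_values: list[float] = field(default_factory=list)
    boyce_values: list[float] = field(default_factory=list)
    auc_min: float = AUC_MIN

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc_values))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.auc_values))

    @property
    def tss_mean(self) -> float:
        return float(np.mean(self.tss_values))

    @property
    def boyce_mean(self) -> float:
        vals = [v for v in self.boyce_values if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def pass_flag(self) -> bool:
        return self.auc_mean >= self.auc_min

    def to_dict(self) -> dict:
        return {
            "auc": self.auc_values, "tss": self.tss_values,
            "boyce": self.boyce_values, "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd, "tss_mean": self.tss_mean,
            "boyce_mean": self.boyce_mean, "pass": self.pass_flag,
        }


ModelFitter = Callable[[Sequence[Cell], Sequence[Cell], int], object]


def bootstrap_evaluate(
    model_fitter: ModelFitter,
    presence_cells: Sequence[Cell],
    background_cells: Sequence[Cell],
    std_stack: EnvStack,
    n_reps: int = 10,
    split: float = 0.8,
    seed: int = 0,
    min_test_presences: int = 2,
    auc_min: float = AUC_MIN,
) -> EvalRecord:
    """Bootstrap cross-validation of a model-fitting routine.

    Per replicate: the presences (and, independently, the background) are
    partitioned into an 80% training portion and a clean 20% holdout; the
    training multiset is drawn with replacement from the training portion;
    the fitted model is scored on the holdout with AUC, TSS and Boyce.
    Replicates whose holdout carries fewer than ``min_test_presences``
    presences are skipped with a warning; if every replicate is skipped an
    :class:`InputError` is raised.  Deterministic under ``seed``.
    """
    presence_cells = list(presence_cells)
    background_cells = list(background_cells)
    n_p, n_b = len(presence_cells), len(background_cells)
    rng = np.random.default_rng(seed)
    rec = EvalRecord(auc_min=auc_min)
    for rep in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        rep_rng = np.random.default_rng(rep_seed)
        p_idx = rep_rng.permutation(n_p)
        b_idx = rep_rng.permutation(n_b)
        n_p_train = int(np.ceil(split * n_p))
        n_b_train = int(np.ceil(split * n_b))
        p_train_pool, p_test = p_idx[:n_p_train], p_idx[n_p_train:]
        b_train_pool, b_test = b_idx[:n_b_train], b_idx[n_b_train:]
        if p_test.size < min_test_presences or b_test.size < 2:
            warnings.warn(f"replicate {rep}: holdout too small, skipped")
            continue
        p_train = rep_rng.choice(p_train_pool, size=p_train_pool.size, replace=True)
        b_train = rep_rng.choice(b_train_pool, size=b_train_pool.size, replace=True)
        model = model_fitter(
            [presence_cells[i] for i in p_train],
            [background_cells[i] for i in b_train],
            rep_seed,
        )
        s_pos = model.score_cells(std_stack, [presence_cells[i] for i in p_test])
        s_neg = model.score_cells(std_stack, [background_cells[i] for i in b_test])
        rec.auc_values.append(auc(s_pos, s_neg))
        rec.tss_values.append(tss(s_pos, s_neg))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec.boyce_values.append(boyce(s_pos, s_neg))
    if not rec.auc_values:
        raise InputError("all bootstrap replicates were skipped")
    return rec


def make_learner_fitter(kind: str, std_stack: EnvStack,
                        layers: Sequence[str] | None = None,
                        n_trees: int = 500) -> ModelFitter:
    """Adapter turning :func:`fit_learner` into a bootstrap model fitter."""

    def fitter(pres: Sequence[Cell], bg: Sequence[Cell], seed: int):
        return fit_learner(kind, pres, bg, std_stack, layers, seed=seed,
                           n_trees=n_trees)

    return fitter


# ---------------------------------------------------------------------------
# Ensembles of small models
# ---------------------------------------------------------------------------

def fit_esm(
    presence_cells: Sequence[Cell],
    background_cells: Sequence[Cell],
    std_stack: EnvStack,
    learner_kinds: Sequence[str] = LEARNER_KINDS,
    seed: int = 0,
    n_reps: int = 10,
    n_trees: int = 500,
    auc_min: float = AUC_MIN,
) -> tuple[WeightedScorer, list[tuple[str, tuple[str, str], EvalRecord]]]:
    """Ensemble of small models: every bivariate layer pair per learner.

    Each of the C(V, 2) layer pairs is fitted with every requested learner
    kind and bootstrap-evaluated; small models with mean AUC < 0.7 are
    dropped and the survivors averaged with AUC weights.  Returns the
    combined scorer and the per-small-model evaluation records.
    """
    layers = std_stack.layer_names
    if len(layers) < 2:
        raise InputError("ESM needs at least 2 layers")
    rng = np.random.default_rng(seed)
    records = []
    passing: list[tuple[object, EvalRecord]] = []
    for pair in combinations(layers, 2):
        for kind in learner_kinds:
            sub_seed = int(rng.integers(2**31))
            fitter = make_learner_fitter(kind, std_stack, list(pair),
                                         n_trees=n_trees)
            rec = bootstrap_evaluate(fitter, presence_cells, background_cells,
                                     std_stack, n_reps=n_reps, seed=sub_seed,
                                     auc_min=auc_min)
            records.append((kind, pair, rec))
            if rec.pass_flag:
                scorer = fit_learner(kind, presence_cells, background_cells,
                                     std_stack, list(pair), seed=sub_seed,
                                     n_trees=n_trees)
                passing.append((scorer, rec))
    if not passing:
        raise ModelRejectedError("every small model fell below AUC 0.7")
    return ensemble_average(passing), records
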