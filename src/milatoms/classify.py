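"""Sparse selection of expanded-embedding columns and SVM bag classification.

The expanded similarity features are screened by a LASSO regression against
the +/-1 labels,

    u* = argmin_u ||Delta u - l||_2^2 + lambda ||u||_1,

and an RBF-kernel SVM is trained on the surviving columns.  Model selection
(lambda and the kernel bandwidth) is nested inside each outer
cross-validation fold so reported accuracies are honest.  The search over
contiguous window-length ranges (q, p) evaluates every admissible expansion
and returns the upper-triangular accuracy matrix plus the best cell; the
absolute LASSO weights of the best cell, aggregated onto the source-window
time axis, form the temporal relevance profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .embedding import ExpandedEmbedding, SimilarityBlock
from .exceptions import DataError, ParameterError

__all__ = [
    "LassoFit",
    "ClassifierSpec",
    "CVResult",
    "SearchResult",
    "TemporalProfile",
    "FoldEmbedding",
    "lasso_fit",
    "kkt_violation",
    "select_and_classify",
    "algorithm1_search",
    "folds_from_full_blocks",
    "temporal_profile",
]


@dataclass
class LassoFit:
    """Sparse selection vector over expanded-embedding columns."""

    u: np.ndarray
    lam: float
    intercept: float
    active_set: np.ndarray

    @property
    def n_active(self) -> int:
        return self.active_set.size


def _as_matrix(embedding) -> np.ndarray:
    if isinstance(embedding, ExpandedEmbedding):
        return embedding.features
    return np.asarray(embedding, dtype=np.float64)


def lasso_fit(embedding, labels, lam: float, tol: float = 1e-10,
              max_iter: int = 200_000) -> LassoFit:
    """Solve the L1-penalized least-squares problem at penalty ``lam``.

    The intercept is handled by centering.  ``lam`` multiplies the plain
    ||u||_1 term of the un-normalized objective ||Delta u - l||^2; it is
    converted internally to scikit-learn's per-sample parametrization.
    ``lam = 0`` returns the exact least-squares solution.
    """
    X = _as_matrix(embedding)
    y = np.asarray(labels, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise DataError("row count must equal number of labels")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DataError("non-finite inputs")
    if lam < 0:
        raise ParameterError("lambda must be non-negative")
    if lam == 0.0:
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        u, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        intercept = float(y.mean() - X.mean(axis=0) @ u)
    else:
        n = X.shape[0]
        model = Lasso(alpha=lam / (2.0 * n), fit_intercept=True, tol=tol,
                      max_iter=max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        u = model.coef_.astype(np.float64)
        intercept = float(model.intercept_)
    active = np.flatnonzero(u != 0.0)
    return LassoFit(u=u, lam=float(lam), intercept=intercept, active_set=active)


def kkt_violation(embedding, labels, fit: LassoFit) -> float:
    """Largest violation of the LASSO stationarity conditions at ``fit``.

    For active columns |2 X_j' r + lam sign(u_j)| must vanish; for inactive
    columns |2 X_j' r| must not exceed lam (r is the residual).
    """
    X = _as_matrix(embedding)
    y = np.asarray(labels, dtype=np.float64)
    r = X @ fit.u + fit.intercept - y
    g = 2.0 * (X.T @ r)
    active = fit.u != 0.0
    v_active = np.abs(g[active] + fit.lam * np.sign(fit.u[active]))
    v_inactive = np.maximum(np.abs(g[~active]) - fit.lam, 0.0)
    parts = np.concatenate([v_active, v_inactive, [abs(r.sum())]])
    return float(parts.max())


@dataclass
class ClassifierSpec:
    """Hyperparameter grids and fold counts for selection + classification.

    Defaults follow the standard protocol for this pipeline: an RBF-SVM
    bandwidth grid of seven decades 1e-3..1e3, a log-spaced LASSO penalty
    grid 1e-10..1e-1, and 10-fold outer cross-validation with nested
    inner folds for model selection.
    """

    gamma_grid: tuple = tuple(10.0 ** k for k in range(-3, 4))
    lasso_grid: tuple = tuple(np.logspace(-10, -1, 10))
    #: interpret lasso_grid as fractions of the analytic death-point
    #: lambda_max of each training set (glmnet-style), instead of absolute
    #: penalties
    lasso_grid_relative: bool = False
    folds: int = 10
    inner_folds: int = 5
    svm_C: float = 1.0
    #: looser solver settings for the many fits inside grid search
    lasso_tol: float = 1e-6
    lasso_max_iter: int = 5000

    def __post_init__(self) -> None:
        if not self.gamma_grid or not self.lasso_grid:
            raise ParameterError("grids must be non-empty")
        if self.folds < 2 or self.inner_folds < 2:
            raise ParameterError("need at least 2 folds")


def _resolve_lams(X, y, spec: ClassifierSpec) -> np.ndarray:
    """Absolute penalty sequence for one training set."""
    lams = np.asarray(spec.lasso_grid, dtype=float)
    if spec.lasso_grid_relative:
        yc = y - y.mean()
        lam_max = 2.0 * np.abs(X.T @ yc).max()
        lams = lams * max(lam_max, 1e-12)
    return lams


def _lasso_path_active(X, y, lams, spec):
    """Active sets along the descending-lambda path (warm-started)."""
    n = X.shape[0]
    order = np.argsort(lams)[::-1]
    model = Lasso(alpha=1.0, fit_intercept=True, warm_start=True,
                  tol=spec.lasso_tol, max_iter=spec.lasso_max_iter)
    out = [None] * len(lams)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for i in order:
            model.alpha = lams[i] / (2.0 * n)
            model.fit(X, y)
            out[i] = np.flatnonzero(model.coef_ != 0.0)
    return out


def _majority(y):
    vals, counts = np.unique(y, return_counts=True)
    return vals[np.argmax(counts)]


def _fit_predict_svm(X_tr, y_tr, X_te, active, gamma, C):
    if active.size == 0:
        return np.full(X_te.shape[0], _majority(y_tr))
    clf = SVC(C=C, kernel="rbf", gamma=gamma)
    clf.fit(X_tr[:, active], y_tr)
    return clf.predict(X_te[:, active])


def _inner_select(X, y, spec: ClassifierSpec, seed: int,
                  lams: np.ndarray | None = None):
    """Nested-CV choice of (lambda, gamma) on training rows only.

    Returns the pair with the best mean inner validation accuracy; ties are
    broken toward the larger (sparser) lambda, then the smaller gamma.
    Penalties that select identical columns share one SVM evaluation.
    """
    if lams is None:
        lams = _resolve_lams(X, y.astype(float), spec)
    gammas = np.asarray(spec.gamma_grid, dtype=float)
    inner = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True,
                            random_state=seed)
    acc = np.zeros((len(lams), len(gammas)))
    for tr, va in inner.split(X, y):
        actives = _lasso_path_active(X[tr], y[tr].astype(float), lams, spec)
        groups: dict[tuple, list[int]] = {}
        for li, active in enumerate(actives):
            groups.setdefault(tuple(active), []).append(li)
        for key_active, members in groups.items():
            active = np.asarray(key_active, dtype=int)
            for gi, g in enumerate(gammas):
                pred = _fit_predict_svm(X[tr], y[tr], X[va], active, g,
                                        spec.svm_C)
                score = np.mean(pred == y[va]) / spec.inner_folds
                for li in members:
                    acc[li, gi] += score
    best = None
    for li in range(len(lams)):
        for gi in range(len(gammas)):
            key = (acc[li, gi], lams[li], -gammas[gi])
            if best is None or key > best[0]:
                best = (key, li, gi)
    _, li, gi = best
    return float(lams[li]), float(gammas[gi])


@dataclass
class CVResult:
    """Outer cross-validation outcome of selection + classification."""

    fold_scores: np.ndarray
    fold_fits: list[LassoFit]
    fold_test_idx: list[np.ndarray]
    chosen_params: list[tuple[float, float]]  # (lambda, gamma) per fold
    empty_fold_flags: list[bool]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_scores))


def select_and_classify(embedding, labels, spec: ClassifierSpec | None = None,
                        seed: int = 0) -> CVResult:
    """Outer-CV accuracy of LASSO column selection followed by an RBF-SVM.

    Within each outer fold, (lambda, gamma) are chosen by nested inner
    cross-validation on the training rows, the LASSO is refit at the chosen
    lambda, and the SVM is trained on the active columns and scored on the
    held-out rows.  A fold whose every lambda yields an empty active set
    falls back to majority-class prediction and is flagged.
    """
    spec = spec or ClassifierSpec()
    X = _as_matrix(embedding)
    y = np.asarray(labels)
    outer = StratifiedKFold(n_splits=spec.folds, shuffle=True,
                            random_state=seed)
    scores, fits, test_idx, chosen, flags = [], [], [], [], []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        lams = _resolve_lams(X[tr], y[tr].astype(float), spec)
        lam, gamma = _inner_select(X[tr], y[tr], spec, seed=seed + 1000 + k,
                                   lams=lams)
        fit = lasso_fit(X[tr], y[tr], lam, tol=spec.lasso_tol,
                        max_iter=spec.lasso_max_iter)
        empty = fit.n_active == 0
        pred = _fit_predict_svm(X[tr], y[tr], X[te], fit.active_set, gamma,
                                spec.svm_C)
        scores.append(np.mean(pred == y[te]))
        fits.append(fit)
        test_idx.append(te)
        chosen.append((lam, gamma))
        flags.append(empty)
    return CVResult(np.asarray(scores), fits, test_idx, chosen, flags)


@dataclass
class FoldEmbedding:
    """Per-fold similarity blocks with train/test rows kept apart.

    ``blocks`` maps the window-size index (tau as a multiple of dtau) to a
    (train matrix, test matrix) pair whose concepts were built from the
    training rows only; ``column_times`` gives the source-window center time
    of every concept column.
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    blocks: dict[int, tuple[np.ndarray, np.ndarray]]
    column_times: dict[int, np.ndarray]
    taus: dict[int, float]


def folds_from_full_blocks(blocks_by_index: dict[int, SimilarityBlock],
                           labels, folds: int, seed: int = 0
                           ) -> list[FoldEmbedding]:
    """Row-split precomputed full blocks into stratified CV folds.

    Convenience path for experiments on fixed feature matrices: the concept
    dictionary behind the blocks is shared, so strict dictionary hygiene
    (concepts from training rows only) must be enforced upstream — the
    pipeline builder does so; this helper merely splits rows.
    """
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out = []
    for tr, te in skf.split(np.zeros_like(y), y):
        blocks = {i: (b.matrix[tr], b.matrix[te])
                  for i, b in blocks_by_index.items()}
        times = {
            i: (b.concept_times if b.concept_times is not None
                else np.full(b.n_concepts, np.nan))
            for i, b in blocks_by_index.items()
        }
        taus = {i: b.tau for i, b in blocks_by_index.items()}
        out.append(FoldEmbedding(tr, te, blocks, times, taus))
    return out


@dataclass
class SearchResult:
    """Outcome of the exhaustive (q, p) expansion search."""

    tau_indices: np.ndarray  # sorted window-size indices
    accuracy_matrix: np.ndarray  # (n, n), NaN below the diagonal
    cell_fold_scores: dict[tuple[int, int], np.ndarray]
    best_q: int
    best_p: int
    fold_scores: np.ndarray  # of the best cell
    best_fits: list[LassoFit]
    #: one column-time vector per fold (concept counts differ across folds)
    best_column_times: list[np.ndarray]
    best_chosen_params: list[tuple[float, float]]

    @property
    def n_configurations(self) -> int:
        n = len(self.tau_indices)
        return n * (n + 1) // 2

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_scores))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_scores))


def _evaluate_cell(fold_embs, labels, idx_range, spec, seed):
    y = np.asarray(labels)
    scores, fits, chosen, col_times = [], [], [], []
    for k, fe in enumerate(fold_embs):
        X_tr = np.concatenate([fe.blocks[i][0] for i in idx_range], axis=1)
        X_te = np.concatenate([fe.blocks[i][1] for i in idx_range], axis=1)
        times = np.concatenate([fe.column_times[i] for i in idx_range])
        y_tr, y_te = y[fe.train_idx], y[fe.test_idx]
        lams = _resolve_lams(X_tr, y_tr.astype(float), spec)
        lam, gamma = _inner_select(X_tr, y_tr, spec, seed=seed + 1000 + k,
                                   lams=lams)
        fit = lasso_fit(X_tr, y_tr, lam, tol=spec.lasso_tol,
                        max_iter=spec.lasso_max_iter)
        pred = _fit_predict_svm(X_tr, y_tr, X_te, fit.active_set, gamma,
                                spec.svm_C)
        scores.append(np.mean(pred == y_te))
        fits.append(fit)
        chosen.append((lam, gamma))
        col_times.append(times)
    return np.asarray(scores), fits, chosen, col_times


def algorithm1_search(blocks, labels, spec: ClassifierSpec | None = None,
                      seed: int = 0, delta_tau: float = 0.1,
                      cells: list[tuple[int, int]] | None = None
                      ) -> SearchResult:
    """Evaluate every contiguous window-size range (q <= p) and pick the best.

    ``blocks`` is either a mapping of window-size index to a full
    :class:`SimilarityBlock` (rows are then split into stratified folds
    here) or a pre-built list of :class:`FoldEmbedding` from the pipeline.
    ``cells`` optionally restricts the search to specific (q, p) pairs of
    window-size indices; by default every admissible pair is evaluated.
    The best cell maximizes mean CV accuracy; ties are broken toward the
    smallest total column count, then the smallest p.
    """
    spec = spec or ClassifierSpec()
    if isinstance(blocks, dict):
        fold_embs = folds_from_full_blocks(blocks, labels, spec.folds, seed)
    else:
        fold_embs = list(blocks)
    if not fold_embs:
        raise DataError("no folds to evaluate")
    indices = np.array(sorted(fold_embs[0].blocks.keys()))
    n = len(indices)
    pos_of = {int(v): i for i, v in enumerate(indices)}
    if cells is None:
        wanted = [(qi, pi) for qi in range(n) for pi in range(qi, n)]
    else:
        wanted = []
        for q, p in cells:
            if q not in pos_of or p not in pos_of or pos_of[q] > pos_of[p]:
                raise ParameterError(f"invalid cell ({q}, {p})")
            wanted.append((pos_of[q], pos_of[p]))
    acc = np.full((n, n), np.nan)
    cell_scores: dict[tuple[int, int], np.ndarray] = {}
    best = None
    for qi, pi in wanted:
        idx_range = indices[qi:pi + 1]
        scores, fits, chosen, times = _evaluate_cell(
            fold_embs, labels, idx_range, spec, seed)
        acc[qi, pi] = scores.mean()
        cell_scores[(int(indices[qi]), int(indices[pi]))] = scores
        ncols = sum(fold_embs[0].blocks[i][0].shape[1] for i in idx_range)
        key = (scores.mean(), -ncols, -int(indices[pi]))
        if best is None or key > best[0]:
            best = (key, qi, pi, scores, fits, chosen, times)
    _, qi, pi, scores, fits, chosen, times = best
    return SearchResult(
        tau_indices=indices,
        accuracy_matrix=acc,
        cell_fold_scores=cell_scores,
        best_q=int(indices[qi]),
        best_p=int(indices[pi]),
        fold_scores=scores,
        best_fits=fits,
        best_column_times=times,
        best_chosen_params=chosen,
    )


@dataclass
class TemporalProfile:
    """Normalized absolute LASSO mass over the motor-imagery time axis."""

    time_grid: np.ndarray
    per_fold: np.ndarray  # (folds, len(time_grid)), each max-normalized
    weights_by_time: np.ndarray  # aggregate profile, max 1 (or all zero)
    zero_fold_flags: np.ndarray


def temporal_profile(fits: list[LassoFit], column_times,
                     time_grid: np.ndarray) -> TemporalProfile:
    """Aggregate per-fold |u| onto the time axis of the source windows.

    Each active column's |u| mass is assigned to the grid point nearest its
    concept's source-window center; every fold's profile is normalized to
    max 1 (an all-zero fit stays zero and is flagged).  ``column_times`` is
    one vector per fold, or a single vector shared by all folds.
    """
    if isinstance(column_times, np.ndarray) and column_times.ndim == 1:
        column_times = [column_times] * len(fits)
    time_grid = np.asarray(time_grid, dtype=float)
    per_fold = np.zeros((len(fits), len(time_grid)))
    flags = np.zeros(len(fits), dtype=bool)
    for k, fit in enumerate(fits):
        times = np.asarray(column_times[k], dtype=float)
        mass = np.abs(fit.u)
        if mass.shape[0] != times.shape[0]:
            raise DataError("fit length does not match column bookkeeping")
        for j in np.flatnonzero(mass):
            if np.isnan(times[j]):
                continue
            g = int(np.argmin(np.abs(time_grid - times[j])))
            per_fold[k, g] += mass[j]
        m = per_fold[k].max()
        if m > 0:
            per_fold[k] /= m
        else:
            flags[k] = True
    agg = per_fold.mean(axis=0)
    if agg.max() > 0:
        agg = agg / agg.max()
    return TemporalProfile(time_grid, per_fold, agg, flags)
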