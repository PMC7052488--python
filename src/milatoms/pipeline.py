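"""End-to-end orchestration of the bag-of-patterns pipeline.

One call runs: filter-bank decomposition -> per-(band, window) CSP atoms ->
optional MILR atom refinement -> per-window-length similarity embedding ->
expansion search with LASSO selection and SVM classification.  Everything
that learns from labels (CSP filters, MILR models, concept dictionaries, the
kernel bandwidth, lambda and the SVM bandwidth) is fitted inside the outer
training folds only, so reported accuracies carry no leakage.  A single
global seed fans out deterministically to every stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold

from . import __version__ as _version
from .classify import (ClassifierSpec, FoldEmbedding, SearchResult,
                       TemporalProfile, algorithm1_search, temporal_profile)
from .csp import (RayleighMap, _class_covs_from_trial_covs, AtomBag,
                  atoms_from_covariances, fit_csp, rayleigh_map,
                  window_covariances)
from .embedding import SimilarityParams, build_dictionary, embed_bags
from .exceptions import DataError, ParameterError
from .milr import milr_fit, milr_fit_cv, refine_atoms
from .preprocess import EEGTrialSet, apply_filter_bank, design_filter_bank, \
    plan_windows

__all__ = ["PipelineConfig", "RunProvenance", "PipelineResult",
           "run_pipeline", "report", "smoke_config"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    The defaults are the full-scale protocol (17-band 4-40 Hz bank, 19
    window lengths 0.2-2.0 s, M = 3 CSP pairs, 10-fold CV with nested inner
    selection); :func:`smoke_config` returns a reduced variant that keeps
    the statistical structure while running on a desktop budget.

    ``milr_alpha`` is specified per instance: the raw L1 weight handed to
    the solver is ``milr_alpha * n_training_instances``, which keeps the
    penalty commensurate with the (summed, not averaged) log-likelihood as
    bag counts change.  ``"auto"`` picks it by bag-level cross-validation
    over ``milr_alpha_grid``.
    """

    # filter bank
    f_min: float = 4.0
    f_max: float = 40.0
    bandwidth: float = 4.0
    band_step: float = 2.0
    filter_order: int = 5
    causal: bool = False
    # analysis segment within the trial
    segment_start_s: float = 0.0
    segment_len_s: float | None = None
    # windowing
    overlap: float = 0.9
    taus: tuple = tuple(round(0.2 + 0.1 * i, 1) for i in range(19))
    delta_tau: float = 0.1
    # CSP
    csp_M: int = 3
    shrinkage: float | str = "auto"
    trace_normalize: bool = True
    # MILR refinement
    refine_enabled: bool = True
    milr_alpha: float | str = "auto"
    milr_alpha_grid: tuple = (3e-4, 1e-3, 3e-3, 1e-2)
    milr_cv_folds: int = 3
    milr_tol: float = 1e-6
    milr_max_sweeps: int = 300
    # embedding: median-heuristic bandwidth, shared across window lengths
    # (pooling the pairwise distances of every length's refined instances)
    # or chosen per window length
    sigma_rule: float | str = "median"
    sigma_shared: bool = True
    # selection + classification
    lasso_grid: tuple = tuple(np.logspace(-10, -1, 10))
    lasso_grid_relative: bool = False
    gamma_grid: tuple = tuple(10.0 ** k for k in range(-3, 4))
    folds: int = 10
    inner_folds: int = 5
    svm_C: float = 1.0
    lasso_tol: float = 1e-6
    lasso_max_iter: int = 5000
    # expansion search; None/None searches every admissible (q, p) cell
    q_index: int | None = None
    p_index: int | None = None
    seed: int = 0

    def tau_index(self, tau: float) -> int:
        idx = tau / self.delta_tau
        if abs(idx - round(idx)) > 1e-6:
            raise ParameterError(f"tau {tau} is not a multiple of delta_tau")
        return int(round(idx))

    def classifier_spec(self) -> ClassifierSpec:
        return ClassifierSpec(
            gamma_grid=tuple(self.gamma_grid),
            lasso_grid=tuple(self.lasso_grid),
            lasso_grid_relative=self.lasso_grid_relative,
            folds=self.folds,
            inner_folds=self.inner_folds,
            svm_C=self.svm_C,
            lasso_tol=self.lasso_tol,
            lasso_max_iter=self.lasso_max_iter,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["taus"] = [float(t) for t in self.taus]
        d["lasso_grid"] = [float(x) for x in self.lasso_grid]
        d["gamma_grid"] = [float(x) for x in self.gamma_grid]
        d["milr_alpha_grid"] = [float(x) for x in self.milr_alpha_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("taus", "lasso_grid", "gamma_grid", "milr_alpha_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def smoke_config(seed: int = 0) -> PipelineConfig:
    """Reduced configuration: 4 bands (4-20 Hz), three window lengths.

    Keeps the full trial count, channel montage, M = 3 and 10-fold outer CV
    of the standard protocol while shrinking the grids that only multiply
    runtime.  The bank still straddles the mu band where the simulated ERD
    lives, and the window lengths 0.4/1.0/2.0 s bracket the simulated
    0.4-1.0 s interval.
    """
    return PipelineConfig(
        f_max=20.0,
        band_step=4.0,
        taus=(0.4, 1.0, 2.0),
        lasso_grid=tuple(np.logspace(-2.5, -0.5, 5)),
        lasso_grid_relative=True,
        lasso_tol=1e-4,
        inner_folds=3,
        milr_alpha_grid=(1e-3, 3e-3),
        milr_cv_folds=2,
        milr_max_sweeps=200,
        seed=seed,
    )


@dataclass
class RunProvenance:
    """Everything needed to reproduce and audit a run."""

    seed: int
    stage_seeds: dict
    fold_test_indices: list
    config: dict
    version: str
    result_hash: str


@dataclass
class PipelineResult:
    search: SearchResult
    profile: TemporalProfile
    spectral: RayleighMap
    provenance: RunProvenance
    config: PipelineConfig


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    names = ("folds", "milr", "sigma", "search")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


def _fit_fold_tau(covs, labels, train_idx, cfg, tau, milr_seed):
    """CSP + atoms + (optional) MILR refinement for one (fold, tau).

    Returns one bag per trial (refined when enabled) plus the refinement
    mask.  CSP filters and the MILR model see training trials only.
    """
    R, F, Nt, C, _ = covs.shape
    y = labels
    M = cfg.csp_M
    W_ret = np.empty((F, Nt, 2 * M, C))
    for f in range(F):
        for t in range(Nt):
            cc = _class_covs_from_trial_covs(covs[train_idx, f, t],
                                             y[train_idx], f, t)
            model = fit_csp(cc, M=M, shrinkage=cfg.shrinkage)
            W_ret[f, t] = model.W_retained
    atoms = atoms_from_covariances(W_ret, covs)  # (R, Nt, 2M*F)
    bags = [AtomBag(trial=r, instances=atoms[r], tau=tau, label=int(y[r]))
            for r in range(R)]
    train_bags = [bags[r] for r in train_idx]
    if not cfg.refine_enabled:
        return bags, None
    n_inst = sum(b.n_instances for b in train_bags)
    if cfg.milr_alpha == "auto":
        grid = np.asarray(cfg.milr_alpha_grid) * n_inst
        model, _, scores = milr_fit_cv(train_bags, grid,
                                       folds=cfg.milr_cv_folds,
                                       seed=milr_seed, tol=cfg.milr_tol,
                                       max_sweeps=cfg.milr_max_sweeps)
        if not np.any(model.beta != 0.0):
            # refinement needs a non-empty support: fall back through the
            # remaining candidates in order of their CV score
            for a in grid[np.argsort(scores)[::-1]]:
                model = milr_fit(train_bags, alpha=float(a), tol=cfg.milr_tol,
                                 max_sweeps=cfg.milr_max_sweeps)
                if np.any(model.beta != 0.0):
                    break
    else:
        model = milr_fit(train_bags, alpha=float(cfg.milr_alpha) * n_inst,
                         tol=cfg.milr_tol, max_sweeps=cfg.milr_max_sweeps)
    refined, mask = refine_atoms(bags, model)
    return refined, mask


def _sigma_params(cfg, refined_by_tau, train_idx, seed, max_points=1000):
    """Kernel bandwidth per window length from training instances only.

    With ``sigma_shared`` the median heuristic is applied to the pooled
    pairwise squared distances of every window length's refined instance
    pool (refinement masks may differ per length, so distances rather than
    instances are pooled); otherwise each length gets its own median.
    """
    from scipy.spatial.distance import pdist

    if cfg.sigma_rule != "median":
        p = SimilarityParams(sigma=float(cfg.sigma_rule), rule="fixed")
        return {tau: p for tau in refined_by_tau}
    rng = np.random.default_rng(seed)
    d2_by_tau = {}
    for tau, bags in refined_by_tau.items():
        pool = np.concatenate([bags[r].instances for r in train_idx], axis=0)
        if pool.shape[0] > max_points:
            pool = pool[rng.choice(pool.shape[0], max_points, replace=False)]
        d2_by_tau[tau] = pdist(pool, metric="sqeuclidean")
    if cfg.sigma_shared:
        med = float(np.median(np.concatenate(list(d2_by_tau.values()))))
        if med <= 0:
            raise DataError("degenerate instance pools (zero median distance)")
        p = SimilarityParams(sigma=float(np.sqrt(med)), rule="median")
        return {tau: p for tau in refined_by_tau}
    out = {}
    for tau, d2 in d2_by_tau.items():
        med = float(np.median(d2))
        if med <= 0:
            raise DataError("degenerate instance pool (zero median distance)")
        out[tau] = SimilarityParams(sigma=float(np.sqrt(med)), rule="median")
    return out


def run_pipeline(trials: EEGTrialSet, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run the whole bag-of-patterns pipeline on one labeled trial set."""
    cfg = config or PipelineConfig()
    seeds = _stage_seeds(cfg.seed)
    bank = design_filter_bank(cfg.f_min, cfg.f_max, cfg.bandwidth,
                              cfg.band_step, cfg.filter_order)

    start = int(round(cfg.segment_start_s * trials.fs))
    if cfg.segment_len_s is None:
        stop = trials.n_samples
    else:
        stop = start + int(round(cfg.segment_len_s * trials.fs))
    if not (0 <= start < stop <= trials.n_samples):
        raise ParameterError("analysis segment outside the trial")
    segment = EEGTrialSet(trials.data[:, :, start:stop], trials.labels,
                          trials.fs)

    filtered = apply_filter_bank(segment, bank, causal=cfg.causal)
    schemes, covs_by_tau = {}, {}
    for tau in cfg.taus:
        scheme = plan_windows(segment.n_samples, tau, trials.fs, cfg.overlap)
        schemes[tau] = scheme
        covs_by_tau[tau] = window_covariances(filtered, scheme,
                                              cfg.trace_normalize)

    y = segment.labels
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                          random_state=seeds["folds"])
    fold_embs: list[FoldEmbedding] = []
    fold_test = []
    for k, (tr, te) in enumerate(skf.split(np.zeros_like(y), y)):
        fold_test.append(te)
        refined_by_tau = {}
        for tau in cfg.taus:
            bags, _ = _fit_fold_tau(covs_by_tau[tau], y, tr, cfg, tau,
                                    milr_seed=seeds["milr"] + k)
            refined_by_tau[tau] = bags
        params_by_tau = _sigma_params(cfg, refined_by_tau, tr, seeds["sigma"])
        blocks, times, taus_of = {}, {}, {}
        for tau in cfg.taus:
            bags = refined_by_tau[tau]
            params = params_by_tau[tau]
            train_bags = [bags[r] for r in tr]
            test_bags = [bags[r] for r in te]
            dictionary = build_dictionary(train_bags, tau)
            centers = schemes[tau].centers_s + cfg.segment_start_s
            concept_times = np.array(
                [centers[t] for (_, t) in dictionary.source_index])
            s_train = embed_bags(train_bags, dictionary, params, concept_times)
            s_test = embed_bags(test_bags, dictionary, params, concept_times)
            idx = cfg.tau_index(tau)
            blocks[idx] = (s_train.matrix, s_test.matrix)
            times[idx] = concept_times
            taus_of[idx] = tau
        fold_embs.append(FoldEmbedding(tr, te, blocks, times, taus_of))

    spec = cfg.classifier_spec()
    cells = None
    if cfg.q_index is not None and cfg.p_index is not None:
        cells = [(cfg.q_index, cfg.p_index)]
    search = algorithm1_search(fold_embs, y, spec, seed=seeds["search"],
                               delta_tau=cfg.delta_tau, cells=cells)

    best_taus = [tau for tau in cfg.taus
                 if search.best_q <= cfg.tau_index(tau) <= search.best_p]
    finest = min(best_taus)
    grid = schemes[finest].centers_s + cfg.segment_start_s
    profile = temporal_profile(search.best_fits, search.best_column_times,
                               grid)

    spectral = rayleigh_map(segment, bank, tau=max(cfg.taus),
                            overlap=cfg.overlap, M=cfg.csp_M,
                            shrinkage=cfg.shrinkage,
                            trace_normalize=cfg.trace_normalize)

    hasher = hashlib.sha256()
    for fit in search.best_fits:
        hasher.update(np.ascontiguousarray(fit.u).tobytes())
    provenance = RunProvenance(
        seed=cfg.seed,
        stage_seeds=seeds,
        fold_test_indices=[t.tolist() for t in fold_test],
        config=cfg.to_dict(),
        version=_version,
        result_hash=hasher.hexdigest(),
    )
    return PipelineResult(search, profile, spectral, provenance, cfg)


def report(result: PipelineResult | None, outdir: str | Path) -> None:
    """Render a run's accuracy matrix, spectral relevance and time profiles.

    Writes a JSON summary plus PNG figures into ``outdir``; never mutates
    the result.  An absent or empty result produces a graceful note instead
    of figures.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if result is None or result.search is None or \
            result.search.accuracy_matrix.size == 0:
        (outdir / "summary.txt").write_text("no results\n")
        return

    s = result.search
    summary = {
        "mean_accuracy": s.mean_accuracy,
        "std_accuracy": s.std_accuracy,
        "best_q": s.best_q,
        "best_p": s.best_p,
        "tau_indices": [int(i) for i in s.tau_indices],
        "fold_scores": [float(x) for x in s.fold_scores],
        "accuracy_matrix": [
            [None if np.isnan(v) else float(v) for v in row]
            for row in s.accuracy_matrix
        ],
        "n_configurations_evaluated": int(np.sum(~np.isnan(s.accuracy_matrix))),
        "provenance": {
            "seed": result.provenance.seed,
            "version": result.provenance.version,
            "result_hash": result.provenance.result_hash,
        },
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(s.accuracy_matrix, origin="lower", vmin=0.5, vmax=1.0,
                   cmap="viridis")
    ax.set_xlabel("p (largest window-size index)")
    ax.set_ylabel("q (smallest window-size index)")
    ax.set_xticks(range(len(s.tau_indices)), [str(i) for i in s.tau_indices])
    ax.set_yticks(range(len(s.tau_indices)), [str(i) for i in s.tau_indices])
    fig.colorbar(im, ax=ax, label="mean CV accuracy")
    fig.tight_layout()
    fig.savefig(outdir / "accuracy_matrix.png", dpi=120)
    plt.close(fig)

    sp = result.spectral
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(sp.band_centers, sp.spectral_relevance, width=1.6, color="0.5")
    ax.set_xlabel("band center [Hz]")
    ax.set_ylabel("spectral relevance (marginal J)")
    fig.tight_layout()
    fig.savefig(outdir / "spectral_relevance.png", dpi=120)
    plt.close(fig)

    pr = result.profile
    fig, ax = plt.subplots(figsize=(5, 3))
    for row in pr.per_fold:
        ax.plot(pr.time_grid, row, color="0.7", lw=0.8)
    ax.plot(pr.time_grid, pr.weights_by_time, color="C3", lw=2,
            label="aggregate")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("normalized |LASSO| mass")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "temporal_profile.png", dpi=120)
    plt.close(fig)
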