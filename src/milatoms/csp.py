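"""Common Spatial Patterns per (band, window) and time-frequency atoms.

For a pair of class covariance matrices the CSP transformation maximizes the
Rayleigh quotient J(w) = (w' S+ w)/(w' S- w); its rows are generalized
eigenvectors sorted by eigenvalue, and the M first plus M last rows are the
most discriminative projections for either class.  Concatenating the
log-normalized variances of those 2M projections over all filter-bank bands
yields the "time-frequency atom" d_rt of one trial and one window; a trial's
windows form its bag for multiple-instance learning.

Covariances of 50-sample, 22-channel windows are badly conditioned, so a
Ledoit-Wolf-style shrinkage toward a scaled identity is applied before the
generalized eigenproblem (intensity estimated from the spread of per-trial
covariances by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import DataError, NumericalError, ParameterError
from .preprocess import EEGTrialSet, FilterBankConfig, WindowScheme, \
    apply_filter_bank, plan_windows

__all__ = [
    "ClassCovariances",
    "CSPModel",
    "AtomBag",
    "RayleighMap",
    "window_covariances",
    "estimate_class_covariances",
    "fit_csp",
    "extract_atom",
    "atoms_from_covariances",
    "build_bags",
    "rayleigh_map",
    "group_concat",
]


def window_covariances(filtered: np.ndarray, scheme: WindowScheme,
                       trace_normalize: bool = True) -> np.ndarray:
    """Per-trial spatial covariance of every (band, window) cell.

    Parameters
    ----------
    filtered : ndarray, (trials, bands, channels, samples)
    trace_normalize : bool
        Divide each covariance by its trace, removing inter-trial amplitude
        differences.  Atom features are invariant to this choice (variance
        ratios cancel); class covariance averages are not.

    Returns
    -------
    ndarray, (trials, bands, n_windows, channels, channels)
    """
    R, F, C, _ = filtered.shape
    out = np.empty((R, F, scheme.n_windows, C, C))
    T = scheme.win_samples
    for i, s in enumerate(scheme.starts):
        X = filtered[..., s:s + T]
        X = X - X.mean(axis=-1, keepdims=True)
        out[:, :, i] = np.einsum("rfct,rfdt->rfcd", X, X) / T
    if trace_normalize:
        tr = np.einsum("rfwcc->rfw", out)[..., None, None]
        tr[tr == 0] = 1.0
        out = out / tr
    return out


@dataclass
class ClassCovariances:
    """Class-conditional spatial covariances for one (band, window) cell."""

    sigma_pos: np.ndarray
    sigma_neg: np.ndarray
    band: int | None = None
    window: int | None = None
    #: suggested shrinkage intensity from the per-trial covariance spread
    lw_intensity: float = 0.0

    def __post_init__(self) -> None:
        for s in (self.sigma_pos, self.sigma_neg):
            if not np.allclose(s, s.T, atol=1e-8):
                raise DataError("class covariance is not symmetric")
            if np.linalg.eigvalsh(s).min() < -1e-8 * max(1.0, np.trace(s)):
                raise DataError("class covariance has negative eigenvalues")


def _lw_intensity(trial_covs: np.ndarray, mean_cov: np.ndarray) -> float:
    """Ledoit-Wolf-style shrinkage intensity toward mu*I.

    Uses the per-trial covariance matrices as the i.i.d. observations: the
    numerator is the estimation variance of the mean covariance, the
    denominator the distance of the mean from the scaled-identity target.
    """
    n = trial_covs.shape[0]
    if n < 2:
        return 0.0
    C = mean_cov.shape[0]
    mu = np.trace(mean_cov) / C
    num = np.mean(np.sum((trial_covs - mean_cov) ** 2, axis=(-2, -1))) / n
    den = np.sum((mean_cov - mu * np.eye(C)) ** 2)
    if den <= 1e-30:
        return 1.0
    return float(min(1.0, num / den))


def estimate_class_covariances(
    windowed: np.ndarray,
    labels: np.ndarray,
    band: int,
    window: int,
    trace_normalize: bool = True,
) -> ClassCovariances:
    """Average per-trial covariances of one (band, window) cell by class.

    ``windowed`` is the (trials, bands, windows, channels, win_samples)
    tensor from :func:`preprocess.segment_trials`.
    """
    labels = np.asarray(labels)
    X = windowed[:, band, window]  # (trials, channels, T)
    X = X - X.mean(axis=-1, keepdims=True)
    covs = np.einsum("rct,rdt->rcd", X, X) / X.shape[-1]
    if trace_normalize:
        tr = np.einsum("rcc->r", covs)[:, None, None]
        tr[tr == 0] = 1.0
        covs = covs / tr
    out = {}
    lw = 0.0
    for lab, key in ((1, "pos"), (-1, "neg")):
        sel = covs[labels == lab]
        if sel.shape[0] == 0:
            raise DataError(f"no trials with label {lab:+d}")
        mean = sel.mean(axis=0)
        mean = (mean + mean.T) / 2.0
        out[key] = mean
        lw = max(lw, _lw_intensity(sel, mean))
    return ClassCovariances(out["pos"], out["neg"], band, window, lw)


@dataclass
class CSPModel:
    """Fitted CSP transformation for one (band, window) cell.

    ``W`` holds one unit-norm spatial filter per row, sorted by generalized
    eigenvalue (the Rayleigh quotient J) in descending order;
    ``retained_rows`` indexes the M first and M last rows.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    M: int
    retained_rows: np.ndarray

    @property
    def W_retained(self) -> np.ndarray:
        """The 2M retained spatial filters, shape (2M, channels)."""
        return self.W[self.retained_rows]


def _shrink(sigma: np.ndarray, gamma: float) -> np.ndarray:
    C = sigma.shape[0]
    mu = np.trace(sigma) / C
    return (1.0 - gamma) * sigma + gamma * mu * np.eye(C)


def fit_csp(cov: ClassCovariances, M: int = 3,
            shrinkage: float | str = "auto") -> CSPModel:
    """Solve the generalized eigenproblem S+ w = lambda S- w.

    Rows of the returned ``W`` are sorted by eigenvalue descending and
    normalized to unit Euclidean norm (J is scale invariant in w, so the
    normalization does not change the eigenvalues).  The sign of each row is
    fixed by making its largest-magnitude entry positive, for deterministic
    output across linear-algebra backends.

    ``shrinkage`` is the identity-shrinkage intensity applied to both class
    covariances; ``"auto"`` uses the intensity estimated from the per-trial
    covariance spread by :func:`estimate_class_covariances`.
    """
    C = cov.sigma_pos.shape[0]
    if not 1 <= 2 * M <= C:
        raise ParameterError(f"need 1 <= 2M <= {C} channels, got M={M}")
    gamma = cov.lw_intensity if shrinkage == "auto" else float(shrinkage)
    sp = _shrink(cov.sigma_pos, gamma)
    sn = _shrink(cov.sigma_neg, gamma)
    min_eig = np.linalg.eigvalsh(sn).min()
    if min_eig <= 1e-14 * max(1.0, np.trace(sn)):
        raise NumericalError(
            "sigma_neg is singular; enable shrinkage (shrinkage='auto' or a "
            "positive intensity) to regularize short-window covariances"
        )
    try:
        eigvals, eigvecs = linalg.eigh(sp, sn)
    except linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"generalized eigensolver failed: {exc}") from exc
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    W = eigvecs[:, order].T
    W = W / np.linalg.norm(W, axis=1, keepdims=True)
    flip = np.sign(W[np.arange(C), np.argmax(np.abs(W), axis=1)])
    W = W * flip[:, None]
    retained = np.r_[np.arange(M), np.arange(C - M, C)]
    return CSPModel(W=W, eigenvalues=eigvals, M=M, retained_rows=retained)


def extract_atom(Z_bands: np.ndarray) -> np.ndarray:
    """Log-normalized variance atom from CSP-projected windows.

    Parameters
    ----------
    Z_bands : ndarray, shape (n_bands, 2M, T)
        The retained projected rows of one trial-window, per band.

    Returns
    -------
    ndarray, length 2M * n_bands
        Per band the entries are ``ln(v_m / sum_m' v_m')`` where ``v_m`` is
        the temporal variance of projected row m; band blocks are
        concatenated in filter-bank order.  Within each block
        ``sum_m exp(d_m) = 1`` by construction.
    """
    Z_bands = np.asarray(Z_bands, dtype=np.float64)
    if Z_bands.ndim != 3:
        raise DataError("expected (bands, 2M, T) projected windows")
    Zc = Z_bands - Z_bands.mean(axis=-1, keepdims=True)
    v = np.mean(Zc ** 2, axis=-1)  # (bands, 2M)
    tot = v.sum(axis=-1, keepdims=True)
    if np.any(tot <= 0):
        raise DataError("zero total variance in a band (degenerate window)")
    return np.log(v / tot).ravel()


def atoms_from_covariances(W_ret: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Atoms for all trials of one window scheme, from covariances alone.

    The temporal variance of a projected row is the quadratic form
    ``w' C w`` of the window covariance, so atoms never need the projected
    time series explicitly.

    Parameters
    ----------
    W_ret : ndarray, (bands, n_windows, 2M, channels)
        Retained CSP filters per (band, window).
    covs : ndarray, (trials, bands, n_windows, channels, channels)

    Returns
    -------
    ndarray, (trials, n_windows, 2M * bands)
    """
    v = np.einsum("fwmc,rfwcd,fwmd->rwfm", W_ret, covs, W_ret,
                  optimize=True)
    v = np.maximum(v, 1e-300)
    tot = v.sum(axis=-1, keepdims=True)
    d = np.log(v / tot)
    R, Nt, F, M2 = d.shape
    return d.reshape(R, Nt, F * M2)


@dataclass
class AtomBag:
    """All time-frequency atoms of one trial at one window length."""

    trial: int
    instances: np.ndarray  # (n_windows, 2M * n_bands)
    tau: float
    label: int

    def __post_init__(self) -> None:
        self.instances = np.asarray(self.instances, dtype=np.float64)
        if self.instances.ndim != 2:
            raise DataError("instances must be (n_windows, dim)")
        if not np.all(np.isfinite(self.instances)):
            raise DataError("non-finite atom entries")

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]


def build_bags(atoms: np.ndarray, labels: np.ndarray, tau: float) -> list[AtomBag]:
    """One bag per trial from the (trials, windows, dim) atom tensor."""
    labels = np.asarray(labels)
    if atoms.shape[0] != labels.shape[0]:
        raise DataError("atoms and labels disagree on trial count")
    return [
        AtomBag(trial=r, instances=atoms[r], tau=tau, label=int(labels[r]))
        for r in range(atoms.shape[0])
    ]


@dataclass
class RayleighMap:
    """Peak Rayleigh quotient per (band, window) and its spectral marginal."""

    J_values: np.ndarray  # (bands, windows)
    spectral_relevance: np.ndarray  # (bands,)
    band_centers: np.ndarray
    window_centers_s: np.ndarray


def rayleigh_map(
    trials: EEGTrialSet,
    bank: FilterBankConfig,
    tau: float = 2.0,
    overlap: float = 0.9,
    M: int = 3,
    shrinkage: float | str = "auto",
    aggregate: str = "mean",
    trace_normalize: bool = True,
) -> RayleighMap:
    """Class-separability map: top Rayleigh quotient per (band, window).

    ``spectral_relevance`` is the per-band marginal over windows
    (``aggregate`` one of mean/max/sum); its peak marks the rhythm carrying
    the class difference.
    """
    filtered = apply_filter_bank(trials, bank)
    scheme = plan_windows(trials.n_samples, tau, trials.fs, overlap)
    covs = window_covariances(filtered, scheme, trace_normalize)
    J = np.empty((bank.n_bands, scheme.n_windows))
    for f in range(bank.n_bands):
        for t in range(scheme.n_windows):
            cc = _class_covs_from_trial_covs(covs[:, f, t], trials.labels, f, t)
            model = fit_csp(cc, M=M, shrinkage=shrinkage)
            J[f, t] = model.eigenvalues[0]
    if aggregate == "mean":
        rel = J.mean(axis=1)
    elif aggregate == "max":
        rel = J.max(axis=1)
    elif aggregate == "sum":
        rel = J.sum(axis=1)
    else:
        raise ParameterError(f"unknown aggregate {aggregate!r}")
    return RayleighMap(J, rel, bank.centers, scheme.centers_s)


def _class_covs_from_trial_covs(trial_covs: np.ndarray, labels: np.ndarray,
                                band: int | None = None,
                                window: int | None = None) -> ClassCovariances:
    """Class averages of precomputed per-trial covariances."""
    out = {}
    lw = 0.0
    for lab, key in ((1, "pos"), (-1, "neg")):
        sel = trial_covs[labels == lab]
        if sel.shape[0] == 0:
            raise DataError(f"no trials with label {lab:+d}")
        mean = sel.mean(axis=0)
        mean = (mean + mean.T) / 2.0
        out[key] = mean
        lw = max(lw, _lw_intensity(sel, mean))
    return ClassCovariances(out["pos"], out["neg"], band, window, lw)


def group_concat(trial_sets: list[EEGTrialSet]) -> EEGTrialSet:
    """Stack several subjects' trials into a single group trial set."""
    if not trial_sets:
        raise DataError("no trial sets to concatenate")
    first = trial_sets[0]
    for ts in trial_sets[1:]:
        if ts.n_channels != first.n_channels or ts.n_samples != first.n_samples:
            raise DataError("trial sets disagree on channels or samples")
        if ts.fs != first.fs:
            raise DataError("trial sets disagree on sampling rate")
    return EEGTrialSet(
        data=np.concatenate([ts.data for ts in trial_sets], axis=0),
        labels=np.concatenate([ts.labels for ts in trial_sets]),
        fs=first.fs,
    )
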