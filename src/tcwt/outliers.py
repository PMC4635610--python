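"""PCA sphering, Mahalanobis distances, and iterative multivariate outlier
rejection of single ERP trials in the frequency domain.

A trial is an outlier when the square root D of its Mahalanobis distance to
the sample mean — computed in the retained principal-component subspace —
exceeds mean(D) + C*SD(D) over the currently accepted trials.  The procedure
alternates PCA refits and re-flagging until the flagged set is stable; the
number of retained components Q_p is frozen once it repeats in two
consecutive iterations, and an anti-oscillation rule re-marks the previous
iteration's outliers whenever the flagged count fails to grow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .epochs import ErpEpochs

__all__ = [
    "PcaModel",
    "OutlierReport",
    "fit_pca",
    "mahalanobis_sq",
    "detect_outliers",
    "per_condition_outliers",
    "project_filtered",
]

_EIG_FLOOR = 1e-12  # relative floor below which components are discarded


@dataclass
class PcaModel:
    """Principal component transform of a trial sample.

    ``loadings`` holds the orthonormal eigenvectors (columns, by decreasing
    eigenvalue) of the unbiased total covariance matrix; numerically null
    components (eigenvalue < 1e-12 of the maximum) are already dropped.
    ``retained`` indexes the columns kept by the retention criterion.
    """

    mean: np.ndarray
    loadings: np.ndarray
    eigvals: np.ndarray
    retained: np.ndarray
    criterion: str

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def reduced_loadings(self) -> np.ndarray:
        """T_hat_p: the retained columns of the loading matrix."""
        return self.loadings[:, self.retained]


@dataclass
class OutlierReport:
    trial_flags: np.ndarray          # (N,) bool
    dataset_flags: dict              # dataset id -> bool
    n_components: int                # Q_p at the final iteration
    iterations: int
    distances: np.ndarray            # final per-trial D (not squared)
    C: float
    converged: bool
    dataset_ids: np.ndarray = None

    @property
    def excluded(self) -> np.ndarray:
        """Trials excluded either individually or with their whole dataset."""
        out = self.trial_flags.copy()
        if self.dataset_ids is not None:
            for ds, bad in self.dataset_flags.items():
                if bad:
                    out |= self.dataset_ids == ds
        return out


def _apply_criterion(eigvals: np.ndarray, criterion) -> np.ndarray:
    if isinstance(criterion, str):
        if criterion != "average":
            raise ValueError(f"unknown PCA criterion {criterion!r}")
        kept = np.flatnonzero(eigvals > eigvals.mean())
        return kept if len(kept) else np.array([0])
    p_v = float(criterion)
    if not (0.0 < p_v <= 100.0):
        raise ValueError("proportion-of-variance criterion must be in (0, 100]")
    frac = np.cumsum(eigvals) / eigvals.sum() * 100.0
    q = int(np.searchsorted(frac, p_v - 1e-9)) + 1
    return np.arange(min(q, len(eigvals)))


def fit_pca(X: np.ndarray, criterion=99.0) -> PcaModel:
    """Eigendecomposition of the unbiased sample covariance about the mean.

    ``criterion`` is either a proportion of explained variance P_v in
    (0, 100], or the string ``"average"`` (retain eigenvalues above the mean
    eigenvalue).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 trials")
    mean = X.mean(axis=0)
    Xc = X - mean
    # economy SVD of the centered sample: identical eigenpairs to the
    # covariance eigendecomposition, but O(n^2 d) instead of O(d^3) when the
    # dimensionality exceeds the trial count (the usual case here)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    w = s * s / (X.shape[0] - 1)
    v = vt.T
    keep = w > max(w[0], 0.0) * _EIG_FLOOR
    w, v = w[keep], v[:, keep]
    if len(w) == 0:
        raise ValueError("sample has no variance")
    return PcaModel(
        mean=mean, loadings=v, eigvals=w,
        retained=_apply_criterion(w, criterion),
        criterion=str(criterion),
    )


def mahalanobis_sq(x: np.ndarray, model: PcaModel) -> np.ndarray | float:
    """Squared Mahalanobis distance to the model mean in the retained subspace.

    Equals the Euclidean distance after sphering (projection onto retained
    components and division by their standard deviations).
    """
    lam = model.eigvals[model.retained]
    if np.any(lam <= 0):
        raise np.linalg.LinAlgError("retained component with zero eigenvalue")
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    z = (np.atleast_2d(x) - model.mean) @ model.loadings[:, model.retained]
    d2 = (z * z / lam).sum(axis=1)
    return float(d2[0]) if single else d2


def _distance_flags(D, active, C):
    mu = D[active].mean()
    sd = D[active].std(ddof=1)
    return D > mu + C * sd


def detect_outliers(
    F: ErpEpochs,
    C: float = 2.7,
    criterion=99.0,
    max_iter: int = 100,
    dataset_limit: float = 0.5,
) -> tuple[OutlierReport, PcaModel]:
    """Iterative PCA-based multivariate outlier rejection on the whole sample.

    Returns the final report and the PCA model fitted on the accepted trials.
    A whole dataset is flagged when more than ``dataset_limit`` of its trials
    are flagged; the dataset rule (like the re-marking of the previous
    iteration's outliers) applies only in iterations where the single-trial
    flag count did not increase.  Flagged datasets, like flagged trials, can
    be re-admitted later.
    """
    if C <= 0:
        raise ValueError("threshold coefficient C must be positive")
    X = F.data
    n = X.shape[0]
    if n < 3:
        raise ValueError("outlier detection needs at least 3 trials")
    ids = F.dataset_ids
    ds_names = list(dict.fromkeys(ids))  # stable order

    trial_flags = np.zeros(n, dtype=bool)
    ds_flags = {ds: False for ds in ds_names}
    q_prev = None
    q_frozen = None
    model = None
    D = np.zeros(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ds_mask = np.isin(ids, [d for d, bad in ds_flags.items() if bad])
        active = ~trial_flags & ~ds_mask
        if active.sum() < 2:
            raise ValueError("all trials flagged: degenerate sample")
        model = fit_pca(X[active], criterion)
        if q_frozen is None:
            q = model.n_retained
            if q == q_prev:
                q_frozen = q
            q_prev = q
        else:
            model.retained = np.arange(min(q_frozen, len(model.eigvals)))
        D = np.sqrt(mahalanobis_sq(X, model))
        new_flags = _distance_flags(D, active, C)
        new_ds = dict(ds_flags)
        if new_flags.sum() <= trial_flags.sum():
            new_flags = new_flags | trial_flags
            for ds in ds_names:
                m = ids == ds
                frac = new_flags[m].mean()
                new_ds[ds] = bool(frac > dataset_limit) or ds_flags[ds]
        if (
            q_frozen is not None
            and np.array_equal(new_flags, trial_flags)
            and new_ds == ds_flags
        ):
            converged = True
            trial_flags, ds_flags = new_flags, new_ds
            break
        trial_flags, ds_flags = new_flags, new_ds
    if not converged:
        warnings.warn(
            f"outlier detection did not converge within {max_iter} iterations; "
            "returning the last flag set",
            RuntimeWarning,
        )
    report = OutlierReport(
        trial_flags=trial_flags,
        dataset_flags=ds_flags,
        n_components=model.n_retained,
        iterations=it,
        distances=D,
        C=C,
        converged=converged,
        dataset_ids=ids,
    )
    return report, model


def per_condition_outliers(
    F: ErpEpochs,
    model: PcaModel,
    C: float = 2.7,
    max_iter: int = 100,
) -> OutlierReport:
    """Outlier pass within each condition subsample, with the PCT frozen.

    The principal axes and the retained count come from ``model`` (fitted on
    the whole sample); only the per-component variances and the subsample
    mean are re-estimated from the accepted trials of each condition.
    """
    X = F.data
    Tr = model.reduced_loadings
    flags = np.zeros(X.shape[0], dtype=bool)
    distances = np.zeros(X.shape[0])
    iters = 0
    converged_all = True
    for tag in np.unique(F.labels.astype(str)):
        rows = np.flatnonzero(F.labels.astype(str) == tag)
        if len(rows) < 3:
            raise ValueError(f"condition {tag!r} has fewer than 3 trials")
        Z = X[rows] @ Tr
        f = np.zeros(len(rows), dtype=bool)
        converged = False
        for it in range(1, max_iter + 1):
            active = ~f
            if active.sum() < 3:
                raise ValueError(
                    f"condition {tag!r} has fewer than 3 accepted trials"
                )
            mu = Z[active].mean(axis=0)
            var = Z[active].var(axis=0, ddof=1)
            var[var <= 0] = np.inf  # direction without spread carries no distance
            D = np.sqrt((((Z - mu) ** 2) / var).sum(axis=1))
            new = _distance_flags(D, active, C)
            if new.sum() <= f.sum():
                new = new | f
            if np.array_equal(new, f):
                converged = True
                break
            f = new
        if not converged:
            converged_all = False
            warnings.warn(
                f"per-condition outlier pass for {tag!r} did not converge",
                RuntimeWarning,
            )
        flags[rows] = f
        distances[rows] = D
        iters = max(iters, it)
    return OutlierReport(
        trial_flags=flags,
        dataset_flags={},
        n_components=model.n_retained,
        iterations=iters,
        distances=distances,
        C=C,
        converged=converged_all,
        dataset_ids=F.dataset_ids,
    )


def project_filtered(F: ErpEpochs, model: PcaModel) -> ErpEpochs:
    """Statistical PCA filter: project rows onto the retained subspace.

    The output stays in the frequency domain with unchanged dimensionality;
    rows flagged as outliers are expected to be removed beforehand.
    """
    Tr = model.reduced_loadings
    if F.data.shape[1] != Tr.shape[0]:
        raise ValueError(
            f"data has {F.data.shape[1]} columns, PCA model expects {Tr.shape[0]}"
        )
    return F.with_data((F.data @ Tr) @ Tr.T)
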