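"""Feature-space post-processing: PCA with step-down component selection,
linear discriminant analysis with unequal priors, Hotelling's T² test, and
back-projection of the discriminant to the frequency and time domains.

The linear discriminant function (LDF) in the selected-principal-component
(SPC) space is d = S⁻¹ (mean_A - mean_B)ᵀ with the unbiased pooled
covariance S; a trial x is assigned to condition A iff

    x · d  >  ½ (mean_A + mean_B) · d + ln(p_B / p_A).

Because every step in the chain (PCA filter, CWT restriction, feature PCA)
is linear, the same decision value can be written as an inner product with a
frequency-domain vector d*_f or a time-domain curve d* — useful both for
plotting the discriminant as an ERP-like waveform and for applying it to raw
trials in O(dim).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import FeatureBasis
from .outliers import PcaModel
from .spectral import SpectralBasis
from .wavelet import CwtBasis

__all__ = [
    "DiscriminantModel",
    "step_down_select",
    "fit_ldf",
    "fit_discriminant",
    "ldf_value",
    "classify",
    "hotelling_t2",
    "backproject_ldf",
]


@dataclass
class DiscriminantModel:
    ldf: np.ndarray                  # d*_w in SPC space
    threshold: float                 # right side of the decision rule
    priors: tuple[float, float]      # (p_A, p_B)
    condition_a: str
    condition_b: str
    feature_pca: PcaModel | None = None
    spc: np.ndarray | None = None    # selected component indices (eigen order)
    d_f: np.ndarray | None = None    # frequency-domain back-projection
    d_time: np.ndarray | None = None # time-domain back-projection

    def to_spc(self, x: np.ndarray) -> np.ndarray:
        """Project feature rows W* into the SPC space (identity if no PCA)."""
        x = np.asarray(x, dtype=float)
        if self.feature_pca is None:
            return x
        return x @ self.feature_pca.loadings[:, self.spc]

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        """x·d for feature rows (N_X columns) or SPC rows (len(ldf) columns)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.ldf):
            x = self.to_spc(x)
        return x @ self.ldf


def step_down_select(Wp, labels, alpha_sd: float = 0.3,
                     condition_a: str | None = None,
                     condition_b: str | None = None) -> np.ndarray:
    """Step-down selection of principal components in eigenvalue order.

    Components (columns of ``Wp``, pre-sorted by decreasing eigenvalue) are
    two-sample t-tested sequentially at level ``alpha_sd``; every component
    significant at that level is kept, in order.  At least the first
    component is always kept, so a discriminant always exists.

    Screening rather than stopping at the first acceptance matters: in EEG
    feature spaces the largest-variance components are typically noise
    common modes, while the condition difference concentrates in mid-rank
    components.  A stop-at-first rule would discard them and collapse the
    discriminant to the (usually uninformative) leading component.
    """
    Wp = np.asarray(Wp, dtype=float)
    if Wp.ndim == 1:
        Wp = Wp[:, None]
    labels = np.asarray([str(x) for x in labels], dtype=object)
    tags = sorted(set(labels))
    if condition_a is None:
        condition_a, condition_b = tags
    ma, mb = labels == condition_a, labels == condition_b
    if ma.sum() < 2 or mb.sum() < 2:
        raise ValueError("step-down needs at least 2 trials per condition")
    selected = []
    for i in range(Wp.shape[1]):
        p = stats.ttest_ind(Wp[ma, i], Wp[mb, i], equal_var=True).pvalue
        if np.isnan(p):
            p = 1.0
        if p < alpha_sd:
            selected.append(i)
    if not selected:
        selected = [0]
    return np.asarray(selected, dtype=np.int64)


def _class_stats(X, labels, condition_a, condition_b):
    labels = np.asarray([str(x) for x in labels], dtype=object)
    A = X[labels == condition_a]
    B = X[labels == condition_b]
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each condition needs at least 2 trials")
    return A, B


def fit_ldf(
    W_spc: np.ndarray,
    labels,
    priors: tuple[float, float] | None = None,
    condition_a: str | None = None,
    condition_b: str | None = None,
    feature_pca: PcaModel | None = None,
    spc: np.ndarray | None = None,
) -> DiscriminantModel:
    """LDA in the SPC space: pooled-covariance discriminant with priors.

    ``priors=None`` means equal priors (no threshold shift).  When
    ``feature_pca``/``spc`` are given, the model can also accept raw feature
    rows and is back-projectable through the full chain.
    """
    W_spc = np.asarray(W_spc, dtype=float)
    if W_spc.ndim == 1:
        W_spc = W_spc[:, None]
    tags = sorted(set(str(x) for x in labels))
    if condition_a is None:
        if len(tags) != 2:
            raise ValueError(f"expected two condition labels, found {tags}")
        condition_a, condition_b = tags
    if priors is None:
        priors = (0.5, 0.5)
    pa, pb = priors
    if not (0 < pa < 1 and 0 < pb < 1) or abs(pa + pb - 1) > 1e-9:
        raise ValueError("priors must lie in (0,1) and sum to 1")

    A, B = _class_stats(W_spc, labels, condition_a, condition_b)
    na, nb = len(A), len(B)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - mean_a, B - mean_b
    S = (Ac.T @ Ac + Bc.T @ Bc) / (na + nb - 2)
    S = np.atleast_2d(S)
    w = np.linalg.eigvalsh(S)
    if w[0] <= w[-1] * 1e-12 or w[-1] <= 0:
        raise np.linalg.LinAlgError(
            f"singular pooled covariance (smallest eigenvalue {w[0]:.3e}); "
            "reduce the SPC count below the class sizes"
        )
    d = np.linalg.solve(S, mean_a - mean_b)
    threshold = float(0.5 * (mean_a + mean_b) @ d + np.log(pb / pa))
    return DiscriminantModel(
        ldf=d, threshold=threshold, priors=(pa, pb),
        condition_a=condition_a, condition_b=condition_b,
        feature_pca=feature_pca, spc=spc,
    )


def fit_discriminant(
    W_star: np.ndarray,
    labels,
    criterion=99.0,
    alpha_sd: float = 0.3,
    priors: tuple[float, float] | None = None,
    condition_a: str | None = None,
    condition_b: str | None = None,
) -> DiscriminantModel:
    """Feature PCA + step-down selection + LDA, composed.

    The PCA retention criterion is applied first (proportion of variance or
    average eigenvalue), then the step-down test prunes the retained
    components in eigenvalue order; the LDF is fitted in the surviving SPC
    space.  The SPC count is additionally capped below the smaller class size
    so the pooled covariance stays invertible.
    """
    from .outliers import fit_pca  # local import avoids a cycle at load time

    labels = np.asarray([str(x) for x in labels], dtype=object)
    tags = sorted(set(labels))
    if condition_a is None:
        condition_a, condition_b = tags
    pca = fit_pca(W_star, criterion)
    n_min = min(int((labels == condition_a).sum()), int((labels == condition_b).sum()))
    cap = max(1, n_min - 2)
    retained = pca.retained[:cap]
    Wp = W_star @ pca.loadings[:, retained]
    rel = step_down_select(Wp, labels, alpha_sd, condition_a, condition_b)
    spc = retained[rel]
    return fit_ldf(
        W_star @ pca.loadings[:, spc], labels, priors,
        condition_a, condition_b, feature_pca=pca, spc=spc,
    )


def ldf_value(x, model: DiscriminantModel):
    """Continuous affiliation measure x·d (before threshold comparison)."""
    vals = model.decision_values(x)
    return float(vals[0]) if np.asarray(x).ndim == 1 else vals


def classify(x, model: DiscriminantModel):
    """Assign condition A iff x·d > threshold; exact ties go to B."""
    vals = model.decision_values(x)
    out = np.where(vals > model.threshold, model.condition_a, model.condition_b)
    return str(out[0]) if np.asarray(x).ndim == 1 else out.astype(object)


def hotelling_t2(
    XA: np.ndarray,
    XB: np.ndarray,
    features_independent: bool = False,
) -> tuple[float, float, float]:
    """Two-sample Hotelling T² test with the F-distribution p-value.

    T² = (n_A n_B / n) D² with the unbiased pooled covariance in D²;
    F = T² (n - p - 1) / ((n - 2) p) ~ F(p, n - p - 1) under H0.

    Set ``features_independent=True`` to confirm the tested variables were
    NOT selected from the very sample being tested; otherwise a
    methodological warning is emitted (feature selection on the test sample
    invalidates the T² null distribution).
    """
    if not features_independent:
        warnings.warn(
            "Hotelling's T2 requires features extracted independently of the "
            "tested sample; pass features_independent=True to confirm",
            UserWarning,
        )
    XA = np.asarray(XA, dtype=float)
    XB = np.asarray(XB, dtype=float)
    if XA.ndim == 1:
        XA = XA[:, None]
    if XB.ndim == 1:
        XB = XB[:, None]
    na, nb = len(XA), len(XB)
    p = XA.shape[1]
    n = na + nb
    if n - 2 < p or n - p - 1 < 1:
        raise ValueError(
            f"insufficient degrees of freedom: n={n} samples for p={p} variables"
        )
    mean_a, mean_b = XA.mean(axis=0), XB.mean(axis=0)
    Ac, Bc = XA - mean_a, XB - mean_b
    S = (Ac.T @ Ac + Bc.T @ Bc) / (n - 2)
    diff = mean_a - mean_b
    d2 = float(diff @ np.linalg.solve(np.atleast_2d(S), diff))
    t2 = na * nb / n * d2
    f = t2 * (n - p - 1) / ((n - 2) * p)
    pval = float(stats.f.sf(f, p, n - p - 1))
    return t2, f, pval


def backproject_ldf(
    model: DiscriminantModel,
    freq_pca: PcaModel,
    fb: FeatureBasis,
    cb: CwtBasis,
    basis: SpectralBasis,
    n_channels: int,
) -> DiscriminantModel:
    """Attach the frequency- and time-domain representations of the LDF.

    d*_f = T̂_p T̂_pᵀ T̃*_w T̂*_p d  and  d* = T̃_f d*_f (per channel block),
    so for any trial the SPC-space, frequency-domain and time-domain inner
    products give the same decision value.
    """
    if model.feature_pca is None or model.spc is None:
        raise ValueError("model lacks the feature PCA needed for back-projection")
    t_star = fb.restricted_block(cb)
    if t_star.shape[0] != n_channels * cb.block.shape[0]:
        t_star = np.vstack([
            t_star,
            np.zeros((n_channels * cb.block.shape[0] - t_star.shape[0],
                      t_star.shape[1])),
        ])
    v = t_star @ (model.feature_pca.loadings[:, model.spc] @ model.ldf)
    Tr = freq_pca.reduced_loadings
    d_f = Tr @ (Tr.T @ v)
    n_f = basis.n_frequencies
    d_time = np.concatenate([
        basis.T_tilde_f @ d_f[k * n_f : (k + 1) * n_f]
        for k in range(n_channels)
    ])
    model.d_f = d_f
    model.d_time = d_time
    return model
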