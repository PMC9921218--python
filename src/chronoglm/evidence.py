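"""Voxel-wise Bayesian GLM and cross-validated log model evidence (cvLME).

Each voxel time series y is modelled as ``y = X b + e`` with AR(1) noise.
After prewhitening, a conjugate normal-gamma prior over (b, tau) yields a
closed-form log marginal likelihood.  Because a flat prior makes the marginal
likelihood improper, model evidence is cross-validated: the data are split
into folds, the posterior from the training folds (started from a
noninformative prior) serves as the prior for the held-out fold, and the
out-of-sample log evidences are summed.  This penalises complexity without a
hand-set prior and is comparable across non-nested models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .design import (DesignMatrix, HRFSpec, ModelSpec, TrialTable,
                     build_design_matrix, build_model_space)

__all__ = [
    "NoisePrewhitener",
    "NormalGammaPosterior",
    "EvidenceMaps",
    "estimate_ar1",
    "bayes_glm_update",
    "log_evidence",
    "cv_log_evidence",
    "subject_evidence_maps",
    "SubjectEvidenceModel",
]


def estimate_ar1(residuals: np.ndarray) -> float:
    """Lag-1 autocorrelation of OLS residuals, pooled over voxels.

    Accepts a vector (scans,) or matrix (scans, voxels).  The estimate is
    clipped to [0, 0.95]; constant residuals yield 0 with a warning.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim == 1:
        r = r[:, None]
    if r.shape[0] < 3:
        raise ValueError("need at least 3 time points to estimate AR(1)")
    r = r - r.mean(axis=0)
    denom = np.sum(r * r)
    if denom <= 0:
        warnings.warn("constant residuals: AR(1) coefficient set to 0", stacklevel=2)
        return 0.0
    num = np.sum(r[1:] * r[:-1])
    return float(np.clip(num / denom, 0.0, 0.95))


@dataclass
class NoisePrewhitener:
    """Applies the inverse square root of the AR(1) noise covariance.

    For ``|rho| < 1`` the transform is ``y'_0 = sqrt(1 - rho^2) y_0`` and
    ``y'_t = y_t - rho y_{t-1}``, which maps AR(1)(rho) noise to white noise
    (up to an overall scale absorbed by the noise precision).
    """

    rho: float

    def __post_init__(self) -> None:
        if not (abs(self.rho) < 1):
            raise ValueError("AR(1) coefficient must satisfy |rho| < 1")

    def whiten(self, arr: np.ndarray) -> np.ndarray:
        a = np.asarray(arr, dtype=float)
        out = a.copy()
        out[0] = np.sqrt(1.0 - self.rho**2) * a[0]
        out[1:] = a[1:] - self.rho * a[:-1]
        return out


@dataclass
class NormalGammaPosterior:
    """Conjugate normal-gamma distribution over (regression weights, precision)."""

    mu: np.ndarray
    Lambda: np.ndarray
    a: float
    b: float

    @classmethod
    def noninformative(cls, p: int) -> "NormalGammaPosterior":
        return cls(mu=np.zeros(p), Lambda=np.zeros((p, p)), a=0.0, b=0.0)

    @property
    def is_proper(self) -> bool:
        if self.a <= 0 or self.b <= 0:
            return False
        try:
            np.linalg.cholesky(self.Lambda)
        except np.linalg.LinAlgError:
            return False
        return True


def _logdet(mat: np.ndarray) -> float:
    L = np.linalg.cholesky(mat)
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def bayes_glm_update(
    y: np.ndarray, X: np.ndarray | DesignMatrix,
    prior: NormalGammaPosterior | None = None,
) -> NormalGammaPosterior:
    """Conjugate normal-gamma update for the linear model with unknown precision.

    With prior (mu, Lambda, a, b):
    ``Lambda' = X'X + Lambda``, ``mu' = Lambda'^-1 (X'y + Lambda mu)``,
    ``a' = a + n/2``, ``b' = b + (y'y + mu' Lambda mu - mu'' Lambda' mu'') / 2``.
    ``prior=None`` means the noninformative prior (all zero).
    """
    if isinstance(X, DesignMatrix):
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("y and X have inconsistent numbers of rows")
    if prior is None:
        prior = NormalGammaPosterior.noninformative(p)
    Lam_post = X.T @ X + prior.Lambda
    rhs = X.T @ y + prior.Lambda @ prior.mu
    try:
        L = np.linalg.cholesky(Lam_post)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"posterior precision is singular (n={n} rows, p={p} regressors); "
            "provide more data or an informative prior") from err
    mu_post = np.linalg.solve(L.T, np.linalg.solve(L, rhs))
    a_post = prior.a + n / 2.0
    b_post = prior.b + 0.5 * (
        y @ y + prior.mu @ prior.Lambda @ prior.mu - mu_post @ Lam_post @ mu_post
    )
    return NormalGammaPosterior(mu=mu_post, Lambda=Lam_post, a=a_post, b=float(b_post))


def log_evidence(
    y: np.ndarray, X: np.ndarray | DesignMatrix, prior: NormalGammaPosterior,
) -> float:
    """Log marginal likelihood of ``y`` under the normal-gamma prior.

    ``log p(y) = (log|Lambda| - log|Lambda'|)/2 + a log b - a' log b'
    + logGamma(a') - logGamma(a) - (n/2) log 2 pi`` with primed quantities
    from :func:`bayes_glm_update`.  Requires a proper prior (e.g. the
    posterior from a training fold); use :func:`cv_log_evidence` otherwise.
    """
    if not prior.is_proper:
        raise ValueError(
            "log_evidence requires a proper prior; use cv_log_evidence to "
            "obtain one from a training fold")
    if isinstance(X, DesignMatrix):
        X = X.values
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    post = bayes_glm_update(y, X, prior)
    return float(
        0.5 * (_logdet(prior.Lambda) - _logdet(post.Lambda))
        + prior.a * np.log(prior.b) - post.a * np.log(post.b)
        + gammaln(post.a) - gammaln(prior.a)
        - 0.5 * n * np.log(2.0 * np.pi)
    )


def _fold_slices(n: int, n_folds: int) -> list[np.ndarray]:
    return [np.asarray(idx) for idx in np.array_split(np.arange(n), n_folds)]


def cv_log_evidence(
    y: np.ndarray, X: np.ndarray | DesignMatrix,
    n_folds: int = 2, label: str | None = None,
) -> float:
    """Cross-validated log model evidence: sum of out-of-sample log evidences.

    The rows are split into ``n_folds`` contiguous blocks.  For each fold the
    noninformative-prior update on the complementary rows yields a proper
    prior, and the held-out fold is scored with :func:`log_evidence`.
    """
    if isinstance(X, DesignMatrix):
        X = X.values
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    folds = _fold_slices(n, n_folds)
    if min(f.size for f in folds) == 0:
        raise ValueError("more folds than rows")
    total = 0.0
    for k, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        if train.size <= p:
            raise ValueError(
                f"training complement of fold {k} has {train.size} rows for "
                f"{p} regressors" + (f" (model {label})" if label else ""))
        Xf = _prune_degenerate_columns(X, train)
        try:
            prior = bayes_glm_update(y[train], Xf[train], None)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "rank-deficient training design"
                + (f" for model {label}" if label else "")) from err
        total += log_evidence(y[test], Xf[test], prior)
    return float(total)


def _prune_degenerate_columns(X: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Drop columns that vanish on the training rows of a fold.

    Event regressors whose events fall entirely inside the held-out block
    (e.g. a lone error-trial nuisance event) carry no training information
    and would make the training precision singular; they are removed from
    that fold's design (train and test alike).
    """
    norms = np.linalg.norm(X[train], axis=0)
    keep = norms > 1e-10 * max(1.0, norms.max())
    return X if keep.all() else X[:, keep]


def _cvlme_many_voxels(Y: np.ndarray, X: np.ndarray, n_folds: int = 2) -> np.ndarray:
    """Vectorised cvLME for many voxels sharing one design.

    ``Y`` is (scans, voxels).  Identical algebra to :func:`cv_log_evidence`
    computed with shared Cholesky factorisations of the fold-wise X'X blocks.
    """
    n, p = X.shape
    V = Y.shape[1]
    folds = _fold_slices(n, n_folds)
    out = np.zeros(V)
    for k, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        if train.size <= p:
            raise ValueError(
                f"training complement of fold {k} has {train.size} rows for "
                f"{p} regressors")
        Xf = _prune_degenerate_columns(X, train)
        X1, X2 = Xf[train], Xf[test]
        Y1, Y2 = Y[train], Y[test]
        Lam1 = X1.T @ X1
        Lam2 = Lam1 + X2.T @ X2
        ld1, ld2 = _logdet(Lam1), _logdet(Lam2)
        B1 = np.linalg.solve(Lam1, X1.T @ Y1)          # (p, V) training means
        B2 = np.linalg.solve(Lam2, X1.T @ Y1 + X2.T @ Y2)
        a1 = train.size / 2.0
        a2 = a1 + test.size / 2.0
        b1 = 0.5 * (np.sum(Y1 * Y1, axis=0) - np.sum(B1 * (Lam1 @ B1), axis=0))
        b2 = b1 + 0.5 * (np.sum(Y2 * Y2, axis=0)
                         + np.sum(B1 * (Lam1 @ B1), axis=0)
                         - np.sum(B2 * (Lam2 @ B2), axis=0))
        b1 = np.maximum(b1, np.finfo(float).tiny)
        b2 = np.maximum(b2, np.finfo(float).tiny)
        out += (0.5 * (ld1 - ld2) + a1 * np.log(b1) - a2 * np.log(b2)
                + gammaln(a2) - gammaln(a1) - 0.5 * test.size * np.log(2 * np.pi))
    return out


@dataclass
class EvidenceMaps:
    """Subject x model x voxel cvLME values on a common mask."""

    cvlme: np.ndarray               # (subjects, models, voxels)
    mask: np.ndarray                # 3D boolean
    model_order: list[ModelSpec]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cvlme = np.atleast_3d(np.asarray(self.cvlme, dtype=float))
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.cvlme.shape[2] != int(self.mask.sum()):
            raise ValueError("cvlme voxel axis does not match mask size")
        if self.cvlme.shape[1] != len(self.model_order):
            raise ValueError("cvlme model axis does not match model_order")

    @property
    def n_subjects(self) -> int:
        return self.cvlme.shape[0]

    @property
    def n_models(self) -> int:
        return self.cvlme.shape[1]

    @classmethod
    def stack(cls, maps: list["EvidenceMaps"]) -> "EvidenceMaps":
        first = maps[0]
        for m in maps[1:]:
            if not np.array_equal(m.mask, first.mask):
                raise ValueError("subjects have different masks")
        return cls(cvlme=np.concatenate([m.cvlme for m in maps], axis=0),
                   mask=first.mask, model_order=first.model_order,
                   affine=first.affine)

    def to_volume(self, subject: int, model: int) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.cvlme[subject, model]
        return vol


def subject_evidence_maps(
    bold: np.ndarray,
    mask: np.ndarray,
    trials: TrialTable,
    model_space: list[ModelSpec] | None = None,
    motion: np.ndarray | None = None,
    TR_s: float = 0.756,
    hrf: HRFSpec | None = None,
    n_folds: int = 2,
    hp_cutoff_s: float = 128.0,
    ar1: str = "pooled",
    affine: np.ndarray | None = None,
) -> EvidenceMaps:
    """One subject's cvLME maps for every model of the space.

    A single pooled AR(1) coefficient (estimated from OLS residuals of the
    richest model) whitens data and all designs identically, and the same
    contiguous folds are used for every model, so evidence differences at a
    voxel reflect only the task-model columns.  Non-finite voxel time series
    are dropped from the mask with a logged count.
    """
    model = SubjectEvidenceModel(model_space=model_space, TR_s=TR_s, hrf=hrf,
                                 n_folds=n_folds, hp_cutoff_s=hp_cutoff_s,
                                 ar1=ar1)
    model.fit(bold, trials=trials, mask=mask, motion=motion, affine=affine)
    return model.evidence_maps_


class SubjectEvidenceModel(BaseEstimator):
    """Subject-level estimator producing cvLME maps over a model space.

    Parameters
    ----------
    model_space : list of ModelSpec, optional
        Defaults to the four-model space (no derivatives).
    TR_s : float
        Repetition time in seconds.
    hrf : HRFSpec, optional
        Hemodynamic kernel parameters (canonical double gamma by default).
    n_folds : int
        Contiguous cross-validation folds for the evidence.
    hp_cutoff_s : float
        High-pass drift cutoff in seconds (discrete-cosine basis).
    ar1 : {"pooled", "none"}
        Noise whitening: one pooled AR(1) coefficient per subject, or none.

    Attributes
    ----------
    evidence_maps_ : EvidenceMaps
        cvLME per model per in-mask voxel (subject axis of length 1).
    rho_ : float
        Pooled AR(1) coefficient used for whitening.
    n_dropped_voxels_ : int
        In-mask voxels removed for non-finite data.
    """

    def __init__(self, model_space=None, TR_s: float = 0.756, hrf=None,
                 n_folds: int = 2, hp_cutoff_s: float = 128.0,
                 ar1: str = "pooled"):
        self.model_space = model_space
        self.TR_s = TR_s
        self.hrf = hrf
        self.n_folds = n_folds
        self.hp_cutoff_s = hp_cutoff_s
        self.ar1 = ar1

    def fit(self, bold, trials=None, mask=None, motion=None, affine=None):
        bold = np.asarray(bold, dtype=float)
        if bold.ndim != 4:
            raise ValueError("bold must be a 4D (x, y, z, t) array")
        if trials is None:
            raise ValueError("trials (a TrialTable) is required")
        if mask is None:
            mask = np.ones(bold.shape[:3], dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != bold.shape[:3]:
            raise ValueError("mask shape does not match bold spatial shape")
        n_scans = bold.shape[3]
        space = self.model_space or build_model_space(False)

        Y = bold[mask].T                      # (scans, voxels)
        finite = np.isfinite(Y).all(axis=0)
        self.n_dropped_voxels_ = int((~finite).sum())
        if self.n_dropped_voxels_:
            warnings.warn(
                f"dropping {self.n_dropped_voxels_} voxels with non-finite data",
                stacklevel=2)
            new_mask = mask.copy()
            new_mask[mask] = finite
            mask = new_mask
            Y = Y[:, finite]

        designs = [
            build_design_matrix(trials, m, hrf=self.hrf, motion=motion,
                                TR_s=self.TR_s, n_scans=n_scans,
                                hp_cutoff_s=self.hp_cutoff_s)
            for m in space
        ]

        rho = 0.0
        if self.ar1 == "pooled" and Y.shape[1] > 0:
            richest = designs[int(np.argmax([d.n_regressors for d in designs]))]
            Xr = richest.values
            beta, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
            rho = estimate_ar1(Y - Xr @ beta)
        self.rho_ = rho

        W = NoisePrewhitener(rho)
        Yw = W.whiten(Y) if Y.shape[1] else Y
        K = len(space)
        cvlme = np.zeros((1, K, Y.shape[1]))
        for k, d in enumerate(designs):
            Xw = W.whiten(d.values)
            if Y.shape[1]:
                cvlme[0, k] = _cvlme_many_voxels(Yw, Xw, n_folds=self.n_folds)
        self.designs_ = designs
        self.mask_ = mask
        self.evidence_maps_ = EvidenceMaps(cvlme=cvlme, mask=mask,
                                           model_order=list(space),
                                           affine=affine)
        return self
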