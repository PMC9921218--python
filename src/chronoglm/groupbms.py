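"""Group-level random-effects Bayesian model selection (RFX-BMS).

Subject-level log model evidences are combined under a hierarchical model in
which the best model varies across subjects: model frequencies r follow a
Dirichlet(alpha) posterior estimated by variational Bayes.  Summaries are the
likeliest frequency (LF, the Dirichlet mode, interpretable as the proportion
of subjects for whom the model is optimal) and the exceedance probability
(EP, the probability that a model's frequency exceeds every competitor's).
LF and EP induce the same model ranking; the winning-model map takes the
argmax with ties broken towards the lowest model index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma
from scipy.stats import beta as beta_dist
from sklearn.base import BaseEstimator

from .evidence import EvidenceMaps

__all__ = [
    "GroupBMSResult",
    "rfx_bms",
    "likeliest_frequency",
    "exceedance_prob",
    "group_bms_maps",
    "GroupBMS",
]


def _rfx_bms_array(
    L: np.ndarray, alpha0: float = 1.0, tol: float = 1e-6, max_iter: int = 1000,
) -> tuple[np.ndarray, bool]:
    """Variational Dirichlet update, vectorised over trailing axes.

    ``L`` is (subjects, models[, voxels]); returns (alpha, converged) with
    alpha of shape (models[, voxels]).
    """
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    N, K = L.shape[0], L.shape[1]
    alpha = np.full(L.shape[1:], alpha0, dtype=float)
    converged = False
    for _ in range(max_iter):
        lnr = L + (digamma(alpha) - digamma(alpha.sum(axis=0)))[None]
        lnr -= lnr.max(axis=1, keepdims=True)
        g = np.exp(lnr)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + g.sum(axis=0)
        delta = np.max(np.abs(alpha_new - alpha))
        alpha = alpha_new
        if delta < tol:
            converged = True
            break
    return alpha, converged


def rfx_bms(
    L: np.ndarray, alpha0: float = 1.0, tol: float = 1e-6, max_iter: int = 1000,
) -> np.ndarray:
    """Dirichlet concentrations from a subjects x models cvLME matrix.

    Iterates the variational update: per-subject responsibilities
    ``g_nk \\propto exp(L_nk + psi(alpha_k) - psi(sum_j alpha_j))`` followed by
    ``alpha_k = alpha0 + sum_n g_nk``, until ``max |d alpha| < tol``.
    """
    L = np.asarray(L, dtype=float)
    if L.ndim != 2:
        raise ValueError("L must be (subjects, models)")
    if L.shape[0] < 1:
        raise ValueError("need at least one subject")
    alpha, converged = _rfx_bms_array(L, alpha0=alpha0, tol=tol, max_iter=max_iter)
    if not converged:
        warnings.warn("RFX-BMS did not converge within max_iter", stacklevel=2)
    return alpha


def likeliest_frequency(alpha: np.ndarray) -> np.ndarray:
    """Most probable model frequencies under Dirichlet(alpha).

    The Dirichlet mode ``(alpha_k - 1) / (sum(alpha) - K)`` when every
    ``alpha_k > 1``; otherwise (mode on the simplex boundary) the Dirichlet
    mean ``alpha_k / sum(alpha)`` is used as a proper fallback.  Vectorised
    over trailing axes (models first).
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha entries must be positive")
    K = alpha.shape[0]
    total = alpha.sum(axis=0)
    mean = alpha / total
    with np.errstate(invalid="ignore", divide="ignore"):
        mode = (alpha - 1.0) / (total - K)
    use_mode = np.all(alpha > 1.0, axis=0)
    return np.where(use_mode, mode, mean)


def exceedance_prob(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """P(model k has the largest frequency) under Dirichlet(alpha).

    Exact via the Beta distribution for K = 2 (``P(r_1 > 1/2)``); Monte-Carlo
    otherwise, with counts that partition the samples so the EPs sum to 1.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1:
        raise ValueError("alpha must be a vector; use group_bms_maps for maps")
    K = alpha.size
    if K == 2:
        p1 = beta_dist.sf(0.5, alpha[0], alpha[1])
        return np.array([p1, 1.0 - p1])
    if rng is None:
        rng = np.random.default_rng(seed)
    gam = rng.standard_gamma(alpha, size=(int(n_samples), K))
    wins = np.argmax(gam, axis=1)
    return np.bincount(wins, minlength=K) / float(n_samples)


def _exceedance_prob_map(
    alpha: np.ndarray, n_samples: int, rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo EP for (models, voxels) concentrations (exact for K=2)."""
    K, V = alpha.shape
    if K == 2:
        p1 = beta_dist.sf(0.5, alpha[0], alpha[1])
        return np.stack([p1, 1.0 - p1])
    ep = np.zeros((K, V))
    # sample in blocks to bound memory at ~n_samples x K doubles per block
    block = max(1, int(5e6 // max(n_samples, 1)))
    for start in range(0, V, block):
        sl = slice(start, min(start + block, V))
        a = alpha[:, sl]                                   # (K, v)
        gam = rng.standard_gamma(a.T[None], size=(n_samples,) + a.T.shape)
        wins = np.argmax(gam, axis=2)                      # (n_samples, v)
        for k in range(K):
            ep[k, sl] = (wins == k).mean(axis=0)
    return ep


@dataclass
class GroupBMSResult:
    """Voxel-wise Dirichlet concentrations and derived group maps."""

    alpha: np.ndarray          # (models, voxels)
    lf: np.ndarray             # (models, voxels)
    ep: np.ndarray             # (models, voxels)
    winner: np.ndarray         # 3D int labels, 1..K in mask, 0 outside
    mask: np.ndarray           # 3D boolean (voxels actually analysed)
    model_order: list
    affine: np.ndarray | None = None

    def lf_volume(self, k: int) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.lf[k]
        return vol

    def ep_volume(self, k: int) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.ep[k]
        return vol


def group_bms_maps(
    evidence: EvidenceMaps,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    ep_samples: int = 10_000,
    seed: int | None = None,
) -> GroupBMSResult:
    """Voxel-wise RFX-BMS over a stacked group of subject evidence maps."""
    est = GroupBMS(alpha0=alpha0, tol=tol, max_iter=max_iter,
                   ep_samples=ep_samples, seed=seed)
    est.fit(evidence)
    return est.result_


class GroupBMS(BaseEstimator):
    """Random-effects Bayesian model selection estimator.

    ``fit`` accepts either a (subjects, models) evidence matrix or an
    :class:`EvidenceMaps` stack.  Fitted attributes: ``alpha_``, ``lf_``,
    ``ep_``; for maps additionally ``winner_`` (3D labels) and ``result_``.

    Parameters
    ----------
    alpha0 : float
        Flat Dirichlet prior concentration (1 by default).
    ep_samples : int
        Monte-Carlo samples per voxel for the exceedance probability
        (exact Beta computation is used for two models).
    """

    def __init__(self, alpha0: float = 1.0, tol: float = 1e-6,
                 max_iter: int = 1000, ep_samples: int = 10_000,
                 seed: int | None = None):
        self.alpha0 = alpha0
        self.tol = tol
        self.max_iter = max_iter
        self.ep_samples = ep_samples
        self.seed = seed

    def fit(self, evidence, y=None):
        rng = np.random.default_rng(self.seed)
        if isinstance(evidence, EvidenceMaps):
            if evidence.n_subjects < 2:
                warnings.warn(
                    "group model selection with fewer than 2 subjects "
                    "degenerates to the single-subject posterior", stacklevel=2)
            L = evidence.cvlme                       # (N, K, V)
            finite = np.isfinite(L).all(axis=(0, 1))
            n_excluded = int((~finite).sum())
            if n_excluded:
                warnings.warn(
                    f"excluding {n_excluded} voxels with non-finite evidence",
                    stacklevel=2)
            mask = evidence.mask.copy()
            mask[evidence.mask] = finite
            L = L[:, :, finite]
            K, V = L.shape[1], L.shape[2]
            if V:
                alpha, converged = _rfx_bms_array(
                    L, alpha0=self.alpha0, tol=self.tol, max_iter=self.max_iter)
                if not converged:
                    warnings.warn("RFX-BMS did not converge at some voxels",
                                  stacklevel=2)
                lf = likeliest_frequency(alpha)
                ep = _exceedance_prob_map(alpha, self.ep_samples, rng)
            else:
                alpha = np.zeros((K, 0))
                lf = np.zeros((K, 0))
                ep = np.zeros((K, 0))
            winner = np.zeros(mask.shape, dtype=int)
            if V:
                winner[mask] = np.argmax(lf, axis=0) + 1
            self.alpha_, self.lf_, self.ep_ = alpha, lf, ep
            self.winner_ = winner
            self.n_excluded_voxels_ = n_excluded
            self.result_ = GroupBMSResult(
                alpha=alpha, lf=lf, ep=ep, winner=winner, mask=mask,
                model_order=list(evidence.model_order), affine=evidence.affine)
            return self
        L = np.asarray(evidence, dtype=float)
        alpha = rfx_bms(L, alpha0=self.alpha0, tol=self.tol,
                        max_iter=self.max_iter)
        self.alpha_ = alpha
        self.lf_ = likeliest_frequency(alpha)
        self.ep_ = exceedance_prob(alpha, n_samples=self.ep_samples, rng=rng)
        return self
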