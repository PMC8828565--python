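"""CSP, whole-brain beamforming, and their unsupervised adaptive variants.

Both filter families solve the same Rayleigh-quotient problem

    w* = argmax_w (w^T S_num w) / (w^T S_den w)

by generalized eigendecomposition of the pencil (S_num, S_den):

* CSP: S_num = Sigma_1 (one class), S_den = Sigma_1 + Sigma_2 (both).
  Eigenvalues then lie in [0, 1] and components from BOTH spectrum ends are
  informative; three per end are kept by default.
* Beamformer: S_num = Sigma_ROI (model-derived, class-agnostic), S_den =
  Sigma_x (measured).  High-eigenvalue components carry much modelled-brain
  power relative to measured power, but eigenvalue rank says nothing about
  class discrimination, so ALL components are kept.

The adaptive variants (CSPa / BFa) keep the numerator frozen and track the
denominator with the exponential covariance update, re-decomposing after
every consumed epoch.  The update never reads labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .model_core import (
    CovarianceEstimate,
    EpochSet,
    FilterBank,
    apply_filters,
    compute_patterns,
    estimate_covariance,
    fix_column_signs,
    shrink,
    update_covariance,
)

__all__ = [
    "GeneralizedEigResult",
    "AdaptationState",
    "solve_rayleigh",
    "train_csp",
    "csp_from_covariances",
    "train_beamformer",
    "identity_bank",
    "adapt_and_filter",
    "adapt_step_covariance",
    "init_adaptation",
]

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e10


@dataclass
class GeneralizedEigResult:
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # channel x channel, column i pairs with value i
    numerator_label: str = "num"
    denominator_label: str = "den"


@dataclass
class AdaptationState:
    """Running denominator covariance for CSPa/BFa plus bookkeeping."""

    running_cov: CovarianceEstimate
    lam: float
    method: str
    epochs_consumed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("cspa", "bfa"):
            raise ValueError("adaptation method must be 'cspa' or 'bfa'")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must lie in (0, 1]")


def _ensure_pd(sigma: np.ndarray, context: str) -> np.ndarray:
    """Raise shrinkage in 0.01 steps until the matrix is safely conditioned."""
    gamma = 0.0
    out = sigma
    while np.linalg.cond(out) > _COND_LIMIT or _min_eig(out) <= 0:
        gamma += 0.01
        if gamma > 1.0:
            raise np.linalg.LinAlgError(
                f"{context}: denominator not positive definite; increase shrinkage"
            )
        out = shrink(sigma, gamma)
    if gamma > 0:
        logger.info("%s: raised shrinkage to gamma=%.2f for positive definiteness", context, gamma)
    return out


def _min_eig(sigma: np.ndarray) -> float:
    return float(scipy.linalg.eigh(sigma, eigvals_only=True, subset_by_index=[0, 0])[0])


def solve_rayleigh(
    sigma_num: CovarianceEstimate | np.ndarray,
    sigma_den: CovarianceEstimate | np.ndarray,
    numerator_label: str = "num",
    denominator_label: str = "den",
) -> GeneralizedEigResult:
    """Full eigensystem of the pencil (S_num, S_den), eigenvalues descending.

    Eigenvectors are S_den-orthonormal (``W^T S_den W = I``), so the filtered
    variance of each component equals 1 under the denominator covariance —
    the normalisation that makes log-variance features comparable after
    denominator adaptation.
    """
    num = sigma_num.sigma if isinstance(sigma_num, CovarianceEstimate) else np.asarray(sigma_num)
    den = sigma_den.sigma if isinstance(sigma_den, CovarianceEstimate) else np.asarray(sigma_den)
    if num.shape != den.shape:
        raise ValueError("covariance dimensions do not match")
    if _min_eig(den) <= 0 or np.linalg.cond(den) > _COND_LIMIT:
        raise np.linalg.LinAlgError("denominator not positive definite; increase shrinkage")
    vals, vecs = scipy.linalg.eigh(num, den)
    order = np.argsort(vals)[::-1]
    return GeneralizedEigResult(vals[order], vecs[:, order], numerator_label, denominator_label)


def _select_ends(n_components: int, n_per_end: int) -> np.ndarray:
    """Indices of the n largest and n smallest eigenvalues (descending input)."""
    return np.r_[np.arange(n_per_end), np.arange(n_components - n_per_end, n_components)]


def csp_from_covariances(
    sigma1: CovarianceEstimate,
    sigma2: CovarianceEstimate,
    n_per_end: int = 3,
) -> FilterBank:
    """CSP from pre-estimated class covariances (see :func:`train_csp`)."""
    n_ch = sigma1.n_channels
    if n_ch != sigma2.n_channels:
        raise ValueError("channel counts differ between classes")
    if n_ch < 2 * n_per_end:
        raise ValueError(f"{n_ch} channels cannot yield {2 * n_per_end} filters")
    den = _ensure_pd(sigma1.sigma + sigma2.sigma, "csp")
    eig = solve_rayleigh(sigma1.sigma, den, "Sigma_1", "Sigma_1+Sigma_2")
    keep = _select_ends(n_ch, n_per_end)
    W = eig.eigenvectors[:, keep]
    A = compute_patterns(W, den)
    A, W = fix_column_signs(A, W)
    return FilterBank(
        W,
        A,
        "csp",
        sigma1.band,
        numerator_cov=sigma1,
        denominator_cov=CovarianceEstimate(
            den, sigma1.n_epochs_seen + sigma2.n_epochs_seen, sigma1.shrinkage_gamma, sigma1.band
        ),
        eigenvalues=eig.eigenvalues[keep],
    )


def train_csp(
    epochs_class1: EpochSet,
    epochs_class2: EpochSet,
    n_per_end: int = 3,
    shrinkage_gamma: float | None = None,
) -> FilterBank:
    """Common Spatial Patterns from two-class epoch sets.

    Maximizes class-1 variance against the summed class covariances; the
    eigenvalue of a component is its class-1 share of total variance, so the
    two spectrum ends hold the most class-discriminative components.
    Keeps ``n_per_end`` from each end (3+3 by default).
    """
    if epochs_class1.n_epochs == 0 or epochs_class2.n_epochs == 0:
        raise ValueError("both classes must be non-empty")
    sigma1 = estimate_covariance(epochs_class1, shrinkage_gamma)
    sigma2 = estimate_covariance(epochs_class2, shrinkage_gamma)
    return csp_from_covariances(sigma1, sigma2, n_per_end)


def train_beamformer(
    sigma_roi: CovarianceEstimate,
    sigma_x: CovarianceEstimate,
) -> FilterBank:
    """Whole-brain-ROI beamformer: maximize modelled ROI power over measured.

    Unlike CSP, eigenvalue rank carries no class meaning here, so every
    component is retained and the classifier decides which are informative.
    """
    if sigma_roi.n_channels != sigma_x.n_channels:
        raise ValueError("covariance dimensions do not match")
    den = _ensure_pd(sigma_x.sigma, "beamformer")
    eig = solve_rayleigh(sigma_roi.sigma, den, "Sigma_ROI", "Sigma_x")
    W = eig.eigenvectors
    A = compute_patterns(W, den)
    A, W = fix_column_signs(A, W)
    return FilterBank(
        W,
        A,
        "bf",
        sigma_x.band,
        numerator_cov=sigma_roi,
        denominator_cov=CovarianceEstimate(den, sigma_x.n_epochs_seen, sigma_x.shrinkage_gamma, sigma_x.band),
        eigenvalues=eig.eigenvalues,
    )


def identity_bank(n_channels: int, band: str) -> FilterBank:
    """The no-filtering variant: W = A = identity."""
    eye = np.eye(n_channels)
    return FilterBank(eye, eye.copy(), "none", band)


def init_adaptation(bank: FilterBank, lam: float = 0.1) -> AdaptationState:
    """Adaptation state seeded from the bank's training-time statistics.

    The running covariance starts at the DATA covariance of the training
    condition: Sigma_x for the beamformer; for CSP, where the training
    denominator is the sum Sigma_1 + Sigma_2 (about twice the pooled data
    covariance), the running matrix starts at half the training denominator
    and is doubled again at re-decomposition time, so that with lam -> 0 the
    adapted bank coincides exactly with the trained one.
    """
    if bank.denominator_cov is None:
        raise ValueError("bank has no training denominator to adapt from")
    method = {"csp": "cspa", "cspa": "cspa", "bf": "bfa", "bfa": "bfa"}.get(bank.method)
    if method is None:
        raise ValueError(f"method {bank.method!r} has no adaptive variant")
    den = bank.denominator_cov
    sigma0 = den.sigma / 2.0 if method == "cspa" else den.sigma
    return AdaptationState(
        CovarianceEstimate(sigma0, den.n_epochs_seen, den.shrinkage_gamma, den.band),
        lam,
        method,
    )


def _redecompose(bank: FilterBank, state: AdaptationState) -> FilterBank:
    den_scale = 2.0 if state.method == "cspa" else 1.0
    den = _ensure_pd(den_scale * state.running_cov.sigma, state.method)
    eig = solve_rayleigh(bank.numerator_cov.sigma, den)
    if state.method == "cspa":
        n_per_end = bank.n_components // 2
        keep = _select_ends(den.shape[0], n_per_end)
    else:
        keep = np.arange(den.shape[0])
    W = eig.eigenvectors[:, keep]
    # sign continuity: align each new column with its predecessor
    flips = np.sign(np.einsum("ck,ck->k", W, bank.W))
    flips[flips == 0] = 1.0
    W = W * flips
    A = compute_patterns(W, den)
    return FilterBank(
        W,
        A,
        state.method,
        bank.band,
        numerator_cov=bank.numerator_cov,
        denominator_cov=CovarianceEstimate(
            den, state.running_cov.n_epochs_seen, state.running_cov.shrinkage_gamma, bank.band
        ),
        eigenvalues=eig.eigenvalues[keep],
    )


def adapt_step_covariance(
    bank: FilterBank,
    state: AdaptationState,
    epoch_cov: np.ndarray,
) -> tuple[FilterBank, AdaptationState]:
    """Absorb one epoch's sample covariance and re-decompose the bank.

    Covariance-level counterpart of :func:`adapt_and_filter` for pipelines
    that precompute per-epoch covariances.
    """
    if bank.numerator_cov is None:
        raise ValueError("bank lacks a frozen numerator; train it first")
    sigma = (1.0 - state.lam) * state.running_cov.sigma + state.lam * epoch_cov
    sigma = 0.5 * (sigma + sigma.T)
    new_running = CovarianceEstimate(
        sigma,
        state.running_cov.n_epochs_seen + 1,
        state.running_cov.shrinkage_gamma,
        state.running_cov.band,
    )
    new_state = AdaptationState(new_running, state.lam, state.method, state.epochs_consumed + 1)
    return _redecompose(bank, new_state), new_state


def adapt_and_filter(
    bank: FilterBank,
    state: AdaptationState,
    epoch: EpochSet,
) -> tuple[EpochSet, FilterBank, AdaptationState]:
    """One step of causal unsupervised adaptation.

    The incoming epoch is filtered with the CURRENT bank (so its own
    statistics never influence its own features), then the running
    denominator covariance absorbs the epoch and the bank is re-decomposed
    with its frozen numerator.  Labels are never consulted.
    """
    if epoch.n_epochs != 1:
        raise ValueError("adapt_and_filter consumes exactly one epoch at a time")
    if epoch.n_channels != bank.W.shape[0]:
        raise ValueError("dimension mismatch between bank and epoch")
    if bank.numerator_cov is None:
        raise ValueError("bank lacks a frozen numerator; train it first")
    filtered = apply_filters(bank, epoch)
    new_running = update_covariance(state.running_cov, epoch, state.lam)
    new_state = AdaptationState(new_running, state.lam, state.method, state.epochs_consumed + 1)
    new_bank = _redecompose(bank, new_state)
    return filtered, new_bank, new_state
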