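"""Linear generative model core: containers, covariance estimation and adaptation.

EEG is modelled as a linear, instantaneous mixture of sources,

    x(t) = A s(t) + eta(t),

so that second-order statistics obey ``Sigma_x = A Sigma_s A^T + Sigma_eta``.
Everything downstream (CSP, beamforming, log-variance features) operates on
channel-space covariance matrices; this module provides the shared containers
(:class:`EEGRecording`, :class:`EpochSet`, :class:`CovarianceEstimate`,
:class:`FilterBank`), shrinkage-regularised covariance estimation, the
exponential unsupervised covariance update used by the adaptive filter
variants, spatial-filter application and the filter-to-pattern conversion
``A = Sigma_x W (W^T Sigma_x W)^{-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Block",
    "EEGRecording",
    "CovarianceEstimate",
    "EpochSet",
    "FilterBank",
    "estimate_covariance",
    "update_covariance",
    "apply_filters",
    "compute_patterns",
    "fix_column_signs",
]

LABELS = ("low", "high")
CONDITIONS = ("nback", "maneuver")
BANDS = ("alpha", "theta", "broadband")


@dataclass
class Block:
    """A contiguous, single-class segment of a recording.

    ``phase`` indexes the repetition of the paradigm (the maneuver run is
    performed twice; repetitions are labelled 1 and 3, mirroring the fact
    that a secondary-task run sits between them).
    """

    start_s: float
    end_s: float
    label: str
    condition: str
    phase: int = 1

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"block must have end_s > start_s, got [{self.start_s}, {self.end_s}]")
        if self.label not in LABELS:
            raise ValueError(f"unknown workload label {self.label!r}; expected one of {LABELS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with montage labels and block annotations.

    data : (n_channels, n_samples) array, microvolts
    annotations : chronologically ordered, non-overlapping :class:`Block` list
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    reference: str = "linked-mastoid"
    annotations: list[Block] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channel x sample array")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        for prev, nxt in zip(self.annotations, self.annotations[1:]):
            if nxt.start_s < prev.end_s - 1e-9:
                raise ValueError("annotations must be chronological and non-overlapping")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class CovarianceEstimate:
    """A (shrunk) channel-space covariance matrix with provenance counters."""

    sigma: np.ndarray
    n_epochs_seen: int
    shrinkage_gamma: float
    band: str = "broadband"

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 2 or self.sigma.shape[0] != self.sigma.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if not 0.0 <= self.shrinkage_gamma <= 1.0:
            raise ValueError("shrinkage_gamma must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.sigma.shape[0]


@dataclass
class EpochSet:
    """Fixed-length, non-overlapping epochs with class labels and block ids.

    epochs : (n_epochs, n_channels, n_samples) tensor
    """

    epochs: np.ndarray
    labels: np.ndarray
    block_ids: np.ndarray
    band: str
    fs: float
    epoch_length_s: float = 60.0
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        self.block_ids = np.asarray(self.block_ids)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a 3-D epoch x channel x sample tensor")
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.block_ids) != n:
            raise ValueError("labels/block_ids must have one entry per epoch")
        if self.phases is not None:
            self.phases = np.asarray(self.phases)
            if len(self.phases) != n:
                raise ValueError("phases must have one entry per epoch")
        expected = int(round(self.epoch_length_s * self.fs))
        if n and self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} samples does not match "
                f"epoch_length_s * fs = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            self.epochs[mask],
            self.labels[mask],
            self.block_ids[mask],
            self.band,
            self.fs,
            self.epoch_length_s,
            None if self.phases is None else self.phases[mask],
        )


@dataclass
class FilterBank:
    """Spatial filters ``W`` (channel x component) with their patterns ``A``.

    ``method`` is one of none/csp/cspa/bf/bfa.  For ``none`` W is the
    identity.  ``numerator_cov`` is the fixed numerator of the Rayleigh
    quotient (class-1 covariance for CSP, the model-derived whole-brain ROI
    covariance for the beamformer); ``denominator_cov`` is the covariance the
    filters were (last) decomposed against.
    """

    W: np.ndarray
    A: np.ndarray
    method: str
    band: str
    numerator_cov: CovarianceEstimate | None = None
    denominator_cov: CovarianceEstimate | None = None
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.W.shape != self.A.shape:
            raise ValueError("W and A must have identical shape")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("filters must be finite")
        if np.any(np.linalg.norm(self.W, axis=0) == 0):
            raise ValueError("filters must be nonzero")
        if self.eigenvalues is not None:
            self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
            if np.any(np.diff(self.eigenvalues) > 1e-12):
                raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


# ---------------------------------------------------------------------------
# covariance estimation and adaptation


def _epoch_covariances(epochs: np.ndarray) -> np.ndarray:
    """Per-epoch sample covariances, epoch-mean removed, normalised by n-1."""
    x = epochs - epochs.mean(axis=2, keepdims=True)
    n = x.shape[2]
    return x @ x.transpose(0, 2, 1) / (n - 1)


def _analytic_gamma(epochs: np.ndarray) -> float:
    """Ledoit-Wolf analytic shrinkage coefficient on pooled, centred samples."""
    from sklearn.covariance import ledoit_wolf_shrinkage

    x = epochs - epochs.mean(axis=2, keepdims=True)
    pooled = x.transpose(0, 2, 1).reshape(-1, x.shape[1])
    # subsample long epochs: the coefficient is stable and this keeps it cheap
    if pooled.shape[0] > 4000:
        step = pooled.shape[0] // 4000 + 1
        pooled = pooled[::step]
    return float(ledoit_wolf_shrinkage(pooled, assume_centered=True))


def shrink(sigma: np.ndarray, gamma: float) -> np.ndarray:
    """Shrink toward the scaled identity: (1-g) S + g (tr S / C) I."""
    c = sigma.shape[0]
    return (1.0 - gamma) * sigma + gamma * (np.trace(sigma) / c) * np.eye(c)


def estimate_covariance(
    epochs: EpochSet, shrinkage_gamma: float | None = None
) -> CovarianceEstimate:
    """Epoch-averaged sample covariance, shrunk toward a scaled identity.

    With ``shrinkage_gamma=None`` the analytic (Ledoit-Wolf) coefficient is
    used; pass an explicit value in [0, 1] to fix it.  Shrinkage stands in
    for the never-explicitly-estimated sensor-noise term of the generative
    model and guarantees a positive semi-definite result.
    """
    if epochs.n_epochs == 0:
        raise ValueError("no epochs")
    if not np.all(np.isfinite(epochs.epochs)):
        raise ValueError("non-finite input")
    if shrinkage_gamma is None:
        gamma = _analytic_gamma(epochs.epochs)
    else:
        if not 0.0 <= shrinkage_gamma <= 1.0:
            raise ValueError("shrinkage_gamma must lie in [0, 1]")
        gamma = float(shrinkage_gamma)
    sigma = _epoch_covariances(epochs.epochs).mean(axis=0)
    sigma = shrink(sigma, gamma)
    sigma = 0.5 * (sigma + sigma.T)
    return CovarianceEstimate(sigma, epochs.n_epochs, gamma, epochs.band)


def update_covariance(
    prev: CovarianceEstimate, new_epoch: EpochSet, lam: float
) -> CovarianceEstimate:
    """Exponential unsupervised covariance update.

    ``Sigma(M) = (1 - lam) Sigma(M-1) + lam Sigma_{x_M}`` where ``Sigma_{x_M}``
    is the incoming epoch's sample covariance.  Class labels are never read:
    the update tracks the overall signal statistics, not the class structure.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError("lam must lie in (0, 1]")
    if new_epoch.n_epochs != 1:
        raise ValueError("update_covariance consumes exactly one epoch at a time")
    if new_epoch.n_channels != prev.n_channels:
        raise ValueError(
            f"channel mismatch: running covariance has {prev.n_channels}, "
            f"epoch has {new_epoch.n_channels}"
        )
    new_cov = _epoch_covariances(new_epoch.epochs)[0]
    sigma = (1.0 - lam) * prev.sigma + lam * new_cov
    sigma = 0.5 * (sigma + sigma.T)
    return CovarianceEstimate(sigma, prev.n_epochs_seen + 1, prev.shrinkage_gamma, prev.band)


# ---------------------------------------------------------------------------
# filtering and patterns


def apply_filters(bank: FilterBank, epochs: EpochSet) -> EpochSet:
    """Project epochs through the bank: each epoch becomes ``W^T epoch``.

    The channel axis turns into a component axis; labels, block ids and
    timing metadata are preserved.
    """
    if bank.W.shape[0] != epochs.n_channels:
        raise ValueError(
            f"dimension mismatch: bank expects {bank.W.shape[0]} channels, "
            f"epochs have {epochs.n_channels}"
        )
    out = np.einsum("ck,ecs->eks", bank.W, epochs.epochs)
    return EpochSet(
        out,
        epochs.labels,
        epochs.block_ids,
        epochs.band,
        epochs.fs,
        epochs.epoch_length_s,
        epochs.phases,
    )


def compute_patterns(W: np.ndarray, sigma_x: CovarianceEstimate | np.ndarray) -> np.ndarray:
    """Forward patterns of a filter set: ``A = Sigma_x W (W^T Sigma_x W)^{-1}``.

    For square invertible W this reduces to ``(W^{-1})^T``.  Patterns, not
    filters, are the physiologically interpretable quantity: column j of A is
    the scalp projection of the j-th extracted component.
    """
    sigma = sigma_x.sigma if isinstance(sigma_x, CovarianceEstimate) else np.asarray(sigma_x)
    W = np.asarray(W, dtype=float)
    sigma_s = W.T @ sigma @ W
    cond = np.linalg.cond(sigma_s)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError("rank-deficient filter set")
    return sigma @ W @ np.linalg.inv(sigma_s)


def fix_column_signs(A: np.ndarray, *companions: np.ndarray) -> tuple[np.ndarray, ...]:
    """Make the largest-|.| entry of each column of A positive.

    The sign of an eigenvector is arbitrary ("the flip in sign is
    meaningless"); this pins a convention for display and comparison.  Any
    companion matrices (e.g. the matching filters) get the same column flips.
    """
    signs = np.sign(A[np.argmax(np.abs(A), axis=0), np.arange(A.shape[1])])
    signs[signs == 0] = 1.0
    out = [A * signs]
    for m in companions:
        out.append(m * signs)
    return tuple(out)
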