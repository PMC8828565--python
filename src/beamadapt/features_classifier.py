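"""Band-pass preprocessing, 60-s epoching, log-variance features, LDA.

Workload classification of continuous EEG rides on band power: the signal is
band-passed to the theta (4-7 Hz) and alpha (8-13 Hz) ranges, cut into
non-overlapping 60-s epochs, spatially filtered, and each component's epoch
variance enters the feature vector through a logarithm (band power is
approximately chi-square distributed; the log makes the two classes
near-Gaussian with similar spread, which is what LDA assumes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .model_core import EEGRecording, EpochSet

__all__ = [
    "BandSpec",
    "ALPHA",
    "THETA",
    "FeatureMatrix",
    "ClassifierModel",
    "bandpass",
    "epoch",
    "logvar_features",
    "logvar_from_covariances",
    "train_lda",
    "predict",
]


@dataclass(frozen=True)
class BandSpec:
    """A Butterworth band-pass specification.

    ``order`` is the overall filter order (4 = two poles per band edge).
    """

    name: str
    low_hz: float
    high_hz: float
    order: int = 4
    design: str = "butterworth"

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be even and >= 2")
        if self.design != "butterworth":
            raise ValueError("only butterworth band-passes are supported")


ALPHA = BandSpec("alpha", 8.0, 13.0)
THETA = BandSpec("theta", 4.0, 7.0)


@dataclass
class FeatureMatrix:
    """Epoch x feature matrix of log-variances with epoch metadata."""

    values: np.ndarray
    feature_names: list[tuple[str, int]]  # (band, component)
    labels: np.ndarray
    block_ids: np.ndarray
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")
        if self.values.shape != (len(self.labels), len(self.feature_names)):
            raise ValueError("values shape must be (n_epochs, n_features)")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ClassifierModel:
    """Linear discriminant: label 'high' iff w^T f + b > 0 (ties -> 'low')."""

    weights: np.ndarray
    bias: float
    class_order: tuple[str, str] = ("low", "high")
    feature_names: list[tuple[str, int]] | None = None


def bandpass(recording: EEGRecording, band: BandSpec, zero_phase: bool = False) -> EEGRecording:
    """Band-pass every channel; causal (forward-only) by default.

    Online workload estimation cannot look ahead, hence the causal default;
    ``zero_phase=True`` switches to forward-backward filtering for offline
    inspection.  Annotations are untouched.
    """
    nyq = recording.fs / 2.0
    if band.high_hz >= nyq:
        raise ValueError(f"band edge {band.high_hz} Hz at or above Nyquist ({nyq} Hz)")
    sos = scipy.signal.butter(
        band.order // 2,
        [band.low_hz, band.high_hz],
        btype="bandpass",
        fs=recording.fs,
        output="sos",
    )
    filt = scipy.signal.sosfiltfilt if zero_phase else scipy.signal.sosfilt
    data = filt(sos, recording.data, axis=1)
    return EEGRecording(
        np.ascontiguousarray(data),
        recording.fs,
        list(recording.channel_labels),
        recording.reference,
        list(recording.annotations),
    )


def epoch(recording: EEGRecording, epoch_length_s: float = 60.0, band: str = "broadband") -> EpochSet:
    """Cut each annotated block into non-overlapping epochs from its onset.

    The epoch grid restarts at every block boundary so no epoch straddles a
    class change; an incomplete trailing window is discarded.
    """
    if not recording.annotations:
        raise ValueError("no usable epochs: recording has no block annotations")
    n_per = int(round(epoch_length_s * recording.fs))
    chunks, labels, block_ids, phases = [], [], [], []
    for bid, blk in enumerate(recording.annotations):
        start = int(round(blk.start_s * recording.fs))
        stop = min(int(round(blk.end_s * recording.fs)), recording.n_samples)
        n_epochs = (stop - start) // n_per
        for k in range(n_epochs):
            chunks.append(recording.data[:, start + k * n_per : start + (k + 1) * n_per])
            labels.append(blk.label)
            block_ids.append(bid)
            phases.append(blk.phase)
    if not chunks:
        raise ValueError("no usable epochs: every block is shorter than the epoch length")
    return EpochSet(
        np.stack(chunks),
        np.array(labels),
        np.array(block_ids),
        band,
        recording.fs,
        epoch_length_s,
        np.array(phases),
    )


def logvar_features(filtered_per_band: dict[str, EpochSet]) -> FeatureMatrix:
    """ln of each component's epoch variance, bands concatenated.

    All bands must hold the same epochs (labels/blocks identical); the
    feature for (band b, component c) of epoch i is
    ``ln var(component c of epoch i in band b)``.
    """
    if not filtered_per_band:
        raise ValueError("no bands given")
    items = list(filtered_per_band.items())
    first = items[0][1]
    cols, names = [], []
    for band_name, eps in items:
        if eps.n_epochs != first.n_epochs or not np.array_equal(eps.labels, first.labels):
            raise ValueError("bands must contain the same epochs and labels")
        var = eps.epochs.var(axis=2, ddof=1)
        if np.any(var <= 0):
            raise ValueError("degenerate component: zero variance would break the log")
        cols.append(np.log(var))
        names.extend((band_name, c) for c in range(eps.n_channels))
    return FeatureMatrix(
        np.hstack(cols), names, first.labels, first.block_ids, first.phases
    )


def logvar_from_covariances(
    per_band_covs: dict[str, np.ndarray],
    per_band_W: dict[str, np.ndarray],
    labels: np.ndarray,
    block_ids: np.ndarray,
    phases: np.ndarray | None = None,
) -> FeatureMatrix:
    """Log-variance features straight from per-epoch covariance tensors.

    ``var(W^T x) = diag(W^T C W)`` for an epoch with sample covariance C, so
    features can be computed without re-filtering time series.  Equivalent to
    :func:`logvar_features` after :func:`~beamadapt.model_core.apply_filters`.
    """
    cols, names = [], []
    for band_name, covs in per_band_covs.items():
        W = per_band_W[band_name]
        var = ((covs @ W) * W[None]).sum(axis=1)
        if np.any(var <= 0):
            raise ValueError("degenerate component: zero variance would break the log")
        cols.append(np.log(var))
        names.extend((band_name, c) for c in range(W.shape[1]))
    return FeatureMatrix(np.hstack(cols), names, labels, block_ids, phases)


def train_lda(features: FeatureMatrix, shrinkage: float | None = None) -> ClassifierModel:
    """Fisher discriminant with shrinkage-regularised pooled covariance.

    ``w = Sigma_pooled^-1 (mu_high - mu_low)``, bias placing the boundary
    midway between the projected class means.  The pooled covariance is
    shrunk toward a scaled identity (analytic Ledoit-Wolf coefficient when
    ``shrinkage`` is None) — indispensable when 128 features meet <= 80
    epochs.
    """
    lab = features.labels
    classes = ("low", "high")
    if not all((lab == c).any() for c in classes):
        raise ValueError("both classes must be present to train the classifier")
    x = features.values
    mu = {c: x[lab == c].mean(axis=0) for c in classes}
    resid = np.vstack([x[lab == c] - mu[c] for c in classes])
    if shrinkage is None:
        from sklearn.covariance import ledoit_wolf_shrinkage

        gamma = float(ledoit_wolf_shrinkage(resid, assume_centered=True))
    else:
        gamma = float(shrinkage)
    n = resid.shape[0]
    sigma = resid.T @ resid / max(n - 2, 1)
    c = sigma.shape[0]
    sigma = (1 - gamma) * sigma + gamma * (np.trace(sigma) / c) * np.eye(c)
    delta = mu["high"] - mu["low"]
    w = np.linalg.solve(sigma, delta)
    b = -float(w @ (mu["high"] + mu["low"]) / 2.0)
    return ClassifierModel(w, b, ("low", "high"), list(features.feature_names))


def predict(model: ClassifierModel, features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Labels and decision values; positive decisions mean 'high', ties 'low'."""
    if features.n_features != len(model.weights):
        raise ValueError(
            f"dimension mismatch: model has {len(model.weights)} weights, "
            f"features have {features.n_features} columns"
        )
    dv = features.values @ model.weights + model.bias
    labels = np.where(dv > 0, model.class_order[1], model.class_order[0])
    return labels, dv
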