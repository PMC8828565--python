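"""Chronological block-wise validation and cross-condition transfer.

EEG epochs are strongly autocorrelated, so random cross-validation splits
leak information; instead, within-condition performance is assessed by
leave-one-block-out cross-validation on chronologically contiguous folds
(one fold per block in the n-back paradigm, one per repetition/phase in the
maneuver paradigm), with spatial filters and the classifier fitted on
training folds only.  Transfer between conditions trains once on the full
training condition and walks the other condition's epochs in order,
optionally adapting the filters' denominator covariance per epoch.

All results are class-wise normalized losses (balanced error rate; 0.5 is
chance for two classes), with an exact Wilcoxon signed-rank test against
chance across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .config import RunConfig
from .features_classifier import (
    ClassifierModel,
    bandpass,
    epoch,
    logvar_from_covariances,
    predict,
    train_lda,
)
from .head_model import Leadfield, roi_covariance
from .model_core import CovarianceEstimate, EEGRecording, shrink
from .model_core import _epoch_covariances  # shared numerics, not re-derived here
from .spatial_filters import (
    AdaptationState,
    adapt_step_covariance,
    csp_from_covariances,
    identity_bank,
    init_adaptation,
    train_beamformer,
)

__all__ = [
    "ScenarioSpec",
    "EvaluationResult",
    "normalized_loss",
    "blockwise_cv",
    "transfer_evaluate",
    "adapted_transfer_patterns",
    "wilcoxon_vs_chance",
    "prepare_session",
    "PreparedSession",
]

METHODS = ("none", "csp", "cspa", "bf", "bfa")


@dataclass
class ScenarioSpec:
    train_condition: str
    test_condition: str
    method: str

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def within(self) -> bool:
        return self.train_condition == self.test_condition


@dataclass
class EvaluationResult:
    per_fold_losses: list[float]
    mean_loss: float
    n_train: list[int]
    n_test: list[int]
    scenario: ScenarioSpec
    p_value_vs_chance: float | None = None


def normalized_loss(true_labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Class-wise normalized loss: mean of the per-class error rates.

    Insensitive to class imbalance; a constant predictor scores exactly 0.5
    on a two-class problem.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.size == 0 or predicted_labels.size == 0:
        raise ValueError("label arrays must be non-empty")
    rates = []
    for c in ("low", "high"):
        mask = true_labels == c
        if not mask.any():
            raise ValueError(f"class missing; loss undefined (no true '{c}' instances)")
        rates.append(float(np.mean(predicted_labels[mask] != c)))
    return float(np.mean(rates))


def _loss_present_classes(true_labels: np.ndarray, predicted_labels: np.ndarray) -> float:
    """Per-fold loss: mean error over the classes present in the fold.

    Single-block folds contain one class, where the balanced loss is
    undefined; this degrades gracefully to that class's error rate.
    """
    rates = [
        float(np.mean(predicted_labels[true_labels == c] != c))
        for c in ("low", "high")
        if (true_labels == c).any()
    ]
    return float(np.mean(rates))


def wilcoxon_vs_chance(per_subject_mean_losses: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank p for losses against 0.5."""
    x = np.asarray(per_subject_mean_losses, dtype=float) - 0.5
    if len(x) < 5:
        raise ValueError("need at least 5 subjects")
    if np.all(x == 0):
        raise ValueError("degenerate: all differences zero")
    method = "exact" if len(x) <= 25 else "auto"
    return float(scipy.stats.wilcoxon(x, alternative="two-sided", method=method).pvalue)


# ---------------------------------------------------------------------------
# shared pipeline plumbing


@dataclass
class PreparedSession:
    """Band-passed, epoched session reduced to per-epoch covariance tensors."""

    condition: str
    reference: str
    labels: np.ndarray
    block_ids: np.ndarray
    phases: np.ndarray
    covs: dict[str, np.ndarray]  # band -> (n_epochs, C, C)
    gammas: dict[str, float]  # band -> shrinkage coefficient
    n_channels: int


def prepare_session(session: EEGRecording, config: RunConfig) -> PreparedSession:
    """Band-pass, epoch, and reduce a recording to per-epoch covariances.

    All downstream statistics (class covariances, running adaptation,
    log-variance features) derive from these tensors; time series are not
    needed again.
    """
    if not session.annotations:
        raise ValueError("session has no block annotations")
    condition = session.annotations[0].condition
    covs: dict[str, np.ndarray] = {}
    gammas: dict[str, float] = {}
    meta = None
    for band in config.bands:
        filt = bandpass(session, band, config.zero_phase)
        eps = epoch(filt, config.epoch_length_s, band.name)
        covs[band.name] = _epoch_covariances(eps.epochs)
        if config.shrinkage is None:
            from .model_core import _analytic_gamma

            gammas[band.name] = _analytic_gamma(eps.epochs)
        else:
            gammas[band.name] = float(config.shrinkage)
        meta = (eps.labels, eps.block_ids, eps.phases)
    labels, block_ids, phases = meta
    return PreparedSession(
        condition, session.reference, labels, block_ids, phases, covs, gammas, session.n_channels
    )


def _cov_estimate(prep: PreparedSession, band: str, mask: np.ndarray) -> CovarianceEstimate:
    sub = prep.covs[band][mask]
    if sub.shape[0] == 0:
        raise ValueError("no epochs selected")
    sigma = shrink(sub.mean(axis=0), prep.gammas[band])
    return CovarianceEstimate(0.5 * (sigma + sigma.T), sub.shape[0], prep.gammas[band], band)


def _fit_banks(
    prep: PreparedSession,
    train_mask: np.ndarray,
    method: str,
    config: RunConfig,
    sigma_roi: CovarianceEstimate | None,
) -> dict[str, "object"]:
    """Per-band filter banks fitted on the training epochs only."""
    base = {"cspa": "csp", "bfa": "bf"}.get(method, method)
    banks = {}
    for band in prep.covs:
        if base == "none":
            banks[band] = identity_bank(prep.n_channels, band)
        elif base == "csp":
            hi = _cov_estimate(prep, band, train_mask & (prep.labels == "high"))
            lo = _cov_estimate(prep, band, train_mask & (prep.labels == "low"))
            banks[band] = csp_from_covariances(hi, lo, config.n_csp_per_end)
        elif base == "bf":
            if sigma_roi is None:
                raise ValueError(
                    "beamformer methods need a leadfield; build one first "
                    "(`beamadapt leadfield build`)"
                )
            sx = _cov_estimate(prep, band, train_mask)
            banks[band] = train_beamformer(sigma_roi, sx)
        else:
            raise ValueError(f"unknown method {method!r}")
    return banks


def _features(prep: PreparedSession, banks: dict, mask: np.ndarray):
    return logvar_from_covariances(
        {b: prep.covs[b][mask] for b in prep.covs},
        {b: banks[b].W for b in prep.covs},
        prep.labels[mask],
        prep.block_ids[mask],
        prep.phases[mask],
    )


def _roi_for(reference: str, leadfield: Leadfield | None) -> CovarianceEstimate | None:
    if leadfield is None:
        return None
    return roi_covariance(leadfield.rereference(reference))


def _as_prepared(session: "EEGRecording | PreparedSession", config: RunConfig) -> PreparedSession:
    if isinstance(session, PreparedSession):
        return session
    return prepare_session(session, config)


# ---------------------------------------------------------------------------
# within-condition cross-validation


def blockwise_cv(
    session: "EEGRecording | PreparedSession",
    method: str,
    config: RunConfig | None = None,
    leadfield: Leadfield | None = None,
) -> EvaluationResult:
    """Chronological leave-one-block-out cross-validation within a condition.

    n-back sessions yield one fold per block; maneuver sessions one fold per
    repetition (phase), training on the other repetition.  The adaptive
    method names fall back to their non-adaptive base within a condition
    (adaptation addresses cross-condition shift, not within-condition CV).
    """
    config = config or RunConfig()
    prep = _as_prepared(session, config)
    sigma_roi = _roi_for(prep.reference, leadfield)
    if prep.condition == "maneuver":
        groups = [prep.phases == p for p in np.unique(prep.phases)]
    else:
        groups = [prep.block_ids == b for b in np.unique(prep.block_ids)]
    if len(groups) < 2:
        raise ValueError("need at least 2 blocks for cross-validation")
    base_method = {"cspa": "csp", "bfa": "bf"}.get(method, method)
    losses, n_train, n_test = [], [], []
    pooled_pred = np.empty(len(prep.labels), dtype=object)
    for test_mask in groups:
        train_mask = ~test_mask
        for c in ("low", "high"):
            if not ((prep.labels == c) & train_mask).any():
                raise ValueError(f"training fold lacks class '{c}'")
        banks = _fit_banks(prep, train_mask, base_method, config, sigma_roi)
        model = train_lda(_features(prep, banks, train_mask), config.shrinkage)
        pred, _ = predict(model, _features(prep, banks, test_mask))
        pooled_pred[test_mask] = pred
        losses.append(_loss_present_classes(prep.labels[test_mask], pred))
        n_train.append(int(train_mask.sum()))
        n_test.append(int(test_mask.sum()))
    # single-block folds hold one class, so the headline number is the
    # class-wise normalized loss over the pooled out-of-fold predictions
    mean_loss = normalized_loss(prep.labels, pooled_pred.astype(str))
    scenario = ScenarioSpec(prep.condition, prep.condition, method)
    return EvaluationResult(losses, mean_loss, n_train, n_test, scenario)


# ---------------------------------------------------------------------------
# cross-condition transfer


def _adaptive_predict(
    prep_test: PreparedSession,
    banks: dict,
    model: ClassifierModel,
    method: str,
    config: RunConfig,
) -> np.ndarray:
    """Walk test epochs chronologically, classifying then adapting (causal)."""
    states: dict[str, AdaptationState] = {
        band: init_adaptation(banks[band], config.lam) for band in banks
    }
    banks = dict(banks)
    n = len(prep_test.labels)
    pred = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.zeros(n, dtype=bool)
        mask[i] = True
        feats = _features(prep_test, banks, mask)
        pred[i] = predict(model, feats)[0][0]
        for band in banks:
            banks[band], states[band] = adapt_step_covariance(
                banks[band], states[band], prep_test.covs[band][i]
            )
    return pred.astype(str)


def _loss_by_phase(prep: PreparedSession, pred: np.ndarray) -> float:
    """Maneuver test sessions: average the per-repetition losses."""
    if prep.condition == "maneuver":
        phase_losses = [
            normalized_loss(prep.labels[prep.phases == p], pred[prep.phases == p])
            for p in np.unique(prep.phases)
        ]
        return float(np.mean(phase_losses))
    return normalized_loss(prep.labels, pred)


def adapted_transfer_patterns(
    train_session: "EEGRecording | PreparedSession",
    test_session: "EEGRecording | PreparedSession",
    method: str = "bfa",
    config: RunConfig | None = None,
    leadfield: Leadfield | None = None,
):
    """Final adapted per-band banks after a transfer pass, with discriminability.

    Trains on the full training condition, walks the test condition's epochs
    updating the denominator covariance (no labels used), and returns
    ``(banks, tstats)`` where ``banks[band]`` is the bank at the end of the
    constant update and ``tstats[band][k]`` the absolute two-sample
    t-statistic of component k's log-variance feature on the test condition —
    a single-feature discriminability score used to rank patterns for
    inspection.
    """
    config = config or RunConfig()
    if method not in ("cspa", "bfa"):
        raise ValueError("adapted patterns are defined for the adaptive variants")
    prep_train = _as_prepared(train_session, config)
    prep_test = _as_prepared(test_session, config)
    sigma_roi = _roi_for(prep_train.reference, leadfield)
    all_train = np.ones(len(prep_train.labels), dtype=bool)
    banks = _fit_banks(prep_train, all_train, method, config, sigma_roi)
    states = {band: init_adaptation(banks[band], config.lam) for band in banks}
    for i in range(len(prep_test.labels)):
        for band in banks:
            banks[band], states[band] = adapt_step_covariance(
                banks[band], states[band], prep_test.covs[band][i]
            )
    tstats: dict[str, np.ndarray] = {}
    lab = prep_test.labels
    for band, bank in banks.items():
        var = ((prep_test.covs[band] @ bank.W) * bank.W[None]).sum(axis=1)
        f = np.log(var)
        hi, lo = f[lab == "high"], f[lab == "low"]
        tstats[band] = np.abs(hi.mean(axis=0) - lo.mean(axis=0)) / np.maximum(
            np.sqrt(hi.var(axis=0, ddof=1) / len(hi) + lo.var(axis=0, ddof=1) / len(lo)), 1e-12
        )
    return banks, tstats


def transfer_evaluate(
    train_session: "EEGRecording | PreparedSession",
    test_session: "EEGRecording | PreparedSession",
    method: str,
    config: RunConfig | None = None,
    leadfield: Leadfield | None = None,
) -> EvaluationResult:
    """Train on one condition, evaluate chronologically on the other.

    Filters and the LDA model are fitted once on the full training condition
    (all 30 maneuver epochs when training on the maneuver); when the
    maneuver is the test condition its two repetitions are scored separately
    and the losses averaged.  For the adaptive variants the filters'
    denominator covariance is updated after each classified test epoch,
    without ever reading test labels.
    """
    config = config or RunConfig()
    prep_train = _as_prepared(train_session, config)
    prep_test = _as_prepared(test_session, config)
    if prep_train.n_channels != prep_test.n_channels:
        raise ValueError("montage mismatch between sessions")
    if prep_train.condition == prep_test.condition:
        raise ValueError("transfer needs two different conditions")
    sigma_roi = _roi_for(prep_train.reference, leadfield)

    train_masks = [np.ones(len(prep_train.labels), dtype=bool)]
    losses, n_train, n_test = [], [], []
    for train_mask in train_masks:
        banks = _fit_banks(prep_train, train_mask, method, config, sigma_roi)
        model = train_lda(_features(prep_train, banks, train_mask), config.shrinkage)
        if method in ("cspa", "bfa"):
            pred = _adaptive_predict(prep_test, banks, model, method, config)
        else:
            pred, _ = predict(model, _features(prep_test, banks, np.ones(len(prep_test.labels), dtype=bool)))
        losses.append(_loss_by_phase(prep_test, pred))
        n_train.append(int(train_mask.sum()))
        n_test.append(len(prep_test.labels))
    scenario = ScenarioSpec(prep_train.condition, prep_test.condition, method)
    return EvaluationResult(losses, float(np.mean(losses)), n_train, n_test, scenario)
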