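"""Synthetic EEG sessions with the statistical structure the pipeline assumes.

A session is the linear generative model made concrete:

    x(t) = sum_k a_k u_k(t)            (neural sources, mixed via the head model)
         + sum_j g_j v_j(t)            (ocular/muscle artifacts, steep scalp profiles)
         + background + sensor noise

* Neural sources are band-limited (theta or alpha) noise whose power switches
  between workload blocks; their class-power maps are SHARED across the two
  paradigms — they are the transferable signal.
* Artifact sources mix through near-electrode exponential gain profiles and
  carry class-power maps that may differ BETWEEN paradigms — they are the
  condition-specific confound that makes naive transfer fail.
* Background is a sum of pink-noise (1/f) brain sources mixed through the
  leadfield, with per-condition source re-weighting providing a global
  covariance shift between paradigms; white sensor noise tops it off.

Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .head_model import ElectrodeMontage, HeadShells, Leadfield, SourceGrid, compute_leadfield
from .model_core import Block, EEGRecording, CONDITIONS, LABELS

__all__ = [
    "ParadigmSchedule",
    "NeuralSource",
    "ArtifactSource",
    "SubjectParams",
    "make_schedule",
    "simulate_session",
    "make_transfer_benchmark",
    "analytic_channel_covariance",
    "default_subject",
]

_BAND_EDGES = {"theta": (4.0, 7.0), "alpha": (8.0, 13.0)}


@dataclass
class ParadigmSchedule:
    """Chronological, gap-free block sequence of one condition."""

    condition: str
    blocks: list[Block]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if abs(nxt.start_s - prev.end_s) > 1e-9:
                raise ValueError("schedule blocks must be chronological and gap-free")

    @property
    def duration_s(self) -> float:
        return self.blocks[-1].end_s if self.blocks else 0.0


@dataclass
class NeuralSource:
    """Workload-modulated oscillatory brain source.

    ``power`` maps workload label -> channel-space variance contributed by
    the source (the mixing column is normalised to unit norm).  The map is
    per-subject, NOT per-condition: neural modulation is what transfers.
    """

    position: np.ndarray  # inside the brain sphere, unit-scalp coordinates
    band: str  # 'theta' or 'alpha'
    power: dict[str, float]
    orientation: np.ndarray | None = None  # None -> radial

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.band not in _BAND_EDGES:
            raise ValueError(f"unknown band {self.band!r}")
        if set(self.power) != set(LABELS) or any(v <= 0 for v in self.power.values()):
            raise ValueError("power must map both workload labels to positive values")


@dataclass
class ArtifactSource:
    """Ocular or muscular contaminant with a steep near-electrode profile.

    ``power`` maps condition -> label -> channel-space variance; unlike
    neural sources the maps MAY differ between conditions, which is the core
    premise behind the failure of non-adaptive transfer.
    """

    name: str
    center: np.ndarray  # unit vector on the scalp sphere
    band_hz: tuple[float, float]
    power: dict[str, dict[str, float]]
    decay: float = 0.25  # chord-distance e-folding of the gain profile

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.center = self.center / np.linalg.norm(self.center)
        for cond, per_label in self.power.items():
            if cond not in CONDITIONS or set(per_label) != set(LABELS):
                raise ValueError("power must map condition -> {low, high} -> value")
            if any(v <= 0 for v in per_label.values()):
                raise ValueError("artifact powers must be positive")


@dataclass
class SubjectParams:
    """Per-subject generative parameters; all randomness flows from ``seed``."""

    neural_sources: list[NeuralSource] = field(default_factory=list)
    artifact_sources: list[ArtifactSource] = field(default_factory=list)
    background_level: float = 2.25
    sensor_noise_level: float = 1.0
    n_background: int = 40
    background_reweight_sigma: float = 1.0
    neural_orientation_jitter: float = 0.0  # radians of per-condition dipole tilt
    seed: int = 0


def make_schedule(
    condition: str,
    epochs_per_block_override: int | None = None,
    epoch_length_s: float = 60.0,
) -> ParadigmSchedule:
    """Default paradigm block schedules.

    n-back: ten alternating 4-min blocks (low first: 0-back precedes 2-back),
    i.e. five repetitions of each level within ~40 min.  Maneuver: 5 min of
    low-workload sailing then 10 min of high-workload connecting, performed
    twice (phases 1 and 3).  ``epochs_per_block_override`` rescales block
    lengths so each n-back block (resp. each maneuver low block, with high
    blocks twice as long) yields the requested number of epochs.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if epochs_per_block_override is not None and epochs_per_block_override <= 0:
        raise ValueError("epochs_per_block_override must be positive")
    blocks: list[Block] = []
    t = 0.0
    if condition == "nback":
        block_s = (
            4 * 60.0 if epochs_per_block_override is None else epochs_per_block_override * epoch_length_s
        )
        for k in range(10):
            label = "low" if k % 2 == 0 else "high"
            blocks.append(Block(t, t + block_s, label, "nback", phase=2))
            t += block_s
    else:
        low_s = 5 * 60.0 if epochs_per_block_override is None else epochs_per_block_override * epoch_length_s
        high_s = 2 * low_s
        for phase in (1, 3):
            blocks.append(Block(t, t + low_s, "low", "maneuver", phase=phase))
            t += low_s
            blocks.append(Block(t, t + high_s, "high", "maneuver", phase=phase))
            t += high_s
    return ParadigmSchedule(condition, blocks)


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance noise band-passed to [lo, hi] Hz."""
    sos = scipy.signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = scipy.signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _pink_noise(rng: np.random.Generator, n: int, fs: float, f_min: float = 0.5) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, f_min))
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _block_scale(schedule: ParadigmSchedule, fs: float, n: int, power: dict[str, float]) -> np.ndarray:
    """Per-sample amplitude sqrt(power[label]) following the block sequence."""
    s = np.zeros(n)
    for blk in schedule.blocks:
        i0 = int(round(blk.start_s * fs))
        i1 = min(int(round(blk.end_s * fs)), n)
        s[i0:i1] = np.sqrt(power[blk.label])
    return s


def _tilt(orient: np.ndarray, axis_seed: list[int], angle: float) -> np.ndarray:
    """Rotate a unit vector by ``angle`` around a seed-determined random axis."""
    if angle == 0.0:
        return orient
    rng = np.random.default_rng(np.random.SeedSequence(axis_seed))
    axis = np.cross(orient, rng.standard_normal(3))
    axis /= np.linalg.norm(axis)
    return float(np.cos(angle)) * orient + float(np.sin(angle)) * axis


def _mixing_column(
    source: NeuralSource,
    leadfield: Leadfield,
    jitter: float = 0.0,
    jitter_seed: list[int] | None = None,
) -> np.ndarray:
    """Unit-norm scalp projection of a neural source (exact, not grid-snapped).

    A non-zero ``jitter`` tilts the dipole orientation by that angle around a
    seed-determined axis — the scalp pattern of a physiological source is not
    perfectly reproducible across sessions and conditions, and this is what
    breaks exact filter transfer even for the shared neural sources.
    """
    orient = (
        source.position / np.linalg.norm(source.position)
        if source.orientation is None
        else np.asarray(source.orientation, dtype=float)
    )
    if jitter:
        orient = _tilt(orient, jitter_seed or [0], jitter)
    grid1 = SourceGrid(source.position[None, :], orient[None, :])
    lf1 = compute_leadfield(leadfield.montage, grid1, leadfield.shells)
    col = lf1.L[:, 0]
    return col / np.linalg.norm(col)


def _artifact_profile(art: ArtifactSource, montage: ElectrodeMontage) -> np.ndarray:
    """Unit-norm exponential gain profile peaking at the artifact's centre.

    Re-expressed in the linked-mastoid reference (like the neural mixing
    columns) so simulated channels share one reference.
    """
    d = np.linalg.norm(montage.positions - art.center, axis=1)
    g = np.exp(-d / art.decay)
    g = g - 0.5 * (g[montage.index("TP9")] + g[montage.index("TP10")])
    return g / np.linalg.norm(g)


def _background_weights(subject: SubjectParams, condition: str) -> np.ndarray:
    """Per-condition lognormal re-weighting of the background sources."""
    idx = CONDITIONS.index(condition)
    rng = np.random.default_rng(np.random.SeedSequence([int(subject.seed), 7, idx]))
    eps = rng.standard_normal(subject.n_background)
    return np.exp(subject.background_reweight_sigma * eps)


def _background_mixing(subject: SubjectParams, leadfield: Leadfield) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm mixing columns of the background sources (condition-invariant)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(subject.seed), 11]))
    n_cols = leadfield.grid.n_sources * leadfield.grid.n_orient
    cols = rng.choice(n_cols, size=subject.n_background, replace=False)
    B = leadfield.L[:, cols].copy()
    B /= np.linalg.norm(B, axis=0, keepdims=True)
    return B, cols


def simulate_session(
    schedule: ParadigmSchedule,
    subject: SubjectParams,
    montage: ElectrodeMontage,
    leadfield: Leadfield,
    fs: float = 200.0,
    return_ground_truth: bool = False,
):
    """Generate one condition's continuous EEG following the schedule.

    Deterministic given (subject.seed, schedule.condition); the two
    conditions of one subject share generative parameters but draw
    independent noise.
    """
    if montage.n_channels != leadfield.montage.n_channels:
        raise ValueError("montage does not match leadfield")
    if not schedule.blocks:
        raise ValueError("schedule has no blocks")
    n = int(round(schedule.duration_s * fs))
    cond_idx = CONDITIONS.index(schedule.condition)
    leadfield = leadfield.rereference("linked-mastoid")
    rng = np.random.default_rng(np.random.SeedSequence([int(subject.seed), 3, cond_idx]))
    x = np.zeros((montage.n_channels, n))
    truth: dict = {"neural": [], "artifact": [], "condition": schedule.condition}

    for k, src in enumerate(subject.neural_sources):
        lo, hi = _BAND_EDGES[src.band]
        u = _band_limited_noise(rng, n, fs, lo, hi)
        u *= _block_scale(schedule, fs, n, src.power)
        a = _mixing_column(
            src,
            leadfield,
            subject.neural_orientation_jitter,
            [int(subject.seed), 13, cond_idx, k],
        )
        x += np.outer(a, u)
        truth["neural"].append({"band": src.band, "mixing": a, "timecourse": u, "power": dict(src.power)})

    for art in subject.artifact_sources:
        v = _band_limited_noise(rng, n, fs, *art.band_hz)
        v *= _block_scale(schedule, fs, n, art.power[schedule.condition])
        g = _artifact_profile(art, montage)
        x += np.outer(g, v)
        truth["artifact"].append({"name": art.name, "mixing": g, "timecourse": v})

    if subject.n_background > 0 and subject.background_level > 0:
        B, _ = _background_mixing(subject, leadfield)
        w = _background_weights(subject, schedule.condition)
        # batched spectral shaping: 1/f power, unit variance per source
        spec = np.fft.rfft(rng.standard_normal((subject.n_background, n)), axis=1)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        scale = 1.0 / np.sqrt(np.maximum(f, 0.5))
        scale[0] = 0.0
        bg = np.fft.irfft(spec * scale, n, axis=1)
        bg /= bg.std(axis=1, keepdims=True)
        x += (B * (subject.background_level * w)) @ bg

    if subject.sensor_noise_level > 0:
        x += subject.sensor_noise_level * rng.standard_normal(x.shape)

    rec = EEGRecording(x, fs, list(montage.labels), "linked-mastoid", list(schedule.blocks))
    if return_ground_truth:
        return rec, truth
    return rec


def analytic_channel_covariance(
    schedule: ParadigmSchedule,
    subject: SubjectParams,
    montage: ElectrodeMontage,
    leadfield: Leadfield,
) -> np.ndarray:
    """Long-run broadband channel covariance predicted from the parameters.

    Duration-weighted source powers times outer products of their mixing
    columns, plus the background and white-noise terms.  The simulator's
    empirical covariance converges to this.
    """
    total = schedule.duration_s
    wdur = {
        lab: sum(b.duration_s for b in schedule.blocks if b.label == lab) / total for lab in LABELS
    }
    leadfield = leadfield.rereference("linked-mastoid")
    c = montage.n_channels
    sigma = np.zeros((c, c))
    cond_idx = CONDITIONS.index(schedule.condition)
    for k, src in enumerate(subject.neural_sources):
        a = _mixing_column(
            src,
            leadfield,
            subject.neural_orientation_jitter,
            [int(subject.seed), 13, cond_idx, k],
        )
        p = sum(wdur[lab] * src.power[lab] for lab in LABELS)
        sigma += p * np.outer(a, a)
    for art in subject.artifact_sources:
        g = _artifact_profile(art, montage)
        p = sum(wdur[lab] * art.power[schedule.condition][lab] for lab in LABELS)
        sigma += p * np.outer(g, g)
    if subject.n_background > 0 and subject.background_level > 0:
        B, _ = _background_mixing(subject, leadfield)
        w = _background_weights(subject, schedule.condition)
        amp2 = (subject.background_level * w) ** 2
        sigma += (B * amp2) @ B.T
    sigma += subject.sensor_noise_level**2 * np.eye(c)
    return sigma


def default_subject(
    montage: ElectrodeMontage,
    seed: int = 0,
    neural_level: float = 1.1,
    artifact_level: float = 2.25,
) -> SubjectParams:
    """Benchmark subject realising the cross-condition transfer phenomenon.

    Shared neural workload modulation (frontal theta up 2:1 with load,
    occipital alpha down 1:2), an ocular source discriminative only in the
    maneuver condition and a temporal-muscle source discriminative only in
    the n-back (3:1 in their discriminative condition, flat elsewhere with
    matched average power).  Effect sizes are benchmark parameters, not
    measurements.
    """
    fp_mid = montage.positions[montage.index("Fp1")] + montage.positions[montage.index("Fp2")]
    ocular = ArtifactSource(
        "ocular",
        fp_mid,
        (1.0, 7.0),
        {
            "maneuver": {"low": 1.0 * artifact_level, "high": 3.0 * artifact_level},
            "nback": {"low": 2.0 * artifact_level, "high": 2.0 * artifact_level},
        },
    )
    muscle = ArtifactSource(
        "muscle",
        montage.positions[montage.index("T8")],
        (8.0, 45.0),
        {
            "nback": {"low": 1.0 * artifact_level, "high": 3.0 * artifact_level},
            "maneuver": {"low": 2.0 * artifact_level, "high": 2.0 * artifact_level},
        },
    )
    frontal_theta = NeuralSource(
        np.array([0.0, 0.45, 0.35]),
        "theta",
        {"low": 1.0 * neural_level, "high": 2.0 * neural_level},
    )
    occipital_alpha = NeuralSource(
        np.array([0.0, -0.5, 0.25]),
        "alpha",
        {"low": 2.0 * neural_level, "high": 1.0 * neural_level},
    )
    return SubjectParams(
        neural_sources=[frontal_theta, occipital_alpha],
        artifact_sources=[ocular, muscle],
        neural_orientation_jitter=0.5,
        seed=seed,
    )


def make_transfer_benchmark(
    seed: int,
    montage: ElectrodeMontage | None = None,
    leadfield: Leadfield | None = None,
    fs: float = 200.0,
    epochs_per_block_override: int | None = None,
):
    """Two sessions of one synthetic subject plus generative ground truth.

    Returns ``(nback_session, maneuver_session, ground_truth)`` where the
    ground truth holds, per session, the neural/artifact mixing columns and
    time courses.  The neural class-power maps are identical across the two
    sessions by construction; the artifacts' are not, and the background is
    re-weighted per condition.
    """
    from .head_model import build_montage, make_source_grid

    if montage is None:
        montage = build_montage(64)
    if leadfield is None:
        leadfield = compute_leadfield(montage, make_source_grid(), HeadShells())
    subject = default_subject(montage, seed=seed)
    nb_sched = make_schedule("nback", epochs_per_block_override)
    mv_sched = make_schedule("maneuver", epochs_per_block_override)
    nb, truth_nb = simulate_session(nb_sched, subject, montage, leadfield, fs, return_ground_truth=True)
    mv, truth_mv = simulate_session(mv_sched, subject, montage, leadfield, fs, return_ground_truth=True)
    ground_truth = {"nback": truth_nb, "maneuver": truth_mv, "subject": subject}
    return nb, mv, ground_truth
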