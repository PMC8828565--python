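"""Analytic three-shell spherical head model and whole-brain ROI covariance.

The forward model maps dipolar sources inside the innermost (brain) sphere to
scalp potentials through three concentric shells (brain / skull / scalp) with
piecewise-constant conductivities.  For each spherical-harmonic order ``n``
the radial part of the potential in shell ``j`` is ``A_j r^n + B_j r^-(n+1)``;
imposing continuity of potential and radial current at the two interfaces and
zero current through the scalp surface yields a small linear system whose
solution gives the per-order transfer gain.  The series is truncated (60
terms by default, ample for sources kept away from the inner surface).

The beamformer needs the channel-space covariance a unit-power, uncorrelated
source distribution over a region of interest would produce:
``Sigma_ROI = L_roi Sigma_s L_roi^T``.  Following the whole-brain-ROI idea,
the default ROI is the entire source grid with identity source covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model_core import CovarianceEstimate

__all__ = [
    "ElectrodeMontage",
    "SourceGrid",
    "HeadShells",
    "Leadfield",
    "ROISpec",
    "build_montage",
    "make_source_grid",
    "compute_leadfield",
    "roi_covariance",
]

# Standard 10/10 labels: the first 32 form the standard 32-channel cap and
# are a strict subset of the 64-channel set.
_LABELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
]
_LABELS_64 = _LABELS_32 + [
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FT9", "FT7", "FC3",
    "FC4", "FT8", "FT10", "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4",
    "TP8", "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]


@dataclass
class ElectrodeMontage:
    """10/10 electrode labels with unit-sphere positions (head-centred)."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3), unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("electrode labels must be unique")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must be unit vectors")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class SourceGrid:
    """Dipole locations strictly inside the brain sphere.

    orientations: (n_orient, 3) shared dipole orientations per location
    (default: the three Cartesian unit vectors).
    """

    positions: np.ndarray  # (n_sources, 3)
    orientations: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )
    spacing: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_sources, 3)")
        if self.orientations.ndim != 2 or self.orientations.shape[1] != 3:
            raise ValueError("orientations must be (n_orient, 3)")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    @property
    def n_orient(self) -> int:
        return self.orientations.shape[0]


@dataclass
class HeadShells:
    """Concentric-sphere radii (fractions of the scalp radius) and relative
    conductivities, innermost first (brain, skull, scalp)."""

    radii: tuple[float, float, float] = (0.87, 0.92, 1.0)
    conductivities: tuple[float, float, float] = (1.0, 1.0 / 50.0, 1.0)

    def __post_init__(self) -> None:
        if not (0 < self.radii[0] < self.radii[1] < self.radii[2]):
            raise ValueError("radii must increase strictly outward")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be positive")


@dataclass
class Leadfield:
    """Channel x (source * orientation) gain matrix, average-referenced.

    Column ordering is source-major: columns [3 s, 3 s + 3) hold the three
    orientations of grid location s (for the default 3-orientation grid).
    """

    L: np.ndarray
    montage: ElectrodeMontage
    grid: SourceGrid
    shells: HeadShells
    reference: str = "average"

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if not np.all(np.isfinite(self.L)):
            raise ValueError("leadfield must be finite")
        if self.L.shape != (self.montage.n_channels, self.grid.n_sources * self.grid.n_orient):
            raise ValueError("leadfield shape does not match montage/grid")

    def rereference(self, reference: str) -> "Leadfield":
        """Return a copy in another reference ('average' or 'linked-mastoid')."""
        if reference == self.reference:
            return self
        if reference == "average":
            L = self.L - self.L.mean(axis=0, keepdims=True)
        elif reference == "linked-mastoid":
            try:
                i9 = self.montage.index("TP9")
                i10 = self.montage.index("TP10")
            except ValueError as exc:
                raise ValueError("linked-mastoid reference needs TP9 and TP10") from exc
            L = self.L - 0.5 * (self.L[i9] + self.L[i10])
        else:
            raise ValueError(f"unknown reference {reference!r}")
        return Leadfield(L, self.montage, self.grid, self.shells, reference)


@dataclass
class ROISpec:
    """Source subset and source covariance defining a region of interest."""

    source_indices: np.ndarray | None = None  # None = whole brain
    source_cov: np.ndarray | None = None  # None = identity

    def resolve_indices(self, grid: SourceGrid) -> np.ndarray:
        if self.source_indices is None:
            return np.arange(grid.n_sources)
        idx = np.asarray(self.source_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("empty ROI")
        if idx.min() < 0 or idx.max() >= grid.n_sources:
            raise ValueError("ROI indices outside grid")
        return idx


def build_montage(n_channels: int = 64) -> ElectrodeMontage:
    """Standard 10/10 montage with positions projected to the unit sphere.

    Coordinates come from the standard-1005 template; a least-squares sphere
    is fitted to the cap and positions are re-expressed as unit vectors from
    its centre (x right, y anterior, z superior; Cz near the vertex).  The
    32-channel set is a subset of the 64-channel one.
    """
    if n_channels == 64:
        labels = list(_LABELS_64)
    elif n_channels == 32:
        labels = list(_LABELS_32)
    else:
        raise ValueError(f"unsupported channel count {n_channels}; use 32 or 64")
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    ch_pos = montage.get_positions()["ch_pos"]
    # fit the sphere on the full 64 cap so the 32 subset shares the centre
    ref = np.array([ch_pos[l] for l in _LABELS_64])
    a = np.c_[2 * ref, np.ones(len(ref))]
    sol, *_ = np.linalg.lstsq(a, (ref**2).sum(axis=1), rcond=None)
    center = sol[:3]
    pos = np.array([ch_pos[l] for l in labels]) - center
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return ElectrodeMontage(labels, pos)


def make_source_grid(
    shells: HeadShells | None = None,
    spacing: float = 0.19,
    max_eccentricity: float = 0.9,
    orientations: np.ndarray | None = None,
) -> SourceGrid:
    """Regular Cartesian grid of dipole locations inside the brain sphere.

    ``max_eccentricity`` caps the source radius as a fraction of the brain
    radius: sources hugging the inner surface would need many more series
    terms.  The default spacing yields roughly 300 locations at 64-channel
    resolution.
    """
    shells = shells or HeadShells()
    r_max = max_eccentricity * shells.radii[0]
    if not 0 < spacing:
        raise ValueError("grid spacing must be positive")
    ax = np.arange(-r_max, r_max + 1e-12, spacing)
    ax -= ax.mean()  # symmetric about the origin
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.c_[xx.ravel(), yy.ravel(), zz.ravel()]
    pts = pts[np.linalg.norm(pts, axis=1) <= r_max + 1e-12]
    orient = np.eye(3) if orientations is None else np.asarray(orientations, dtype=float)
    return SourceGrid(pts, orient, spacing)


def _shell_gains(n_terms: int, shells: HeadShells) -> np.ndarray:
    """Per-order scalp-surface gain for a unit inner-shell source coefficient.

    For order n the innermost-shell potential carries a source term
    ``r^-(n+1)``; this solves the interface/boundary conditions and returns
    the resulting potential amplitude at the scalp surface, order 1..n_terms.
    """
    r1, r2, r3 = shells.radii
    s1, s2, s3 = shells.conductivities
    gains = np.empty(n_terms)
    for n in range(1, n_terms + 1):
        m = np.zeros((5, 5))
        rhs = np.zeros(5)
        # unknowns: A1, A2, B2, A3, B3
        # potential continuity at r1
        m[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0, 0]
        rhs[0] = -(r1 ** -(n + 1))
        # radial current continuity at r1
        m[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0,
            0,
        ]
        rhs[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # potential continuity at r2
        m[2] = [0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # radial current continuity at r2
        m[3] = [
            0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # insulating scalp surface
        m[4] = [0, 0, 0, n * r3 ** (n - 1), -(n + 1) * r3 ** -(n + 2)]
        a1, a2, b2, a3, b3 = np.linalg.solve(m, rhs)
        gains[n - 1] = a3 * r3**n + b3 * r3 ** -(n + 1)
    return gains


def compute_leadfield(
    montage: ElectrodeMontage,
    grid: SourceGrid,
    shells: HeadShells | None = None,
    n_terms: int = 60,
) -> Leadfield:
    """Scalp potentials of every (source, orientation) pair, average-referenced.

    For a dipole at radius b with moment q, the scalp potential at electrode
    direction e is::

        V = 1/(4 pi s1) sum_n g_n b^(n-1)
            [ n (q . r0hat) P_n(c) + (q . (e - c r0hat)) P_n'(c) ]

    with c the cosine between source and electrode directions and g_n the
    per-order shell gain.  Units are arbitrary but consistent; only relative
    gains matter downstream.
    """
    shells = shells or HeadShells()
    radii = np.linalg.norm(grid.positions, axis=1)
    if np.any(radii >= shells.radii[0] - 1e-12):
        raise ValueError("source outside brain compartment")
    gains = _shell_gains(n_terms, shells)
    e_hat = montage.positions  # unit vectors, scalp radius normalised to 1
    n_e = montage.n_channels
    n_s = grid.n_sources
    n_o = grid.n_orient
    L = np.zeros((n_e, n_s * n_o))
    s1 = shells.conductivities[0]
    # source direction handling: at the exact centre only n=1 survives and the
    # potential reduces to g1 (q . e); use an arbitrary axis there.
    r0_hat = np.where(radii[:, None] > 1e-12, grid.positions / np.maximum(radii, 1e-300)[:, None], [0.0, 0.0, 1.0])
    c = e_hat @ r0_hat.T  # (n_e, n_s)
    c = np.clip(c, -1.0, 1.0)
    # Legendre P_n and P_n' by recurrence, accumulating the series.
    p_prev = np.ones_like(c)  # P_0
    p_cur = c.copy()  # P_1
    dp_prev = np.zeros_like(c)  # P_0'
    dp_cur = np.ones_like(c)  # P_1'
    qr = grid.orientations @ r0_hat.T  # (n_o, n_s): q . r0hat
    qe = np.einsum("oc,ec->eo", grid.orientations, e_hat)  # q . e
    acc = np.zeros((n_e, n_s, n_o))
    b_pow = np.ones(n_s)  # b^(n-1)
    for n in range(1, n_terms + 1):
        if n > 1:
            p_next = ((2 * n - 1) * c * p_cur - (n - 1) * p_prev) / n
            dp_next = dp_prev + (2 * n - 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            b_pow = b_pow * radii
        # radial term: n (q.r0hat) P_n ; tangential: (q.e - c q.r0hat) P_n'
        radial = n * p_cur[:, :, None] * qr.T[None, :, :]
        tangential = dp_cur[:, :, None] * (qe[:, None, :] - c[:, :, None] * qr.T[None, :, :])
        acc += (gains[n - 1] * b_pow)[None, :, None] * (radial + tangential)
    L = (acc / (4.0 * np.pi * s1)).reshape(n_e, n_s * n_o)
    L = L - L.mean(axis=0, keepdims=True)  # average reference
    return Leadfield(L, montage, grid, shells, "average")


def roi_covariance(leadfield: Leadfield, roi: ROISpec | None = None) -> CovarianceEstimate:
    """Channel-space covariance of unit-power ROI sources: L Sigma_s L^T.

    This is the numerator of the beamformer's Rayleigh quotient.  With the
    default whole-brain ROI and identity source covariance it measures, for
    a candidate filter w, how much power the modelled brain as a whole can
    feed into w^T x.
    """
    roi = roi or ROISpec()
    idx = roi.resolve_indices(leadfield.grid)
    n_o = leadfield.grid.n_orient
    cols = (idx[:, None] * n_o + np.arange(n_o)[None, :]).ravel()
    L = leadfield.L[:, cols]
    if roi.source_cov is None:
        sigma = L @ L.T
    else:
        sc = np.asarray(roi.source_cov, dtype=float)
        if sc.shape != (len(cols), len(cols)):
            raise ValueError("source_cov shape does not match ROI size")
        if not np.allclose(sc, sc.T, atol=1e-10):
            raise ValueError("source_cov must be symmetric")
        sigma = L @ sc @ L.T
    sigma = 0.5 * (sigma + sigma.T)
    return CovarianceEstimate(sigma, 0, 0.0, "broadband")
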