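"""Phase lag index (PLI) connectivity and cluster summaries.

The PLI of two phase series is the absolute time-average of the sign of
their wrapped phase difference:

    PLI = | < sign(dphi_t) > |,     dphi wrapped to (-pi, pi]

It is 0 for no coupling or coupling at exactly zero (or pi) lag, and 1
for perfect locking at any other lag — which is what makes it robust to
volume conduction, whose spurious correlations are instantaneous.  The
directed variant (dPLI) is the time-average Heaviside step of the same
differences: 0.5 means no leading/lagging asymmetry, above 0.5 the first
channel leads.  The two are tied by ``|2 dPLI - 1| = PLI``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import BandDefinition, PhaseEpoch

#: Electrode clusters used for short- vs long-range summaries.
FRONTAL_LABELS: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
POSTERIOR_LABELS: tuple[str, ...] = ("P3", "Pz", "P4", "O1", "Oz", "O2")


@dataclass(frozen=True)
class ClusterDefinition:
    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("cluster labels must be unique")


DEFAULT_FRONTAL = ClusterDefinition("frontal", FRONTAL_LABELS)
DEFAULT_POSTERIOR = ClusterDefinition("posterior", POSTERIOR_LABELS)


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel connectivity, zero diagonal."""

    values: np.ndarray
    channels: tuple[str, ...]
    measure: str = "pli"  # "pli" or "dpli"
    band: BandDefinition | None = None
    level: str = "subject"  # "epoch" or "subject"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match channel labels")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("connectivity values must lie in [0, 1]")


@dataclass
class ClusterConnectivity:
    """Mean PLI within and between the frontal and posterior clusters."""

    frontal_short: float
    posterior_short: float
    long_range: float


def _phase_diff(phase_a: np.ndarray, phase_b: np.ndarray) -> np.ndarray:
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"phase series lengths differ: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty phase series")
    return a - b


def _sign_wrapped(d: np.ndarray) -> np.ndarray:
    """sign(wrap(d)) for raw differences d of two angles in (-pi, pi].

    Equivalent to wrapping d into (-pi, pi] first, but without the
    modulo pass: d in (pi, 2pi) wraps negative, d in (-2pi, -pi] wraps
    positive, and sign(0) = 0.
    """
    return np.where(d > np.pi, -1.0, np.where(d <= -np.pi, 1.0, np.sign(d)))


def pli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase lag index of two wrapped phase series; symmetric, in [0, 1]."""
    return float(np.abs(np.mean(_sign_wrapped(_phase_diff(phase_a, phase_b)))))


def dpli(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Directed PLI: fraction of time the first series leads (H(0) = 0.5)."""
    s = _sign_wrapped(_phase_diff(phase_a, phase_b))
    return float(np.mean((s + 1.0) / 2.0))


def _epoch_matrix(phases: np.ndarray, measure: str) -> np.ndarray:
    # sign of the wrapped pairwise difference, all pairs at once; the
    # wrap is folded into the sign in place to avoid large temporaries
    s = phases[:, None, :] - phases[None, :, :]
    big_pos = s > np.pi
    big_neg = s <= -np.pi
    np.sign(s, out=s)
    s[big_pos] = -1.0
    s[big_neg] = 1.0
    if measure == "pli":
        m = np.abs(np.mean(s, axis=-1))
    elif measure == "dpli":
        m = (np.mean(s, axis=-1) + 1.0) / 2.0
    else:
        raise ValueError(f"unknown measure {measure!r}")
    np.fill_diagonal(m, 0.0)
    return m


def connectivity_matrix(phases: list[PhaseEpoch] | PhaseEpoch,
                        measure: str = "pli",
                        band: BandDefinition | None = None) -> ConnectivityMatrix:
    """Connectivity over all channel pairs, averaged over epochs.

    The matrix is computed per epoch and averaged entrywise, so a single
    epoch returns that epoch's matrix unchanged.
    """
    if isinstance(phases, PhaseEpoch):
        phases = [phases]
    if not phases:
        raise ValueError("at least one phase epoch required")
    channels = tuple(phases[0].channels)
    for p in phases:
        if tuple(p.channels) != channels:
            raise ValueError("inconsistent channel labels across epochs")
    mats = [_epoch_matrix(np.asarray(p.phases, dtype=float), measure) for p in phases]
    level = "epoch" if len(mats) == 1 else "subject"
    return ConnectivityMatrix(np.mean(mats, axis=0), channels, measure, band, level)


def global_mean_pli(matrix: ConnectivityMatrix) -> float:
    """Mean PLI over all distinct channel pairs (upper triangle)."""
    if matrix.measure != "pli":
        raise ValueError("global mean is defined for PLI matrices only")
    iu = np.triu_indices(matrix.values.shape[0], k=1)
    return float(np.mean(matrix.values[iu]))


def _pair_mean(values: np.ndarray, idx_a: list[int], idx_b: list[int],
               within: bool) -> float:
    if within:
        pairs = [(i, j) for k, i in enumerate(idx_a) for j in idx_a[k + 1:]]
    else:
        pairs = [(i, j) for i in idx_a for j in idx_b]
    return float(np.mean([values[i, j] for i, j in pairs]))


def cluster_means(matrix: ConnectivityMatrix,
                  frontal: ClusterDefinition = DEFAULT_FRONTAL,
                  posterior: ClusterDefinition = DEFAULT_POSTERIOR,
                  ) -> ClusterConnectivity:
    """Short-range (within-cluster) and long-range (cross-cluster) mean PLI."""
    if set(frontal.labels) & set(posterior.labels):
        raise ValueError("frontal and posterior clusters overlap")
    lowered = [c.lower() for c in matrix.channels]

    def indices(cluster: ClusterDefinition) -> list[int]:
        out = []
        for lab in cluster.labels:
            try:
                out.append(lowered.index(lab.lower()))
            except ValueError:
                raise KeyError(
                    f"cluster {cluster.name!r} label {lab!r} not in matrix channels"
                ) from None
        return out

    fi, pi_ = indices(frontal), indices(posterior)
    return ClusterConnectivity(
        frontal_short=_pair_mean(matrix.values, fi, fi, within=True),
        posterior_short=_pair_mean(matrix.values, pi_, pi_, within=True),
        long_range=_pair_mean(matrix.values, fi, pi_, within=False),
    )
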