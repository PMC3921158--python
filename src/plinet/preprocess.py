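"""Band filtering, epoch segmentation, and instantaneous phase extraction.

The analysis path mirrors standard resting-state practice: the continuous
recording is zero-phase band-pass filtered into the classical EEG bands,
cut into fixed-length artifact-free epochs (six epochs of 4096 samples by
default), and the instantaneous phase of every channel is taken as the
argument of the analytic (Hilbert) signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .montage import MultichannelRecording

DEFAULT_N_EPOCHS = 6
DEFAULT_EPOCH_LENGTH = 4096


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges {self.low}-{self.high} Hz")


#: The classical resting-state bands: delta through gamma.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha_low", 8.0, 10.0),
    BandDefinition("alpha_high", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in DEFAULT_BANDS}


@dataclass
class EpochedRecording:
    """Fixed-length epochs cut from one band-filtered recording."""

    epochs: list[np.ndarray]  # each (n_channels, epoch_length)
    sfreq: float
    channels: tuple[str, ...]
    band: BandDefinition | None = None  # None = broadband

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError(f"epochs have inconsistent shapes: {shapes}")

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


@dataclass
class PhaseEpoch:
    """Instantaneous phase (radians, wrapped to (-pi, pi]) for one epoch."""

    phases: np.ndarray  # (n_channels, n_samples)
    channels: tuple[str, ...] = field(default_factory=tuple)


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to the half-open interval (-pi, pi]."""
    w = np.mod(np.asarray(x, dtype=float), 2.0 * np.pi)
    return np.where(w > np.pi, w - 2.0 * np.pi, w)


def _band_sos(band: BandDefinition, sfreq: float, order: int = 4) -> np.ndarray:
    nyq = sfreq / 2.0
    if not 0 < band.low < band.high < nyq:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) outside the "
            f"valid range (0, {nyq}) Hz for sampling rate {sfreq} Hz"
        )
    return sps.butter(order, [band.low, band.high], btype="bandpass",
                      fs=sfreq, output="sos")


def bandpass(recording: MultichannelRecording, band: BandDefinition,
             order: int = 4) -> MultichannelRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward filtering (``sosfiltfilt``) doubles the effective
    order and cancels the group delay, so filtered epochs stay aligned
    with the raw ones.
    """
    sos = _band_sos(band, recording.sfreq, order=order)
    filtered = sps.sosfiltfilt(sos, recording.data, axis=-1)
    return MultichannelRecording(filtered, recording.sfreq, tuple(recording.channels))


def make_epochs(recording: MultichannelRecording,
                n_epochs: int = DEFAULT_N_EPOCHS,
                epoch_length: int = DEFAULT_EPOCH_LENGTH,
                band: BandDefinition | None = None) -> EpochedRecording:
    """Cut contiguous, non-overlapping epochs from the start of the recording."""
    needed = n_epochs * epoch_length
    if recording.n_samples < needed:
        raise ValueError(
            f"recording has {recording.n_samples} samples but "
            f"{n_epochs} x {epoch_length} = {needed} are required"
        )
    epochs = [
        recording.data[:, i * epoch_length:(i + 1) * epoch_length].copy()
        for i in range(n_epochs)
    ]
    return EpochedRecording(epochs, recording.sfreq, tuple(recording.channels), band)


def instantaneous_phase(epoch: np.ndarray,
                        channels: tuple[str, ...] = ()) -> PhaseEpoch:
    """Instantaneous phase of each channel via the analytic signal.

    The phase is the argument of the Hilbert analytic signal, wrapped to
    (-pi, pi].  An all-zero channel has no defined phase and raises.
    """
    epoch = np.asarray(epoch, dtype=float)
    if not np.all(np.isfinite(epoch)):
        raise ValueError("epoch contains non-finite samples")
    flat = np.where(~epoch.any(axis=-1))[0]
    if flat.size:
        names = [channels[i] if channels else str(i) for i in flat]
        raise ValueError(f"phase undefined for all-zero channel(s): {names}")
    analytic = sps.hilbert(epoch, axis=-1)
    return PhaseEpoch(wrap_phase(np.angle(analytic)), channels)


def band_power(epochs: EpochedRecording | list[np.ndarray]) -> np.ndarray:
    """Mean squared amplitude per channel of band-limited epochs.

    Input epochs are assumed already band-filtered; several epochs are
    averaged.  For a unit-amplitude sinusoid this is 0.5.
    """
    mats = epochs.epochs if isinstance(epochs, EpochedRecording) else list(epochs)
    if not mats:
        raise ValueError("no epochs given")
    return np.mean([np.mean(np.square(m), axis=-1) for m in mats], axis=0)
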