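"""Electrode montage and the multichannel recording container.

The default montage is a 26-electrode 10/20 cap (Fp1 ... O2) sampled at
500 Hz, the geometry the rest of the package assumes unless told otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Ordered 10/20 labels of the default 26-channel cap.  Note the cap is
#: asymmetric (FC6 without FC5); override via a custom Montage if needed.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC1", "FCz", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP1", "CP2",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

DEFAULT_SFREQ: float = 500.0


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus the nominal sampling rate."""

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    sfreq: float = DEFAULT_SFREQ

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("montage labels must be unique")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, label: str) -> int:
        """Index of ``label``, matched case-insensitively."""
        lowered = [c.lower() for c in self.channels]
        try:
            return lowered.index(label.lower())
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None


DEFAULT_MONTAGE = Montage()


@dataclass
class MultichannelRecording:
    """A channels x samples signal matrix with labels and sampling rate."""

    data: np.ndarray  # (n_channels, n_samples), float
    sfreq: float
    channels: tuple[str, ...] = field(default_factory=lambda: DEFAULT_CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channels)} channel labels were given"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def copy(self) -> "MultichannelRecording":
        return MultichannelRecording(self.data.copy(), self.sfreq, tuple(self.channels))
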