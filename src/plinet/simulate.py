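"""Coupled-oscillator cohorts with known band-specific phase-lag structure.

Every channel is a sum of narrow-band phase-diffusion oscillators (one
per frequency band) plus a small 1/f background.  A band oscillator's
phase advances by ``2*pi*f/fs`` per sample plus Gaussian increments of
standard deviation ``phase_sigma`` (rad/sqrt(sample)), which sets the
linewidth.  Coupling between a (leader, follower) channel pair in one
band pins the follower's phasor partway onto ``leader - phase_lag``:

    phi_follower = angle((1 - s) * exp(i*phi_free) + s * exp(i*(phi_leader - lag)))

so strength ``s = 1`` with zero diffusion yields a constant lag (PLI 1
downstream), ``s = 0`` leaves the phases independent, and the realized
PLI grows monotonically with ``s`` in between.  Zero-lag linear mixing
(volume conduction / common sources) is a separate instantaneous matrix
multiply, which the PLI should ignore by construction.

Group templates bundle a base configuration with a coupling list; the
two stock templates contrast an FXS-like pattern (strong fronto-posterior
theta coupling, weak upper-alpha and beta coupling) against a
control-like one (the reverse).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import DEFAULT_CHANNELS, MultichannelRecording
from .preprocess import DEFAULT_EPOCH_LENGTH, DEFAULT_N_EPOCHS


@dataclass(frozen=True)
class BandComponent:
    """One narrow-band oscillator per channel.

    Each channel's natural frequency is drawn uniformly from
    ``freq +/- freq_spread`` (frequency heterogeneity makes uncoupled
    channels sweep through each other's phase, so their PLI averages
    out), and the phase additionally diffuses with per-sample Gaussian
    increments of standard deviation ``phase_sigma`` (rad/sqrt(sample)),
    which sets the linewidth.
    """

    name: str
    freq: float  # Hz
    amplitude: float = 1.0
    phase_sigma: float = 0.05  # rad / sqrt(sample)
    freq_spread: float = 0.0  # Hz, half-width of per-channel detuning

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError("center frequency must be positive")
        if self.amplitude < 0 or self.phase_sigma < 0 or self.freq_spread < 0:
            raise ValueError("amplitude, phase_sigma, freq_spread must be >= 0")


#: One oscillator per analysis band, centered mid-band.  Linewidth
#: (phase_sigma) and channel detuning (freq_spread) scale with the
#: band's width, mirroring the broader spectral peaks of faster rhythms.
DEFAULT_COMPONENTS: tuple[BandComponent, ...] = (
    BandComponent("delta", 2.0, phase_sigma=0.08, freq_spread=0.8),
    BandComponent("theta", 6.0, phase_sigma=0.10, freq_spread=1.2),
    BandComponent("alpha_low", 9.0, phase_sigma=0.07, freq_spread=0.6),
    BandComponent("alpha_high", 11.5, phase_sigma=0.08, freq_spread=0.9),
    BandComponent("beta", 20.0, phase_sigma=0.22, freq_spread=4.0),
    BandComponent("gamma", 37.0, phase_sigma=0.25, freq_spread=3.5),
)


@dataclass(frozen=True)
class SimulationConfig:
    n_channels: int = 26
    sampling_rate: float = 500.0
    duration: float = 50.0  # seconds; >= 6 epochs of 4096 samples at 500 Hz
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    band_components: tuple[BandComponent, ...] = DEFAULT_COMPONENTS
    noise_amplitude: float = 0.1  # 1/f background scale

    def __post_init__(self) -> None:
        if self.n_channels != len(self.channel_labels):
            raise ValueError(
                f"n_channels = {self.n_channels} but "
                f"{len(self.channel_labels)} labels given"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.noise_amplitude < 0:
            raise ValueError("noise amplitude must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def check_epochable(self, n_epochs: int = DEFAULT_N_EPOCHS,
                        epoch_length: int = DEFAULT_EPOCH_LENGTH) -> None:
        if self.n_samples < n_epochs * epoch_length:
            raise ValueError(
                f"duration {self.duration} s gives {self.n_samples} samples, "
                f"fewer than {n_epochs} x {epoch_length} required"
            )


@dataclass(frozen=True)
class CouplingSpec:
    """Directed phase coupling of one channel pair within one band."""

    channel_pair: tuple[str, str]  # (leader, follower)
    band: str
    phase_lag: float  # radians in (-pi, pi], nonzero for detectable PLI
    strength: float  # fraction of pinning in [0, 1]

    def __post_init__(self) -> None:
        if self.channel_pair[0] == self.channel_pair[1]:
            raise ValueError("coupling requires two distinct channels")
        if not -np.pi < self.phase_lag <= np.pi:
            raise ValueError("phase lag must lie in (-pi, pi]")
        if not 0 <= self.strength <= 1:
            raise ValueError("strength must lie in [0, 1]")


@dataclass(frozen=True)
class MixingMatrix:
    """Instantaneous (zero-lag) channel mixing, e.g. volume conduction."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mixing matrix must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("mixing matrix must be finite")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class GroupTemplate:
    """A named group: base signal configuration plus its coupling list."""

    label: str
    base_config: SimulationConfig = SimulationConfig()
    couplings: tuple[CouplingSpec, ...] = ()

    def __post_init__(self) -> None:
        labels = set(self.base_config.channel_labels)
        for c in self.couplings:
            missing = set(c.channel_pair) - labels
            if missing:
                raise ValueError(f"coupling references unknown channels {missing}")


def _one_over_f_noise(rng: np.random.Generator, n_channels: int,
                      n_samples: int) -> np.ndarray:
    """Spectrally shaped white noise with ~1/f power, unit variance."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 => power ~ 1/f
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def generate_recording(config: SimulationConfig,
                       couplings: tuple[CouplingSpec, ...] | list[CouplingSpec] = (),
                       seed: int | np.random.Generator = 0,
                       ) -> MultichannelRecording:
    """Simulate one multichannel recording; same seed gives identical output."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(config.channel_labels)
    for c in couplings:
        for lab in c.channel_pair:
            if lab not in labels:
                raise ValueError(f"coupling references unknown channel {lab!r}")
    n = config.n_samples
    nc = config.n_channels
    dt = 1.0 / config.sampling_rate
    data = np.zeros((nc, n))
    by_band: dict[str, list[CouplingSpec]] = {}
    for c in couplings:
        by_band.setdefault(c.band, []).append(c)
    for comp in config.band_components:
        # free-running phase walks with per-channel detuning
        freqs = comp.freq + rng.uniform(-comp.freq_spread, comp.freq_spread,
                                        size=(nc, 1))
        incr = 2.0 * np.pi * freqs * dt + comp.phase_sigma * rng.standard_normal((nc, n))
        phi = rng.uniform(-np.pi, np.pi, size=(nc, 1)) + np.cumsum(incr, axis=-1)
        for c in by_band.get(comp.name, []):
            li = labels.index(c.channel_pair[0])
            fi = labels.index(c.channel_pair[1])
            target = phi[li] - c.phase_lag
            mix = ((1.0 - c.strength) * np.exp(1j * phi[fi])
                   + c.strength * np.exp(1j * target))
            phi[fi] = np.angle(mix)
        data += comp.amplitude * np.cos(phi)
    if config.noise_amplitude > 0:
        data += config.noise_amplitude * _one_over_f_noise(rng, nc, n)
    return MultichannelRecording(data, config.sampling_rate, tuple(labels))


def apply_mixing(recording: MultichannelRecording,
                 mixing: MixingMatrix) -> MultichannelRecording:
    """Mix channels instantaneously: out[:, t] = M @ in[:, t]."""
    m = mixing.matrix
    if m.shape[0] != recording.n_channels:
        raise ValueError(
            f"mixing matrix is {m.shape[0]}x{m.shape[1]} but the recording "
            f"has {recording.n_channels} channels"
        )
    return MultichannelRecording(m @ recording.data, recording.sfreq,
                                 tuple(recording.channels))


@dataclass
class Subject:
    subject_id: str
    group: str
    seed: int
    recording: MultichannelRecording


def subject_seed(master_seed: int, group_index: int, subject_index: int) -> int:
    """Deterministic per-subject seed, stable under cohort reordering."""
    ss = np.random.SeedSequence([int(master_seed), int(group_index),
                                 int(subject_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_cohort(template_a: GroupTemplate, template_b: GroupTemplate,
                    n_per_group: int, seed: int) -> list[Subject]:
    """Two labelled groups of independent subjects from a master seed."""
    if n_per_group < 0:
        raise ValueError("n_per_group must be non-negative")
    cohort: list[Subject] = []
    for gi, tpl in enumerate((template_a, template_b)):
        for si in range(n_per_group):
            s = subject_seed(seed, gi, si)
            rec = generate_recording(tpl.base_config, tpl.couplings, s)
            cohort.append(Subject(f"{tpl.label}_{si:03d}", tpl.label, s, rec))
    return cohort


# ---------------------------------------------------------------------------
# Stock group templates

#: Fronto-posterior (long-range) channel pairs carrying the theta coupling.
THETA_LONG_RANGE_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "O1"), ("Fp2", "O2"), ("F3", "P3"),
    ("Fz", "Pz"), ("F4", "P4"), ("F7", "Oz"),
)


def _disjoint_pairs(labels: tuple[str, ...]) -> tuple[tuple[str, str], ...]:
    return tuple((labels[i], labels[i + 1]) for i in range(0, len(labels) - 1, 2))


#: Whole-head disjoint pairs used for the diffuse alpha/beta coupling.
GLOBAL_PAIRS: tuple[tuple[str, str], ...] = _disjoint_pairs(DEFAULT_CHANNELS)

_LAG = np.pi / 4


def _couplings(theta_s: float, alpha_high_s: float, beta_s: float,
               ) -> tuple[CouplingSpec, ...]:
    out = [CouplingSpec(p, "theta", _LAG, theta_s) for p in THETA_LONG_RANGE_PAIRS]
    out += [CouplingSpec(p, "alpha_high", _LAG, alpha_high_s) for p in GLOBAL_PAIRS]
    out += [CouplingSpec(p, "beta", _LAG, beta_s) for p in GLOBAL_PAIRS]
    return tuple(out)


def fxs_like_template(config: SimulationConfig = SimulationConfig()) -> GroupTemplate:
    """Elevated fronto-posterior theta coupling, weak upper-alpha/beta coupling."""
    return GroupTemplate("fxs_like", config,
                         _couplings(theta_s=0.75, alpha_high_s=0.30, beta_s=0.30))


def control_like_template(config: SimulationConfig = SimulationConfig()) -> GroupTemplate:
    """Weak theta coupling, stronger diffuse upper-alpha/beta coupling."""
    return GroupTemplate("control_like", config,
                         _couplings(theta_s=0.35, alpha_high_s=0.65, beta_s=0.60))
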