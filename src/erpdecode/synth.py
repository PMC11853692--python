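"""Synthetic auditory-oddball ERP session generator.

Emulates a multi-block oddball recording: two trial classes (frequent
standards, rare duration deviants) whose difference wave carries an
MMN-like frontocentral negativity (~150-230 ms) and a P3a-like positivity
(~250-350 ms), on top of 1/f ("pink") plus white background noise.  A
block-level gain process scales the deviant-only components, which lets the
generator reproduce the waxing and waning of the mismatch response reported
in comatose patients: blocks with gain 0 contain no class difference at
all, blocks with gain 1 the full effect.

Every draw is governed by a single integer seed in :class:`SimulationConfig`,
so a configuration maps to exactly one dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .epochs import DEFAULT_MONTAGE, DEVIANT, STANDARD, EpochSet, concatenate

#: FWHM of a Gaussian in units of its standard deviation.
_FWHM = 2.355
#: Gaussian bumps are truncated at +-3 sd around the peak.
_SUPPORT_SD = 3.0

#: Frontocentral topography: maximal at Fz/Cz, falling off toward parietal
#: and temporal sites, matching the scalp distribution of MMN/P3a.
DEFAULT_TOPOGRAPHY = {
    "Fz": 1.0, "Cz": 1.0,
    "F3": 0.7, "F4": 0.7, "C3": 0.7, "C4": 0.7,
    "P3": 0.4, "Pz": 0.4, "P4": 0.4,
    "T7": 0.2, "T8": 0.2,
}


@dataclass(frozen=True)
class ComponentSpec:
    """One deviant-only ERP component (a smooth unimodal bump).

    Parameters
    ----------
    name:
        Label, e.g. ``"MMN"`` or ``"P3a"``.
    peak_latency:
        Seconds post-stimulus at which the bump peaks.
    width:
        Full width at half maximum of the bump, seconds.
    amplitude:
        Peak amplitude in microvolts, signed (MMN negative, P3a positive).
    topography:
        Per-channel weight in [0, 1].  Either a mapping from channel name
        to weight (unnamed channels get 0) or a sequence with one weight
        per montage channel.
    """

    name: str
    peak_latency: float
    width: float
    amplitude: float
    topography: dict | tuple = field(default_factory=lambda: dict(DEFAULT_TOPOGRAPHY))

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("component width must be > 0")

    @property
    def sigma(self) -> float:
        return self.width / _FWHM

    def support(self) -> tuple[float, float]:
        """Time interval outside which the bump is identically zero."""
        return (self.peak_latency - _SUPPORT_SD * self.sigma,
                self.peak_latency + _SUPPORT_SD * self.sigma)

    def topography_vector(self, montage: Sequence[str]) -> np.ndarray:
        if isinstance(self.topography, dict):
            unknown = set(self.topography) - set(montage)
            if unknown:
                raise ValueError(f"topography names not in montage: {sorted(unknown)}")
            w = np.array([float(self.topography.get(ch, 0.0)) for ch in montage])
        else:
            w = np.asarray(self.topography, dtype=float)
            if len(w) != len(montage):
                raise ValueError("topography length must equal montage length")
        if (w < 0).any() or (w > 1).any():
            raise ValueError("topography weights must lie in [0, 1]")
        if not (w > 0).any():
            raise ValueError("topography needs at least one positive weight")
        return w

    def waveform(self, times: np.ndarray) -> np.ndarray:
        """Evaluate the unit-amplitude bump on a time grid.

        The bump is a Gaussian truncated at +-3 sd and additionally
        restricted to the post-stimulus interval (t >= 0), so the
        pre-stimulus baseline never carries component signal.
        """
        t = np.asarray(times, dtype=float)
        w = np.exp(-((t - self.peak_latency) ** 2) / (2.0 * self.sigma**2))
        w[np.abs(t - self.peak_latency) > _SUPPORT_SD * self.sigma] = 0.0
        w[t < 0] = 0.0
        return w


def mmn_component(amplitude: float = -3.0, peak_latency: float = 0.190,
                  width: float = 0.080, topography: dict | tuple | None = None,
                  ) -> ComponentSpec:
    """Default mismatch-negativity component (frontocentral, -3 uV at 190 ms)."""
    return ComponentSpec("MMN", peak_latency, width, amplitude,
                         topography or dict(DEFAULT_TOPOGRAPHY))


def p3a_component(amplitude: float = 4.0, peak_latency: float = 0.300,
                  width: float = 0.100, topography: dict | tuple | None = None,
                  ) -> ComponentSpec:
    """Default P3a component (frontocentral, +4 uV at 300 ms)."""
    return ComponentSpec("P3a", peak_latency, width, amplitude,
                         topography or dict(DEFAULT_TOPOGRAPHY))


@dataclass(frozen=True)
class GainProfile:
    """Block-level multipliers applied to all deviant-only components.

    A gain of 0 in a block removes the class difference entirely in that
    block; a constant gain of 1 reproduces a stable responder.
    """

    per_block_gain: tuple
    description: str = "custom"

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.per_block_gain)
        object.__setattr__(self, "per_block_gain", g)
        if any(x < 0 for x in g):
            raise ValueError("block gains must be >= 0")

    def __len__(self) -> int:
        return len(self.per_block_gain)

    @classmethod
    def constant(cls, n_blocks: int, value: float = 1.0) -> "GainProfile":
        return cls((value,) * n_blocks, "constant")

    @classmethod
    def sinusoidal(cls, n_blocks: int, period: float, phase: float = 0.0,
                   low: float = 0.0, high: float = 1.0) -> "GainProfile":
        """Gain oscillating between ``low`` and ``high`` with the given period
        (in blocks) — a smooth wax/wane fixture."""
        b = np.arange(n_blocks)
        g = low + (high - low) * 0.5 * (1 + np.sin(2 * math.pi * b / period + phase))
        return cls(tuple(g.tolist()), "sinusoidal")


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic oddball session.

    Defaults mirror a realistic bedside recording: 512 Hz sampling, the
    11-channel reduced 10/20 montage, epochs from -100 to 600 ms, five
    blocks of 400 tones with 15% duration deviants, and MMN/P3a difference
    components of -3/+4 microvolts under ~10 uV single-trial noise.
    """

    n_blocks: int = 5
    trials_per_block: int = 400
    p_deviant: float = 0.15
    sfreq: float = 512.0
    epoch_window: tuple = (-0.100, 0.600)
    montage: tuple = DEFAULT_MONTAGE
    components: tuple = ()
    noise_white_sd: float = 10.0
    noise_pink_scale: float = 5.0
    trial_amplitude_jitter_sd: float = 0.2
    gain: GainProfile | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.components == ():
            object.__setattr__(self, "components", (mmn_component(), p3a_component()))
        object.__setattr__(self, "montage", tuple(self.montage))
        object.__setattr__(self, "epoch_window", tuple(self.epoch_window))
        if self.gain is None:
            object.__setattr__(self, "gain", GainProfile.constant(self.n_blocks))
        if not (0 < self.p_deviant < 1):
            raise ValueError("p_deviant must be in (0, 1)")
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ValueError("counts must be positive")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be > 0")
        start, end = self.epoch_window
        if not (start < 0 < end):
            raise ValueError("epoch window must straddle stimulus onset")
        if len(self.gain) != self.n_blocks:
            raise ValueError("gain profile length must equal n_blocks")
        for comp in self.components:
            lo, hi = comp.support()
            if lo < start or hi > end:
                raise ValueError(
                    f"component {comp.name!r} support ({lo:.3f}, {hi:.3f}) s "
                    f"exceeds epoch window {self.epoch_window}")

    def times(self) -> np.ndarray:
        """Sample grid: ``[start, end)`` half-open, spacing 1/sfreq."""
        start, end = self.epoch_window
        n = int(round((end - start) * self.sfreq))
        return start + np.arange(n) / self.sfreq

    def difference_wave(self) -> np.ndarray:
        """Noiseless unit-gain deviant-minus-standard wave, channels x samples."""
        t = self.times()
        wave = np.zeros((len(self.montage), len(t)))
        for comp in self.components:
            topo = comp.topography_vector(self.montage)
            wave += comp.amplitude * np.outer(topo, comp.waveform(t))
        return wave

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def generate_trial_sequence(n_trials: int, p_deviant: float,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw an oddball label sequence with no two consecutive deviants.

    A first-order Markov chain emits a deviant with probability
    ``p_deviant / (1 - p_deviant)`` after a standard and never after a
    deviant; its stationary deviant fraction is exactly ``p_deviant``.

    Raises
    ------
    ValueError
        If ``p_deviant >= 0.5`` (unreachable without consecutive deviants)
        or ``n_trials < 2``.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if not (0 < p_deviant < 1):
        raise ValueError("p_deviant must be in (0, 1)")
    if p_deviant >= 0.5:
        raise ValueError(
            "no-consecutive-deviants sequences cannot reach a deviant "
            f"fraction of {p_deviant}; need p_deviant < 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    q = p_deviant / (1.0 - p_deviant)
    u = rng.random(n_trials)
    labels = np.empty(n_trials, dtype=object)
    prev_dev = u[0] < p_deviant  # stationary start
    labels[0] = DEVIANT if prev_dev else STANDARD
    for i in range(1, n_trials):
        dev = (not prev_dev) and (u[i] < q)
        labels[i] = DEVIANT if dev else STANDARD
        prev_dev = dev
    return labels


def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                sfreq: float) -> np.ndarray:
    """1/f-power noise, unit variance per trace, independent across traces.

    White Gaussian noise is shaped in the frequency domain with an
    amplitude profile proportional to f^(-1/2) (power ~ 1/f), then
    renormalized to unit standard deviation.
    """
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5
    spec *= scale
    pink = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = pink.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _generate_block(config: SimulationConfig, block_index: int,
                    rng: np.random.Generator) -> EpochSet:
    times = config.times()
    n = config.trials_per_block
    n_ch = len(config.montage)
    labels = generate_trial_sequence(n, config.p_deviant, rng)
    data = np.zeros((n, n_ch, len(times)))
    if config.noise_pink_scale > 0:
        data += config.noise_pink_scale * _pink_noise(
            rng, (n, n_ch), len(times), config.sfreq)
    if config.noise_white_sd > 0:
        data += rng.normal(0.0, config.noise_white_sd, size=data.shape)
    block_gain = config.gain.per_block_gain[block_index]
    jitter = rng.normal(0.0, config.trial_amplitude_jitter_sd, size=n)
    trial_gain = block_gain * np.clip(1.0 + jitter, 0.0, None)
    signal = config.difference_wave()
    dev = np.flatnonzero(labels == DEVIANT)
    data[dev] += trial_gain[dev, None, None] * signal[None]
    return EpochSet(
        data=data,
        labels=labels,
        times=times,
        sfreq=config.sfreq,
        channels=config.montage,
        block_id=np.full(n, block_index + 1),
        meta={"block": block_index + 1,
              "block_gain": block_gain,
              "seed": config.seed},
    )


def generate_session(config: SimulationConfig) -> list[EpochSet]:
    """Generate one :class:`EpochSet` per recording block.

    Per-block RNG streams are spawned deterministically from the config
    seed, so concatenating the returned blocks is byte-identical to
    :func:`generate_epochs` on the same config.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_blocks)
    return [_generate_block(config, b, np.random.default_rng(streams[b]))
            for b in range(config.n_blocks)]


def generate_epochs(config: SimulationConfig) -> EpochSet:
    """Generate the full session as one concatenated superblock."""
    return concatenate(generate_session(config))
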