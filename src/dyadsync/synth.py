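"""Synthetic two-person EEG and behavior generator.

Produces dyadic recordings with a known ground truth: theta-band phase
coupling between chosen adult/infant channel pairs at a nonzero lag,
1/f background noise, and optional jump/ocular artifacts whose times and
spatial patterns are recorded for downstream assertions.

Signal model, per channel::

    x(t) = A * cos(phi(t)) + pink_noise(t)

Each uncoupled channel carries its own phase-diffusing theta oscillator
(Wiener phase noise on top of the carrier), so phase differences between
independent channels decorrelate across epochs. A coupled infant channel
instead inherits the partner adult channel's phase plus a fixed lag and a
slowly varying wrapped-Gaussian jitter whose spread shrinks linearly with
the coupling strength ``kappa``:

    phi_infant(t) = phi_adult(t) + phase_lag + eps(t),
    eps(t) ~ WrappedNormal(0, sigma(kappa)),  sigma(kappa) = pi * (1 - kappa)

so ``kappa = 0`` is indistinguishable from independence and ``kappa = 1``
is a deterministic constant-lag copy.

Randomness is split with counter-based ``SeedSequence`` keys derived from
``(seed, dyad, condition, channel, purpose)``, so e.g. adding artifacts
never perturbs the underlying signal draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np

from .datatypes import EventLog, Recording

__all__ = [
    "SimulationConfig",
    "simulate_dyad",
    "inject_artifacts",
    "simulate_behavior",
    "ocular_pattern",
    "stream",
    "DEFAULT_LAYOUT",
    "GAZE_CODES",
    "AFFECT_CODES",
]

#: 16-channel 10/20 montage: frontal row plus the six grid sites per side.
DEFAULT_LAYOUT = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "C3", "Cz", "C4", "T7", "T8",
    "P3", "P4", "P7", "P8",
)

GAZE_CODES = (
    "social_gaze",
    "gaze_to_object",
    "joint_attention",
    "gaze_aversion",
    "gaze_to_environment",
    "drowsy",
    "uncodable",
)
AFFECT_CODES = ("positive", "neutral", "negative", "uncodable")


def stream(seed: int, *keys: Any) -> np.random.Generator:
    """Independent RNG stream keyed by ``(seed, *keys)``.

    Keys are reduced with CRC32 over their repr, which is stable across
    runs and platforms, and fed into a ``SeedSequence`` so streams for
    distinct purposes never collide or interact.
    """
    words = [int(seed) & 0xFFFFFFFF]
    words += [zlib.crc32(repr(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(words))


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated study.

    ``coupling_table`` maps ``(condition, adult_channel, infant_channel)``
    to a coupling strength ``kappa`` in [0, 1]; absent entries are
    independent. ``phase_lag`` must not be a multiple of pi, otherwise
    lag-sensitive metrics are blind to the injected coupling by design.
    """

    n_dyads: int = 10
    sampling_rate: float = 250.0
    duration: float = 180.0
    channel_layout: tuple[str, ...] = DEFAULT_LAYOUT
    conditions: tuple[str, ...] = ("blank", "BO")
    coupling_table: dict[tuple[str, str, str], float] = field(default_factory=dict)
    phase_lag: float = math.pi / 4
    theta_freq: float = 5.5
    noise_exponent: float = 1.0
    snr_db: float = 0.0
    phase_diffusion: float = 3.0  # rad^2 / s of Wiener phase noise
    jitter_block: float = 1.0  # s; coupling jitter redrawn per block
    amplitude: float = 10.0  # microvolts, oscillation peak
    jump_rate: float = 0.0  # transient jumps per minute
    ocular_rate: float = 0.0  # ocular events per minute
    behavior_targets: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_bout: float = 2.0  # s, behavioral bout mean length
    engagement_sd: float = 0.0  # per-dyad latent scalar spread
    engagement_kappa_slope: float = 0.0
    engagement_attention_slope: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_layout = tuple(self.channel_layout)
        self.conditions = tuple(self.conditions)
        if self.n_dyads <= 0:
            raise ValueError("n_dyads must be positive")
        if self.duration < 2.0:
            raise ValueError("duration must be at least 2 s")
        if not (4.0 <= self.theta_freq <= 7.0):
            raise ValueError("theta_freq must lie within [4, 7] Hz")
        if abs(math.sin(self.phase_lag)) < 1e-9:
            raise ValueError("phase_lag must not be 0 mod pi")
        seen_infant: dict[tuple[str, str], str] = {}
        for (cond, a_ch, i_ch), kappa in self.coupling_table.items():
            if not (0.0 <= kappa <= 1.0):
                raise ValueError(f"kappa must lie in [0, 1], got {kappa}")
            if cond not in self.conditions:
                raise ValueError(f"coupling references unknown condition {cond!r}")
            for ch in (a_ch, i_ch):
                if ch not in self.channel_layout:
                    raise ValueError(f"coupled channel {ch!r} not in layout")
            key = (cond, i_ch)
            if key in seen_infant and seen_infant[key] != a_ch:
                raise ValueError(
                    f"infant channel {i_ch!r} coupled to two adult channels in {cond!r}"
                )
            seen_infant[key] = a_ch

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def engagement(self, dyad_index: int, condition: str) -> float:
        """Latent engagement scalar for one session (0 when disabled).

        Drawn per (dyad, condition): the same draw shifts both the
        coupling strength and the behavioral attention target, so
        neural and behavioral change scores become correlated.
        """
        if self.engagement_sd == 0.0:
            return 0.0
        rng = stream(self.seed, "engagement", dyad_index, condition)
        return float(rng.normal(0.0, self.engagement_sd))

    def effective_kappa(self, kappa: float, dyad_index: int, condition: str) -> float:
        e = self.engagement(dyad_index, condition)
        return float(np.clip(kappa + self.engagement_kappa_slope * e, 0.0, 1.0))


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shaping, n=n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _oscillator_phase(
    rng: np.random.Generator, n: int, fs: float, freq: float, diffusion: float
) -> np.ndarray:
    """Carrier phase with Wiener phase noise and a uniform initial phase."""
    t = np.arange(n) / fs
    phi = 2.0 * math.pi * freq * t + rng.uniform(0.0, 2.0 * math.pi)
    if diffusion > 0:
        phi = phi + np.cumsum(rng.normal(0.0, math.sqrt(diffusion / fs), n))
    return phi


def _coupling_jitter(
    rng: np.random.Generator, n: int, fs: float, block_s: float, sigma: float
) -> np.ndarray:
    """Piecewise-constant wrapped-Gaussian phase jitter, redrawn per block."""
    if sigma == 0.0:
        return np.zeros(n)
    block = max(1, int(round(block_s * fs)))
    n_blocks = -(-n // block)
    draws = rng.normal(0.0, sigma, n_blocks)
    return np.repeat(draws, block)[:n]


def simulate_dyad(
    config: SimulationConfig, dyad_index: int, condition: str
) -> tuple[Recording, Recording]:
    """Simulate one dyad's (infant, adult) recordings for one condition.

    Deterministic given ``(config.seed, dyad_index, condition)``. The
    returned recordings carry the ground-truth coupling table entry under
    ``annotations["coupling"]``.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if not (0 <= dyad_index < config.n_dyads):
        raise ValueError(f"dyad_index {dyad_index} out of range [0, {config.n_dyads})")

    fs = config.sampling_rate
    n = config.n_samples
    noise_rms = (config.amplitude / math.sqrt(2.0)) * 10 ** (-config.snr_db / 20.0)

    adult_phase: dict[str, np.ndarray] = {}
    for ch in config.channel_layout:
        rng = stream(config.seed, "phase", dyad_index, condition, "adult", ch)
        adult_phase[ch] = _oscillator_phase(rng, n, fs, config.theta_freq, config.phase_diffusion)

    coupled_infant: dict[str, tuple[str, float]] = {}
    for (cond, a_ch, i_ch), kappa in config.coupling_table.items():
        if cond == condition:
            k_eff = config.effective_kappa(kappa, dyad_index, condition)
            # kappa = 0 must be *indistinguishable* from independence, so
            # it takes the independent-oscillator path, not sigma = pi jitter
            if k_eff > 0:
                coupled_infant[i_ch] = (a_ch, k_eff)

    infant_phase: dict[str, np.ndarray] = {}
    for ch in config.channel_layout:
        if ch in coupled_infant:
            a_ch, kappa = coupled_infant[ch]
            sigma = math.pi * (1.0 - kappa)
            rng = stream(config.seed, "jitter", dyad_index, condition, ch)
            eps = _coupling_jitter(rng, n, fs, config.jitter_block, sigma)
            infant_phase[ch] = adult_phase[a_ch] + config.phase_lag + eps
        else:
            rng = stream(config.seed, "phase", dyad_index, condition, "infant", ch)
            infant_phase[ch] = _oscillator_phase(
                rng, n, fs, config.theta_freq, config.phase_diffusion
            )

    recordings = []
    for role, phases in (("infant", infant_phase), ("adult", adult_phase)):
        signal = np.empty((len(config.channel_layout), n))
        for ci, ch in enumerate(config.channel_layout):
            rng = stream(config.seed, "noise", dyad_index, condition, role, ch)
            noise = _pink_noise(rng, n, fs, config.noise_exponent) * noise_rms
            signal[ci] = config.amplitude * np.cos(phases[ch]) + noise
        recordings.append(
            Recording(
                dyad_id=f"dyad{dyad_index:03d}",
                role=role,
                condition=condition,
                sampling_rate=fs,
                channels=list(config.channel_layout),
                signal=signal,
                annotations={
                    "coupling": {
                        i_ch: {"adult_channel": a_ch, "kappa": k}
                        for i_ch, (a_ch, k) in coupled_infant.items()
                    },
                    "seed": config.seed,
                    "dyad_index": dyad_index,
                },
            )
        )
    return recordings[0], recordings[1]


def ocular_pattern(channels: Iterable[str]) -> np.ndarray:
    """Canonical frontal-dominated spatial pattern of ocular activity.

    Unit-norm weights: frontopolar sites strongest, frontal row at half
    weight, everything else near zero.
    """
    weights = []
    for ch in channels:
        if ch.startswith("Fp"):
            weights.append(1.0)
        elif ch.startswith("F"):
            weights.append(0.5)
        else:
            weights.append(0.05)
    w = np.asarray(weights, dtype=float)
    return w / np.linalg.norm(w)


def inject_artifacts(
    recording: Recording, config: SimulationConfig, seed: int
) -> Recording:
    """Add transient jumps and ocular events; ground truth goes to annotations.

    Jumps are 200-ms square offsets on one randomly chosen channel, with
    amplitude 5x the background's maximum peak-to-peak. Ocular events are
    sub-4-Hz half-cosine deflections projected through a fixed
    frontal-dominated spatial pattern. With both rates at zero the
    recording is returned unchanged.
    """
    if config.jump_rate < 0 or config.ocular_rate < 0:
        raise ValueError("artifact rates must be non-negative")
    minutes = recording.duration / 60.0
    n_jumps = int(round(config.jump_rate * minutes))
    n_ocular = int(round(config.ocular_rate * minutes))
    if n_jumps == 0 and n_ocular == 0:
        return recording

    rng = stream(seed, "artifacts", recording.dyad_id, recording.role, recording.condition)
    fs = recording.sampling_rate
    signal = recording.signal.copy()
    background_p2p = float(np.max(np.ptp(recording.signal, axis=1)))

    jumps = []
    jump_len = int(round(0.2 * fs))
    for _ in range(n_jumps):
        start = int(rng.integers(0, recording.n_samples - jump_len))
        ch = int(rng.integers(0, recording.n_channels))
        amp = 5.0 * background_p2p * (1.0 if rng.random() < 0.5 else -1.0)
        signal[ch, start : start + jump_len] += amp
        jumps.append(
            {
                "onset_s": start / fs,
                "duration_s": jump_len / fs,
                "channel": recording.channels[ch],
                "amplitude": amp,
            }
        )

    pattern = ocular_pattern(recording.channels)
    ocular_events = []
    for _ in range(n_ocular):
        dur = float(rng.uniform(0.3, 0.6))  # 1.7-3.3 Hz content: below 4 Hz
        length = int(round(dur * fs))
        start = int(rng.integers(0, max(1, recording.n_samples - length)))
        amp = float(rng.uniform(8.0, 12.0)) * config.amplitude
        pulse = amp * np.sin(np.pi * np.arange(length) / length) ** 2
        signal[:, start : start + length] += np.outer(pattern, pulse)
        ocular_events.append({"onset_s": start / fs, "duration_s": dur, "amplitude": amp})

    return recording.copy_with(
        signal,
        pre_artifact_signal=recording.signal.copy(),
        jumps=jumps,
        ocular_events=ocular_events,
        ocular_pattern=pattern,
    )


_DEFAULT_TARGETS = {"attention": 0.8, "positive": 0.2}


def _renewal_log(
    rng: np.random.Generator,
    duration: float,
    codes: tuple[str, ...],
    probs: np.ndarray,
    mean_bout: float,
    channel: str,
) -> EventLog:
    """Alternating-renewal interval process tiling [0, duration].

    Bout codes are i.i.d. categorical and bout lengths i.i.d. exponential
    with a common mean, so the expected time fraction of code c equals
    its probability (renewal-reward).
    """
    intervals: list[tuple[str, float, float]] = []
    t = 0.0
    while t < duration:
        code = codes[int(rng.choice(len(codes), p=probs))]
        bout = float(rng.exponential(mean_bout))
        bout = max(bout, 1e-3)
        end = min(t + bout, duration)
        intervals.append((code, t, end))
        t = end
    return EventLog(channel=channel, intervals=intervals, session_duration=duration)


def simulate_behavior(
    config: SimulationConfig,
    condition: str,
    seed: int,
    dyad_index: int | None = None,
) -> tuple[EventLog, EventLog]:
    """Simulate (gaze, affect) event logs for one session.

    Target proportions come from ``config.behavior_targets[condition]``
    (keys ``attention`` and ``positive``); when ``dyad_index`` is given
    and engagement is enabled, the attention target is shifted by the
    same latent scalar that shifts coupling, enabling correlated
    brain/behavior change scores.
    """
    if config.duration <= 0:
        raise ValueError("duration must be positive")
    targets = dict(_DEFAULT_TARGETS)
    targets.update(config.behavior_targets.get(condition, {}))
    attention = targets["attention"]
    positive = targets["positive"]
    if dyad_index is not None and config.engagement_sd > 0:
        e = config.engagement(dyad_index, condition)
        attention = float(np.clip(attention + config.engagement_attention_slope * e, 0.02, 0.98))

    rng = stream(seed, "behavior", condition, dyad_index)

    # gaze: attention mass split 85/15 between social gaze and joint
    # attention; the rest spread over non-attentive codes.
    rest = max(1.0 - attention, 0.0)
    gaze_probs = np.array(
        [
            0.85 * attention,  # social_gaze
            0.40 * rest,  # gaze_to_object
            0.15 * attention,  # joint_attention
            0.15 * rest,  # gaze_aversion
            0.35 * rest,  # gaze_to_environment
            0.05 * rest,  # drowsy
            0.05 * rest,  # uncodable
        ]
    )
    gaze_probs /= gaze_probs.sum()
    gaze = _renewal_log(rng, config.duration, GAZE_CODES, gaze_probs, config.mean_bout, "gaze")

    rest_affect = max(1.0 - positive, 0.0)
    affect_probs = np.array(
        [
            positive,
            0.88 * rest_affect,  # neutral
            0.07 * rest_affect,  # negative
            0.05 * rest_affect,  # uncodable
        ]
    )
    affect_probs /= affect_probs.sum()
    affect = _renewal_log(
        rng, config.duration, AFFECT_CODES, affect_probs, config.mean_bout, "affect"
    )
    return gaze, affect
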