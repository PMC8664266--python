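"""Core data containers shared across the pipeline.

All containers are plain dataclasses with eager validation: invalid
structures fail at construction time, not deep inside an analysis stage.
Signals are stored as float arrays in microvolts, shaped
``(n_channels, n_samples)``; epoch tensors are
``(n_epochs, n_channels, n_samples_per_epoch)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "Recording",
    "EpochSet",
    "MatchedDyadEpochs",
    "BandSpec",
    "PairGrid",
    "ConnectivityMap",
    "GroupConnectivity",
    "EventLog",
    "BehaviorScores",
    "MassUnivariateResult",
    "DEFAULT_GRID_CHANNELS",
]

#: Inter-subject grid used by default: central, temporal and
#: occipito-temporal sites of the 10/20 system, six per subject.
DEFAULT_GRID_CHANNELS = ("C3", "C4", "T7", "T8", "P7", "P8")


@dataclass
class Recording:
    """One subject's continuous multichannel signal.

    Parameters
    ----------
    dyad_id : str
        Identifier shared by the two members of a dyad.
    role : {"infant", "adult"}
    condition : str
        Experimental condition label.
    sampling_rate : float
        Sampling rate in Hz.
    channels : list of str
        Ordered 10/20 channel labels; must be unique.
    signal : ndarray, shape (n_channels, n_samples)
        Signal in microvolts. Must be finite and at least 1 s long.
    reference_label : str
        Label of the (physical) reference electrode.
    annotations : dict
        Free-form metadata (e.g. ground-truth artifact events from the
        simulator, processing reports).
    """

    dyad_id: str
    role: str
    condition: str
    sampling_rate: float
    channels: list[str]
    signal: np.ndarray
    reference_label: str = "FCz"
    annotations: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("infant", "adult"):
            raise ValueError(f"role must be 'infant' or 'adult', got {self.role!r}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.channels = list(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValueError(
                f"signal must be (n_channels={len(self.channels)}, n_samples), "
                f"got shape {self.signal.shape}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.signal.shape[1] < self.sampling_rate:
            raise ValueError("recording must be at least 1 s long")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return int(self.signal.shape[1])

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy_with(self, signal: np.ndarray, **extra_annotations: Any) -> "Recording":
        """Return a copy of this recording carrying a new signal array."""
        ann = dict(self.annotations)
        ann.update(extra_annotations)
        return Recording(
            dyad_id=self.dyad_id,
            role=self.role,
            condition=self.condition,
            sampling_rate=self.sampling_rate,
            channels=list(self.channels),
            signal=signal,
            reference_label=self.reference_label,
            annotations=ann,
        )


@dataclass
class EpochSet:
    """Overlapping fixed-length windows cut from one recording."""

    source: dict[str, Any]
    sampling_rate: float
    channels: list[str]
    epoch_length: float
    epoch_step: float
    onsets: np.ndarray
    data: np.ndarray
    good_mask: np.ndarray
    report: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.good_mask = np.asarray(self.good_mask, dtype=bool)
        n = len(self.onsets)
        if self.data.shape[0] != n or self.good_mask.shape[0] != n:
            raise ValueError("onsets, data and good_mask must agree on n_epochs")
        if n > 1:
            steps = np.diff(self.onsets)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
                raise ValueError("onsets must be strictly increasing with constant step")

    @property
    def n_epochs(self) -> int:
        return len(self.onsets)

    @property
    def n_good(self) -> int:
        return int(self.good_mask.sum())


@dataclass
class MatchedDyadEpochs:
    """Dyad epochs restricted to indices good for *both* members."""

    dyad_id: str
    condition: str
    sampling_rate: float
    infant_channels: list[str]
    adult_channels: list[str]
    infant_data: np.ndarray
    adult_data: np.ndarray
    onsets: np.ndarray
    epoch_length: float
    epoch_step: float
    excluded: bool = False
    report: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.infant_data.shape[0] != self.adult_data.shape[0]:
            raise ValueError("members must share the retained epoch indices")
        if self.infant_data.shape[0] != len(self.onsets):
            raise ValueError("onsets must match retained epochs")

    @property
    def n_matched(self) -> int:
        return int(self.infant_data.shape[0])

    @property
    def matched_seconds(self) -> float:
        """Total length of the union of retained epoch windows."""
        if self.n_matched == 0:
            return 0.0
        # windows are [onset, onset + length); merge overlapping ones
        total = 0.0
        cur_lo = float(self.onsets[0])
        cur_hi = cur_lo + self.epoch_length
        for onset in self.onsets[1:]:
            lo = float(onset)
            hi = lo + self.epoch_length
            if lo <= cur_hi:
                cur_hi = max(cur_hi, hi)
            else:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
        total += cur_hi - cur_lo
        return total


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band."""

    name: str = "theta"
    fmin: float = 4.0
    fmax: float = 7.0

    def __post_init__(self) -> None:
        if not (0 < self.fmin <= self.fmax):
            raise ValueError(f"require 0 < fmin <= fmax, got ({self.fmin}, {self.fmax})")


@dataclass(frozen=True)
class PairGrid:
    """Ordered adult x infant channel selection for inter-brain metrics."""

    adult_channels: tuple[str, ...] = DEFAULT_GRID_CHANNELS
    infant_channels: tuple[str, ...] = DEFAULT_GRID_CHANNELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "adult_channels", tuple(self.adult_channels))
        object.__setattr__(self, "infant_channels", tuple(self.infant_channels))
        if not self.adult_channels or not self.infant_channels:
            raise ValueError("channel selections must be non-empty")

    @property
    def n_pairs(self) -> int:
        return len(self.adult_channels) * len(self.infant_channels)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        """All (adult, infant) combinations in row-major order."""
        return [(a, i) for a in self.adult_channels for i in self.infant_channels]

    def pair_index(self, adult: str, infant: str) -> int:
        return self.adult_channels.index(adult) * len(self.infant_channels) + self.infant_channels.index(infant)


@dataclass
class ConnectivityMap:
    """Adult-channel x infant-channel matrix of band-averaged coupling."""

    dyad_id: str
    condition: str
    metric: str
    band: BandSpec
    adult_channels: tuple[str, ...]
    infant_channels: tuple[str, ...]
    values: np.ndarray
    n_epochs_used: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.adult_channels), len(self.infant_channels))
        if self.values.shape != expected:
            raise ValueError(f"values must have shape {expected}, got {self.values.shape}")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("connectivity values must lie in [0, 1]")

    @property
    def n_pairs(self) -> int:
        return self.values.size

    def value(self, adult: str, infant: str) -> float:
        return float(
            self.values[self.adult_channels.index(adult), self.infant_channels.index(infant)]
        )

    def flat(self) -> np.ndarray:
        """Row-major flattened values, matching ``PairGrid.pairs`` order."""
        return self.values.reshape(-1)


@dataclass
class GroupConnectivity:
    """Dense dyads x conditions x pairs connectivity array."""

    dyads: list[str]
    conditions: list[str]
    pairs: list[tuple[str, str]]
    values: np.ndarray
    metric: str = "wpli"
    band: BandSpec = field(default_factory=BandSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.dyads), len(self.conditions), len(self.pairs))
        if self.values.shape != expected:
            raise ValueError(f"values must have shape {expected}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("group connectivity must be dense: non-finite cell found")

    @property
    def n_dyads(self) -> int:
        return len(self.dyads)

    def condition_index(self, label: str) -> int:
        try:
            return self.conditions.index(label)
        except ValueError:
            raise KeyError(f"condition {label!r} not present") from None


@dataclass
class EventLog:
    """Non-overlapping coded intervals on one behavioral channel."""

    channel: str
    intervals: list[tuple[str, float, float]]
    session_duration: float

    def __post_init__(self) -> None:
        for code, onset, offset in self.intervals:
            if onset < 0 or offset <= onset:
                raise ValueError(f"invalid interval ({code}, {onset}, {offset})")
        ordered = sorted(self.intervals, key=lambda iv: iv[1])
        for (_, _, off_a), (_, on_b, _) in zip(ordered, ordered[1:]):
            if on_b < off_a - 1e-9:
                raise ValueError("intervals within one channel must not overlap")
        self.intervals = ordered

    def duration_of(self, *codes: str) -> float:
        return sum(off - on for c, on, off in self.intervals if c in codes)

    def spans(self, *codes: str) -> list[tuple[float, float]]:
        return [(on, off) for c, on, off in self.intervals if c in codes]


@dataclass
class BehaviorScores:
    """The three infant measures derived from coding."""

    visual_attention: float
    positive_arousal: float
    cib_safety: float | None = None

    def __post_init__(self) -> None:
        for name in ("visual_attention", "positive_arousal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.cib_safety is not None and not (1.0 <= self.cib_safety <= 5.0):
            raise ValueError("cib_safety must lie in the Likert range [1, 5]")


@dataclass
class MassUnivariateResult:
    """Per-pair F map with max-statistic permutation inference."""

    pairs: list[tuple[str, str]]
    F: np.ndarray
    eta_sq_p: np.ndarray
    p_perm: np.ndarray
    p_naive: np.ndarray
    null_max_F: np.ndarray
    alpha: float
    n_perm: int
    seed: int | None
    exhaustive: bool
    df: tuple[int, int]

    @property
    def significant_pairs(self) -> set[tuple[str, str]]:
        return {p for p, pv in zip(self.pairs, self.p_perm) if pv <= self.alpha}

    def to_dict(self) -> dict[str, Any]:
        """JSON-ready report (null distribution exported separately)."""
        return {
            "alpha": self.alpha,
            "n_perm": int(self.n_perm),
            "seed": self.seed,
            "exhaustive": bool(self.exhaustive),
            "df": list(self.df),
            "pairs": [
                {
                    "adult": a,
                    "infant": i,
                    "F": float(f),
                    "eta_sq_p": float(e),
                    "p_perm": float(pp),
                    "p_naive": float(pn),
                    "significant": bool(pp <= self.alpha),
                }
                for (a, i), f, e, pp, pn in zip(
                    self.pairs, self.F, self.eta_sq_p, self.p_perm, self.p_naive
                )
            ],
        }
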