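"""Band-limited cross-spectra and inter-brain connectivity metrics.

Connectivity between the two members of a dyad is estimated from
epoch-wise cross-spectra S_e(f) = X_adult(f) * conj(X_infant(f)) of
Hann-windowed, demeaned 1-s epochs, evaluated at the integer-Hz bins
inside the requested band (theta -> 4, 5, 6, 7 Hz).

Two metrics are provided:

* ``wpli`` — weighted phase lag index, |sum_e Im S_e| / sum_e |Im S_e|.
  Phase differences near zero (or pi) carry almost no weight, so
  zero-lag coupling from shared sensory input contributes minimally.
* ``plv`` — phase locking value, |mean_e exp(i arg S_e)|. Sensitive to
  coupling at any lag, including zero; serves as the comparison metric.

Both range over [0, 1]; band-level values are the unweighted mean of
the per-bin metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .datatypes import BandSpec, ConnectivityMap, GroupConnectivity, MatchedDyadEpochs, PairGrid

__all__ = [
    "CrossSpectra",
    "epoch_cross_spectra",
    "cross_spectra_from_arrays",
    "wpli",
    "plv",
    "group_connectivity",
    "MIN_EPOCHS",
]

#: Minimum matched-epoch count for a connectivity estimate.
MIN_EPOCHS = 20


@dataclass
class CrossSpectra:
    """Epoch-wise cross-spectra for a set of channel pairs at band bins."""

    values: np.ndarray  # complex, (n_epochs, n_pairs, n_bins)
    freqs: np.ndarray  # Hz, length n_bins
    band: BandSpec
    grid: PairGrid
    dyad_id: str = "?"
    condition: str = "?"

    @property
    def n_epochs(self) -> int:
        return int(self.values.shape[0])


def _band_bins(n_samples: int, fs: float, band: BandSpec) -> tuple[np.ndarray, np.ndarray]:
    """Indices and frequencies of the integer-Hz rfft bins inside the band."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    lo = int(np.ceil(band.fmin))
    hi = int(np.floor(band.fmax))
    targets = np.arange(lo, hi + 1, dtype=float)
    targets = targets[targets < fs / 2.0]
    idx = []
    kept = []
    for f in targets:
        j = int(np.argmin(np.abs(freqs - f)))
        if abs(freqs[j] - f) < 1e-6:
            idx.append(j)
            kept.append(f)
    if not idx:
        raise ValueError(
            f"band {band.name} ({band.fmin}-{band.fmax} Hz) contains no integer-Hz bin "
            f"for epochs of {n_samples} samples at {fs} Hz"
        )
    return np.asarray(idx), np.asarray(kept)


def cross_spectra_from_arrays(
    x_epochs: np.ndarray,
    y_epochs: np.ndarray,
    sampling_rate: float,
    band: BandSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-spectra of two single-channel epoch arrays.

    ``x_epochs`` and ``y_epochs`` have shape (n_epochs, n_samples).
    Returns ``(S, freqs)`` with S complex of shape (n_epochs, n_bins),
    S_e(f) = X_e(f) * conj(Y_e(f)) from Hann-windowed, demeaned epochs.
    """
    if x_epochs.shape != y_epochs.shape:
        raise ValueError("epoch arrays must have identical shapes")
    n = x_epochs.shape[1]
    idx, freqs = _band_bins(n, sampling_rate, band)
    win = hann(n, sym=False)
    xw = (x_epochs - x_epochs.mean(axis=1, keepdims=True)) * win
    yw = (y_epochs - y_epochs.mean(axis=1, keepdims=True)) * win
    X = np.fft.rfft(xw, axis=1)[:, idx]
    Y = np.fft.rfft(yw, axis=1)[:, idx]
    return X * np.conj(Y), freqs


def epoch_cross_spectra(
    matched: MatchedDyadEpochs,
    grid: PairGrid | None = None,
    band: BandSpec | None = None,
    min_epochs: int = MIN_EPOCHS,
) -> CrossSpectra:
    """Per-epoch adult x infant cross-spectra over a pair grid."""
    grid = grid or PairGrid()
    band = band or BandSpec()
    if matched.n_matched < min_epochs:
        raise ValueError(
            f"only {matched.n_matched} matched epochs; need at least {min_epochs}"
        )
    n = matched.infant_data.shape[2]
    idx, freqs = _band_bins(n, matched.sampling_rate, band)
    win = hann(n, sym=False)

    def spectra(data: np.ndarray, channels: list[str], wanted: tuple[str, ...]) -> np.ndarray:
        sel = [channels.index(ch) for ch in wanted]
        sub = data[:, sel, :]
        sub = (sub - sub.mean(axis=2, keepdims=True)) * win
        return np.fft.rfft(sub, axis=2)[:, :, idx]

    try:
        A = spectra(matched.adult_data, matched.adult_channels, grid.adult_channels)
        I = spectra(matched.infant_data, matched.infant_channels, grid.infant_channels)
    except ValueError as exc:
        raise KeyError(f"grid channel missing from recording: {exc}") from exc

    # (epochs, adult, infant, bins) -> (epochs, pairs, bins), row-major pairs
    S = A[:, :, None, :] * np.conj(I[:, None, :, :])
    S = S.reshape(S.shape[0], grid.n_pairs, len(idx))
    return CrossSpectra(
        values=S,
        freqs=freqs,
        band=band,
        grid=grid,
        dyad_id=matched.dyad_id,
        condition=matched.condition,
    )


def _to_map(cross: CrossSpectra, per_pair: np.ndarray, metric: str) -> ConnectivityMap:
    n_a = len(cross.grid.adult_channels)
    n_i = len(cross.grid.infant_channels)
    return ConnectivityMap(
        dyad_id=cross.dyad_id,
        condition=cross.condition,
        metric=metric,
        band=cross.band,
        adult_channels=cross.grid.adult_channels,
        infant_channels=cross.grid.infant_channels,
        values=per_pair.reshape(n_a, n_i),
        n_epochs_used=cross.n_epochs,
    )


def wpli(cross: CrossSpectra, min_epochs: int = MIN_EPOCHS) -> ConnectivityMap:
    """Weighted phase lag index, averaged over band bins.

    Per pair and bin: |sum_e Im S_e| / sum_e |Im S_e|, with 0/0 := 0
    (degenerate zero-lag pairs).
    """
    if cross.n_epochs < min_epochs:
        raise ValueError(f"need at least {min_epochs} epochs, got {cross.n_epochs}")
    im = np.imag(cross.values)
    # imaginary parts at rounding level (e.g. identical signals under FMA)
    # are genuine zero lag: flush them so the 0/0 convention applies
    im = np.where(np.abs(im) <= 1e-12 * np.abs(cross.values), 0.0, im)
    num = np.abs(im.sum(axis=0))
    den = np.abs(im).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_bin = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return _to_map(cross, per_bin.mean(axis=1), "wpli")


def plv(cross: CrossSpectra, min_epochs: int = MIN_EPOCHS) -> ConnectivityMap:
    """Phase locking value, averaged over band bins.

    Per pair and bin: |mean_e exp(i arg S_e)|. Epochs with zero
    cross-spectral power contribute a unit phasor at angle 0.
    """
    if cross.n_epochs < min_epochs:
        raise ValueError(f"need at least {min_epochs} epochs, got {cross.n_epochs}")
    mags = np.abs(cross.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        phasors = np.where(mags > 0, cross.values / np.where(mags > 0, mags, 1.0), 1.0)
    per_bin = np.abs(phasors.mean(axis=0))
    return _to_map(cross, per_bin.mean(axis=1), "plv")


def group_connectivity(maps: list[ConnectivityMap]) -> GroupConnectivity:
    """Stack per-dyad, per-condition maps into a dense group array.

    Every dyad must be present in every condition; a missing cell is an
    error rather than a NaN, because downstream permutation inference
    assumes complete within-dyad pairing.
    """
    if not maps:
        raise ValueError("no connectivity maps supplied")
    ref = maps[0]
    pairs = [(a, i) for a in ref.adult_channels for i in ref.infant_channels]
    for m in maps:
        if (m.adult_channels, m.infant_channels, m.metric) != (
            ref.adult_channels,
            ref.infant_channels,
            ref.metric,
        ):
            raise ValueError("maps differ in grid or metric (ragged input)")

    dyads = sorted({m.dyad_id for m in maps})
    conditions = sorted({m.condition for m in maps})
    values = np.full((len(dyads), len(conditions), len(pairs)), np.nan)
    for m in maps:
        d = dyads.index(m.dyad_id)
        c = conditions.index(m.condition)
        if not np.isnan(values[d, c]).all():
            raise ValueError(f"duplicate map for dyad {m.dyad_id!r}, condition {m.condition!r}")
        values[d, c] = m.flat()
    missing = np.argwhere(np.isnan(values[:, :, 0]))
    if missing.size:
        d, c = missing[0]
        raise ValueError(f"dyad {dyads[d]!r} missing condition {conditions[c]!r}")
    return GroupConnectivity(
        dyads=dyads, conditions=conditions, pairs=pairs, values=values,
        metric=ref.metric, band=ref.band,
    )
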