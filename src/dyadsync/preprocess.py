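"""Continuous-signal conditioning, epoching, rejection and dyad matching.

The chain mirrors a standard two-person pipeline: zero-phase FIR
band-pass -> 1-s epochs with 500-ms overlap -> subject-wise peak-to-peak
rejection with an automatically selected threshold -> template-correlation
removal of stereotyped (ocular) components -> duration and epoch matching
across the two members of each dyad.
"""

from __future__ import annotations

import warnings
from typing import Any

import numpy as np
from scipy import signal as sps

from .datatypes import EpochSet, MatchedDyadEpochs, Recording

__all__ = [
    "bandpass",
    "epoch",
    "reject_epochs",
    "remove_template_components",
    "match_durations",
    "match_epochs",
    "enforce_minimum",
]


def _fir_taps(low: float, high: float, fs: float) -> np.ndarray:
    # transition width tied to the low edge (the tight side for a 1 Hz
    # high-pass); Hamming window: ~53 dB stopband, doubled by filtfilt
    trans = min(max(low * 0.5, 0.5), 2.0)
    numtaps = int(round(3.3 * fs / trans))
    numtaps |= 1  # odd length -> linear phase type I
    return sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")


def bandpass(recording: Recording, low: float = 1.0, high: float = 50.0) -> Recording:
    """Zero-phase FIR band-pass, applied forward-backward per channel.

    Raises if the band is not inside (0, Nyquist) or the recording is
    shorter than three filter lengths (edge effects would dominate).
    """
    nyq = recording.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high < {nyq}")
    taps = _fir_taps(low, high, recording.sampling_rate)
    if recording.n_samples < 3 * len(taps):
        raise ValueError(
            f"recording too short for filtering: {recording.n_samples} samples "
            f"< 3 x {len(taps)} taps"
        )
    filtered = sps.filtfilt(taps, [1.0], recording.signal, axis=1)
    return recording.copy_with(filtered, filter_band=(low, high))


def epoch(recording: Recording, length: float = 1.0, step: float = 0.5) -> EpochSet:
    """Cut overlapping windows of ``length`` seconds every ``step`` seconds.

    Epoch k covers the half-open window [k*step, k*step + length),
    anchored at t=0; n_epochs = floor((duration - length)/step) + 1.
    """
    if length <= 0 or step <= 0:
        raise ValueError("length and step must be positive")
    fs = recording.sampling_rate
    len_samp = int(round(length * fs))
    step_samp = int(round(step * fs))
    if len_samp > recording.n_samples:
        raise ValueError(
            f"recording of {recording.duration:.3f} s shorter than epoch length {length} s"
        )
    n_epochs = (recording.n_samples - len_samp) // step_samp + 1
    onsets = np.arange(n_epochs) * (step_samp / fs)
    starts = np.arange(n_epochs) * step_samp
    data = np.stack([recording.signal[:, s : s + len_samp] for s in starts])
    return EpochSet(
        source={
            "dyad_id": recording.dyad_id,
            "role": recording.role,
            "condition": recording.condition,
        },
        sampling_rate=fs,
        channels=list(recording.channels),
        epoch_length=len_samp / fs,
        epoch_step=step_samp / fs,
        onsets=onsets,
        data=data,
        good_mask=np.ones(n_epochs, dtype=bool),
    )


def reject_epochs(
    epochs: EpochSet,
    tau_grid: np.ndarray | None = None,
) -> EpochSet:
    """Flag epochs whose worst-channel peak-to-peak exceeds a threshold.

    The threshold tau is selected subject-wise from a log-spaced grid
    (default 40-400 uV, 20 points) by minimizing the RMS difference
    between the mean of retained epochs and the channel-wise median
    epoch — a robust template that artifact epochs pull the mean away
    from. Ties resolve toward the most permissive tau. The chosen tau
    and rejection fraction are recorded in ``report``.
    """
    if epochs.n_epochs < 10:
        raise ValueError("need at least 10 epochs to select a rejection threshold")
    if tau_grid is None:
        tau_grid = np.logspace(np.log10(40.0), np.log10(400.0), 20)
    p2p = np.ptp(epochs.data, axis=2).max(axis=1)  # worst channel per epoch
    median_epoch = np.median(epochs.data, axis=0)

    best_tau, best_obj = None, np.inf
    for tau in sorted(tau_grid, reverse=True):  # permissive first wins ties
        keep = epochs.good_mask & (p2p <= tau)
        if not keep.any():
            continue
        obj = float(np.sqrt(np.mean((epochs.data[keep].mean(axis=0) - median_epoch) ** 2)))
        if obj < best_obj - 1e-12:
            best_obj, best_tau = obj, tau
    if best_tau is None:
        raise ValueError("every epoch exceeds every candidate threshold")

    good = epochs.good_mask & (p2p <= best_tau)
    report = dict(epochs.report)
    report["rejection"] = {
        "tau_uV": float(best_tau),
        "fraction_rejected": float(1.0 - good.sum() / epochs.n_epochs),
    }
    return EpochSet(
        source=epochs.source,
        sampling_rate=epochs.sampling_rate,
        channels=list(epochs.channels),
        epoch_length=epochs.epoch_length,
        epoch_step=epochs.epoch_step,
        onsets=epochs.onsets,
        data=epochs.data,
        good_mask=good,
        report=report,
    )


def remove_template_components(
    recording: Recording,
    template: np.ndarray,
    r_threshold: float = 0.8,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[Recording, dict[str, Any]]:
    """Remove independent components matching a spatial template.

    The signal is unmixed into as many independent components as
    channels (FastICA); any component whose mixing pattern has
    ``|Pearson r| >= r_threshold`` with the template is zeroed before
    reconstruction. If the decomposition fails outright the input is
    returned unmodified with ``report["failed"] = True``.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    template = np.asarray(template, dtype=float)
    if template.shape != (recording.n_channels,):
        raise ValueError("template length must equal the channel count")

    X = recording.signal.T  # samples x channels
    report: dict[str, Any] = {"removed": [], "converged": True, "failed": False}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                ica = FastICA(
                    n_components=recording.n_channels,
                    random_state=seed,
                    max_iter=max_iter,
                    whiten="unit-variance",
                )
                sources = ica.fit_transform(X)
            except ConvergenceWarning:
                # retry leniently: a max_iter warning still yields a usable
                # unmixing, only flag it
                report["converged"] = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    ica = FastICA(
                        n_components=recording.n_channels,
                        random_state=seed,
                        max_iter=max_iter,
                        whiten="unit-variance",
                    )
                    sources = ica.fit_transform(X)
    except Exception as exc:  # hard failure: signal and bail out unmodified
        report["failed"] = True
        report["error"] = str(exc)
        warnings.warn(f"ICA decomposition failed ({exc}); recording left unmodified")
        return recording, report

    patterns = ica.mixing_  # channels x components
    t_c = template - template.mean()
    t_norm = np.linalg.norm(t_c)
    for comp in range(patterns.shape[1]):
        p = patterns[:, comp] - patterns[:, comp].mean()
        denom = np.linalg.norm(p) * t_norm
        r = float(p @ t_c / denom) if denom > 0 else 0.0
        if abs(r) >= r_threshold:
            report["removed"].append({"component": comp, "r": r})

    if not report["removed"]:
        return recording.copy_with(recording.signal.copy(), ica_report=report), report

    kept = sources.copy()
    for item in report["removed"]:
        kept[:, item["component"]] = 0.0
    cleaned = (kept @ ica.mixing_.T + ica.mean_).T
    return recording.copy_with(cleaned, ica_report=report), report


def match_durations(rec_a: Recording, rec_b: Recording) -> tuple[Recording, Recording]:
    """Truncate both recordings (from the start) to the shorter duration."""
    if rec_a.sampling_rate != rec_b.sampling_rate:
        raise ValueError("recordings must share a sampling rate")
    n = min(rec_a.n_samples, rec_b.n_samples)
    out = []
    for rec in (rec_a, rec_b):
        if rec.n_samples == n:
            out.append(rec)
        else:
            out.append(rec.copy_with(rec.signal[:, :n].copy(), truncated_to_s=n / rec.sampling_rate))
    return out[0], out[1]


def match_epochs(infant: EpochSet, adult: EpochSet) -> MatchedDyadEpochs:
    """Keep only epoch indices good for both dyad members."""
    if infant.n_epochs != adult.n_epochs or not np.allclose(infant.onsets, adult.onsets):
        raise ValueError("members must share the same epoch grid")
    if infant.epoch_length != adult.epoch_length or infant.epoch_step != adult.epoch_step:
        raise ValueError("members must share epoch length and step")
    keep = infant.good_mask & adult.good_mask
    return MatchedDyadEpochs(
        dyad_id=str(infant.source.get("dyad_id", "?")),
        condition=str(infant.source.get("condition", "?")),
        sampling_rate=infant.sampling_rate,
        infant_channels=list(infant.channels),
        adult_channels=list(adult.channels),
        infant_data=infant.data[keep],
        adult_data=adult.data[keep],
        onsets=infant.onsets[keep],
        epoch_length=infant.epoch_length,
        epoch_step=infant.epoch_step,
        report={
            "n_epochs_total": infant.n_epochs,
            "n_good_infant": infant.n_good,
            "n_good_adult": adult.n_good,
            "n_matched": int(keep.sum()),
        },
    )


def enforce_minimum(
    matched: MatchedDyadEpochs,
    min_seconds: float = 60.0,
    cap_seconds: float | None = 90.0,
) -> MatchedDyadEpochs:
    """Apply the minimum-duration exclusion and the analysis-window cap.

    Dyads whose matched span (union of retained windows) falls below
    ``min_seconds`` are flagged ``excluded``; with a cap, only epochs
    with onset strictly below ``cap_seconds`` are retained.
    """
    keep = np.ones(matched.n_matched, dtype=bool)
    if cap_seconds is not None:
        keep &= matched.onsets < cap_seconds
    trimmed = MatchedDyadEpochs(
        dyad_id=matched.dyad_id,
        condition=matched.condition,
        sampling_rate=matched.sampling_rate,
        infant_channels=list(matched.infant_channels),
        adult_channels=list(matched.adult_channels),
        infant_data=matched.infant_data[keep],
        adult_data=matched.adult_data[keep],
        onsets=matched.onsets[keep],
        epoch_length=matched.epoch_length,
        epoch_step=matched.epoch_step,
        report=dict(matched.report),
    )
    trimmed.excluded = matched.matched_seconds < min_seconds
    trimmed.report["min_seconds"] = min_seconds
    trimmed.report["cap_seconds"] = cap_seconds
    trimmed.report["matched_seconds_precap"] = matched.matched_seconds
    return trimmed
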