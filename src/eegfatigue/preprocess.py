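"""Preprocessing: raw two-channel recordings -> normalized 1-s epochs.

Stage order is pinned to

    notch -> band-pass -> wavelet denoise -> epoch -> variance gate
          -> per-epoch min-max normalization

so that the artifact gate operates on physical units (uV^2) before
normalization destroys them.  All filters are zero-phase (forward-backward
IIR), hence length-preserving and non-shifting, so epoch boundaries line up
with the raw recording.

On two forehead channels ICA-based ocular removal is ill-posed; the wavelet
soft-threshold stage is the package's sole transient-artifact suppressor,
a deliberate simplification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

from .data import Epoch, EEGRecording

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    notch_hz: float = 50.0
    notch_q: float = 30.0
    band: tuple[float, float] = (1.0, 50.0)
    filter_order: int = 4
    denoise_wavelet: str = "db4"
    denoise_levels: int = 4
    denoise_threshold_scale: float = 1.0
    max_var: float = 50.0   # uV^2, per channel, per epoch
    denoise: bool = True


def notch_filter(x: np.ndarray, fs: float, notch_hz: float = 50.0,
                 q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at ``notch_hz`` (power-line removal)."""
    if fs <= 2 * notch_hz:
        raise ValueError(f"fs={fs} must exceed twice the notch frequency")
    b, a = sps.iirnotch(notch_hz, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))


def bandpass_filter(x: np.ndarray, fs: float, lo: float = 1.0,
                    hi: float = 50.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (drift + high-frequency removal)."""
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"invalid band ({lo}, {hi}) for fs={fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def wavelet_denoise(x: np.ndarray, wavelet: str = "db4", levels: int = 4,
                    threshold_scale: float = 1.0) -> np.ndarray:
    """Soft-threshold wavelet shrinkage to suppress spiky muscle artifacts.

    All detail levels are shrunk toward zero with the universal threshold
    ``sigma * sqrt(2 log n)``.  ``sigma`` is estimated from the *finest*
    detail level (its standard deviation): after band-pass filtering, that
    level holds only out-of-band residue and transient artifacts, so dense
    in-band oscillations do not inflate the threshold and survive the
    shrinkage, while spiky artifacts — which spread across all levels — are
    attenuated.  (A per-level MAD estimate, by contrast, treats dense
    alpha/beta oscillations as noise and removes them.)
    ``threshold_scale=0`` reduces to a pure analysis/synthesis round-trip
    (identity up to numerical precision).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 ** levels:
        raise ValueError(f"signal of {n} samples too short for "
                         f"{levels}-level decomposition")
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode="periodization")
    sigma = float(np.std(coeffs[-1]))
    thr = threshold_scale * sigma * np.sqrt(2 * np.log(max(n, 2)))
    out = [coeffs[0]]
    for detail in coeffs[1:]:
        # thr == 0 (e.g. all-zero input) makes shrinkage a no-op
        out.append(pywt.threshold(detail, thr, mode="soft") if thr > 0
                   else detail)
    rec = pywt.waverec(out, wavelet, mode="periodization")
    return rec[:n]


def quality_check(epoch_samples: np.ndarray, max_var: float = 50.0) -> bool:
    """True iff every channel's sample variance is below ``max_var`` (uV^2)."""
    arr = np.atleast_2d(np.asarray(epoch_samples, dtype=float))
    if arr.size == 0:
        raise ValueError("empty epoch")
    return bool(np.all(arr.var(axis=1) < max_var))


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Affine map of a signal onto [0, 1]; constant input maps to all 0.5."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant signal in min-max normalization; returning 0.5",
                      stacklevel=2)
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def epoch_recording(recording: EEGRecording) -> list[Epoch]:
    """Cut a recording into contiguous non-overlapping 1-s epochs.

    The trailing partial second is dropped; a recording shorter than 1 s
    yields an empty list with a warning.
    """
    fs = int(round(recording.fs))
    n_epochs = recording.n_samples // fs
    if n_epochs == 0:
        warnings.warn(f"recording of {recording.n_samples} samples is shorter "
                      "than one epoch; returning no epochs", stacklevel=2)
        return []
    epochs = []
    for i in range(n_epochs):
        window = recording.channels[:, i * fs:(i + 1) * fs]
        epochs.append(Epoch(subject_id=recording.subject_id,
                            state=recording.state, fs=recording.fs,
                            samples=window.copy(), index=i))
    return epochs


def preprocess_pipeline(recording: EEGRecording,
                        config: PreprocessConfig | None = None,
                        ) -> tuple[list[Epoch], int]:
    """Full preprocessing of one recording.

    Returns ``(epochs, n_rejected)`` where each surviving epoch is min-max
    normalized per channel into [0, 1] and ``n_rejected`` counts epochs
    removed by the variance gate.
    """
    config = config or PreprocessConfig()
    stage = "notch"
    try:
        filtered = np.vstack([
            notch_filter(ch, recording.fs, config.notch_hz, config.notch_q)
            for ch in recording.channels])
        stage = "bandpass"
        filtered = np.vstack([
            bandpass_filter(ch, recording.fs, *config.band,
                            order=config.filter_order)
            for ch in filtered])
        if config.denoise:
            stage = "wavelet_denoise"
            filtered = np.vstack([
                wavelet_denoise(ch, config.denoise_wavelet,
                                config.denoise_levels,
                                config.denoise_threshold_scale)
                for ch in filtered])
    except ValueError as err:
        raise ValueError(f"preprocessing failed at stage {stage!r}: {err}") from err

    clean = EEGRecording(recording.subject_id, recording.state, recording.fs,
                         filtered)
    epochs = epoch_recording(clean)

    kept: list[Epoch] = []
    rejected = 0
    for epoch in epochs:
        if quality_check(epoch.samples, config.max_var):
            epoch.samples = np.vstack([minmax_normalize(ch)
                                       for ch in epoch.samples])
            kept.append(epoch)
        else:
            rejected += 1
    if rejected:
        logger.info("rejected %d/%d epochs of subject %s (%s) by variance gate",
                    rejected, len(epochs), recording.subject_id,
                    recording.state)
    return kept, rejected
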