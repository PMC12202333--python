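"""Synthetic two-state forehead-EEG cohort generator.

Real driver-fatigue EEG studies record a "normal" and a "fatigue" segment per
subject.  This module emulates the statistical structure such a cohort is
assumed to carry, so every downstream stage (filtering, entropy features,
stacking classifier, leave-one-subject-out evaluation) can be exercised
end-to-end without any recording hardware:

* each channel is a sum of four band-limited oscillators (delta 1-4 Hz,
  theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz) with randomized frequency,
  phase and slow amplitude modulation, plus 1/f background noise;
* fatigue raises theta amplitude and lowers broadband noise (the signal
  becomes slower and more regular, so sample/fuzzy entropy drops);
* FP2 receives a lagged, scaled copy of FP1's oscillatory component, making
  directed FP1->FP2 coupling detectable by symbolic transfer entropy;
* a per-subject multiplicative baseline factor (drawn once, applied to both
  states) makes between-subject amplitude variance exceed within-subject
  state variance, which is what stresses leave-one-subject-out validation.

All randomness derives from ``numpy.random.SeedSequence`` keyed on
``(seed, subject_id, state)``, so cohorts are bit-reproducible and
individual recordings can be regenerated in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .data import (STATE_FATIGUE, STATE_NORMAL, STATES, EEGRecording,
                   state_to_label)

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: baseline oscillator amplitudes (uV) for the normal state
_NORMAL_AMPS = {"delta": 2.0, "theta": 1.5, "alpha": 2.0, "beta": 1.0}
_NORMAL_NOISE = 2.0
_NORMAL_COUPLING = (1, 0.2)  # (lag samples, gain)

#: fatigue multipliers keyed by effect-size preset:
#: (theta amp, delta amp, beta amp, noise amp, coupling gain).
#: Fatigue enriches slow waves (theta up strongly, delta moderately),
#: suppresses fast beta activity, calms the broadband background (the
#: signal becomes more regular) and strengthens frontal cross-channel
#: coupling.
EFFECT_SIZES = {
    "zero": (1.0, 1.0, 1.0, 1.0, 1.0),
    "weak": (1.3, 1.15, 0.85, 0.8, 1.5),
    "moderate": (1.8, 1.4, 0.6, 0.6, 2.0),
    "strong": (2.5, 1.8, 0.4, 0.4, 3.0),
}

_AM_DEPTH = 0.3          # slow amplitude-modulation depth
_AM_FREQ = (0.05, 0.2)   # Hz range of the modulation
_COMPONENTS_PER_BAND = 3  # band power spread over several lines, not one


@dataclass
class SignalModelParams:
    """Parameters of the two-state signal model.

    ``band_amps``, ``noise_amp`` and ``coupling`` map each state label to,
    respectively, per-band oscillator amplitudes (uV), the 1/f background
    amplitude (uV RMS), and a ``(lag_samples, gain)`` pair for the shared
    FP1->FP2 component.  ``subject_sd`` is the SD of the log of the
    per-subject multiplicative baseline factor.
    """

    fs: float = 1000.0
    duration_s: float = 300.0
    band_amps: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_amp: dict[str, float] = field(default_factory=dict)
    coupling: dict[str, tuple[int, float]] = field(default_factory=dict)
    subject_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.band_amps:
            self.band_amps = _default_band_amps("moderate")
        if not self.noise_amp:
            self.noise_amp = _default_noise_amp("moderate")
        if not self.coupling:
            self.coupling = _default_coupling("moderate")
        self.validate()

    def validate(self) -> None:
        highest = max(hi for _, hi in BANDS.values())
        if self.fs <= 2 * highest:
            raise ValueError(
                f"fs={self.fs} must exceed twice the highest oscillator "
                f"frequency ({highest} Hz)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for state in STATES:
            for band, amp in self.band_amps[state].items():
                if amp < 0:
                    raise ValueError(f"negative amplitude for {state}/{band}")
            if self.noise_amp[state] < 0:
                raise ValueError("noise amplitude must be non-negative")
        # the generator's contract: fatigue is slow-wave enriched
        if self.theta_delta_share(STATE_FATIGUE) <= self.theta_delta_share(
                STATE_NORMAL):
            raise ValueError(
                "fatigue band amplitudes must give a strictly larger "
                "theta+delta power share than normal")

    def theta_delta_share(self, state: str) -> float:
        """Fraction of total oscillator power in the theta+delta bands."""
        amps = self.band_amps[state]
        power = {b: a ** 2 for b, a in amps.items()}
        total = sum(power.values())
        return (power["theta"] + power["delta"]) / total

    def replace(self, **kwargs) -> "SignalModelParams":
        return dataclasses.replace(self, **kwargs)


def _default_band_amps(effect_size: str) -> dict[str, dict[str, float]]:
    theta_mult, delta_mult, beta_mult, _, _ = EFFECT_SIZES[effect_size]
    normal = dict(_NORMAL_AMPS)
    fatigue = dict(_NORMAL_AMPS)
    fatigue["theta"] = _NORMAL_AMPS["theta"] * theta_mult
    fatigue["delta"] = _NORMAL_AMPS["delta"] * delta_mult
    fatigue["beta"] = _NORMAL_AMPS["beta"] * beta_mult
    return {STATE_NORMAL: normal, STATE_FATIGUE: fatigue}


def _default_noise_amp(effect_size: str) -> dict[str, float]:
    noise_mult = EFFECT_SIZES[effect_size][3]
    return {STATE_NORMAL: _NORMAL_NOISE,
            STATE_FATIGUE: _NORMAL_NOISE * noise_mult}


def _default_coupling(effect_size: str) -> dict[str, tuple[int, float]]:
    gain_mult = EFFECT_SIZES[effect_size][4]
    lag, gain = _NORMAL_COUPLING
    return {STATE_NORMAL: (lag, gain), STATE_FATIGUE: (lag, gain * gain_mult)}


def default_params(effect_size: str = "moderate", fs: float = 1000.0,
                   duration_s: float = 300.0, seed: int = 0,
                   subject_sd: float = 0.1) -> SignalModelParams:
    """Build :class:`SignalModelParams` from a named effect-size preset.

    ``effect_size="zero"`` makes the two state distributions identical
    (the null cohort used to check that the pipeline does not leak labels).
    Note the zero preset fails the theta/delta enrichment invariant by
    design, so validation of that clause is skipped for it.
    """
    if effect_size not in EFFECT_SIZES:
        raise ValueError(f"unknown effect size {effect_size!r}; "
                         f"choose from {sorted(EFFECT_SIZES)}")
    params = SignalModelParams.__new__(SignalModelParams)
    params.fs = fs
    params.duration_s = duration_s
    params.band_amps = _default_band_amps(effect_size)
    params.noise_amp = _default_noise_amp(effect_size)
    params.coupling = _default_coupling(effect_size)
    params.subject_sd = subject_sd
    params.seed = seed
    if effect_size != "zero":
        params.validate()
    return params


def _recording_rng(params: SignalModelParams, subject_id: int,
                   state: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF,
                                int(subject_id), state_to_label(state), 11]))


def _subject_factor(params: SignalModelParams, subject_id: int) -> float:
    rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF,
                                int(subject_id), 7777]))
    return float(np.exp(params.subject_sd * rng.standard_normal()))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f-amplitude noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz] / freqs[nz][0])
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _oscillator_sum(t: np.ndarray, amps: dict[str, float],
                    rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(t)
    k = _COMPONENTS_PER_BAND
    for band, (lo, hi) in BANDS.items():
        amp = amps[band]
        if amp == 0:
            continue
        # spread band power over k components at stratified frequencies so
        # one extreme draw cannot dominate the band's apparent speed
        edges = np.linspace(lo, hi, k + 1)
        for j in range(k):
            f = rng.uniform(edges[j], edges[j + 1])
            phase = rng.uniform(0, 2 * np.pi)
            f_am = rng.uniform(*_AM_FREQ)
            phase_am = rng.uniform(0, 2 * np.pi)
            am = 1.0 + _AM_DEPTH * np.sin(2 * np.pi * f_am * t + phase_am)
            out += (amp / np.sqrt(k)) * am * np.sin(2 * np.pi * f * t + phase)
    return out


def generate_recording(subject_id: int, state: str,
                       params: SignalModelParams) -> EEGRecording:
    """Generate one subject/state recording of ``duration_s * fs`` samples.

    FP2 = its own oscillators + noise + ``gain`` x a ``lag``-sample delayed
    copy of FP1's oscillatory component, so information flows FP1 -> FP2.
    """
    state_to_label(state)  # raises on unknown label
    rng = _recording_rng(params, subject_id, state)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    amps = params.band_amps[state]
    noise_amp = params.noise_amp[state]
    lag, gain = params.coupling[state]

    osc_fp1 = _oscillator_sum(t, amps, rng)
    osc_fp2 = _oscillator_sum(t, amps, rng)
    noise_fp1 = noise_amp * _pink_noise(n, rng)
    noise_fp2 = noise_amp * _pink_noise(n, rng)

    shared = np.roll(osc_fp1, int(lag))
    factor = _subject_factor(params, subject_id)

    fp1 = factor * (osc_fp1 + noise_fp1)
    fp2 = factor * (osc_fp2 + noise_fp2 + gain * shared)
    return EEGRecording(subject_id=subject_id, state=state, fs=params.fs,
                        channels=np.vstack([fp1, fp2]))


def generate_cohort(n_subjects: int,
                    params: SignalModelParams) -> list[EEGRecording]:
    """Generate ``2 * n_subjects`` recordings (one per state per subject)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    recordings = []
    for subject_id in range(1, n_subjects + 1):
        for state in STATES:
            recordings.append(generate_recording(subject_id, state, params))
    return recordings
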