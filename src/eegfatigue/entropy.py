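"""Entropy feature extraction for 1-s EEG epochs.

Nine estimators are provided: approximate (AE), sample (SE) and fuzzy (FE)
entropy — regularity statistics counting recurrences of m-length templates
within a tolerance r = r_factor * SD; second-order Kolmogorov entropy (KE)
via a maximum-likelihood escape-time estimator; coarse-grained permutation
entropy (PE); spectral entropy (SPE) of the in-band periodogram; symbolic
transfer entropy (STE) on first-difference binarized sequences; wavelet log
energy entropy (WLE, one value per leaf band); and wavelet packet energy
entropy (WPE).  A relative-band-power (RBP) extractor serves as the linear
FFT baseline feature set.

Conventions (documented because the literature varies):

* Chebyshev (max-norm) template distance for AE/SE/FE/KE.
* AE includes self-matches (Pincus); SE excludes them (Richman-Moorman,
  with both template lengths counted over the first N-m templates).
* FE mean-centers each template and uses the membership exp(-(d/r)^n).
* PE coarse-grains by non-overlapping window means of width ``scale`` and
  is normalized by ln(m!) to [0, 1].
* Natural log for AE/SE/FE/KE/PE/SPE/WLE; base-2 log for STE and WPE
  (STE/WPE are in bits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy.spatial.distance import cdist

from .data import CHANNELS, META_COLUMNS, Epoch, FeatureTable, state_to_label

EEG_BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
             "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}


class EstimatorError(ValueError):
    """An entropy estimator could not produce a finite value."""


@dataclass
class EntropyConfig:
    """Estimator parameters.

    Defaults are the values reported as grid-search optima for forehead EEG:
    embedding dimension 2 with tolerance 0.7 * SD for AE/SE/FE, KE embedding
    dimension 6, PE at scale 2 / order 5 / delay 4, db3 wavelet with 2
    decomposition levels for both wavelet entropies.
    """

    m_aef: int = 2
    r_factor: float = 0.7
    fe_gradient: float = 2.0
    m_ke: int = 6
    pe_m: int = 5
    pe_tau: int = 4
    pe_scale: int = 2
    spe_band: tuple[float, float] = (1.0, 50.0)
    ste_k: int = 1
    wavelet: str = "db3"
    wle_levels: int = 2
    wpe_depth: int = 2

    def __post_init__(self) -> None:
        for name in ("m_aef", "m_ke", "pe_m", "pe_tau", "pe_scale", "ste_k",
                     "wle_levels", "wpe_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")


def _embed(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    """Delay-embedding matrix of shape (N - (m-1)*tau, m)."""
    n = x.size - (m - 1) * tau
    if n < 1:
        raise EstimatorError(f"sequence too short to embed at m={m}, tau={tau}")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def approximate_entropy(x: np.ndarray, m: int = 2,
                        r_factor: float = 0.7) -> float:
    """Pincus approximate entropy, Phi(m) - Phi(m+1), self-matches included."""
    x = np.asarray(x, dtype=float)
    if x.size <= m + 1:
        raise EstimatorError("sequence too short for approximate entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def phi(mm: int) -> float:
        tpl = _embed(x, mm)
        d = cdist(tpl, tpl, metric="chebyshev")
        c = (d <= r).mean(axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.7) -> float:
    """Richman-Moorman sample entropy, -ln(A/B), self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise EstimatorError("sequence too short for sample entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd
    tpl_m = _embed(x, m)[: n - m]          # N-m templates of each length
    tpl_m1 = _embed(x, m + 1)
    d_m = cdist(tpl_m, tpl_m, metric="chebyshev")
    d_m1 = cdist(tpl_m1, tpl_m1, metric="chebyshev")
    b = int(np.count_nonzero(d_m <= r) - len(tpl_m))       # exclude i == j
    a = int(np.count_nonzero(d_m1 <= r) - len(tpl_m1))
    if b == 0:
        raise EstimatorError("no template matches at length m")
    if a == 0:
        # no matches at m+1: report the guarded upper bound -ln(1/B)
        return float(np.log(b + 1e-12))
    return float(-np.log(a / b))


def fuzzy_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.7,
                  n_grad: float = 2.0) -> float:
    """Fuzzy entropy with mean-centered templates and exp(-(d/r)^n) membership."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise EstimatorError("sequence too short for fuzzy entropy")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def phi(mm: int) -> float:
        tpl = _embed(x, mm)[: n - m]
        tpl = tpl - tpl.mean(axis=1, keepdims=True)
        d = cdist(tpl, tpl, metric="chebyshev")
        mu = np.exp(-((d / r) ** n_grad))
        k = len(tpl)
        return float((mu.sum() - k) / (k * (k - 1)))   # exclude i == j

    return float(np.log(phi(m)) - np.log(phi(m + 1)))


def kolmogorov_r0(x: np.ndarray) -> float:
    """Distance scale r0 = mean absolute deviation of the series."""
    x = np.asarray(x, dtype=float)
    return float(np.mean(np.abs(x - x.mean())))


def kolmogorov_entropy(x: np.ndarray, m: int = 6) -> float:
    """Second-order Kolmogorov (correlation) entropy, nats per sample step.

    Maximum-likelihood escape-time estimator: template pairs initially
    within r0 (Chebyshev) are followed forward one sample at a time; the
    per-step escape probability p is estimated as
    (number of escapes) / (total pair-steps observed), counting pairs that
    reach the end of the series as censored, and K2 = -ln(1 - p).
    Periodic signals give near-zero K2 (pairs persist); stochastic signals
    give K2 > 0 (pairs escape quickly).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= m + 1:
        raise EstimatorError("sequence too short for Kolmogorov entropy")
    r0 = kolmogorov_r0(x)
    if r0 == 0:
        return 0.0
    tpl = _embed(x, m)
    d = cdist(tpl, tpl, metric="chebyshev")
    iu, ju = np.triu_indices(len(tpl), k=1)
    close = d[iu, ju] <= r0
    ai, aj = iu[close], ju[close]
    if ai.size == 0:
        raise EstimatorError("no template pairs within r0; series too short "
                             "or too irregular for this embedding dimension")
    total_steps = 0
    n_escaped = 0
    k = 0
    while ai.size:
        k += 1
        pos = aj + m - 1 + k            # j > i, so j runs off the end first
        in_data = pos < n
        total_steps += (k - 1) * int(np.count_nonzero(~in_data))  # censored
        ai, aj = ai[in_data], aj[in_data]
        if ai.size == 0:
            break
        escaped = np.abs(x[ai + m - 1 + k] - x[aj + m - 1 + k]) > r0
        n_esc = int(np.count_nonzero(escaped))
        n_escaped += n_esc
        total_steps += k * n_esc
        ai, aj = ai[~escaped], aj[~escaped]
    if total_steps == 0 or n_escaped == 0:
        return 0.0
    p = min(n_escaped / total_steps, 1.0 - 1e-12)
    return float(-np.log1p(-p))


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping window means of width ``scale`` (multiscale step)."""
    x = np.asarray(x, dtype=float)
    n = x.size // scale
    if n < 1:
        raise EstimatorError(f"sequence too short to coarse-grain at scale {scale}")
    return x[: n * scale].reshape(n, scale).mean(axis=1)


def permutation_entropy(x: np.ndarray, m: int = 5, tau: int = 4,
                        scale: int = 2) -> float:
    """Normalized permutation entropy of the coarse-grained series, in [0, 1].

    Shannon entropy of the ordinal-pattern distribution (order ``m``, delay
    ``tau``), divided by ln(m!).  Ties are broken by temporal order.
    """
    y = coarse_grain(x, scale)
    span = (m - 1) * tau
    n_pat = y.size - span
    if n_pat < 1:
        raise EstimatorError(
            f"need at least {(span + 1) * scale} samples for permutation "
            f"entropy at m={m}, tau={tau}, scale={scale}")
    idx = np.arange(n_pat)[:, None] + tau * np.arange(m)[None, :]
    patterns = np.argsort(y[idx], axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(math.factorial(m))


def spectral_entropy(x: np.ndarray, fs: float,
                     band: tuple[float, float] = (1.0, 50.0)) -> float:
    """Normalized Shannon entropy of the in-band periodogram, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    freqs, psd = sps.periodogram(x, fs=fs)
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    psd = psd[mask]
    total = psd.sum()
    if psd.size < 2 or total <= 0:
        raise EstimatorError("no spectral power in the requested band")
    p = psd / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / np.log(p.size))


def binarize_increments(x: np.ndarray) -> np.ndarray:
    """Symbolization rule: 1 where the next sample increases, else 0."""
    return (np.diff(np.asarray(x, dtype=float)) > 0).astype(np.int64)


def symbolic_transfer_entropy(source: np.ndarray, target: np.ndarray,
                              k: int = 1) -> float:
    """Transfer entropy source -> target on binarized increments, in bits.

    TE = sum p(y+, y_k, x_k) log2[ p(y+ | y_k, x_k) / p(y+ | y_k) ] with
    history length ``k`` and plug-in joint frequencies.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source and target must have equal length")
    s = binarize_increments(source)
    t = binarize_increments(target)
    n_sym = t.size
    n_trans = n_sym - k
    if n_trans < 1:
        raise EstimatorError("sequence too short for symbolic transfer entropy")

    pow2 = 2 ** np.arange(k)[::-1]
    t_hist = np.array([t[i:i + k] @ pow2 for i in range(n_trans)])
    s_hist = np.array([s[i:i + k] @ pow2 for i in range(n_trans)])
    y_next = t[k:]

    n_h = 2 ** k
    code = (y_next * n_h + t_hist) * n_h + s_hist
    joint = np.bincount(code, minlength=2 * n_h * n_h).reshape(2, n_h, n_h)
    joint = joint / joint.sum()

    p_yh_xh = joint.sum(axis=0)            # p(y_k, x_k)
    p_ynext_yh = joint.sum(axis=2)         # p(y+, y_k)
    p_yh = joint.sum(axis=(0, 2))          # p(y_k)

    te = 0.0
    for a in range(2):
        for b in range(n_h):
            for c in range(n_h):
                pj = joint[a, b, c]
                if pj <= 0:
                    continue
                num = pj * p_yh[b]
                den = p_yh_xh[b, c] * p_ynext_yh[a, b]
                te += pj * math.log2(num / den)
    return max(te, 0.0)


def wavelet_log_energy(x: np.ndarray, wavelet: str = "db3",
                       levels: int = 2) -> np.ndarray:
    """Sum of log squared wavelet coefficients per leaf band.

    Returns ``levels + 1`` values ordered [approximation, deepest detail,
    ..., shallowest detail].  Exactly-zero coefficients are floored at
    1e-12 inside the log.
    """
    x = np.asarray(x, dtype=float)
    coeffs = pywt.wavedec(x, wavelet, level=levels)
    out = np.empty(levels + 1)
    for i, c in enumerate(coeffs):
        c2 = c * c
        c2 = np.where(c2 == 0, 1e-12, c2)
        out[i] = float(np.log(c2).sum())
    return out


def wavelet_packet_energy_entropy(x: np.ndarray, wavelet: str = "db3",
                                  depth: int = 2) -> float:
    """Shannon entropy (bits) of leaf-energy fractions of the packet tree.

    A full wavelet-packet tree to ``depth`` has 2**depth leaves; p_i is the
    i-th leaf's share of total leaf energy and WPE = -sum p_i log2 p_i,
    bounded by ``depth`` bits.
    """
    x = np.asarray(x, dtype=float)
    wp = pywt.WaveletPacket(data=x, wavelet=wavelet, maxlevel=depth)
    energies = np.array([np.sum(node.data ** 2)
                         for node in wp.get_level(depth, order="natural")])
    total = energies.sum()
    if total <= 0:
        raise EstimatorError("zero total wavelet-packet energy")
    p = energies / total
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


def relative_band_power(x: np.ndarray, fs: float,
                        total_band: tuple[float, float] = (1.0, 50.0),
                        ) -> np.ndarray:
    """FFT relative band power: (delta, theta, alpha, beta) fractions.

    Fractions of periodogram power within ``total_band``; bands are
    [lo, hi) except that the total band is edge-inclusive, so the four
    fractions need not sum to 1 (the 30-50 Hz residual is excluded).
    """
    x = np.asarray(x, dtype=float)
    freqs, psd = sps.periodogram(x, fs=fs)
    in_total = (freqs >= total_band[0]) & (freqs <= total_band[1])
    total = psd[in_total].sum()
    if total <= 0:
        raise EstimatorError("zero spectral power in the total band")
    out = np.empty(len(EEG_BANDS))
    for i, (lo, hi) in enumerate(EEG_BANDS.values()):
        out[i] = psd[(freqs >= lo) & (freqs < hi)].sum() / total
    return out


# ---------------------------------------------------------------------------
# per-epoch feature assembly


def entropy_feature_names(config: EntropyConfig | None = None) -> list[str]:
    """Ordered feature-column names (22 at default config)."""
    config = config or EntropyConfig()
    names = []
    for ch in CHANNELS:
        names += [f"AE_{ch}", f"FE_{ch}", f"KE_{ch}", f"PE_{ch}", f"SE_{ch}",
                  f"SPE_{ch}", f"WPE_{ch}"]
        names += [f"WLE_{i + 1}_{ch}" for i in range(config.wle_levels + 1)]
        names += [f"STE_{ch}"]
    return names


def rbp_feature_names() -> list[str]:
    return [f"RBP_{band}_{ch}" for ch in CHANNELS for band in EEG_BANDS]


class FeatureExtractionError(RuntimeError):
    """Raised when an estimator fails on an epoch; carries the feature name."""

    def __init__(self, feature: str, epoch: Epoch, cause: Exception):
        self.feature = feature
        super().__init__(
            f"feature {feature!r} failed on epoch {epoch.index} of subject "
            f"{epoch.subject_id} ({epoch.state}): {cause}")


def extract_features(epoch: Epoch, config: EntropyConfig | None = None,
                     include_rbp: bool = False) -> dict[str, float]:
    """All entropy features of one epoch as an ordered name -> value map.

    STE_{ch} is the information flowing INTO channel ch from the other
    channel.  With ``include_rbp`` the four relative-band-power fractions
    per channel are appended (the linear baseline features).
    """
    config = config or EntropyConfig()
    values: dict[str, float] = {}
    other = {CHANNELS[0]: CHANNELS[1], CHANNELS[1]: CHANNELS[0]}

    def run(name: str, fn, *args):
        try:
            values[name] = float(fn(*args))
        except Exception as err:   # noqa: BLE001 - re-raised with context
            raise FeatureExtractionError(name, epoch, err) from err

    for ch in CHANNELS:
        x = epoch.channel(ch)
        run(f"AE_{ch}", approximate_entropy, x, config.m_aef, config.r_factor)
        run(f"FE_{ch}", fuzzy_entropy, x, config.m_aef, config.r_factor,
            config.fe_gradient)
        run(f"KE_{ch}", kolmogorov_entropy, x, config.m_ke)
        run(f"PE_{ch}", permutation_entropy, x, config.pe_m, config.pe_tau,
            config.pe_scale)
        run(f"SE_{ch}", sample_entropy, x, config.m_aef, config.r_factor)
        run(f"SPE_{ch}", spectral_entropy, x, epoch.fs, config.spe_band)
        run(f"WPE_{ch}", wavelet_packet_energy_entropy, x, config.wavelet,
            config.wpe_depth)
        try:
            wle = wavelet_log_energy(x, config.wavelet, config.wle_levels)
        except Exception as err:   # noqa: BLE001
            raise FeatureExtractionError(f"WLE_{ch}", epoch, err) from err
        for i, v in enumerate(wle):
            values[f"WLE_{i + 1}_{ch}"] = float(v)
        run(f"STE_{ch}", symbolic_transfer_entropy, epoch.channel(other[ch]),
            x, config.ste_k)

    if include_rbp:
        for ch in CHANNELS:
            rbp = relative_band_power(epoch.channel(ch), epoch.fs)
            for band, v in zip(EEG_BANDS, rbp):
                values[f"RBP_{band}_{ch}"] = float(v)

    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise FeatureExtractionError(bad[0], epoch,
                                     ValueError("non-finite feature value"))
    return values


def build_feature_table(epochs: list[Epoch],
                        config: EntropyConfig | None = None,
                        include_rbp: bool = False) -> FeatureTable:
    """Extract features for a list of epochs into a :class:`FeatureTable`."""
    config = config or EntropyConfig()
    rows = []
    for epoch in epochs:
        row = {"subject_id": epoch.subject_id, "state": epoch.state,
               "label": state_to_label(epoch.state),
               "epoch_index": epoch.index}
        row.update(extract_features(epoch, config, include_rbp=include_rbp))
        rows.append(row)
    if not rows:
        raise ValueError("no epochs to extract features from")
    df = pd.DataFrame(rows)
    names = [c for c in df.columns if c not in META_COLUMNS]
    return FeatureTable(df, names)
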