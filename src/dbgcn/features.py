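"""Band decomposition and differential-entropy (DE) features.

Each segment is decomposed into the four canonical EEG rhythms — delta
(0.5-4 Hz), theta (4-8 Hz), alpha (8-12 Hz), beta (12-30 Hz) — with
fourth-order Butterworth band-pass filters, and a scalar complexity feature
is computed per (channel, sub-window, band).  For a Gaussian signal the
differential entropy has the closed form

    DE = 1/2 * ln(2 * pi * e * sigma^2),

which for a fixed-length band-limited segment coincides (up to constants)
with the log energy in that band; both the closed form and the literal
log-power reading are available, plus a plain log-PSD feature for
comparison experiments.

Features are assembled into a tensor X of shape (n channels, t sub-windows,
d bands) per segment — the input sequence of the BiLSTM node encoder — and
z-scored per (channel, band) with statistics fitted on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Segment

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "FeatureTensor",
    "NormStats",
    "band_decompose",
    "differential_entropy",
    "psd_feature",
    "build_feature_tensor",
    "fit_normalizer",
    "apply_normalizer",
]

_LN_2PIE = float(np.log(2.0 * np.pi * np.e))


@dataclass(frozen=True)
class BandSpec:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: need 0 < low < high, got [{self.low_hz}, {self.high_hz})")


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
)


@dataclass
class FeatureTensor:
    """Per-segment feature array of shape (n, t, d): channels x sub-windows x bands."""

    values: np.ndarray
    feature_kind: str  # "DE" or "PSD"
    band_names: list[str]
    subject_id: str
    label: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"feature tensor must be 3-D (n, t, d), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature tensor contains NaN or Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class NormStats:
    """Per-(channel, band) z-score statistics, fitted on training tensors only."""

    mean: np.ndarray  # (n, d)
    std: np.ndarray   # (n, d)


def band_decompose(seg: Segment, bands: tuple[BandSpec, ...] = DEFAULT_BANDS, order: int = 4) -> dict[str, np.ndarray]:
    """Filter the segment into one same-shape array per frequency band.

    Zero-phase fourth-order Butterworth band-passes; a pure tone's energy
    lands almost entirely in the band that contains it.
    """
    fs = seg.sampling_rate_hz
    nyq = fs / 2.0
    out: dict[str, np.ndarray] = {}
    for band in bands:
        if band.high_hz >= nyq:
            raise ValueError(
                f"band {band.name} [{band.low_hz}, {band.high_hz}) Hz exceeds the Nyquist "
                f"frequency {nyq} Hz at sampling rate {fs} Hz"
            )
        sos = signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")
        out[band.name] = signal.sosfiltfilt(sos, seg.data, axis=-1)
    return out


def differential_entropy(band_signal: np.ndarray, variant: str = "gaussian_closed_form") -> float:
    """Differential entropy of one band-filtered sub-window.

    ``gaussian_closed_form`` (default) returns 1/2 ln(2*pi*e*sigma^2) with
    sigma^2 the unbiased sample variance — the standard DE estimate under a
    Gaussian model, exactly +ln(c) equivariant under amplitude scaling by c.
    ``literal_log_power`` returns 1/2 ln(P) + 1/2 ln(2*pi*e*N) with P the mean
    band power and N the sub-window length in samples.
    """
    x = np.asarray(band_signal, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples to estimate differential entropy")
    if variant == "gaussian_closed_form":
        var = x.var(ddof=1)
        if var <= 0:
            raise ValueError("zero-variance (degenerate) signal: differential entropy undefined")
        return 0.5 * float(np.log(var)) + 0.5 * _LN_2PIE
    if variant == "literal_log_power":
        power = float(np.mean(x * x))
        if power <= 0:
            raise ValueError("zero-power signal: differential entropy undefined")
        return 0.5 * float(np.log(power)) + 0.5 * float(np.log(2.0 * np.pi * np.e * x.size))
    raise ValueError(f"unknown DE variant {variant!r}")


def psd_feature(band_signal: np.ndarray) -> float:
    """Log mean band power — the comparison feature to DE."""
    x = np.asarray(band_signal, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    power = float(np.mean(x * x))
    if power <= 0:
        raise ValueError("zero-power signal")
    return float(np.log(power))


def build_feature_tensor(
    seg: Segment,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    t_subwindows: int = 4,
    feature_kind: str = "DE",
    de_variant: str = "gaussian_closed_form",
) -> FeatureTensor:
    """Compute the (n, t, d) feature tensor for one segment.

    The segment is band-filtered as a whole, then split into ``t_subwindows``
    equal non-overlapping sub-windows (1 s each for the default 4 s / t=4),
    and the per-band feature is evaluated on each sub-window.
    """
    n_samp = seg.n_samples
    if t_subwindows < 1 or n_samp % t_subwindows != 0:
        valid = [t for t in range(1, min(n_samp, 33)) if n_samp % t == 0]
        raise ValueError(
            f"segment length {n_samp} is not divisible into {t_subwindows} equal "
            f"sub-windows; valid choices include {valid}"
        )
    if feature_kind not in ("DE", "PSD"):
        raise ValueError(f"feature_kind must be 'DE' or 'PSD', got {feature_kind!r}")
    sub_len = n_samp // t_subwindows
    per_band = band_decompose(seg, bands)
    n = seg.n_channels
    d = len(bands)
    values = np.empty((n, t_subwindows, d), dtype=np.float64)
    for b, band in enumerate(bands):
        sig = per_band[band.name]
        for j in range(t_subwindows):
            chunk = sig[:, j * sub_len:(j + 1) * sub_len]
            for c in range(n):
                if feature_kind == "DE":
                    values[c, j, b] = differential_entropy(chunk[c], variant=de_variant)
                else:
                    values[c, j, b] = psd_feature(chunk[c])
    return FeatureTensor(
        values=values,
        feature_kind=feature_kind,
        band_names=[band.name for band in bands],
        subject_id=seg.subject_id,
        label=seg.label,
    )


def fit_normalizer(train_tensors: list[FeatureTensor]) -> NormStats:
    """Fit per-(channel, band) z-score statistics over training tensors.

    Sub-windows and segments are pooled, so the statistics describe the
    feature distribution each (channel, band) pair produces on the training
    folds; held-out data must be transformed with these same statistics.
    """
    if not train_tensors:
        raise ValueError("cannot fit a normalizer on an empty training set")
    stacked = np.concatenate([t.values for t in train_tensors], axis=1)  # (n, sum_t, d)
    mean = stacked.mean(axis=1)
    std = stacked.std(axis=1)
    if np.any(std <= 0):
        bad = np.argwhere(std <= 0)
        pairs = [(int(c), train_tensors[0].band_names[int(b)]) for c, b in bad[:10]]
        raise ValueError(f"zero-std (degenerate) features at (channel, band): {pairs}")
    return NormStats(mean=mean, std=std)


def apply_normalizer(tensor: FeatureTensor, stats: NormStats) -> FeatureTensor:
    """Z-score a tensor with previously fitted statistics (not idempotent)."""
    values = (tensor.values - stats.mean[:, None, :]) / stats.std[:, None, :]
    return FeatureTensor(
        values=values,
        feature_kind=tensor.feature_kind,
        band_names=list(tensor.band_names),
        subject_id=tensor.subject_id,
        label=tensor.label,
    )
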