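"""Raw-EEG cleaning: line-noise removal, band-pass filtering, baseline
correction, channel selection and sliding-window segmentation.

The filter chain follows common resting-state depression-EEG protocols: a
50 Hz notch against mains interference, a 0.3-50 Hz band-pass, then a 1-50 Hz
fourth-order Butterworth.  All filters are applied forward-backward
(zero-phase) so windowed features are never time-shifted.  The two band-pass
stages overlap; the composite passband is effectively 1-50 Hz, and either
stage can be disabled through :class:`FilterSpec`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal

from .recording import RawRecording, Segment

__all__ = [
    "FilterSpec",
    "apply_filters",
    "baseline_correct",
    "segment",
    "select_channels",
    "remove_artifacts_hook",
]

logger = logging.getLogger("dbgcn.preprocess")


@dataclass
class FilterSpec:
    """Parameters of the cleaning filter cascade.

    ``notch_q`` is the quality factor of the second-order IIR notch; 30 gives
    a ~1.7 Hz -3 dB width at 50 Hz.  Set ``notch_hz``/``bandpass_low_hz``/
    ``butter_low_hz`` to ``None`` to skip the corresponding stage.
    """

    notch_hz: float | None = 50.0
    notch_q: float = 30.0
    bandpass_low_hz: float | None = 0.3
    bandpass_high_hz: float = 50.0
    butter_order: int = 4
    butter_low_hz: float | None = 1.0
    butter_high_hz: float = 50.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        for name, hi in (("bandpass_high_hz", self.bandpass_high_hz if self.bandpass_low_hz is not None else None),
                         ("butter_high_hz", self.butter_high_hz if self.butter_low_hz is not None else None),
                         ("notch_hz", self.notch_hz)):
            if hi is not None and hi >= nyq:
                raise ValueError(
                    f"{name}={hi} Hz is at or above the Nyquist frequency {nyq} Hz "
                    f"for sampling rate {fs} Hz"
                )
        if self.bandpass_low_hz is not None and not 0 < self.bandpass_low_hz < self.bandpass_high_hz:
            raise ValueError("bandpass cutoffs must satisfy 0 < low < high")
        if self.butter_low_hz is not None and not 0 < self.butter_low_hz < self.butter_high_hz:
            raise ValueError("Butterworth cutoffs must satisfy 0 < low < high")


def apply_filters(rec: RawRecording, spec: FilterSpec | None = None) -> RawRecording:
    """Run the notch + dual band-pass cascade over every channel, zero-phase.

    Returns a new recording of identical shape.  The 50 Hz component is
    attenuated by well over 20 dB while mid-band rhythms (e.g. 10 Hz alpha)
    pass essentially unchanged.
    """
    spec = spec or FilterSpec()
    fs = rec.sampling_rate_hz
    spec.validate(fs)
    out = rec.data
    if spec.notch_hz is not None:
        b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    if spec.bandpass_low_hz is not None:
        sos = signal.butter(spec.butter_order, [spec.bandpass_low_hz, spec.bandpass_high_hz],
                            btype="bandpass", fs=fs, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=-1)
    if spec.butter_low_hz is not None:
        sos = signal.butter(spec.butter_order, [spec.butter_low_hz, spec.butter_high_hz],
                            btype="bandpass", fs=fs, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=-1)
    return rec.with_data(np.ascontiguousarray(out))


def baseline_correct(rec: RawRecording, baseline_s: float = 120.0) -> RawRecording:
    """Subtract each channel's mean over the first ``baseline_s`` seconds.

    Removes the DC offset recorded by the amplifier so that every channel is
    centred on its resting baseline (the first 2 min by default).
    """
    n_base = int(round(baseline_s * rec.sampling_rate_hz))
    if n_base > rec.n_samples:
        raise ValueError(
            f"recording is {rec.duration_s:.1f} s, shorter than the {baseline_s} s baseline "
            f"window; pass a smaller baseline_s (<= {rec.duration_s:.1f})"
        )
    if n_base < 1:
        raise ValueError("baseline_s must cover at least one sample")
    means = rec.data[:, :n_base].mean(axis=1, keepdims=True)
    return rec.with_data(rec.data - means)


def segment(rec: RawRecording, window_s: float = 4.0, stride_s: float = 2.0) -> list[Segment]:
    """Cut the recording into overlapping fixed-length windows.

    With the defaults (4 s window, 2 s stride) consecutive segments overlap by
    50%.  Produces ``floor((duration - window) / stride) + 1`` segments; a
    recording shorter than one window yields an empty list with a warning so
    batch jobs skip short files instead of crashing.
    """
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    fs = rec.sampling_rate_hz
    win = int(round(window_s * fs))
    if win > rec.n_samples:
        logger.warning(
            "recording %s (%.1f s) shorter than %.1f s window; produced 0 segments",
            rec.subject_id, rec.duration_s, window_s,
        )
        return []
    stride = stride_s * fs
    n_seg = int(np.floor((rec.n_samples - win) / stride)) + 1
    segments = []
    for k in range(n_seg):
        start = int(round(k * stride))
        segments.append(
            Segment(
                subject_id=rec.subject_id,
                label=rec.label,
                sampling_rate_hz=fs,
                start_time_s=start / fs,
                data=rec.data[:, start:start + win].copy(),
            )
        )
    return segments


def select_channels(rec: RawRecording, subset: list[str]) -> RawRecording:
    """Keep (and reorder to) the named channels.

    Used to harmonise montages, e.g. reducing a 128-channel net to the 64
    channels shared with another system.  The channel subset is an explicit
    input; no default montage is assumed.
    """
    missing = [name for name in subset if name not in rec.channel_names]
    if missing:
        raise KeyError(f"channels not present in recording: {missing}")
    idx = [rec.channel_names.index(name) for name in subset]
    from dataclasses import replace
    return replace(rec, data=rec.data[idx, :].copy(), channel_names=list(subset))


def remove_artifacts_hook(
    rec: RawRecording,
    method: str = "none",
    external: Callable[[RawRecording], RawRecording] | None = None,
) -> RawRecording:
    """Artifact-removal extension point.

    Semi-automatic ICA cleaning is an interactive, established procedure that
    this package deliberately delegates: ``method='external_ica'`` invokes a
    user-supplied callable (e.g. wrapping an MNE ICA session) and validates
    that it preserved the recording's shape.  ``method='none'`` is a strict
    pass-through.
    """
    if method == "none":
        return rec
    if method == "external_ica":
        if external is None:
            raise ValueError("method='external_ica' requires an `external` callable")
        cleaned = external(rec)
        if cleaned.data.shape != rec.data.shape:
            raise ValueError(
                f"external artifact remover changed the data shape from "
                f"{rec.data.shape} to {cleaned.data.shape}"
            )
        return cleaned
    raise ValueError(f"unknown artifact-removal method {method!r}; use 'none' or 'external_ica'")
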