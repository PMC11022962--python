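"""Synthetic two-class resting-state EEG with the structure the classifier assumes.

Each subject is a sum of band-limited Gaussian noise processes (one per
canonical rhythm, produced by the same fourth-order Butterworth band filters
the feature extractor uses), with

* class-dependent band power: the depressed class multiplies delta and theta
  power by (1 + effect_size), emulating the elevated low-frequency activity
  associated with depression;
* community-structured inter-channel correlation: channels are grouped into
  communities sharing a latent signal, giving within-community Pearson
  correlation ``rho`` (depressed subjects get a higher ``rho`` scaled by the
  same effect_size, so effect_size = 0 makes the classes distributionally
  identical);
* an optional 50 Hz line-noise sinusoid and a per-channel DC offset, so the
  notch filter and baseline correction have real work to do.

This emulates the second-order statistics the pipeline consumes; it does not
model dipole physics, non-Gaussian transients, or artifacts beyond line noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .features import DEFAULT_BANDS, BandSpec
from .recording import RawRecording

__all__ = ["SimConfig", "simulate_subject", "simulate_dataset", "preset_config", "PRESETS"]


@dataclass
class SimConfig:
    """Generator parameters.

    ``band_power_profile`` gives the relative variance of each rhythm for the
    control class (a 1/f-like decay by default); ``low_bands`` lists the
    rhythms whose power the depressed class multiplies by (1 + effect_size).
    ``base_connectivity`` is the within-community correlation of controls;
    depressed subjects use ``base + connectivity_effect * effect_size``.
    """

    n_channels: int = 64
    fs_hz: float = 250.0
    duration_s: float = 122.0
    n_depressed: int = 24
    n_control: int = 29
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    band_power_profile: dict[str, float] = field(
        default_factory=lambda: {"delta": 1.0, "theta": 0.8, "alpha": 0.6, "beta": 0.4}
    )
    low_bands: tuple[str, ...] = ("delta", "theta")
    n_communities: int = 4
    base_connectivity: float = 0.3
    connectivity_effect: float = 0.1
    effect_size: float = 1.0
    amplitude_uv: float = 10.0
    dc_offset_uv: float = 5.0
    line_noise_amp: float = 2.0
    line_noise_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.band_power_profile.values()):
            raise ValueError("band powers must be positive")
        if not 0 <= self.base_connectivity < 1:
            raise ValueError("base_connectivity must be in [0, 1)")
        for label in (0, 1):
            rho = self.connectivity(label)
            if not 0 <= rho < 1:
                raise ValueError(
                    f"requested within-community correlation {rho:.3f} for class {label} "
                    "does not yield a valid (positive-definite) covariance; keep it in [0, 1)"
                )
        if self.n_communities < 1 or self.n_communities > self.n_channels:
            raise ValueError("need 1 <= n_communities <= n_channels")

    def connectivity(self, label: int) -> float:
        rho = self.base_connectivity
        if label == 1:
            rho += self.connectivity_effect * self.effect_size
        return rho

    def band_power(self, band: str, label: int) -> float:
        p = self.band_power_profile[band]
        if label == 1 and band in self.low_bands:
            p *= 1.0 + self.effect_size
        return p

    def communities(self) -> list[np.ndarray]:
        return np.array_split(np.arange(self.n_channels), self.n_communities)


def simulate_subject(class_label: int, cfg: SimConfig, subject_seed: int,
                     subject_id: str | None = None) -> RawRecording:
    """One subject's multichannel recording; bit-reproducible from its seed."""
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 (control) or 1 (depressed)")
    rng = np.random.default_rng(subject_seed)
    fs = cfg.fs_hz
    n_samp = int(round(cfg.duration_s * fs))
    n_ch = cfg.n_channels
    rho = cfg.connectivity(class_label)
    comms = cfg.communities()
    comm_of = np.empty(n_ch, dtype=np.int64)
    for ci, members in enumerate(comms):
        comm_of[members] = ci

    data = np.zeros((n_ch, n_samp))
    for band in cfg.bands:
        own = rng.standard_normal((n_ch, n_samp))
        latent = rng.standard_normal((len(comms), n_samp))
        mixed = np.sqrt(1.0 - rho) * own + np.sqrt(rho) * latent[comm_of]
        sos = signal.butter(4, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")
        band_sig = signal.sosfiltfilt(sos, mixed, axis=-1)
        # per-channel unit variance, then the class's band amplitude; rescaling
        # a channel leaves Pearson correlations untouched
        band_sig /= band_sig.std(axis=1, keepdims=True)
        data += band_sig * (cfg.amplitude_uv * np.sqrt(cfg.band_power(band.name, class_label)))

    if cfg.dc_offset_uv > 0:
        data += rng.normal(0.0, cfg.dc_offset_uv, size=(n_ch, 1))
    if cfg.line_noise_amp > 0:
        t = np.arange(n_samp) / fs
        phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
        data += cfg.line_noise_amp * np.sin(2 * np.pi * cfg.line_noise_hz * t[None, :] + phase)

    if subject_id is None:
        subject_id = f"{'mdd' if class_label else 'ctl'}-{subject_seed}"
    return RawRecording(
        subject_id=subject_id,
        label=class_label,
        sampling_rate_hz=fs,
        channel_names=[f"CH{i:03d}" for i in range(n_ch)],
        data=data,
    )


def simulate_dataset(cfg: SimConfig) -> tuple[list[RawRecording], list[dict]]:
    """A labeled cohort plus a manifest sufficient for bit-identical regeneration.

    Per-subject seeds are drawn deterministically from ``cfg.seed``; the
    manifest records (subject_id, label, seed) per subject.
    """
    n_total = cfg.n_depressed + cfg.n_control
    if n_total < 2:
        raise ValueError("need at least 2 subjects")
    seeds = np.random.default_rng(cfg.seed).integers(0, 2 ** 31 - 1, size=n_total)
    labels = [1] * cfg.n_depressed + [0] * cfg.n_control
    recordings, manifest = [], []
    for i, (label, seed) in enumerate(zip(labels, seeds)):
        sid = f"{'mdd' if label else 'ctl'}-{i:03d}"
        recordings.append(simulate_subject(label, cfg, int(seed), subject_id=sid))
        manifest.append({"subject_id": sid, "label": label, "seed": int(seed)})
    return recordings, manifest


PRESETS: dict[str, dict] = {
    # scaled-down study conditions for self-contained experiments
    "easy": dict(n_channels=16, duration_s=30.0, n_depressed=10, n_control=10,
                 n_communities=4, effect_size=2.0),
    "hard": dict(n_channels=16, duration_s=30.0, n_depressed=10, n_control=10,
                 n_communities=4, effect_size=0.5),
    "null": dict(n_channels=16, duration_s=30.0, n_depressed=10, n_control=10,
                 n_communities=4, effect_size=0.0),
    # full-size cohort compositions of the public depression datasets
    "modma_like": dict(n_channels=64, duration_s=122.0, n_depressed=24, n_control=29,
                       fs_hz=250.0),
    "predct_like": dict(n_channels=64, duration_s=122.0, n_depressed=44, n_control=75,
                        fs_hz=500.0),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named study presets: 'easy'/'hard'/'null' scaled two-class cohorts, or
    full-size 'modma_like'/'predct_like' compositions."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)
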