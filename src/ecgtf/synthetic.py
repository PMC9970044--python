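"""Synthetic annotated ECG with five beat morphologies and realistic noise.

Beats are sums of Gaussian components (a parametric PQRST model in the
spirit of the McSharry dynamical ECG): each template lists components as
(role, center offset s relative to the R apex, width s, amplitude mV).
Five templates cover the beat classes used throughout the package:

  N  canonical PQRST, ~75 bpm;
  A  atrial premature beat: early, peaked P wave and a shortened coupling
     interval (own RR well below normal);
  V  premature ventricular beat: wide, large-amplitude QRS, no P wave,
     discordant (negative) T;
  L  left bundle branch block: broad notched R (two merged positive
     peaks), late S, inverted T;
  R  right bundle branch block: rsR'-like shape with a deep wide S and a
     secondary R' deflection.

Noise follows the usual ECG taxonomy: baseline wander (low-frequency
sinusoid, ~0.3 Hz), myoelectric interference (broadband high-pass-filtered
white noise) and powerline interference (50/60 Hz sinusoid).  Records
carry exact R-apex indices and labels as ground truth, and identical seeds
reproduce records bit-for-bit.

These synthetic records exercise every pipeline stage at desk scale; they
are not physiologically validated morphologies (no heart-rate variability,
respiration modulation or beat-to-beat morphology drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import BEAT_CLASSES, ECGRecord

__all__ = [
    "BeatTemplate",
    "NoiseConfig",
    "make_beat",
    "make_record",
    "default_template_bank",
]

QRS_ROLES = ("Q", "R", "S", "R2")  # components flipped by r_polarity


@dataclass
class BeatTemplate:
    class_symbol: str
    #: (role, center offset s from R apex, width s, amplitude mV)
    wave_params: list[tuple[str, float, float, float]]
    rr_mean: float
    rr_jitter: float
    r_polarity: int = 1

    def __post_init__(self) -> None:
        if self.class_symbol not in BEAT_CLASSES:
            raise ValueError(f"unknown beat class {self.class_symbol!r}")
        if self.rr_mean <= 0:
            raise ValueError("rr_mean must be positive")
        if any(w <= 0 for _, _, w, _ in self.wave_params):
            raise ValueError("component widths must be positive")
        amps = {role: abs(a) for role, _, _, a in self.wave_params}
        r_amp = amps.get("R", 0.0)
        if any(amps.values()) and any(
                a >= r_amp for role, a in amps.items() if role != "R"):
            raise ValueError("the R component must dominate the template")


@dataclass
class NoiseConfig:
    """Additive noise amplitudes in mV; zero everywhere means a clean record."""

    baseline_amp: float = 0.15
    baseline_freq: float = 0.3
    emg_amp: float = 0.05
    powerline_amp: float = 0.05
    powerline_freq: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_amp", "emg_amp", "powerline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseConfig":
        return cls(baseline_amp=0.0, emg_amp=0.0, powerline_amp=0.0, seed=seed)


#: fraction of the RR interval preceding the R apex within one beat window
_R_FRACTION = 0.35


def make_beat(template: BeatTemplate, fs: float = 360.0,
              rr: float | None = None) -> tuple[np.ndarray, int]:
    """One beat spanning an RR interval; returns (samples, R-apex index).

    The apex index is the extremum of |waveform| (the R trough for
    inverted templates); for an all-zero template it falls back to the
    nominal R-component sample.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    rr = template.rr_mean if rr is None else rr
    n = max(1, int(round(rr * fs)))
    # snap the nominal R apex onto the sample grid so component maxima are
    # sampled exactly
    r_sample = int(round(_R_FRACTION * rr * fs))
    t = (np.arange(n) - r_sample) / fs
    y = np.zeros(n)
    for role, c, w, a in template.wave_params:
        if role in QRS_ROLES:
            a = a * template.r_polarity
        y += a * np.exp(-((t - c) ** 2) / (2.0 * w ** 2))
    if np.any(y):
        apex = int(np.argmax(np.abs(y)))
    else:
        apex = int(np.clip(r_sample, 0, n - 1))
    return y, apex


def make_record(beat_sequence: list[str],
                templates: dict[str, BeatTemplate] | None = None,
                noise: NoiseConfig | None = None,
                fs: float = 360.0,
                seed: int | None = None,
                record_id: str = "synthetic") -> ECGRecord:
    """Concatenated beats with jittered RR and additive noise.

    ``seed`` overrides ``noise.seed``.  RR jitter is a truncated normal
    (clipped at +-3 sigma) around each template's rr_mean.  Ground-truth
    annotation indices point at each beat's R apex.
    """
    templates = templates or default_template_bank()
    noise = noise or NoiseConfig.none()
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    pieces: list[np.ndarray] = []
    ann_idx: list[int] = []
    ann_lab: list[str] = []
    offset = 0
    for sym in beat_sequence:
        tpl = templates[sym]
        jitter = float(np.clip(rng.normal(0.0, tpl.rr_jitter),
                               -3 * tpl.rr_jitter, 3 * tpl.rr_jitter)) if tpl.rr_jitter else 0.0
        rr = max(0.3, tpl.rr_mean + jitter)
        beat, apex = make_beat(tpl, fs=fs, rr=rr)
        pieces.append(beat)
        ann_idx.append(offset + apex)
        ann_lab.append(sym)
        offset += beat.size
    x = np.concatenate(pieces) if pieces else np.zeros(1)
    n = x.size
    t = np.arange(n) / fs

    if noise.baseline_amp > 0:
        x = x + noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.powerline_amp > 0:
        x = x + noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi))
    if noise.emg_amp > 0:
        white = rng.normal(size=n)
        # myoelectric interference: irregular and high-frequency; keep the
        # band above ~60 Hz so it is spectrally distinct from the QRS
        sos = sps.butter(4, 60.0, btype="highpass", fs=fs, output="sos")
        emg = sps.sosfiltfilt(sos, white)
        emg = emg / max(emg.std(), 1e-12) * noise.emg_amp
        x = x + emg

    return ECGRecord(samples=x, fs=fs,
                     ann_indices=np.asarray(ann_idx, dtype=np.int64),
                     ann_labels=ann_lab, record_id=record_id)


def default_template_bank() -> dict[str, BeatTemplate]:
    """Five morphologically distinct beat templates keyed by class symbol.

    Amplitudes are on the MIT-BIH millivolt scale: the QRS deflections
    dominate (R around 1 mV or more, several times the detector's 0.15 mV
    window-range threshold) and P/T waves stay a few tenths of a mV.
    """
    return {
        "N": BeatTemplate("N", [
            ("P", -0.170, 0.022, 0.15),
            ("Q", -0.035, 0.010, -0.15),
            ("R", 0.000, 0.012, 1.20),
            ("S", 0.035, 0.010, -0.25),
            ("T", 0.220, 0.050, 0.35),
        ], rr_mean=0.80, rr_jitter=0.030),
        "A": BeatTemplate("A", [
            ("P", -0.110, 0.014, 0.28),  # early, peaked ectopic P
            ("Q", -0.030, 0.010, -0.12),
            ("R", 0.000, 0.011, 1.05),
            ("S", 0.032, 0.010, -0.22),
            ("T", 0.200, 0.045, 0.30),
        ], rr_mean=0.58, rr_jitter=0.030),
        "V": BeatTemplate("V", [
            # wide overall complex built from sharp slurred deflections so
            # the third-scale detail band retains QRS energy
            ("Q", -0.075, 0.018, -0.45),
            ("R", 0.000, 0.016, 1.70),
            ("S", 0.065, 0.020, -0.65),
            ("T", 0.300, 0.060, -0.45),  # discordant T
        ], rr_mean=0.88, rr_jitter=0.035),
        "L": BeatTemplate("L", [
            ("R", -0.022, 0.013, 1.05),
            ("R2", 0.028, 0.013, 0.85),  # notched broad R
            ("S", 0.095, 0.020, -0.45),
            ("T", 0.260, 0.055, -0.30),
        ], rr_mean=0.82, rr_jitter=0.030),
        "R": BeatTemplate("R", [
            ("P", -0.165, 0.022, 0.14),
            ("R", 0.000, 0.014, 1.10),
            ("S", 0.050, 0.030, -0.50),  # slurred wide S
            ("R2", 0.105, 0.018, 0.45),
            ("T", 0.250, 0.050, 0.25),
        ], rr_mean=0.78, rr_jitter=0.030),
    }
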