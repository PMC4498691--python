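"""Synthetic EHG-like records with a controllable term/preterm effect.

Real uterine EMG in the 0.3-3 Hz analysis band looks like 1/f-shaped
background activity with intermittent amplitude-modulated oscillatory
bursts (contraction surrogates).  The generator reproduces that structure:

* background: pink (1/f-shaped) noise band-passed to 0.3-3 Hz, plus a small
  wide-band floor so broadband content guarantees a deep IMF ladder;
* bursts: Hann-windowed sinusoidal carriers with sinusoidal amplitude
  modulation, carrier frequency and AM depth drawn from class-conditional
  ranges.

The class effect shifts the preterm burst-carrier distribution upward and
deepens/complicates its amplitude modulation, so it propagates into both the
instantaneous-frequency and instantaneous-amplitude entropies downstream.
``class_effect="none"`` makes the two label distributions identical (a
negative control); ``"strong"`` produces a cleanly separable cohort.

This is a statistical stand-in, not a physiological model: no propagation,
no electrode geometry, no gestation-dependent drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sps

from .signal_io import EHGRecord

__all__ = ["SynthConfig", "generate_record", "generate_cohort"]

Label = Literal["term", "preterm"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate a 30-min, 3-channel, 20 Hz record."""

    fs: float = 20.0
    duration_s: float = 1800.0
    n_channels: int = 3
    n_bursts: tuple[int, int] = (6, 12)          # uniform range per record
    burst_freq_hz: tuple[float, float] = (0.4, 1.0)   # term carrier range
    burst_am_depth: float = 0.25                  # term AM depth
    noise_sigma: float = 0.35                     # pink background RMS
    wideband_fraction: float = 0.06               # white floor vs pink RMS
    burst_amplitude: float = 1.0
    class_effect: Literal["none", "weak", "strong"] = "strong"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0 or self.n_channels < 1:
            raise ValueError("fs, duration_s and n_channels must be positive")
        if self.duration_s * self.fs < 4096:
            raise ValueError("record must have at least 4096 samples")
        lo, hi = self.burst_freq_hz
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError("burst frequencies must lie in (0, fs/2)")
        if self.class_effect not in ("none", "weak", "strong"):
            raise ValueError(f"unknown class_effect {self.class_effect!r}")

    def class_params(self, label: Label) -> tuple[tuple[float, float], float]:
        """(carrier range, AM depth) for a label under the configured effect."""
        if label == "term" or self.class_effect == "none":
            return self.burst_freq_hz, self.burst_am_depth
        lo, hi = self.burst_freq_hz
        if self.class_effect == "weak":
            return (lo + 0.3, hi + 0.4), min(self.burst_am_depth + 0.25, 1.0)
        return (lo + 1.1, hi + 1.6), min(self.burst_am_depth + 0.6, 1.0)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _channel(config: SynthConfig, label: Label, rng: np.random.Generator) -> np.ndarray:
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs

    sos = sps.butter(4, [0.3, 3.0], btype="bandpass", fs=config.fs, output="sos")
    noise = sps.sosfiltfilt(sos, _pink_noise(n, rng))
    noise = noise / noise.std() * config.noise_sigma
    # small broadband floor: keeps high-frequency IMFs populated
    noise = noise + rng.standard_normal(n) * (config.noise_sigma * config.wideband_fraction)

    (f_lo, f_hi), am_depth = config.class_params(label)
    x = noise.copy()
    n_bursts = int(rng.integers(config.n_bursts[0], config.n_bursts[1] + 1))
    burst_len = int(60 * config.fs)  # ~1 min contractions
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(n - burst_len, 1)))
        L = min(burst_len, n - start)
        tb = t[:L]
        carrier = np.sin(2 * np.pi * rng.uniform(f_lo, f_hi) * tb + rng.uniform(0, 2 * np.pi))
        am = 1.0 + am_depth * np.sin(2 * np.pi * rng.uniform(0.02, 0.08) * tb
                                     + rng.uniform(0, 2 * np.pi))
        if am_depth > 0.5:  # complex envelope for the high-effect class
            am += 0.5 * am_depth * np.sin(2 * np.pi * rng.uniform(0.1, 0.25) * tb
                                          + rng.uniform(0, 2 * np.pi))
        window = np.hanning(L)
        x[start:start + L] += config.burst_amplitude * window * am * carrier
    return x


def generate_record(
    config: SynthConfig, label: Label, record_id: str | None = None
) -> EHGRecord:
    """One synthetic multi-channel record; deterministic given (config, label)."""
    if label not in ("term", "preterm"):
        raise ValueError(f"label must be 'term' or 'preterm', got {label!r}")
    rng = np.random.default_rng([config.seed, 0 if label == "term" else 1])
    samples = np.vstack([_channel(config, label, rng) for _ in range(config.n_channels)])
    gestation = (
        float(rng.uniform(30.0, 36.9)) if label == "preterm"
        else float(rng.uniform(38.0, 41.5))
    )
    return EHGRecord(
        samples=samples,
        fs=config.fs,
        gestation_at_delivery=gestation,
        gestation_at_recording=float(rng.uniform(22.0, 33.0)),
        record_id=record_id or f"synth_{label}_{config.seed}",
    )


def generate_cohort(
    config: SynthConfig, n_term: int, n_preterm: int
) -> list[EHGRecord]:
    """A cohort with exactly the requested label counts.

    Per-record seeds are spawned from the master seed, so the cohort is
    reproducible and records are mutually independent.  The TPEHG-scale
    cohort is (262, 38).
    """
    if n_term < 0 or n_preterm < 0:
        raise ValueError("counts must be non-negative")
    from dataclasses import replace

    seeds = np.random.SeedSequence(config.seed).generate_state(n_term + n_preterm)
    records = []
    for i in range(n_term + n_preterm):
        label: Label = "term" if i < n_term else "preterm"
        sub = replace(config, seed=int(seeds[i] % (2**31)))
        records.append(generate_record(sub, label, record_id=f"synth_{label}_{i:04d}"))
    return records
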