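"""Reading, writing and preprocessing of EHG (uterine EMG) records.

Records follow the PhysioBank WFDB convention used by the TPEHG dataset:
a plain-text header (``.hea``) describing channels, sampling rate and
gestation metadata, plus a little-endian 16-bit signal file (``.dat``)
with per-channel gain/baseline scaling.  Only that subset of the WFDB
specification (format 16, single signal file, interleaved samples) is
supported here.

The analysis band for uterine EMG is 0.3-3 Hz: it carries the uterine
burst activity while excluding motion, respiration and maternal ECG
artifacts.  :func:`bandpass_filter` applies a zero-phase Butterworth
filter to that band by default.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "EHGRecord",
    "FilterSpec",
    "DEFAULT_FILTER",
    "read_wfdb_record",
    "write_wfdb_record",
    "bandpass_filter",
    "select_channel",
]

PRETERM_THRESHOLD_WEEKS = 37.0

#: Header comment keys recognized as gestation metadata (case-insensitive).
#: ``Gestation`` is the gestational age at delivery, ``Rectime`` the age at
#: recording, both in weeks -- the TPEHG naming.
_META_KEYS = {
    "gestation": "gestation_at_delivery",
    "rectime": "gestation_at_recording",
}


class WFDBFormatError(ValueError):
    """Header/signal inconsistency or unsupported WFDB feature."""


@dataclass
class EHGRecord:
    """A multi-channel uterine EMG recording.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, in physical units.
    fs
        Sampling rate in Hz (20 Hz for TPEHG-layout records).
    channel_names
        One label per channel.
    gestation_at_recording, gestation_at_delivery
        Gestational age in weeks, if known.
    record_id
        Free-form identifier, used in feature matrices and manifests.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    gestation_at_recording: Optional[float] = None
    gestation_at_delivery: Optional[float] = None
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.size == 0 or self.samples.shape[1] == 0:
            raise ValueError("record must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("one channel name required per channel")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def label(self) -> Optional[str]:
        """``"preterm"`` iff delivery occurred before 37 weeks, else ``"term"``.

        ``None`` when the gestational age at delivery is unknown.
        """
        if self.gestation_at_delivery is None:
            return None
        if self.gestation_at_delivery < PRETERM_THRESHOLD_WEEKS:
            return "preterm"
        return "term"


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification."""

    low_hz: float = 0.3
    high_hz: float = 3.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"upper edge {self.high_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


#: The TPEHG documentation describes the shipped 0.3-3 Hz channels as produced
#: by bidirectional (zero-phase) Butterworth filtering; this reproduces it.
DEFAULT_FILTER = FilterSpec()


# ---------------------------------------------------------------------------
# WFDB header + format-16 signal files
# ---------------------------------------------------------------------------

def write_wfdb_record(record: EHGRecord, path: str | os.PathLike) -> None:
    """Write ``record`` as a WFDB header (.hea) + format-16 signal (.dat) pair.

    ``path`` is the record path without extension.  Samples are quantized to
    16-bit integers with a per-channel gain; integer-valued signals within the
    int16 range round-trip bitwise.
    """
    path = os.fspath(path)
    name = os.path.basename(path)
    n_sig, n_samp = record.samples.shape

    gains = np.empty(n_sig)
    adc = np.empty((n_sig, n_samp), dtype="<i2")
    for c in range(n_sig):
        x = record.samples[c]
        if np.allclose(x, np.round(x)) and np.max(np.abs(x), initial=0) < 32767:
            gains[c] = 1.0
        else:
            peak = float(np.max(np.abs(x)))
            gains[c] = 32000.0 / peak if peak > 0 else 1.0
        adc[c] = np.round(x * gains[c]).astype("<i2")

    lines = [f"{name} {n_sig} {record.fs:g} {n_samp}"]
    for c in range(n_sig):
        lines.append(
            f"{name}.dat 16 {gains[c]:.12g}(0)/mV 16 0 {int(adc[c, 0])} 0 0 "
            f"{record.channel_names[c]}"
        )
    if record.gestation_at_delivery is not None:
        lines.append(f"# Gestation {record.gestation_at_delivery:g}")
    if record.gestation_at_recording is not None:
        lines.append(f"# Rectime {record.gestation_at_recording:g}")

    try:
        with open(path + ".hea", "w") as fh:
            fh.write("\n".join(lines) + "\n")
        # WFDB format 16: little-endian int16, samples interleaved by channel
        adc.T.tofile(path + ".dat")
    except OSError as exc:
        raise IOError(f"cannot write WFDB record at {path!r}: {exc}") from exc


_SIGNAL_LINE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)"
    r"(?:\s+(?P<gain>[-+0-9.eE]+)(?:\((?P<baseline>[-+0-9]+)\))?(?:/(?P<units>\S+))?)?"
    r"(?:\s+(?P<rest>.*))?$"
)


def read_wfdb_record(path: str | os.PathLike) -> EHGRecord:
    """Read a WFDB record (header + format-16 signal file).

    Gestation metadata is parsed from ``# Gestation`` / ``# Rectime`` comment
    lines when present; unknown comment keys are ignored.
    """
    path = os.fspath(path)
    hea = path if path.endswith(".hea") else path + ".hea"
    base = hea[: -len(".hea")]
    try:
        with open(hea) as fh:
            raw = [ln.strip() for ln in fh if ln.strip()]
    except OSError as exc:
        raise IOError(f"cannot read WFDB header {hea!r}: {exc}") from exc

    head = raw[0].split()
    if len(head) < 4:
        raise WFDBFormatError(f"malformed record line in {hea!r}: {raw[0]!r}")
    n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])

    gains: list[float] = []
    names: list[str] = []
    dat_file: Optional[str] = None
    meta: dict[str, float] = {}
    for line in raw[1:]:
        if line.startswith("#"):
            parts = line.lstrip("#").split()
            if len(parts) >= 2:
                key = _META_KEYS.get(parts[0].lower())
                if key is not None:
                    try:
                        meta[key] = float(parts[1])
                    except ValueError:
                        pass
            continue
        if len(gains) == n_sig:
            continue
        m = _SIGNAL_LINE.match(line)
        if m is None:
            raise WFDBFormatError(f"malformed signal line in {hea!r}: {line!r}")
        if int(m.group("fmt")) != 16:
            raise WFDBFormatError(
                f"unsupported WFDB format {m.group('fmt')} (only 16 supported)"
            )
        if dat_file is None:
            dat_file = m.group("file")
        elif m.group("file") != dat_file:
            raise WFDBFormatError("multi-file signal groups are not supported")
        gains.append(float(m.group("gain") or 200.0))
        rest = (m.group("rest") or "").split()
        names.append(rest[-1] if rest else f"ch{len(gains)}")
    if len(gains) != n_sig:
        raise WFDBFormatError(
            f"header declares {n_sig} signals but describes {len(gains)}"
        )

    dat_path = os.path.join(os.path.dirname(base) or ".", dat_file or "")
    try:
        adc = np.fromfile(dat_path, dtype="<i2")
    except OSError as exc:
        raise IOError(f"cannot read WFDB signal file {dat_path!r}: {exc}") from exc
    if adc.size != n_sig * n_samp:
        raise WFDBFormatError(
            f"signal file {dat_path!r} holds {adc.size} samples, "
            f"header declares {n_sig * n_samp}"
        )
    samples = adc.reshape(n_samp, n_sig).T.astype(float)
    samples /= np.asarray(gains)[:, None]

    return EHGRecord(
        samples=samples,
        fs=fs,
        channel_names=names,
        record_id=os.path.basename(base),
        **meta,
    )


# ---------------------------------------------------------------------------
# Filtering and channel selection
# ---------------------------------------------------------------------------

def bandpass_filter(
    x: Sequence[float], fs: float, spec: FilterSpec = DEFAULT_FILTER
) -> np.ndarray:
    """Butterworth band-pass; zero-phase (forward-backward) by default."""
    x = np.asarray(x, dtype=float)
    spec.validate(fs)
    if x.size <= 3 * spec.order:
        raise ValueError(
            f"signal too short ({x.size} samples) for an order-{spec.order} filter"
        )
    sos = sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def bandpass_gain(freq_hz: float, fs: float, spec: FilterSpec = DEFAULT_FILTER) -> float:
    """Magnitude response |H(f)| of the designed filter at ``freq_hz``.

    For the zero-phase (forward-backward) variant the effective gain is
    |H(f)|^2.
    """
    sos = sps.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    g = float(np.abs(h[0]))
    return g * g if spec.zero_phase else g


def select_channel(record: EHGRecord, channel_index: int) -> np.ndarray:
    """Return one channel's samples; ``channel_index`` is 1-based.

    Channel 3 of a TPEHG-layout record is the pair of electrodes below the
    navel, the placement with the best reported discrimination.
    """
    if not 1 <= channel_index <= record.n_channels:
        raise ValueError(
            f"channel_index {channel_index} out of range 1..{record.n_channels}"
        )
    return record.samples[channel_index - 1]
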