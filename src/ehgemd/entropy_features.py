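"""Shannon-entropy ratio features over IMF pairs.

For each record/channel, EMD yields the first ten IMFs; the Shannon entropy
of each IMF's instantaneous amplitude and instantaneous frequency gives
twenty entropy values E_amp(i), E_freq(i), i = 1..10.  The features are the
entropy ratios over all ordered pairs i != j:

    R_amp(i, j)  = E_amp(i)  / E_amp(j)
    R_freq(i, j) = E_freq(i) / E_freq(j)

90 amplitude ratios + 90 frequency ratios = 180 features per channel.
Because the features are ratios, the entropy log base cancels and the
feature vector is invariant to it.

Entropies are estimated with an equal-width histogram (default 100 bins over
[min, max]) on the boundary-trimmed ``valid_range`` of each track.  Ratio
ordering is fixed and documented: amplitude pairs first, row-major over
(i, j) with i != j, then frequency pairs; names ``A_i_j`` / ``F_i_j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .emd import SiftConfig, DEFAULT_SIFT, decompose
from .hilbert_spectral import AnalyticComponent, TooFewIMFsError, hilbert_all
from .signal_io import DEFAULT_FILTER, EHGRecord, FilterSpec, bandpass_filter, select_channel

__all__ = [
    "EntropyProfile",
    "FeatureVector",
    "FeatureMatrix",
    "N_IMF_COMPONENTS",
    "RATIO_CAP",
    "pair_order",
    "feature_names",
    "shannon_entropy",
    "entropy_profile",
    "entropy_ratio_features",
    "extract_features",
    "build_feature_matrix",
    "concat_channels",
]

log = logging.getLogger(__name__)

N_IMF_COMPONENTS = 10
DEFAULT_BIN_COUNT = 100
#: Sentinel magnitude for ratios with a zero-entropy denominator.
RATIO_CAP = 1e6

LogBase = Literal["natural", "base-2"]


def pair_order(n: int = N_IMF_COMPONENTS) -> list[tuple[int, int]]:
    """The fixed (i, j) enumeration: row-major, 1-based, diagonal excluded."""
    return [(i, j) for i in range(1, n + 1) for j in range(1, n + 1) if i != j]


def feature_names(n: int = N_IMF_COMPONENTS) -> list[str]:
    pairs = pair_order(n)
    return [f"A_{i}_{j}" for i, j in pairs] + [f"F_{i}_{j}" for i, j in pairs]


def shannon_entropy(
    values: Sequence[float],
    bin_count: int = DEFAULT_BIN_COUNT,
    log_base: LogBase = "natural",
) -> float:
    """Histogram Shannon entropy -sum p_k log p_k over non-empty bins.

    Equal-width bins span [min, max]; a constant input has a single-outcome
    distribution and entropy 0.  Because equal-width binning over [min, max]
    is scale-free, floating-point ripple on an otherwise constant track would
    otherwise masquerade as structure, so a track whose total spread is below
    ``1e-9`` of its magnitude is treated as constant.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot compute entropy of an empty sequence")
    if bin_count < 1:
        raise ValueError("bin_count must be >= 1")
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi - lo <= 1e-9 * max(abs(lo), abs(hi)):
        return 0.0
    counts, _ = np.histogram(v, bins=bin_count, range=(lo, hi))
    p = counts[counts > 0] / v.size
    h = -float(np.sum(p * np.log(p)))
    if log_base == "base-2":
        h /= np.log(2.0)
    return h


@dataclass
class EntropyProfile:
    """Per-IMF entropies of instantaneous amplitude and frequency."""

    e_amplitude: np.ndarray  # E_amp(i), i = 1..10
    e_frequency: np.ndarray  # E_freq(i)
    bin_count: int = DEFAULT_BIN_COUNT
    log_base: LogBase = "natural"


def entropy_profile(
    components: list[AnalyticComponent],
    bin_count: int = DEFAULT_BIN_COUNT,
    log_base: LogBase = "natural",
) -> EntropyProfile:
    """Twenty entropy values from the first ten analytic components."""
    if len(components) != N_IMF_COMPONENTS:
        raise ValueError(
            f"expected exactly {N_IMF_COMPONENTS} components, got {len(components)}"
        )
    e_amp = np.array(
        [shannon_entropy(c.amplitude[c.valid_range], bin_count, log_base) for c in components]
    )
    e_freq = np.array(
        [shannon_entropy(c.frequency[c.valid_range], bin_count, log_base) for c in components]
    )
    return EntropyProfile(e_amp, e_freq, bin_count, log_base)


@dataclass
class FeatureVector:
    """The 180 entropy-ratio features for one record/channel."""

    r_amplitude: np.ndarray  # 90 ordered-pair ratios
    r_frequency: np.ndarray
    record_id: str = "record"
    channel_index: int = 3
    capped: bool = False  # any ratio hit the zero-denominator sentinel

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.r_amplitude, self.r_frequency])

    @property
    def names(self) -> list[str]:
        return feature_names()


def _ratios(e: np.ndarray) -> tuple[np.ndarray, bool]:
    out = np.empty(len(pair_order()))
    capped = False
    for k, (i, j) in enumerate(pair_order()):
        num, den = e[i - 1], e[j - 1]
        if den == 0.0:
            out[k] = RATIO_CAP if num >= 0 else -RATIO_CAP
            capped = True
        else:
            r = num / den
            if abs(r) > RATIO_CAP:
                r = np.sign(r) * RATIO_CAP
                capped = True
            out[k] = r
    return out, capped


def entropy_ratio_features(profile: EntropyProfile) -> FeatureVector:
    """All 90+90 ordered-pair entropy ratios (diagonal excluded).

    A zero-entropy denominator would make the ratio undefined; such features
    are set to the sentinel ``RATIO_CAP`` and the vector flagged, so a
    degenerate track cannot silently poison a feature matrix.
    """
    r_amp, c1 = _ratios(np.asarray(profile.e_amplitude, dtype=float))
    r_freq, c2 = _ratios(np.asarray(profile.e_frequency, dtype=float))
    return FeatureVector(r_amp, r_freq, capped=c1 or c2)


def extract_features(
    record: EHGRecord,
    channel_index: int = 3,
    sift: SiftConfig = DEFAULT_SIFT,
    bin_count: int = DEFAULT_BIN_COUNT,
    log_base: LogBase = "natural",
    filter_spec: Optional[FilterSpec] = DEFAULT_FILTER,
) -> FeatureVector:
    """Full single-channel pipeline: filter, EMD, Hilbert, entropy ratios.

    Pass ``filter_spec=None`` for records whose channels are already
    band-limited (e.g. the dataset's shipped 0.3-3 Hz signals).
    Raises :class:`TooFewIMFsError` if the decomposition yields fewer than
    ten IMFs; cohort-level handling (skip + report) lives in
    :func:`build_feature_matrix`.
    """
    x = select_channel(record, channel_index)
    if filter_spec is not None:
        x = bandpass_filter(x, record.fs, filter_spec)
    dec = decompose(x, sift)
    comps = hilbert_all(dec, record.fs, N_IMF_COMPONENTS)
    fv = entropy_ratio_features(entropy_profile(comps, bin_count, log_base))
    fv.record_id = record.record_id
    fv.channel_index = channel_index
    return fv


@dataclass
class FeatureMatrix:
    """Feature rows with aligned labels, ids and origin flags."""

    data: np.ndarray                     # (n_records, n_features)
    labels: list[str]                    # "term" / "preterm" per row
    feature_names: list[str]
    record_ids: list[str]
    origin: list[str] = field(default_factory=list)   # "original" / "synthetic"
    skipped: list[dict] = field(default_factory=list)  # skip report

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.origin:
            self.origin = ["original"] * self.data.shape[0]
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.record_ids) == len(self.origin) == n):
            raise ValueError("labels/record_ids/origin must align with rows")
        if self.data.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must align with columns")

    @property
    def n_records(self) -> int:
        return self.data.shape[0]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=self.feature_names)
        df.insert(0, "record_id", self.record_ids)
        df.insert(1, "label", self.labels)
        df.insert(2, "origin", self.origin)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        meta = [c for c in ("record_id", "label", "origin") if c in df.columns]
        feat_cols = [c for c in df.columns if c not in meta]
        return cls(
            data=df[feat_cols].to_numpy(dtype=float),
            labels=list(df["label"].astype(str)),
            feature_names=feat_cols,
            record_ids=list(df["record_id"].astype(str)) if "record_id" in meta
            else [f"r{i}" for i in range(len(df))],
            origin=list(df["origin"].astype(str)) if "origin" in meta else [],
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))


def build_feature_matrix(
    records: Sequence[EHGRecord],
    channel_index: int = 3,
    sift: SiftConfig = DEFAULT_SIFT,
    bin_count: int = DEFAULT_BIN_COUNT,
    log_base: LogBase = "natural",
    filter_spec: Optional[FilterSpec] = DEFAULT_FILTER,
) -> FeatureMatrix:
    """Feature matrix over a cohort; records with < 10 IMFs are skipped.

    Row order follows the input order of surviving records; every skipped
    record appears in the ``skipped`` report with its IMF count.
    """
    rows, labels, ids, skipped = [], [], [], []
    for rec in records:
        try:
            fv = extract_features(
                rec, channel_index, sift, bin_count, log_base, filter_spec
            )
        except TooFewIMFsError as exc:
            log.warning(
                "skipping record %s: only %d IMFs (need %d)",
                rec.record_id, exc.available, exc.requested,
            )
            skipped.append(
                {"record_id": rec.record_id, "imf_count": exc.available,
                 "reason": "too_few_imfs"}
            )
            continue
        rows.append(fv.values)
        labels.append(rec.label or "unknown")
        ids.append(rec.record_id)
    if not rows:
        raise ValueError("all records were skipped; no feature matrix to build")
    return FeatureMatrix(
        data=np.vstack(rows),
        labels=labels,
        feature_names=[f"ch{channel_index}_{n}" for n in feature_names()],
        record_ids=ids,
        skipped=skipped,
    )


def concat_channels(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-concatenate per-channel matrices of the same records.

    Three TPEHG channels give 3 x 180 = 540 features per record.  Only
    records surviving extraction in every channel are kept.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    common = set(matrices[0].record_ids)
    for m in matrices[1:]:
        common &= set(m.record_ids)
    if not common:
        raise ValueError("no record survives extraction in all channels")
    base_ids = [r for r in matrices[0].record_ids if r in common]
    blocks, names = [], []
    for m in matrices:
        idx = [m.record_ids.index(r) for r in base_ids]
        blocks.append(m.data[idx])
        names.extend(m.feature_names)
    first = matrices[0]
    lab_of = dict(zip(first.record_ids, first.labels))
    skipped = [s for m in matrices for s in m.skipped]
    return FeatureMatrix(
        data=np.hstack(blocks),
        labels=[lab_of[r] for r in base_ids],
        feature_names=names,
        record_ids=base_ids,
        skipped=skipped,
    )
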