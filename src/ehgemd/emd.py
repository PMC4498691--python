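"""Empirical mode decomposition by sifting.

EMD adaptively decomposes a signal x(t) into a small number of intrinsic
mode functions (IMFs) plus a residue:

    x(t) = sum_i IMF_i(t) + r(t)

An IMF is an oscillation whose numbers of extrema and zero crossings differ
by at most one and whose upper/lower envelope mean is near zero.  Each IMF
is extracted by *sifting*: repeatedly subtracting the mean of the cubic
spline envelopes through the local maxima and minima until the Rilling
stopping criterion holds.  IMFs come out ordered from high to low frequency;
sifting the running residue extracts the next one until the residue is
monotone (fewer than three interior extrema).

Completeness is exact by construction: each residue is formed by direct
subtraction, so the IMFs plus final residue telescope back to the input to
floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SiftConfig",
    "IMFDecomposition",
    "find_extrema",
    "envelope_mean",
    "sift_imf",
    "decompose",
]


@dataclass(frozen=True)
class SiftConfig:
    """Sifting parameters (Rilling-style stopping criterion).

    The criterion evaluates sigma(t) = |envelope mean| / envelope amplitude
    and accepts the candidate IMF when sigma < ``theta1`` on at least a
    fraction ``1 - alpha`` of samples and sigma < ``theta2`` everywhere.
    Defaults are the conventional (0.05, 0.5, 0.05).
    """

    theta1: float = 0.05
    theta2: float = 0.5
    alpha: float = 0.05
    max_sift_iterations: int = 100
    max_imfs: int = 14
    boundary_extension: int = 2  # extrema mirrored beyond each end

    def __post_init__(self) -> None:
        if not 0 < self.theta1 < self.theta2:
            raise ValueError("need 0 < theta1 < theta2")
        if not 0 <= self.alpha < 1:
            raise ValueError("need 0 <= alpha < 1")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")


DEFAULT_SIFT = SiftConfig()


@dataclass
class IMFDecomposition:
    """Ordered IMFs (high to low frequency) plus the final residue."""

    imfs: list[np.ndarray] = field(default_factory=list)
    residue: np.ndarray = field(default_factory=lambda: np.empty(0))
    source_length: int = 0

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(x: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Locate strictly interior local maxima and minima.

    Returns ``(max_pos, max_val, min_pos, min_val)``.  A flat plateau that is
    a local extremum is reported once, at its midpoint (rounded down).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        e = np.empty(0, dtype=int)
        return e, np.empty(0), e.copy(), np.empty(0)
    s = np.sign(np.diff(x))
    nz = np.flatnonzero(s)
    if nz.size < 2:
        e = np.empty(0, dtype=int)
        return e, np.empty(0), e.copy(), np.empty(0)
    a, b = nz[:-1], nz[1:]
    mid = (a + 1 + b) // 2  # plateau a+1..b collapses to its midpoint
    is_max = (s[a] > 0) & (s[b] < 0)
    is_min = (s[a] < 0) & (s[b] > 0)
    max_pos = mid[is_max]
    min_pos = mid[is_min]
    return max_pos, x[max_pos], min_pos, x[min_pos]


def count_zero_crossings(x: np.ndarray) -> int:
    x = np.asarray(x, dtype=float)
    s = np.sign(x)
    s = s[s != 0]  # exact zeros join the neighbouring segment
    return int(np.count_nonzero(np.diff(s)))


def _mirror(pos: np.ndarray, val: np.ndarray, n: int, nb: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to ``nb`` extrema beyond each end of the index range [0, n-1]."""
    kl = min(nb, pos.size)
    kr = min(nb, pos.size)
    lp = -pos[:kl][::-1]
    lv = val[:kl][::-1]
    rp = 2 * (n - 1) - pos[-kr:][::-1]
    rv = val[-kr:][::-1]
    return np.concatenate([lp, pos, rp]), np.concatenate([lv, val, rv])


def _envelope(pos: np.ndarray, val: np.ndarray, n: int, nb: int) -> np.ndarray:
    pos, val = _mirror(pos, val, n, nb)
    # mirroring can duplicate knots when an extremum sits on a boundary
    pos, keep = np.unique(pos, return_index=True)
    val = val[keep]
    t = np.arange(n)
    if pos.size >= 4:
        return CubicSpline(pos, val, bc_type="natural")(t)
    return np.interp(t, pos, val)


class TooFewExtremaError(ValueError):
    """Raised when a signal has too few extrema to build both envelopes
    (monotone-residue condition)."""


def envelope_mean(
    x: Sequence[float],
    max_pos: np.ndarray,
    max_val: np.ndarray,
    min_pos: np.ndarray,
    min_val: np.ndarray,
    config: SiftConfig = DEFAULT_SIFT,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and half-width of the cubic-spline extrema envelopes.

    Returns ``(mean, amplitude)`` where ``mean = (upper + lower) / 2`` and
    ``amplitude = (upper - lower) / 2``, both full signal length.
    """
    x = np.asarray(x, dtype=float)
    if max_pos.size < 2 or min_pos.size < 2:
        raise TooFewExtremaError(
            f"need >= 2 maxima and >= 2 minima, got {max_pos.size}/{min_pos.size}"
        )
    upper = _envelope(max_pos, max_val, x.size, config.boundary_extension)
    lower = _envelope(min_pos, min_val, x.size, config.boundary_extension)
    return (upper + lower) / 2.0, (upper - lower) / 2.0


def sift_imf(
    x: Sequence[float], config: SiftConfig = DEFAULT_SIFT
) -> tuple[np.ndarray, bool]:
    """Extract one IMF from ``x`` by iterative envelope-mean subtraction.

    Iterates d <- d - m(d) until the Rilling criterion holds or the iteration
    budget is exhausted; non-convergence is reported via the boolean flag,
    never an exception.
    """
    d = np.asarray(x, dtype=float).copy()
    tiny = np.finfo(float).tiny
    for _ in range(config.max_sift_iterations):
        mx_p, mx_v, mn_p, mn_v = find_extrema(d)
        if mx_p.size < 2 or mn_p.size < 2:
            return d, True  # nothing left to sift
        mean, amp = envelope_mean(d, mx_p, mx_v, mn_p, mn_v, config)
        sigma = np.abs(mean) / np.maximum(np.abs(amp), tiny)
        zc = count_zero_crossings(d)
        n_ext = mx_p.size + mn_p.size
        if (
            np.mean(sigma > config.theta1) < config.alpha
            and np.all(sigma < config.theta2)
            and abs(n_ext - zc) <= 1
        ):
            return d, True
        d -= mean
    return d, False


def decompose(
    x: Sequence[float], config: SiftConfig = DEFAULT_SIFT
) -> IMFDecomposition:
    """Full EMD of ``x``: extract IMFs until the residue is monotone.

    Termination: the residue has fewer than 3 interior extrema (further
    sifting would yield no oscillatory component) or ``max_imfs`` is reached.
    A constant or monotone input yields zero IMFs with residue equal to the
    input.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError(f"signal too short for EMD ({x.size} samples)")
    residue = x.copy()
    out = IMFDecomposition(source_length=x.size)
    while len(out.imfs) < config.max_imfs:
        mx_p, _, mn_p, _ = find_extrema(residue)
        if mx_p.size + mn_p.size < 3:
            break
        imf, _converged = sift_imf(residue, config)
        out.imfs.append(imf)
        residue = residue - imf
    out.residue = residue
    return out


def crossing_rate(x: np.ndarray) -> float:
    """Zero crossings per sample; decreases from IMF_1 to IMF_n."""
    return count_zero_crossings(x) / max(len(x), 1)
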