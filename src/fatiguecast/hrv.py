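"""Inter-beat-interval cleaning and Poincaré heart-rate-variability metrics.

All dispersion statistics use the population (divide-by-n) convention so that
small hand-computed examples are exact.  SDNN is the population SD of the
inter-beat intervals; SD1 and SD2 are the population SDs of the distances of
consecutive-IBI pairs to the -45 and +45 degree lines of the Poincaré plot.
Under this convention SD1 equals the population SD of successive differences
(SDSD) divided by sqrt(2) exactly; the classical RMSSD omits the
mean-difference centering and agrees with SDSD only approximately (the mean
successive difference of a stationary beat series is near zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FatiguecastError, InsufficientDataError, ParameterError

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class HRVMetrics:
    """Poincaré summary of one cleaned IBI window, in milliseconds."""

    sdnn: float
    sd1: float
    sd2: float


class WindowRejected(FatiguecastError):
    """A 5-min IBI window failed the artifact or beat-count rules."""


def _pop_sd(x: np.ndarray) -> float:
    return float(np.std(np.asarray(x, dtype=float)))


def sdnn(ibis) -> float:
    """Population SD of the IBIs (overall variability), ms."""
    return _pop_sd(ibis)


def sdsd(ibis) -> float:
    """Population SD of successive IBI differences, ms."""
    d = np.diff(np.asarray(ibis, dtype=float))
    return float(np.std(d))


def rmssd(ibis) -> float:
    """Root-mean-square of successive differences (classical definition)."""
    d = np.diff(np.asarray(ibis, dtype=float))
    return float(np.sqrt(np.mean(d * d)))


def poincare_metrics(ibis, min_ibis: int = 10) -> HRVMetrics:
    """SDNN / SD1 / SD2 of a cleaned IBI list.

    For consecutive pairs (x_i, x_{i+1}), SD1 is the population SD of the
    signed perpendicular distances (x - y)/sqrt(2) to the identity line
    (short-term, parasympathetically driven variability) and SD2 the
    population SD of the along-line coordinate (x + y)/sqrt(2) (long-term
    variability).

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_ibis`` intervals are supplied.
    """
    x = np.asarray(ibis, dtype=float)
    if x.size < min_ibis:
        raise InsufficientDataError(
            f"need >= {min_ibis} IBIs for Poincaré metrics, got {x.size}")
    if np.any(x <= 0):
        raise ParameterError("IBIs must be strictly positive")
    a, b = x[:-1], x[1:]
    sd1 = _pop_sd((a - b) / _SQRT2)
    sd2 = _pop_sd((a + b) / _SQRT2)
    return HRVMetrics(sdnn=_pop_sd(x), sd1=sd1, sd2=sd2)


def flag_artifacts(ibis, dev_fraction: float = 0.25) -> np.ndarray:
    """Boolean artifact flags using a Malik-style running-median rule.

    An IBI is an artifact when it deviates by more than ``dev_fraction``
    (relative) from the median of the up to 5 preceding *accepted* IBIs.
    The first interval is always accepted (no history to judge it against).
    Accepted history excludes artifacts, so a missed-beat doubling does not
    poison the reference for its neighbours.
    """
    x = np.asarray(ibis, dtype=float)
    flags = np.zeros(x.size, dtype=bool)
    if x.size < 2:
        return flags
    # fast path: when no beat deviates from the median of its 5 *raw*
    # predecessors, the sequential rule (whose accepted history then equals
    # the raw history) flags nothing either
    from statistics import median
    if x.size > 6:
        from numpy.lib.stride_tricks import sliding_window_view
        refs = np.median(sliding_window_view(x[:-1], 5), axis=1)
        ok = bool(np.all(np.abs(x[5:] - refs) <= dev_fraction * refs))
        if ok:
            for i in range(1, 5):
                ref = median(x[:i].tolist())
                if abs(x[i] - ref) > dev_fraction * ref:
                    ok = False
                    break
        if ok:
            return flags
    accepted: list[float] = []
    for i, v in enumerate(x):
        if accepted:
            ref = median(accepted[-5:])
            if abs(v - ref) > dev_fraction * ref:
                flags[i] = True
                continue
        accepted.append(v)
    return flags


def clean_with_flags(ibis, dev_fraction: float = 0.25,
                     max_interpolated: int = 3,
                     min_ibis: int = 10) -> tuple[np.ndarray, int]:
    """Like :func:`clean_ibi_window`, also returning the number of
    interpolated beats."""
    x = np.asarray(ibis, dtype=float)
    if x.size < min_ibis:
        raise WindowRejected(
            f"only {x.size} IBIs in window (< {min_ibis})")
    flags = flag_artifacts(x, dev_fraction)
    n_bad = int(flags.sum())
    if n_bad > max_interpolated:
        raise WindowRejected(
            f"{n_bad} artifact IBIs (> {max_interpolated} allowed)")
    if n_bad == 0:
        return x.copy(), 0
    good = ~flags
    idx = np.arange(x.size)
    cleaned = x.copy()
    cleaned[flags] = np.interp(idx[flags], idx[good], x[good])
    return cleaned, n_bad


def clean_ibi_window(ibis, dev_fraction: float = 0.25,
                     max_interpolated: int = 3,
                     min_ibis: int = 10) -> np.ndarray:
    """Replace artifact IBIs by linear interpolation, or reject the window.

    Raises :class:`WindowRejected` if the window holds fewer than
    ``min_ibis`` beats or needs more than ``max_interpolated``
    interpolations (i.e. >= 4 artifacts at the defaults).  Artifact-free
    windows are returned unchanged (a copy).
    """
    return clean_with_flags(ibis, dev_fraction, max_interpolated,
                            min_ibis)[0]
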