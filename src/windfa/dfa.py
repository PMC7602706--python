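"""Classical detrended fluctuation analysis (DFA).

The estimator proceeds in three steps, each exposed as a separate
function so that intermediate results can be inspected and tested:

1. :func:`build_profile` — cumulative sum of the mean-centered signal
   (the "random walk" representation).
2. :func:`fluctuation_function` — the profile is cut into non-overlapping
   segments of length ``n``, each segment is detrended by a least-squares
   polynomial fit, and the root-mean-square residual ``F(n)`` is computed
   over the covered samples.
3. :func:`fit_scaling_exponent` — ``F(n) ~ n**alpha``; ``alpha`` is the
   slope of ``lg F`` versus ``lg n`` over a chosen fit range
   (base-10 logarithms throughout).

:func:`dfa` composes the three.  ``alpha = 0.5`` indicates an
uncorrelated signal, ``0.5 < alpha < 1`` persistent power-law
correlations, ``alpha < 0.5`` anti-persistence, and ``alpha > 1``
non-power-law persistent behaviour (e.g. an integrated process).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawSignal",
    "FluctuationCurve",
    "ScalingFit",
    "build_profile",
    "default_scales",
    "fluctuation_function",
    "fit_scaling_exponent",
    "dfa",
]


@dataclass(frozen=True)
class RawSignal:
    """A single-channel signal with an optional sampling rate.

    Parameters
    ----------
    samples : ndarray
        One-dimensional array of finite values.
    sampling_rate : float, optional
        Samples per second; only required by time-aware consumers
        (sliding-window analysis, epoching).
    """

    samples: np.ndarray
    sampling_rate: float | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError(f"signal must be 1-D, got shape {samples.shape}")
        if samples.size < 2:
            raise ValueError(f"signal must hold at least 2 samples, got {samples.size}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate is not None and self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class FluctuationCurve:
    """``F(n)`` evaluated on a strictly increasing integer scale grid."""

    scales: np.ndarray
    fluctuations: np.ndarray
    detrend_order: int = 1

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=int)
        fluct = np.asarray(self.fluctuations, dtype=float)
        if scales.ndim != 1 or fluct.ndim != 1 or scales.size != fluct.size:
            raise ValueError("scales and fluctuations must be 1-D of equal length")
        if scales.size and np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be strictly increasing")
        if np.any(fluct < 0):
            raise ValueError("fluctuations must be non-negative")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "fluctuations", fluct)


@dataclass(frozen=True)
class ScalingFit:
    """Result of the log-log linear fit of a fluctuation curve.

    ``alpha`` is NaN when the fit is degenerate (all-zero fluctuations
    from a constant input signal).
    """

    alpha: float
    intercept: float
    fit_range: tuple[float, float]
    residual_rms: float
    n_points: int = field(default=0)


def build_profile(signal: RawSignal | np.ndarray) -> np.ndarray:
    """Cumulative sum of the mean-centered signal.

    The final profile value is zero up to floating-point error.
    """
    x = signal.samples if isinstance(signal, RawSignal) else np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"signal must be 1-D, got shape {x.shape}")
    if x.size < 2:
        raise ValueError(f"need at least 2 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return np.cumsum(x - x.mean())


def default_scales(n_samples: int, n_min: int = 8, n_max: int | None = None,
                   num: int = 12) -> np.ndarray:
    """Log-spaced integer scale grid in ``[n_min, n_max]``.

    ``n_max`` defaults to ``n_samples // 4``.  Duplicate integers arising
    from rounding are dropped.
    """
    if n_max is None:
        n_max = n_samples // 4
    if n_max < n_min:
        raise ValueError(f"n_max={n_max} < n_min={n_min} (signal too short)")
    grid = np.unique(np.round(np.logspace(np.log10(n_min), np.log10(n_max), num)).astype(int))
    return grid


def _segment_residual_sq(profile: np.ndarray, n: int, order: int,
                         from_end: bool = False) -> tuple[float, int]:
    """Sum of squared detrending residuals over segments of length ``n``.

    Returns ``(sum_sq, covered)`` where ``covered`` is the number of
    samples included (``(N // n) * n``).
    """
    n_seg = profile.size // n
    if from_end:
        y = profile[profile.size - n_seg * n:]
    else:
        y = profile[: n_seg * n]
    y = y.reshape(n_seg, n)
    t = np.arange(n, dtype=float)
    # shared Vandermonde design: trend fit is identical least squares per segment
    design = np.vander(t, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    resid = y.T - design @ coef
    return float(np.sum(resid ** 2)), n_seg * n


def fluctuation_function(profile: np.ndarray, scales: np.ndarray | None = None,
                         detrend_order: int = 1, *,
                         both_ends: bool = False) -> FluctuationCurve:
    """RMS detrending residual ``F(n)`` per scale ``n``.

    Parameters
    ----------
    profile : ndarray
        Output of :func:`build_profile`.
    scales : array of int, optional
        Strictly increasing segment lengths; defaults to
        :func:`default_scales`.
    detrend_order : int
        Polynomial order of the per-segment trend fit (1 = linear).
    both_ends : bool
        When the profile length is not a multiple of ``n``, the default
        segments from the start and discards the tail.  ``both_ends=True``
        additionally segments from the end and averages both passes, so no
        sample is ever discarded.
    """
    profile = np.asarray(profile, dtype=float)
    N = profile.size
    if scales is None:
        scales = default_scales(N)
    scales = np.asarray(scales, dtype=int)
    if scales.size == 0:
        raise ValueError("empty scale grid")
    if np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly increasing")
    if detrend_order < 0:
        raise ValueError("detrend_order must be non-negative")
    lo, hi = int(scales[0]), int(scales[-1])
    if lo < detrend_order + 2:
        raise ValueError(f"smallest scale {lo} < detrend_order + 2 = {detrend_order + 2}")
    if hi > N // 2:
        raise ValueError(f"largest scale {hi} exceeds N//2 = {N // 2}")

    fluct = np.empty(scales.size)
    for i, n in enumerate(scales):
        ss, covered = _segment_residual_sq(profile, int(n), detrend_order)
        if both_ends:
            ss2, covered2 = _segment_residual_sq(profile, int(n), detrend_order, from_end=True)
            ss, covered = ss + ss2, covered + covered2
        fluct[i] = np.sqrt(ss / covered)
    return FluctuationCurve(scales=scales, fluctuations=fluct, detrend_order=detrend_order)


def fit_scaling_exponent(curve: FluctuationCurve,
                         fit_range: tuple[float, float] | None = None) -> ScalingFit:
    """Least-squares slope of ``lg F`` vs ``lg n`` inside ``fit_range``.

    ``fit_range`` is given as ``(lg n_min, lg n_max)`` inclusive; it
    defaults to the full scale grid.  Scales with ``F(n) = 0`` are
    excluded with a warning.  At least 3 usable points are required,
    except in the fully degenerate all-zero case where ``alpha`` is NaN.
    """
    lg_n = np.log10(curve.scales.astype(float))
    if fit_range is None:
        fit_range = (float(lg_n[0]), float(lg_n[-1]))
    lo, hi = fit_range
    in_range = (lg_n >= lo - 1e-12) & (lg_n <= hi + 1e-12)
    f = curve.fluctuations
    zero = in_range & (f <= 0)
    if np.all(f[in_range] <= 0) and np.any(in_range):
        # constant signal: F(n) == 0 everywhere, exponent undefined
        return ScalingFit(alpha=float("nan"), intercept=float("nan"),
                          fit_range=(lo, hi), residual_rms=0.0, n_points=0)
    if np.any(zero):
        warnings.warn(f"excluding {int(zero.sum())} scale(s) with F(n)=0 from the fit",
                      stacklevel=2)
    usable = in_range & (f > 0)
    if usable.sum() < 3:
        raise ValueError(f"need >= 3 usable scales inside fit range, got {int(usable.sum())}")
    x = lg_n[usable]
    y = np.log10(f[usable])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return ScalingFit(alpha=float(slope), intercept=float(intercept),
                      fit_range=(float(lo), float(hi)),
                      residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                      n_points=int(usable.sum()))


def dfa(signal: RawSignal | np.ndarray, scales: np.ndarray | None = None,
        detrend_order: int = 1, fit_range: tuple[float, float] | None = None,
        *, both_ends: bool = False) -> ScalingFit:
    """Profile construction, fluctuation function and log-log fit in one call.

    For full-length signals with a default grid the fit range defaults to
    ``lg n >= 1.2`` (long-range scales); pass ``fit_range`` explicitly to
    override.
    """
    x = signal.samples if isinstance(signal, RawSignal) else np.asarray(signal, dtype=float)
    if x.size and np.ptp(x) == 0:
        # constant signal: F(n) = 0 for all n, exponent undefined
        lo, hi = fit_range if fit_range is not None else (float("nan"), float("nan"))
        return ScalingFit(alpha=float("nan"), intercept=float("nan"),
                          fit_range=(lo, hi), residual_rms=0.0, n_points=0)
    profile = build_profile(signal)
    if scales is None and fit_range is None:
        scales = default_scales(profile.size)
        fit_range = (max(1.2, np.log10(scales[0])), float(np.log10(scales[-1])))
    curve = fluctuation_function(profile, scales, detrend_order, both_ends=both_ends)
    return fit_scaling_exponent(curve, fit_range)
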