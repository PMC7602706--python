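"""Time-resolved DFA: the scaling exponent over a floating window.

A window of ``window_len`` samples slides along the signal in steps of
``step`` samples; DFA is applied to each excerpt in isolation, yielding a
trajectory ``alpha(t)``.  Each alpha value is attributed to the window's
anchor time (start, center or end of the window).

The per-window computation is vectorised across windows: the trend-fit
design matrix depends only on the scale, so detrending all windows at a
given scale is a single batched least-squares solve.  The result is
numerically identical to calling :func:`windfa.dfa.dfa` on each excerpt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dfa import RawSignal, default_scales

__all__ = ["AlphaTrajectory", "sliding_alpha", "max_alpha_jump"]

_ANCHORS = ("start", "center", "end")

# below ~100 samples the upper fit scales (lg n ~ 2) are unavailable and
# the per-window fit error grows quickly
MIN_RECOMMENDED_WINDOW = 100


@dataclass(frozen=True)
class AlphaTrajectory:
    """``alpha`` as a function of floating-window position.

    ``times`` are anchor times in seconds, strictly increasing with
    constant spacing ``step / sampling_rate``.
    """

    times: np.ndarray
    alphas: np.ndarray
    window_len: int
    step: int
    anchor: str = "center"
    dfa_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        alphas = np.asarray(self.alphas, dtype=float)
        if times.shape != alphas.shape or times.ndim != 1:
            raise ValueError("times and alphas must be 1-D of equal length")
        if self.anchor not in _ANCHORS:
            raise ValueError(f"anchor must be one of {_ANCHORS}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "alphas", alphas)

    def __len__(self) -> int:
        return self.times.size


def _window_scales(window_len: int, scales: np.ndarray | None) -> np.ndarray:
    if scales is not None:
        return np.asarray(scales, dtype=int)
    # n in [8, W // 4]; for W = 500 this spans lg n in [0.9, ~2.1]
    return default_scales(window_len, n_min=8, n_max=window_len // 4)


def sliding_alpha(signal: RawSignal | np.ndarray,
                  window_len: int = 500,
                  step: int = 25,
                  *,
                  sampling_rate: float | None = None,
                  scales: np.ndarray | None = None,
                  detrend_order: int = 1,
                  fit_range: tuple[float, float] | None = None,
                  anchor: str = "center") -> AlphaTrajectory:
    """Evaluate the DFA exponent over a sliding window.

    Parameters
    ----------
    signal : RawSignal or ndarray
        The input series.  ``sampling_rate`` is taken from the
        ``RawSignal`` when not given explicitly; without a rate the
        trajectory times are expressed in samples.
    window_len, step : int
        Window length and hop, in samples.  The trajectory holds
        ``(N - window_len) // step + 1`` values.
    scales, detrend_order, fit_range
        Per-window DFA parameters; the scale grid defaults to log-spaced
        ``n`` in ``[8, window_len // 4]`` and the fit range to the whole
        grid.
    anchor : {'start', 'center', 'end'}
        Which point of the window each alpha is attributed to.
    """
    if isinstance(signal, RawSignal):
        if sampling_rate is None:
            sampling_rate = signal.sampling_rate
        x = signal.samples
    else:
        x = np.asarray(signal, dtype=float)
    N = x.size
    if window_len > N:
        raise ValueError(f"window_len={window_len} exceeds signal length {N}")
    if window_len < MIN_RECOMMENDED_WINDOW:
        warnings.warn(
            f"window_len={window_len} < {MIN_RECOMMENDED_WINDOW} samples: "
            "fit error on the upper scales will be large", stacklevel=2)
    if step < 1:
        raise ValueError("step must be >= 1")
    if anchor not in _ANCHORS:
        raise ValueError(f"anchor must be one of {_ANCHORS}")

    grid = _window_scales(window_len, scales)
    if grid[-1] > window_len // 2:
        raise ValueError(f"largest scale {grid[-1]} exceeds window_len//2")
    if fit_range is None:
        fit_range = (float(np.log10(grid[0])), float(np.log10(grid[-1])))

    windows = np.lib.stride_tricks.sliding_window_view(x, window_len)[::step]
    n_win = windows.shape[0]

    # profiles: per-window cumulative sum of the mean-centered excerpt
    profiles = np.cumsum(windows - windows.mean(axis=1, keepdims=True), axis=1)

    log_f = np.full((n_win, grid.size), -np.inf)
    for j, n in enumerate(grid):
        n = int(n)
        n_seg = window_len // n
        covered = n_seg * n
        seg = profiles[:, :covered].reshape(n_win, n_seg, n)
        t = np.arange(n, dtype=float)
        design = np.vander(t, detrend_order + 1, increasing=True)
        pinv = np.linalg.pinv(design)
        coef = seg @ pinv.T
        resid = seg - coef @ design.T
        ss = np.einsum("wsn,wsn->w", resid, resid)
        with np.errstate(divide="ignore"):
            log_f[:, j] = 0.5 * np.log10(ss / covered)

    lg_n = np.log10(grid.astype(float))
    lo, hi = fit_range
    mask = (lg_n >= lo - 1e-12) & (lg_n <= hi + 1e-12)
    if mask.sum() < 3:
        raise ValueError("fit range must contain at least 3 scales")
    xs = lg_n[mask]
    ys = log_f[:, mask]
    x_c = xs - xs.mean()
    denom = np.sum(x_c ** 2)
    with np.errstate(invalid="ignore"):
        alphas = (ys @ x_c) / denom
    # degenerate windows (constant excerpt -> F(n) = 0) get NaN
    alphas = np.where(np.all(np.isfinite(ys), axis=1), alphas, np.nan)

    starts = np.arange(n_win) * step
    offset = {"start": 0.0, "center": window_len / 2.0, "end": float(window_len)}[anchor]
    if sampling_rate is not None:
        times = (starts + offset) / sampling_rate
    else:
        times = starts + offset
    return AlphaTrajectory(times=times, alphas=alphas, window_len=window_len,
                           step=step, anchor=anchor,
                           dfa_params={"scales": grid.tolist(),
                                       "detrend_order": detrend_order,
                                       "fit_range": (float(lo), float(hi))})


def max_alpha_jump(traj: AlphaTrajectory) -> float:
    """Largest absolute first difference of the trajectory.

    Serves as a smoothness diagnostic: on a signal whose correlation
    structure switches abruptly, larger windows produce smaller jumps.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 trajectory points")
    return float(np.nanmax(np.abs(np.diff(traj.alphas))))
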