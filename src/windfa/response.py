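"""Response quantification on alpha trajectories.

Per trial, a segment of the trajectory is rescaled so it starts at 1.0
("growth in normalised units"); the per-second growth rate r of the
normalised curve is the discriminating statistic.  Averaging is done
twice: over trials within a subject, then over subjects within a group,
so every subject contributes with equal weight regardless of trial
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sliding import AlphaTrajectory

__all__ = [
    "NormalizedResponse",
    "SlopeEstimate",
    "GroupCurve",
    "normalize_segment",
    "estimate_slope",
    "average_trials",
    "average_subjects",
    "lh_rh_contrast",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizedResponse:
    """Alpha segment rescaled to start at exactly 1.0.

    ``times_s`` are relative to the segment start.
    """

    times_s: np.ndarray
    normalized_alpha: np.ndarray
    segment: str = ""
    channel: str = ""
    subject: str = ""
    hand: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.normalized_alpha, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "normalized_alpha", a)

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS growth rate of the normalised response (1/s) with its stderr."""

    r: float
    stderr: float
    fit_interval_s: tuple[float, float]
    n_points: int = 0


@dataclass(frozen=True)
class GroupCurve:
    """Pointwise mean +/- SE of normalised responses on a common grid."""

    times_s: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n: int


def normalize_segment(traj: AlphaTrajectory, t_start_s: float,
                      t_end_s: float, **labels) -> NormalizedResponse:
    """Divide ``alpha(t)`` on ``[t_start, t_end]`` by its starting value.

    The divisor is alpha at the grid point nearest ``t_start``; the first
    returned value is therefore exactly 1.0.
    """
    if t_end_s <= t_start_s:
        raise ValueError("t_end_s must exceed t_start_s")
    t = traj.times
    if t_start_s < t[0] - 1e-9 or t_end_s > t[-1] + 1e-9:
        raise ValueError(
            f"segment [{t_start_s}, {t_end_s}] outside trajectory "
            f"[{t[0]:.3f}, {t[-1]:.3f}]")
    i0 = int(np.argmin(np.abs(t - t_start_s)))
    sel = slice(i0, int(np.searchsorted(t, t_end_s + 1e-9)))
    a0 = traj.alphas[i0]
    if not np.isfinite(a0) or a0 <= 0:
        raise ValueError(f"alpha at segment start is not positive ({a0})")
    return NormalizedResponse(
        times_s=t[sel] - t[i0],
        normalized_alpha=traj.alphas[sel] / a0,
        **labels)


def estimate_slope(resp: NormalizedResponse,
                   fit_interval_s: tuple[float, float] | None = None) -> SlopeEstimate:
    """OLS slope of the normalised response against time in seconds."""
    t = resp.times_s
    a = resp.normalized_alpha
    if fit_interval_s is None:
        fit_interval_s = (float(t[0]), float(t[-1]))
    lo, hi = fit_interval_s
    mask = (t >= lo - 1e-9) & (t <= hi + 1e-9) & np.isfinite(a)
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 points in fit interval, got {int(mask.sum())}")
    x = t[mask]
    y = a[mask]
    xc = x - x.mean()
    sxx = float(np.sum(xc ** 2))
    slope = float(np.sum(xc * y) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    dof = x.size - 2
    stderr = float(np.sqrt(np.sum(resid ** 2) / dof / sxx)) if dof > 0 else 0.0
    return SlopeEstimate(r=slope, stderr=stderr,
                         fit_interval_s=(float(lo), float(hi)),
                         n_points=int(mask.sum()))


def _common_grid(curves: list[np.ndarray]) -> None:
    first = curves[0]
    for c in curves[1:]:
        if c.shape != first.shape or not np.allclose(c, first, atol=1e-9):
            raise ValueError("responses are not on a common time grid")


def average_trials(responses: list[NormalizedResponse]) -> GroupCurve:
    """Pointwise mean over repeated trials of one subject/channel/segment.

    SE is across trials (NaN for a single trial).
    """
    if not responses:
        raise ValueError("no responses to average")
    _common_grid([r.times_s for r in responses])
    stack = np.vstack([r.normalized_alpha for r in responses])
    n = stack.shape[0]
    mean = np.nanmean(stack, axis=0)
    se = (np.nanstd(stack, axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.full(mean.shape, np.nan)
    return GroupCurve(times_s=responses[0].times_s, mean=mean, se=se, n=n)


def average_subjects(subject_curves: list[GroupCurve]) -> GroupCurve:
    """Second averaging stage: across subjects, SE = sd / sqrt(n)."""
    if not subject_curves:
        raise ValueError("no subject curves to average")
    _common_grid([c.times_s for c in subject_curves])
    stack = np.vstack([c.mean for c in subject_curves])
    n = stack.shape[0]
    mean = np.nanmean(stack, axis=0)
    if n > 1:
        se = np.nanstd(stack, axis=0, ddof=1) / np.sqrt(n)
    else:
        se = np.full(mean.shape, np.nan)
    return GroupCurve(times_s=subject_curves[0].times_s, mean=mean, se=se, n=n)


def lh_rh_contrast(slopes: pd.DataFrame) -> pd.DataFrame:
    """Hand-asymmetry summary from per-subject, per-channel slopes.

    Parameters
    ----------
    slopes : DataFrame
        Columns ``group, subject, channel, hand, r`` (one row per cell;
        extra columns such as ``segment`` are averaged over first).

    Returns
    -------
    DataFrame with one row per group: mean and SE over subjects of the
    channel-averaged ``|r_LH - r_RH|``, plus the signed equivalents.
    Subject/channel cells missing either hand are excluded with a
    warning.
    """
    required = {"group", "subject", "channel", "hand", "r"}
    missing = required - set(slopes.columns)
    if missing:
        raise ValueError(f"slope table missing columns: {sorted(missing)}")
    cell = (slopes.groupby(["group", "subject", "channel", "hand"], sort=True)["r"]
            .mean().unstack("hand"))
    if not {"LH", "RH"} <= set(cell.columns):
        raise ValueError("both LH and RH slopes are required")
    incomplete = cell["LH"].isna() | cell["RH"].isna()
    if incomplete.any():
        logger.warning("%d subject/channel cells missing a hand; excluded",
                       int(incomplete.sum()))
        cell = cell[~incomplete]
    diff = cell["LH"] - cell["RH"]
    per_subject = pd.DataFrame({
        "abs_diff": diff.abs().groupby(["group", "subject"]).mean(),
        "signed_diff": diff.groupby(["group", "subject"]).mean(),
    })
    rows = []
    for group, sub in per_subject.groupby(level="group"):
        n = len(sub)
        rows.append({
            "group": group,
            "n_subjects": n,
            "mean_abs_diff": float(sub["abs_diff"].mean()),
            "se_abs_diff": float(sub["abs_diff"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "mean_signed_diff": float(sub["signed_diff"].mean()),
            "se_signed_diff": float(sub["signed_diff"].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        })
    return pd.DataFrame(rows)
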