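"""Nonparametric inter-group comparison and channel difference maps.

The Mann-Whitney U test is implemented from first principles: for small
samples without ties the exact two-sided p-value is obtained from the
null distribution of U (counted by dynamic programming over all
label assignments); otherwise a tie-corrected normal approximation with
midranks is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "MannWhitneyResult",
    "ChannelDifferenceMap",
    "mann_whitney",
    "channel_difference_map",
    "compare_groups",
]

logger = logging.getLogger(__name__)

EXACT_LIMIT = 20  # exact enumeration up to n1 + n2 samples


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float            # U statistic of the first sample
    p_value: float      # two-sided
    method: str         # 'exact' or 'normal_approx'
    n1: int
    n2: int


@dataclass(frozen=True)
class ChannelDifferenceMap:
    """Per-channel raw and max-normalised group difference of r values."""

    channels: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {c: (float(r), float(n))
                for c, r, n in zip(self.channels, self.raw, self.normalized)}


@lru_cache(maxsize=512)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Number of label assignments giving each U value, U = 0..n1*n2.

    Classic recursion c(u; n1, n2) = c(u - n2; n1 - 1, n2)
    + c(u; n1, n2 - 1); the array sums to C(n1 + n2, n1).
    """
    if n1 == 0 or n2 == 0:
        return np.array([1.0])
    out = np.zeros(n1 * n2 + 1)
    a = _u_null_counts(n1 - 1, n2)
    out[n2: n2 + a.size] += a
    b = _u_null_counts(n1, n2 - 1)
    out[: b.size] += b
    out.flags.writeable = False
    return out


def _exact_p(u: float, n1: int, n2: int) -> float:
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    max_u = n1 * n2
    u_lo = min(int(round(u)), max_u - int(round(u)))
    lo_tail = counts[: u_lo + 1].sum()
    hi_tail = counts[max_u - u_lo:].sum()
    return float(min(1.0, (lo_tail + hi_tail) / total))


def mann_whitney(group_a, group_b, *, force_method: str | None = None) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact null-distribution p-value when ``n1 + n2 <= 20`` and there are
    no ties; midrank, tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    method = force_method
    if method is None:
        method = "exact" if (n1 + n2 <= EXACT_LIMIT and not has_ties) else "normal_approx"
    if method == "exact" and has_ties:
        logger.info("ties present: falling back to the normal approximation")
        method = "normal_approx"

    if method == "exact":
        p = _exact_p(u1, n1, n2)
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            # continuity-corrected two-sided p
            z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
            z = max(z, 0.0)
            p = float(min(1.0, 2.0 * sstats.norm.sf(z)))
    return MannWhitneyResult(u=float(u1), p_value=float(p), method=method, n1=n1, n2=n2)


def channel_difference_map(r_by_channel_a: dict[str, float],
                           r_by_channel_b: dict[str, float], *,
                           normalization: str = "max") -> ChannelDifferenceMap:
    """Signed per-channel difference of group-level r values.

    ``raw = r_a - r_b``; ``normalized`` divides by ``max |raw|``
    (``normalization='max'``, default) or z-scores across channels
    (``normalization='zscore'``).  All-zero maps are passed through
    unchanged.
    """
    if set(r_by_channel_a) != set(r_by_channel_b):
        raise ValueError("channel sets differ between groups")
    channels = tuple(r_by_channel_a)
    raw = np.array([r_by_channel_a[c] - r_by_channel_b[c] for c in channels])
    if normalization == "max":
        peak = np.max(np.abs(raw))
        normalized = raw / peak if peak > 0 else raw.copy()
    elif normalization == "zscore":
        sd = raw.std(ddof=0)
        normalized = (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return ChannelDifferenceMap(channels=channels, raw=raw, normalized=normalized)


def compare_groups(slopes: pd.DataFrame, *, alpha: float = 0.05,
                   group_order: tuple[str, str] = ("elderly", "young"),
                   bh_correction: bool = False) -> pd.DataFrame:
    """Cell-by-cell group comparison of per-subject slopes.

    Parameters
    ----------
    slopes : DataFrame
        Per-subject slopes with columns
        ``group, subject, channel, segment, hand, r``.
    alpha : float
        Significance threshold for the flag column.
    bh_correction : bool
        Apply Benjamini-Hochberg across all cells (off by default,
        matching per-channel reporting without correction).

    Returns
    -------
    One row per (channel, segment, hand-condition) with hand-condition
    in {'all', 'LH', 'RH'}: group means +/- SE, U, p and a significance
    flag.
    """
    required = {"group", "subject", "channel", "segment", "hand", "r"}
    missing = required - set(slopes.columns)
    if missing:
        raise ValueError(f"slope table missing columns: {sorted(missing)}")
    g_a, g_b = group_order
    rows = []
    for channel in sorted(slopes["channel"].unique()):
        for segment in sorted(slopes["segment"].unique()):
            for hand_cond in ("all", "LH", "RH"):
                sub = slopes[(slopes["channel"] == channel) & (slopes["segment"] == segment)]
                if hand_cond != "all":
                    sub = sub[sub["hand"] == hand_cond]
                per_subj = sub.groupby(["group", "subject"])["r"].mean()
                try:
                    va = per_subj.loc[g_a].to_numpy()
                    vb = per_subj.loc[g_b].to_numpy()
                except KeyError:
                    continue
                if va.size < 2 or vb.size < 2:
                    continue
                res = mann_whitney(va, vb)
                rows.append({
                    "channel": channel, "segment": segment, "hand": hand_cond,
                    f"mean_{g_a}": va.mean(),
                    f"se_{g_a}": va.std(ddof=1) / np.sqrt(va.size),
                    f"mean_{g_b}": vb.mean(),
                    f"se_{g_b}": vb.std(ddof=1) / np.sqrt(vb.size),
                    "u": res.u, "p_value": res.p_value, "method": res.method,
                })
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    if bh_correction:
        p = report["p_value"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        report["p_adjusted"] = adj
        report["significant"] = report["p_adjusted"] < alpha
    else:
        report["significant"] = report["p_value"] < alpha
    return report
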