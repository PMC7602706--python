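"""End-to-end orchestration: recordings -> trajectories -> slopes -> stats.

The heavy loop (sliding DFA per channel of every kept epoch) is kept in
:func:`analyze_cohort`; it produces per-trial normalised responses, the
two-stage (trial, then subject) averages, per-subject slopes for the
nonparametric tests, and group-level summary tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .preprocess import MultichannelRecording, bandpass, notch, extract_epochs
from .response import (GroupCurve, average_subjects, average_trials,
                       estimate_slope, lh_rh_contrast, normalize_segment)
from .sliding import sliding_alpha
from .stats import channel_difference_map, compare_groups
from . import io as wio

__all__ = ["AnalysisResult", "analyze_cohort", "run_pipeline"]

logger = logging.getLogger(__name__)

SEGMENTS = ("clench", "unclench")


@dataclass
class AnalysisResult:
    """Everything the reporting stage needs."""

    subject_slopes: pd.DataFrame      # group, subject, channel, segment, hand, r, stderr
    group_slopes: pd.DataFrame        # slopes fitted on group-averaged curves
    group_curves: pd.DataFrame        # long form: group, channel, segment, hand, time_s, mean, se, n
    stats_report: pd.DataFrame
    hand_contrast: pd.DataFrame
    channel_map: pd.DataFrame
    config: PipelineConfig


def _segment_bounds(config: PipelineConfig) -> dict[str, tuple[float, float]]:
    """Segment windows in epoch time (cue onset sits at epoch_pre_s)."""
    t0 = config.epoch_pre_s
    return {
        "clench": (t0 + config.clench_start_s,
                   t0 + config.clench_start_s + config.segment_len_s),
        "unclench": (t0 + config.unclench_start_s,
                     t0 + config.unclench_start_s + config.segment_len_s),
    }


def _preprocess(recording: MultichannelRecording,
                config: PipelineConfig) -> MultichannelRecording:
    if not config.apply_filters:
        return recording
    out = bandpass(recording, config.bandpass_low_hz, config.bandpass_high_hz,
                   config.bandpass_order)
    return notch(out, config.notch_hz, config.notch_q)


def analyze_cohort(recordings: dict[str, MultichannelRecording],
                   events: dict[str, pd.DataFrame],
                   groups: dict[str, str],
                   config: PipelineConfig | None = None,
                   channels: list[str] | None = None) -> AnalysisResult:
    """Run the full analysis over a cohort of recordings.

    Parameters
    ----------
    recordings, events, groups : dict
        Keyed by subject id; ``groups`` maps each subject to its group
        label (e.g. ``'elderly'`` / ``'young'``).
    channels : list of str, optional
        Restrict the analysis to a channel subset (all by default).
    """
    config = config or PipelineConfig()
    bounds = _segment_bounds(config)
    fit_range = None
    if config.fit_lg_min is not None and config.fit_lg_max is not None:
        fit_range = (config.fit_lg_min, config.fit_lg_max)
    scale_max = config.scale_max or config.window_samples // 4

    from .dfa import default_scales
    scales = default_scales(config.window_samples, n_min=config.scale_min,
                            n_max=scale_max)

    # responses[(subject, channel, segment, hand)] -> list of NormalizedResponse
    responses: dict[tuple, list] = {}
    for sid, recording in recordings.items():
        rec = _preprocess(recording, config)
        epochs = extract_epochs(rec, events[sid], config.epoch_pre_s,
                                config.epoch_post_s, subject=sid)
        if not epochs:
            logger.warning("subject %s: no usable epochs", sid)
            continue
        chan_list = channels if channels is not None else rec.channel_labels
        for epoch in epochs:
            for ch in chan_list:
                traj = sliding_alpha(
                    epoch.channel(ch), config.window_samples,
                    config.step_samples, sampling_rate=epoch.sampling_rate,
                    scales=scales, detrend_order=config.detrend_order,
                    fit_range=fit_range, anchor=config.anchor)
                for segment in SEGMENTS:
                    lo, hi = bounds[segment]
                    resp = normalize_segment(traj, lo, hi, segment=segment,
                                             channel=ch, subject=sid,
                                             hand=epoch.hand)
                    responses.setdefault((sid, ch, segment, epoch.hand), []).append(resp)

    fit_iv = (0.0, config.fit_interval_s)
    subj_rows = []
    subject_curves: dict[tuple, GroupCurve] = {}
    for (sid, ch, segment, hand), resps in sorted(responses.items()):
        curve = average_trials(resps)
        subject_curves[(sid, ch, segment, hand)] = curve
        est = estimate_slope(
            _curve_as_response(curve, segment, ch, sid, hand), fit_iv)
        subj_rows.append({
            "group": groups[sid], "subject": sid, "channel": ch,
            "segment": segment, "hand": hand, "r": est.r,
            "stderr": est.stderr, "n_trials": curve.n,
        })
    subject_slopes = pd.DataFrame(subj_rows)

    group_curve_rows = []
    group_slope_rows = []
    group_labels = sorted(set(groups.values()))
    chan_set = sorted({k[1] for k in subject_curves})
    for group in group_labels:
        sids = sorted(s for s, g in groups.items() if g == group)
        for ch in chan_set:
            for segment in SEGMENTS:
                for hand_cond in ("all", "LH", "RH"):
                    hands = ("LH", "RH") if hand_cond == "all" else (hand_cond,)
                    per_subject = []
                    for sid in sids:
                        trial_resps = []
                        for hand in hands:
                            key = (sid, ch, segment, hand)
                            if key in responses:
                                trial_resps.extend(responses[key])
                        if trial_resps:
                            per_subject.append(average_trials(trial_resps))
                    if not per_subject:
                        continue
                    gcurve = average_subjects(per_subject)
                    est = estimate_slope(
                        _curve_as_response(gcurve, segment, ch, group, hand_cond),
                        fit_iv)
                    group_slope_rows.append({
                        "group": group, "channel": ch, "segment": segment,
                        "hand": hand_cond, "r": est.r, "stderr": est.stderr,
                        "n_subjects": gcurve.n,
                    })
                    for t, m, s in zip(gcurve.times_s, gcurve.mean, gcurve.se):
                        group_curve_rows.append({
                            "group": group, "channel": ch, "segment": segment,
                            "hand": hand_cond, "time_s": t, "mean": m,
                            "se": s, "n": gcurve.n,
                        })
    group_slopes = pd.DataFrame(group_slope_rows)
    group_curves = pd.DataFrame(group_curve_rows)

    stats_report = compare_groups(subject_slopes, alpha=config.stat_alpha,
                                  group_order=tuple(group_labels)[:2]
                                  if len(group_labels) >= 2 else ("a", "b"),
                                  bh_correction=config.bh_correction) \
        if len(group_labels) >= 2 else pd.DataFrame()
    hand_contrast = lh_rh_contrast(subject_slopes) \
        if {"LH", "RH"} <= set(subject_slopes.get("hand", [])) else pd.DataFrame()

    channel_map = pd.DataFrame()
    if len(group_labels) >= 2:
        g_a, g_b = group_labels[0], group_labels[1]
        means = (subject_slopes.groupby(["group", "channel"])["r"].mean()
                 .unstack("channel"))
        if g_a in means.index and g_b in means.index:
            cmap = channel_difference_map(means.loc[g_a].to_dict(),
                                          means.loc[g_b].to_dict(),
                                          normalization=config.map_normalization)
            channel_map = pd.DataFrame({
                "channel": cmap.channels,
                "raw_diff": cmap.raw,
                "normalized_diff": cmap.normalized,
            })

    return AnalysisResult(subject_slopes=subject_slopes, group_slopes=group_slopes,
                          group_curves=group_curves, stats_report=stats_report,
                          hand_contrast=hand_contrast, channel_map=channel_map,
                          config=config)


def _curve_as_response(curve: GroupCurve, segment: str, channel: str,
                       subject: str, hand: str):
    from .response import NormalizedResponse
    return NormalizedResponse(times_s=curve.times_s, normalized_alpha=curve.mean,
                              segment=segment, channel=channel,
                              subject=subject, hand=hand)


def run_pipeline(config: PipelineConfig, out_dir, *,
                 cohort=None,
                 recordings: dict | None = None,
                 events: dict | None = None,
                 groups: dict | None = None,
                 channels: list[str] | None = None) -> AnalysisResult:
    """Analyze a cohort and write every result table under ``out_dir``.

    Either a :class:`~windfa.synth.SyntheticCohort` or explicit
    ``recordings``/``events``/``groups`` dicts must be supplied.  All
    outputs are TSV stamped with the config hash, plus ``run_log.json``
    recording every parameter.
    """
    if cohort is not None:
        recordings = cohort.recordings
        events = cohort.events
        groups = {s["subject"]: s["group"] for s in cohort.manifest["subjects"]}
    if not (recordings and events and groups):
        raise ValueError("pipeline needs a cohort or recordings+events+groups")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    result = analyze_cohort(recordings, events, groups, config, channels)
    h = config.hash()
    wio.write_table(result.subject_slopes, out_dir / "subject_slopes.tsv", config_hash=h)
    wio.write_table(result.group_slopes, out_dir / "group_slopes.tsv", config_hash=h)
    wio.write_table(result.group_curves, out_dir / "group_curves.tsv", config_hash=h)
    wio.write_table(result.stats_report, out_dir / "stats_report.tsv", config_hash=h)
    wio.write_table(result.hand_contrast, out_dir / "hand_contrast.tsv", config_hash=h)
    wio.write_table(result.channel_map, out_dir / "channel_map.tsv", config_hash=h)
    log = {"config": config.to_dict(), "config_hash": h,
           "n_subjects": len(recordings),
           "channels": channels or "all"}
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return result
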