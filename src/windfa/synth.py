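"""Ground-truthed synthetic signals and cohorts.

The generator produces the statistical structure the analysis pipeline
measures: power-law-correlated noise whose Hurst exponent is transiently
raised during event-locked "clench" and "unclench" intervals, with
group-, hand- and channel-dependent effect sizes.

Fractional Gaussian noise (fGn) is synthesised exactly by circulant
embedding (Davies–Harte); DFA applied to fGn with Hurst exponent ``H``
yields a scaling exponent ``alpha = H``, which keeps the generator's
ground truth directly comparable with the analysis output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dfa import RawSignal

__all__ = [
    "HurstProfile",
    "CohortSpec",
    "SyntheticCohort",
    "generate_fgn",
    "generate_modulated_signal",
    "generate_cohort",
    "DEFAULT_CHANNELS",
    "DEFAULT_CHANNEL_GAINS",
]

logger = logging.getLogger(__name__)

# 31-channel 10-10 montage used for synthetic recordings
DEFAULT_CHANNELS = (
    "O2", "O1", "P4", "P3", "C4", "C3", "F4", "F3", "Fp2", "Fp1",
    "P8", "P7", "T8", "T7", "F8", "F7", "Oz", "Pz", "Cz", "Fz",
    "Fpz", "FT7", "FC3", "FCz", "FC4", "FT8", "TP7", "CP3", "CPz",
    "CP4", "TP8",
)

# response-gain topography: maximal over the sensorimotor area
DEFAULT_CHANNEL_GAINS = {"C4": 1.0, "Cz": 1.0, "C3": 0.8, "CP4": 0.8, "FC4": 0.8}
DEFAULT_OTHER_GAIN = 0.5


def _fgn_autocovariance(H: float, lags: np.ndarray) -> np.ndarray:
    """gamma(k) = 0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H), unit variance."""
    k = np.abs(lags).astype(float)
    return 0.5 * (np.abs(k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))


def generate_fgn(H: float, N: int, seed: int | np.random.Generator = 0) -> RawSignal:
    """Exact fractional Gaussian noise by circulant embedding.

    Produces a stationary, unit-variance Gaussian sequence with the fGn
    autocovariance for Hurst exponent ``H``; ``H = 0.5`` gives white
    noise.  Deterministic for a given seed.  If the circulant embedding
    is not non-negative definite (pathological ``H``/``N`` combinations)
    the negative eigenvalues are clipped with a logged note, which yields
    an approximate spectral synthesis.
    """
    if not 0.0 < H < 1.0:
        raise ValueError(f"H must be in (0, 1), got {H}")
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    m = 1
    while m < 2 * (N - 1):
        m *= 2
    gamma = _fgn_autocovariance(H, np.arange(m // 2 + 1))
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.rfft(circ).real
    if np.any(eig < 0):
        worst = float(eig.min())
        logger.warning(
            "circulant embedding not nonneg-definite (min eig %.3g); "
            "clipping to approximate spectral synthesis", worst)
        eig = np.clip(eig, 0.0, None)

    # complex Gaussian spectrum with Hermitian-symmetry endpoints real
    n_freq = eig.size
    z = rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
    z[0] = np.sqrt(2.0) * z[0].real
    z[-1] = np.sqrt(2.0) * z[-1].real
    spectrum = z * np.sqrt(eig / (2.0 * m))
    x = np.fft.irfft(spectrum, n=m)[:N] * m
    return RawSignal(samples=x)


@dataclass(frozen=True)
class HurstProfile:
    """Piecewise-constant target Hurst exponent versus time.

    ``segments`` is a list of ``(t_start_s, t_end_s, H)`` tuples that
    must be contiguous and non-overlapping.  Adjacent segments are joined
    by an equal-power raised-cosine crossfade of ``crossfade_s`` seconds
    so the variance stays flat through transitions.
    """

    segments: tuple[tuple[float, float, float], ...]
    crossfade_s: float = 0.5

    def __post_init__(self) -> None:
        segs = tuple((float(a), float(b), float(h)) for a, b, h in self.segments)
        if not segs:
            raise ValueError("profile must contain at least one segment")
        for a, b, h in segs:
            if b <= a:
                raise ValueError(f"segment ({a}, {b}) has non-positive duration")
            if not 0.0 < h < 1.0:
                raise ValueError(f"H={h} outside (0, 1)")
        for (a0, b0, _), (a1, b1, _) in zip(segs, segs[1:]):
            if abs(b0 - a1) > 1e-9:
                raise ValueError("segments must be contiguous")
        object.__setattr__(self, "segments", segs)
        shortest = min(b - a for a, b, _ in segs)
        if self.crossfade_s < 0:
            raise ValueError("crossfade_s must be non-negative")
        if len(segs) > 1 and self.crossfade_s > shortest:
            raise ValueError(
                f"crossfade_s={self.crossfade_s} exceeds shortest segment ({shortest} s)")

    @property
    def duration_s(self) -> float:
        return self.segments[-1][1] - self.segments[0][0]


def generate_modulated_signal(profile: HurstProfile, sampling_rate: float = 250.0,
                              seed: int | np.random.Generator = 0) -> RawSignal:
    """Piecewise-stationary fGn following a Hurst profile.

    Each profile segment is an independent unit-variance fGn realisation;
    neighbours are blended with an equal-power raised-cosine crossfade
    centred on the segment boundary.  Sliding-window DFA on the output
    tracks the profile, smoothed by the analysis window.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_total = int(round(profile.duration_s * sampling_rate))
    half = int(round(profile.crossfade_s * sampling_rate / 2.0))
    t0 = profile.segments[0][0]

    out = np.zeros(n_total)
    weight_sq = np.zeros(n_total)
    n_segs = len(profile.segments)
    for idx, (a, b, h) in enumerate(profile.segments):
        i0 = int(round((a - t0) * sampling_rate))
        i1 = int(round((b - t0) * sampling_rate))
        lo = max(i0 - half, 0) if idx > 0 else i0
        hi = min(i1 + half, n_total) if idx < n_segs - 1 else i1
        seg = generate_fgn(h, hi - lo, rng).samples
        w = np.ones(hi - lo)
        if idx > 0:
            ramp = hi - lo if hi - lo < 2 * half else 2 * half
            # equal-power fade-in: sin ramp so w^2 sums to 1 with neighbour
            w[:ramp] = np.sin(np.linspace(0, np.pi / 2, ramp, endpoint=False))
        if idx < n_segs - 1:
            ramp = hi - lo if hi - lo < 2 * half else 2 * half
            w[len(w) - ramp:] = np.cos(np.linspace(0, np.pi / 2, ramp, endpoint=False))
        out[lo:hi] += w * seg
        weight_sq[lo:hi] += w ** 2
    # guard: fades are designed to be power-complementary
    np.divide(out, np.sqrt(np.maximum(weight_sq, 1e-12)), out=out)
    return RawSignal(samples=out, sampling_rate=sampling_rate)


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a two-group event-locked experiment.

    Per-(group, hand, segment) target slopes are expressed in the units
    the analysis reports: per-second growth rate of the normalised
    scaling exponent.  The generator converts a target slope ``r`` into a
    relative Hurst elevation ``2 * r * ramp window`` so that the
    window-smoothed trajectory rises linearly at rate ``r`` over the
    analysis fit interval.
    """

    n_subjects: int = 10
    trials_per_hand: int = 30
    keep_per_hand: int = 15
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 250.0
    baseline_hurst: float = 0.6
    baseline_sd: float = 0.05
    # target normalised-alpha slopes (1/s), keyed (group, hand, segment)
    slope_targets: dict = field(default_factory=lambda: {
        ("elderly", "RH", "clench"): 0.116, ("elderly", "LH", "clench"): 0.127,
        ("young", "RH", "clench"): 0.101, ("young", "LH", "clench"): 0.072,
        ("elderly", "RH", "unclench"): 0.081, ("elderly", "LH", "unclench"): 0.054,
        ("young", "RH", "unclench"): 0.057, ("young", "LH", "unclench"): 0.024,
    })
    slope_sd_frac: float = 0.2
    channel_gains: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_GAINS))
    other_gain: float = DEFAULT_OTHER_GAIN
    # task timeline (seconds, relative to first cue)
    baseline_s: float = 2.0
    active_s: float = 4.5
    unclench_bump_s: float = 2.0
    trial_period_s: float = 14.0
    bump_latency_s: float = 1.0
    crossfade_s: float = 0.5
    cue_duration_lh_s: float = 0.3
    cue_duration_rh_s: float = 0.75
    signal_rms_uv: float = 10.0
    noise_snr_db: float | None = None
    analysis_window_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_hand < 1:
            raise ValueError("counts must be positive")
        if self.keep_per_hand > self.trials_per_hand:
            raise ValueError("keep_per_hand cannot exceed trials_per_hand")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if not 0 < self.baseline_hurst < 1:
            raise ValueError("baseline_hurst must be in (0, 1)")
        for key in self.slope_targets:
            if len(key) != 3:
                raise ValueError(f"slope target key {key} must be (group, hand, segment)")

    def gain(self, channel: str) -> float:
        return float(self.channel_gains.get(channel, self.other_gain))


@dataclass
class SyntheticCohort:
    """Recordings, event tables and the ground-truth manifest."""

    recordings: dict          # subject_id -> MultichannelRecording
    events: dict              # subject_id -> EventTable
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2, sort_keys=True)


def _trial_profile(spec: CohortSpec, H0: float, bump_clench: float,
                   bump_unclench: float) -> list[tuple[float, float, float]]:
    """Per-trial Hurst segments, times relative to the first cue.

    The elevation starts ``bump_latency_s`` after each cue so that, after
    smoothing by the centred analysis window, the measured trajectory
    begins rising exactly at the cue.
    """
    lat = spec.bump_latency_s
    w = spec.analysis_window_s
    clip = 0.995
    h_clench = min(H0 * (1.0 + bump_clench), clip)
    h_unclench = min(H0 * (1.0 + bump_unclench), clip)
    t_cue2 = spec.active_s
    # the clench elevation ends one analysis half-window plus one
    # crossfade before the second cue so its decay cannot leak into the
    # unclench normalisation point
    clench_end = t_cue2 - w / 2.0 - spec.crossfade_s
    return [
        (-spec.baseline_s, lat, H0),
        (lat, clench_end, h_clench),
        (clench_end, t_cue2 + lat, H0),
        (t_cue2 + lat, t_cue2 + lat + spec.unclench_bump_s, h_unclench),
        (t_cue2 + lat + spec.unclench_bump_s, spec.trial_period_s - spec.baseline_s, H0),
    ]


def generate_cohort(spec: CohortSpec):
    """Generate a fully reproducible two-group synthetic cohort.

    For every subject one continuous multichannel recording is produced
    together with an event table (randomised LH/RH order, ``keep`` flags
    marking the retained trials) and a manifest of every drawn parameter.

    Infeasible elevations (requiring ``H >= 1``) are clipped with a
    warning and flagged in the manifest.
    """
    from .preprocess import MultichannelRecording  # deferred: avoid cycle

    rng = np.random.default_rng(spec.seed)
    n_trials = 2 * spec.trials_per_hand
    rec_duration = spec.baseline_s + n_trials * spec.trial_period_s + 2.0
    clip = 0.995

    recordings: dict[str, object] = {}
    events: dict[str, pd.DataFrame] = {}
    subjects_manifest = []
    clipped_any = False

    for group in ("elderly", "young"):
        for s_idx in range(spec.n_subjects):
            sid = f"{group}{s_idx:02d}"
            H0 = float(np.clip(rng.normal(spec.baseline_hurst, spec.baseline_sd), 0.3, 0.8))
            # per-subject slopes around the group/hand/segment targets
            subj_slopes = {}
            for (grp, hand, segment), target in spec.slope_targets.items():
                if grp != group:
                    continue
                sd = abs(target) * spec.slope_sd_frac
                subj_slopes[(hand, segment)] = float(max(rng.normal(target, sd), 0.0))

            hands = np.array(["LH"] * spec.trials_per_hand + ["RH"] * spec.trials_per_hand)
            rng.shuffle(hands)
            keep = np.zeros(n_trials, dtype=bool)
            for hand in ("LH", "RH"):
                idx = np.flatnonzero(hands == hand)
                keep[rng.choice(idx, size=spec.keep_per_hand, replace=False)] = True

            onsets = spec.baseline_s + np.arange(n_trials) * spec.trial_period_s
            cue_dur = np.where(hands == "LH", spec.cue_duration_lh_s, spec.cue_duration_rh_s)
            ev = pd.DataFrame({
                "onset_s": onsets, "hand": hands,
                "cue_duration_s": cue_dur, "keep": keep,
            })

            n_samples = int(round(rec_duration * spec.sampling_rate))
            data = np.empty((n_samples, len(spec.channels)))
            channel_truth = {}
            for c_idx, ch in enumerate(spec.channels):
                gain = spec.gain(ch)
                segments: list[tuple[float, float, float]] = []
                for t_idx in range(n_trials):
                    hand = hands[t_idx]
                    # bump amplitude implementing the target slope under
                    # boxcar smoothing by the analysis window: dH = 2*r*w/2... see docs
                    amp_c = 2.0 * subj_slopes[(hand, "clench")] * gain
                    amp_u = 2.0 * subj_slopes[(hand, "unclench")] * gain
                    if H0 * (1 + amp_c) > clip or H0 * (1 + amp_u) > clip:
                        clipped_any = True
                    trial_segs = _trial_profile(spec, H0, amp_c, amp_u)
                    cue = onsets[t_idx]
                    for a, b, h in trial_segs:
                        segments.append((cue + a, cue + b, h))
                # leading/trailing padding at baseline H
                first = segments[0][0]
                last = segments[-1][1]
                if first > 0:
                    segments.insert(0, (0.0, first, H0))
                if last < rec_duration:
                    segments.append((last, rec_duration, H0))
                profile = HurstProfile(segments=tuple(segments), crossfade_s=spec.crossfade_s)
                sig = generate_modulated_signal(profile, spec.sampling_rate, rng)
                samples = sig.samples[:n_samples]
                # exact per-channel RMS normalisation (scale-invariant for DFA)
                samples = samples * (spec.signal_rms_uv / np.std(samples))
                if spec.noise_snr_db is not None:
                    noise_sd = spec.signal_rms_uv * 10 ** (-spec.noise_snr_db / 20.0)
                    samples = samples + rng.normal(0.0, noise_sd, size=samples.size)
                data[:, c_idx] = samples
                channel_truth[ch] = {"gain": gain}

            recordings[sid] = MultichannelRecording(
                data=data, sampling_rate=spec.sampling_rate,
                channel_labels=list(spec.channels))
            events[sid] = ev
            subjects_manifest.append({
                "subject": sid, "group": group, "baseline_hurst": H0,
                "slopes": {f"{h}:{seg}": v for (h, seg), v in subj_slopes.items()},
            })

    if clipped_any:
        warnings.warn("some bump targets required H >= 1 and were clipped", stacklevel=2)

    manifest = {
        "seed": spec.seed,
        "n_subjects_per_group": spec.n_subjects,
        "trials_per_hand": spec.trials_per_hand,
        "keep_per_hand": spec.keep_per_hand,
        "sampling_rate": spec.sampling_rate,
        "baseline_hurst": spec.baseline_hurst,
        "slope_targets": {f"{g}:{h}:{s}": v for (g, h, s), v in spec.slope_targets.items()},
        "channel_gains": {ch: spec.gain(ch) for ch in spec.channels},
        "clipped": clipped_any,
        "generator_model": "piecewise-fGn, alpha == Hurst, bump amplitude 2*r*gain",
        "subjects": subjects_manifest,
    }
    return SyntheticCohort(recordings=recordings, events=events, manifest=manifest)
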