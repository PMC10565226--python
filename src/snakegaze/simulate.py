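"""Synthetic study generator: participants, order assignment, and binocular
gaze streams with a controllable attentional bias toward the threat posture.

The generative model is deliberately simple but produces the statistical
structure the downstream mixed model assumes.  A trial is a sequence of
fixation episodes separated by short saccade transits.  Each episode lands on
the central AOI with a small probability (gaze returning to the fixation-cross
region) and otherwise on one of the two lateral stimulus AOIs; the threat side
is chosen with probability ``logistic(bias)`` where the log-odds ``bias`` is
the sum of

* a morphotype- and nationality-specific attentional bias,
* a participant-specific offset (normal across participants) — this is what
  the mixed model's random intercept recovers, and
* a per-trial disturbance whose spread may differ by nationality — this is
  what the heteroscedastic residual structure recovers.

Within an episode, samples jitter around the episode anchor with a Gaussian
sd well below the dispersion radius, so each episode is detected as one
fixation.  Both eyes report the common gaze point plus small independent
noise.  With a per-trial dropout probability, a long contiguous block of
samples is invalid (tracking loss / distraction), which is what the 2000 ms
quality cut downstream removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    AoiSet,
    Rect,
    ScreenGeometry,
    Stimulus,
    build_presentation_orders,
    build_stimulus_set,
    make_aoi_set,
    stimuli_frame,
)

__all__ = [
    "ParticipantProfile",
    "AttentionParams",
    "StudyConfig",
    "DEFAULT_BIAS",
    "simulate_participants",
    "simulate_trial_gaze",
    "simulate_study",
]

NATIONALITIES = ("somali", "czech")
GENDERS = ("woman", "man")

#: Default threat-side log-odds per (nationality, morphotype), calibrated from
#: the generative model so that, at the default episode statistics (~18
#: lateral fixations per 5 s trial), the expected fixation-count differences
#: are ~1.85 (cobras), ~0.46 (vipers) and ~0.28 (others), with the
#: nationality asymmetry following the dwell-time pattern of the study design
#: (cobra bias similar in both groups; viper/other bias mostly in Czechs).
DEFAULT_BIAS: dict[str, dict[str, float]] = {
    "somali": {"cobra": 0.2243, "viper": 0.0050, "other": 0.0190},
    "czech": {"cobra": 0.1828, "viper": 0.0961, "other": 0.0426},
}


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    nationality: str  # somali | czech
    gender: str       # woman | man
    age: float
    assigned_order: int  # 1..4


@dataclass(frozen=True)
class AttentionParams:
    """Tunable parameters of the per-trial gaze generator."""

    bias_by_morphotype: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIAS["czech"])
    )
    mean_fixation_duration_ms: float = 230.0
    fixation_duration_sd_ms: float = 80.0
    within_fixation_jitter_sd_px: float = 5.0
    saccade_duration_samples: int = 1
    dropout_rate: float = 0.0734
    center_dwell_fraction: float = 0.08
    eye_noise_sd_px: float = 2.0
    trial_logodds_sd: float = 0.2
    participant_logodds_sd: float = 0.15
    single_eye_invalid_rate: float = 0.02

    def __post_init__(self) -> None:
        for p in (self.dropout_rate, self.center_dwell_fraction,
                  self.single_eye_invalid_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_fixation_duration_ms <= 0:
            raise ValueError("fixation durations must be positive")
        if self.within_fixation_jitter_sd_px < 0:
            raise ValueError("jitter sd must be non-negative")


@dataclass(frozen=True)
class StudyConfig:
    """Counts, demographics and generator parameters for one synthetic study."""

    n_by_group: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "somali": {"woman": 25, "man": 46},
            "czech": {"woman": 25, "man": 46},
        }
    )
    #: nationality -> (mean, sd, low, high) for truncated-normal ages
    age_dist: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "somali": (22.37, 3.5, 19.0, 39.0),
            "czech": (24.63, 5.0, 18.0, 44.0),
        }
    )
    params_by_nationality: dict[str, AttentionParams] = field(
        default_factory=lambda: {
            "somali": AttentionParams(
                bias_by_morphotype=dict(DEFAULT_BIAS["somali"]),
                trial_logodds_sd=0.24,
            ),
            "czech": AttentionParams(
                bias_by_morphotype=dict(DEFAULT_BIAS["czech"]),
                trial_logodds_sd=0.2,
            ),
        }
    )
    catalogue: tuple[tuple[str, str], ...] | None = None
    allow_nonstandard_counts: bool = False
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    slide_duration_s: float = 5.0
    sample_rate_hz: float = 30.0

    @property
    def n_participants(self) -> int:
        return sum(sum(g.values()) for g in self.n_by_group.values())


def simulate_participants(
    config: StudyConfig, seed: int | np.random.Generator
) -> list[ParticipantProfile]:
    """Draw the participant roster: exact counts per nationality x gender,
    truncated-normal ages, and uniform random order assignment."""
    rng = np.random.default_rng(seed)
    profiles: list[ParticipantProfile] = []
    idx = 0
    for nat in sorted(config.n_by_group):
        mean, sd, lo, hi = config.age_dist[nat]
        for gender in sorted(config.n_by_group[nat]):
            n = config.n_by_group[nat][gender]
            if n < 0:
                raise ValueError("participant counts must be non-negative")
            for _ in range(n):
                idx += 1
                age = float(np.clip(rng.normal(mean, sd), lo, hi))
                profiles.append(
                    ParticipantProfile(
                        participant_id=f"P{idx:03d}",
                        nationality=nat,
                        gender=gender,
                        age=round(age, 1),
                        assigned_order=int(rng.integers(1, 5)),
                    )
                )
    return profiles


def _uniform_in_rect(rect: Rect, rng: np.random.Generator, margin: float) -> np.ndarray:
    m = min(margin, (rect.x1 - rect.x0) / 4, (rect.y1 - rect.y0) / 4)
    return np.array(
        [
            rng.uniform(rect.x0 + m, rect.x1 - m),
            rng.uniform(rect.y0 + m, rect.y1 - m),
        ]
    )


def simulate_trial_gaze(
    stimulus: Stimulus,
    aois: AoiSet,
    params: AttentionParams,
    seed: int | np.random.Generator,
    participant_logodds_offset: float = 0.0,
    n_samples: int | None = None,
    sample_rate_hz: float = 30.0,
    slide_duration_s: float = 5.0,
) -> pd.DataFrame:
    """Simulate one binocular gaze stream for one slide.

    Returns a DataFrame with columns ``t_ms, lx, ly, rx, ry, valid_l, valid_r``.
    Invalid samples carry NaN coordinates.
    """
    rng = np.random.default_rng(seed)
    if n_samples is None:
        n_samples = int(round(sample_rate_hz * slide_duration_s))
    interval = 1000.0 / sample_rate_hz

    bias = 0.0 if stimulus.is_practise else params.bias_by_morphotype.get(
        stimulus.morphotype, 0.0
    )
    trial_logodds = (
        bias
        + participant_logodds_offset
        + rng.normal(0.0, params.trial_logodds_sd)
    )
    p_threat = 1.0 / (1.0 + np.exp(-trial_logodds))
    threat_aoi = aois.left if stimulus.side_of_threat == "left" else aois.right
    relax_aoi = aois.right if stimulus.side_of_threat == "left" else aois.left

    xs = np.empty(n_samples)
    ys = np.empty(n_samples)
    pos = 0
    prev_anchor: np.ndarray | None = None
    margin = 3.0 * params.within_fixation_jitter_sd_px
    while pos < n_samples:
        if rng.random() < params.center_dwell_fraction:
            rect = aois.central
        elif rng.random() < p_threat:
            rect = threat_aoi
        else:
            rect = relax_aoi
        anchor = _uniform_in_rect(rect, rng, margin)
        # saccade transit from the previous anchor
        if prev_anchor is not None and params.saccade_duration_samples > 0:
            k = min(params.saccade_duration_samples, n_samples - pos)
            frac = (np.arange(1, k + 1)) / (params.saccade_duration_samples + 1)
            pts = prev_anchor[None, :] + frac[:, None] * (anchor - prev_anchor)[None, :]
            xs[pos : pos + k] = pts[:, 0]
            ys[pos : pos + k] = pts[:, 1]
            pos += k
            if pos >= n_samples:
                break
        dur_ms = rng.normal(params.mean_fixation_duration_ms,
                            params.fixation_duration_sd_ms)
        n_fix = int(np.clip(round(dur_ms / interval), 2, n_samples))
        n_fix = min(n_fix, n_samples - pos)
        if n_fix <= 0:
            break
        jit = rng.normal(0.0, params.within_fixation_jitter_sd_px, size=(n_fix, 2))
        xs[pos : pos + n_fix] = anchor[0] + jit[:, 0]
        ys[pos : pos + n_fix] = anchor[1] + jit[:, 1]
        pos += n_fix
        prev_anchor = anchor

    eye = params.eye_noise_sd_px
    lx = xs + rng.normal(0.0, eye, n_samples)
    ly = ys + rng.normal(0.0, eye, n_samples)
    rx = xs + rng.normal(0.0, eye, n_samples)
    ry = ys + rng.normal(0.0, eye, n_samples)
    valid_l = rng.random(n_samples) >= params.single_eye_invalid_rate
    valid_r = rng.random(n_samples) >= params.single_eye_invalid_rate

    if rng.random() < params.dropout_rate:
        # a long tracking-loss episode that leaves < 2 s of usable gaze
        min_len = min(n_samples, int(np.ceil(n_samples * 2 / 3)))
        length = int(rng.integers(min_len, n_samples + 1))
        start = int(rng.integers(0, n_samples - length + 1))
        valid_l[start : start + length] = False
        valid_r[start : start + length] = False

    lx[~valid_l] = np.nan
    ly[~valid_l] = np.nan
    rx[~valid_r] = np.nan
    ry[~valid_r] = np.nan
    t_ms = np.arange(n_samples) * (1000.0 / sample_rate_hz)
    return pd.DataFrame(
        {
            "t_ms": t_ms,
            "lx": lx,
            "ly": ly,
            "rx": rx,
            "ry": ry,
            "valid_l": valid_l,
            "valid_r": valid_r,
        }
    )


def simulate_study(
    config: StudyConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a complete study and optionally write the raw CSV files.

    Returns ``(participants, trials, samples)`` DataFrames.  One gaze stream is
    generated per participant x slide, with the practise slide first and
    flagged.  Output is deterministic given ``config`` and ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(4)
    stimuli = build_stimulus_set(
        config.catalogue, allow_nonstandard_counts=config.allow_nonstandard_counts
    )
    by_version = {s.version_id: s for s in stimuli}
    practise = next(s for s in stimuli if s.is_practise)
    orders = build_presentation_orders(
        stimuli, seed=int(seeds[0].generate_state(1)[0] % (2**31))
    )
    orders_by_id = {o.order_id: o for o in orders}
    participants = simulate_participants(
        config, np.random.default_rng(seeds[1])
    )
    offsets_rng = np.random.default_rng(seeds[2])
    trial_rng_root = seeds[3]

    aois = make_aoi_set(config.screen)
    n_samples = int(round(config.sample_rate_hz * config.slide_duration_s))

    trial_rows = []
    sample_frames = []
    child_seeds = trial_rng_root.spawn(len(participants))
    for p, pseed in zip(participants, child_seeds):
        params = config.params_by_nationality[p.nationality]
        prng = np.random.default_rng(pseed)
        offset = offsets_rng.normal(0.0, params.participant_logodds_sd)
        sequence = [practise.version_id] + list(
            orders_by_id[p.assigned_order].slide_sequence
        )
        for position, version_id in enumerate(sequence):
            stim = by_version[version_id]
            trial_id = f"{p.participant_id}:{position:02d}"
            frame = simulate_trial_gaze(
                stim,
                aois,
                params,
                prng,
                participant_logodds_offset=offset,
                n_samples=n_samples,
                sample_rate_hz=config.sample_rate_hz,
                slide_duration_s=config.slide_duration_s,
            )
            frame.insert(0, "trial_id", trial_id)
            sample_frames.append(frame)
            trial_rows.append(
                {
                    "trial_id": trial_id,
                    "participant_id": p.participant_id,
                    "stimulus_version_id": version_id,
                    "order_id": p.assigned_order,
                    "position": position,
                    "is_practise": stim.is_practise,
                }
            )

    participants_df = pd.DataFrame([vars(p) for p in participants])
    trials_df = pd.DataFrame(trial_rows)
    samples_df = pd.concat(sample_frames, ignore_index=True)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        participants_df.to_csv(out / "participants.csv", index=False)
        trials_df.to_csv(out / "trials.csv", index=False)
        samples_df.to_csv(out / "samples.csv", index=False)
        stimuli_frame(stimuli).to_csv(out / "stimuli.csv", index=False)
        orders_df = pd.DataFrame(
            [
                {"order_id": o.order_id, "position": pos + 1,
                 "stimulus_version_id": vid}
                for o in orders
                for pos, vid in enumerate(o.slide_sequence)
            ]
        )
        orders_df.to_csv(out / "orders.csv", index=False)
    return participants_df, trials_df, samples_df


def scaled_config(
    n_per_cell: int = 5,
    catalogue: tuple[tuple[str, str], ...] | None = None,
    **overrides,
) -> StudyConfig:
    """A reduced-size configuration for fast simulation experiments.

    Keeps the study's structure (two nationalities, both genders, mirror-paired
    catalogue) at a fraction of the size.
    """
    if catalogue is None:
        catalogue = (
            ("cobra_a", "cobra"),
            ("cobra_b", "cobra"),
            ("viper_a", "viper"),
            ("viper_b", "viper"),
            ("python_a", "python"),
            ("colubrid_a", "colubrid"),
        )
    cfg = StudyConfig(
        n_by_group={
            "somali": {"woman": n_per_cell, "man": n_per_cell},
            "czech": {"woman": n_per_cell, "man": n_per_cell},
        },
        catalogue=catalogue,
        allow_nonstandard_counts=True,
    )
    return replace(cfg, **overrides) if overrides else cfg
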