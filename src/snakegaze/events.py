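"""Gaze-stream processing: binocular averaging, dispersion-based fixation
detection, and per-trial AOI metrics.

The fixation detector is a lead-sample dispersion rule: the first valid sample
of a trial is the lead of the first prospective fixation; every subsequent
valid sample within the dispersion radius of the lead joins the group; the
first sample beyond the radius closes the group and becomes the new lead.  A
closed group is a fixation when it holds at least ``min_run`` samples.  A run
of invalid samples (blink / tracking loss) closes the current group: fixation
membership requires temporal contiguity.

Dwell time is sample-based — the number of valid samples whose position lies
in an AOI times the sample interval — not the sum of fixation durations, so
singleton leads still contribute gaze time and the quality cut operates on raw
gaze time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import AoiSet

__all__ = [
    "Fixation",
    "TrialMetrics",
    "average_binocular",
    "detect_fixations",
    "compute_trial_metrics",
    "process_trials",
]

AOI_LABELS = ("left", "right", "central", "none")


@dataclass(frozen=True)
class Fixation:
    lead_index: int          # index into the sample timeline
    member_indices: tuple[int, ...]
    start_ms: float
    end_ms: float
    duration_ms: float
    centroid: tuple[float, float]
    aoi: str

    @property
    def n_samples(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class TrialMetrics:
    trial_id: str
    n_samples_total: int
    n_valid_samples: int
    n_fixations: dict[str, int]
    dwell_ms: dict[str, float]

    @property
    def combined_lr_dwell_ms(self) -> float:
        return self.dwell_ms["left"] + self.dwell_ms["right"]


def average_binocular(samples: pd.DataFrame, strict_both_eyes: bool = False) -> pd.DataFrame:
    """Collapse a binocular stream to mean monocular coordinates.

    Both eyes valid: midpoint.  Exactly one valid: that eye's coordinates
    (unless ``strict_both_eyes``).  Neither valid: the sample stays in the
    timeline but is marked invalid.  Sample count is preserved.
    """
    lx = samples["lx"].to_numpy(float)
    ly = samples["ly"].to_numpy(float)
    rx = samples["rx"].to_numpy(float)
    ry = samples["ry"].to_numpy(float)
    vl = samples["valid_l"].to_numpy(bool)
    vr = samples["valid_r"].to_numpy(bool)

    x = np.full(len(samples), np.nan)
    y = np.full(len(samples), np.nan)
    both = vl & vr
    x[both] = 0.5 * (lx[both] + rx[both])
    y[both] = 0.5 * (ly[both] + ry[both])
    if strict_both_eyes:
        valid = both
    else:
        only_l = vl & ~vr
        only_r = vr & ~vl
        x[only_l] = lx[only_l]
        y[only_l] = ly[only_l]
        x[only_r] = rx[only_r]
        y[only_r] = ry[only_r]
        valid = vl | vr
    out = pd.DataFrame({"t_ms": samples["t_ms"].to_numpy(float),
                        "x": x, "y": y, "valid": valid})
    if "trial_id" in samples.columns:
        out.insert(0, "trial_id", samples["trial_id"].to_numpy())
    return out


def detect_fixations(
    stream: pd.DataFrame,
    aois: AoiSet | None = None,
    radius_px: float = 23.0,
    min_run: int = 2,
    sample_rate_hz: float = 30.0,
) -> list[Fixation]:
    """Scan a monocular stream and emit dispersion-grouped fixations.

    ``stream`` must hold ``t_ms, x, y, valid`` in time order.  The duration
    convention is ``(last - first member time) + one sample interval`` so that
    an n-sample fixation at rate r lasts n/r seconds.  When ``aois`` is given,
    each fixation is labelled with the AOI containing its centroid.
    """
    t = stream["t_ms"].to_numpy(float)
    x = stream["x"].to_numpy(float)
    y = stream["y"].to_numpy(float)
    valid = stream["valid"].to_numpy(bool)
    interval = 1000.0 / sample_rate_hz
    r2 = float(radius_px) * float(radius_px)

    fixations: list[Fixation] = []
    members: list[int] = []
    lead_x = lead_y = 0.0

    def close() -> None:
        if len(members) >= min_run:
            mi = tuple(members)
            cx = float(np.mean(x[list(mi)]))
            cy = float(np.mean(y[list(mi)]))
            aoi = aois.assign(cx, cy) if aois is not None else "none"
            fixations.append(
                Fixation(
                    lead_index=mi[0],
                    member_indices=mi,
                    start_ms=float(t[mi[0]]),
                    end_ms=float(t[mi[-1]]),
                    duration_ms=float(t[mi[-1]] - t[mi[0]]) + interval,
                    centroid=(cx, cy),
                    aoi=aoi,
                )
            )

    for i in range(len(t)):
        if not valid[i]:
            if members:
                close()
                members = []
            continue
        xi = x[i]
        yi = y[i]
        if not members:
            members = [i]
            lead_x, lead_y = xi, yi
            continue
        dx = xi - lead_x
        dy = yi - lead_y
        if dx * dx + dy * dy <= r2:
            members.append(i)
        else:
            close()
            members = [i]
            lead_x, lead_y = xi, yi
    if members:
        close()
    return fixations


def compute_trial_metrics(
    stream: pd.DataFrame,
    fixations: list[Fixation],
    aois: AoiSet,
    sample_rate_hz: float = 30.0,
    trial_id: str = "",
) -> TrialMetrics:
    """Per-AOI fixation counts and sample-based dwell times for one trial."""
    valid = stream["valid"].to_numpy(bool)
    x = stream["x"].to_numpy(float)
    y = stream["y"].to_numpy(float)
    labels = aois.assign_array(x[valid], y[valid])
    dwell = {}
    for name in AOI_LABELS:
        n_in = int(np.sum(labels == name))
        dwell[name] = (n_in * 1000.0) / sample_rate_hz
    n_fix = {name: sum(1 for f in fixations if f.aoi == name) for name in AOI_LABELS}
    if not trial_id and "trial_id" in stream.columns and len(stream):
        trial_id = str(stream["trial_id"].iloc[0])
    return TrialMetrics(
        trial_id=trial_id,
        n_samples_total=len(stream),
        n_valid_samples=int(valid.sum()),
        n_fixations=n_fix,
        dwell_ms=dwell,
    )


def metrics_to_frame(metrics: list[TrialMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append(
            {
                "trial_id": m.trial_id,
                "n_samples": m.n_samples_total,
                "n_valid_samples": m.n_valid_samples,
                "n_fix_left": m.n_fixations["left"],
                "n_fix_right": m.n_fixations["right"],
                "n_fix_central": m.n_fixations["central"],
                "n_fix_none": m.n_fixations["none"],
                "dwell_left_ms": m.dwell_ms["left"],
                "dwell_right_ms": m.dwell_ms["right"],
                "dwell_central_ms": m.dwell_ms["central"],
                "dwell_none_ms": m.dwell_ms["none"],
                "combined_lr_dwell_ms": m.combined_lr_dwell_ms,
            }
        )
    return pd.DataFrame(rows)


def fixations_to_frame(trial_id: str, fixations: list[Fixation]) -> pd.DataFrame:
    rows = []
    for k, f in enumerate(fixations):
        rows.append(
            {
                "trial_id": trial_id,
                "fixation_index": k,
                "start_ms": f.start_ms,
                "duration_ms": f.duration_ms,
                "centroid_x": f.centroid[0],
                "centroid_y": f.centroid[1],
                "n_samples": f.n_samples,
                "aoi": f.aoi,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trial_id", "fixation_index", "start_ms", "duration_ms",
            "centroid_x", "centroid_y", "n_samples", "aoi",
        ],
    )


def process_trials(
    samples: pd.DataFrame,
    aois: AoiSet,
    radius_px: float = 23.0,
    min_run: int = 2,
    sample_rate_hz: float = 30.0,
    strict_both_eyes: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full processing chain for every trial in a raw sample table.

    Returns ``(fixations_df, trial_metrics_df)``.
    """
    fixation_frames = []
    metrics: list[TrialMetrics] = []
    for trial_id, chunk in samples.groupby("trial_id", sort=True):
        mono = average_binocular(chunk, strict_both_eyes=strict_both_eyes)
        fixes = detect_fixations(
            mono, aois=aois, radius_px=radius_px, min_run=min_run,
            sample_rate_hz=sample_rate_hz,
        )
        fixation_frames.append(fixations_to_frame(str(trial_id), fixes))
        metrics.append(
            compute_trial_metrics(
                mono, fixes, aois, sample_rate_hz=sample_rate_hz,
                trial_id=str(trial_id),
            )
        )
    nonempty = [f for f in fixation_frames if len(f)]
    fixations_df = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else fixations_to_frame("", [])
    )
    return fixations_df, metrics_to_frame(metrics)
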