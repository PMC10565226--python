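"""Curation of trial metrics into model-ready observations.

Chain: quality exclusion (trials with under 2000 ms of combined gaze on the
two lateral AOIs are discarded), averaging over the two horizontally mirrored
slide versions of each species (observation weight 2 when both versions
survived, 1 when only one did), and the threat-minus-relaxed difference
variables.  Positive differences mean more attention to the threatening
posture.

Also holds the demographic age comparison (Mann-Whitney U with a
tie-corrected normal approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "qc_filter",
    "mirror_pair_average",
    "compute_differences",
    "compare_ages",
    "CurationSummary",
    "curate",
]

_REQUIRED_TRIAL_COLS = [
    "trial_id", "participant_id", "species_id", "morphotype", "side_of_threat",
    "nationality", "gender", "age",
    "n_fix_left", "n_fix_right", "dwell_left_ms", "dwell_right_ms",
    "combined_lr_dwell_ms",
]


def qc_filter(
    trial_metrics: pd.DataFrame, min_combined_dwell_ms: float = 2000.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split trials into (kept, excluded) by combined lateral dwell time.

    The cut is strict: a trial is excluded when its combined left+right dwell
    is under the threshold; exactly at the threshold it is kept.  The excluded
    frame carries a ``reason`` column.
    """
    below = trial_metrics["combined_lr_dwell_ms"] < min_combined_dwell_ms
    kept = trial_metrics.loc[~below].copy()
    excluded = trial_metrics.loc[below].copy()
    excluded["reason"] = (
        f"combined_lr_dwell_ms < {min_combined_dwell_ms:g}"
    )
    return kept, excluded


def mirror_pair_average(kept_trials: pd.DataFrame) -> pd.DataFrame:
    """Average metrics over mirror pairs into participant x species observations.

    ``kept_trials`` must carry trial metadata (participant, species,
    side_of_threat, demographics) alongside the per-side metrics.  Threat-side
    metrics are read off each trial according to its ``side_of_threat``; when
    both slide versions of a species survived the quality cut their metrics
    are arithmetically averaged (weight 2), a lone survivor keeps its metrics
    with weight 1.  Averaged fixation counts may be half-integer and are kept
    as such.
    """
    missing = [c for c in _REQUIRED_TRIAL_COLS if c not in kept_trials.columns]
    if missing:
        raise ValueError(f"kept_trials is missing columns: {missing}")

    df = kept_trials.copy()
    threat_is_left = df["side_of_threat"] == "left"
    df["fix_threat"] = np.where(threat_is_left, df["n_fix_left"], df["n_fix_right"])
    df["fix_relax"] = np.where(threat_is_left, df["n_fix_right"], df["n_fix_left"])
    df["dwell_threat_ms"] = np.where(
        threat_is_left, df["dwell_left_ms"], df["dwell_right_ms"]
    )
    df["dwell_relax_ms"] = np.where(
        threat_is_left, df["dwell_right_ms"], df["dwell_left_ms"]
    )

    sizes = df.groupby(["participant_id", "species_id"]).size()
    if (sizes > 2).any():
        bad = sizes[sizes > 2].index.tolist()
        raise ValueError(
            f"more than two surviving trials for participant x species: {bad}"
        )

    grouped = df.groupby(["participant_id", "species_id"], sort=True)
    obs = grouped.agg(
        morphotype=("morphotype", "first"),
        nationality=("nationality", "first"),
        gender=("gender", "first"),
        age=("age", "first"),
        weight=("trial_id", "size"),
        fix_threat=("fix_threat", "mean"),
        fix_relax=("fix_relax", "mean"),
        dwell_threat_ms=("dwell_threat_ms", "mean"),
        dwell_relax_ms=("dwell_relax_ms", "mean"),
    ).reset_index()
    obs["weight"] = obs["weight"].astype(int)
    return obs


def compute_differences(observations: pd.DataFrame) -> pd.DataFrame:
    """Add the threat-minus-relaxed response variables (positive = more
    attention to the threatening posture)."""
    out = observations.copy()
    out["diff_fix"] = out["fix_threat"] - out["fix_relax"]
    out["diff_dwell_ms"] = out["dwell_threat_ms"] - out["dwell_relax_ms"]
    return out


def compare_ages(ages_a, ages_b, method: str = "asymptotic") -> tuple[float, float, float]:
    """Mann-Whitney comparison of two age samples.

    Returns ``(U, Z, p)`` where U is the statistic for the first sample and Z
    its tie-corrected normal deviate (no continuity correction).  With
    ``method="asymptotic"`` (the default, appropriate at study sample sizes)
    p is the two-sided normal p-value; with ``method="exact"`` p is the exact
    two-sided permutation p-value, obtained by enumerating every assignment
    of the pooled ages to the two groups (small samples only).
    """
    a = np.asarray(ages_a, dtype=float)
    b = np.asarray(ages_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both age groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (u1 - mu) / np.sqrt(var) if var > 0 else 0.0

    if method == "asymptotic":
        p = 2.0 * stats.norm.sf(abs(z)) if var > 0 else 1.0
    elif method == "exact":
        import itertools

        if n > 18:
            raise ValueError("exact enumeration is limited to small samples")
        obs = abs(u1 - mu)
        hits = 0
        total = 0
        for comb in itertools.combinations(range(n), n1):
            r = ranks[list(comb)].sum()
            u = r - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(u1), float(z), float(min(p, 1.0))


@dataclass(frozen=True)
class CurationSummary:
    n_trials_total: int
    n_excluded: int
    n_retained: int
    excluded_percent: float
    n_observations: int
    n_weight2: int
    retained_by_nationality: dict[str, int]

    @classmethod
    def from_frames(
        cls,
        trial_metrics: pd.DataFrame,
        excluded: pd.DataFrame,
        kept: pd.DataFrame,
        observations: pd.DataFrame,
    ) -> "CurationSummary":
        total = len(trial_metrics)
        n_exc = len(excluded)
        by_nat = (
            kept.groupby("nationality").size().to_dict()
            if "nationality" in kept.columns
            else {}
        )
        return cls(
            n_trials_total=total,
            n_excluded=n_exc,
            n_retained=total - n_exc,
            excluded_percent=round(100.0 * n_exc / total, 2) if total else 0.0,
            n_observations=len(observations),
            n_weight2=int((observations["weight"] == 2).sum()) if len(observations) else 0,
            retained_by_nationality={str(k): int(v) for k, v in by_nat.items()},
        )


def curate(
    trial_metrics: pd.DataFrame,
    trials: pd.DataFrame,
    participants: pd.DataFrame,
    stimuli: pd.DataFrame,
    min_combined_dwell_ms: float = 2000.0,
) -> tuple[pd.DataFrame, pd.DataFrame, CurationSummary]:
    """Full curation chain from per-trial metrics to model observations.

    Joins metrics with trial, stimulus and participant metadata, drops the
    practise slide, applies the quality cut, averages mirror pairs and adds
    the difference variables.  Returns ``(observations, excluded, summary)``.
    """
    merged = (
        trial_metrics.merge(
            trials[["trial_id", "participant_id", "stimulus_version_id",
                    "is_practise"]],
            on="trial_id", how="left", validate="one_to_one",
        )
        .merge(
            stimuli[["stimulus_version_id", "species_id", "morphotype",
                     "side_of_threat"]],
            on="stimulus_version_id", how="left",
        )
        .merge(
            participants[["participant_id", "nationality", "gender", "age"]],
            on="participant_id", how="left",
        )
    )
    if merged["participant_id"].isna().any() or merged["species_id"].isna().any():
        raise ValueError("trial metadata mismatch: unmatched trial_id rows")
    experimental = merged.loc[~merged["is_practise"].astype(bool)].copy()
    kept, excluded = qc_filter(experimental, min_combined_dwell_ms)
    observations = compute_differences(mirror_pair_average(kept))
    summary = CurationSummary.from_frames(experimental, excluded, kept, observations)
    return observations, excluded, summary
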