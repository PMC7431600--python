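"""Reduction of diameter time series to constriction-versus-distance profiles.

Each vessel's diameters are normalized to the mean resting diameter at the
same position; the stimulated diameter is the average of the three samples
taken 10, 20 and 30 s after stimulation onset.  Relative constriction is
(rest - stim) / rest, positive for narrowing.  Once the profile reaches 0
or a negative value at some distance, it is set to exactly 0 from that
distance onward (the conducted response is considered extinguished).
Vessels then pass three inclusion criteria before their points are pooled
per group: >= 5% local constriction, recovery to >= 50% of baseline at the
stimulation site, and >= 3 measurable positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import (PHASE_BASELINE, PHASE_RECOVERY, PHASE_STIMULATION,
                        VesselRecording)

__all__ = [
    "ConstrictionProfile",
    "InclusionDecision",
    "PooledGroupData",
    "resting_diameter",
    "stimulation_diameter",
    "relative_constriction",
    "truncate_profile",
    "build_profile",
    "apply_inclusion_criteria",
    "pool_group",
]

LOCAL_CONSTRICTION_MIN = 0.05
RECOVERY_DIAMETER_MIN_FRACTION = 0.50
MIN_MEASURABLE_POSITIONS = 3

CRITERION_LOCAL = "local_constriction_min"
CRITERION_RECOVERY = "recovery_min"
CRITERION_POSITIONS = "position_min"


@dataclass(frozen=True)
class ConstrictionProfile:
    """Per-vessel relative constriction as a function of distance, after
    zero-truncation.  ``truncated_from`` is the index of the first
    zero-truncated distance, or ``None`` if the rule never fired."""

    vessel_id: str
    group_label: str
    distances: np.ndarray
    constriction: np.ndarray
    truncated_from: int | None
    resting_diameters: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "distances", np.asarray(self.distances, float))
        object.__setattr__(self, "constriction",
                           np.asarray(self.constriction, float))
        object.__setattr__(self, "resting_diameters",
                           np.asarray(self.resting_diameters, float))
        if np.any(self.constriction > 1):
            raise ValueError("relative constriction cannot exceed 1")
        if self.truncated_from is not None and not np.all(
                self.constriction[self.truncated_from:] == 0.0):
            raise ValueError("values after the truncation index must be 0")


@dataclass(frozen=True)
class InclusionDecision:
    """Outcome of the inclusion criteria for one vessel; ``failed_criteria``
    maps each failed criterion name to the measured value."""

    vessel_id: str
    included: bool
    failed_criteria: dict[str, float]

    def __post_init__(self) -> None:
        if self.included != (len(self.failed_criteria) == 0):
            raise ValueError("included must mirror an empty failed_criteria")


@dataclass(frozen=True)
class PooledGroupData:
    """All (distance, constriction) points of one group, pooled across its
    included vessels, plus per-distance mean / SEM / n summaries."""

    group_label: str
    points: pd.DataFrame        # columns: distance_um, constriction, vessel_id
    per_distance: pd.DataFrame  # columns: distance_um, mean, sem, n

    def point_array(self) -> np.ndarray:
        """(N, 2) array of (distance, constriction) for fitting."""
        return self.points[["distance_um", "constriction"]].to_numpy(float)

    def values_at(self, distance: float) -> np.ndarray:
        m = np.isclose(self.points["distance_um"].to_numpy(float), distance)
        return self.points.loc[m, "constriction"].to_numpy(float)


def _phase_values(recording: VesselRecording, position: float,
                  phase: str) -> np.ndarray:
    i = recording.position_index(position)
    return recording.diameters[i, recording.time_mask(phase)]


def resting_diameter(recording: VesselRecording, position: float) -> float:
    """Mean baseline-phase diameter at ``position`` (um)."""
    vals = _phase_values(recording, position, PHASE_BASELINE)
    if vals.size == 0:
        raise ValueError(
            f"vessel {recording.vessel_id}: no baseline samples at {position} um")
    return float(np.mean(vals))


def stimulation_diameter(recording: VesselRecording, position: float) -> float:
    """Mean of the samples 10, 20 and 30 s after stimulation onset."""
    i = recording.position_index(position)
    onset = _stimulation_onset(recording)
    wanted = onset + np.array([10.0, 20.0, 30.0])
    vals = []
    for t in wanted:
        j = np.nonzero(np.isclose(recording.times, t))[0]
        if j.size == 0 or not np.isfinite(recording.diameters[i, j[0]]):
            raise ValueError(
                f"vessel {recording.vessel_id}: missing stimulation sample at "
                f"t = {t:g} s ({t - onset:g} s after onset) for {position} um")
        vals.append(recording.diameters[i, j[0]])
    return float(np.mean(vals))


def _stimulation_onset(recording: VesselRecording) -> float:
    stim = recording.time_mask(PHASE_STIMULATION)
    if not stim.any():
        raise ValueError(f"vessel {recording.vessel_id}: no stimulation phase")
    # samples are interval-ending: onset is one interval before the first
    # stimulation-phase sample
    first = recording.times[stim][0]
    dt = np.diff(recording.times).min() if recording.times.size > 1 else first
    return float(first - dt)


def relative_constriction(d_rest: float, d_stim: float) -> float:
    """(d_rest - d_stim) / d_rest: positive for narrowing, negative for
    dilation."""
    if not (np.isfinite(d_rest) and d_rest > 0):
        raise ValueError(f"resting diameter must be > 0, got {d_rest}")
    if not (np.isfinite(d_stim) and d_stim >= 0):
        raise ValueError(f"stimulated diameter must be >= 0, got {d_stim}")
    return (d_rest - d_stim) / d_rest


def truncate_profile(values: np.ndarray) -> tuple[np.ndarray, int | None]:
    """Zero out the profile from the first non-positive entry onward.

    Returns the truncated copy and the truncation index (``None`` if no
    entry was <= 0).  Idempotent.
    """
    vals = np.asarray(values, float).copy()
    nonpos = np.nonzero(vals <= 0)[0]
    if nonpos.size == 0:
        return vals, None
    k = int(nonpos[0])
    vals[k:] = 0.0
    return vals, k


def build_profile(recording: VesselRecording) -> ConstrictionProfile:
    """Per-position relative constriction for one vessel, zero-truncated."""
    rest = np.array([resting_diameter(recording, x) for x in recording.positions])
    stim = np.array([stimulation_diameter(recording, x)
                     for x in recording.positions])
    raw = np.array([relative_constriction(r, s) for r, s in zip(rest, stim)])
    vals, k = truncate_profile(raw)
    return ConstrictionProfile(vessel_id=recording.vessel_id,
                               group_label=recording.group_label,
                               distances=recording.positions.copy(),
                               constriction=vals, truncated_from=k,
                               resting_diameters=rest)


def apply_inclusion_criteria(profile: ConstrictionProfile,
                             recording: VesselRecording) -> InclusionDecision:
    """Evaluate the three inclusion criteria for one vessel.

    1. local constriction at 0 um of at least 5%;
    2. mean recovery-phase diameter at 0 um of at least 50% of the resting
       diameter there;
    3. measurable diameters at >= 3 positions (stimulation site included).
    """
    failed: dict[str, float] = {}

    # criterion 1 uses the pre-truncation local value, which at index 0 is
    # identical to the truncated one unless the local response itself is <= 0
    local = float(profile.constriction[0])
    if profile.truncated_from == 0:
        rest0 = resting_diameter(recording, 0.0)
        local = relative_constriction(rest0, stimulation_diameter(recording, 0.0))
    if local < LOCAL_CONSTRICTION_MIN:
        failed[CRITERION_LOCAL] = local

    rest0 = float(profile.resting_diameters[0])
    recovery = _phase_values(recording, 0.0, PHASE_RECOVERY)
    recovery_frac = float(np.mean(recovery)) / rest0 if recovery.size else 0.0
    if recovery_frac < RECOVERY_DIAMETER_MIN_FRACTION:
        failed[CRITERION_RECOVERY] = recovery_frac

    n_positions = int(np.sum(np.isfinite(recording.diameters).all(axis=1)))
    if n_positions < MIN_MEASURABLE_POSITIONS:
        failed[CRITERION_POSITIONS] = float(n_positions)

    return InclusionDecision(vessel_id=profile.vessel_id,
                             included=not failed, failed_criteria=failed)


def pool_group(profiles: list[ConstrictionProfile], label: str) -> PooledGroupData:
    """Pool all (distance, constriction) points of one group's included
    vessels and summarise per distance (mean, SEM = sd/sqrt(n), n).

    Zero-truncated values are retained as exact 0s: a vessel contributes a
    point at every distance it could be traced to, so per-distance counts
    are non-increasing with distance.
    """
    if not profiles:
        raise ValueError(f"group {label!r}: no profiles to pool")
    for p in profiles:
        if p.group_label != label:
            raise ValueError(
                f"profile {p.vessel_id} belongs to {p.group_label!r}, not {label!r}")
    rows = [(float(x), float(c), p.vessel_id)
            for p in profiles for x, c in zip(p.distances, p.constriction)]
    points = pd.DataFrame(rows, columns=["distance_um", "constriction",
                                         "vessel_id"])
    g = points.groupby("distance_um")["constriction"]
    per_distance = pd.DataFrame({
        "distance_um": g.mean().index,
        "mean": g.mean().to_numpy(),
        "sem": g.apply(lambda v: v.std(ddof=1) / np.sqrt(len(v))
                       if len(v) > 1 else np.nan).to_numpy(),
        "n": g.size().to_numpy(),
    }).reset_index(drop=True)
    return PooledGroupData(group_label=label, points=points,
                           per_distance=per_distance)
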