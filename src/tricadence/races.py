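"""Race-table processing: exclusions, same-day averaging, GPS imputation.

Observations are rows of a pandas DataFrame in the longitudinal CSV dialect
(``participant_id, week, season, discipline, cadence, distance_m,
duration_s, flags``), with flags a semicolon-joined subset of
{unwell, injured_during_race, imu_attachment_fault, gps_fail}.  A ``date``
column may stand in for ``week`` when calendar dates are available; grouping
keys fall back to ``week`` otherwise.

Rules applied when assembling the analysable dataset:

1. races carrying any exclusion flag are dropped as units;
2. multiple races by one participant on one day in one discipline are
   averaged to a single observation (longitudinal, not acute, change is the
   target);
3. discipline chaining — a cycle leg is kept only if the same-day swim
   survived, and a run leg only if both swim and cycle survived, because the
   preceding leg's performance carries into the next.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUSION_FLAGS",
    "remove_flagged",
    "apply_exclusions",
    "merge_same_day",
    "impute_distance",
    "race_velocity",
    "assemble_dataset",
]

EXCLUSION_FLAGS = frozenset(
    {"unwell", "injured_during_race", "imu_attachment_fault", "gps_fail"}
)

_MERGE_COLS = ("cadence", "distance_m", "duration_s", "velocity_ms")


class InconsistentRecordError(ValueError):
    """Same-day races disagree on a label that must be constant."""


class ImputationImpossibleError(ValueError):
    """No peer distances available to impute from."""


def _flag_set(value) -> set[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return set()
    return {tok for tok in str(value).split(";") if tok}


def _date_key(df: pd.DataFrame) -> str:
    return "date" if "date" in df.columns else "week"


def remove_flagged(observations: pd.DataFrame) -> pd.DataFrame:
    """Drop every observation carrying at least one exclusion flag."""
    if observations.empty:
        return observations.copy()
    keep = observations["flags"].apply(lambda v: not (_flag_set(v) & EXCLUSION_FLAGS))
    return observations[keep].reset_index(drop=True)


def apply_exclusions(observations: pd.DataFrame) -> pd.DataFrame:
    """Remove flagged races, then enforce discipline chaining per
    participant-date: cycle needs the swim, run needs swim and cycle."""
    clean = remove_flagged(observations)
    if clean.empty:
        return clean
    key = _date_key(clean)

    def _chain(group: pd.DataFrame) -> pd.DataFrame:
        present = set(group["discipline"])
        allowed = {"swim"}
        if "swim" in present:
            allowed.add("cycle")
            if "cycle" in present:
                allowed.add("run")
        return group[group["discipline"].isin(allowed)]

    out = (
        clean.groupby(["participant_id", key], group_keys=False, sort=False)[clean.columns]
        .apply(_chain)
        .reset_index(drop=True)
    )
    return out


def merge_same_day(observations: pd.DataFrame) -> pd.DataFrame:
    """Average same-day races per (participant, date, discipline).

    Cadence, distance, duration and velocity (when present) are replaced by
    the group arithmetic mean; season and week must agree within a group.
    """
    if observations.empty:
        return observations.copy()
    key = _date_key(observations)
    group_cols = ["participant_id", key, "discipline"]

    rows = []
    for _, group in observations.groupby(group_cols, sort=False):
        if group["season"].nunique() > 1:
            raise InconsistentRecordError(
                f"conflicting season labels within {tuple(group[group_cols].iloc[0])}"
            )
        merged = group.iloc[0].copy()
        for col in _MERGE_COLS:
            if col in group.columns:
                merged[col] = group[col].mean()
        merged["flags"] = ";".join(sorted(set().union(*(map(_flag_set, group["flags"])))))
        rows.append(merged)
    return pd.DataFrame(rows).reset_index(drop=True)


def impute_distance(peer_distances_m) -> float:
    """Impute a failed-GPS race distance as the mean of the distances
    recorded by other participants' working sensors in the same race."""
    peers = np.asarray([d for d in peer_distances_m if np.isfinite(d)], dtype=float)
    if peers.size == 0:
        raise ImputationImpossibleError("no functioning peer GPS distances in this race")
    return float(peers.mean())


def race_velocity(distance_m: float, duration_s: float) -> float:
    """Average race velocity in m/s."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    return distance_m / duration_s


def assemble_dataset(observations: pd.DataFrame) -> pd.DataFrame:
    """Full assembly: drop flagged races, average same-day repeats, chain
    disciplines, and attach average race velocity."""
    staged = merge_same_day(remove_flagged(observations))
    out = apply_exclusions(staged)
    if not out.empty:
        out = out.copy()
        out["velocity_ms"] = out["distance_m"] / out["duration_s"]
    return out
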