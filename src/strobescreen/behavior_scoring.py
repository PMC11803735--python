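"""Strobe-response scoring and solvent-null hit calling.

The strobe score for a well is the average, over six 5-second windows spread
across a strobing-light segment, of the maximum MI inside each window, minus
the mean MI over a pre-strobe baseline interval.  Vehicle larvae freeze under
the strobe, so their scores are negative; the hyperactive phenotype scores
strongly positive.  A screening compound is a hit when its blue strobe score
is at least two solvent-score standard deviations above the highest solvent
well's score — an empirical-max null that needs no distributional assumption
on the compound scores.
"""

from __future__ import annotations


from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .battery import StimulusSchedule
from .motion_index import WellTrace

N_WINDOWS = 6
WINDOW_S = 5.0
DEFAULT_BASELINE_S = 30.0


def strobe_windows(
    schedule: StimulusSchedule,
    segment_label: str,
    n_windows: int = N_WINDOWS,
    window_s: float = WINDOW_S,
) -> list[tuple[float, float]]:
    """Six 5 s scoring windows evenly spread across a strobe segment.

    Window i starts at ``seg.start + i * (D - w) / (n - 1)`` for segment
    duration D, so the first window opens the segment and the last closes it
    (for D = 120 s: starts 0, 23, 46, 69, 92, 115 s; D = 30 s gives six
    contiguous windows).  Segments shorter than ``n * w`` are rejected.
    """
    seg = schedule.segment(segment_label)
    D = seg.duration_s
    if D < n_windows * window_s:
        raise ValueError(
            f"segment {segment_label!r} ({D:g} s) too short for "
            f"{n_windows} windows of {window_s:g} s"
        )
    step = (D - window_s) / (n_windows - 1)
    return [
        (seg.start_s + i * step, seg.start_s + i * step + window_s)
        for i in range(n_windows)
    ]


def _window_slice(trace: WellTrace, start_s: float, end_s: float) -> np.ndarray:
    i0 = int(round(start_s * trace.frame_rate_hz))
    i1 = int(round(end_s * trace.frame_rate_hz))
    return trace.mi[max(i0, 0) : i1]


def strobe_score(
    trace: WellTrace,
    windows: Sequence[tuple[float, float]],
    baseline_interval: tuple[float, float],
) -> float:
    """Mean of per-window MI maxima minus the mean MI over the baseline interval.

    The baseline term makes freezing phenotypes score negative; raw (un-
    normalized) scores are the hit-calling currency.
    """
    if not windows:
        raise ValueError("no scoring windows supplied")
    maxima = []
    for (w0, w1) in windows:
        vals = _window_slice(trace, w0, w1)
        if vals.size == 0:
            raise ValueError(f"window [{w0}, {w1}) s contains no samples")
        maxima.append(vals.max())
    base = _window_slice(trace, *baseline_interval)
    if base.size == 0:
        raise ValueError(f"baseline interval {baseline_interval} contains no samples")
    return float(np.mean(maxima) - base.mean())


def default_baseline_interval(
    schedule: StimulusSchedule, segment_label: str, baseline_s: float = DEFAULT_BASELINE_S
) -> tuple[float, float]:
    """The ``baseline_s`` seconds immediately preceding the strobe segment."""
    seg = schedule.segment(segment_label)
    start = max(seg.start_s - baseline_s, 0.0)
    if start >= seg.start_s:
        raise ValueError(f"no room for a baseline before segment {segment_label!r}")
    return (start, seg.start_s)


def score_traces(
    traces: Sequence[WellTrace],
    schedule: StimulusSchedule,
    blue_label: str = "blue_strobe",
    green_label: str = "green_strobe",
    baseline_s: float = DEFAULT_BASELINE_S,
) -> pd.DataFrame:
    """Blue and green strobe scores for every well, raw and batch-normalized.

    Returns a DataFrame with one row per well: plate, well, treatment,
    concentration_um, battery_avg_mi (the viability metric: below 1 is
    consistent with lethality), blue_score, green_score, normalized_blue,
    normalized_green.  Normalization is min-max over the batch per channel;
    with fewer than two distinct values the normalized columns are NaN.
    """
    if not traces:
        raise ValueError("no traces supplied")
    rows = []
    wins = {
        "blue": strobe_windows(schedule, blue_label),
        "green": strobe_windows(schedule, green_label),
    }
    bases = {
        "blue": default_baseline_interval(schedule, blue_label, baseline_s),
        "green": default_baseline_interval(schedule, green_label, baseline_s),
    }
    for t in traces:
        rows.append(
            {
                "plate": t.plate,
                "well": t.well,
                "treatment": t.treatment,
                "concentration_um": t.concentration_um,
                "battery_avg_mi": float(t.mi.mean()),
                "blue_score": strobe_score(t, wins["blue"], bases["blue"]),
                "green_score": strobe_score(t, wins["green"], bases["green"]),
            }
        )
    df = pd.DataFrame(rows)
    for ch in ("blue", "green"):
        col = df[f"{ch}_score"]
        try:
            df[f"normalized_{ch}"] = normalize_scores(col.to_numpy())
        except ValueError:
            df[f"normalized_{ch}"] = np.nan
    return df


def normalize_scores(scores: Sequence[float]) -> np.ndarray:
    """Min-max rescaling of a batch of scores to [0, 1] (order preserving).

    Constant input has an undefined range and is rejected.
    """
    arr = np.asarray(scores, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValueError("cannot normalize a constant score batch")
    return (arr - lo) / (hi - lo)


def call_hits(
    test_scores: Mapping[str, float] | pd.Series,
    solvent_scores: Sequence[float],
) -> pd.DataFrame:
    """Empirical-max hit rule: threshold = max(solvent) + 2 x SD(solvent).

    ``test_scores`` maps compound id to its (blue) strobe score.  A score
    tied with the threshold counts as a hit (the rule reads "at least").
    The returned table carries the threshold provenance per row.
    """
    sol = np.asarray(list(solvent_scores), dtype=float)
    if sol.size < 2:
        raise ValueError("need at least 2 solvent wells to estimate the SD")
    if isinstance(test_scores, pd.Series):
        items = list(test_scores.items())
    else:
        items = list(test_scores.items())
    solvent_max = float(sol.max())
    solvent_sd = float(sol.std(ddof=1))
    threshold = solvent_max + 2.0 * solvent_sd
    rows = [
        {
            "compound": cid,
            "score": float(s),
            "solvent_max": solvent_max,
            "solvent_sd": solvent_sd,
            "threshold": threshold,
            "is_hit": bool(s >= threshold),
        }
        for cid, s in items
    ]
    return pd.DataFrame(rows)


def retest_dose_summary(
    scores: pd.DataFrame,
    vehicle_treatment: str = "vehicle",
    score_col: str = "blue_score",
) -> pd.DataFrame:
    """Replicate retest summary: mean score per compound x concentration,
    flagged distinct when the condition mean clears the vehicle mean by at
    least two vehicle SDs.

    ``scores`` is a per-well table with treatment, concentration_um and the
    score column (as produced by :func:`score_traces`).
    """
    if score_col not in scores.columns:
        raise ValueError(f"missing score column {score_col!r}")
    veh = scores.loc[scores["treatment"] == vehicle_treatment, score_col]
    if veh.empty:
        raise ValueError(f"no wells with vehicle treatment {vehicle_treatment!r}")
    veh_mean = float(veh.mean())
    veh_sd = float(veh.std(ddof=1)) if len(veh) > 1 else 0.0
    cutoff = veh_mean + 2.0 * veh_sd
    grouped = (
        scores.groupby(["treatment", "concentration_um"], dropna=False)[score_col]
        .agg(mean_score="mean", n_wells="count")
        .reset_index()
    )
    grouped["vehicle_mean"] = veh_mean
    grouped["vehicle_sd"] = veh_sd
    grouped["distinct_from_vehicle"] = grouped["mean_score"] > cutoff
    return grouped
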