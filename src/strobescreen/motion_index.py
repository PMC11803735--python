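"""Motion-index quantification from well-plate video.

The motion index (MI) for a well is the sum over the well's region of
interest of absolute pixel-intensity differences between consecutive video
frames: ``MI_t = sum(abs(frame_{t+1} - frame_t))``.  A stack of N frames
therefore yields N-1 MI samples, each time-stamped at the later frame of the
pair.  MI is left in raw arbitrary units; wells are compared at identical
ROI areas so no per-well normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FrameStack:
    """Grayscale video frames plus a well-ROI grid.

    ``frames`` is an integer array of shape (n_frames, height, width).
    ``rois`` maps well labels to half-open pixel rectangles
    ``(row0, col0, row1, col1)``.
    """

    frames: np.ndarray
    frame_rate_hz: float
    rois: Mapping[str, tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n_frames, H, W) array with n >= 1")
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise ValueError("frames must have an integer dtype")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        _, h, w = self.frames.shape
        boxes = []
        for well, (r0, c0, r1, c1) in self.rois.items():
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(f"ROI for well {well!r} outside frame bounds")
            boxes.append((well, r0, c0, r1, c1))
        for i, (wa, a0, b0, a1, b1) in enumerate(boxes):
            for wb, c0_, d0, c1_, d1 in boxes[i + 1:]:
                if a0 < c1_ and c0_ < a1 and b0 < d1 and d0 < b1:
                    raise ValueError(f"ROIs for wells {wa!r} and {wb!r} overlap")


@dataclass
class WellTrace:
    """One well's MI time series with plate/treatment annotation."""

    plate: str
    well: str
    treatment: str
    concentration_um: Optional[float]
    mi: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.mi = np.asarray(self.mi, dtype=float)
        if self.mi.ndim != 1:
            raise ValueError("mi must be a 1-D array")
        if self.mi.size and self.mi.min() < 0:
            raise ValueError("MI values must be nonnegative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def times_s(self) -> np.ndarray:
        # sample t covers the interval ending at frame t+1
        return (np.arange(self.mi.size) + 1) / self.frame_rate_hz


def compute_mi(
    stack: FrameStack,
    roi: str | tuple[int, int, int, int],
    *,
    plate: str = "",
    treatment: str = "",
    concentration_um: Optional[float] = None,
) -> WellTrace:
    """Frame-difference MI trace for one well ROI.

    The absolute differences are accumulated in int64 so 8/16-bit frames can
    never wrap around.  A single-frame stack yields an empty trace.
    """
    if isinstance(roi, str):
        well = roi
        r0, c0, r1, c1 = stack.rois[roi]
    else:
        well = ""
        r0, c0, r1, c1 = roi
    sub = stack.frames[:, r0:r1, c0:c1].astype(np.int64)
    if sub.shape[0] < 2:
        mi = np.zeros(0)
    else:
        mi = np.abs(np.diff(sub, axis=0)).sum(axis=(1, 2)).astype(float)
    return WellTrace(
        plate=plate,
        well=well,
        treatment=treatment,
        concentration_um=concentration_um,
        mi=mi,
        frame_rate_hz=stack.frame_rate_hz,
    )


def battery_average_mi(trace: WellTrace) -> float:
    """Arithmetic mean MI over the entire battery (a single activity value)."""
    if trace.mi.size == 0:
        raise ValueError("cannot average an empty trace")
    return float(trace.mi.mean())


def lethality_flag(avg_mi: float) -> bool:
    """A battery-average MI below 1 is consistent with lethality (strict)."""
    if avg_mi < 0:
        raise ValueError("battery-average MI must be nonnegative")
    return avg_mi < 1.0


def dose_response_summary(
    traces: Sequence[WellTrace], confidence: float = 0.95
) -> pd.DataFrame:
    """Per treatment x concentration mean battery-average MI with t-based CI.

    Returns a DataFrame with columns treatment, concentration_um, mean_mi,
    ci_low, ci_high, n_wells.  The CI is Student-t with n-1 df (small per-dose
    well counts); it degenerates to the mean when n = 1.
    """
    if not traces:
        raise ValueError("no traces supplied")
    rows = []
    key = lambda t: (t.treatment, t.concentration_um)
    groups: dict[tuple, list[float]] = {}
    for t in traces:
        groups.setdefault(key(t), []).append(battery_average_mi(t))
    for (treatment, conc), vals in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1] if kv[0][1] is not None else -1.0)
    ):
        arr = np.asarray(vals)
        n = arr.size
        m = arr.mean()
        if n > 1:
            sem = arr.std(ddof=1) / np.sqrt(n)
            half = stats.t.ppf(0.5 + confidence / 2, df=n - 1) * sem
        else:
            half = 0.0
        rows.append(
            {
                "treatment": treatment,
                "concentration_um": conc,
                "mean_mi": m,
                "ci_low": m - half,
                "ci_high": m + half,
                "n_wells": n,
            }
        )
    return pd.DataFrame(rows)
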