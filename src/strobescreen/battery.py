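"""Stimulus battery schedules.

A behavioral battery is a timed sequence of assay segments (acoustic pulses,
plate taps, steady light, strobing light, and inter-assay rest) during which
larval activity is recorded.  Segments use half-open intervals ``[start, end)``
in seconds; the schedule is the scoring frame of reference for every
downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Optional

SEGMENT_KINDS = ("rest", "acoustic", "tap", "light", "strobe")


@dataclass(frozen=True)
class Segment:
    """One battery segment.

    Parameters
    ----------
    label : str
        Unique name within a schedule, e.g. ``"blue_strobe"``.
    kind : str
        One of :data:`SEGMENT_KINDS`.
    start_s, end_s : float
        Half-open interval in seconds from battery start.
    wavelength_nm, irradiance_uw_mm2 : float, optional
        Nominal light parameters for light/strobe segments.
    strobe_hz : float, optional
        Flash frequency for strobe segments.
    """

    label: str
    kind: str
    start_s: float
    end_s: float
    wavelength_nm: Optional[float] = None
    irradiance_uw_mm2: Optional[float] = None
    strobe_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise ValueError(
                f"segment {self.label!r} has non-positive duration "
                f"[{self.start_s}, {self.end_s})"
            )
        if self.kind == "strobe" and not self.strobe_hz:
            raise ValueError(f"strobe segment {self.label!r} needs strobe_hz")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class StimulusSchedule:
    """An ordered, non-overlapping sequence of :class:`Segment`."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise ValueError("schedule must contain at least one segment")
        labels = [s.label for s in segs]
        if len(set(labels)) != len(labels):
            raise ValueError("segment labels must be unique")
        for a, b in zip(segs, segs[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"segments {a.label!r} and {b.label!r} overlap or are unordered"
                )
        object.__setattr__(self, "segments", segs)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def total_s(self) -> float:
        return self.segments[-1].end_s

    def segment(self, label: str) -> Segment:
        for s in self.segments:
            if s.label == label:
                return s
        raise KeyError(f"no segment labeled {label!r}")

    def strobe_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.kind == "strobe"]

    def to_records(self) -> list[dict]:
        return [asdict(s) for s in self.segments]

    @classmethod
    def from_records(cls, records: list[dict]) -> "StimulusSchedule":
        return cls(tuple(Segment(**r) for r in records))
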