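"""Source-event tracking and localization scoring.

Frame-wise MUSIC peaks are strung into contiguous source events: a peak
joins the most recent open event whose last azimuth lies within
MIN_SRC_INTERVAL degrees (circularly), and an event closes once no peak
has joined for PAUSE_LENGTH milliseconds.  Localization accuracy follows
the field convention of dividing the annotated ("actual") call duration
by the localized event duration, reported as an unclamped percentage —
it is a coverage ratio, so over-long localizations push it below 100%
and under-coverage can push it above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrackingParams",
    "SourceEvent",
    "circular_difference_deg",
    "form_events",
    "localization_accuracy",
    "doa_histogram",
    "temporal_distribution",
]


@dataclass(frozen=True)
class TrackingParams:
    """Event-formation parameters (field defaults).

    pause_length: ms a source may fall silent before its event closes.
    min_src_interval: max angular jump (deg) still counted as the same source.
    period: frames between localization evaluations.
    thresh: spatial-spectrum threshold separating source from noise.
    lower_hz/upper_hz: localization frequency band.
    num_source: sources tracked simultaneously.
    """

    pause_length: float = 500.0
    min_src_interval: float = 10.0
    period: int = 16
    thresh: float = 13.0
    lower_hz: float = 100.0
    upper_hz: float = 200.0
    num_source: int = 1

    def __post_init__(self) -> None:
        if self.pause_length <= 0:
            raise ValueError("pause_length must be positive")
        if not 0 < self.min_src_interval <= 180:
            raise ValueError("min_src_interval must be in (0, 180] degrees")


@dataclass
class SourceEvent:
    """One tracked contiguous detection."""

    onset_s: float
    offset_s: float
    azimuth_track: list[float] = field(default_factory=list)
    peak_powers: list[float] = field(default_factory=list)
    frame_times: list[float] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    @property
    def mean_azimuth(self) -> float:
        """Circular (vector-sum) mean of the azimuth track, degrees in [0, 360)."""
        a = np.deg2rad(self.azimuth_track)
        return float(np.rad2deg(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360)

    @property
    def n_frames(self) -> int:
        return len(self.azimuth_track)


def circular_difference_deg(a: float, b: float) -> float:
    """Smallest absolute angular difference between two azimuths, degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def form_events(
    frame_peaks: list[list[tuple[float, float]]],
    params: TrackingParams,
    frame_hop_s: float,
    t0: float = 0.0,
) -> list[SourceEvent]:
    """Assemble per-frame peaks into source events.

    ``frame_peaks[k]`` holds the ``(azimuth_deg, power)`` peaks of
    evaluation frame k (time ``t0 + k * frame_hop_s``).  A peak joins the
    most recently updated open event whose last azimuth is within
    ``min_src_interval`` degrees circularly; otherwise it opens a new
    event, provided fewer than ``num_source`` events are open (if not,
    the stronger peak wins within the frame, so the weaker is dropped).
    An event closes once ``pause_length`` ms pass without a joining peak;
    its offset is the time of its last peak.
    """
    pause_s = params.pause_length / 1000.0
    open_events: list[SourceEvent] = []
    closed: list[SourceEvent] = []

    for k, peaks in enumerate(frame_peaks):
        t = t0 + k * frame_hop_s
        # close events whose last peak is too old
        still_open = []
        for ev in open_events:
            if t - ev.frame_times[-1] > pause_s:
                ev.offset_s = ev.frame_times[-1]
                closed.append(ev)
            else:
                still_open.append(ev)
        open_events = still_open
        for az, power in sorted(peaks, key=lambda p: -p[1]):
            target = None
            for ev in sorted(open_events, key=lambda e: -e.frame_times[-1]):
                if ev.frame_times[-1] < t and circular_difference_deg(
                    ev.azimuth_track[-1], az
                ) <= params.min_src_interval:
                    target = ev
                    break
            if target is None:
                if len(open_events) >= params.num_source:
                    continue  # weaker simultaneous source dropped
                target = SourceEvent(onset_s=t, offset_s=t)
                open_events.append(target)
            target.azimuth_track.append(az)
            target.peak_powers.append(power)
            target.frame_times.append(t)
    for ev in open_events:
        ev.offset_s = ev.frame_times[-1]
        closed.append(ev)
    return sorted(closed, key=lambda e: e.onset_s)


def localization_accuracy(
    events: list[SourceEvent], annotated_intervals: list[tuple[float, float]]
) -> float | None:
    """Annotated duration / localized duration, as a percentage.

    Returns None when nothing was localized (ratio undefined).  The value
    is deliberately unclamped: > 100% signals under-coverage.
    """
    localized = sum(ev.duration_s for ev in events)
    actual = sum(b - a for a, b in annotated_intervals)
    if localized <= 0:
        return None
    return 100.0 * actual / localized


def doa_histogram(events: list[SourceEvent], bin_width_deg: float = 10.0) -> np.ndarray:
    """Circular histogram of per-frame event azimuths.

    Bin k covers [k*w, (k+1)*w) degrees; counts across bins sum to the
    total number of frames over all events.
    """
    if bin_width_deg <= 0 or 360.0 % bin_width_deg != 0:
        raise ValueError("bin width must divide 360 degrees")
    n_bins = int(round(360.0 / bin_width_deg))
    counts = np.zeros(n_bins, dtype=int)
    for ev in events:
        idx = (np.asarray(ev.azimuth_track) % 360.0 / bin_width_deg).astype(int)
        np.add.at(counts, idx, 1)
    return counts


def temporal_distribution(
    events: list[SourceEvent], bin_minutes: float = 15.0, t_start_s: float = 0.0
) -> np.ndarray:
    """Event counts per wall-clock bin; events are binned by onset time."""
    if bin_minutes <= 0:
        raise ValueError("bin_minutes must be positive")
    if not events:
        return np.zeros(0, dtype=int)
    width = bin_minutes * 60.0
    idx = [int((ev.onset_s - t_start_s) // width) for ev in events]
    counts = np.zeros(max(idx) + 1, dtype=int)
    for i in idx:
        counts[i] += 1
    return counts
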