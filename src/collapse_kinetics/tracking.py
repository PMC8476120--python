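"""Threading of per-frame peaks into active-region tracks.

Active regions are sparse (microns apart) and nearly stationary, so a
greedy nearest-neighbour frame-to-frame linker is sufficient: each frame,
candidate (track, peak) pairs within ``max_link_distance_px`` are linked in
order of increasing distance; unmatched peaks start new tracks and a track
is closed once it has gone unmatched for more than ``max_gap_frames``
frames.  Bridged gap frames carry no intensity and therefore no count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import UNASSIGNED, CalibrationModel, assign_count
from .peaks import PeakTable

__all__ = ["RegionTrack", "link_tracks", "tracks_to_count_series"]


@dataclass
class RegionTrack:
    """One threaded active region: (frame, position, intensity) samples."""

    track_id: int
    frames: list[int] = field(default_factory=list)
    positions_px: list[float] = field(default_factory=list)
    integrals: list[float] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.frames[0]

    @property
    def end_frame(self) -> int:
        return self.frames[-1]

    @property
    def gap_frames(self) -> list[int]:
        """Frames inside the track span with no observation (bridged gaps)."""
        present = set(self.frames)
        return [f for f in range(self.start_frame, self.end_frame + 1)
                if f not in present]

    def __len__(self) -> int:
        return len(self.frames)


def link_tracks(
    peaks: PeakTable,
    max_link_distance_px: float = 4.0,
    max_gap_frames: int = 1,
) -> list[RegionTrack]:
    """Greedy nearest-neighbour linking of peaks into tracks.

    Ties are broken by smaller distance, then by leftmost peak position.
    Only converged peak fits are threaded.  Every above-threshold peak is
    assigned to exactly one track (possibly a new single-peak track).
    """
    obs = [p for p in peaks.peaks if p.converged]
    if not obs:
        return []
    by_frame: dict[int, list] = {}
    for p in obs:
        by_frame.setdefault(p.frame, []).append(p)

    tracks: list[RegionTrack] = []
    open_tracks: list[RegionTrack] = []
    next_id = 0
    for f in range(min(by_frame), max(by_frame) + 1):
        frame_peaks = sorted(by_frame.get(f, []), key=lambda p: p.position_px)
        # candidate links, sorted by (distance, peak position) for tie-breaks
        pairs = []
        for ti, tr in enumerate(open_tracks):
            for pi, p in enumerate(frame_peaks):
                d = abs(p.position_px - tr.positions_px[-1])
                if d <= max_link_distance_px:
                    pairs.append((d, p.position_px, ti, pi))
        pairs.sort()
        used_t: set[int] = set()
        used_p: set[int] = set()
        for d, _, ti, pi in pairs:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            tr = open_tracks[ti]
            p = frame_peaks[pi]
            tr.frames.append(f)
            tr.positions_px.append(p.position_px)
            tr.integrals.append(p.integral)
        for pi, p in enumerate(frame_peaks):
            if pi in used_p:
                continue
            tr = RegionTrack(track_id=next_id, frames=[f],
                             positions_px=[p.position_px], integrals=[p.integral])
            next_id += 1
            open_tracks.append(tr)
            tracks.append(tr)
        # close tracks that exceeded the allowed gap
        open_tracks = [t for t in open_tracks if f - t.end_frame <= max_gap_frames]
    return tracks


def tracks_to_count_series(
    tracks: list[RegionTrack],
    calibration: CalibrationModel,
    n_frames: int | None = None,
) -> list[np.ndarray]:
    """Convert tracked intensities into per-region count time series.

    Each series covers the track's frame span; gap or UNASSIGNED frames are
    NaN (missing, excluded from transition counting).  A track that ends
    before the movie does contributes a terminal transition to count 0 at
    the first peak-free frame; a track running to the final frame is
    right-censored.  Tracks with fewer than two observed frames are dropped
    (they cannot contribute a transition).

    Parameters
    ----------
    n_frames : int, optional
        Total frames in the source kymograph, used for censoring.  If
        omitted, every track end is treated as a genuine disappearance.
    """
    out = []
    for tr in tracks:
        if len(tr) < 2:
            continue
        span = tr.end_frame - tr.start_frame + 1
        series = np.full(span, np.nan)
        for f, integral in zip(tr.frames, tr.integrals):
            c = assign_count(integral, calibration)
            series[f - tr.start_frame] = np.nan if c == UNASSIGNED else float(c)
        if n_frames is None or tr.end_frame + 1 < n_frames:
            series = np.append(series, 0.0)  # complete detachment observed
        out.append(series)
    return out
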