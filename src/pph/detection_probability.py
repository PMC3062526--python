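"""Per-protein recruitment detection probabilities.

Two complementary strategies estimate how often a tagged protein is
detectable at scission sites.  The object strategy (biased toward
slower, sustained recruitment) asks, frame by frame in the 80 s around
scission, whether a segmented red object larger than 3 px with more
than 8 s dwell time overlaps a small circle at the event site.  The
peak strategy (biased toward transient signals) counts events whose
quantified red trace carries a significant peak (> 6 x tail noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quantification import TRACE_HALF, EventTraces
from .randomization import detect_peak
from .screening import ScissionEvent
from .segmentation import SpotObject
from .tracking import Track, link_tracks, objects_to_dict


@dataclass
class DetectionProfile:
    """Probability of object presence per frame relative to scission."""

    p_detect: np.ndarray          # 41 values, frames -20..+20 (4-s grid)
    p_max: float
    peak_fraction: float | None = None

    def __post_init__(self):
        self.p_detect = np.asarray(self.p_detect, dtype=float)
        if self.p_detect.shape != (2 * TRACE_HALF + 1,):
            raise ValueError("profile must cover frames -20..+20")
        if np.any((self.p_detect < 0) | (self.p_detect > 1)):
            raise ValueError("probabilities must lie in [0, 1]")


def qualifying_object_map(objects_by_frame: list[list[SpotObject]],
                          min_area_px: int = 3, min_dwell_frames: int = 3,
                          max_disp_px: float = 4.0, max_gap_frames: int = 2,
                          frame_interval_s: float = 4.0
                          ) -> dict[int, list[tuple[float, float]]]:
    """Centroids, per frame, of segmented objects that belong to a track
    of >= ``min_dwell_frames`` consecutive-ish frames (> 8 s dwell) and
    exceed ``min_area_px`` pixels."""
    tracks: list[Track] = link_tracks(objects_to_dict(objects_by_frame),
                                      max_disp_px=max_disp_px,
                                      max_gap_frames=max_gap_frames,
                                      frame_interval_s=frame_interval_s)
    out: dict[int, list[tuple[float, float]]] = {}
    for t in tracks:
        if len(t.frames) < min_dwell_frames:
            continue
        for frame, pos, area in zip(t.frames, t.positions, t.areas):
            if area > min_area_px:
                out.setdefault(frame, []).append(pos)
    return out


def object_detection_profile(events: list[ScissionEvent],
                             rfp_objects_by_frame: list[list[SpotObject]],
                             radius_px: float = 3.0, min_area_px: int = 3,
                             min_dwell_frames: int = 3) -> DetectionProfile:
    """Fraction of events, per frame in -80..+80 s, with a qualifying
    red object within ``radius_px`` of the scission site."""
    if not events:
        raise ValueError("no events to profile")
    sites = qualifying_object_map(rfp_objects_by_frame,
                                  min_area_px=min_area_px,
                                  min_dwell_frames=min_dwell_frames)
    n_frames = len(rfp_objects_by_frame)
    scores = np.zeros((len(events), 2 * TRACE_HALF + 1))
    for e_i, ev in enumerate(events):
        er, ec = ev.position
        for i in range(-TRACE_HALF, TRACE_HALF + 1):
            k = ev.detection_frame + i
            if not 0 <= k < n_frames:
                continue
            for (r, c) in sites.get(k, ()):
                if np.hypot(r - er, c - ec) <= radius_px:
                    scores[e_i, i + TRACE_HALF] = 1.0
                    break
    profile = scores.mean(axis=0)
    return DetectionProfile(p_detect=profile, p_max=float(profile.max()))


def peak_detection_fraction(traces: list[EventTraces]) -> float:
    """Proportion of events whose corrected interlaced red trace has a
    significant recruitment peak."""
    if not traces:
        return 0.0
    hits = sum(detect_peak(t.f_rfp_interlaced)[0] for t in traces)
    return hits / len(traces)
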