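"""Particle linking with gap closing.

Objects are linked frame-to-frame by greedy mutual-nearest-neighbour
assignment within ``max_disp_px``; unmatched track ends are kept alive
for ``max_gap_frames`` before termination, closing transient breaks of
1-2 frames in track histories.  On a split a new track id is opened; the
new track records its parent so downstream screening can reject objects
that did not appear de novo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import SpotObject


@dataclass
class Track:
    """A linked spot trajectory on one channel's frame grid."""

    id: int
    frames: list[int] = field(default_factory=list)
    positions: list[tuple[float, float]] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)
    intensities: list[float] = field(default_factory=list)
    channel: str = ""
    frame_interval_s: float = 4.0
    split_parent: int | None = None   # track id this one budded from
    merged_from: list[int] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.frames[0]

    @property
    def end_frame(self) -> int:
        return self.frames[-1]

    @property
    def lifetime_s(self) -> float:
        return (self.end_frame - self.start_frame) * self.frame_interval_s

    @property
    def de_novo(self) -> bool:
        """True if the track neither split from nor absorbed another."""
        return self.split_parent is None and not self.merged_from

    def position_at(self, frame: int) -> tuple[float, float] | None:
        """Position at ``frame``; linear interpolation across closed gaps,
        ``None`` outside the track's life."""
        if frame < self.start_frame or frame > self.end_frame:
            return None
        frames = np.asarray(self.frames)
        idx = np.searchsorted(frames, frame)
        if idx < len(frames) and frames[idx] == frame:
            return self.positions[idx]
        f0, f1 = frames[idx - 1], frames[idx]
        w = (frame - f0) / (f1 - f0)
        (r0, c0), (r1, c1) = self.positions[idx - 1], self.positions[idx]
        return (r0 + w * (r1 - r0), c0 + w * (c1 - c0))


def _canonical_order(objects: list[SpotObject]) -> list[SpotObject]:
    """Intrinsic within-frame order so linking is invariant to input
    permutation: by (row, col, intensity)."""
    return sorted(objects, key=lambda o: (o.centroid[0], o.centroid[1],
                                          o.integrated_intensity))


def link_tracks(objects_by_frame: dict[int, list[SpotObject]],
                max_disp_px: float = 4.0, max_gap_frames: int = 2,
                channel: str = "", frame_interval_s: float = 4.0
                ) -> list[Track]:
    """Link per-frame objects into tracks.

    Assignment within each frame is greedy over candidate (track,
    object) pairs sorted by distance (ties by lower track id, then by
    canonical object index), restricted to mutual nearest neighbours at
    each greedy step by construction of the sort.  Unmatched objects
    start new tracks; a new track starting within ``max_disp_px`` of a
    surviving track is flagged as a split, and a track that dies within
    ``max_disp_px`` of a surviving track marks the survivor as a merge
    target.
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be > 0")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")

    tracks: list[Track] = []
    active: list[Track] = []
    for frame in sorted(objects_by_frame):
        objs = _canonical_order(objects_by_frame[frame])
        # retire tracks whose gap exceeded the limit
        survivors, retiring = [], []
        for t in active:
            (survivors if frame - t.end_frame <= max_gap_frames + 1 else
             retiring).append(t)
        active = survivors

        pairs = []
        for ti, t in enumerate(active):
            tr, tc = t.positions[-1]
            for oi, o in enumerate(objs):
                d = float(np.hypot(o.centroid[0] - tr, o.centroid[1] - tc))
                if d <= max_disp_px:
                    pairs.append((d, t.id, oi, ti))
        pairs.sort()
        used_t: set[int] = set()
        used_o: set[int] = set()
        for d, _tid, oi, ti in pairs:
            if ti in used_t or oi in used_o:
                continue
            used_t.add(ti)
            used_o.add(oi)
            t, o = active[ti], objs[oi]
            t.frames.append(frame)
            t.positions.append(o.centroid)
            t.areas.append(o.area_px)
            t.intensities.append(o.integrated_intensity)

        matched_tracks = [active[ti] for ti in used_t]
        # new tracks from unmatched objects
        for oi, o in enumerate(objs):
            if oi in used_o:
                continue
            t = Track(id=len(tracks), channel=channel,
                      frame_interval_s=frame_interval_s)
            t.frames.append(frame)
            t.positions.append(o.centroid)
            t.areas.append(o.area_px)
            t.intensities.append(o.integrated_intensity)
            if frame > min(objects_by_frame):
                parent = _nearest_track(matched_tracks, o.centroid, max_disp_px)
                if parent is not None:
                    t.split_parent = parent.id
            tracks.append(t)
            active.append(t)

        # unmatched active tracks near a matched one: candidate merge
        for ti, t in enumerate(active):
            if ti in used_t or t.end_frame != frame - 1 or not t.positions:
                continue
            target = _nearest_track(matched_tracks, t.positions[-1], max_disp_px)
            if target is not None and target is not t:
                if t.id not in target.merged_from:
                    target.merged_from.append(t.id)
    return tracks


def _nearest_track(tracks: list[Track], pos: tuple[float, float],
                   max_disp_px: float) -> Track | None:
    best, best_d = None, max_disp_px
    for t in tracks:
        d = float(np.hypot(t.positions[-1][0] - pos[0],
                           t.positions[-1][1] - pos[1]))
        if d < best_d or (d == best_d and best is not None and t.id < best.id):
            best, best_d = t, d
    return best


def merge_ph_timelines(objects7: list[list[SpotObject]],
                       objects5: list[list[SpotObject]]
                       ) -> dict[int, list[SpotObject]]:
    """Interleave pH 7.4 and pH 5.5 object lists onto a single 2-s
    timeline (frame ``2k`` = pH 7.4 image of cycle k, ``2k + 1`` = pH 5.5
    image), as done for the clathrin channel before linking."""
    merged: dict[int, list[SpotObject]] = {}
    for k, objs in enumerate(objects7):
        merged[2 * k] = [SpotObject(2 * k, o.centroid, o.area_px,
                                    o.integrated_intensity) for o in objs]
    for k, objs in enumerate(objects5):
        merged[2 * k + 1] = [SpotObject(2 * k + 1, o.centroid, o.area_px,
                                        o.integrated_intensity) for o in objs]
    return merged


def objects_to_dict(objects: list[list[SpotObject]]
                    ) -> dict[int, list[SpotObject]]:
    return {k: objs for k, objs in enumerate(objects)}
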