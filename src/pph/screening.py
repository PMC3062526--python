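"""Seven-criterion screening of candidate scission events.

Candidates come from tracks in the pH 5.5 cargo (TfR5) sub-movie.  A
bona fide scission event requires a TfR5 vesicle that

(i)   persisted for at least 3 frames (8 s) after appearance;
(ii)  appeared at least 20 frames after the movie start and 20 frames
      before its end, so fluorescence can be quantified for +/-80 s;
(iii) stayed more than 7 px (0.7 um) from the image edge;
(iv)  appeared de novo (not by fusion or fission of existing objects);
(v)   overlapped, on appearance, a pre-existing cluster in the segmented
      TfR7 movie (the host CCS);
(vi)  had SNR > 5, with SNR = (F0 - av)/std over the five pre-appearance
      frames of the background-subtracted TfR5 trace;
(vii) was near-maximal at appearance: fractional slope over the first
      three frames <= 0.1 (a 10% increase).

Criteria (i)-(v) use tracks and segmentation only; (vi)-(vii) need the
quantified per-event TfR5 trace and are filled in by
:func:`screen_events`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation

from .tracking import Track

CRITERIA = ("persist", "time_margin", "edge_margin", "de_novo",
            "host_overlap", "snr", "slope")


@dataclass
class ScreeningParams:
    min_persist_frames: int = 3
    margin_frames: int = 20
    edge_margin_px: float = 7.0
    snr_threshold: float = 5.0
    slope_threshold: float = 0.1
    require_host_overlap: bool = True

    def validate(self) -> None:
        if min(self.min_persist_frames, self.margin_frames) < 1 or \
                min(self.edge_margin_px, self.snr_threshold,
                    self.slope_threshold) <= 0:
            raise ValueError("all screening parameters must be positive")


@dataclass
class ScissionEvent:
    """A candidate or confirmed scission event; t = 0 is the detection
    frame (TfR5 sub-movie index)."""

    id: int
    detection_frame: int
    position: tuple[float, float]
    track_id: int
    host_ccs_track_id: int | None = None
    criterion_flags: dict[str, bool] = field(default_factory=dict)
    snr: float = math.nan
    f0: float = math.nan
    pre_mean: float = math.nan
    pre_std: float = math.nan
    slope: float = math.nan
    confirmed: bool = False
    provenance: str = "automatic"

    def passes(self, *criteria: str) -> bool:
        return all(self.criterion_flags.get(c, False) for c in criteria)


def compute_snr(f_trace_before: np.ndarray, f0: float) -> float:
    """SNR = (F0 - av)/std over exactly five pre-appearance values.

    ``std`` is the sample (n-1) standard deviation.  A zero std returns
    +inf when F0 exceeds the mean (trivially clean appearance) and -inf
    otherwise (rejection).
    """
    pre = np.asarray(f_trace_before, dtype=float)
    if pre.shape != (5,):
        raise ValueError("SNR requires exactly 5 pre-appearance values")
    av = float(np.mean(pre))
    std = float(np.std(pre, ddof=1))
    if std == 0.0:
        return math.inf if f0 > av else -math.inf
    return (f0 - av) / std


def compute_appearance_slope(f_frames_0_1_2: np.ndarray) -> float:
    """Fractional fluorescence change across the first three frames of
    vesicle appearance: (F2 - F0)/F0, so 0.1 means a 10% increase.

    Returns NaN when F0 <= 0 (the event cannot be scored and is
    rejected).
    """
    f = np.asarray(f_frames_0_1_2, dtype=float)
    if f.shape != (3,):
        raise ValueError("slope requires the values at frames 0, 1, 2")
    if f[0] <= 0:
        return math.nan
    return float((f[2] - f[0]) / f[0])


def find_candidates(tfr5_tracks: list[Track], tfr7_masks: np.ndarray,
                    params: ScreeningParams, image_shape: tuple[int, int],
                    n_frames: int) -> list[ScissionEvent]:
    """Apply criteria (i)-(v) to TfR5 tracks.

    ``tfr7_masks`` are the per-cycle segmentation masks of the TfR7
    sub-movie; the overlap test (v) checks the appearance centroid
    against the 1-px-dilated masks of the five preceding pH 7.4 frames
    (up to and including the image acquired 2 s before detection): the
    host cluster must pre-exist, but its surface signal may drop at the
    moment of scission when the vesicle takes the cargo.
    """
    params.validate()
    h, w = image_shape
    m = params.edge_margin_px
    out: list[ScissionEvent] = []
    for t in tfr5_tracks:
        n_obs = len(t.frames)
        first = t.start_frame
        row, col = t.positions[0]
        flags = {
            "persist": n_obs >= params.min_persist_frames,
            "time_margin": (first >= params.margin_frames and
                            first <= n_frames - 1 - params.margin_frames),
            "edge_margin": all(m <= r <= h - 1 - m and m <= c <= w - 1 - m
                               for r, c in t.positions),
            "de_novo": t.de_novo,
        }
        if params.require_host_overlap:
            flags["host_overlap"] = _overlaps_host(tfr7_masks, first, row, col)
        else:
            flags["host_overlap"] = True
        out.append(ScissionEvent(id=len(out), detection_frame=first,
                                 position=(row, col), track_id=t.id,
                                 criterion_flags=flags))
    return out


def _overlaps_host(tfr7_masks: np.ndarray, frame: int, row: float,
                   col: float, lookback: int = 5) -> bool:
    if frame < 0 or frame >= len(tfr7_masks):
        return False
    r, c = int(round(row)), int(round(col))
    h, w = tfr7_masks.shape[1:]
    if not (0 <= r < h and 0 <= c < w):
        return False
    for k in range(frame, max(-1, frame - lookback), -1):
        if binary_dilation(tfr7_masks[k])[r, c]:
            return True
    return False


def screen_events(candidates: list[ScissionEvent],
                  tfr5_traces: dict[int, np.ndarray],
                  params: ScreeningParams,
                  recall_ids: set[int] | None = None
                  ) -> tuple[list[ScissionEvent], dict]:
    """Fill criteria (vi)-(vii) from the quantified TfR5 traces and
    confirm events passing all seven.

    ``tfr5_traces`` maps candidate id to its 41-point background-
    subtracted TfR5 trace (frames -20..+20; index 20 is F0).  Events in
    ``recall_ids`` are confirmed regardless of flags, with provenance
    "recalled" (mirrors the manual recall screen).  Returns the
    confirmed events and a per-criterion attrition report.
    """
    recall_ids = recall_ids or set()
    confirmed: list[ScissionEvent] = []
    for ev in candidates:
        trace = tfr5_traces.get(ev.id)
        if trace is not None:
            trace = np.asarray(trace, dtype=float)
            pre = trace[15:20]
            ev.f0 = float(trace[20])
            ev.pre_mean = float(np.mean(pre))
            ev.pre_std = float(np.std(pre, ddof=1))
            ev.snr = compute_snr(pre, ev.f0)
            ev.slope = compute_appearance_slope(trace[20:23])
            ev.criterion_flags["snr"] = ev.snr > params.snr_threshold
            ev.criterion_flags["slope"] = (not math.isnan(ev.slope) and
                                           ev.slope <= params.slope_threshold)
        else:
            ev.criterion_flags.setdefault("snr", False)
            ev.criterion_flags.setdefault("slope", False)
        if ev.passes(*CRITERIA):
            ev.confirmed = True
            confirmed.append(ev)
        elif ev.id in recall_ids:
            ev.confirmed = True
            ev.provenance = "recalled"
            confirmed.append(ev)

    report = {"n_candidates": len(candidates),
              "n_confirmed": len(confirmed),
              "n_recalled": sum(e.provenance == "recalled" for e in confirmed)}
    surviving = list(candidates)
    for crit in CRITERIA:
        surviving = [e for e in surviving if e.criterion_flags.get(crit, False)]
        report[f"after_{crit}"] = len(surviving)
    n_sites = [e for e in candidates
               if e.passes("persist", "time_margin", "edge_margin", "de_novo")]
    n_final = [e for e in n_sites if e.passes(*CRITERIA)]
    report["frac_pass_v_vii"] = (len(n_final) / len(n_sites)
                                 if n_sites else math.nan)
    return confirmed, report
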