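"""End-to-end pipeline orchestration.

Runs the full analysis on a movie set (simulated or loaded):
segmentation and tracking of the TfR5/TfR7 sub-movies, candidate
screening, per-event quantification, bleed-through correction and
interlacing, randomization bands and the normalized recruitment
signature, terminal sorting, peak detection, CCS-level statistics, and
the detection-probability profiles.  All randomness (simulation,
coordinate shifts, bootstraps) derives from the single configured seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ccs as ccs_mod
from . import detection_probability as dp
from . import io as io_mod
from . import randomization as rand_mod
from . import signatures as sig_mod
from .config import PipelineConfig
from .quantification import (EventTraces, average_traces, correct_and_interlace,
                             estimate_bleedthrough, identity_transform,
                             measure_event_fluorescence, measure_site_traces)
from .randomization import NullBands, TerminalClass
from .screening import ScissionEvent, find_candidates, screen_events
from .segmentation import segment_stack
from .signatures import RecruitmentSignature
from .synthetic import GroundTruth, PPHMovieSet, simulate_movie_set
from .tracking import Track, link_tracks, objects_to_dict


@dataclass
class PipelineResult:
    """Everything the downstream analyses and tables need."""

    config: PipelineConfig
    movies: PPHMovieSet
    truth: GroundTruth | None
    tfr5_tracks: list[Track] = field(default_factory=list)
    tfr7_tracks: list[Track] = field(default_factory=list)
    tfr7_masks: np.ndarray | None = None
    rfp_objects: list | None = None
    candidates: list[ScissionEvent] = field(default_factory=list)
    events: list[ScissionEvent] = field(default_factory=list)
    screening_report: dict = field(default_factory=dict)
    bt: float = 0.0
    traces: dict[int, EventTraces] = field(default_factory=dict)
    bands: NullBands | None = None
    signature: RecruitmentSignature | None = None
    terminal: dict[int, TerminalClass] = field(default_factory=dict)
    peaks: dict[int, tuple[bool, float]] = field(default_factory=dict)
    ccs_records: list[ccs_mod.CCSRecord] = field(default_factory=list)
    ccs_summary: dict = field(default_factory=dict)
    detection_profile: dp.DetectionProfile | None = None
    stages_complete: list[str] = field(default_factory=list)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig,
                 movies: PPHMovieSet | None = None,
                 truth: GroundTruth | None = None,
                 out_dir: str | Path | None = None,
                 stop_after: str | None = None) -> PipelineResult:
    """Execute the pipeline; optionally stop after a named stage and/or
    write the result tables and a manifest to ``out_dir``."""
    rng = np.random.default_rng(config.seed + 1_000_003)

    def boundary(stage: str) -> bool:
        res.stages_complete.append(stage)
        return stop_after == stage

    try:
        stage = "simulate"
        if movies is None:
            movies, truth = simulate_movie_set(config.sim)
        res = PipelineResult(config=config, movies=movies, truth=truth)
        if boundary(stage):
            return _finish(res, out_dir)

        stage = "segment"
        seg = config.segmentation
        tfr5_objects, _ = segment_stack(movies.tfr5, seg.n_scales, seg.k_sigma)
        tfr7_objects, tfr7_masks = segment_stack(movies.tfr7, seg.n_scales,
                                                 seg.k_sigma)
        res.tfr7_masks = tfr7_masks
        if boundary(stage):
            return _finish(res, out_dir)

        stage = "track"
        res.tfr5_tracks = link_tracks(objects_to_dict(tfr5_objects),
                                      seg.max_disp_px, seg.max_gap_frames,
                                      channel="tfr5", frame_interval_s=4.0)
        res.tfr7_tracks = link_tracks(objects_to_dict(tfr7_objects),
                                      seg.max_disp_px, seg.max_gap_frames,
                                      channel="tfr7", frame_interval_s=4.0)
        if boundary(stage):
            return _finish(res, out_dir)

        stage = "detect"
        res.candidates = find_candidates(res.tfr5_tracks, tfr7_masks,
                                         config.screening,
                                         movies.frame_shape, movies.n_frames)
        if boundary(stage):
            return _finish(res, out_dir)

        stage = "quantify"
        transform = identity_transform()
        track_by_id = {t.id: t for t in res.tfr5_tracks}
        raw_traces: dict[int, EventTraces] = {}
        for ev in res.candidates:
            if ev.passes("time_margin", "edge_margin"):
                raw_traces[ev.id] = measure_event_fluorescence(
                    movies, ev, track_by_id.get(ev.track_id), transform)
        res.events, res.screening_report = screen_events(
            res.candidates, {eid: t.f_tfr5 for eid, t in raw_traces.items()},
            config.screening)
        confirmed_raw = [raw_traces[e.id] for e in res.events]
        if confirmed_raw:
            cell_avg = average_traces(confirmed_raw)
            res.bt = estimate_bleedthrough(cell_avg.f_rfp5, cell_avg.f_rfp7,
                                           cell_avg.f_tfr5, cell_avg.f_tfr7)
        res.traces = {e.id: correct_and_interlace(raw_traces[e.id], res.bt)
                      for e in res.events}
        if boundary(stage):
            return _finish(res, out_dir)

        stage = "stats"
        if res.events:
            footprint = rand_mod.cell_footprint(movies.tfr7)
            shifts = rand_mod.generate_randomized_events(
                res.events, footprint, config.randomization.n_shifts, rng,
                margin_px=config.screening.edge_margin_px)
            shift_avgs = np.empty((len(shifts),
                                   len(res.traces[res.events[0].id]
                                       .f_rfp_interlaced)))
            for s_i, shifted in enumerate(shifts):
                site_traces = [measure_site_traces(movies, r, c, k)
                               for (r, c, k) in shifted]
                avg = average_traces(site_traces)
                shift_avgs[s_i] = correct_and_interlace(
                    avg, res.bt).f_rfp_interlaced
            res.bands = rand_mod.build_null_bands(shift_avgs)
            for ev in res.events:
                tr = res.traces[ev.id]
                res.terminal[ev.id] = rand_mod.classify_terminal(tr.f_tfr7)
                res.peaks[ev.id] = rand_mod.detect_peak(tr.f_rfp_interlaced)
        if boundary(stage):
            return _finish(res, out_dir)

        stage = "signatures"
        if res.events:
            event_stack = np.stack([res.traces[e.id].f_rfp_interlaced
                                    for e in res.events])
            res.signature = sig_mod.average_signature(event_stack, "rfp",
                                                      bands=res.bands)
        if boundary(stage):
            return _finish(res, out_dir)

        stage = "ccs-stats"
        detected = ccs_mod.classify_scission_detected(
            res.tfr7_tracks, res.events, config.ccs.association_radius_px)
        all_int = [v for t in res.tfr7_tracks for v in t.intensities]
        norm = np.mean(all_int) if all_int else 1.0
        res.ccs_records = [
            ccs_mod.CCSRecord(track_id=t.id, scission_detected=detected[t.id],
                              median_norm_fluor=float(np.median(t.intensities))
                              / norm,
                              lifetime_s=t.lifetime_s)
            for t in res.tfr7_tracks]
        res.ccs_summary = ccs_mod.ccs_statistics(res.ccs_records)
        if boundary(stage):
            return _finish(res, out_dir)

        stage = "detprob"
        rfp7_objects, _ = segment_stack(movies.rfp7, seg.n_scales, seg.k_sigma)
        res.rfp_objects = rfp7_objects
        if res.events:
            profile = dp.object_detection_profile(
                res.events, rfp7_objects, config.detprob.radius_px,
                config.detprob.min_area_px, config.detprob.min_dwell_frames)
            profile.peak_fraction = dp.peak_detection_fraction(
                list(res.traces.values()))
            res.detection_profile = profile
        res.stages_complete.append("detprob")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return _finish(res, out_dir)


def _finish(res: PipelineResult, out_dir: str | Path | None) -> PipelineResult:
    if out_dir is not None:
        write_result_tables(res, out_dir)
    return res


def write_result_tables(res: PipelineResult, out_dir: str | Path) -> None:
    """Write the canonical CSV/JSON output bundle and the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io_mod.tracks_to_frame(res.tfr5_tracks + res.tfr7_tracks).to_csv(
        out_dir / "tracks.csv", index=False)
    ev_frame = io_mod.events_to_frame(res.candidates)
    if not ev_frame.empty:
        ev_frame["terminal"] = [
            res.terminal[eid].label if eid in res.terminal else ""
            for eid in ev_frame["event_id"]]
    ev_frame.to_csv(out_dir / "events.csv", index=False)
    io_mod.traces_to_frame(res.traces).to_csv(out_dir / "traces.csv",
                                              index=False)
    if res.bands is not None and res.signature is not None:
        import pandas as pd

        from .quantification import INTERLACED_TIMES_S
        pd.DataFrame({
            "time_s": INTERLACED_TIMES_S,
            "signature": res.signature.trace,
            "null_median": res.bands.median,
            "null_lo95": res.bands.lo95,
            "null_hi95": res.bands.hi95,
        }).to_csv(out_dir / "signature.csv", index=False)
    counts = {
        "n_tfr5_tracks": len(res.tfr5_tracks),
        "n_tfr7_tracks": len(res.tfr7_tracks),
        "n_candidates": len(res.candidates),
        "n_confirmed": len(res.events),
        "bt": res.bt,
        "screening": res.screening_report,
    }
    io_mod.write_manifest(out_dir / "manifest.json", res.config,
                          res.config.seed, res.movies,
                          res.stages_complete, counts)
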