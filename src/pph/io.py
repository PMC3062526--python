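"""Standard-format I/O glue: TIFF movie sets in, CSV/JSON tables out."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quantification import INTERLACED_TIMES_S, EventTraces, TIMES_PH5_S, TIMES_PH7_S
from .screening import CRITERIA, ScissionEvent
from .synthetic import CHANNEL_FILES, PPHMovieSet
from .tracking import Track

SCHEMA_VERSION = 1


def read_movieset(movie_dir: str | Path) -> PPHMovieSet:
    """Load the four sub-movie TIFF stacks from a fixture directory."""
    movie_dir = Path(movie_dir)
    stacks = {}
    for name, fname in CHANNEL_FILES.items():
        path = movie_dir / fname
        if not path.exists():
            raise FileNotFoundError(f"missing sub-movie for channel "
                                    f"{name!r}: {path}")
        try:
            stacks[name] = np.asarray(tifffile.imread(path), dtype=float)
        except Exception as exc:
            raise OSError(f"corrupt TIFF for channel {name!r}: "
                          f"{path} ({exc})") from exc
        if stacks[name].ndim == 2:
            stacks[name] = stacks[name][None]
    return PPHMovieSet(**stacks)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for frame, (r, c), area, inten in zip(t.frames, t.positions,
                                              t.areas, t.intensities):
            rows.append({"track_id": t.id, "frame": frame, "row": r,
                         "col": c, "area": area, "intensity": inten,
                         "channel": t.channel})
    return pd.DataFrame(rows, columns=["track_id", "frame", "row", "col",
                                       "area", "intensity", "channel"])


def events_to_frame(events: list[ScissionEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        row = {"event_id": e.id, "frame": e.detection_frame,
               "row": e.position[0], "col": e.position[1],
               "track_id": e.track_id, "snr": e.snr, "slope": e.slope,
               "confirmed": e.confirmed, "provenance": e.provenance}
        for crit in CRITERIA:
            row[f"crit_{crit}"] = e.criterion_flags.get(crit, False)
        rows.append(row)
    return pd.DataFrame(rows)


def traces_to_frame(traces: dict[int, EventTraces]) -> pd.DataFrame:
    """Long-format per-event trace table (event_id, time_s, channel, F)."""
    rows = []
    for eid, tr in sorted(traces.items()):
        for channel, times, values in (
                ("tfr7", TIMES_PH7_S, tr.f_tfr7),
                ("tfr5", TIMES_PH5_S, tr.f_tfr5),
                ("rfp7", TIMES_PH7_S, tr.f_rfp7),
                ("rfp5", TIMES_PH5_S, tr.f_rfp5)):
            for t, v in zip(times, values):
                rows.append({"event_id": eid, "time_s": t,
                             "channel": channel, "F": v})
        if tr.f_rfp_interlaced is not None:
            for t, v in zip(INTERLACED_TIMES_S, tr.f_rfp_interlaced):
                rows.append({"event_id": eid, "time_s": t,
                             "channel": "rfp_interlaced", "F": v})
    return pd.DataFrame(rows)


def stack_sha256(stack: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(stack).tobytes()).hexdigest()


def write_manifest(path: str | Path, config, seed: int,
                   movies: PPHMovieSet | None, stages: list[str],
                   counts: dict) -> None:
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "stages_complete": stages,
        "counts": counts,
    }
    if movies is not None:
        manifest["input_hashes"] = {name: stack_sha256(stack)
                                    for name, stack in movies.channels().items()}
    Path(path).write_text(json.dumps(manifest, indent=1, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
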