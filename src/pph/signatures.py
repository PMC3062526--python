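"""Recruitment signatures: averaging, module clustering, cloud plots.

A protein's recruitment signature is the pointwise average of its
aligned per-event traces, normalized to the randomization bands.
Signatures are compared by correlation distance (1 - Pearson r over the
full -82..+76 s window) and grouped by average-linkage hierarchical
clustering; flat modules are read off below a correlation-distance cut
of 0.2, and the cophenetic correlation reports how faithfully the tree
represents the pairwise distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import pdist

from .quantification import INTERLACED_LEN
from .randomization import NullBands, normalize_signature


@dataclass
class RecruitmentSignature:
    protein: str
    trace: np.ndarray            # 80 normalized values on -82..+76 s
    n_events: int = 0
    n_cells: int = 0

    def __post_init__(self):
        self.trace = np.asarray(self.trace, dtype=float)
        if self.trace.shape != (INTERLACED_LEN,):
            raise ValueError("signature must have 80 samples")


@dataclass
class ModuleAssignment:
    linkage_matrix: np.ndarray   # scipy merge list with heights
    modules: dict[str, int]      # protein label -> module id
    cut_distance: float
    cophenetic_r: float
    proteins: list[str] = field(default_factory=list)

    @property
    def n_modules(self) -> int:
        return len(set(self.modules.values()))


def average_signature(event_traces: np.ndarray, protein: str = "",
                      bands: NullBands | None = None,
                      n_cells: int = 1) -> RecruitmentSignature:
    """Pointwise mean over events (simple event mean), optionally
    normalized to randomization bands."""
    arr = np.asarray(event_traces, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty trace set")
    arr = np.atleast_2d(arr)
    avg = arr.mean(axis=0)
    if bands is not None:
        avg, _ = normalize_signature(avg, bands)
    return RecruitmentSignature(protein=protein, trace=avg,
                                n_events=arr.shape[0], n_cells=n_cells)


def cluster_signatures(signatures: list[RecruitmentSignature],
                       cut_distance: float = 0.2) -> ModuleAssignment:
    """Average-linkage hierarchical clustering of signatures under the
    correlation distance; modules are flat clusters below the cut."""
    if len(signatures) < 2:
        raise ValueError("need >= 2 signatures to cluster")
    X = np.stack([s.trace for s in signatures])
    if np.any(np.std(X, axis=1) == 0):
        raise ValueError("constant signature: correlation undefined")
    d = pdist(X, metric="correlation")
    Z = linkage(d, method="average")
    flat = fcluster(Z, t=cut_distance, criterion="distance")
    if len(signatures) > 2:
        coph_r, _ = cophenet(Z, d)
    else:
        coph_r = np.nan   # undefined for a single merge
    labels = [s.protein for s in signatures]
    return ModuleAssignment(linkage_matrix=Z,
                            modules=dict(zip(labels, (int(v) for v in flat))),
                            cut_distance=cut_distance,
                            cophenetic_r=float(coph_r), proteins=labels)


def cloud_plot(event_traces: np.ndarray, cell_ids: np.ndarray | None = None,
               n_value_bins: int = 200) -> np.ndarray:
    """Log-scaled 2-D density of overlaid single-event traces.

    Trace amplitudes are min-max normalized per cell to [0, 1], each
    trace's mean is subtracted to reduce vertical dispersion, and each
    polyline is rasterized into a (value x time) grid, adding 1 to every
    bin it crosses.  Returns log(1 + counts) with one time bin per
    native sample and ``n_value_bins`` value bins (row 0 = lowest
    value).
    """
    arr = np.atleast_2d(np.asarray(event_traces, dtype=float))
    if arr.size == 0:
        raise ValueError("cloud plot needs at least one trace")
    n_traces, n_t = arr.shape
    if cell_ids is None:
        cell_ids = np.zeros(n_traces, dtype=int)
    cell_ids = np.asarray(cell_ids)

    norm = np.empty_like(arr)
    for cid in np.unique(cell_ids):
        sel = cell_ids == cid
        block = arr[sel]
        lo, hi = block.min(), block.max()
        norm[sel] = (block - lo) / (hi - lo) if hi > lo else 0.0
    norm = norm - norm.mean(axis=1, keepdims=True)

    vmin, vmax = norm.min(), norm.max()
    span = vmax - vmin if vmax > vmin else 1.0
    rows = np.clip(((norm - vmin) / span * (n_value_bins - 1)).round(),
                   0, n_value_bins - 1).astype(int)
    counts = np.zeros((n_value_bins, n_t))
    for trace_rows in rows:
        cells = set()
        for t in range(n_t - 1):
            r0, r1 = trace_rows[t], trace_rows[t + 1]
            cells.add((r0, t))
            # vertical run of the segment, split between the two columns
            lo_r, hi_r = sorted((r0, r1))
            for r in range(lo_r, hi_r + 1):
                cells.add((r, t if abs(r - r0) <= abs(r - r1) else t + 1))
        cells.add((trace_rows[-1], n_t - 1))
        for r, t in cells:
            counts[r, t] += 1.0
    return np.log1p(counts)


def restricted_window_comparison(signatures: list[RecruitmentSignature],
                                 times_s: np.ndarray,
                                 t_min: float = -44.0, t_max: float = 36.0,
                                 cut_distance: float = 0.2) -> dict:
    """Stability check: recluster on a restricted time window and count
    proteins whose module co-membership changes."""
    full = cluster_signatures(signatures, cut_distance)
    sel = (times_s >= t_min) & (times_s <= t_max)
    clipped = [RecruitmentSignature(s.protein,
                                    _pad_to_80(s.trace[sel]), s.n_events)
               for s in signatures]
    restricted = cluster_signatures(clipped, cut_distance)
    changed = _co_membership_changes(full.modules, restricted.modules)
    return {"full": full, "restricted": restricted,
            "n_pairings_changed": changed}


def _pad_to_80(trace: np.ndarray) -> np.ndarray:
    out = np.zeros(INTERLACED_LEN)
    out[:len(trace)] = trace
    out[len(trace):] = trace[-1]
    return out


def _co_membership_changes(a: dict[str, int], b: dict[str, int]) -> int:
    names = sorted(a)
    changed = 0
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            if (a[x] == a[y]) != (b[x] == b[y]):
                changed += 1
    return changed
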