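"""Randomization null bands, peak significance, terminal sorting.

Whether a protein's fluorescence at scission sites is meaningful is
judged against pseudo-events: the same measurement repeated at
coordinates shifted uniformly at random within the cell footprint,
keeping each event's time structure.  200 randomized datasets per cell
give pointwise median and 95% bands; signatures are expressed relative
to these bands so the null maps to [-1, +1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.filters import threshold_otsu
from skimage.measure import label

from .quantification import INTERLACED_TIMES_S, TRACE_HALF


@dataclass
class NullBands:
    """Pointwise null summary across randomized datasets (2-s grid)."""

    median: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_shifts: int

    def __post_init__(self):
        if not (np.all(self.lo95 <= self.median + 1e-12) and
                np.all(self.median <= self.hi95 + 1e-12)):
            raise ValueError("bands must satisfy lo95 <= median <= hi95")


@dataclass
class TerminalClass:
    """Terminal / non-terminal sorting of one event."""

    label: str                    # "terminal" | "non-terminal" | "unsorted"
    ratio: float                  # mean F_TfR7 after / before scission
    before_nonpositive: bool = False


def cell_footprint(tfr7_stack: np.ndarray) -> np.ndarray:
    """Cell footprint from the TfR7 maximum projection: Otsu threshold,
    largest connected component, holes filled."""
    proj = np.max(np.asarray(tfr7_stack, float), axis=0)
    mask = proj > threshold_otsu(proj)
    if not mask.any():
        raise ValueError("empty footprint: no pixels above Otsu threshold")
    lab = label(mask, connectivity=2)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return binary_fill_holes(lab == largest)


def generate_randomized_events(events: list, footprint: np.ndarray,
                               n_shifts: int, rng: np.random.Generator,
                               margin_px: float = 7.0
                               ) -> list[list[tuple[float, float, int]]]:
    """``n_shifts`` randomized coordinate sets for the given events.

    Each shift assigns every event a uniform-random pixel inside the
    footprint (eroded by the edge margin so the measurement annulus
    stays in bounds), keeping the event's detection frame.  Returns one
    list of (row, col, detection_frame) per shift.
    """
    if n_shifts < 1:
        raise ValueError("n_shifts must be >= 1")
    footprint = np.asarray(footprint, dtype=bool)
    if not footprint.any():
        raise ValueError("empty footprint")
    h, w = footprint.shape
    m = int(np.ceil(margin_px))
    valid = footprint.copy()
    if h > 2 * m and w > 2 * m:
        border = np.zeros_like(valid)
        border[m:h - m, m:w - m] = True
        eroded = valid & border
        if eroded.any():
            valid = eroded
    coords = np.argwhere(valid)
    out = []
    for _ in range(n_shifts):
        picks = coords[rng.integers(len(coords), size=len(events))]
        out.append([(float(r), float(c), ev.detection_frame)
                    for (r, c), ev in zip(picks, events)])
    return out


def build_null_bands(randomized_averages: np.ndarray) -> NullBands:
    """Pointwise median and 2.5/97.5 percentiles (linear interpolation)
    across the per-shift average traces (shape: n_shifts x 80)."""
    arr = np.asarray(randomized_averages, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 randomized average traces")
    lo, med, hi = np.percentile(arr, [2.5, 50.0, 97.5], axis=0)
    return NullBands(median=med, lo95=lo, hi95=hi, n_shifts=arr.shape[0])


def normalize_signature(avg_trace: np.ndarray, bands: NullBands
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(avg - median) / half-width of the 95% interval, so the null
    bands map to +/-1 and the median to 0.

    Returns the normalized trace and a boolean mask of points where the
    interval width was zero (flagged NaN, not divided).
    """
    avg = np.asarray(avg_trace, dtype=float)
    half = (bands.hi95 - bands.lo95) / 2.0
    degenerate = half == 0
    out = np.full_like(avg, np.nan)
    np.divide(avg - bands.median, half, out=out, where=~degenerate)
    return out, degenerate


def detect_peak(f_rfp_interlaced: np.ndarray,
                times_s: np.ndarray = INTERLACED_TIMES_S
                ) -> tuple[bool, float]:
    """Significance and time of the biggest recruitment peak.

    Noise is the sample standard deviation of the last six values (12 s)
    of the recording, the baseline their mean; the peak is significant
    iff the trace maximum is strictly greater than baseline + 6 x noise.
    The earliest maximum wins ties.
    """
    trace = np.asarray(f_rfp_interlaced, dtype=float)
    tail = trace[-6:]
    noise = float(np.std(tail, ddof=1))
    baseline = float(np.mean(tail))
    imax = int(np.argmax(trace))
    significant = trace[imax] > baseline + 6.0 * noise
    return bool(significant), float(times_s[imax])


def classify_terminal(f_tfr7: np.ndarray) -> TerminalClass:
    """Sort an event by the fate of its host CCS.

    ratio = mean F_TfR7 over the nine frames (36 s) after scission /
    mean over the four frames before.  ratio < 0.4 -> terminal;
    ratio > 0.6 -> non-terminal; ratios in [0.4, 0.6] are not sorted.
    """
    f = np.asarray(f_tfr7, dtype=float)
    before = float(np.mean(f[TRACE_HALF - 4:TRACE_HALF]))
    after = float(np.mean(f[TRACE_HALF + 1:TRACE_HALF + 10]))
    if before <= 0:
        return TerminalClass("unsorted", np.nan, before_nonpositive=True)
    ratio = after / before
    if ratio < 0.4:
        lab = "terminal"
    elif ratio > 0.6:
        lab = "non-terminal"
    else:
        lab = "unsorted"
    return TerminalClass(lab, ratio)
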