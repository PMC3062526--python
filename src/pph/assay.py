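"""The ppH assay clock.

The pulsed-pH (ppH) protocol alternates the extracellular buffer between
pH 7.4 and pH 5.5 in synchrony with image acquisition at 0.5 Hz.  Within
one 4-s cycle ``k`` the pH 7.4 image is acquired at time ``4k`` and the
pH 5.5 image 2 s later, at ``4k + 2``.  Surface pHluorin is quenched at
pH 5.5, so a scission event manifests as the abrupt appearance of a
pH-insulated pHluorin spot in a pH 5.5 image.

Timing model used throughout the package: the cell sits in pH 7.4 buffer
during the half-cycle ``(4k - 2, 4k]`` and in pH 5.5 buffer during
``(4k, 4k + 2]``.  A scission at continuous time ``tau`` is detectable
only if it occurs while the cell is at pH 7.4 (the cargo is then sealed
in its fluorescent state and survives the next acidification); it first
appears in the pH 5.5 frame acquired at ``4k + 2``, the earliest pH 5.5
acquisition after ``tau``.  Scissions during the pH 5.5 half-cycle seal
quenched cargo and are invisible, which caps the detectable fraction of
all events at 50%.  The timing error of a detected event is therefore at
most one half-cycle: the detection frame at ``4k + 2`` tags an event
that actually occurred in ``(4k - 2, 4k]``.
"""

from __future__ import annotations

import math

import numpy as np

CYCLE_S: float = 4.0
"""Length of one full pH cycle (one pH 7.4 image + one pH 5.5 image)."""

PH55_OFFSET_S: float = 2.0
"""Delay of the pH 5.5 acquisition after the pH 7.4 acquisition."""


def ph74_frame_time(k: int) -> float:
    """Acquisition time of the ``k``-th pH 7.4 (sub-movie) frame."""
    return CYCLE_S * k


def ph55_frame_time(k: int) -> float:
    """Acquisition time of the ``k``-th pH 5.5 (sub-movie) frame."""
    return CYCLE_S * k + PH55_OFFSET_S


def is_detectable(tau: float) -> bool:
    """True if a scission at continuous time ``tau`` falls in the pH 7.4
    half-cycle and is therefore recoverable by the ppH detector."""
    phase = tau % CYCLE_S
    return phase > PH55_OFFSET_S or phase == 0.0


def detection_frame(tau: float) -> int | None:
    """Index of the pH 5.5 sub-movie frame in which a scission at ``tau``
    first appears, or ``None`` if the event is not detectable.

    The event appears in the pH 5.5 frame whose acquisition time is the
    smallest pH 5.5 time strictly greater than ``tau``.
    """
    if not is_detectable(tau):
        return None
    return math.ceil(tau / CYCLE_S)


def detectable_mask(taus: np.ndarray) -> np.ndarray:
    """Vectorised :func:`is_detectable`."""
    taus = np.asarray(taus, dtype=float)
    phase = np.mod(taus, CYCLE_S)
    return (phase > PH55_OFFSET_S) | (phase == 0.0)


def detection_frames(taus: np.ndarray) -> np.ndarray:
    """Vectorised :func:`detection_frame`; undetectable events get -1."""
    taus = np.asarray(taus, dtype=float)
    frames = np.ceil(taus / CYCLE_S).astype(int)
    frames[~detectable_mask(taus)] = -1
    return frames


def timing_errors(taus: np.ndarray) -> np.ndarray:
    """Error of the assay's implied scission time for detectable events.

    The detection frame at ``4k + 2`` implies a nominal scission time of
    ``4k`` (the centre offset of the detection window is -2 s).  The
    returned values, nominal minus true time, are uniform on ``[0, 2)`` s
    for uniform ``tau`` and never exceed one half-cycle.
    """
    taus = np.asarray(taus, dtype=float)
    mask = detectable_mask(taus)
    frames = np.ceil(taus[mask] / CYCLE_S)
    nominal = frames * CYCLE_S
    return nominal - taus[mask]


def detectable_fraction(taus: np.ndarray) -> float:
    """Fraction of scission times recoverable by the ppH detector."""
    mask = detectable_mask(taus)
    return float(np.mean(mask)) if mask.size else 0.0
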