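"""Ground-truthed synthetic ppH movie sets.

Generates two-channel, two-pH time-lapse data that embody the physics of
the pulsed-pH assay: clathrin-coated structures (CCSs) as diffraction-
limited pHluorin/cargo spots on a cell footprint, scission events that
appear as persistent pH-insulated spots in the pH 5.5 cargo sub-movie,
per-protein red-channel recruitment trace families, spectral
bleed-through from the green into the red channel, textured background,
and shot + read noise.  Every planted quantity is recorded in a
:class:`GroundTruth` object so downstream stages can be tested without
any real data.

Units: intensities are arbitrary camera units, scaled so that a
canonical scission vesicle has an integrated spot sum of ~500 units
above background; lengths are pixels (100 nm each); times are seconds.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import assay

# Red recruitment trace families.  Each maps a time offset from scission
# (s) to a unit-amplitude recruitment profile; peak offsets are chosen to
# mimic the canonical behaviour of the named protein class.
FAMILY_PEAK_OFFSET_S: dict[str, float] = {
    "dynamin-like": -3.0,   # transient burst 2-4 s before scission
    "clathrin-like": 0.0,   # slow build peaking at scission, then uncoating
    "gak-like": 8.0,        # post-scission (uncoating) recruitment
    "none": 0.0,            # negative control: no recruitment
}


def family_profile(dt: np.ndarray | float, family: str) -> np.ndarray:
    """Unit-peak recruitment profile of ``family`` at offset ``dt`` from
    the true scission time (``dt`` < 0 is pre-scission)."""
    dt = np.asarray(dt, dtype=float)
    if family == "dynamin-like":
        return np.exp(-((dt + 3.0) ** 2) / (2 * 2.5**2))
    if family == "clathrin-like":
        return np.where(dt < 0, np.exp(dt / 30.0), np.exp(-dt / 12.0))
    if family == "gak-like":
        return np.exp(-((dt - 8.0) ** 2) / (2 * 4.0**2))
    if family == "none":
        return np.zeros_like(dt)
    raise ValueError(f"unknown trace family: {family!r}")


@dataclass
class SimConfig:
    """Parameters of the synthetic ppH experiment.

    Defaults are calibrated so the pipeline's fixed thresholds (SNR 5,
    25-unit disappearance step) are exercised on both sides by a typical
    movie, and the timing matches the assay: 0.5 Hz acquisition, pH
    alternating every image, 4-s full cycle.
    """

    image_size_px: tuple[int, int] = (128, 128)
    pixel_size_nm: float = 100.0
    n_cycles: int = 150
    psf_sigma_px: float = 1.3
    n_ccs: int = 40
    # CCS lifetimes: left-skewed log-normal (median exp(mu), shape sigma).
    lifetime_median_s: float = 60.0
    lifetime_sigma_log: float = 0.9
    event_rate_per_s: float = 0.015   # scission events per CCS per second alive
    frac_terminal: float = 0.5
    bleedthrough_true: float = 0.03
    # Noise: shot noise via Poisson at `shot_gain` photons per intensity
    # unit (0 disables), plus Gaussian read noise of std `read_noise`.
    shot_gain: float = 1.0
    read_noise: float = 2.0
    background_amp: float = 30.0      # red-channel texture amplitude
    background_corr_px: float = 12.0  # its spatial correlation length
    membrane_level: float = 40.0      # diffuse surface pHluorin inside footprint
    footprint_area_frac: float = 0.6
    # Spot amplitude scales (integrated Gaussian sums, units).
    ccs_sum_median: float = 1500.0
    ccs_sum_sigma_log: float = 0.6
    event_sum_mean: float = 500.0
    event_sum_sigma_log: float = 0.3
    red_sum_mean: float = 150.0
    red_families: tuple[str, ...] = ("dynamin-like", "clathrin-like", "gak-like")
    red_family_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    vesicle_persist_frames: tuple[int, int] = (3, 8)  # inclusive range
    rng_seed: int = 0

    def validate(self) -> None:
        if len(self.image_size_px) != 2 or min(self.image_size_px) < 1:
            raise ValueError("image_size_px must be a positive integer pair")
        if self.n_cycles < 0 or self.n_ccs < 0:
            raise ValueError("n_cycles and n_ccs must be non-negative")
        for name in ("event_rate_per_s", "lifetime_median_s", "psf_sigma_px",
                     "shot_gain", "read_noise", "background_amp",
                     "membrane_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_terminal <= 1.0:
            raise ValueError("frac_terminal must be in [0, 1]")
        if not 0.0 <= self.bleedthrough_true <= 0.05:
            raise ValueError("bleedthrough_true must be in [0, 0.05]")
        if len(self.red_families) != len(self.red_family_weights):
            raise ValueError("red_families and red_family_weights differ in length")
        lo, hi = self.vesicle_persist_frames
        if not (1 <= lo <= hi):
            raise ValueError("vesicle_persist_frames must be an increasing pair >= 1")

    @property
    def duration_s(self) -> float:
        return assay.CYCLE_S * self.n_cycles

    def footprint_mask(self) -> np.ndarray:
        """Filled-ellipse cell footprint covering ``footprint_area_frac``
        of the frame."""
        h, w = self.image_size_px
        alpha = np.sqrt(self.footprint_area_frac / np.pi) * 2.0
        a, b = alpha * h / 2.0, alpha * w / 2.0
        if a < 1.0 or b < 1.0:
            raise ValueError("cell footprint has zero area at this image size")
        rr, cc = np.mgrid[0:h, 0:w]
        return ((rr - (h - 1) / 2) / a) ** 2 + ((cc - (w - 1) / 2) / b) ** 2 <= 1.0


@dataclass
class CCSRecord:
    """A planted clathrin-coated structure (static centroid)."""

    id: int
    row: float
    col: float
    t_birth: float
    t_death: float
    tfr7_sum: float      # integrated TfR7 spot sum at plateau, units

    @property
    def lifetime_s(self) -> float:
        return self.t_death - self.t_birth


@dataclass
class EventRecord:
    """A planted scission event with its red recruitment trace."""

    id: int
    ccs_id: int
    t_scission: float        # continuous true time, s
    terminal: bool
    family: str
    peak_time_s: float       # absolute time of planted red peak
    red_sum: float           # integrated red spot sum at peak, units
    tfr5_sum: float          # integrated vesicle spot sum, units
    persist_frames: int
    detectable: bool
    detection_frame: int | None  # tfr5 sub-movie index, None if invisible


@dataclass
class GroundTruth:
    ccs_records: list[CCSRecord] = field(default_factory=list)
    event_records: list[EventRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ccs_records": [dataclasses.asdict(c) for c in self.ccs_records],
            "event_records": [dataclasses.asdict(e) for e in self.event_records],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            ccs_records=[CCSRecord(**c) for c in d["ccs_records"]],
            event_records=[EventRecord(**e) for e in d["event_records"]],
        )


@dataclass
class PPHMovieSet:
    """The four aligned sub-movies plus timing metadata.

    Stacks are (frames, rows, cols) float arrays of non-negative
    intensities.  ``tfr7``/``rfp7`` frames are acquired at ``4k``;
    ``tfr5``/``rfp5`` frames at ``4k + 2``.
    """

    tfr7: np.ndarray
    tfr5: np.ndarray
    rfp7: np.ndarray
    rfp5: np.ndarray
    frame_interval_s: float = assay.CYCLE_S
    ph74_to_ph55_offset_s: float = assay.PH55_OFFSET_S
    pixel_size_nm: float = 100.0

    def __post_init__(self) -> None:
        shapes = {self.tfr7.shape, self.tfr5.shape, self.rfp7.shape, self.rfp5.shape}
        if len(shapes) != 1:
            raise ValueError(f"sub-movies differ in shape: {shapes}")

    @property
    def n_frames(self) -> int:
        return self.tfr7.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.tfr7.shape[1:]

    def channels(self) -> dict[str, np.ndarray]:
        return {"tfr7": self.tfr7, "tfr5": self.tfr5,
                "rfp7": self.rfp7, "rfp5": self.rfp5}


def simulate_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw CCS and scission-event ground truth from the configured model.

    CCS births are uniform in time over the movie and uniform in space
    inside the cell footprint; lifetimes are log-normal (left-skewed
    toward short lifetimes).  Scission times are Poisson events at
    ``event_rate_per_s`` along each CCS's alive-within-movie span, with
    continuous-uniform times.  A CCS hosting events is terminal with
    probability ``frac_terminal``: its final event kills it within one
    cycle.  Each event draws a red recruitment family, amplitude and
    vesicle persistence.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    footprint = config.footprint_mask()
    if not footprint.any():
        raise ValueError("cell footprint has zero area")
    fp_coords = np.argwhere(footprint)

    truth = GroundTruth()
    mu = np.log(config.lifetime_median_s)
    weights = np.asarray(config.red_family_weights, dtype=float)
    weights = weights / weights.sum()

    event_id = 0
    for i in range(config.n_ccs):
        r, c = fp_coords[rng.integers(len(fp_coords))]
        # sub-pixel jitter keeps centroids off the integer grid
        row = float(r) + rng.uniform(-0.5, 0.5)
        col = float(c) + rng.uniform(-0.5, 0.5)
        t_birth = rng.uniform(0.0, config.duration_s)
        lifetime = float(rng.lognormal(mu, config.lifetime_sigma_log))
        t_death = t_birth + lifetime
        tfr7_sum = float(rng.lognormal(np.log(config.ccs_sum_median),
                                       config.ccs_sum_sigma_log))
        ccs = CCSRecord(id=i, row=row, col=col, t_birth=t_birth,
                        t_death=t_death, tfr7_sum=tfr7_sum)

        span_end = min(t_death, config.duration_s)
        span = max(0.0, span_end - t_birth)
        n_events = rng.poisson(config.event_rate_per_s * span) if span > 0 else 0
        times = np.sort(rng.uniform(t_birth, span_end, size=n_events))

        terminal_ccs = bool(n_events) and rng.uniform() < config.frac_terminal
        if terminal_ccs:
            # host dies within one cycle of its final event
            ccs.t_death = float(times[-1]) + rng.uniform(1.0, assay.CYCLE_S)

        for j, tau in enumerate(times):
            family = str(rng.choice(config.red_families, p=weights))
            red_sum = float(rng.lognormal(np.log(config.red_sum_mean), 0.3))
            tfr5_sum = float(rng.lognormal(np.log(config.event_sum_mean),
                                           config.event_sum_sigma_log))
            lo, hi = config.vesicle_persist_frames
            persist = int(rng.integers(lo, hi + 1))
            det = assay.detection_frame(tau)
            if det is not None and det > config.n_cycles - 1:
                det = None
            truth.event_records.append(EventRecord(
                id=event_id, ccs_id=i, t_scission=float(tau),
                terminal=terminal_ccs and j == n_events - 1,
                family=family,
                peak_time_s=float(tau) + FAMILY_PEAK_OFFSET_S[family],
                red_sum=red_sum, tfr5_sum=tfr5_sum, persist_frames=persist,
                detectable=det is not None, detection_frame=det))
            event_id += 1
        truth.ccs_records.append(ccs)
    return truth


def _add_gaussian_spot(img: np.ndarray, row: float, col: float,
                       sigma: float, total: float) -> None:
    """Add a 2-D Gaussian with integrated sum ``total`` in place."""
    if total <= 0:
        return
    h, w = img.shape
    half = int(np.ceil(4 * sigma)) + 1
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    amp = total / (2 * np.pi * sigma**2)
    img[r0:r1, c0:c1] += amp * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def _ccs_profile(ccs: CCSRecord, events: list[EventRecord], t: float) -> float:
    """Relative TfR7/clathrin amplitude of a CCS at time ``t``.

    Linear build-up over the first min(20 s, 20% of lifetime); terminal
    hosts ramp to zero between the terminal event and death; non-terminal
    hosts dip by 25% after each scission and partially regrow, and fade
    over their last 10 s.
    """
    if t < ccs.t_birth or t > ccs.t_death:
        return 0.0
    life = ccs.t_death - ccs.t_birth
    rise = min(20.0, 0.2 * life)
    level = 1.0
    if rise > 0 and t < ccs.t_birth + rise:
        level = (t - ccs.t_birth) / rise
    terminal_ev = next((e for e in events if e.terminal), None)
    if terminal_ev is not None and t >= terminal_ev.t_scission:
        span = ccs.t_death - terminal_ev.t_scission
        level *= max(0.0, 1.0 - (t - terminal_ev.t_scission) / span) if span > 0 else 0.0
        return level
    fall = 10.0
    if t > ccs.t_death - fall:
        level *= (ccs.t_death - t) / fall
    for e in events:
        if not e.terminal and t > e.t_scission:
            level *= 1.0 - 0.25 * np.exp(-(t - e.t_scission) / 10.0)
    return max(0.0, float(level))


def _textured_background(shape: tuple[int, int], amp: float,
                         corr_px: float, rng: np.random.Generator) -> np.ndarray:
    """Static low-pass-filtered noise field, non-negative, mean ~``amp``.

    Emulates stress-fibre-like texture that limits red-channel detection.
    """
    from scipy.ndimage import gaussian_filter

    if amp <= 0:
        return np.zeros(shape)
    raw = rng.normal(0.0, 1.0, size=shape)
    sm = gaussian_filter(raw, corr_px, mode="reflect")
    sm = sm / (np.std(sm) + 1e-12)
    return np.maximum(0.0, amp * (1.0 + 0.4 * sm))


def render_movie_set(truth: GroundTruth, config: SimConfig) -> PPHMovieSet:
    """Render the four sub-movies from ground truth.

    pH 7.4 cargo frames show the diffuse membrane plus CCS spots; pH 5.5
    cargo frames contain only internalized (post-scission, pre-departure)
    vesicles — surface pHluorin is fully quenched.  Red frames are the
    true recruitment signal plus ``bleedthrough_true`` times the
    corresponding cargo frame, plus static textured background and noise.
    """
    config.validate()
    h, w = config.image_size_px
    n = config.n_cycles
    if n == 0:
        raise ValueError("cannot render a movie of zero cycles")
    rng = np.random.default_rng(config.rng_seed + 1)  # independent of truth draw
    footprint = config.footprint_mask().astype(float)
    sigma = config.psf_sigma_px

    events_by_ccs: dict[int, list[EventRecord]] = {}
    for e in truth.event_records:
        events_by_ccs.setdefault(e.ccs_id, []).append(e)
    ccs_by_id = {c.id: c for c in truth.ccs_records}

    red_bg = _textured_background((h, w), config.background_amp,
                                  config.background_corr_px, rng)
    # the pHluorin membrane signal is textured too (same physics, its
    # own static field); only the quenched tfr5 channel is dark
    green_bg = _textured_background((h, w), config.membrane_level,
                                    config.background_corr_px, rng)

    tfr7 = np.empty((n, h, w))
    tfr5 = np.empty((n, h, w))
    rfp7 = np.empty((n, h, w))
    rfp5 = np.empty((n, h, w))

    for k in range(n):
        t7 = assay.ph74_frame_time(k)
        t5 = assay.ph55_frame_time(k)

        g7 = green_bg * footprint
        for ccs in truth.ccs_records:
            lvl = _ccs_profile(ccs, events_by_ccs.get(ccs.id, []), t7)
            _add_gaussian_spot(g7, ccs.row, ccs.col, sigma, lvl * ccs.tfr7_sum)

        g5 = np.zeros((h, w))
        for e in truth.event_records:
            if e.detection_frame is None:
                continue
            if e.detection_frame <= k < e.detection_frame + e.persist_frames:
                ccs = ccs_by_id[e.ccs_id]
                _add_gaussian_spot(g5, ccs.row, ccs.col, sigma, e.tfr5_sum)

        r7 = red_bg.copy()
        r5 = red_bg.copy()
        for e in truth.event_records:
            ccs = ccs_by_id[e.ccs_id]
            a7 = e.red_sum * float(family_profile(t7 - e.t_scission, e.family))
            a5 = e.red_sum * float(family_profile(t5 - e.t_scission, e.family))
            _add_gaussian_spot(r7, ccs.row, ccs.col, sigma, a7)
            _add_gaussian_spot(r5, ccs.row, ccs.col, sigma, a5)
        r7 += config.bleedthrough_true * g7
        r5 += config.bleedthrough_true * g5

        tfr7[k], tfr5[k], rfp7[k], rfp5[k] = g7, g5, r7, r5

    for stack in (tfr7, tfr5, rfp7, rfp5):
        _apply_noise(stack, config, rng)

    return PPHMovieSet(tfr7=tfr7, tfr5=tfr5, rfp7=rfp7, rfp5=rfp5,
                       pixel_size_nm=config.pixel_size_nm)


def _apply_noise(stack: np.ndarray, config: SimConfig,
                 rng: np.random.Generator) -> None:
    if config.shot_gain > 0:
        stack[:] = rng.poisson(np.maximum(stack, 0.0) * config.shot_gain
                               ) / config.shot_gain
    if config.read_noise > 0:
        stack += rng.normal(0.0, config.read_noise, size=stack.shape)
    np.maximum(stack, 0.0, out=stack)


def simulate_movie_set(config: SimConfig) -> tuple[PPHMovieSet, GroundTruth]:
    """Convenience: draw ground truth and render it."""
    truth = simulate_ground_truth(config)
    return render_movie_set(truth, config), truth


CHANNEL_FILES = {"tfr7": "tfr7.tif", "tfr5": "tfr5.tif",
                 "rfp7": "rfp7.tif", "rfp5": "rfp5.tif"}


def write_fixture(movies: PPHMovieSet, truth: GroundTruth | None,
                  out_dir: str | Path, config: SimConfig | None = None
                  ) -> dict[str, Path]:
    """Write a movie set (uint16 multi-page TIFFs), optional ground-truth
    JSON and config YAML.  Quantisation to uint16 round-trips bit-exactly
    on re-write."""
    out_dir = Path(out_dir)
    if movies.n_frames == 0:
        raise ValueError("refusing to write an empty movie (0 frames)")
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        for name, stack in movies.channels().items():
            p = out_dir / CHANNEL_FILES[name]
            data = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
            tifffile.imwrite(p, data)
            paths[name] = p
        if truth is not None:
            p = out_dir / "ground_truth.json"
            p.write_text(json.dumps(truth.to_dict(), indent=1))
            paths["ground_truth"] = p
        if config is not None:
            p = out_dir / "sim_config.yaml"
            p.write_text(yaml.safe_dump(dataclasses.asdict(config)))
            paths["config"] = p
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out_dir}: {exc}") from exc
    return paths


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def read_sim_config(path: str | Path) -> SimConfig:
    d = yaml.safe_load(Path(path).read_text())
    for key in ("image_size_px", "red_families", "red_family_weights",
                "vesicle_persist_frames"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return SimConfig(**d)
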