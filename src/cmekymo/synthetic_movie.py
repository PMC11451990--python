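"""Synthetic budded-yeast fluorescence movies with full ground truth.

Emulates the statistical structure that the cortical kymograph analysis
assumes: a two-lobe budded cell, diffraction-limited endocytic events
appearing on the cortex at Poisson rates per unit length (about five-fold
higher on the daughter cortex during polarized growth), event lifetimes
that are short and regular on the daughter (CV around 20%) but long and
irregular on the mother (CV around 50%), optional two-stage (low-then-high
abundance) recruitment, a delayed second channel, interior cytoplasmic
puncta, immobile cortical puncta (eisosome analogues), and Poisson + read
camera noise on top of cytoplasmic autofluorescence.

Geometry is two overlapping disks: the analysis must not depend on cell
shape, and disks make contour-length oracles analytic. Events are immobile
in arclength over their lifetime, so each one renders as a vertical streak
on the kymograph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .cell_geometry import Contour
from .core import (
    DEFAULT_FRAME_INTERVAL_S,
    DEFAULT_PIXEL_SIZE_NM,
    ConfigError,
    FrameStack,
    substream,
)

log = logging.getLogger(__name__)

MIN_LIFETIME_FRAMES = 2


@dataclass
class CompartmentParams:
    """Event statistics for one cortical compartment.

    rate_per_um_min
        Event initiation rate, events per micrometre of retained cortex
        per minute.
    lifetime_mean_s, lifetime_cv
        Mean and coefficient of variation (fraction in (0, 1)) of the
        event lifetime distribution.
    lifetime_family
        'gaussian' (truncated at 2 frame intervals; regular,
        daughter-like) or 'lognormal' (heavy-tailed; irregular,
        mother-like).
    amplitude
        Peak photons per frame added by one event at its centre pixel.
    profile
        'plateau' (constant while alive) or 'ramp' (triangular up-down).
    two_stage
        Optional ``(low_fraction, low_duration_s)``: the event spends its
        first ``low_duration_s`` at ``low_fraction * amplitude`` before
        stepping up to full amplitude (low-then-high recruitment).
    """

    rate_per_um_min: float
    lifetime_mean_s: float = 30.0
    lifetime_cv: float = 0.2
    lifetime_family: str = "gaussian"
    amplitude: float = 60.0
    profile: str = "plateau"
    two_stage: tuple[float, float] | None = None

    def validate(self, name: str) -> None:
        if self.rate_per_um_min < 0:
            raise ConfigError(f"{name}: rate must be >= 0")
        if self.lifetime_mean_s <= 0:
            raise ConfigError(f"{name}: lifetime mean must be > 0")
        if not 0 < self.lifetime_cv < 1:
            raise ConfigError(f"{name}: lifetime CV must be in (0, 1)")
        if self.lifetime_family not in ("gaussian", "lognormal"):
            raise ConfigError(f"{name}: unknown lifetime family {self.lifetime_family!r}")
        if self.profile not in ("plateau", "ramp"):
            raise ConfigError(f"{name}: unknown profile {self.profile!r}")
        if self.two_stage is not None:
            frac, dur = self.two_stage
            if not 0 <= frac < 1 or dur <= 0:
                raise ConfigError(f"{name}: two_stage needs 0 <= low_fraction < 1 and low_duration > 0")


def _default_mother() -> CompartmentParams:
    # long, irregular, heavy-tailed lifetimes; ~5x lower initiation rate
    return CompartmentParams(
        rate_per_um_min=0.2, lifetime_mean_s=90.0, lifetime_cv=0.5, lifetime_family="lognormal", amplitude=60.0
    )


def _default_daughter() -> CompartmentParams:
    # short, regular lifetimes at the polarized (bud) cortex
    return CompartmentParams(
        rate_per_um_min=1.0, lifetime_mean_s=30.0, lifetime_cv=0.2, lifetime_family="gaussian", amplitude=60.0
    )


@dataclass
class SimulationConfig:
    """Everything needed to generate one budded-cell movie."""

    mother_radius_px: float = 30.0
    daughter_radius_px: float = 15.0
    neck_halfwidth_px: float = 6.0
    center_distance_px: float | None = None  # default: circles overlap with chord half-width above
    mother: CompartmentParams = field(default_factory=_default_mother)
    daughter: CompartmentParams = field(default_factory=_default_daughter)
    channel_offset_s: tuple[float, float] | None = None  # (birth, death) offsets of channel 2
    psf_sigma_px: float = 1.4
    background: float = 10.0  # photons/pixel/frame outside cells
    cell_background: float = 30.0  # cytoplasmic autofluorescence photons/pixel/frame
    read_noise_sd: float = 1.0  # camera counts
    bleach_rate_per_s: float = 0.0
    n_interior_puncta: int = 0
    puncta_amplitude: float = 30.0  # cytoplasmic spots are dimmer than cortical patches
    puncta_clearance_px: float = 12.0  # min distance of interior puncta from the cortex
    n_eisosomes: int = 0
    eisosome_amplitude: float = 60.0
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    duration_s: float = 180.0
    neck_margin_px: float = 5.0
    step_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mother_radius_px <= 0 or self.daughter_radius_px <= 0:
            raise ConfigError("cell radii must be > 0")
        if self.daughter_radius_px > self.mother_radius_px:
            raise ConfigError("daughter radius must not exceed mother radius")
        if not 0 < self.neck_halfwidth_px < self.daughter_radius_px:
            raise ConfigError("neck half-width must be in (0, daughter radius)")
        for val, name in (
            (self.psf_sigma_px, "psf_sigma_px"),
            (self.pixel_size_nm, "pixel_size_nm"),
            (self.frame_interval_s, "frame_interval_s"),
            (self.duration_s, "duration_s"),
            (self.step_px, "step_px"),
        ):
            if val <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.background < 0 or self.cell_background < 0 or self.read_noise_sd < 0:
            raise ConfigError("noise parameters must be >= 0")
        if self.bleach_rate_per_s < 0:
            raise ConfigError("bleach rate must be >= 0")
        self.mother.validate("mother")
        self.daughter.validate("daughter")
        if self.center_distance_px is not None:
            if self.center_distance_px >= self.mother_radius_px + self.daughter_radius_px:
                raise ConfigError("daughter does not touch mother: circles do not overlap")
            if self.center_distance_px <= self.mother_radius_px - self.daughter_radius_px:
                raise ConfigError("daughter is contained inside mother")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.frame_interval_s))

    def compartment(self, name: str) -> CompartmentParams:
        return {"mother": self.mother, "daughter": self.daughter}[name]


@dataclass
class EventRecord:
    """Simulator ground truth for one fluorescent object."""

    event_id: int
    cell_id: int
    compartment: str  # mother | daughter | interior | eisosome
    arclength_um: float  # along the compartment's truth contour; NaN for interior
    t_birth_s: float
    t_death_s: float
    channel: int
    amplitude: float
    y_px: float
    x_px: float
    censored_start_truth: bool
    censored_end_truth: bool
    first_frame: int  # first visible frame, -1 if never visible
    last_frame: int
    low_fraction: float = 1.0
    low_duration_s: float = 0.0
    profile: str = "plateau"

    @property
    def censored_truth(self) -> bool:
        return self.censored_start_truth or self.censored_end_truth

    @property
    def n_visible_frames(self) -> int:
        return 0 if self.first_frame < 0 else self.last_frame - self.first_frame + 1


@dataclass
class CellGeometryTruth:
    """Label mask plus analytic ground-truth contours of one budded cell."""

    label_mask: np.ndarray  # 0 background, 1 mother, 2 daughter
    mother_center: tuple[float, float]
    daughter_center: tuple[float, float]
    config: SimulationConfig
    contours: dict[str, Contour] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_mask.shape


@dataclass
class SimulationResult:
    """Movie channels, ground-truth events and geometry from one run."""

    config: SimulationConfig
    geometry: CellGeometryTruth
    events: list[EventRecord]
    stacks: dict[int, FrameStack]

    @property
    def events_table(self) -> pd.DataFrame:
        return events_to_dataframe(self.events)


# ---------------------------------------------------------------------------
# geometry


def _circle_contour(
    center: tuple[float, float],
    radius: float,
    other_center: tuple[float, float],
    other_radius: float,
    config: SimulationConfig,
    compartment: str,
) -> Contour:
    """Analytic circle contour with the neck region excluded.

    Samples within the other lobe's disk form the junction; the exclusion
    is dilated along the arc by the configured neck margin, mirroring the
    mask-based pipeline's Euclidean margin around neck pixels.
    """
    n = max(8, int(round(2 * math.pi * radius / config.step_px)))
    theta = 2 * math.pi * np.arange(n) / n
    # counter-clockwise in math axes (y up) means decreasing row with theta
    ys = center[0] - radius * np.sin(theta)
    xs = center[1] + radius * np.cos(theta)
    pts = np.stack([ys, xs], axis=1)
    step = 2 * math.pi * radius / n
    inside_other = (ys - other_center[0]) ** 2 + (xs - other_center[1]) ** 2 <= other_radius**2
    n_dilate = int(math.ceil(config.neck_margin_px / step))
    excluded = inside_other.copy()
    for k in range(1, n_dilate + 1):
        excluded |= np.roll(inside_other, k) | np.roll(inside_other, -k)
    return Contour(
        points=pts,
        step_px=step,
        pixel_size_nm=config.pixel_size_nm,
        excluded=excluded,
        compartment=compartment,
        cell_id=1,
    )


def make_cell_geometry(config: SimulationConfig, pad_px: int = 12) -> CellGeometryTruth:
    """Two-lobe budded-cell label mask plus analytic ground-truth contours.

    Mother and daughter are overlapping disks whose intersection chord has
    the configured neck half-width. The mask assigns the full mother disk
    label 1 and the daughter crescent label 2, so the two objects touch
    along the neck exactly as external segmenter masks do.
    """
    big_r, small_r, h = config.mother_radius_px, config.daughter_radius_px, config.neck_halfwidth_px
    if config.center_distance_px is not None:
        d = config.center_distance_px
    else:
        d = math.sqrt(big_r**2 - h**2) + math.sqrt(small_r**2 - h**2)
    if d >= big_r + small_r:
        raise ConfigError("daughter does not touch mother")
    height = int(math.ceil(2 * big_r + 2 * pad_px))
    width = int(math.ceil(big_r + d + small_r + 2 * pad_px))
    cy = height / 2.0
    mc = (cy, pad_px + big_r)
    dc = (cy, pad_px + big_r + d)
    yy, xx = np.mgrid[0:height, 0:width]
    in_mother = (yy - mc[0]) ** 2 + (xx - mc[1]) ** 2 <= big_r**2
    in_daughter = (yy - dc[0]) ** 2 + (xx - dc[1]) ** 2 <= small_r**2
    mask = np.zeros((height, width), dtype=np.int32)
    mask[in_mother] = 1
    mask[in_daughter & ~in_mother] = 2
    geometry = CellGeometryTruth(label_mask=mask, mother_center=mc, daughter_center=dc, config=config)
    geometry.contours = {
        "mother": _circle_contour(mc, big_r, dc, small_r, config, "mother"),
        "daughter": _circle_contour(dc, small_r, mc, big_r, config, "daughter"),
    }
    return geometry


# ---------------------------------------------------------------------------
# event sampling


def event_frame_span(t_birth_s: float, t_death_s: float, n_frames: int, frame_interval_s: float) -> tuple[int, int]:
    """First and last movie frame in which an event is alive, or (-1, -1).

    An event is alive in frame k when ``t_birth <= k * dt < t_death``
    (frames sample instants at k * dt).
    """
    first = max(0, int(math.ceil(t_birth_s / frame_interval_s - 1e-9)))
    last = min(n_frames - 1, int(math.ceil(t_death_s / frame_interval_s - 1e-9)) - 1)
    if last < first:
        return -1, -1
    return first, last


def _sample_lifetimes(params: CompartmentParams, n: int, min_s: float, rng: np.random.Generator) -> np.ndarray:
    mean, cv = params.lifetime_mean_s, params.lifetime_cv
    out = np.empty(n)
    todo = np.arange(n)
    while len(todo):
        if params.lifetime_family == "gaussian":
            draw = rng.normal(mean, cv * mean, size=len(todo))
        else:
            sigma2 = math.log(1 + cv**2)
            draw = rng.lognormal(math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2), size=len(todo))
        out[todo] = draw
        todo = np.nonzero(out < min_s)[0]  # rejection: resample below-truncation draws
    return out


def _contour_position(contour: Contour, u_px: float) -> tuple[float, float, float]:
    """Map a uniform draw on retained arclength (px) to (arclength_um, y, x)."""
    idx = contour.retained_indices
    k = idx[min(int(u_px / contour.step_px), len(idx) - 1)]
    y, x = contour.points[k]
    return contour.arclength_um[k], float(y), float(x)


def sample_events(
    config: SimulationConfig, geometry: CellGeometryTruth, rng: np.random.Generator | None = None
) -> list[EventRecord]:
    """Draw ground-truth cortical events, interior puncta and eisosomes.

    Cortical births form a homogeneous Poisson process in (arclength x
    time) on each compartment's retained contour, extended before t = 0 so
    that events already in progress at the movie start appear (and are
    censored). Lifetimes are truncated at two frame intervals. When a
    two-channel offset is configured, every cortical event gets a
    channel-2 twin with shifted birth/death times.
    """
    if rng is None:
        rng = substream(config.seed, "synthetic_movie.events")
    dt = config.frame_interval_s
    n_frames = config.n_frames
    min_life = MIN_LIFETIME_FRAMES * dt
    events: list[EventRecord] = []

    def add(compartment: str, arc_um: float, y: float, x: float, t0: float, t1: float,
            channel: int, amplitude: float, params: CompartmentParams | None) -> None:
        first, last = event_frame_span(t0, t1, n_frames, dt)
        if first < 0:
            return
        low_frac, low_dur, profile = 1.0, 0.0, "plateau"
        if params is not None:
            profile = params.profile
            if params.two_stage is not None:
                low_frac, low_dur = params.two_stage
        events.append(
            EventRecord(
                event_id=len(events) + 1,
                cell_id=1,
                compartment=compartment,
                arclength_um=arc_um,
                t_birth_s=t0,
                t_death_s=t1,
                channel=channel,
                amplitude=amplitude,
                y_px=y,
                x_px=x,
                censored_start_truth=first == 0,
                censored_end_truth=last == n_frames - 1,
                first_frame=first,
                last_frame=last,
                low_fraction=low_frac,
                low_duration_s=low_dur,
                profile=profile,
            )
        )

    for name in ("mother", "daughter"):
        params = config.compartment(name)
        contour = geometry.contours[name]
        length_um = contour.retained_length_um
        pad_s = min(config.duration_s, 4.0 * params.lifetime_mean_s)
        window_min = (config.duration_s + pad_s) / 60.0
        n = rng.poisson(params.rate_per_um_min * length_um * window_min)
        if n == 0:
            continue
        births = rng.uniform(-pad_s, config.duration_s, size=n)
        lifetimes = _sample_lifetimes(params, n, min_life, rng)
        positions = rng.uniform(0.0, contour.retained_length_px, size=n)
        order = np.argsort(births)
        for b, life, u in zip(births[order], lifetimes[order], positions[order]):
            arc_um, y, x = _contour_position(contour, u)
            add(name, arc_um, y, x, b, b + life, 1, params.amplitude, params)
            if config.channel_offset_s is not None:
                off_b, off_d = config.channel_offset_s
                add(name, arc_um, y, x, b + off_b, b + life + off_d, 2, params.amplitude, params)

    # interior cytoplasmic puncta: static spots clear of the cortex
    if config.n_interior_puncta > 0:
        clearance = config.puncta_clearance_px
        dist_in = ndi.distance_transform_edt(geometry.label_mask > 0)
        candidates = np.argwhere(dist_in >= clearance)
        if len(candidates) == 0:
            raise ConfigError("cell too small to place interior puncta clear of the cortex")
        pick = candidates[rng.choice(len(candidates), size=config.n_interior_puncta, replace=False)]
        for y, x in pick:
            add("interior", float("nan"), float(y), float(x), 0.0, config.duration_s + dt, 1,
                config.puncta_amplitude, None)

    # eisosome analogues: immobile puncta on the mother cortex
    if config.n_eisosomes > 0:
        contour = geometry.contours["mother"]
        for u in rng.uniform(0.0, contour.retained_length_px, size=config.n_eisosomes):
            arc_um, y, x = _contour_position(contour, u)
            add("eisosome", arc_um, y, x, 0.0, config.duration_s + dt, 1, config.eisosome_amplitude, None)

    return events


def events_to_dataframe(events: list[EventRecord]) -> pd.DataFrame:
    cols = [
        "event_id", "cell_id", "compartment", "channel", "arclength_um",
        "t_birth_s", "t_death_s", "amplitude", "y_px", "x_px",
        "first_frame", "last_frame", "censored_start_truth", "censored_end_truth",
        "low_fraction", "low_duration_s", "profile",
    ]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events], columns=cols)


# ---------------------------------------------------------------------------
# rendering


def _amplitude_at(event: EventRecord, t_s: float) -> float:
    if not event.t_birth_s <= t_s < event.t_death_s:
        return 0.0
    amp = event.amplitude
    if event.low_duration_s > 0 and t_s < event.t_birth_s + event.low_duration_s:
        amp *= event.low_fraction
    if event.profile == "ramp":
        life = event.t_death_s - event.t_birth_s
        frac = (t_s - event.t_birth_s) / life
        amp *= 1.0 - abs(2.0 * frac - 1.0)
    return amp


def render_movie(
    events: list[EventRecord],
    geometry: CellGeometryTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> dict[int, FrameStack]:
    """Render one :class:`FrameStack` per channel.

    Each event is an isotropic Gaussian spot (sigma = ``psf_sigma_px``) at
    its fixed position, modulated by its temporal profile. The expected
    photon image (cytoplasmic + camera background included) is bleached
    globally by ``exp(-bleach_rate * t)``, Poisson-sampled, and Gaussian
    read noise is added. ``noise=False`` returns the noiseless expectation
    (useful for oracles).
    """
    if rng is None:
        rng = substream(config.seed, "synthetic_movie.render")
    shape = geometry.shape
    n_frames = config.n_frames
    dt = config.frame_interval_s
    base = np.full(shape, config.background, dtype=float)
    base[geometry.label_mask > 0] = config.cell_background
    base = ndi.gaussian_filter(base, 1.0)  # soft cell edge, as in real cytoplasm
    sigma = config.psf_sigma_px
    half = int(math.ceil(4 * sigma))
    for params in (config.mother, config.daughter):
        snr = params.amplitude / math.sqrt(params.amplitude + config.cell_background)
        if snr < 1:
            log.warning("expected peak SNR %.2f < 1 for amplitude %.1f", snr, params.amplitude)
    channels = sorted({e.channel for e in events}) or [1]
    stacks: dict[int, FrameStack] = {}
    for channel in channels:
        frames = np.tile(base, (n_frames, 1, 1))
        for event in events:
            if event.channel != channel:
                continue
            y0, x0 = event.y_px, event.x_px
            iy, ix = int(round(y0)), int(round(x0))
            ylo, yhi = max(0, iy - half), min(shape[0], iy + half + 1)
            xlo, xhi = max(0, ix - half), min(shape[1], ix + half + 1)
            if ylo >= yhi or xlo >= xhi:
                continue
            yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
            stamp = np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sigma**2))
            for k in range(max(0, event.first_frame), min(n_frames - 1, event.last_frame) + 1):
                amp = _amplitude_at(event, k * dt)
                if amp > 0:
                    frames[k, ylo:yhi, xlo:xhi] += amp * stamp
        if config.bleach_rate_per_s > 0:
            decay = np.exp(-config.bleach_rate_per_s * dt * np.arange(n_frames))
            frames *= decay[:, None, None]
        if noise:
            frames = rng.poisson(frames).astype(float)
            if config.read_noise_sd > 0:
                frames += rng.normal(0.0, config.read_noise_sd, size=frames.shape)
            frames = np.clip(frames, 0.0, None)
        stacks[channel] = FrameStack(
            pixels=frames,
            pixel_size_nm=config.pixel_size_nm,
            frame_interval_s=config.frame_interval_s,
            channel_name=f"ch{channel}",
        )
    return stacks


def simulate(config: SimulationConfig, noise: bool = True) -> SimulationResult:
    """Full generation pass: geometry, events, rendered channels."""
    geometry = make_cell_geometry(config)
    events = sample_events(config, geometry, substream(config.seed, "synthetic_movie.events"))
    stacks = render_movie(events, geometry, config, substream(config.seed, "synthetic_movie.render"), noise=noise)
    return SimulationResult(config=config, geometry=geometry, events=events, stacks=stacks)


# ---------------------------------------------------------------------------
# small two-channel colocalization scenes


def simulate_coloc_scene(
    n_puncta: int = 12,
    colocalized: bool = True,
    amplitude: float = 60.0,
    background: float = 20.0,
    psf_sigma_px: float = 1.4,
    shape: tuple[int, int] = (96, 96),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-channel projection images with shared or independent puncta.

    Returns ``(img_a, img_b, mask)`` where the mask is a centred disk
    (the cell). With ``colocalized=True`` channel-B puncta sit at the
    channel-A positions; otherwise they are placed independently.
    """
    rng = substream(seed, "synthetic_movie.coloc_scene")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    radius = min(shape) / 2.0 - 6
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2

    def draw_positions() -> np.ndarray:
        r = radius * np.sqrt(rng.uniform(0, 1, n_puncta))
        th = rng.uniform(0, 2 * math.pi, n_puncta)
        return np.stack([cy + r * np.sin(th), cx + r * np.cos(th)], axis=1)

    pos_a = draw_positions()
    pos_b = pos_a if colocalized else draw_positions()

    def render(positions: np.ndarray) -> np.ndarray:
        img = np.full(shape, background, dtype=float)
        for y0, x0 in positions:
            img += amplitude * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * psf_sigma_px**2))
        return rng.poisson(img).astype(float)

    return render(pos_a), render(pos_b), mask
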