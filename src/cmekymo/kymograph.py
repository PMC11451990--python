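"""Circumferential kymographs.

A circumferential kymograph maps intensity along a compartment's retained
cortical contour (rows) against time (columns). Endocytic events appear as
vertical streaks whose length is the protein's lifetime at that site. Rows
are the retained contour samples in order; the closed-contour seam keeps
rows adjacent, while rows flanking an excluded (bud-neck) gap are not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .cell_geometry import Contour
from .core import ConfigError, FrameStack


@dataclass
class Kymograph:
    """Cortex-position x time intensity map for one compartment.

    ``adjacent_next[i]`` says whether row ``i`` and row ``(i+1) % S`` are
    spatial neighbours on the cortex. It is True across the closed-contour
    seam and False across excluded (neck) gaps, which trace detection must
    respect when connecting pixels.
    """

    values: np.ndarray  # (S, T)
    row_arclength_um: np.ndarray  # (S,)
    adjacent_next: np.ndarray  # (S,) bool
    pixel_size_nm: float
    frame_interval_s: float
    cell_id: int | None = None
    compartment: str | None = None
    channel_name: str = "ch1"
    row_valid: np.ndarray | None = None  # False where band mostly out of bounds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("kymograph values must be 2D (rows x frames)")
        s = self.values.shape[0]
        if len(self.row_arclength_um) != s or len(self.adjacent_next) != s:
            raise ConfigError("row metadata length must match row count")
        if self.row_valid is None:
            self.row_valid = np.ones(s, dtype=bool)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def duration_min(self) -> float:
        return self.n_frames * self.frame_interval_s / 60.0

    @property
    def retained_length_um(self) -> float:
        if self.n_rows < 2:
            return 0.0
        step_um = np.median(np.diff(np.sort(self.row_arclength_um)))
        return float(self.n_rows * step_um)


def max_intensity_projection(stack: FrameStack) -> np.ndarray:
    """Per-pixel maximum over time; summarises every event in one image."""
    return stack.pixels.max(axis=0)


def _band_coordinates(contour: Contour, width_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample coordinates for a centred band of odd width along the normals.

    Returns (ys, xs) of shape (S_retained, width_px): for each retained
    contour sample, ``width_px`` points spaced 1 px along the local normal.
    """
    if width_px < 1 or width_px % 2 == 0:
        raise ConfigError("band width must be an odd integer >= 1")
    idx = contour.retained_indices
    pts = contour.points[idx]
    normals = contour.normals()[idx]
    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    ys = pts[:, 0, None] + offsets[None, :] * normals[:, 0, None]
    xs = pts[:, 1, None] + offsets[None, :] * normals[:, 1, None]
    return ys, xs


def _interp(frame: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Bilinear interpolation; coordinates outside the image give NaN."""
    frame = np.asarray(frame, dtype=float)
    vals = map_coordinates(frame, [ys.ravel(), xs.ravel()], order=1, mode="constant", cval=np.nan)
    inside = (
        (ys.ravel() >= 0)
        & (ys.ravel() <= frame.shape[0] - 1)
        & (xs.ravel() >= 0)
        & (xs.ravel() <= frame.shape[1] - 1)
    )
    vals[~inside] = np.nan
    return vals.reshape(ys.shape)


def sample_band(
    frame: np.ndarray,
    contour: Contour,
    width_px: int = 5,
    reduction: str = "max",
) -> np.ndarray:
    """Reduce a centred normal band to one intensity per retained sample.

    ``reduction='max'`` is robust to sub-pixel contour placement error;
    ``'mean'`` is better suited to photometry. Out-of-bounds band points
    are ignored; rows with more than half of the band outside the image
    are returned as NaN (callers flag them).
    """
    if reduction not in ("max", "mean"):
        raise ConfigError("reduction must be 'max' or 'mean'")
    ys, xs = _band_coordinates(contour, width_px)
    vals = _interp(frame, ys, xs)
    bad = np.isnan(vals).sum(axis=1) > 0.5 * width_px
    with np.errstate(all="ignore"):
        out = np.nanmax(vals, axis=1) if reduction == "max" else np.nanmean(vals, axis=1)
    out[bad] = np.nan
    return out


def _row_adjacency(contour: Contour) -> np.ndarray:
    """adjacent_next over retained rows: neighbours iff consecutive samples."""
    idx = contour.retained_indices
    s = len(idx)
    nxt = np.roll(idx, -1)
    gap = (nxt - idx) % contour.n_points
    adjacent = gap == 1
    if not contour.closed:
        adjacent[-1] = False
    return adjacent if s > 1 else np.zeros(s, dtype=bool)


def build_kymograph(
    stack: FrameStack,
    contour: Contour,
    width_px: int = 5,
    reduction: str = "max",
) -> Kymograph:
    """Build the circumferential kymograph of one compartment.

    Column ``t`` is :func:`sample_band` applied to frame ``t``. Rows with a
    mostly out-of-bounds band are zeroed and flagged in ``row_valid``.
    """
    idx = contour.retained_indices
    if len(idx) == 0:
        raise ConfigError("contour has no retained samples")
    ys, xs = _band_coordinates(contour, width_px)
    s = ys.shape[0]
    values = np.empty((s, stack.n_frames), dtype=float)
    valid = np.ones(s, dtype=bool)
    for t in range(stack.n_frames):
        vals = _interp(stack.pixels[t], ys, xs)
        bad = np.isnan(vals).sum(axis=1) > 0.5 * width_px
        with np.errstate(all="ignore"):
            col = np.nanmax(vals, axis=1) if reduction == "max" else np.nanmean(vals, axis=1)
        col = np.nan_to_num(col, nan=0.0)
        values[:, t] = col
        valid &= ~bad
    return Kymograph(
        values=values,
        row_arclength_um=contour.arclength_um[idx],
        adjacent_next=_row_adjacency(contour),
        pixel_size_nm=contour.pixel_size_nm,
        frame_interval_s=stack.frame_interval_s,
        cell_id=contour.cell_id,
        compartment=contour.compartment,
        channel_name=stack.channel_name,
        row_valid=valid,
    )


def pair_two_color(kymo_a: Kymograph, kymo_b: Kymograph) -> tuple[Kymograph, Kymograph]:
    """Pair two kymographs built on the same contour for two-colour analysis."""
    if kymo_a.values.shape[0] != kymo_b.values.shape[0] or not np.allclose(
        kymo_a.row_arclength_um, kymo_b.row_arclength_um
    ):
        raise ConfigError("kymographs were not built from the same contour")
    if kymo_a.cell_id != kymo_b.cell_id or kymo_a.compartment != kymo_b.compartment:
        raise ConfigError("kymographs belong to different cells or compartments")
    return kymo_a, kymo_b


def render_kymograph_png(kymo: Kymograph, path, scalebar_s: float = 30.0) -> None:
    """Save a PNG render (time horizontal) with a 30-s time scale bar."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.imshow(kymo.values, cmap="gray", aspect="auto", interpolation="nearest")
    bar_frames = scalebar_s / kymo.frame_interval_s
    y = kymo.n_rows * 0.95
    ax.plot([1, 1 + bar_frames], [y, y], color="white", lw=3)
    ax.set_xlabel("time (frames)")
    ax.set_ylabel("cortex position (samples)")
    title = f"cell {kymo.cell_id} {kymo.compartment or ''} {kymo.channel_name}"
    ax.set_title(title.strip())
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
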