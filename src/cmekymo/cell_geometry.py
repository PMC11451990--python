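"""Cell-contour extraction from label masks.

A budded yeast cell is segmented into two labelled objects, the mother and
the daughter (bud). Each object's boundary becomes an ordered, uniformly
resampled closed contour; the bud-neck region — where the two objects touch
and endocytic sites are too crowded to resolve — is excluded from the
contour before any kymograph is built.

Coordinates are 0-based ``(row, col)`` = ``(y, x)``; contour points are
sub-pixel. Orientation is counter-clockwise with respect to conventional
math axes (x right, y up), i.e. clockwise on a screen that draws row 0 at
the top. Arclength is reported in micrometres using the pixel size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure
from skimage.feature import peak_local_max
from skimage.filters import median as median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import disk, erosion
from skimage.segmentation import watershed

from .core import DEFAULT_PIXEL_SIZE_NM, ConfigError, GeometryError

MIN_CONTOUR_PIXELS = 9


# ---------------------------------------------------------------------------
# containers


@dataclass
class BuddedCell:
    """A mother/daughter label pair with the pixels where they touch."""

    cell_id: int
    mother_label: int
    daughter_label: int
    neck_pixels: np.ndarray  # (K, 2) int array of (y, x) boundary coordinates

    def __post_init__(self) -> None:
        self.neck_pixels = np.atleast_2d(np.asarray(self.neck_pixels))
        if self.neck_pixels.size == 0:
            raise GeometryError("BuddedCell requires non-empty neck pixels")


@dataclass
class Contour:
    """Closed cell outline, uniformly resampled, with excluded intervals.

    ``points`` holds all samples of the closed boundary in order; the
    boolean ``excluded`` mask marks samples removed from analysis (the bud
    neck). Spacing between consecutive samples is ``step_px`` everywhere on
    the closed curve, so arclengths are exact multiples of the step.
    """

    points: np.ndarray  # (N, 2) float, (y, x), closed (last connects to first)
    step_px: float
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM
    excluded: np.ndarray | None = None
    compartment: str | None = None
    cell_id: int | None = None
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.excluded is None:
            self.excluded = np.zeros(len(self.points), dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if len(self.excluded) != len(self.points):
            raise ConfigError("excluded mask length must match points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def retained(self) -> np.ndarray:
        return ~self.excluded

    @property
    def retained_indices(self) -> np.ndarray:
        return np.nonzero(self.retained)[0]

    @property
    def arclength_px(self) -> np.ndarray:
        """Cumulative arclength (px) of every sample along the closed curve."""
        return np.arange(self.n_points) * self.step_px

    @property
    def arclength_um(self) -> np.ndarray:
        return self.arclength_px * self.pixel_size_nm / 1000.0

    @property
    def total_length_px(self) -> float:
        return self.n_points * self.step_px

    @property
    def total_length_um(self) -> float:
        return self.total_length_px * self.pixel_size_nm / 1000.0

    @property
    def retained_length_px(self) -> float:
        return int(self.retained.sum()) * self.step_px

    @property
    def retained_length_um(self) -> float:
        return self.retained_length_px * self.pixel_size_nm / 1000.0

    @property
    def excluded_length_px(self) -> float:
        return int(self.excluded.sum()) * self.step_px

    def excluded_intervals(self) -> list[tuple[int, int]]:
        """Inclusive index intervals of excluded runs (circular runs split)."""
        exc = self.excluded
        if not exc.any():
            return []
        if exc.all():
            return [(0, self.n_points - 1)]
        edges = np.diff(exc.astype(int))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0])
        if exc[0]:
            starts = [0] + starts
        if exc[-1]:
            ends = ends + [self.n_points - 1]
        return list(zip(starts, ends))

    def normals(self) -> np.ndarray:
        """Unit normals at every sample (central differences, circular)."""
        pts = self.points
        tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        # rotate tangent by 90 degrees; sign is irrelevant for symmetric bands
        return np.stack([-tang[:, 1], tang[:, 0]], axis=1)


# ---------------------------------------------------------------------------
# image preparation and segmentation


def blur_frame(image: np.ndarray, median_radius_px: int = 2, erosion_radius_px: int = 1) -> np.ndarray:
    """Median-filter then grayscale-erode an image with disk footprints.

    Used to suppress background noise before segmentation. Radius 0 skips
    the corresponding step, so ``blur_frame(img, 0, 0)`` is the identity.
    """
    image = np.asarray(image)
    if median_radius_px < 0 or erosion_radius_px < 0:
        raise ConfigError("blur radii must be >= 0")
    half = min(image.shape) // 2
    if median_radius_px > half or erosion_radius_px > half:
        raise ConfigError("blur radius exceeds half the image size")
    out = image
    if median_radius_px > 0:
        out = median_filter(out, footprint=disk(median_radius_px))
    if erosion_radius_px > 0:
        out = erosion(out, footprint=disk(erosion_radius_px))
    return out


def segment_cells(blurred: np.ndarray, method: str = "otsu-watershed", min_size_px: int = 64) -> np.ndarray:
    """Label cell lobes in a blurred image.

    The built-in method (a stand-in for an external deep-learning
    segmenter) applies a global Otsu threshold, fills holes, removes
    specks, and splits touching lobes with a distance-transform watershed.
    External masks should be passed through :func:`validate_mask` instead.
    """
    if method != "otsu-watershed":
        raise ConfigError(f"unknown segmentation method: {method!r}")
    blurred = np.asarray(blurred, dtype=float)
    if np.ptp(blurred) == 0:
        raise ConfigError("cannot segment a constant image")
    binary = blurred > threshold_otsu(blurred)
    binary = ndi.binary_fill_holes(binary)
    lab, n = ndi.label(binary)
    if n:
        sizes = np.bincount(lab.ravel())
        binary = sizes[lab] >= min_size_px
        binary &= lab > 0
    if not binary.any():
        raise ConfigError("no objects found above threshold")
    distance = ndi.distance_transform_edt(binary)
    coords = peak_local_max(distance, min_distance=8, labels=binary, exclude_border=False)
    markers = np.zeros_like(binary, dtype=int)
    for i, (y, x) in enumerate(coords, start=1):
        markers[y, x] = i
    labels = watershed(-distance, markers, mask=binary)
    return labels.astype(np.int32)


def validate_mask(labels: np.ndarray) -> np.ndarray:
    """Validate an externally produced label mask (8-connected regions)."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ConfigError("label mask must be 2D")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.allclose(labels, np.round(labels)):
            raise ConfigError("label mask must be integer-valued")
        labels = np.round(labels).astype(np.int32)
    if labels.min() < 0:
        raise ConfigError("label mask values must be >= 0")
    struct = np.ones((3, 3), dtype=bool)
    for lab in np.unique(labels):
        if lab == 0:
            continue
        _, n = ndi.label(labels == lab, structure=struct)
        if n != 1:
            raise ConfigError(f"label {lab} is not a single connected region")
    return labels.astype(np.int32)


# ---------------------------------------------------------------------------
# pairing


def _adjacency_pixels(mask: np.ndarray, a: int, b: int) -> np.ndarray:
    """(y, x) pixels of label a or b that are 8-adjacent to the other label."""
    struct = np.ones((3, 3), dtype=bool)
    am, bm = mask == a, mask == b
    touch_a = am & ndi.binary_dilation(bm, structure=struct)
    touch_b = bm & ndi.binary_dilation(am, structure=struct)
    return np.argwhere(touch_a | touch_b)


def pair_mother_daughter(mask: np.ndarray) -> tuple[list[BuddedCell], list[int]]:
    """Pair touching labels into budded cells; the larger lobe is the mother.

    Returns ``(cells, singletons)`` where ``singletons`` lists labels with
    no touching partner (unbudded cells). A label touching two or more
    partners is ambiguous and raises :class:`GeometryError`.
    """
    mask = validate_mask(mask)
    labels = [int(v) for v in np.unique(mask) if v > 0]
    struct = np.ones((3, 3), dtype=bool)
    partners: dict[int, list[int]] = {lab: [] for lab in labels}
    for lab in labels:
        dil = ndi.binary_dilation(mask == lab, structure=struct)
        touched = np.unique(mask[dil & (mask > 0) & (mask != lab)])
        partners[lab] = [int(t) for t in touched]
    for lab, p in partners.items():
        if len(p) > 1:
            raise GeometryError(f"label {lab} touches multiple partners {sorted(p)}: ambiguous pairing")
    cells: list[BuddedCell] = []
    singletons: list[int] = []
    seen: set[int] = set()
    areas = {lab: int((mask == lab).sum()) for lab in labels}
    for lab in labels:
        if lab in seen:
            continue
        if not partners[lab]:
            singletons.append(lab)
            seen.add(lab)
            continue
        other = partners[lab][0]
        seen.update({lab, other})
        mother, daughter = (lab, other) if areas[lab] >= areas[other] else (other, lab)
        cells.append(
            BuddedCell(
                cell_id=len(cells) + 1,
                mother_label=mother,
                daughter_label=daughter,
                neck_pixels=_adjacency_pixels(mask, mother, daughter),
            )
        )
    return cells, singletons


# ---------------------------------------------------------------------------
# contours


def _signed_area(points: np.ndarray) -> float:
    # shoelace in math axes: x = col, y = -row
    x = points[:, 1]
    y = -points[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def extract_contour(
    mask: np.ndarray,
    label: int,
    step_px: float = 1.0,
    pixel_size_nm: float = DEFAULT_PIXEL_SIZE_NM,
    compartment: str | None = None,
    cell_id: int | None = None,
) -> Contour:
    """Sub-pixel closed boundary of one label, resampled to uniform spacing.

    The label's indicator image is lightly smoothed (Gaussian, sigma 1 px)
    to suppress the pixel staircase before tracing the 0.5 iso-level, so
    the measured perimeter approximates the underlying smooth boundary
    rather than the jagged pixel outline. The polygon is oriented
    counter-clockwise and resampled by arclength (with refinement passes)
    to uniform spacing of ``total / round(total / step_px)``.
    """
    mask = np.asarray(mask)
    region = mask == label
    if not region.any():
        raise GeometryError(f"label {label} not present in mask")
    if region.sum() < MIN_CONTOUR_PIXELS:
        raise GeometryError(f"label {label} has fewer than {MIN_CONTOUR_PIXELS} pixels")
    indicator = ndi.gaussian_filter(np.pad(region.astype(float), 3), 1.0)
    contours = measure.find_contours(indicator, 0.5)
    pts = max(contours, key=len) - 3.0  # undo padding
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    resampled = pts
    for _ in range(3):  # refine: equal path spacing converges to equal chords
        closed = np.vstack([resampled, resampled[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        n = max(8, int(round(total / step_px)))
        s = np.arange(n) * total / n
        resampled = np.stack(
            [np.interp(s, cum, closed[:, 0]), np.interp(s, cum, closed[:, 1])], axis=1
        )
    return Contour(
        points=resampled,
        step_px=total / n,
        pixel_size_nm=pixel_size_nm,
        compartment=compartment,
        cell_id=cell_id,
    )


def exclude_neck(contour: Contour, neck_pixels: np.ndarray, margin_px: float) -> Contour:
    """Mark contour samples within ``margin_px`` of any neck pixel excluded.

    CME sites at the bud neck are too crowded to analyse, so the affected
    arc (plus a safety margin) is removed from downstream kymographs.
    """
    if not contour.closed:
        raise ConfigError("exclude_neck requires a closed contour")
    if margin_px < 0:
        raise ConfigError("margin must be >= 0")
    neck_pixels = np.atleast_2d(np.asarray(neck_pixels, dtype=float))
    if neck_pixels.size == 0:
        return replace(contour, excluded=contour.excluded.copy())
    dist, _ = cKDTree(neck_pixels).query(contour.points)
    excluded = contour.excluded | (dist <= margin_px)
    if excluded.sum() > 0.5 * contour.n_points:
        raise GeometryError("neck exclusion removes more than half of the contour")
    return replace(contour, excluded=excluded)


# ---------------------------------------------------------------------------
# band width


def band_width_from_mip(
    mip: np.ndarray,
    contour: Contour,
    coverage_fraction: float = 0.95,
    psf_sigma_px: float = 2.0,
    background: float | None = None,
    default_width: int = 5,
) -> int:
    """Smallest odd band width capturing the cortical signal in a MIP.

    Mirrors the manual practice of widening the outline until it covers all
    cortical fluorescence in the movie's maximum intensity projection: the
    above-background MIP intensity is integrated along the contour normals
    and the narrowest centred odd width holding at least
    ``coverage_fraction`` of the mass within 3 PSF sigmas is returned.
    """
    from .kymograph import _band_coordinates, _interp  # local import avoids cycle

    if not 0 < coverage_fraction <= 1:
        raise ConfigError("coverage_fraction must be in (0, 1]")
    mip = np.asarray(mip, dtype=float)
    if background is None:
        background = float(np.median(mip))
    half_max = int(np.ceil(3 * psf_sigma_px))
    w_max = 2 * half_max + 1
    ys, xs = _band_coordinates(contour, w_max)
    vals = _interp(mip, ys, xs)  # (S, w_max), NaN out of bounds
    above = np.clip(np.nan_to_num(vals, nan=0.0) - background, 0.0, None)
    total = above.sum()
    if total <= 0 or np.nanmax(vals) <= background:
        warnings.warn("no above-background cortical signal in MIP; using default band width")
        return default_width
    centre = half_max
    for w in range(1, w_max + 1, 2):
        h = (w - 1) // 2
        if above[:, centre - h : centre + h + 1].sum() >= coverage_fraction * total:
            return w
    return w_max
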