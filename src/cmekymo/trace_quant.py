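"""Event-trace detection and lifetime statistics on kymographs.

An endocytic event shows up on a circumferential kymograph as a vertical
streak: the protein appears, accumulates, and disappears at a fixed cortex
position. A trace's temporal extent is the protein's lifetime at that site;
traces touching the first or last frame are censored (their true lifetime
is underestimated). Frequencies are normalised per retained micrometre of
cortex per minute, correcting for the different surface distance sampled in
mother and daughter compartments.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sstats

from .core import ConfigError
from .kymograph import Kymograph

MAD_TO_SIGMA = 1.4826


@dataclass
class Trace:
    """One detected endocytic event on a kymograph."""

    rows: np.ndarray  # sorted row indices covered by the trace
    t_start: int  # first frame, inclusive
    t_end: int  # last frame, inclusive
    frame_interval_s: float
    censored_start: bool
    censored_end: bool
    intensity_profile: np.ndarray  # per-frame above-baseline sum over the trace pixels
    peak: float
    trace_id: int = 0

    @property
    def lifetime_frames(self) -> int:
        return self.t_end - self.t_start + 1

    @property
    def lifetime_s(self) -> float:
        return self.lifetime_frames * self.frame_interval_s

    @property
    def censored(self) -> bool:
        return self.censored_start or self.censored_end

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def row_centre(self) -> float:
        return float(np.median(self.rows))


@dataclass
class LifetimeSummary:
    """Per-compartment lifetime and frequency statistics."""

    n_events: int
    n_censored: int
    mean_s: float
    sd_s: float
    cv_percent: float
    frequency_per_um_min: float
    retained_length_um: float
    duration_min: float
    compartment: str | None = None
    channel_name: str | None = None
    n_in_moments: int = 0


@dataclass
class TwoStageSplit:
    """Piecewise-constant split of a trace into low/high intensity stages."""

    change_frame: int  # absolute frame index of the first high-stage frame
    low_duration_s: float
    high_duration_s: float
    low_mean: float
    high_mean: float
    step_significant: bool


# ---------------------------------------------------------------------------
# baseline and detection


def estimate_baseline(kymo: Kymograph) -> tuple[np.ndarray, float]:
    """Per-row temporal-median baseline and a pooled robust noise scale.

    The median tolerates up to 50% event contamination per row; the noise
    scale is 1.4826 x the median absolute deviation of the residuals,
    pooled over all rows (consistent for Gaussian noise).
    """
    if kymo.n_frames < 5:
        raise ConfigError("baseline estimation requires at least 5 frames")
    baseline = np.median(kymo.values, axis=1)
    resid = kymo.values - baseline[:, None]
    noise = MAD_TO_SIGMA * float(np.median(np.abs(resid)))
    return baseline, noise


def _label_with_adjacency(binary: np.ndarray, adjacent_next: np.ndarray) -> np.ndarray:
    """8-connected components respecting row adjacency (seam and gaps).

    Non-adjacent consecutive rows are separated by inserting a blank row
    before labelling; the circular seam (last row adjacent to row 0) is
    handled by merging labels that touch across it.
    """
    s, t = binary.shape
    breaks = [i for i in range(s - 1) if not adjacent_next[i]]
    expanded = np.zeros((s + len(breaks), t), dtype=bool)
    row_map = np.empty(s, dtype=int)
    offset = 0
    brk = set(breaks)
    for i in range(s):
        row_map[i] = i + offset
        expanded[i + offset] = binary[i]
        if i in brk:
            offset += 1
    struct = np.ones((3, 3), dtype=bool)
    lab_exp, n = ndi.label(expanded, structure=struct)
    labels = lab_exp[row_map]
    if n and s > 1 and adjacent_next[s - 1]:
        # union labels touching across the seam (8-connectivity in time)
        parent = list(range(n + 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        top, bot = labels[0], labels[s - 1]
        for dt_ in (-1, 0, 1):
            shifted = np.roll(bot, dt_)
            if dt_ == 1:
                shifted[0] = 0
            elif dt_ == -1:
                shifted[-1] = 0
            for a, b in zip(top, shifted):
                if a and b:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[rb] = ra
        lut = np.arange(n + 1)
        for i in range(1, n + 1):
            lut[i] = find(i)
        labels = lut[labels]
    return labels


def detect_traces(
    kymo: Kymograph,
    k_sigma: float = 4.0,
    min_len_frames: int = 3,
    min_rows: int = 1,
    baseline: np.ndarray | None = None,
    noise: float | None = None,
) -> list[Trace]:
    """Threshold the kymograph and extract connected event traces.

    Pixels above ``baseline + k_sigma * noise`` are grouped by
    8-connectivity in (row, frame); rows wrap across the closed-contour
    seam but never across excluded-gap boundaries. Components shorter than
    ``min_len_frames`` frames or thinner than ``min_rows`` rows are
    discarded. Two events at the same cortex position separated by at
    least one sub-threshold frame stay distinct. Traces touching the first
    or last frame are flagged censored.
    """
    if baseline is None or noise is None:
        baseline, noise = estimate_baseline(kymo)
    binary = kymo.values > (baseline[:, None] + k_sigma * noise)
    if not binary.any():
        return []
    labels = _label_with_adjacency(binary, kymo.adjacent_next)
    resid = kymo.values - baseline[:, None]
    traces: list[Trace] = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        comp = labels == lab
        rows = np.nonzero(comp.any(axis=1))[0]
        frames = np.nonzero(comp.any(axis=0))[0]
        t0, t1 = int(frames[0]), int(frames[-1])
        if t1 - t0 + 1 < min_len_frames or len(rows) < min_rows:
            continue
        profile = np.array([resid[:, t][comp[:, t]].sum() for t in range(t0, t1 + 1)])
        traces.append(
            Trace(
                rows=rows,
                t_start=t0,
                t_end=t1,
                frame_interval_s=kymo.frame_interval_s,
                censored_start=t0 == 0,
                censored_end=t1 == kymo.n_frames - 1,
                intensity_profile=profile,
                peak=float(kymo.values[comp].max()),
                trace_id=len(traces) + 1,
            )
        )
    traces.sort(key=lambda tr: (tr.t_start, tr.row_centre))
    for i, tr in enumerate(traces, start=1):
        tr.trace_id = i
    return traces


# ---------------------------------------------------------------------------
# summaries and comparisons


def summarize_lifetimes(
    traces: list[Trace],
    retained_length_um: float,
    duration_min: float,
    censor_policy: str = "exclude",
    compartment: str | None = None,
    channel_name: str | None = None,
) -> LifetimeSummary:
    """Lifetime mean/SD/CV and initiation frequency for one compartment.

    With the default ``censor_policy='exclude'``, censored traces are left
    out of the moments (their lifetimes are underestimates) but are still
    counted in ``n_events`` and in the frequency, which is events per
    retained micrometre of cortex per minute.
    """
    if duration_min <= 0 or retained_length_um <= 0:
        raise ConfigError("duration and retained length must be positive")
    if censor_policy not in ("exclude", "include-flagged"):
        raise ConfigError("censor_policy must be 'exclude' or 'include-flagged'")
    n = len(traces)
    censored = [tr for tr in traces if tr.censored]
    pool = traces if censor_policy == "include-flagged" else [tr for tr in traces if not tr.censored]
    lifetimes = np.array([tr.lifetime_s for tr in pool], dtype=float)
    if len(lifetimes) >= 1:
        mean = float(lifetimes.mean())
        sd = float(lifetimes.std(ddof=1)) if len(lifetimes) > 1 else 0.0
        cv = 100.0 * sd / mean if mean > 0 else np.nan
    else:
        mean = sd = cv = float("nan")
    return LifetimeSummary(
        n_events=n,
        n_censored=len(censored),
        mean_s=mean,
        sd_s=sd,
        cv_percent=cv,
        frequency_per_um_min=n / (retained_length_um * duration_min),
        retained_length_um=retained_length_um,
        duration_min=duration_min,
        compartment=compartment,
        channel_name=channel_name,
        n_in_moments=len(lifetimes),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x (number of (x_i, y_j) pairs with x_i > y_j, ties 1/2)."""
    ranks = sstats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of label assignments when n1 + n2 <= 12
    and there are no ties; otherwise the normal approximation with
    mid-rank tie correction (no continuity correction, so identical
    samples give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ConfigError("Mann-Whitney requires two non-empty samples")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < n1 + n2
    if n1 + n2 <= 12 and not has_ties:
        # exhaustive enumeration of all C(n1+n2, n1) group assignments
        total = math.comb(n1 + n2, n1)
        u_low = min(u, n1 * n2 - u)
        count = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            xi = combined[list(idx)]
            yi = np.delete(combined, list(idx))
            ui = _u_statistic(xi, yi)
            if min(ui, n1 * n2 - ui) <= u_low + 1e-12:
                count += 1
        return u, count / total
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n1 + n2) * (n1 + n2 - 1))
    var = n1 * n2 / 12.0 * ((n1 + n2 + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    z = (u - mu) / math.sqrt(var)
    return u, float(min(1.0, 2.0 * sstats.norm.sf(abs(z))))


def compare_lifetimes(lifetimes_a, lifetimes_b) -> tuple[float, float]:
    """Compare two lifetime samples (Mann-Whitney U, two-sided p)."""
    return mann_whitney(lifetimes_a, lifetimes_b)


# ---------------------------------------------------------------------------
# two-stage (low-then-high) traces


def split_two_stage(trace: Trace, noise_scale: float = 0.0) -> TwoStageSplit:
    """Best two-segment piecewise-constant split of a trace's intensity.

    Models proteins recruited in a low-abundance stage followed by a
    high-abundance stage: the change point minimises the two-segment
    residual sum of squares over all interior split positions. The step is
    significant when the high mean exceeds the low mean by more than twice
    the noise scale.
    """
    profile = np.asarray(trace.intensity_profile, dtype=float)
    n = len(profile)
    if n < 6:
        raise ConfigError("trace too short to split (need >= 6 frames)")
    cum = np.concatenate([[0.0], np.cumsum(profile)])
    cum2 = np.concatenate([[0.0], np.cumsum(profile**2)])
    ks = np.arange(1, n)
    left_n, right_n = ks.astype(float), (n - ks).astype(float)
    left_sum, right_sum = cum[ks], cum[n] - cum[ks]
    rss = (cum2[n] - left_sum**2 / left_n - right_sum**2 / right_n)
    k = int(ks[np.argmin(rss)])
    low_mean = float(profile[:k].mean())
    high_mean = float(profile[k:].mean())
    dt = trace.frame_interval_s
    return TwoStageSplit(
        change_frame=trace.t_start + k,
        low_duration_s=k * dt,
        high_duration_s=(n - k) * dt,
        low_mean=low_mean,
        high_mean=high_mean,
        step_significant=(high_mean - low_mean) > 2.0 * noise_scale,
    )


# ---------------------------------------------------------------------------
# two-channel alignment


def _row_distance(rows_a: np.ndarray, rows_b: np.ndarray, n_rows_total: int) -> int:
    """Minimal circular row distance between two row sets."""
    best = n_rows_total
    for a in rows_a:
        d = np.abs(rows_b - a)
        d = np.minimum(d, n_rows_total - d)
        best = min(best, int(d.min()))
        if best == 0:
            return 0
    return best


def align_traces(
    traces_a: list[Trace],
    traces_b: list[Trace],
    n_rows_total: int,
    row_tol: int = 1,
    frame_tol: int = 5,
) -> tuple[list[bool], float]:
    """Greedy one-to-one matching of channel-A traces to channel-B traces.

    Trace ``a`` can match ``b`` when their row extents come within
    ``row_tol`` rows (circularly) and their time intervals overlap once
    dilated by ``frame_tol`` frames. Candidates are ranked by row-time
    overlap area and assigned greedily one-to-one. Returns the per-A-trace
    matched flags and the matched fraction (the complement of e.g. "87% of
    Myo5 traces did not align with Yap1802").
    """
    if not traces_a:
        raise ConfigError("channel A has no traces to align")
    candidates = []
    for i, a in enumerate(traces_a):
        for j, b in enumerate(traces_b):
            if _row_distance(a.rows, b.rows, n_rows_total) > row_tol:
                continue
            t_overlap = min(a.t_end, b.t_end) + frame_tol - max(a.t_start, b.t_start) + 1
            if t_overlap <= 0:
                continue
            r_overlap = len(np.intersect1d(a.rows, b.rows)) + 1
            candidates.append((t_overlap * r_overlap, i, j))
    candidates.sort(key=lambda c: -c[0])
    matched = [False] * len(traces_a)
    used_b: set[int] = set()
    for _, i, j in candidates:
        if matched[i] or j in used_b:
            continue
        matched[i] = True
        used_b.add(j)
    return matched, sum(matched) / len(traces_a)
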