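"""Ground-truth validation experiments.

Because the study's raw movies are not deposited, the pipeline is
validated against the synthetic generator: each experiment here builds a
seeded scene, runs the *blind* analysis (which never sees the ground
truth), and scores recovery against the simulator's event table. The same
experiments back both the test suite and the reproduction script.

Scene sizes (replicate counts, initiation rates) are package choices,
documented in the methods note: rates are kept low enough that kymograph
traces are individually resolvable — matching the visual density of real
circumferential kymographs — and replicate single-cell movies are pooled
to reach the stated event counts, as the study pooled events over cells.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from .cell_geometry import Contour
from .core import substream
from .kymograph import Kymograph
from .pipeline import AnalysisParams, ReportTable, analyze_movie
from .synthetic_movie import (
    CompartmentParams,
    EventRecord,
    SimulationConfig,
    simulate,
)
from .trace_quant import Trace, align_traces, detect_traces, split_two_stage
from .puncta_coloc import detect_interior_puncta


# ---------------------------------------------------------------------------
# reference (brute-force) trace labelling


def flood_fill_traces_reference(binary: np.ndarray, adjacent_next: np.ndarray) -> list[set]:
    """Brute-force connected components of a thresholded kymograph.

    Pure breadth-first flood fill over pixels, using 8-connectivity in
    (row, frame) where row neighbourhood follows ``adjacent_next`` (the
    closed-contour seam connects; excluded-gap boundaries do not). Serves
    as the independent reference for :func:`~cmekymo.trace_quant.detect_traces`.
    """
    s, t = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps: list[set] = []
    for r0 in range(s):
        for c0 in range(t):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            queue = deque([(r0, c0)])
            seen[r0, c0] = True
            while queue:
                r, c = queue.popleft()
                comp.add((r, c))
                neigh_rows = [(r, True)]
                if s > 1:
                    if adjacent_next[r]:
                        neigh_rows.append(((r + 1) % s, True))
                    if adjacent_next[(r - 1) % s]:
                        neigh_rows.append(((r - 1) % s, True))
                for rr, _ in neigh_rows:
                    for cc in (c - 1, c, c + 1):
                        if 0 <= cc < t and binary[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
            comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# truth <-> trace matching


def expected_row(contour: Contour, y: float, x: float) -> int:
    """Kymograph row index (among retained rows) nearest a truth position."""
    idx = contour.retained_indices
    pts = contour.points[idx]
    d2 = (pts[:, 0] - y) ** 2 + (pts[:, 1] - x) ** 2
    return int(np.argmin(d2))


def match_events_to_traces(
    events: list[EventRecord],
    traces: list[Trace],
    contour: Contour,
    kymo: Kymograph,
    row_tol: int = 4,
    min_overlap_frac: float = 0.5,
) -> dict[int, Trace | None]:
    """Greedy one-to-one matching of truth events to detected traces.

    An event can match a trace whose rows come within ``row_tol`` of the
    event's expected row (circularly) and whose frame span overlaps at
    least ``min_overlap_frac`` of the event's visible span. Candidates are
    ranked by time overlap. Returns event_id -> matched trace (or None).
    """
    s = kymo.n_rows
    candidates = []
    for e in events:
        if e.first_frame < 0:
            continue
        row = expected_row(contour, e.y_px, e.x_px)
        span = e.n_visible_frames
        for j, tr in enumerate(traces):
            d = np.abs(tr.rows - row)
            if int(np.minimum(d, s - d).min()) > row_tol:
                continue
            overlap = min(e.last_frame, tr.t_end) - max(e.first_frame, tr.t_start) + 1
            if overlap < min_overlap_frac * span:
                continue
            candidates.append((overlap, e.event_id, j))
    candidates.sort(key=lambda c: -c[0])
    matched: dict[int, Trace | None] = {e.event_id: None for e in events}
    used: set[int] = set()
    for _, eid, j in candidates:
        if matched[eid] is not None or j in used:
            continue
        matched[eid] = traces[j]
        used.add(j)
    return matched


# ---------------------------------------------------------------------------
# scene builders


def _recovery_config(seed: int, daughter_rate: float = 0.1, mother_rate: float | None = None,
                     symmetric_lifetimes: bool = False, **kw) -> SimulationConfig:
    daughter = CompartmentParams(rate_per_um_min=daughter_rate, lifetime_mean_s=30.0,
                                 lifetime_cv=0.2, lifetime_family="gaussian", amplitude=60.0)
    if symmetric_lifetimes:
        mother = replace(daughter, rate_per_um_min=mother_rate if mother_rate is not None else daughter_rate)
    else:
        mother = CompartmentParams(rate_per_um_min=mother_rate if mother_rate is not None else 0.2,
                                   lifetime_mean_s=90.0, lifetime_cv=0.5,
                                   lifetime_family="lognormal", amplitude=60.0)
    return SimulationConfig(mother=mother, daughter=daughter, seed=seed, **kw)


def _analyze(result, params: AnalysisParams | None = None, channels=(1,)) -> ReportTable:
    """Run the blind pipeline on a simulation, consuming the truth label
    mask the way an external segmenter's mask would be consumed."""
    stacks = [result.stacks[c] for c in channels]
    return analyze_movie(stacks, mask=result.geometry.label_mask, params=params or AnalysisParams())


def _compartment_result(report: ReportTable, compartment: str, channel: str = "ch1"):
    for r in report.results:
        if r.compartment == compartment and r.channel_name == channel:
            return r
    raise LookupError(f"no result for {compartment}/{channel}")


# ---------------------------------------------------------------------------
# experiments


@dataclass
class LifetimeRecovery:
    mean_recovered_s: float
    cv_recovered_pct: float
    mean_truth_s: float
    cv_truth_pct: float
    n_events: int


def lifetime_recovery_experiment(seed: int, n_replicates: int = 140, rate: float = 0.1) -> LifetimeRecovery:
    """Recover daughter-cortex lifetime mean and CV from pooled movies.

    Daughter lifetimes are Gaussian (mean 30 s, CV 20%); replicate 180-s
    single-cell movies are pooled until >= 150 uncensored events. Censored
    traces are excluded from the moments, as in the default policy.
    """
    lifetimes, truth = [], []
    for i in range(n_replicates):
        cfg = _recovery_config(int(substream(seed, f"lifetime.{i}").integers(2**31)), daughter_rate=rate)
        result = simulate(cfg)
        report = _analyze(result)
        res = _compartment_result(report, "daughter")
        lifetimes.extend(tr.lifetime_s for tr in res.traces if not tr.censored)
        truth.extend(
            e.t_death_s - e.t_birth_s
            for e in result.events
            if e.compartment == "daughter" and e.channel == 1 and not e.censored_truth
        )
    lifetimes = np.asarray(lifetimes)
    truth = np.asarray(truth)
    return LifetimeRecovery(
        mean_recovered_s=float(lifetimes.mean()),
        cv_recovered_pct=100.0 * float(lifetimes.std(ddof=1) / lifetimes.mean()),
        mean_truth_s=float(truth.mean()),
        cv_truth_pct=100.0 * float(truth.std(ddof=1) / truth.mean()),
        n_events=len(lifetimes),
    )


@dataclass
class FrequencyRatioRecovery:
    ratio_configured: float
    ratio_recovered: float
    n_daughter_events: int
    n_mother_events: int


def frequency_ratio_experiment(seed: int, ratio: float, n_replicates: int | None = None,
                               daughter_rate: float = 0.15) -> FrequencyRatioRecovery:
    """Recover a configured daughter:mother initiation-rate ratio.

    Frequencies are pooled counts normalised per retained micrometre per
    minute, correcting for the different surface distance sampled in the
    two compartments. Lifetime laws are identical in both compartments so
    the only asymmetry is the rate. Larger lobes (38/20 px radii) keep the
    mother event count workable at high ratios.
    """
    if n_replicates is None:
        # the mother compartment is the count-limited side at high ratios;
        # scale replicates so its Poisson error stays well inside +/-20%
        n_replicates = max(100, int(np.ceil(175 * ratio / 7.0)))
    counts = {"mother": 0, "daughter": 0}
    exposure = {"mother": 0.0, "daughter": 0.0}  # um * min
    for i in range(n_replicates):
        cfg = _recovery_config(
            int(substream(seed, f"freq.{ratio}.{i}").integers(2**31)),
            daughter_rate=daughter_rate,
            mother_rate=daughter_rate / ratio,
            symmetric_lifetimes=True,
            mother_radius_px=38.0,
            daughter_radius_px=20.0,
        )
        report = _analyze(simulate(cfg))
        for comp in ("mother", "daughter"):
            res = _compartment_result(report, comp)
            counts[comp] += res.summary.n_events
            exposure[comp] += res.summary.retained_length_um * res.summary.duration_min
    freq = {c: counts[c] / exposure[c] for c in counts}
    return FrequencyRatioRecovery(
        ratio_configured=ratio,
        ratio_recovered=freq["daughter"] / freq["mother"],
        n_daughter_events=counts["daughter"],
        n_mother_events=counts["mother"],
    )


@dataclass
class CensoringScore:
    n_boundary_truth: int
    n_boundary_flagged: int
    n_interior_truth: int
    n_interior_false_flags: int

    @property
    def sensitivity(self) -> float:
        return self.n_boundary_flagged / self.n_boundary_truth if self.n_boundary_truth else float("nan")


def censoring_experiment(seed: int, n_replicates: int = 20) -> CensoringScore:
    """Score censoring flags against the simulator's boundary truth.

    Truth events visible for fewer frames than the detector's minimum
    trace length cannot be detected by construction and are not scored.
    Both compartments use the regular 30-s lifetime law: the temporal-median
    baseline is only valid while a row is event-free for most of the movie,
    which events far outliving the movie (mother-like 90-s tails) violate.
    Events are matched one-to-one to traces. Because a trace occasionally
    spans two overlapping truth events, flags are judged at the trace
    level: a matched boundary event's trace must carry the corresponding
    censored flag, and a trace matched to an interior event is a false
    flag only when *none* of the truth events it overlaps touches the
    movie boundary.
    """
    params = AnalysisParams()
    score = CensoringScore(0, 0, 0, 0)
    for i in range(n_replicates):
        cfg = _recovery_config(int(substream(seed, f"censor.{i}").integers(2**31)),
                              mother_rate=0.1, symmetric_lifetimes=True)
        result = simulate(cfg)
        report = _analyze(result)
        for comp in ("mother", "daughter"):
            res = _compartment_result(report, comp)
            events = [
                e
                for e in result.events
                if e.compartment == comp and e.channel == 1
                and e.n_visible_frames >= params.min_len_frames
            ]
            matched = match_events_to_traces(events, res.traces, res.contour, res.kymograph)
            s = res.kymograph.n_rows

            def overlapping_truth(tr: Trace) -> list[EventRecord]:
                out = []
                for e in events:
                    row = expected_row(res.contour, e.y_px, e.x_px)
                    d = np.abs(tr.rows - row)
                    if int(np.minimum(d, s - d).min()) > 4:
                        continue
                    if min(e.last_frame, tr.t_end) >= max(e.first_frame, tr.t_start):
                        out.append(e)
                return out

            for e in events:
                tr = matched[e.event_id]
                if tr is None:
                    continue
                if e.censored_truth:
                    score.n_boundary_truth += 1
                    ok = (not e.censored_start_truth or tr.censored_start) and (
                        not e.censored_end_truth or tr.censored_end
                    )
                    score.n_boundary_flagged += int(ok)
                else:
                    score.n_interior_truth += 1
                    if tr.censored and not any(x.censored_truth for x in overlapping_truth(tr)):
                        score.n_interior_false_flags += 1
    return score


@dataclass
class AlignmentScore:
    matched_fraction: float
    n_traces: int


def alignment_experiment(seed: int, independent: bool, n_replicates: int = 8,
                         row_tol: int = 1, frame_tol: int = 5) -> AlignmentScore:
    """Two-channel trace alignment on the mother cortex.

    With ``independent=False`` the second channel contains the same events
    delayed by 5 s, so nearly every channel-1 trace should align. With
    ``independent=True`` the two channels come from independently seeded
    movies on the same geometry, giving only chance-level alignment.
    """
    n_matched = n_total = 0
    for i in range(n_replicates):
        base_seed = int(substream(seed, f"align.{i}").integers(2**31))
        mother = CompartmentParams(rate_per_um_min=0.12, lifetime_mean_s=30.0, lifetime_cv=0.2,
                                   amplitude=60.0)
        daughter = CompartmentParams(rate_per_um_min=0.0, lifetime_mean_s=30.0, lifetime_cv=0.2)
        if independent:
            res_a = simulate(SimulationConfig(mother=mother, daughter=daughter, seed=base_seed))
            res_b = simulate(SimulationConfig(mother=mother, daughter=daughter, seed=base_seed + 1))
            rep_a, rep_b = _analyze(res_a), _analyze(res_b)
            ka = _compartment_result(rep_a, "mother").kymograph
            kb = _compartment_result(rep_b, "mother").kymograph
            tr_a = _compartment_result(rep_a, "mother").traces
            tr_b = _compartment_result(rep_b, "mother").traces
        else:
            cfg = SimulationConfig(mother=mother, daughter=daughter, seed=base_seed,
                                   channel_offset_s=(5.0, 5.0))
            result = simulate(cfg)
            report = _analyze(result, channels=(1, 2))
            ra = _compartment_result(report, "mother", "ch1")
            rb = _compartment_result(report, "mother", "ch2")
            ka, kb, tr_a, tr_b = ra.kymograph, rb.kymograph, ra.traces, rb.traces
        if not tr_a:
            continue
        flags, _ = align_traces(tr_a, tr_b, n_rows_total=ka.n_rows, row_tol=row_tol, frame_tol=frame_tol)
        n_matched += sum(flags)
        n_total += len(flags)
    return AlignmentScore(matched_fraction=n_matched / n_total, n_traces=n_total)


@dataclass
class PunctaClassifierScore:
    sensitivity_pct: float
    specificity_pct: float
    n_positive: int
    n_negative: int


def puncta_classifier_experiment(seed: int, n_cells: int = 100) -> PunctaClassifierScore:
    """Interior-puncta classifier sensitivity/specificity on simulated cells.

    Half of the cells carry 1-3 cytoplasmic puncta (spot SNR ~5.5 over the
    cytoplasmic background), the other half none; all have cortical events
    that must not be miscounted as cytoplasmic. The classifier sees the
    movie's maximum intensity projection and the cell mask only.
    """
    rng = substream(seed, "puncta.experiment")
    tp = fn = tn = fp = 0
    n_pos = n_cells // 2
    for i in range(n_cells):
        truth_positive = i < n_pos
        n_puncta = int(rng.integers(1, 4)) if truth_positive else 0
        cfg = _recovery_config(
            int(rng.integers(2**31)),
            daughter_rate=0.5,
            mother_rate=0.5,
            symmetric_lifetimes=True,
            duration_s=5.0,
            n_interior_puncta=n_puncta,
            puncta_amplitude=30.0,
        )
        result = simulate(cfg)
        mip = result.stacks[1].pixels.max(axis=0)
        call = detect_interior_puncta(mip, result.geometry.label_mask > 0, cortex_margin_px=8,
                                      spot_sigma_px=cfg.psf_sigma_px, cell_id=i)
        if truth_positive:
            tp += call.positive
            fn += not call.positive
        else:
            tn += not call.positive
            fp += call.positive
    return PunctaClassifierScore(
        sensitivity_pct=100.0 * tp / (tp + fn),
        specificity_pct=100.0 * tn / (tn + fp),
        n_positive=tp + fn,
        n_negative=tn + fp,
    )


@dataclass
class IntensityRatioRecovery:
    ratio_truth: float
    ratio_recovered: float
    per_cell: list[float]


def intensity_ratio_experiment(seed: int, n_cells: int = 12, amplitude_ratio: float = 2.0) -> IntensityRatioRecovery:
    """Recover a configured daughter/mother cortical amplitude ratio.

    Equal initiation rates and lifetime laws; only the event amplitude
    differs. The per-cell ratio uses the time-averaged movie with its
    temporal-median image subtracted (a background estimate immune to the
    noise-maximum bias of a MIP), band-averaged along each retained
    contour; the cohort mean over >= 10 polarized cells is reported.
    """
    from .puncta_coloc import cortical_intensity_ratio

    rng = substream(seed, "ratio.experiment")
    ratios = []
    for _ in range(n_cells):
        cfg = _recovery_config(int(rng.integers(2**31)), daughter_rate=3.0, mother_rate=3.0,
                               symmetric_lifetimes=True)
        cfg.daughter.amplitude = cfg.mother.amplitude * amplitude_ratio
        result = simulate(cfg)
        report = _analyze(result)
        pixels = result.stacks[1].pixels
        signal = pixels.mean(axis=0) - np.median(pixels, axis=0)
        ratios.append(
            cortical_intensity_ratio(
                signal,
                _compartment_result(report, "daughter").contour,
                _compartment_result(report, "mother").contour,
                width_px=5,
                background=0.0,
            )
        )
    return IntensityRatioRecovery(
        ratio_truth=amplitude_ratio,
        ratio_recovered=float(np.mean(ratios)),
        per_cell=ratios,
    )


@dataclass
class TwoStageScore:
    hit_rate_pct: float
    n_profiles: int


def synthetic_step_trace(low: float, high: float, n_low: int, n_high: int,
                         noise_sd: float, rng: np.random.Generator) -> Trace:
    """A bare trace with a step intensity profile (for change-point tests)."""
    profile = np.concatenate([np.full(n_low, low), np.full(n_high, high)])
    if noise_sd > 0:
        profile = profile + rng.normal(0.0, noise_sd, size=len(profile))
    return Trace(
        rows=np.array([0]),
        t_start=0,
        t_end=n_low + n_high - 1,
        frame_interval_s=1.0,
        censored_start=False,
        censored_end=False,
        intensity_profile=profile,
        peak=float(profile.max()),
    )


def two_stage_experiment(seed: int, n_profiles: int = 100, n_low: int = 35, n_high: int = 25,
                         step_snr: float = 3.0, tol_frames: int = 2) -> TwoStageScore:
    """Change-point recovery on noisy low-then-high step profiles."""
    rng = substream(seed, "twostage.experiment")
    hits = 0
    for _ in range(n_profiles):
        tr = synthetic_step_trace(1.0, 1.0 + step_snr, n_low, n_high, 1.0, rng)
        split = split_two_stage(tr, noise_scale=1.0)
        hits += abs(split.change_frame - n_low) <= tol_frames
    return TwoStageScore(hit_rate_pct=100.0 * hits / n_profiles, n_profiles=n_profiles)
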