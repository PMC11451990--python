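# cmekymo

Circumferential-kymograph analysis of clathrin-mediated endocytosis
(CME) in budded yeast, quantified **separately for the mother and the
daughter (bud) cortex**, plus a ground-truth fluorescence-movie
simulator for validating the whole pipeline.

## The problem

During polarized growth, the two compartments of a budded
*S. cerevisiae* cell behave differently: endocytic sites initiate far
more frequently on the daughter cortex, and early/mid-arriving coat
proteins (Ede1, Sla2, Syp1, Pan1...) live for a short, regular time on
the daughter (~30 s, CV ~20%) but much longer and more variably on the
mother. Measuring this requires per-compartment statistics from 2D
equatorial-plane movies: each CME event is an immobile diffraction-
limited cortical patch, so sampling intensity along the cell outline
over time — a *circumferential kymograph* — renders every event as a
vertical streak whose length is the protein's lifetime at that site.

`cmekymo` automates the workflow for people doing quantitative yeast
CME microscopy: blur → segment (or consume an external segmenter's
label mask) → pair mother/daughter lobes → extract sub-pixel contours →
exclude the crowded bud neck → build per-compartment kymographs →
detect traces → lifetime/frequency statistics, censoring, two-stage
(low-then-high abundance) splitting, two-colour trace alignment,
cytoplasmic-puncta classification and Pearson colocalization.

Key quantities, in the field's notation:

* lifetime of a trace spanning frames *t₀..t₁*: (t₁ − t₀ + 1)·Δt, with
  Δt the frame interval (default 1 s; pixel size default 65 nm);
* CV = 100·SD/mean of uncensored lifetimes; traces touching the first
  or last frame are censored (true lifetime underestimated);
* frequency = events·μm⁻¹·min⁻¹ of **retained** cortex arclength,
  correcting for the different surface distance sampled in the two
  compartments;
* Mann–Whitney *U* (exact for small untied samples) for comparisons;
* Pearson correlation over a cell mask for colocalization.

## Worked example

Simulate one budded cell (daughter: Gaussian lifetimes 30 s, CV 20%,
1 event/μm/min; mother: lognormal 90 s, CV 50%, 0.2 events/μm/min —
the ~5× initiation asymmetry) and analyse it blind:

```python
from cmekymo import SimulationConfig, simulate, analyze_movie
from cmekymo.trace_quant import compare_lifetimes

result = simulate(SimulationConfig(seed=7))
report = analyze_movie([result.stacks[1]], mask=result.geometry.label_mask)
print(report.summary_frame.round(3).to_string(index=False))
```

```
 cell_id compartment channel  n_events  n_censored  mean_lifetime_s  sd_lifetime_s  cv_percent  frequency_per_um_min  retained_length_um  duration_min
       1      mother     ch1         6           4           79.000          7.071       8.951                 0.186              10.724           3.0
       1    daughter     ch1        13           5           34.625         15.436      44.580                 0.953               4.547           3.0
```

Reading it: the daughter cortex hosted 13 events over 4.5 μm of
retained outline in 3 min (0.95 events·μm⁻¹·min⁻¹) versus 0.19 on the
mother — a ~5× initiation asymmetry, as configured. Four of six mother
traces are censored (their events outlast the 3-min movie), so the
mother mean of 79 s is a lower bound; per-compartment moments use only
uncensored traces. A Mann–Whitney test on the uncensored lifetimes
(`compare_lifetimes`) gives U = 16.0, p = 0.036.

The `cme-kymo` CLI exposes the same steps
(`simulate | segment | kymo | trace | compare | puncta | coloc | run`),
reading/writing TIFF movies with JSON calibration sidecars and
versioned CSV tables.

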