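# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `echotype`, and what the synthetic-data experiments
do and do not demonstrate.

## Detection model

The energy detector operates on band-pass-filtered (10–90 kHz),
calibrated audio. Instantaneous energy is smoothed with a 50 µs moving
average and converted to dB re 1 µPa via the calibration offset;
detection bounds are the first/last samples above the boundary
threshold (default 95 dB re 1 µPa). Two conventions are not dictated by
the method itself and were fixed here:

* **Filter realization.** A 5th-order Butterworth band-pass applied
  forward–backward (`sosfiltfilt`). Zero phase means detection times
  carry no group-delay bias and translation equivariance holds to within
  a sample; the doubled effective order gives > 40 dB of stopband
  rejection an octave below the low edge.
* **Merge rule.** Threshold crossings separated by < 100 µs are merged
  into one detection, so amplitude ripple within a single click does not
  split it.

Spectra are Hann-weighted over the snippet length and zero-padded to a
400-point DFT, i.e. 500 Hz per bin at 200 kHz. Snippets longer than 400
samples (rare for impulsive clicks) are truncated to 400 samples
centered on the Hilbert-envelope peak, because the DFT size is fixed by
the interface. QC retains clicks with peak frequency in 15–85 kHz,
received level > 120 dB_pp re 1 µPa and a high-energy envelope duration
(span where the Hilbert envelope exceeds half its maximum) below a
configurable maximum. The default maximum is **1 ms**: a microsecond-
scale bound would be smaller than the sampling interval permits for
real delphinid clicks, so the criterion is kept as a loose sanity bound
and exposed in `DetectorConfig` for instruments where a tight bound is
meaningful.

All thresholds presume a calibrated recording chain; the synthetic audio
generator therefore attaches an explicit calibration offset (140 dB re
1 µPa for unit digital amplitude) so the defaults are exercised at their
real scale.

## Similarity and pruning

Spectral similarity works on the first differences of min-max-normalized
spectra restricted to 10–70 kHz: *D = 1 − r* (Pearson correlation of
Δ*u_n*, Δ*v_n*), *S_SPEC = exp(−D)* ∈ [e⁻², 1]. Differencing plus
correlation makes the measure exactly invariant to affine transforms of
the dB spectrum — received level and gain drop out, only shape remains.
ICI similarity is *exp(−|Δ modal ICI|)* with ICIs in seconds, so
*S_ICI* ∈ [e⁻⁰·⁴⁹, 1]; no rescaling of either factor is applied before
the product *S₂ = S_ICI · S_SPEC* (transformation hooks would change the
relative influence of the two cues and are deliberately left to the
caller).

Pruning is a **dynamic percentile**: the weakest `p_e` fraction of each
network's edges is removed, with the retained count
`round((1 − p_e) · E)`. Two edge-counting conventions coexist: the
internal one (distinct unordered pairs, `n(n−1)/2`), which drives actual
pruning, and the self-inclusive-halved reporting convention (`n²/2`)
used for printed network sizes; `complete_edge_count` exposes both.
Degenerate pairs (zero-variance first differences, which have no defined
correlation) are discarded *before* the quota is computed — the quota
then describes the informative edges actually present. Ties at the cut
are resolved by a stable sort on (weight, node pair), which also makes
surviving edge sets nested across increasing `p_e`.

A consequence worth knowing: because the percentile is per network, a
subpopulation with systematically higher internal similarity can absorb
the entire quota of a small network. With the default `p_e` = 0.95 this
matters below a few hundred nodes or with fewer than ~4 types; the
method is meant to run at thousands of nodes per network.

## Clustering and consensus

Chinese Whispers starts every non-isolated node in its own cluster and,
in each iteration, visits nodes in a fresh random permutation; a node
adopts the label with the largest summed incident edge weight among its
neighbors (asynchronous updates, ties broken uniformly at random).
Convergence is a full pass without changes, capped at 20 iterations.
Summed-weight neighbor influence is the standard formulation and the
natural reading of "most strongly connected".

NMI between partitions is computed from the contingency table as
2 I(a;b)/(H(a)+H(b)) in natural logs (the base cancels). The 0/0 case —
both partitions a single all-node cluster — is defined as 1: two
trivial partitions agree perfectly. Best-of-K returns the candidate
with the highest mean pairwise NMI, ties to the lowest run index. In
Phase 2, clusters under 20 nodes are dropped from each run *before* the
NMI comparisons, and each pairwise NMI is computed on the intersection
of the two runs' labeled node sets (an empty intersection scores 0);
nodes in dropped clusters are treated as unlabeled rather than as a
catch-all cluster, which would otherwise dominate the statistic.

## Phase 1 / Phase 2 conventions

* Bins are clock-aligned 300 s windows per (site, deployment); bins with
  < 100 clicks are dropped and bins with > 5000 clicks are uniformly
  subsampled (seeded per bin, time order preserved).
* ICIs are first differences of the time-sorted clicks *within one
  cluster*, histogrammed on 0.01–0.5 s in 10 ms bins. The modal ICI is
  the argmax bin center (ties to the lower bin) unless the distribution
  is *saturated* — argmax within the lowest three bins and counts
  monotonically declining across them, the signature of interleaved
  trains from several animals — in which case the first strict local
  maximum is used, falling back to the argmax when none exists.
* Summary-node mean spectra are means of member dB spectra;
  normalization happens at comparison time (Phase 2, classification,
  reports), not at storage time.
* Encounters are maximal runs of detections with gaps < 15 min; a gap of
  exactly 15 min splits.
* Template labels (A, B, …) are assigned by descending modal ICI, then
  ascending mean peak frequency — a stable, human-readable ordering.
* Classification prunes the pooled test-to-training score set once per
  test node (one percentile computation across all templates); each
  template's score is the mean of its surviving edges, 0 if none
  survive. The per-template mean uses the survivors-only denominator.
  Confusion reports carry both evaluation conventions: the default
  counts Unknown–Unknown agreement as agreement (the convention behind
  the headline share of mismatches that are auto-typed/reference-
  Unknown), the strict option counts any Unknown as a mismatch.

## Synthetic data: what it emulates

`ClickTypeSpec` describes a type by a dB spectral template on the
10–70 kHz grid — a dominant lobe (Gaussian, or flat-topped
super-Gaussian for band-like types) plus secondary peaks and notches on
a tilted baseline, lobes combined by envelope maximum so the nominal
peak keeps the argmax — together with a modal ICI, jitter, and level
statistics. The seven-type preset uses peak frequencies of 27.1, 33.2,
21.7, 42.2, 32.3, 30.3 and 36.5 kHz with modal ICIs of 0.155, 0.125,
0.165, 0.035, 0.065, 0.065 and 0.035 s and the qualitative structure of
the dominant types observed in long-term Gulf of Mexico monitoring
(narrow multi-peaked spectra for the Risso's-like type, low-frequency
content, a broadband shallow-water type, and a near-degenerate pair
sharing a 0.065 s ICI that differs only in low-frequency structure).
Observed training prevalence (of 5,000 click-positive bins) is stored
alongside as preset metadata.

Variability is modeled at three levels, all seeded:

* **per click** — frequency-correlated spectral noise (2.5 dB,
  Gaussian-smoothed over a 4-bin scale: propagation and orientation
  perturb spectra smoothly in frequency, and white per-bin noise would
  destroy the first-difference correlation structure the method relies
  on), plus a level offset (σ 4 dB) and ICI jitter (CV 0.05, keeping the
  per-bin mode inside the planted 10 ms histogram bin);
* **per bin** — a 0.3 kHz wander of the whole peak structure, a smooth
  1.2 dB spectral perturbation shared by the bin's entire train
  (bin-scale propagation/noise conditions that do not average out
  within a bin), and a 5% scale wander of the ICI;
* **false positives** — snapping-shrimp-like transients: ~35 µs tone
  bursts centered near 93 kHz whose detections fail the 15–85 kHz peak
  criterion, and broadband rising-spectrum impostors at detection level.

The per-bin perturbation deserves emphasis: without it, types with
smooth templates reach within-type similarities near 1 while structured
types sit near 0.8, and the dynamic pruning quota concentrates on the
most coherent type, which fragments everything else. The balanced
defaults give all seven preset types within-type *S₂* of 0.86–0.93 —
the regime in which the method's published behavior (one cluster per
bin in the vast majority of bins; seven recoverable types) reproduces.

What passing the synthetic tests does **not** show: robustness to
unmodeled real-data effects — off-axis spectral distortion, clipping,
multipath, ship noise, overlapping multi-species aggregations beyond
two interleaved trains, and instrument-to-instrument calibration error.
The generator also emits clicks whose QC features are consistent by
construction, so QC pass rates on real data will be lower.

## Problem sizes

Test and acceptance runs use desk-scale versions of the study
conditions: 5 sites × 84 bins (12 per type), 150–400 clicks per bin
(~10⁵ clicks in total), giving ~420 summary nodes in the Phase 2
network; detector tests use 10–15 s of 200 kHz audio. These sizes keep
every similarity computation exact (no approximations are introduced at
scale) while the full seven-type discovery completes in seconds.

## Known limitations

* Chinese Whispers has no convergence guarantee on weighted graphs with
  ties; the 20-iteration cap matches the interface contract, and the
  Best-of-K consensus absorbs run-to-run variation.
* The per-network pruning percentile makes small, few-type networks
  winner-take-all (see above); classification certainty scores are
  comparable within a template set but not across sets trained with
  different `p_e`.
* Modal-ICI saturation detection is a heuristic trigger (lowest three
  bins, monotone decline); genuinely bimodal ICI distributions with a
  dominant low mode are treated as saturated.
* No click-train tracking: interleaved trains inflate low-ICI counts,
  which the modal statistic tolerates but the full histogram reflects.
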