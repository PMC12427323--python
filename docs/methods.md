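# Methods

This note documents the models, parameters and design choices behind
`rarecell`, in the order the pipeline runs them, and states what the synthetic
data do and do not establish about behavior on real scans.

## Synthetic slides

A slide is a grid of stage positions (default desk scale 6 × 6; production
scale 48 × 48 = 2304 positions), each imaged in four channels (D, CK, V, CD)
as 16-bit frames (default 512 × 512 px). Per channel, background is Gaussian
read noise (mean 300, sd 30 counts by default). Cells are isotropic 2-D
Gaussian intensity profiles with σ = radius/2, truncated at 3σ, with peak
amplitude drawn per positive channel (foreground mean 3000, sd 300). No
optical PSF, autofluorescence spectra, chromatic registration error or stain
chemistry is modelled; intensities are arbitrary counts.

Population structure mirrors a processed blood slide:

* **Common events** (exact count, default 2000 at desk scale) are
  leukocyte-like: D+/CD+, radius ~N(6, 1) px, placed uniformly with rejection
  resampling so no two cells overlap by more than ~50% (monolayer plating).
* **Rare cells** are drawn Poisson per phenotype from an expected-count map
  over all 8 channel types. They are rendered 1.8× larger and 2× brighter
  than common events. This is the deliberate realism choice of the generator:
  circulating tumor and endothelial cells are larger and more intensely
  stained than resting leukocytes, and size/brightness is the *only*
  morphometric handle separating a D|CD rare cell from the D|CD leukocyte
  bulk. With equal-size rendering that phenotype would be undetectable in
  principle.
* **Artifacts** fluoresce in every channel (broad-spectrum junk), while their
  ground-truth biological positivity is all-negative: bubbles are annular
  rings with radius 5–20× the mean cell radius; flares are saturated
  rectangles spanning ≥25% of the frame width. Flares overwrite underlying
  pixels, so a rare cell under a flare is genuinely unrecoverable — the
  simulator does not protect spiked cells from artifacts.

Fixed seed ⇒ bitwise-identical frames and truth tables. What passing tests on
these slides show: the chain recovers known spiked events through every
filtering stage under controlled noise. What they do not show: robustness to
focus drift, uneven illumination, debris diversity, staining batch effects,
or real biological morphology variation.

## Segmentation

Per frame, the DAPI channel is smoothed (Gaussian, σ = 1 px) and thresholded
at `max(Otsu, floor)`. Otsu runs in the log-intensity domain over unsaturated
pixels: in the linear domain, one saturated flare drags the threshold to a
flare-vs-background split and silently loses every ordinary nucleus on the
frame. A second guard re-runs Otsu below the first threshold when the
foreground class is implausibly tiny (<0.5% of pixels — a bright-artifact
split) and accepts the re-split if it finds a plausible nuclei class (≤5%).
The default floor is median + 5·1.4826·MAD of the smoothed frame, which keeps
pure-noise frames empty (plain Otsu on unimodal noise would binarize half the
frame). Touching nuclei are split by watershed from smoothed-intensity peaks
(min distance 5 px). Components outside [20 px, 10× median event area] are
dropped; the upper bound removes most bubble rims and flare fragments before
classification. Constant or >50%-saturated frames yield zero events plus a
logged warning. Coordinates are 0-based (row, col).

## Morphometric features (761)

The schema is a pure function of its parameters; defaults give exactly 761
features in four families:

| family | count | content |
|---|---|---|
| shape | 32 | nuclear mask: area, perimeter, eccentricity, axis lengths, orientation, solidity, extent, convexity, boundary-radius stats, Feret diameter, Euler number, 7 Hu moments; cellular mask: area, perimeter, eccentricity, solidity, form factor, nuclear/cellular area ratio |
| intensity | 4 ch × 2 compartments × 71 = 568 | 13 basic stats (mean, sd, MAD, min, max, total, energy, entropy, skewness, kurtosis, mass displacement, center shift, uniformity), 48 quantiles (0.02 … 0.96 step 0.02), 4 gradient/Laplacian texture stats, 6 radial-ring means |
| pair | 6 pairs × 2 × 13 = 156 | Pearson and Spearman correlation, covariance, cosine, mean ratio/difference, log total ratio, over-median Jaccard, two Manders-style overlap fractions, product mean, sum/difference sd |
| neighbor | 5 | nearest-neighbor distance, mean distance to 3 nearest, counts within 50/100 px, frame event count |

The *nuclear* compartment is the DAPI mask; the *cellular* compartment is its
3 px dilation (cytoplasmic markers extend beyond the nucleus). Degenerate
inputs follow fixed conventions so vectors are always finite: correlations of
constant signals are 0, entropy of a constant patch is 0, and the
no-neighbor sentinel distance is the frame diagonal. The count per family is
a tuning of this reconstruction; the schema module is its normative
definition, and `FeatureSchema.hash` pins it so trained models refuse tables
from a different schema.

## Outlier detection

Features are z-scored (heterogeneous units), zero-variance columns dropped
with a warning, and the table projected onto the top 350 principal components
(capped at min(F, n−1) with the cap reported). Candidates are the union of:

* **small clusters** — Ward linkage on Euclidean distance in PC space, tree
  cut at the 0.99 quantile of merge heights; clusters with ≤10 members;
* **large distance** — Euclidean distance from the *median cell*
  (component-wise median of PC coordinates, a synthetic reference point)
  above a 0.999 cutoff.

The distance cutoff is calibrated on the **bulk**, not the empirical
distance distribution: the threshold is `median(d) · χ_ppf(q, n_eff) /
χ_ppf(0.5, n_eff)`, where n_eff is the Satterthwaite effective degrees of
freedom computed from robust (MAD-based) per-component scales. On clean
Gaussian data this equals the plain empirical quantile (the candidate
fraction tracks 1 − q, which is property-tested), but it cannot be masked by
the outliers themselves: at desk scale spiked rares are ~1.5% of events, so
an empirical 99.9th percentile — which by construction flags at most 0.1% —
would hide moderate outliers such as oversized D|CD cells behind the extreme
CK/V ones. The plain empirical rule remains available as
`distance_calibration="empirical"`. For very large slides a per-frame-batch
clustering mode would be the natural extension; at desk scale a single global
clustering is used.

## Classification

**Interesting filter.** A histogram gradient-boosting classifier selected by
randomized search (default 50 sampled configurations; production-scale 1000
reachable by config) over a hyperparameter grid × four feature-group subsets
(shape only; intensity+pair; all; all+neighbor), scored by stratified k-fold
(default k = 5) cross-validated balanced accuracy; ties break toward the
smaller ensemble. Prediction is positive when confidence ≥ τ (closed lower
bound); the threshold sweep reports accuracy/precision/sensitivity/
specificity as percentages and per-slide mean false negatives ("rare events
missed") and false positives ("common predicted rare") at
τ ∈ {0.5, 0.6, 0.7, 0.8, 0.9}.

In the pipeline, training labels come from the training slide's ground truth:
positives are detected events matched to spiked rare cells (nearest centroid
on the same frame within 1.5× the true radius, min 5 px); negatives are
non-rare candidates (artifacts and swept-up commons) plus a seeded background
sample of ordinary events (default 200), mirroring analyst-rejected
candidates and guaranteeing both classes even when the area filter removes
most artifacts at segmentation.

**Channel trio.** Three independent random forests (200 trees) call CK, V,
and CD positivity; each consumes only the intensity and pair features
involving its channel. Binary calls at probability 0.5 map the 2³
combinations bijectively onto the 8 phenotypes; DAPI positivity is never
predicted — segmentation guarantees it. Multi-level expression calls were
considered and rejected in favor of binary calls, which the 8-type
stratification requires.

## Enumeration

`ml_analyzed = total nucleated events / WBC concentration`;
`cells/mL = count / ml_analyzed`, never rounded. The WBC concentration is an
input column per sample; absent that, the fallback estimator
`total events / nominal plated volume` (default 0.5 mL, i.e. a 7.5 mL draw
over ~14 slides) is used. Slides of one sample are pooled by summing events
and counts before normalizing — equivalent to the blood-volume-weighted mean
of per-slide rates — with per-slide values reportable alongside.

## Cohort statistics

Two-sided Mann–Whitney U per cohort pair × phenotype at α = 0.05. Exact null
distribution when both groups are ≤20 and untied; tie-corrected normal
approximation otherwise (identical duplicated cohorts give p = 1 through the
z = 0 path). No multiple-testing correction by default, matching plain
per-test reporting; Benjamini–Hochberg is available off by default. UMAP
(15 neighbors, min_dist 0.1, Euclidean, fixed seed, exact single-threaded
mode for determinism) embeds interesting events from six morphometrics:
cellular and nuclear area plus the four cellular mean channel intensities.
Box plots use log(count + ε) with ε = smallest nonzero count/10 so zero
counts remain visible.

## Pipeline scales and runtime choices

The `desk` preset — one labeled training slide and one spike-evaluation slide
at 6 × 6 × 512 px with 2000 common events each, plus four smaller cohort
samples (two per cohort, the minimum for a Mann–Whitney comparison) — is
sized so a full run completes in a few minutes on one CPU; `mini` is a
smoke-test scale; `full` sets the production geometry (2304 positions, ~3M
cells, 1000 search iterations) and is config-reachable only. Reruns under a
fixed config reproduce byte-identical tabular outputs; every written file
appears in exactly one manifest entry, and the manifest records the event
funnel (nucleated events → candidates → interesting → typed) per slide.

## Known limitations

* The 761-feature schema is a reconstruction in the spirit of
  EBImage-derived morphometrics; exact parity with any particular historical
  feature set is neither claimed nor verifiable.
* Artifact morphology (rings, saturated streaks) is a plausible stand-in; no
  quantitative artifact model was available.
* The spike-recovery figure is measured on synthetic slides whose rare cells
  are separable by construction; it validates the plumbing and the detection
  logic, not clinical sensitivity.
* Cohort comparisons at the desk scale use the minimum viable cohort sizes;
  their p-values exercise the code path, not statistical power (the power
  property is tested separately at realistic sample counts on count-level
  simulations).
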