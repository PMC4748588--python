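# Methods

This note documents the models, parameter defaults and numerical choices
behind `hcscreen`, and what the synthetic-plate tests do and do not show
about real data.

## Synthetic plates

The simulator is the package's test substrate: it generates field images
and a ground-truth cell table with exactly the statistical structure the
analysis assumes, so every downstream stage can be validated by parameter
recovery.  It is an idealisation, not a microscope model.

**Phenotypes and markers.** Each cell draws a class from the configured
proportions (defaults: K19+ 40.6 %, K14+ 25.2 %, DP 22.9 %, DN 11.3 % — a
representative mixed first-passage composition; FACS-sorted cultures are
emulated simply as altered proportions).  Marker intensity is log-normal:
negative cells and secondary-only control wells share one background
component (location ln 20 ≈ 3.0, scale 0.35 on the natural-log scale);
positive cells draw from a positive component (location 5.0, scale 0.40).
The defaults put the components ~5.3 pooled SDs apart, the regime where
the quadrant classifier's Bayes error is below 2 % — chosen to represent a
well-stained cytokeratin panel, in which the positive and negative modes
are separated by roughly an order of magnitude in intensity.  K14 is
rendered in Cy3, K19 in Cy5; FITC carries γH2AX (or EdU, or a third
marker, selectable).

**DNA content.** Integrated nuclear DAPI ("mass") follows a two-peak
model: a G1 peak at `g1_mass` (arbitrary units, default 20,000) and a
G2/M peak at `g2_ratio` × that (default 2.0), each t-distributed
(scale 5 % of location, df 12) *truncated* at ±`z_band` scales
(z_band = 2); S, sub-G1 and post-G2 cells fill uniform bands between and
beyond the peaks.  Truncation makes a cell's phase label and its
DNA-content band agree by construction: the label "G1" denotes membership
of the 2n band, which is the quantity a band-cut phase caller can in
principle recover.  Without truncation the mapping from label to band is
ambiguous for tail cells and no caller could match the truth table to
better than the tail mass (~4 points of G1 at df 12), which would say
nothing about the caller itself.

**γH2AX kinetics.** Mean specific signal is
`baseline + amp_per_gy · dose · shape(t)` with per-archetype shape
profiles over {0, 1, 2, 6, 24, 48} h: *resolver* peaks at 1 h and decays
to 4 % of peak induction by 48 h; *non-resolver* retains ≥ 80 % of the
1-h induction through 24–48 h.  Cells multiply the mean by log-normal
noise (σ = 0.3, mean-one).  Secondary-only wells show only the
secondary-antibody background, which is also added to experimental cells
so row-wise control subtraction has something real to remove.

**Growth.** Expected counts are exponential,
`n(t) = n₀ · 2^(t·inh(dose)/DT_class)`, with per-class doubling times
(DP 24 h < K19+ 28 h < K14+ 30 h < DN 60 h, encoding the observation that
double-positive cells cycle fastest and double-negative cells are
quiescent-like) and a dose-dependent multiplicative inhibition of the
slope (1.0 / 0.8 / 0.6 / 0.3 at 0 / 1 / 2 / 5 Gy).

**Rendering.** Nuclei are anti-aliased filled ellipses (area ~N(110, 20²)
µm² clipped, eccentricity uniform on [0, 0.6] so true circularity stays
above 0.97) placed by dart throwing with a clearance of 5 px beyond
touching so "non-overlapping" nuclei remain resolvable after the σ = 1 px
Gaussian blur; Gaussian read noise (σ = 2) is added last.  DAPI is
rendered so integrated intensity equals the drawn mass; markers as mean
intensity; γH2AX/EdU as integrated totals.  Each well uses a private
random stream derived from (master seed, plate, well), so outputs are
byte-identical per seed regardless of generation order.

**What the simulator does not model:** optical PSF beyond a token blur,
uneven illumination, staining gradients within wells, cell clumping and
debris, mitotic figures, segmentation-hostile morphologies, or any
correlation between phenotype and nuclear shape.  Passing recovery tests
therefore demonstrates correctness of the analysis chain under its own
assumptions, not robustness to real-world imaging artefacts.

## Segmentation

Auto thresholding is Otsu computed on the log-compressed
(min-shifted `log1p`) histogram: nuclear intensities span a wide dynamic
range (2n–4n content × variable staining) and linear-domain Otsu drifts
into the foreground class, dropping dim sub-G1 nuclei.  A robust floor of
median + 6 MAD-σ guards the degenerate case of nearly empty fields, where
any histogram split lands inside the read noise.  Both choices keep the
binary mask exactly invariant to additive constant backgrounds.  Linear
Otsu (`"otsu-linear"`) and fixed numeric thresholds remain available.

Watershed seeds are local maxima of the Euclidean distance transform
(lightly smoothed, σ = 1 px, to remove quantisation plateau ties that
oversplit elongated nuclei) with minimum separation
`0.7·√(min_area)/pixel_size`.  The sieve (default 30–350 µm²) and the
circularity filter (default > 0.8) run after watershed splitting; failing
objects are dropped, not re-split.  Perimeter is measured as the
marching-squares contour length of the lightly smoothed object mask —
raw border-pixel counts bias the form factor of a rasterized circle down
to ~0.86, while the smoothed contour tracks true boundary length within
~2 % (circularity is capped at 1.0 to absorb the residual rasterization
undershoot on small objects).  Defaults: pixel size 0.65 µm/px;
coordinates are 0-based, pixel-centre.

## Phenotype gating

Mixtures are fitted per technical-replicate row, never pooled across
plates — staining and acquisition vary enough between rows that a single
plate-wide threshold misclassifies.  The EM uses deterministic quantile
initialisation, tolerance 1e-8, ≤ 500 iterations, and a variance floor of
1e-3 × sample SD; k = 2 components by default, with BIC selection up to 4
(`k="bic"`) for skewed null populations.

The threshold anchor: the control's kernel density (512-point grid over
its data range ± 3 bandwidths) defines x₀ as the control *mode* — past
it the control population only decays toward zero — and τ is the first
point beyond x₀ where the locally dominant weighted component changes,
refined by root finding; ties are broken by smallest x.  An earlier
formulation anchored x₀ where the control density falls to 10⁻³ of its
maximum, but that point lies ~3.7 control SDs above the null mean —
*above* the two-component crossing whenever the populations are less than
~5 SDs apart — so it degenerates to the fallback exactly in the regime
the method is meant to handle; the mode anchor keeps τ equal to the
density intersection there.  Crossings between heavily overlapping
components (means closer than 1.5 × the larger SD) are ignored as
artefacts of fitting two components to unimodal data.  When no valid
crossing exists beyond x₀ (positive population absent), τ falls back to
the control's 99.9th percentile and all cells are negative.  Zero or
negative intensities are replaced by half the smallest positive observed
value before logging so every cell stays classifiable.

Per-well class percentages sum to 100 exactly; group summaries are the
mean ± SEM (sd/√n) over technical-replicate wells, with SEM reported
missing at n = 1.  Overlap tables for ≥ 3 markers report all 2ⁿ disjoint
regions plus per-marker marginals and the total.

## Cell cycle

The two-peak t-mixture EM has three stabilizers, all addressing the same
failure mode (the G2 component drifting off its peak to swallow the
S-phase plateau): a uniform background component over the data range with
estimated weight; a cap on each peak's coefficient of variation (9 % —
DNA histograms of usable quality have peak CVs well under this); and
projection of the second location into 1.6–2.4 × the first (the 2n/4n
prior, identical to the accepted-fit invariant).  The common df is chosen
from the grid {3, 5, 8, 12, 20, 30} by likelihood — a grid rather than
continuous optimisation for stability on small wells (≥ 200 cells
required).  Initialisation is deterministic: dominant histogram mode and
twice it.

Cut-points default to `µ ± z·s` with z = 2.0 (a single z for all four
cuts); an alternative `cutpoint_method="crossing"` places the G1/S and
S/G2 cuts at the weighted-density intersection instead.  If the inner
cut-points cross, both collapse to the peak midpoint and the fit is
flagged.  Fits with a second-component weight < 0.05 or peaks closer than
2 scales are flagged `unimodal`; location ratios outside [1.6, 2.4] are
flagged rather than silently accepted.  Phase assignment uses half-open,
lower-inclusive intervals (a mass exactly at the G1/S cut is S).

## γH2AX normalization

Row normalization subtracts the *mean* of the control well's per-cell
totals (the obvious summary; medians differ negligibly for the log-normal
noise used).  The plate/column model is Huber M-estimation (tuning 1.345,
the conventional 95 %-efficiency constant) on time-zero values with
sum-to-zero factor coding; the interaction term enters only when every
plate × column cell at time zero holds ≥ 2 wells.  Estimated effects are
subtracted from all wells on all plates; because the correction is a
per-well constant, within-well cell ordering is preserved.  Both the
row-normalized and the plate-adjusted values are emitted.

## Growth and inference

`fit_growth` is OLS on log2 counts; zero counts are excluded with a
warning (they carry no log information) and ≥ 3 usable points are
required.  The primary doubling time is `1/b` hours, because the literal
convention `2^b` is dimensionless; both are reported.

The split-plot test: with one plate per treatment the treatment main
effect is fully confounded with plate and has no valid error term, so
only the time × plate interaction — time continuous, tested against the
within-plate well residual — is reported.  That interaction is precisely
the hypothesis that subpopulation trajectories are equivalent across
treatments.  Implementation is a nested-model F test (full vs
no-interaction OLS); its type-I error calibrates to 0.05 in simulation.
No multiple-testing correction is applied by default to the per-donor
ANOVAs; a Holm adjustment helper is provided.

## Problem sizes used in validation

Recovery experiments use the full study geometry — 5 replicate wells of
~2,000 cells plus a control well, 25 fields per well in a 5 × 5 grid of
512-px fields at 0.65 µm/px — which the package processes in well under
a minute per well.  Distributional checks (mixture recovery, threshold
oracle agreement, cell-cycle and split-plot calibration) run at
3,000–10,000 cells or 100–1,000 replicates, sizes at which binomial and
Monte-Carlo error are comfortably below the tolerances being asserted.

## Known limitations

Nuclear-only measurements; no 3-D, tracking, or focus/exposure modelling;
the cell-cycle model assumes exactly one 2n and one 4n peak (no higher
ploidy); γH2AX is total nuclear intensity, not focus counts; and the
split-plot design requires ≥ 2 wells per plate-time and ≥ 2 plates to be
estimable.
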