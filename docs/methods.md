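# Methods

## Geometry and coordinate conventions

The invasive front is an oriented polyline in image coordinates (μm,
origin top-left, y downward) with a flag for which side of the travel
direction holds the tumor. An analysis rectangle is placed by arc
position along the polyline: the anchor is the interpolated point, the
local tangent is the containing segment's direction (at shared vertices,
the bisector of the adjacent directions, which keeps normals stable on
polylines), and the normal is the tangent rotated ±90° toward the tumor
side. Scripting the placement by arc position makes runs reproducible
where an interactive viewer placement would not be.

The local frame puts the front at v = L/2, tumor at v > L/2; curves are
reported over v ∈ [0, L] with the host region on [0, 2 mm] and the tumor
on [2, 4] mm, and peak locations as front-relative offsets v − L/2
(negative = host side). A curved front is represented by the single
tangent at the anchor — the rectangle itself is straight; no curvilinear
unwarping is attempted, so strongly curved fronts should be covered with
several shorter rectangles instead.

Defaults: W = 1000 μm, L = 4000 μm, Δ = 5 μm (Δ must divide L). The
rectangle's 4 mm² is ≈ 14.1 times the area of a 0.6 mm TMA core, which
is the point of the method: a large, front-crossing sample instead of a
small core.

## Detection

A pixel is candidate-positive when B < `blue_intensity` (default 160),
R > `red_intensity` (default 100) and R > B — a plain RGB proxy that
separates DAB brown from hematoxylin blue and from unstained background.
Touching cells are split by a watershed on the negated Euclidean distance
transform with markers at distance-transform maxima no closer than 4 μm;
every connected component is guaranteed at least one marker, so splitting
can only refine, never lose, objects. The marker separation is the
control against over-splitting of densely packed lymphocytes. Objects
are kept when their area lies in [`size_min`, `size_max`] = [15, 150] μm²
by default (equivalent diameter ≈ 4.4–13.8 μm, lymphocyte scale); an
object straddling the rectangle edge is kept iff its centroid is inside
(an unbiased counting rule). All three thresholds and the size bounds are
config-overridable; the defaults are declared choices of this package,
tuned to nothing beyond the lymphocyte scale they encode. Detection is
deterministic: identical image and parameters give byte-identical
detection lists.

## Profiles

Counts per Δ-bin (half-open bins, closed final edge, so totals are
conserved exactly) are standardized by 1000/W to cells per 5000 μm².
Mean curves over several rectangles are per-bin arithmetic means; merging
commutes with standardization at equal W. Smoothing is a centered moving
average with edge truncation (window shrinks at the boundaries, so
constant curves are preserved exactly); the default window of 21 bins
(105 μm) sits below the 200–400 μm structure scale of margin peaks and
above per-bin Poisson noise. Window 1 is the identity.

Peak statistics take the argmax of the smoothed curve over a margin
window of [1400, 2400] μm (600 μm outside to 400 μm inside the front,
containing the few-hundred-μm band where margin peaks occur). On an
argmax plateau the middle bin is reported — for an even plateau, the
member nearer the front — which is the stable choice for smoothed
impulses; an entirely flat window sets a `degenerate` flag. Max/min
heterogeneity ratios are computed on the smoothed curve over a stated
window with the denominator floored at 0.2 cells/5000 μm² so empty bins
cannot produce infinite ratios; the default windows are the tumor half
[2000, 4000] μm, the far-outside band [0, 500] μm and the deep-tumor
band near v = 4000 μm.

## Pattern classification

The cascade on the smoothed curve s, with m_in the mean over the tumor
core window [2500, 4000] μm, m_out the mean over the peritumoral window
[0, 1500] μm, and baseline the mean of s outside the margin window:

* **R1** (pattern 1): m_in ≥ τ and m_in ≥ ρ · max(m_out, baseline);
* **R2** (pattern 2): margin peak height ≥ τ and ≥ π · baseline;
* **R3** (pattern 3): otherwise.

Defaults τ = 3.0 cells/5000 μm² (the smallest margin-peak height
observed to constitute a significant peak), ρ = 1.5, π = 2.0. The
cascade is total and deterministic; R1 precedence resolves curves that
are both high inside and peaked at the margin. ρ and π were chosen so
that the three archetype shapes separate cleanly with comfortable noise
margins; they are exposed in the config, and "high peak" versus "low
peak" sub-variants of pattern 2 are reported through the peak height
rather than as separate classes.

## Cohort statistics

Percentages are rounded to the nearest integer, half away from zero
(published tables and prose occasionally disagree at exactly this
boundary; the rule here is fixed and documented). Cohen's κ is computed
from the standard formula with chance agreement from marginal products;
the degenerate case of both raters constant on the same category is
defined as κ = 1. Agreement among three or more raters is pooled as the
mean pairwise κ. Survival analysis is deliberately out of scope — it is
standard-library territory (lifelines/R survival), not bespoke
computation; the cohort table simply tolerates extra columns for
downstream use.

## Synthetic data: what it emulates, and what not

The generator draws cell positions from an inhomogeneous Poisson point
process whose axis intensity λ(v) (cells per 5000 μm²) encodes the three
archetypes: a step λ_out→λ_in at the front (pattern 1), a baseline plus
an asymmetric Gaussian bump (pattern 2), or a flat low level (pattern 3).
The bump is centered `peak_mu` = −400 μm from the front with outer width
σ_out = 200 μm and inner width σ_in = 100 μm, encoding the asymmetry of
margin peaks — a gradual build-up a few hundred μm ahead of the front and
a decline within ~200 μm beyond it; peak height defaults to 6.7
cells/5000 μm², the mean of the reported range [3, 14].

Density calibration: reported mean in-tumor CD3+ densities by pattern are
922, 581 and 392 cells/mm²; the unit conversion to per-5000 μm² is
×0.005. The 922 anchor sets the pattern-1 intratumoral default (4.61)
and 392 sets the pattern-3 default (1.96). For pattern 2 the in-tumor
core density of strongly heterogeneous tumors is not an estimate of the
flat flank baseline of the archetype curve, and a baseline of 2.91 would
make the smallest reported peaks (height 3) non-prominent by
construction; the default baseline is therefore 1.5 cells/5000 μm²,
which keeps the whole reported height range prominent over its flanks.
Cohort simulation draws per-patient parameters uniformly from ranges
centered on these anchors (pattern-1 λ_in ∈ [3.8, 5.5], λ_out ∈
[0.2, 0.5]; pattern-2 baseline ∈ [1, 2], height ∈ [3, 14], center ∈
[−500, −300] μm; pattern-3 λ ∈ [0.5, 2.5]) and mixes patterns at the
reported prevalences 21/61/18 %.

Profiles are independent Poisson per bin; no within-tumor spatial
correlation beyond the mean curve is simulated, because no published
correlation structure is available to calibrate one. Slides are rendered
simply — uniform brown discs of radius 3.5 μm with per-cell color jitter,
scattered stain-negative blue nuclei, pixel noise — at 1 μm/px. That is
sufficient to exercise thresholding, watershed splitting and size
filtering, but it does *not* imitate real histology: no chromatin
texture, stain gradients, tissue folds, necrosis or out-of-focus blur.
Passing the round-trip tests therefore demonstrates the correctness of
the pipeline's logic and its behavior under Poisson spatial statistics,
not its robustness to real-world staining variation; on real slides the
three intensity thresholds should be checked visually, as the tunable
parameters are exposed for exactly that purpose.

TMA emulation samples three 0.6 mm-diameter circular cores placed
uniformly in the tumor half of the rectangle and reports the mean core
density in cells/mm². On identical pattern-2 point processes, single-core
densities are several-fold more variable than whole-rectangle densities —
the sampling-area argument that motivates the curve-based method — and
this is asserted by test rather than assumed.

## Numerical choices and degenerate inputs

* Bins are half-open with a closed final edge; a detection at exactly
  v = L makes it into the last bin, so count conservation is exact.
* ROI containment uses closed boundaries with a 1e-9 μm tolerance.
* Profile CSVs store floats with `repr`, so read/write round-trips are
  bit-exact; malformed rows raise errors naming the line.
* Zero-density inputs propagate cleanly: empty masks give zero labels,
  empty detection lists give all-zero profiles, which classify as
  pattern 3 with a degenerate peak flag.
* All randomness flows through `numpy.random.Generator`; every simulation
  accepts a seed or a shared generator, and same-seed runs are identical.

## Problem sizes in the checks

The self-checks run at the method's native scale: full 1 × 4 mm slides at
1 μm/px (≈ 4.3 Mpx) for detection round-trips (100 slides), 100
pattern-2 simulations for peak recovery, 100 curves per class for
classifier recall, n = 10⁴ for the independent-rater κ check and 200
replicates for the core-versus-rectangle variance comparison. These sizes
give sampling errors comfortably below the asserted tolerances.

## Known limitations

* The front must be annotated by a human; automatic front detection from
  pixels is out of scope, as is reading proprietary whole-slide formats
  (standard TIFF/PNG rasters are accepted instead).
* The RGB thresholding rule is a proxy for proper stain unmixing; heavily
  counterstained brown cells can fall below the red threshold. A
  color-deconvolution mode would be the natural extension.
* The classifier thresholds are fixed, interpretable constants, not
  learned from outcomes — deliberately so, since outcome-optimized
  cutoffs do not transfer between patient series.
* Rectangle placement spacing along the front (2–8 rectangles per tumor)
  is left to the user; no automatic spacing rule is imposed.
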